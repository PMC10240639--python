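"""Access to packaged defaults files."""

from importlib import resources


def default_path(name: str):
    """Filesystem path of a packaged defaults file."""
    return resources.files("pfjforce").joinpath("defaults", name)
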