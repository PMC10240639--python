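"""Patellofemoral joint contact force from quadriceps force and knee flexion.

The contact force is the resultant of the quadriceps-tendon and
patellar-tendon force vectors acting on the patella:

    F_pfj = sqrt(F_q^2 + F_p^2 + 2 F_q F_p cos(beta))

with F_p = k(theta) * F_q.  Both the force ratio k(theta) and the mechanism
angle beta(theta) are configurable polynomials of knee flexion angle,
shipped as a versioned defaults file, because the original in vitro
coefficients are not available in machine-readable form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import AlignmentError, InputError


@dataclass(frozen=True)
class PatellarMechanism:
    """Polynomials k(theta) and beta(theta) with a clamped validity range."""

    k_coeffs: tuple[float, ...]          # ascending powers, theta in degrees
    beta_coeffs: tuple[float, ...]       # ascending powers, degrees out
    valid_range: tuple[float, float] = (0.0, 120.0)
    version: int = 0
    provenance: str = ""

    def __post_init__(self):
        lo, hi = self.valid_range
        if not hi > lo:
            raise InputError("patellar mechanism: empty valid range")
        grid = np.linspace(lo, hi, 241)
        if np.any(self._k(grid) <= 0):
            raise InputError("patellar mechanism: k(theta) must be > 0 over the valid range")
        beta = self._beta(grid)
        if np.any(beta <= 0) or np.any(beta >= 180):
            raise InputError("patellar mechanism: beta(theta) must lie in (0, 180) deg")

    @classmethod
    def from_yaml(cls, path=None) -> "PatellarMechanism":
        from .resources import default_path
        path = default_path("patellar_mechanism.yaml") if path is None else path
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            k_coeffs=tuple(float(c) for c in raw["k_coeffs"]),
            beta_coeffs=tuple(float(c) for c in raw["beta_coeffs"]),
            valid_range=tuple(float(v) for v in raw["valid_range_deg"]),
            version=int(raw.get("version", 0)),
            provenance=str(raw.get("provenance", "")).strip(),
        )

    def _k(self, theta):
        return np.polynomial.polynomial.polyval(theta, self.k_coeffs)

    def _beta(self, theta):
        return np.polynomial.polynomial.polyval(theta, self.beta_coeffs)

    def clamp(self, theta):
        """Clamp theta to the valid range; returns (theta_clamped, clamped_mask)."""
        theta = np.asarray(theta, dtype=float)
        lo, hi = self.valid_range
        clamped = (theta < lo) | (theta > hi)
        return np.clip(theta, lo, hi), clamped

    def force_ratio(self, theta):
        """k(theta) with clamping; returns (k, clamped_mask)."""
        t, clamped = self.clamp(theta)
        return self._k(t), clamped

    def mechanism_angle(self, theta):
        """beta(theta) in degrees with clamping; returns (beta, clamped_mask)."""
        t, clamped = self.clamp(theta)
        return self._beta(t), clamped


@dataclass
class PFJForceSeries:
    """Per-sample patellofemoral force decomposition, in body weights."""

    time: np.ndarray
    f_q: np.ndarray       # quadriceps force, BW
    f_p: np.ndarray       # patellar tendon force, BW
    beta: np.ndarray      # mechanism angle, deg
    f_pfj: np.ndarray     # contact force, BW
    clamped: np.ndarray   # bool per sample
    mechanism_version: int = 0
    meta: dict = field(default_factory=dict)


def patellar_tendon_force(f_q, theta, mech: PatellarMechanism):
    """Patellar tendon force F_p = k(theta) * F_q (same units as ``f_q``).

    Returns ``(f_p, clamped_mask)``; theta outside the mechanism's valid
    range is clamped and flagged.
    """
    f_q = np.asarray(f_q, dtype=float)
    if np.any(f_q < 0):
        raise InputError("quadriceps force must be >= 0")
    k, clamped = mech.force_ratio(theta)
    return k * f_q, clamped


def pfj_contact_force(f_q, f_p, beta):
    """Law-of-cosines resultant of the two tendon forces.

    ``beta`` is in degrees and must lie in [0, 180]; no wrapping is applied.
    """
    f_q = np.asarray(f_q, dtype=float)
    f_p = np.asarray(f_p, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(f_q < 0) or np.any(f_p < 0):
        raise InputError("tendon forces must be >= 0")
    if np.any(beta < 0) or np.any(beta > 180):
        raise InputError("beta must lie in [0, 180] degrees")
    sq = f_q**2 + f_p**2 + 2.0 * f_q * f_p * np.cos(np.radians(beta))
    # roundoff can push the antiparallel case fractionally below zero
    return np.sqrt(np.maximum(sq, 0.0))


def pfj_series(f_q_bw, kin, mech: PatellarMechanism) -> PFJForceSeries:
    """Apply the mechanism sample-by-sample along a trial.

    ``f_q_bw`` is the quadriceps force in BW on the same time base as the
    knee flexion angle in ``kin`` (a :class:`~pfjforce.kinematics.JointKinematics`).
    """
    f_q = np.asarray(f_q_bw, dtype=float)
    theta = np.asarray(kin.angles["knee"], dtype=float)
    if f_q.shape != theta.shape or f_q.size == 0:
        raise AlignmentError(
            f"quadriceps series (n={f_q.size}) does not align with kinematics (n={theta.size})")
    f_p, clamped = patellar_tendon_force(f_q, theta, mech)
    beta, _ = mech.mechanism_angle(theta)
    return PFJForceSeries(
        time=np.asarray(kin.time, dtype=float),
        f_q=f_q,
        f_p=f_p,
        beta=beta,
        f_pfj=pfj_contact_force(f_q, f_p, beta),
        clamped=clamped,
        mechanism_version=mech.version,
    )
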