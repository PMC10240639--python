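"""Static optimization: decompose net joint moments into muscle forces.

Per sample, solves the convex quadratic program

    min  sum_i a_i^2
    s.t. sum_i a_i * f_max_i * r_ij(theta_j) = M_j   for each joint j
         0 <= a_i <= 1

with a deterministic active-set method warm-started across frames.  Frames
whose moment demand exceeds the muscle set's capacity are flagged and carry
the bound-constrained least-residual solution instead of aborting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .errors import InputError, ModelError

JOINTS = ("hip", "knee", "ankle")


@dataclass(frozen=True)
class MuscleSpec:
    """One lumped muscle: strength and moment-arm polynomials per joint.

    ``arms`` maps joint name -> polynomial coefficients (metres, ascending
    powers of the joint angle in degrees) with package moment sign
    conventions, so extensors of the knee have positive knee coefficients.
    """

    name: str
    f_max: float
    arms: dict[str, tuple[float, ...]]
    group: str = ""
    is_quadriceps: bool = False

    def __post_init__(self):
        if self.f_max <= 0:
            raise ModelError(f"muscle {self.name!r}: f_max must be > 0")
        for joint, coeffs in self.arms.items():
            grid = np.linspace(-10.0, 130.0, 57)
            if np.max(np.abs(np.polynomial.polynomial.polyval(grid, coeffs))) > 0.12:
                raise ModelError(
                    f"muscle {self.name!r}: |moment arm| exceeds 0.12 m at {joint}")

    def moment_arm(self, joint: str, theta):
        """Moment arm (m) about ``joint`` at angle ``theta`` (deg)."""
        if joint not in self.arms:
            return np.zeros_like(np.asarray(theta, dtype=float))
        return np.polynomial.polynomial.polyval(np.asarray(theta, dtype=float),
                                                self.arms[joint])


@dataclass
class MuscleSolution:
    """Activations, forces and diagnostics for a static-optimization run."""

    time: np.ndarray
    muscle_names: list[str]
    activations: np.ndarray        # (n, m) in [0, 1]
    forces: np.ndarray             # (n, m) N; a_i * f_max_i
    objective: np.ndarray          # (n,) sum of squared activations
    residuals: np.ndarray          # (n, 3) N m per joint
    infeasible: np.ndarray         # (n,) bool
    quadriceps_mask: np.ndarray    # (m,) bool

    @property
    def quadriceps_force_n(self) -> np.ndarray:
        """Summed quadriceps force in newtons per sample."""
        return self.forces[:, self.quadriceps_mask].sum(axis=1)


def _min_norm_box_qp(R, m_target, warm_active=None, tol=1e-10, max_iter=200):
    """min ||a||^2 s.t. R a = m, 0 <= a <= 1, by primal active set.

    Returns (a, active_state, feasible) where active_state is an int8 array
    (-1 lower bound, 0 free, +1 upper bound).
    """
    k, m = R.shape
    state = np.zeros(m, dtype=np.int8) if warm_active is None else warm_active.copy()

    for _ in range(max_iter):
        free = state == 0
        a = np.where(state > 0, 1.0, 0.0)
        rhs = m_target - R[:, state > 0].sum(axis=1)
        if free.any():
            G = R[:, free]
            gram = G @ G.T
            nu = np.linalg.lstsq(gram, 2.0 * rhs, rcond=None)[0]
            a_free = 0.5 * (G.T @ nu)
            a[free] = a_free
        else:
            nu = np.linalg.lstsq(R @ R.T, 2.0 * rhs, rcond=None)[0]

        # primal violations among free variables: clamp the worst
        lo_viol = np.where(free, -a, 0.0)
        hi_viol = np.where(free, a - 1.0, 0.0)
        worst_lo, worst_hi = lo_viol.max(initial=0.0), hi_viol.max(initial=0.0)
        if max(worst_lo, worst_hi) > tol:
            if worst_lo >= worst_hi:
                state[int(np.argmax(lo_viol))] = -1
            else:
                state[int(np.argmax(hi_viol))] = 1
            continue

        # dual feasibility of active bounds: release the worst violator
        grad = R.T @ nu  # = 2 a_i at an unconstrained optimum
        release_lo = np.where(state == -1, grad, -np.inf)   # want grad <= 0
        release_hi = np.where(state == 1, 2.0 - grad, -np.inf)  # want grad >= 2
        worst_rl, worst_rh = release_lo.max(initial=-np.inf), release_hi.max(initial=-np.inf)
        if max(worst_rl, worst_rh) > tol:
            if worst_rl >= worst_rh:
                state[int(np.argmax(release_lo))] = 0
            else:
                state[int(np.argmax(release_hi))] = 0
            continue

        a = np.clip(a, 0.0, 1.0)
        feasible = np.max(np.abs(R @ a - m_target)) < 1e-6
        return a, state, feasible

    a = np.clip(a, 0.0, 1.0)
    return a, state, bool(np.max(np.abs(R @ a - m_target)) < 1e-6)


def static_optimization(moments, kin, model) -> MuscleSolution:
    """Frame-by-frame muscle force decomposition of net joint moments."""
    muscles = model.muscles
    if not muscles:
        raise ModelError("empty muscle set")
    for joint in JOINTS:
        if not any(m.arms.get(joint, None) and
                   np.polynomial.polynomial.polyval(45.0, m.arms[joint]) > 0
                   for m in muscles):
            raise ModelError(f"no muscle produces positive moment at {joint}")

    t = np.asarray(kin.time, dtype=float)
    M = moments.stacked()
    if M.shape[0] != t.size:
        raise InputError("moments and kinematics are not aligned")
    n, m = t.size, len(muscles)
    theta = {j: kin.angles[j] for j in JOINTS}
    fmax = np.array([mu.f_max for mu in muscles])

    # R[i, j, k]: frame i, joint j, muscle k (already scaled by f_max)
    R = np.zeros((n, 3, m))
    for k, mu in enumerate(muscles):
        for j, joint in enumerate(JOINTS):
            if joint in mu.arms:
                R[:, j, k] = mu.f_max * mu.moment_arm(joint, theta[joint])

    activations = np.zeros((n, m))
    objective = np.zeros(n)
    residuals = np.zeros((n, 3))
    infeasible = np.zeros(n, dtype=bool)
    warm = None
    for i in range(n):
        a, warm, ok = _min_norm_box_qp(R[i], M[i], warm_active=warm)
        if not ok and warm is not None:
            # a stale active set can pin every muscle spanning a joint; re-solve cold
            a, warm, ok = _min_norm_box_qp(R[i], M[i], warm_active=None)
        if not ok:
            res = lsq_linear(R[i], M[i], bounds=(0.0, 1.0), method="bvls")
            a = res.x
            infeasible[i] = True
        activations[i] = a
        objective[i] = float(a @ a)
        residuals[i] = R[i] @ a - M[i]

    return MuscleSolution(
        time=t,
        muscle_names=[mu.name for mu in muscles],
        activations=activations,
        forces=activations * fmax,
        objective=objective,
        residuals=residuals,
        infeasible=infeasible,
        quadriceps_mask=np.array([mu.is_quadriceps for mu in muscles]),
    )


def quadriceps_force(solution: MuscleSolution, body_mass: float,
                     gravity: float = 9.81) -> np.ndarray:
    """Summed quadriceps force normalized to body weight."""
    if body_mass <= 0:
        raise InputError("body mass must be > 0")
    return solution.quadriceps_force_n / (body_mass * gravity)
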