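"""Force-dependent kinematics (FDK): quasi-static contact equilibrium.

On top of the kinematically driven Cardan wrist, the carpal block is given
a small set of extra displacement coordinates alpha_s (here: its three
translations relative to the radius/ulna).  Each alpha_s is imposed through
a driver constraint Phi_s(q, t) - alpha_s = 0, and the reaction force along
that driver is the *FDK residual*.  The solver searches the alpha_s at
which all FDK residuals vanish, i.e. where the axial external load is
balanced purely by the elastic-foundation contact forces of the articular
pairs.  Time derivatives of alpha_s are taken as zero throughout, so every
solve is a static equilibrium.

The root find is a damped Newton iteration with a forward-difference
Jacobian, step clamping and a displacement box; tolerance is on the maximum
absolute residual force.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .contact import ContactPair
from .errors import ConvergenceError, ValidationError
from .model import WristModel


@dataclass(frozen=True)
class FdkProblem:
    """An FDK equilibrium problem on the synthetic or imported wrist.

    ``dofs`` are unit displacement directions of the carpal block (the
    alpha_s coordinates); ``axial_load_N`` acts along ``load_direction``
    (default: compressive, along the forearm axis toward proximal).
    """

    model: WristModel | None
    pairs: tuple[ContactPair, ...]
    axial_load_N: float = 140.0
    load_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    dofs: np.ndarray = field(default_factory=lambda: np.eye(3))
    bounds_m: float = 2e-3

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        d = np.atleast_2d(np.asarray(self.dofs, dtype=float))
        object.__setattr__(self, "dofs", d)
        ld = np.asarray(self.load_direction, dtype=float).reshape(3)
        n = np.linalg.norm(ld)
        if n < 1e-12:
            raise ValidationError("load_direction must be nonzero")
        object.__setattr__(self, "load_direction", ld / n)
        if self.axial_load_N < 0:
            raise ValidationError(
                f"axial load must be >= 0, got {self.axial_load_N}"
            )
        if d.shape[0] < 1 or d.shape[1] != 3:
            raise ValidationError("dofs must be a (k, 3) array with k >= 1")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValidationError("FDK dof directions must be unit vectors")

    def with_pressure_module(self, pm: float) -> "FdkProblem":
        return replace(
            self, pairs=tuple(p.with_pressure_module(pm) for p in self.pairs)
        )


@dataclass(frozen=True)
class FdkSolution:
    """Equilibrium displacements, per-pair contact forces and resultant."""

    alpha_m: np.ndarray
    pair_forces_N: dict
    resultant_N: float
    residual_N: float
    iterations: int


def aggregate_resultant(pair_forces_N) -> float:
    """Total articular contact force: scalar sum of the pair magnitudes."""
    total = 0.0
    for f in pair_forces_N:
        f = float(f)
        if f < 0:
            raise ValidationError(f"pair force magnitudes must be >= 0, got {f}")
        total += f
    return total


def _total_force(problem: FdkProblem, alpha: np.ndarray) -> tuple[np.ndarray, list]:
    disp = problem.dofs.T @ alpha
    total = problem.axial_load_N * problem.load_direction
    mags = []
    for pair in problem.pairs:
        fvec, _vol = pair.force(disp)
        total = total + fvec
        mags.append(float(np.linalg.norm(fvec)))
    return total, mags


def fdk_residual(problem: FdkProblem, alpha_s) -> np.ndarray:
    """FDK reaction force along each free displacement direction [N].

    The carpal block is held at the prescribed alpha_s; the returned vector
    is the net force (external axial load plus contact) projected on the
    dof directions -- the force the drivers must supply, which vanishes at
    the FDK equilibrium.
    """
    alpha = np.atleast_1d(np.asarray(alpha_s, dtype=float))
    k = problem.dofs.shape[0]
    if alpha.shape != (k,):
        raise ValidationError(f"alpha_s must have length {k}")
    if np.any(np.abs(alpha) > problem.bounds_m + 1e-12):
        raise ValidationError(
            f"alpha_s outside displacement bounds +/-{problem.bounds_m} m"
        )
    total, _ = _total_force(problem, alpha)
    return problem.dofs @ total


def fdk_solve(
    problem: FdkProblem,
    tol_N: float = 1e-6,
    max_iter: int = 200,
    fd_step_m: float = 1e-6,
    max_step_m: float = 5e-4,
) -> FdkSolution:
    """Find the displacements at which the FDK reaction forces vanish.

    Damped Newton from alpha_s = 0 with a forward-difference Jacobian,
    per-iteration step clamp ``max_step_m`` and the problem's displacement
    box.  Converged when max |residual| <= ``tol_N``; raises
    :class:`ConvergenceError` otherwise.
    """
    k = problem.dofs.shape[0]
    alpha = np.zeros(k)
    r = fdk_residual(problem, alpha)
    best_r = float(np.abs(r).max())

    def _solution(it: int) -> FdkSolution:
        _total, mags = _total_force(problem, alpha)
        forces = dict(zip((p.name for p in problem.pairs), mags))
        return FdkSolution(
            alpha_m=alpha,
            pair_forces_N=forces,
            resultant_N=aggregate_resultant(mags),
            residual_N=best_r,
            iterations=it,
        )

    def _clamp(step: np.ndarray) -> np.ndarray:
        norm = np.linalg.norm(step)
        return step if norm <= max_step_m else step * (max_step_m / norm)

    for it in range(1, max_iter + 1):
        if best_r <= tol_N:
            return _solution(it - 1)
        # forward-difference Jacobian
        J = np.empty((k, k))
        for j in range(k):
            step = np.zeros(k)
            step[j] = fd_step_m
            J[:, j] = (fdk_residual(problem, np.clip(alpha + step,
                                                     -problem.bounds_m,
                                                     problem.bounds_m)) - r) / fd_step_m
        try:
            newton = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            newton, *_ = np.linalg.lstsq(J, -r, rcond=None)
        if not np.all(np.isfinite(newton)) or np.linalg.norm(newton) == 0.0:
            newton = None
        # Relaxation step along the unbalanced force: outside contact the
        # residual is locally flat (zero Jacobian), but displacing the
        # carpal block along the net force eventually engages a pair.
        relax = max_step_m * r / max(np.linalg.norm(r), 1e-30)

        # try the (clamped) Newton step first, damped; fall back to the
        # relaxation step if it cannot reduce the residual
        accepted = False
        for delta in ([_clamp(newton)] if newton is not None else []) + [relax]:
            scale = 1.0
            for _ in range(12):
                trial = np.clip(alpha + scale * delta,
                                -problem.bounds_m, problem.bounds_m)
                r_trial = fdk_residual(problem, trial)
                if float(np.abs(r_trial).max()) < best_r:
                    accepted = True
                    break
                scale *= 0.5
            if accepted:
                break
        if not accepted:
            break  # stagnated: report non-convergence below
        alpha = trial
        r = r_trial
        best_r = float(np.abs(r).max())

    if best_r <= tol_N:
        return _solution(max_iter)
    raise ConvergenceError(
        f"FDK did not converge in {max_iter} iterations; "
        f"last residual {best_r:.3e} N",
        residual=best_r,
    )
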