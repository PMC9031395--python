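"""Operations on the Cardan-joint wrist model.

Forward kinematics, tendon-excursion moment arms, generalized loads,
muscle-recruitment optimization and 3D joint reaction forces, evaluated
quasi-statically sample by sample along FE / RUD motion cycles.

Moment arms use the tendon-excursion definition r = -dL/dtheta, evaluated
by central finite differences of the polyline muscle length with respect to
each Cardan angle.  Because the same forward kinematics generates both the
muscle lengths and the external generalized load, the static equilibrium

    sum_i r_ij f_i = tau_j        (j in {FE, RUD})

is consistent by virtual work regardless of the axis bookkeeping.

Recruitment distributes the demanded torque among the five muscles by
minimizing the polynomial criterion sum_i (f_i / N_i)^p (p = 3 by default,
N_i the isometric strength) subject to equilibrium and 0 <= f_i <= N_i; a
min/max criterion is available as an alternative.  The problem is solved
through its KKT stationarity conditions (a small root find in the torque
multipliers) with an SLSQP fallback, after an LP feasibility check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize, root
from scipy.spatial.transform import Rotation

from .errors import (
    ConvergenceError,
    InfeasibleLoadError,
    RangeError,
    ValidationError,
)
from .model import (
    MUSCLE_NAMES,
    CardanWristJoint,
    MotionCycle,
    Muscle,
    PathPoint,
    RecruitmentSolution,
    Segment,
    WristModel,
)

#: Central-difference step for tendon-excursion moment arms [rad].
MOMENT_ARM_STEP = 1e-4

#: Equilibrium residual tolerance for recruitment [N*m].
RECRUIT_TOL = 1e-8

# Default synthetic muscle geometry [m], forearm/hand frames at neutral.
# Columns: origin (forearm), retinaculum via point (forearm), insertion
# (hand), strength [N].  Palmar is -y, radial is +x.  Strengths are
# synthetic: large enough that the motion protocols under the 100 N
# metacarpal load stay feasible at the extreme postures, where the
# effective lever arms collapse to a few millimetres.
_DEFAULT_MUSCLES = {
    "ECU": ((-0.012, 0.015, -0.250), (-0.015, 0.013, -0.010), (-0.017, 0.011, 0.045), 1500.0),
    "ECRB": ((0.010, 0.015, -0.250), (0.008, 0.014, -0.010), (0.010, 0.013, 0.048), 1600.0),
    "ECRL": ((0.015, 0.015, -0.260), (0.016, 0.014, -0.010), (0.018, 0.012, 0.050), 2400.0),
    "FCR": ((0.010, -0.020, -0.250), (0.012, -0.014, -0.010), (0.015, -0.012, 0.045), 1700.0),
    "FCU": ((-0.010, -0.020, -0.250), (-0.014, -0.015, -0.010), (-0.015, -0.012, 0.040), 2000.0),
}


def build_default_model(params: dict | None = None) -> WristModel:
    """Instantiate the five-muscle Cardan wrist with synthetic geometry.

    ``params`` may override ``strengths`` (dict name -> N), the external
    load (``external_force_N`` 3-vector, ``load_point`` 3-vector [m]), and
    request a reproducible jitter of the muscle path points with
    ``perturb_mm`` (default 0) and ``seed``.
    """
    params = dict(params or {})
    strengths = dict(params.pop("strengths", {}))
    scale = float(params.pop("scale", 1.0))
    perturb_mm = float(params.pop("perturb_mm", 0.0))
    seed = int(params.pop("seed", 0))
    force = params.pop("external_force_N", (0.0, 100.0, 0.0))
    point = params.pop("load_point", (0.0, 0.0, 0.08))
    fe_axis = np.asarray(params.pop("fe_axis", (1.0, 0.0, 0.0)), dtype=float)
    rud_axis = np.asarray(params.pop("rud_axis", (0.0, -1.0, 0.0)), dtype=float)
    if params:
        raise ValidationError(f"unknown model parameters: {sorted(params)}")

    rng = np.random.default_rng(seed)
    muscles = []
    for name in MUSCLE_NAMES:
        origin, via, insertion, default_strength = _DEFAULT_MUSCLES[name]
        strength = float(strengths.get(name, default_strength))
        if strength <= 0:
            raise ValidationError(f"muscle {name}: strength must be > 0, got {strength}")
        pts = [scale * np.array(origin), scale * np.array(via), scale * np.array(insertion)]
        if perturb_mm > 0:
            pts = [p + rng.normal(0.0, perturb_mm * 1e-3, 3) for p in pts]
        muscles.append(
            Muscle(
                name,
                (
                    PathPoint(pts[0], "forearm"),
                    PathPoint(pts[1], "forearm"),
                    PathPoint(pts[2], "hand"),
                ),
                strength,
            )
        )
    joint = CardanWristJoint(fe_axis=fe_axis, rud_axis=rud_axis)
    return WristModel(joint=joint, muscles=tuple(muscles),
                      external_force_N=force, load_point=point)


# ---------------------------------------------------------------------------
# kinematics


def _hand_rotation(joint: CardanWristJoint, fe_deg: float, rud_deg: float) -> np.ndarray:
    """Hand attitude: FE rotation first, RUD applied on top (Cardan)."""
    r_fe = Rotation.from_rotvec(math.radians(fe_deg) * joint.fe_axis)
    r_rud = Rotation.from_rotvec(math.radians(rud_deg) * joint.rud_axis)
    return (r_rud * r_fe).as_matrix()


def _segments(model: WristModel, fe_deg: float, rud_deg: float) -> dict[str, Segment]:
    R = _hand_rotation(model.joint, fe_deg, rud_deg)
    c = model.joint.center
    return {
        "forearm": Segment("forearm"),
        "hand": Segment("hand", rotation=R, translation=c - R @ c),
    }


def _check_range(model: WristModel, fe_deg: float, rud_deg: float) -> None:
    lo, hi = model.fe_range
    if not lo - 1e-9 <= fe_deg <= hi + 1e-9:
        raise RangeError(f"FE angle {fe_deg} deg outside [{lo}, {hi}]")
    lo, hi = model.rud_range
    if not lo - 1e-9 <= rud_deg <= hi + 1e-9:
        raise RangeError(f"RUD angle {rud_deg} deg outside [{lo}, {hi}]")


def forward_kinematics(
    model: WristModel, fe_deg: float, rud_deg: float
) -> dict[str, Segment]:
    """Posed segments at the given Cardan angles (forearm stays fixed)."""
    _check_range(model, fe_deg, rud_deg)
    return _segments(model, fe_deg, rud_deg)


def posed_axes(model: WristModel, fe_deg: float, rud_deg: float) -> np.ndarray:
    """Instantaneous FE and RUD axes in the global frame, rows (2, 3).

    With the hand attitude composed as R = R_rud R_fe, the instantaneous
    axis of the FE coordinate is the FE axis rotated by the RUD rotation,
    while the RUD axis stays fixed.
    """
    r_rud = Rotation.from_rotvec(
        math.radians(rud_deg) * model.joint.rud_axis
    ).as_matrix()
    return np.vstack([r_rud @ model.joint.fe_axis, model.joint.rud_axis])


def _posed_path(model: WristModel, muscle: Muscle, fe_deg: float, rud_deg: float) -> np.ndarray:
    segs = _segments(model, fe_deg, rud_deg)
    return np.array([segs[pp.segment].pose_point(pp.point) for pp in muscle.path])


def muscle_length(
    model: WristModel, fe_deg: float, rud_deg: float, validate: bool = True
) -> np.ndarray:
    """Polyline length of every muscle path at the given posture [m]."""
    if validate:
        _check_range(model, fe_deg, rud_deg)
    out = np.empty(len(model.muscles))
    for i, m in enumerate(model.muscles):
        pts = _posed_path(model, m, fe_deg, rud_deg)
        out[i] = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    return out


def moment_arms(
    model: WristModel,
    fe_deg: float,
    rud_deg: float,
    step_rad: float = MOMENT_ARM_STEP,
) -> np.ndarray:
    """Tendon-excursion moment arms, shape (n_muscles, 2) [m].

    Column 0 is the FE axis (positive = flexor), column 1 the RUD axis
    (positive = ulnar deviator): r_ij = -dL_i/dtheta_j by central
    difference.  The probe postures skip range validation so that moment
    arms remain defined on the range boundary.
    """
    _check_range(model, fe_deg, rud_deg)
    h = math.degrees(step_rad)
    r = np.empty((len(model.muscles), 2))
    for j, (dfe, drud) in enumerate(((h, 0.0), (0.0, h))):
        lp = muscle_length(model, fe_deg + dfe, rud_deg + drud, validate=False)
        lm = muscle_length(model, fe_deg - dfe, rud_deg - drud, validate=False)
        r[:, j] = -(lp - lm) / (2.0 * step_rad)
    return r


def generalized_load(
    model: WristModel,
    fe_deg: float,
    rud_deg: float,
    force_N=None,
    point=None,
) -> np.ndarray:
    """External-load torque about the posed FE and RUD axes [N*m].

    The application point rides on the hand segment; the force keeps its
    global direction (gravity-style load).  Returns [tau_FE, tau_RUD].
    """
    _check_range(model, fe_deg, rud_deg)
    force = model.external_force_N if force_N is None else np.asarray(force_N, float)
    pt = model.load_point if point is None else np.asarray(point, float)
    segs = _segments(model, fe_deg, rud_deg)
    p = segs["hand"].pose_point(pt)
    axes = posed_axes(model, fe_deg, rud_deg)
    moment = np.cross(p - model.joint.center, force)
    return axes @ moment


# ---------------------------------------------------------------------------
# recruitment


def _dual_forces(lam: np.ndarray, R: np.ndarray, strengths: np.ndarray, p: float) -> np.ndarray:
    """Stationarity map: forces as a function of the torque multipliers.

    From d/df_i sum (f_i/N_i)^p = sum_j lam_j r_ij (with f >= 0):
    f_i = N_i (N_i g_i / p)^(1/(p-1)) for positive pull g_i, clipped at N_i.
    """
    g = R @ lam  # per-muscle pull, shape (n,)
    base = np.maximum(strengths * g / p, 0.0)
    x = base ** (1.0 / (p - 1.0))
    return np.minimum(x * strengths, strengths)


def solve_recruitment(
    moment_arm_matrix: np.ndarray,
    torques_Nm: np.ndarray,
    strengths_N: np.ndarray,
    p: float = 3.0,
    criterion: str = "polynomial",
    axis_names: tuple[str, ...] = ("FE", "RUD"),
    tol: float = RECRUIT_TOL,
) -> tuple[np.ndarray, float]:
    """Distribute ``torques_Nm`` among muscles; returns (forces, residual).

    ``moment_arm_matrix`` has shape (n_muscles, n_axes).
    """
    R = np.atleast_2d(np.asarray(moment_arm_matrix, float))
    tau = np.atleast_1d(np.asarray(torques_Nm, float))
    N = np.asarray(strengths_N, float)
    n, k = R.shape
    if tau.shape != (k,):
        raise ValidationError(f"torque vector must have length {k}")

    # Drop axes the muscle set cannot influence; a demand there is either
    # negligible or outright infeasible.
    capacity = np.abs(R).T @ N  # per-axis max |torque|
    keep = []
    for j in range(k):
        if capacity[j] < tol:
            if abs(tau[j]) > tol:
                raise InfeasibleLoadError(
                    f"axis {axis_names[j]}: demand {tau[j]:.3g} N*m but no "
                    f"muscle has a moment arm about it",
                    axis=axis_names[j],
                )
        else:
            keep.append(j)
    if not keep:
        return np.zeros(n), float(np.abs(tau).max(initial=0.0))
    Rk, tauk = R[:, keep], tau[keep]
    names_k = tuple(axis_names[j] for j in keep)

    if np.all(np.abs(tauk) <= tol):
        return np.zeros(n), float(np.abs(tauk).max())

    _check_feasible(Rk, tauk, N, names_k, tol)

    if criterion == "minmax":
        f = _solve_minmax(Rk, tauk, N)
    elif criterion == "polynomial":
        f = _solve_polynomial(Rk, tauk, N, p, tol)
    else:
        raise ValidationError(f"unknown recruitment criterion {criterion!r}")

    residual = float(np.abs(R.T @ f - tau).max())
    if residual > tol:
        raise ConvergenceError(
            f"recruitment residual {residual:.3e} N*m exceeds {tol:.0e}",
            residual=residual,
        )
    return f, residual


def _check_feasible(R, tau, N, axis_names, tol) -> None:
    """LP elastic feasibility: min sum of torque violations."""
    n, k = R.shape
    # variables: f (n), e+ (k), e- (k)
    c = np.concatenate([np.zeros(n), np.ones(2 * k)])
    A_eq = np.hstack([R.T, np.eye(k), -np.eye(k)])
    bounds = [(0.0, float(Ni)) for Ni in N] + [(0.0, None)] * (2 * k)
    res = linprog(c, A_eq=A_eq, b_eq=tau, bounds=bounds, method="highs")
    if not res.success:
        raise InfeasibleLoadError("recruitment feasibility LP failed")
    viol = res.x[n : n + k] + res.x[n + k :]
    if res.fun > max(100 * tol, 1e-7):
        j = int(np.argmax(viol))
        raise InfeasibleLoadError(
            f"torque demand infeasible about axis {axis_names[j]}: "
            f"violation {viol[j]:.3g} N*m",
            axis=axis_names[j],
        )


def _solve_minmax(R, tau, N) -> np.ndarray:
    n, k = R.shape
    # variables: f (n), t
    c = np.concatenate([np.zeros(n), [1.0]])
    A_eq = np.hstack([R.T, np.zeros((k, 1))])
    A_ub = np.hstack([np.diag(1.0 / N), -np.ones((n, 1))])
    bounds = [(0.0, float(Ni)) for Ni in N] + [(0.0, None)]
    res = linprog(c, A_eq=A_eq, b_eq=tau, A_ub=A_ub, b_ub=np.zeros(n),
                  bounds=bounds, method="highs")
    if not res.success:
        raise ConvergenceError("min/max recruitment LP did not converge")
    return res.x[:n]


def _solve_polynomial(R, tau, N, p, tol) -> np.ndarray:
    n, k = R.shape

    def g(lam):
        return R.T @ _dual_forces(lam, R, N, p) - tau

    # scale-aware multiplier guess: mean activation needed per axis
    lam0 = np.zeros(k)
    for j in range(k):
        cap = float(np.abs(R[:, j]) @ N)
        xbar = min(abs(tau[j]) / max(cap, 1e-12), 0.9)
        rbar = max(float(np.abs(R[:, j]).mean()), 1e-9)
        nbar = float(N.mean())
        lam0[j] = math.copysign(p * xbar ** (p - 1.0) / (nbar * rbar), tau[j])

    best = None
    for start in (lam0, 10 * lam0, np.zeros(k) + 1e-6):
        sol = root(g, start, method="hybr", options={"xtol": 1e-14})
        f = _dual_forces(sol.x, R, N, p)
        res = float(np.abs(R.T @ f - tau).max())
        if best is None or res < best[1]:
            best = (f, res)
        if res <= tol:
            return f

    # SLSQP fallback on normalized activations
    x0 = best[0] / N

    def obj(x):
        return float(np.sum(x ** p))

    def jac(x):
        return p * x ** (p - 1.0)

    cons = {
        "type": "eq",
        "fun": lambda x: R.T @ (x * N) - tau,
        "jac": lambda x: (R * N[:, None]).T,
    }
    resopt = minimize(obj, x0, jac=jac, bounds=[(0.0, 1.0)] * n,
                      constraints=[cons], method="SLSQP",
                      options={"maxiter": 500, "ftol": 1e-16})
    f2 = resopt.x * N
    res2 = float(np.abs(R.T @ f2 - tau).max())
    return f2 if res2 < best[1] else best[0]


def recruit(
    model: WristModel,
    posture: tuple[float, float],
    torques_Nm,
    p: float = 3.0,
    criterion: str = "polynomial",
) -> RecruitmentSolution:
    """Solve muscle recruitment for a (FE, RUD) torque demand [N*m]."""
    fe, rud = posture
    R = moment_arms(model, fe, rud)
    forces, residual = solve_recruitment(
        R, np.asarray(torques_Nm, float), model.strengths, p=p, criterion=criterion
    )
    objective = float(np.sum((forces / model.strengths) ** p))
    return RecruitmentSolution(model.muscle_names, forces, objective, residual)


# ---------------------------------------------------------------------------
# reactions and motion


def muscle_force_vectors(
    model: WristModel, posture: tuple[float, float], forces_N: np.ndarray
) -> np.ndarray:
    """Force each muscle applies to the hand, shape (n, 3) [N].

    The tendon pulls the insertion toward the adjacent (proximal) path
    point along the posed distal path segment.
    """
    fe, rud = posture
    out = np.zeros((len(model.muscles), 3))
    for i, m in enumerate(model.muscles):
        pts = _posed_path(model, m, fe, rud)
        d = pts[-2] - pts[-1]
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            raise ValidationError(f"muscle {m.name}: degenerate distal segment")
        out[i] = forces_N[i] * d / norm
    return out


def joint_reaction(
    model: WristModel,
    posture: tuple[float, float],
    recruitment: RecruitmentSolution,
    external_force_N=None,
) -> np.ndarray:
    """Joint reaction force on the hand segment, global frame [N].

    Static force balance of the hand: reaction = -(external force + sum of
    muscle force vectors).
    """
    force = (
        model.external_force_N
        if external_force_N is None
        else np.asarray(external_force_N, float)
    )
    vecs = muscle_force_vectors(model, posture, recruitment.forces_N)
    return -(force + vecs.sum(axis=0))


_CYCLES = {
    "FE": ((0.0, 0.25, 0.5, 0.75, 1.0), (0.0, 80.0, 0.0, -60.0, 0.0)),
    "RUD": ((0.0, 0.25, 0.5, 0.75, 1.0), (0.0, -20.0, 0.0, 40.0, 0.0)),
}


def make_motion_cycle(plane: str, n_samples: int = 121) -> MotionCycle:
    """Standard motion protocol: FE 80-0-60, RUD 20-0-40 (out and back).

    Flexion and ulnar deviation are positive; the cycle starts and ends at
    neutral and is piecewise linear in normalized time.  The waypoint times
    are merged into the sample grid so the extrema are attained exactly.
    """
    if plane not in _CYCLES:
        raise ValidationError(f"plane must be 'FE' or 'RUD', got {plane!r}")
    if n_samples < 3:
        raise ValidationError(f"n_samples must be >= 3, got {n_samples}")
    wt, wa = _CYCLES[plane]
    t = np.unique(np.concatenate([np.linspace(0.0, 1.0, int(n_samples)), wt]))
    return MotionCycle(plane, t, np.interp(t, wt, wa))


def simulate_motion(
    model: WristModel,
    cycle: MotionCycle,
    external_force_N=None,
    p: float = 3.0,
    criterion: str = "polynomial",
) -> pd.DataFrame:
    """Quasi-static sweep: recruitment + joint reaction at every sample.

    Returns a table with columns ``time, fe_deg, rud_deg, torque_fe_Nm,
    torque_rud_Nm``, one ``<muscle>_N`` column per muscle and
    ``reaction_x_N, reaction_y_N, reaction_z_N``.
    """
    force = (
        model.external_force_N
        if external_force_N is None
        else np.asarray(external_force_N, float)
    )
    rows = []
    for idx, (t, ang) in enumerate(zip(cycle.time, cycle.angles_deg)):
        fe, rud = (ang, 0.0) if cycle.plane == "FE" else (0.0, ang)
        tau_ext = generalized_load(model, fe, rud, force_N=force)
        demand = -tau_ext  # muscles balance the external torque
        try:
            sol = recruit(model, (fe, rud), demand, p=p, criterion=criterion)
        except InfeasibleLoadError as err:
            raise InfeasibleLoadError(
                f"sample {idx} (t={t:.3f}, {cycle.plane}={ang:.1f} deg): {err}",
                axis=err.axis,
                sample=idx,
            ) from err
        reaction = joint_reaction(model, (fe, rud), sol, external_force_N=force)
        row = {
            "time": float(t),
            "fe_deg": fe,
            "rud_deg": rud,
            "torque_fe_Nm": float(demand[0]),
            "torque_rud_Nm": float(demand[1]),
        }
        row.update({f"{n}_N": float(f) for n, f in zip(sol.muscles, sol.forces_N)})
        row.update(
            {
                "reaction_x_N": float(reaction[0]),
                "reaction_y_N": float(reaction[1]),
                "reaction_z_N": float(reaction[2]),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
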