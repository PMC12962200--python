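"""Static RF-shim solvers: CP mode, subject-specific and universal shims.

A static shim is one complex weight per transmit channel, normalised so the
L2 norm of the weight vector is one (total power).  Solvers minimise either
an efficiency cost (the reciprocal of the mean |B1+| over the target
region, so maximal mean field per unit total power) or the coefficient of
variation of |B1+| over the region, subject to

* flip-angle homogeneity bounds on the region, evaluated on the
  region-mean-calibrated relative flip angle (alpha_min <= alpha(r) <=
  alpha_max, defaults 0.8 and 1.3), and
* a per-channel cap on the normalised weight magnitude (default 0.35,
  i.e. at most twice the power of a single channel in an equal-magnitude
  solution).

The universal solver fits a single weight vector to a whole training
database by minimising the L2 norm of the per-subject objective values,
sqrt(sum_s f_s(w)^2); per-subject flip-angle bounds become quadratic hinge
penalties there (joint hard feasibility over many subjects may be empty),
while the channel-weight cap stays hard.

Estimators follow the scikit-learn protocol: construct with
hyper-parameters, ``fit`` on a field map (or database), read the fitted
weights from ``weights_``, and ``predict`` relative flip-angle maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax
from sklearn.base import BaseEstimator

from .fields import ChannelFieldMap, _check_mask, combine_fields, flip_angle_map
from .grid import CoilGeometry

#: sharpness of the log-sum-exp soft maximum used for hard flip-angle
#: constraints; the soft max over- (soft min under-) estimates the true
#: extremum by at most ln(M)/k, so feasibility of the smoothed constraint
#: implies feasibility of the exact one.
_LSE_SHARPNESS = 1000.0
#: hinge-penalty weight for flip-angle bounds in universal (soft) mode
_SOFT_PENALTY_WEIGHT = 100.0
#: feasibility tolerance on constraint violations
FEASIBILITY_TOL = 1e-6

MODES = ("phase_only", "phase_magnitude")
COST_KINDS = ("efficiency", "coefficient_of_variation")


@dataclass
class ShimVector:
    """Complex per-channel shim weights, unit L2 norm after normalisation.

    All costs, constraints and metrics are invariant under a global phase
    factor; the stored convention rotates channel 1 to zero phase.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=complex).ravel()
        if self.weights.size < 1:
            raise ValueError("shim needs at least one weight")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def __array__(self, dtype=None, copy=None):
        w = self.weights
        return np.array(w, dtype=dtype) if dtype else np.array(w)

    @property
    def n_channels(self) -> int:
        return self.weights.size

    def normalized(self) -> "ShimVector":
        """Unit-norm copy with the global phase fixed (channel 1 real >= 0)."""
        return ShimVector(_normalize(self.weights))

    def to_mag_phase(self) -> list[dict[str, float]]:
        """Serialise as (magnitude, phase in degrees) per channel."""
        return [
            {"mag": float(abs(w)), "phase_deg": float(np.rad2deg(np.angle(w)))}
            for w in self.weights
        ]

    @classmethod
    def from_mag_phase(cls, entries) -> "ShimVector":
        w = np.array(
            [e["mag"] * np.exp(1j * np.deg2rad(e["phase_deg"])) for e in entries]
        )
        return cls(w)


@dataclass(frozen=True)
class ShimConstraints:
    """Flip-angle bounds, channel-weight cap and optimisation mode."""

    alpha_max: float = 1.3
    alpha_min: float = 0.8
    w_max: float = 0.35
    mode: str = "phase_magnitude"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_min < 1.0 < self.alpha_max):
            raise ValueError(
                f"need 0 < alpha_min < 1 < alpha_max, got "
                f"({self.alpha_min}, {self.alpha_max})"
            )
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def validate_for(self, n_channels: int) -> None:
        lo = 1.0 / np.sqrt(n_channels)
        if not lo - 1e-12 <= self.w_max <= 1.0 + 1e-12:
            raise ValueError(
                f"w_max must lie in [1/sqrt(n_channels), 1] = [{lo:.4f}, 1], "
                f"got {self.w_max}"
            )


@dataclass(frozen=True)
class CostSpec:
    """Which scalar cost to optimise and over which region."""

    kind: str = "efficiency"
    region: str = "roi"  # "roi" (shimming target) or "brain" (whole brain)

    def __post_init__(self) -> None:
        if self.kind not in COST_KINDS:
            raise ValueError(f"kind must be one of {COST_KINDS}")
        if self.region not in ("roi", "brain"):
            raise ValueError("region must be 'roi' or 'brain'")


@dataclass
class OptimizationResult:
    shim: ShimVector
    cost_value: float
    constraint_report: dict
    n_restarts_used: int
    converged: bool


def _normalize(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=complex).ravel()
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("cannot normalise a zero shim vector")
    w = w / nrm
    # global phase: rotate channel 1 to zero phase
    if abs(w[0]) > 1e-12:
        w = w * np.exp(-1j * np.angle(w[0]))
    return w


def cp_mode(geometry: CoilGeometry) -> ShimVector:
    """Circularly-polarised reference shim from the element azimuths.

    Equal magnitudes 1/sqrt(n_channels); the element at azimuth phi is
    driven with phase -phi, so elements whose transmit-field phase rotates
    with azimuth combine constructively on the coil axis.  Second-ring
    elements use their own azimuths, including the ring offset.
    """
    phi = np.deg2rad(geometry.element_azimuths_deg())
    w = np.exp(-1j * phi) / np.sqrt(geometry.n_channels)
    return ShimVector(_normalize(w))


# ---------------------------------------------------------------------------
# scalar costs and constraint report


def _roi_matrix(field_map: ChannelFieldMap, roi: np.ndarray) -> np.ndarray:
    roi = _check_mask(roi, field_map.grid)
    return field_map.values[:, roi].T.copy()  # (M, C)


def efficiency_cost(field_map: ChannelFieldMap, shim, roi: np.ndarray) -> float:
    """Reciprocal mean |B1+| over the region for a unit-norm shim.

    Lower is better; +inf when the combined field vanishes on the region.
    """
    w = np.asarray(shim, dtype=complex).ravel()
    e = float(np.abs(combine_fields(field_map, w))[_check_mask(roi, field_map.grid)].mean())
    if e == 0.0:
        return float("inf")
    return 1.0 / e


def cv_cost(field_map: ChannelFieldMap, shim, roi: np.ndarray) -> float:
    """Coefficient of variation (population std / mean) of |B1+| over the region."""
    mag = np.abs(combine_fields(field_map, shim))[_check_mask(roi, field_map.grid)]
    mean = float(mag.mean())
    if mean == 0.0:
        raise ValueError("combined field has zero mean on the region")
    return float(mag.std() / mean)


def shim_cost(field_map: ChannelFieldMap, shim, roi: np.ndarray, kind: str) -> float:
    if kind == "efficiency":
        return efficiency_cost(field_map, shim, roi)
    if kind == "coefficient_of_variation":
        return cv_cost(field_map, shim, roi)
    raise ValueError(f"unknown cost kind {kind!r}")


def constraint_violations(
    field_map: ChannelFieldMap,
    shim,
    constraints: ShimConstraints,
    roi: np.ndarray,
) -> dict:
    """Worst-case constraint values for a unit-norm shim on a region.

    Flip angles are region-mean calibrated (mean alpha = 1 on the region)
    before comparison with the bounds.
    """
    w = np.asarray(shim, dtype=complex).ravel()
    alpha = flip_angle_map(field_map, w, roi)[np.asarray(roi, dtype=bool)]
    max_w = float(np.abs(w).max())
    report = {
        "max_alpha": float(alpha.max()),
        "min_alpha": float(alpha.min()),
        "max_weight_mag": max_w,
        "alpha_max_ok": bool(alpha.max() <= constraints.alpha_max + FEASIBILITY_TOL),
        "alpha_min_ok": bool(alpha.min() >= constraints.alpha_min - FEASIBILITY_TOL),
        "weight_cap_ok": bool(max_w <= constraints.w_max + FEASIBILITY_TOL),
    }
    report["feasible"] = (
        report["alpha_max_ok"] and report["alpha_min_ok"] and report["weight_cap_ok"]
    )
    return report


# ---------------------------------------------------------------------------
# optimisation engine


class _ShimProblem:
    """Smooth real-parametrised shim problem over one or more subjects.

    Parametrisation: phase_magnitude uses x = [Re u; Im u] with
    w = u/||u||; phase_only uses x = channel phases with fixed magnitudes
    1/sqrt(C).  Every cost and constraint is scale- and global-phase
    invariant in u, so the unconstrained parametrisation carries no
    normalisation constraint.
    """

    def __init__(
        self,
        B_list: list[np.ndarray],
        cost_kind: str,
        constraints: ShimConstraints,
        hard_alpha: bool,
        joint_l2: bool,
    ) -> None:
        self.B_list = [np.ascontiguousarray(B) for B in B_list]
        self.Bc_list = [B.conj().T for B in self.B_list]
        self.C = self.B_list[0].shape[1]
        self.cost_kind = cost_kind
        self.constraints = constraints
        self.hard_alpha = hard_alpha
        self.joint_l2 = joint_l2
        self.mode = constraints.mode
        self.dim = self.C if self.mode == "phase_only" else 2 * self.C
        self._cache_key: bytes | None = None
        self._cache: tuple | None = None

    # -- parametrisation ----------------------------------------------------
    def u_of_x(self, x: np.ndarray) -> np.ndarray:
        if self.mode == "phase_only":
            return np.exp(1j * x) / np.sqrt(self.C)
        return x[: self.C] + 1j * x[self.C :]

    def chain(self, u: np.ndarray, G: np.ndarray) -> np.ndarray:
        """Convert a complex gradient (df = sum Re(conj(G) du)) to d/dx."""
        if self.mode == "phase_only":
            return np.real(np.conj(G) * 1j * u)
        return np.concatenate([G.real, G.imag])

    # -- per-subject field state --------------------------------------------
    def _state(self, s: int, u: np.ndarray) -> dict:
        b = self.B_list[s] @ u
        m = np.abs(b)
        msafe = np.maximum(m, 1e-30)
        return {"m": m, "unit": b / msafe, "e": float(m.mean())}

    def _states(self, x: np.ndarray) -> tuple[np.ndarray, list[dict]]:
        """u and per-subject field states at x, cached for the last x.

        SLSQP evaluates the objective and every constraint at the same
        point each iteration; the cache collapses those into one set of
        channel-combination matvecs.
        """
        key = x.tobytes()
        if key != self._cache_key:
            u = self.u_of_x(x)
            self._cache = (u, [self._state(s, u) for s in range(len(self.B_list))])
            self._cache_key = key
        return self._cache

    def _row_grad(self, s: int, a: np.ndarray, st: dict) -> np.ndarray:
        """Complex gradient of sum_r a_r * m_r for subject s."""
        return self.Bc_list[s] @ (a * st["unit"])

    def _alpha_row_weights(self, c: np.ndarray, st: dict) -> np.ndarray:
        """Convert d/d(alpha_r) coefficients c to d/d(m_r) row weights."""
        e, m = st["e"], st["m"]
        M = m.size
        return c / e - (c @ m) / (e * e * M)

    # -- subject cost f_s and complex gradient ------------------------------
    def _cost_s(self, s: int, u: np.ndarray, st: dict):
        m, e = st["m"], st["e"]
        M = m.size
        if self.cost_kind == "efficiency":
            n = np.linalg.norm(u)
            if e <= 0:
                return 1e12, np.zeros(self.C, complex)
            f = n / e
            G = u / (n * e) - (n / e**2) * self._row_grad(s, np.full(M, 1.0 / M), st)
            return f, G
        # coefficient of variation
        if e <= 0:
            return 1e12, np.zeros(self.C, complex)
        sd = float(m.std())
        if sd == 0.0:
            return 0.0, np.zeros(self.C, complex)
        a = (m - e) / (M * sd * e) - sd / (e * e * M)
        return sd / e, self._row_grad(s, a, st)

    def _alpha_penalty_s(self, s: int, st: dict):
        m, e = st["m"], st["e"]
        M = m.size
        alpha = m / e
        over = np.maximum(alpha - self.constraints.alpha_max, 0.0)
        under = np.maximum(self.constraints.alpha_min - alpha, 0.0)
        p = _SOFT_PENALTY_WEIGHT / M * float(over @ over + under @ under)
        c = 2.0 * _SOFT_PENALTY_WEIGHT / M * (over - under)
        return p, self._row_grad(s, self._alpha_row_weights(c, st), st)

    # -- full objectives -----------------------------------------------------
    def objective(self, x: np.ndarray):
        """Cost (plus soft alpha penalties in joint mode) and gradient."""
        u, states = self._states(x)
        fs, Gs = zip(*(self._cost_s(s, u, st) for s, st in enumerate(states)))
        fs = np.asarray(fs)
        if self.joint_l2:
            F = float(np.sqrt(np.sum(fs**2)))
            G = sum((f / max(F, 1e-30)) * g for f, g in zip(fs, Gs))
            if not self.hard_alpha:
                for s, st in enumerate(states):
                    p, Gp = self._alpha_penalty_s(s, st)
                    F += p
                    G = G + Gp
        else:
            F = float(fs[0])
            G = Gs[0]
        return F, self.chain(u, G)

    def penalty_objective(self, x: np.ndarray, mu: float = 1e3):
        """Objective plus hinge penalties for every constraint (warm-up stage)."""
        F, grad = self.objective(x)
        u, states = self._states(x)
        if self.hard_alpha:
            for s, st in enumerate(states):
                m, e = st["m"], st["e"]
                M = m.size
                alpha = m / e
                over = np.maximum(alpha - self.constraints.alpha_max, 0.0)
                under = np.maximum(self.constraints.alpha_min - alpha, 0.0)
                F += mu / M * float(over @ over + under @ under)
                c = 2.0 * mu / M * (over - under)
                grad = grad + self.chain(u, self._row_grad(s, self._alpha_row_weights(c, st), st))
        if self.mode == "phase_magnitude":
            n = np.linalg.norm(u)
            ratio = np.abs(u) / n
            h = np.maximum(ratio - self.constraints.w_max, 0.0)
            if h.any():
                F += mu * float(h @ h)
                usafe = np.where(np.abs(u) > 1e-30, u, 1e-30)
                G = 2.0 * mu * (
                    h * usafe / np.abs(usafe) / n - (h @ ratio) * u / (n * n)
                )
                grad = grad + self.chain(u, G)
        return F, grad

    # -- SLSQP constraints ----------------------------------------------------
    def slsqp_constraints(self) -> list[dict]:
        cons: list[dict] = []
        k = _LSE_SHARPNESS
        if self.hard_alpha:
            for s in range(len(self.B_list)):

                def g_max(x, s=s):
                    _, states = self._states(x)
                    st = states[s]
                    smax = logsumexp(k * st["m"] / st["e"]) / k
                    return self.constraints.alpha_max - smax

                def g_max_jac(x, s=s):
                    u, states = self._states(x)
                    st = states[s]
                    p = softmax(k * st["m"] / st["e"])
                    G = self._row_grad(s, self._alpha_row_weights(p, st), st)
                    return -self.chain(u, G)

                def g_min(x, s=s):
                    _, states = self._states(x)
                    st = states[s]
                    smin = -logsumexp(-k * st["m"] / st["e"]) / k
                    return smin - self.constraints.alpha_min

                def g_min_jac(x, s=s):
                    u, states = self._states(x)
                    st = states[s]
                    q = softmax(-k * st["m"] / st["e"])
                    G = self._row_grad(s, self._alpha_row_weights(q, st), st)
                    return self.chain(u, G)

                cons.append({"type": "ineq", "fun": g_max, "jac": g_max_jac})
                cons.append({"type": "ineq", "fun": g_min, "jac": g_min_jac})
        if self.mode == "phase_magnitude":

            def g_cap(x):
                # tightened by the feasibility tolerance: the cap is a strict
                # inequality, so solutions should land strictly below it
                u = self.u_of_x(x)
                cap = self.constraints.w_max - FEASIBILITY_TOL
                return cap - np.abs(u) / np.linalg.norm(u)

            def g_cap_jac(x):
                u = self.u_of_x(x)
                n = np.linalg.norm(u)
                usafe = np.where(np.abs(u) > 1e-30, u, 1e-30)
                jac = np.empty((self.C, self.dim))
                for c in range(self.C):
                    G = np.zeros(self.C, complex)
                    G[c] = usafe[c] / np.abs(usafe[c]) / n
                    G -= (np.abs(u[c]) / n**2) * (u / n)
                    jac[c] = -self.chain(u, G)
                return jac

            cons.append({"type": "ineq", "fun": g_cap, "jac": g_cap_jac})
        return cons


def _starting_points(problem: _ShimProblem, n_restarts: int, seed: int,
                     geometry: CoilGeometry | None, warm_starts=()) -> list[np.ndarray]:
    """Deterministic starts (warm, phase-matched, CP mode) then random phases.

    The deterministic starts are always kept, even when ``n_restarts`` is
    smaller than their number; random-phase starts fill the remainder.
    """
    rng = np.random.default_rng(seed)
    C = problem.C
    starts: list[np.ndarray] = []

    def x_of_w(w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, complex).ravel()
        if problem.mode == "phase_only":
            return np.angle(w)
        return np.concatenate([w.real, w.imag])

    for w in warm_starts:
        starts.append(x_of_w(w))
    # phase-matched start: conjugate of the mean channel phasor over all rows
    col_mean = np.mean(np.vstack(problem.B_list), axis=0)
    phases = -np.angle(col_mean)
    starts.append(x_of_w(np.exp(1j * phases) / np.sqrt(C)))
    if geometry is not None and geometry.n_channels == C:
        starts.append(x_of_w(cp_mode(geometry).weights))
    while len(starts) < n_restarts:
        starts.append(x_of_w(np.exp(1j * rng.uniform(0, 2 * np.pi, C)) / np.sqrt(C)))
    return starts


def _with_bounds(problem: _ShimProblem, alpha_min: float, alpha_max: float) -> _ShimProblem:
    cons = ShimConstraints(
        alpha_max=alpha_max, alpha_min=alpha_min,
        w_max=problem.constraints.w_max, mode=problem.mode,
    )
    return _ShimProblem(
        problem.B_list, problem.cost_kind, cons,
        hard_alpha=problem.hard_alpha, joint_l2=problem.joint_l2,
    )


def _homogeneity_start(problem: _ShimProblem, x0: np.ndarray) -> np.ndarray:
    """Homogeneity-first initialisation: minimise the CV before the cost.

    The coefficient of variation has a wide, well-behaved basin toward
    uniform fields, which is exactly the neighbourhood where the
    flip-angle bounds are satisfiable; starting the constrained search
    there is far more reliable than random phases alone.
    """
    cv_problem = _ShimProblem(
        problem.B_list, "coefficient_of_variation", problem.constraints,
        hard_alpha=False, joint_l2=problem.joint_l2,
    )
    x = x0
    for mu in (1e2, 1e3, 1e4):
        x = minimize(
            lambda xx: cv_problem.penalty_objective(xx, mu), x,
            jac=True, method="L-BFGS-B", options={"maxiter": 400},
        ).x
    return x


def _feasibility_homotopy(problem: _ShimProblem, x: np.ndarray) -> np.ndarray:
    """Drive hard flip-angle violations to zero by tightening the bounds.

    Minimises the pure hinge violation (no cost term) over a schedule of
    progressively narrower alpha bands ending at the target band; each
    step warm-starts from the previous one.
    """
    lo_t, hi_t = problem.constraints.alpha_min, problem.constraints.alpha_max
    for s in (2.5, 1.75, 1.25, 1.0, 1.0):
        lo = max(1.0 - s * (1.0 - lo_t), 0.25 * lo_t)
        sub = _with_bounds(problem, lo, 1.0 + s * (hi_t - 1.0))

        def violation(xx):
            fp, gp = sub.penalty_objective(xx, mu=1e5)
            fo, go = sub.objective(xx)
            return fp - fo, gp - go

        x = minimize(
            violation, x, jac=True, method="L-BFGS-B", options={"maxiter": 600}
        ).x
    return x


def _solve(
    problem: _ShimProblem,
    n_restarts: int,
    seed: int,
    geometry: CoilGeometry | None = None,
    warm_starts=(),
) -> tuple[np.ndarray, float, bool, int]:
    """Multi-start smooth constrained search; returns (w, cost, feasible, n).

    Per start: a hinge-penalty warm-up, then (hard-constraint problems
    only) a feasibility homotopy when the warm-up left the alpha band
    violated, then an SLSQP polish with smooth conservative constraint
    aggregates.  The first start is additionally preceded by a
    homogeneity-first (CV-minimising) initialisation.
    """
    starts = _starting_points(problem, n_restarts, seed, geometry, warm_starts)
    if not warm_starts:
        # a warm start (e.g. the previous increment of an expanding-database
        # fit) is already homogeneous; otherwise buy one with a CV descent
        starts.insert(0, _homogeneity_start(problem, starts[0]))
    candidates = []
    for x0 in starts:
        warm = minimize(
            problem.penalty_objective, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": 250},
        )
        x = warm.x
        if problem.hard_alpha and not _is_feasible(problem, _normalize(problem.u_of_x(x))):
            x = _feasibility_homotopy(problem, x)
        cons = problem.slsqp_constraints()
        if cons:
            res = minimize(
                problem.objective, x, jac=True, method="SLSQP",
                constraints=cons, options={"maxiter": 200, "ftol": 1e-10},
            )
            if np.all(np.isfinite(res.x)):
                # keep the polish only if it did not lose feasibility
                w_new = _normalize(problem.u_of_x(res.x))
                w_old = _normalize(problem.u_of_x(x))
                if _is_feasible(problem, w_new) or not _is_feasible(problem, w_old):
                    x = res.x
        else:
            x = minimize(
                problem.objective, x, jac=True, method="L-BFGS-B",
                options={"maxiter": 500},
            ).x
        u = problem.u_of_x(x)
        if np.linalg.norm(u) == 0:
            continue
        w = _normalize(u)
        candidates.append((w, _pure_cost(problem, w), _is_feasible(problem, w)))
    if not candidates:
        raise RuntimeError("optimizer produced no candidate solutions")
    feas = [c for c in candidates if c[2]]
    pool = feas if feas else candidates
    pool.sort(key=lambda c: (c[1], float(np.abs(c[0]).max())))
    w, cost, feasible = pool[0]
    return w, cost, feasible, len(starts)


def _pure_cost(problem: _ShimProblem, w: np.ndarray) -> float:
    """Constraint-free cost value (joint L2 of subject costs in joint mode)."""
    fs = []
    for s, B in enumerate(problem.B_list):
        m = np.abs(B @ w)
        e = m.mean()
        if problem.cost_kind == "efficiency":
            fs.append(1.0 / e if e > 0 else 1e12)
        else:
            fs.append(m.std() / e if e > 0 else 1e12)
    fs = np.asarray(fs)
    return float(np.sqrt(np.sum(fs**2)) if problem.joint_l2 else fs[0])


def _is_feasible(problem: _ShimProblem, w: np.ndarray) -> bool:
    if np.abs(w).max() > problem.constraints.w_max + FEASIBILITY_TOL:
        return False
    if problem.hard_alpha:
        for B in problem.B_list:
            m = np.abs(B @ w)
            alpha = m / m.mean()
            if alpha.max() > problem.constraints.alpha_max + FEASIBILITY_TOL:
                return False
            if alpha.min() < problem.constraints.alpha_min - FEASIBILITY_TOL:
                return False
    return True


# ---------------------------------------------------------------------------
# estimators


class _BaseShim(BaseEstimator):
    """Shared predict/report machinery for fitted shim estimators."""

    weights_: np.ndarray

    def predict(self, field_map: ChannelFieldMap, roi: np.ndarray) -> np.ndarray:
        """Relative flip-angle map of the fitted shim, ROI-mean calibrated."""
        self._check_fitted()
        return flip_angle_map(field_map, self.weights_, roi)

    def shim_vector(self) -> ShimVector:
        self._check_fitted()
        return ShimVector(self.weights_.copy())

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise AttributeError("estimator is not fitted yet; call fit first")


class CPModeShim(_BaseShim):
    """Reference circularly-polarised mode derived from element azimuths."""

    def fit(self, geometry: CoilGeometry, y=None) -> "CPModeShim":
        self.weights_ = cp_mode(geometry).weights
        self.n_channels_ = geometry.n_channels
        return self


class SubjectShim(_BaseShim):
    """Subject-specific constrained shim for one field map and region.

    Parameters
    ----------
    cost : {"efficiency", "coefficient_of_variation"}
        Scalar objective over the target region.
    mode : {"phase_magnitude", "phase_only"}
        Whether channel magnitudes are optimised or fixed equal.
    alpha_min, alpha_max : float
        Hard bounds on the region-mean-calibrated relative flip angle.
    w_max : float
        Hard cap on per-channel normalised weight magnitude.
    n_restarts : int
        Number of optimisation starts (deterministic phase-matched and CP
        starts first, then random phases).
    geometry : CoilGeometry, optional
        When given (and channel counts match), CP mode is one start.
    seed : int
        Seed for the random restarts.
    """

    def __init__(
        self,
        cost: str = "efficiency",
        mode: str = "phase_magnitude",
        alpha_min: float = 0.8,
        alpha_max: float = 1.3,
        w_max: float = 0.35,
        n_restarts: int = 32,
        geometry: CoilGeometry | None = None,
        seed: int = 0,
    ) -> None:
        self.cost = cost
        self.mode = mode
        self.alpha_min = alpha_min
        self.alpha_max = alpha_max
        self.w_max = w_max
        self.n_restarts = n_restarts
        self.geometry = geometry
        self.seed = seed

    def _constraints(self) -> ShimConstraints:
        return ShimConstraints(
            alpha_max=self.alpha_max, alpha_min=self.alpha_min,
            w_max=self.w_max, mode=self.mode,
        )

    def fit(self, field_map: ChannelFieldMap, roi: np.ndarray) -> "SubjectShim":
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        constraints = self._constraints()
        constraints.validate_for(field_map.n_channels)
        if self.cost not in COST_KINDS:
            raise ValueError(f"cost must be one of {COST_KINDS}")
        B = _roi_matrix(field_map, roi)
        problem = _ShimProblem(
            [B], self.cost, constraints, hard_alpha=True, joint_l2=False
        )
        w, cost, feasible, n_used = _solve(
            problem, self.n_restarts, self.seed, geometry=self.geometry
        )
        self.weights_ = w
        self.cost_ = cost
        self.n_channels_ = field_map.n_channels
        self.constraint_report_ = constraint_violations(field_map, w, constraints, roi)
        self.n_restarts_used_ = n_used
        self.converged_ = bool(feasible)
        return self

    def result(self) -> OptimizationResult:
        self._check_fitted()
        return OptimizationResult(
            shim=ShimVector(self.weights_.copy()),
            cost_value=self.cost_,
            constraint_report=self.constraint_report_,
            n_restarts_used=self.n_restarts_used_,
            converged=self.converged_,
        )


class UniversalShim(_BaseShim):
    """Population shim: joint L2-norm of per-subject objectives.

    Minimises sqrt(sum_s f_s(w)^2) over a training database, where f_s is
    the subject-specific cost on subject s's target region.  Flip-angle
    bounds enter as quadratic hinge penalties per subject; the channel
    weight cap remains a hard constraint.  The fitted vector applies to
    unseen subjects without any per-subject calibration beyond the usual
    power normalisation.
    """

    def __init__(
        self,
        cost: str = "efficiency",
        mode: str = "phase_magnitude",
        alpha_min: float = 0.8,
        alpha_max: float = 1.3,
        w_max: float = 0.35,
        cost_region: str = "roi",
        n_restarts: int = 32,
        geometry: CoilGeometry | None = None,
        seed: int = 0,
    ) -> None:
        self.cost = cost
        self.mode = mode
        self.alpha_min = alpha_min
        self.alpha_max = alpha_max
        self.w_max = w_max
        self.cost_region = cost_region
        self.n_restarts = n_restarts
        self.geometry = geometry
        self.seed = seed

    def fit(self, database, y=None, warm_starts=()) -> "UniversalShim":
        if len(database) < 1:
            raise ValueError("training database is empty")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        constraints = ShimConstraints(
            alpha_max=self.alpha_max, alpha_min=self.alpha_min,
            w_max=self.w_max, mode=self.mode,
        )
        n_channels = database[0].field_map.n_channels
        constraints.validate_for(n_channels)
        B_list = []
        for ds in database:
            mask = (
                ds.phantom.roi_mask if self.cost_region == "roi" else ds.phantom.brain_mask
            )
            B_list.append(_roi_matrix(ds.field_map, mask))
        problem = _ShimProblem(
            B_list, self.cost, constraints, hard_alpha=False, joint_l2=True
        )
        geometry = self.geometry or getattr(database, "geometry", None)
        w, cost, feasible, n_used = _solve(
            problem, self.n_restarts, self.seed, geometry=geometry,
            warm_starts=warm_starts,
        )
        self.weights_ = w
        self.cost_ = cost
        self.n_channels_ = n_channels
        self.n_restarts_used_ = n_used
        self.converged_ = bool(feasible)
        self.constraint_report_ = {"max_weight_mag": float(np.abs(w).max())}
        return self

    def result(self) -> OptimizationResult:
        self._check_fitted()
        return OptimizationResult(
            shim=ShimVector(self.weights_.copy()),
            cost_value=self.cost_,
            constraint_report=self.constraint_report_,
            n_restarts_used=self.n_restarts_used_,
            converged=self.converged_,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def optimize_subject(
    field_map: ChannelFieldMap,
    roi: np.ndarray,
    constraints: ShimConstraints | None = None,
    cost_spec: CostSpec | None = None,
    n_restarts: int = 32,
    seed: int = 0,
    geometry: CoilGeometry | None = None,
) -> OptimizationResult:
    """Fit a subject-specific shim; thin wrapper over :class:`SubjectShim`."""
    constraints = constraints or ShimConstraints()
    cost_spec = cost_spec or CostSpec()
    est = SubjectShim(
        cost=cost_spec.kind, mode=constraints.mode,
        alpha_min=constraints.alpha_min, alpha_max=constraints.alpha_max,
        w_max=constraints.w_max, n_restarts=n_restarts,
        geometry=geometry, seed=seed,
    )
    est.fit(field_map, roi)
    return est.result()


def optimize_universal(
    database,
    constraints: ShimConstraints | None = None,
    cost_spec: CostSpec | None = None,
    n_restarts: int = 32,
    seed: int = 0,
    geometry: CoilGeometry | None = None,
    warm_starts=(),
) -> OptimizationResult:
    """Fit a universal shim; thin wrapper over :class:`UniversalShim`."""
    constraints = constraints or ShimConstraints()
    cost_spec = cost_spec or CostSpec()
    est = UniversalShim(
        cost=cost_spec.kind, mode=constraints.mode,
        alpha_min=constraints.alpha_min, alpha_max=constraints.alpha_max,
        w_max=constraints.w_max, cost_region=cost_spec.region,
        n_restarts=n_restarts, geometry=geometry, seed=seed,
    )
    est.fit(database, warm_starts=warm_starts)
    return est.result()


def apply_shim(
    field_map: ChannelFieldMap,
    shim,
    roi: np.ndarray,
    constraints: ShimConstraints | None = None,
) -> tuple[np.ndarray, dict]:
    """Apply a shim to a subject: calibrated flip-angle map plus report."""
    constraints = constraints or ShimConstraints()
    w = _normalize(np.asarray(shim, dtype=complex).ravel())
    alpha = flip_angle_map(field_map, w, roi)
    report = constraint_violations(field_map, w, constraints, roi)
    return alpha, report
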