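"""Advanced optimum contribution selection (OCS).

Decision variable: the genetic contribution c_i of each selection candidate
to the next birth cohort (males total 1/2, females total 1/2).  Predicted
population means at the next evaluation are

* linear in c for numeric traits:            (r0 c + v)' X,
* quadratic for kinships:                    (r0 c + v)' F (r0 c + v) + l(c),
* rational for native kinships:              ratio of two such forms,

where r0 is the share of the population represented by the incoming cohort
and v are the weights of the existing individuals.  Exactly one criterion is
optimized; any other registered parameter can be bounded.  The small linear
correction l(c) is zero by default; an opt-in surrogate penalizing
self-contribution (drift at finite cohort size) is available, see
:func:`correction_coefficients`.

Backends
--------
``slsqp``
    Sequential least-squares quadratic programming from multiple feasible
    starts (the general-purpose path; the only recommended backend for the
    non-convex rational objective besides ``dinkelbach``).
``ip``
    Interior-point / trust-region convex backend (``trust-constr``) for
    linear or convex-quadratic objectives under quadratic and rational
    constraints; rejects rational objectives, which are non-convex.
``dinkelbach``
    Fractional programming for rational objectives: iterates parametric
    subproblems min N(c) - lambda D(c), whose optimum lambda* equals the
    optimal ratio.
``brute``
    Simplex-grid search with refinement; exact-ish oracle for problems with
    at most five free candidates, intended for tests.

Every returned solution is revalidated from scratch, independent of the
backend's own claim of success.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import KinshipMatrix, NativeKinshipComponents
from .population import PopulationState

__all__ = [
    "OCSProblem",
    "OCSSolution",
    "OCSError",
    "build_problem",
    "solve",
    "validate",
    "predicted_mean_linear",
    "predicted_mean_kinship",
    "predicted_mean_native_kinship",
]

CONSTRAINT_RTOL = 1e-6   # relative feasibility tolerance defining "valid"
SEXSUM_TOL = 1e-8
BOUND_TOL = 1e-8


class OCSError(ValueError):
    pass


# ---------------------------------------------------------------------------
# predicted means
# ---------------------------------------------------------------------------

def _full_contribution(state: PopulationState, c) -> np.ndarray:
    """Zero-pad a candidate contribution vector to all phen individuals."""
    c = np.asarray(c, dtype=float)
    n = len(state.phen)
    if len(c) == n:
        return c
    mask = state.candidate_mask()
    if len(c) != mask.sum():
        raise OCSError(f"contribution vector length {len(c)} matches neither "
                       f"candidates ({mask.sum()}) nor phen ({n})")
    full = np.zeros(n)
    full[mask] = c
    return full


def correction_coefficients(state: PopulationState, F: np.ndarray,
                            mode: str, N0: int) -> np.ndarray:
    """Per-candidate coefficients of the linear correction term l(c).

    Mode "none" gives l = 0.  Mode "self" is a documented surrogate for the
    drift term at finite cohort size N0: l(c) = r0^2/(2 N0) * sum_i c_i F_ii,
    charging each candidate its self-kinship in proportion to its use.
    """
    n = len(state.phen)
    if mode == "none":
        return np.zeros(n)
    if mode == "self":
        return (state.r0 ** 2) / (2.0 * N0) * np.diag(F)
    raise OCSError(f"unknown correction mode {mode!r}")


def predicted_mean_linear(state: PopulationState, X, c) -> float:
    """Predicted mean (r0 c + v)' X of a numeric column at t+1."""
    if isinstance(X, str):
        X = state.phen[X].to_numpy(dtype=float)
    u = state.r0 * _full_contribution(state, c) + state.v
    return float(u @ np.asarray(X, dtype=float))


def predicted_mean_kinship(state: PopulationState, F, c,
                           correction: str = "none", N0: int = 200) -> float:
    """Predicted mean kinship (r0 c + v)' F (r0 c + v) + l(c) at t+1."""
    if isinstance(F, str):
        F = state.kinships[F]
    if isinstance(F, KinshipMatrix):
        F = F.submatrix(state.ids).values
    F = np.asarray(F, dtype=float)
    cf = _full_contribution(state, c)
    u = state.r0 * cf + state.v
    l = correction_coefficients(state, F, correction, N0) @ cf
    return float(u @ F @ u + l)


def predicted_mean_native_kinship(state: PopulationState, comp, c,
                                  correction: str = "none",
                                  N0: int = 200) -> float:
    """Predicted mean native kinship at t+1: ratio of the corrected
    numerator and denominator quadratic forms."""
    if isinstance(comp, str):
        comp = state.kinships[comp]
    if not isinstance(comp, NativeKinshipComponents):
        raise OCSError("expected NativeKinshipComponents")
    sub = comp.submatrix(state.ids)
    num = predicted_mean_kinship(state, sub.numerator.values, c, correction, N0)
    den = predicted_mean_kinship(state, sub.denominator.values, c, correction, N0)
    if den <= 0:
        raise OCSError("planned offspring carry no native genetic material "
                       "(zero both-native probability)")
    return num / den


# ---------------------------------------------------------------------------
# problem construction
# ---------------------------------------------------------------------------

@dataclass
class Constraint:
    kind: str   # linear-lb | linear-ub | quadratic-ub | rational-ub
    name: str
    bound: float


@dataclass
class OCSProblem:
    state: PopulationState
    direction: str           # max | min
    criterion: str
    criterion_kind: str      # linear | quadratic | rational
    constraints: list[Constraint]
    candidate_ids: list[str]
    free: np.ndarray         # bool over candidates
    c_fixed: np.ndarray      # fixed contributions (uniform sex), 0 for free
    lb: np.ndarray           # over free variables
    ub: np.ndarray
    sex_groups: list[tuple[np.ndarray, float]]  # (mask over free vars, total)
    uniform: str | None = None
    correction: str = "none"
    N0: int = 200
    # cached affine map u = A x + b over phen individuals
    _A: np.ndarray = field(default=None, repr=False)
    _b: np.ndarray = field(default=None, repr=False)

    @property
    def n_free(self) -> int:
        return int(self.free.sum())

    def full_candidate_vector(self, x: np.ndarray) -> np.ndarray:
        c = self.c_fixed.copy()
        c[self.free] = x
        return c


def _resolve_kind(state: PopulationState, name: str) -> str:
    if name in state.kinships:
        obj = state.kinships[name]
        return ("rational" if isinstance(obj, NativeKinshipComponents)
                else "quadratic")
    if name in state.numeric_columns:
        return "linear"
    valid = sorted(state.numeric_columns) + sorted(state.kinships)
    raise OCSError(f"unknown parameter {name!r}; valid names: {valid}")


def build_problem(
    state: PopulationState,
    objective: str,
    constraints: dict[str, float] | None = None,
    lb=None,
    ub=None,
    uniform: str | None = None,
    correction: str = "none",
    N0: int = 200,
) -> OCSProblem:
    """Assemble an OCS problem.

    ``objective`` is "max.NAME" or "min.NAME" where NAME is a numeric
    column, kinship, or native kinship registered in the state (exactly one
    criterion).  ``constraints`` maps "ub.NAME"/"lb.NAME" to bounds;
    kinships become quadratic constraints and native kinships rational
    constraints.  ``lb``/``ub`` are per-candidate contribution bounds
    (scalar or mapping id -> value).  ``uniform`` fixes one sex's
    contributions to equal within-class shares and removes that sex from
    the decision vector.
    """
    m = re.fullmatch(r"(max|min)\.([A-Za-z0-9_.]+)", objective.strip())
    if m is None:
        raise OCSError(
            f"objective must be a single 'max.NAME' or 'min.NAME' "
            f"criterion, got {objective!r}")
    direction, crit = m.group(1), m.group(2)
    crit_kind = _resolve_kind(state, crit)

    cons: list[Constraint] = []
    for key, bound in (constraints or {}).items():
        km = re.fullmatch(r"(ub|lb)\.([A-Za-z0-9_.]+)", key)
        if km is None:
            raise OCSError(f"constraint key {key!r} must look like "
                           f"'ub.NAME' or 'lb.NAME'")
        side, name = km.group(1), km.group(2)
        kind = _resolve_kind(state, name)
        if kind != "linear" and side == "lb":
            raise OCSError(f"lower bounds on {kind} parameters are not "
                           f"supported ({key})")
        cons.append(Constraint(f"{kind}-{side}", name, float(bound)))

    cand = state.candidates
    cand_ids = cand["Indiv"].tolist()
    ncand = len(cand_ids)
    if ncand == 0:
        raise OCSError("no selection candidates")
    sex = cand["Sex"].fillna("unknown").to_numpy()
    known = np.isin(sex, ("male", "female"))
    if known.any() and not known.all():
        raise OCSError("candidates mix known and unknown sex; label all "
                       "candidates or none")

    free = np.ones(ncand, dtype=bool)
    c_fixed = np.zeros(ncand)
    if uniform is not None:
        if uniform not in ("male", "female"):
            raise OCSError("uniform must be 'male' or 'female'")
        umask = sex == uniform
        if not umask.any():
            raise OCSError(f"no {uniform} candidates for uniform mode")
        free = ~umask
        ages = cand["Age"].to_numpy()
        weights = np.zeros(ncand)
        for k in np.flatnonzero(umask):
            a = ages[k]
            w = state.cont.contribution(int(a), uniform) if pd.notna(a) else 0.0
            weights[k] = w
        if weights.sum() <= 0:
            weights[umask] = 1.0
        c_fixed[umask] = 0.5 * weights[umask] / weights[umask].sum()

    # per-candidate bounds on the free variables
    sex_total = {True: 0.5, False: 1.0}[bool(known.any())]
    lb_vec = np.zeros(ncand)
    ub_vec = np.full(ncand, sex_total)

    def _fill(vec, spec):
        if spec is None:
            return
        if np.isscalar(spec):
            vec[:] = float(spec)
        elif isinstance(spec, dict):
            pos = {cid: k for k, cid in enumerate(cand_ids)}
            for cid, val in spec.items():
                if str(cid) not in pos:
                    raise OCSError(f"bound for unknown candidate {cid!r}")
                vec[pos[str(cid)]] = float(val)
        else:
            arr = np.asarray(spec, dtype=float)
            if len(arr) != ncand:
                raise OCSError("bound vector length mismatch")
            vec[:] = arr

    _fill(lb_vec, lb)
    _fill(ub_vec, ub)
    if np.any(lb_vec > ub_vec + 1e-15):
        raise OCSError("lb exceeds ub for some candidate")

    sex_groups: list[tuple[np.ndarray, float]] = []
    if known.any():
        for s in ("male", "female"):
            m_free = (sex == s) & free
            if uniform == s:
                continue
            total = 0.5 - c_fixed[sex == s].sum()
            if m_free.any():
                sex_groups.append((m_free[free], total))
    else:
        sex_groups.append((np.ones(int(free.sum()), dtype=bool), 1.0))

    prob = OCSProblem(
        state=state, direction=direction, criterion=crit,
        criterion_kind=crit_kind, constraints=cons,
        candidate_ids=cand_ids, free=free, c_fixed=c_fixed,
        lb=lb_vec[free], ub=ub_vec[free], sex_groups=sex_groups,
        uniform=uniform, correction=correction, N0=N0,
    )
    _attach_affine(prob)
    return prob


def _attach_affine(prob: OCSProblem) -> None:
    state = prob.state
    n = len(state.phen)
    mask = state.candidate_mask()
    cand_rows = np.flatnonzero(mask)
    free_rows = cand_rows[prob.free]
    k = len(free_rows)
    A = np.zeros((n, k))
    A[free_rows, np.arange(k)] = state.r0
    b = state.v.copy()
    b[cand_rows] += state.r0 * prob.c_fixed
    prob._A = A
    prob._b = b


# -- scalar parameter evaluators over the free variables x ------------------

class _Quad:
    """q(x) = x'Qx + g'x + c for (Ax+b)' F (Ax+b) + l(c(x))."""

    def __init__(self, prob: OCSProblem, F: np.ndarray):
        A, b = prob._A, prob._b
        lcoef = correction_coefficients(prob.state, F, prob.correction,
                                        prob.N0)
        mask = prob.state.candidate_mask()
        l_free = lcoef[np.flatnonzero(mask)[prob.free]]
        l_const = lcoef[np.flatnonzero(mask)] @ prob.c_fixed
        FA = F @ A
        self.Q = A.T @ FA
        self.g = 2.0 * (FA.T @ b) + l_free
        self.c = float(b @ F @ b) + l_const

    def __call__(self, x):
        return float(x @ self.Q @ x + self.g @ x + self.c)

    def grad(self, x):
        return 2.0 * self.Q @ x + self.g


class _Lin:
    def __init__(self, prob: OCSProblem, X: np.ndarray):
        self.a = prob._A.T @ X
        self.c = float(prob._b @ X)

    def __call__(self, x):
        return float(self.a @ x + self.c)

    def grad(self, x):
        return self.a


def _evaluator(prob: OCSProblem, name: str):
    """Return (kind, value_fn) for a registered parameter name (cached)."""
    cache = prob.__dict__.setdefault("_eval_cache", {})
    if name in cache:
        return cache[name]
    state = prob.state
    kind = _resolve_kind(state, name)
    if kind == "linear":
        out = kind, _Lin(prob, state.phen[name].to_numpy(dtype=float))
    elif kind == "quadratic":
        obj = state.kinships[name]
        out = kind, _Quad(prob, obj.submatrix(state.ids).values)
    else:
        sub = state.kinships[name].submatrix(state.ids)
        out = kind, (_Quad(prob, sub.numerator.values),
                     _Quad(prob, sub.denominator.values))
    cache[name] = out
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(problem: OCSProblem, c) -> dict:
    """Recheck every constraint, bound, and sex sum for contributions ``c``
    (over candidates), independently of any solver output."""
    c = np.asarray(c, dtype=float)
    if len(c) != len(problem.candidate_ids):
        raise OCSError("contribution vector must cover all candidates")
    x = c[problem.free]
    violations: list[tuple[str, float]] = []

    for mask, total in problem.sex_groups:
        dev = abs(x[mask].sum() - total)
        if dev > SEXSUM_TOL:
            violations.append((f"sex sum (target {total:.6g})", dev))
    if np.any(x < problem.lb - BOUND_TOL) or np.any(x > problem.ub + BOUND_TOL):
        worst = max(np.max(problem.lb - x, initial=0.0),
                    np.max(x - problem.ub, initial=0.0))
        violations.append(("per-candidate bounds", float(worst)))

    for con in problem.constraints:
        kind, ev = _evaluator(problem, con.name)
        if kind == "rational":
            num, den = ev
            d = den(x)
            val = num(x) / d if d > 0 else np.inf
        else:
            val = ev(x)
        tol = CONSTRAINT_RTOL * max(1.0, abs(con.bound))
        if con.kind.endswith("ub") and val > con.bound + tol:
            violations.append((f"{con.kind} {con.name} <= {con.bound:.6g}",
                               float(val - con.bound)))
        elif con.kind.endswith("lb") and val < con.bound - tol:
            violations.append((f"{con.kind} {con.name} >= {con.bound:.6g}",
                               float(con.bound - val)))

    worst = max((v for _, v in violations), default=0.0)
    return {"valid": not violations,
            "violations": violations,
            "worst_violation": worst}


def diagnose_feasibility(problem: OCSProblem) -> list[str]:
    """Check the equal-contribution point and explain which constraints it
    violates although the current population already meets them."""
    x0 = _equal_point(problem)
    info = validate(problem, problem.full_candidate_vector(x0))
    notes = []
    for desc, amount in info["violations"]:
        notes.append(f"equal-contribution point violates {desc} "
                     f"by {amount:.3g}")
    return notes


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------

@dataclass
class OCSSolution:
    c: pd.Series                # contributions per candidate (incl. fixed)
    objective_value: float
    mean: dict[str, float]      # predicted means at t+1
    info: dict
    parent: pd.DataFrame = None  # candidate table with column oc


def _objective_funcs(prob: OCSProblem):
    kind, ev = _evaluator(prob, prob.criterion)
    sign = -1.0 if prob.direction == "max" else 1.0
    if kind == "rational":
        num, den = ev

        def f(x):
            d = den(x)
            return sign * (num(x) / d) if d > 0 else np.inf

        def g(x):
            d = den(x)
            nv = num(x)
            return sign * (num.grad(x) * d - nv * den.grad(x)) / d ** 2

        def raw(x):
            d = den(x)
            return num(x) / d if d > 0 else np.inf
    else:
        def f(x):
            return sign * ev(x)

        def g(x):
            return sign * ev.grad(x)

        def raw(x):
            return ev(x)
    return f, g, raw


def _scipy_constraints(prob: OCSProblem):
    cons = []
    for mask, total in prob.sex_groups:
        a = mask.astype(float)
        cons.append({"type": "eq",
                     "fun": (lambda x, a=a, t=total: a @ x - t),
                     "jac": (lambda x, a=a: a)})
    for con in prob.constraints:
        kind, ev = _evaluator(prob, con.name)
        if kind == "rational":
            num, den = ev
            b = con.bound
            # num(x) - b * den(x) <= 0, a quadratic difference
            cons.append({"type": "ineq",
                         "fun": (lambda x, num=num, den=den, b=b:
                                 b * den(x) - num(x)),
                         "jac": (lambda x, num=num, den=den, b=b:
                                 b * den.grad(x) - num.grad(x))})
        elif con.kind.endswith("ub"):
            cons.append({"type": "ineq",
                         "fun": (lambda x, ev=ev, b=con.bound: b - ev(x)),
                         "jac": (lambda x, ev=ev: -ev.grad(x))})
        else:
            cons.append({"type": "ineq",
                         "fun": (lambda x, ev=ev, b=con.bound: ev(x) - b),
                         "jac": (lambda x, ev=ev: ev.grad(x))})
    return cons


def _equal_point(prob: OCSProblem) -> np.ndarray:
    x = np.zeros(prob.n_free)
    for mask, total in prob.sex_groups:
        k = mask.sum()
        if k:
            x[mask] = total / k
    return np.clip(x, prob.lb, prob.ub)


def _random_points(prob: OCSProblem, rng, n: int) -> list[np.ndarray]:
    pts = []
    for _ in range(n):
        x = np.zeros(prob.n_free)
        for mask, total in prob.sex_groups:
            k = int(mask.sum())
            if k:
                x[mask] = rng.dirichlet(np.ones(k)) * total
        pts.append(np.clip(x, prob.lb, prob.ub))
    return pts


def _project_sex_sums(prob: OCSProblem, x: np.ndarray) -> np.ndarray:
    """Rescale within each sex group to restore the exact group totals."""
    x = np.clip(x, prob.lb, prob.ub)
    for mask, total in prob.sex_groups:
        s = x[mask].sum()
        if s > 0:
            x[mask] *= total / s
    return x


def _solve_slsqp(prob: OCSProblem, seed: int, n_starts: int,
                 maxiter: int = 500):
    f, g, raw = _objective_funcs(prob)
    cons = _scipy_constraints(prob)
    bounds = list(zip(prob.lb, prob.ub))
    rng = np.random.default_rng(seed)
    starts = [_equal_point(prob)] + _random_points(prob, rng, n_starts - 1)
    best = None
    for x0 in starts:
        res = optimize.minimize(f, x0, jac=g, bounds=bounds,
                                constraints=cons, method="SLSQP",
                                options={"maxiter": maxiter, "ftol": 1e-12})
        x = _project_sex_sums(prob, res.x)
        info = validate(prob, prob.full_candidate_vector(x))
        score = (not info["valid"], f(x) if info["valid"]
                 else info["worst_violation"])
        if best is None or score < best[0]:
            best = (score, x, res.message, info)
    _, x, message, info = best
    return x, str(message), info


def _solve_ip(prob: OCSProblem, maxiter: int = 1000):
    if prob.criterion_kind == "rational":
        raise OCSError("the 'ip' backend handles linear or convex-quadratic "
                       "objectives only; use 'dinkelbach' or 'slsqp' for a "
                       "rational (native-kinship) objective")
    f, g, raw = _objective_funcs(prob)
    k = prob.n_free
    kind, ev = _evaluator(prob, prob.criterion)
    sign = -1.0 if prob.direction == "max" else 1.0
    if kind == "quadratic":
        hess = lambda x: sign * 2.0 * ev.Q
    else:
        hess = lambda x: np.zeros((k, k))
    constraints = []
    for mask, total in prob.sex_groups:
        constraints.append(optimize.LinearConstraint(
            mask.astype(float)[None, :], total, total))
    for con in prob.constraints:
        kind, ev = _evaluator(prob, con.name)
        if kind == "linear":
            lo = con.bound if con.kind.endswith("lb") else -np.inf
            hi = con.bound if con.kind.endswith("ub") else np.inf
            constraints.append(optimize.LinearConstraint(
                ev.a[None, :], lo - ev.c, hi - ev.c))
        elif kind == "quadratic":
            constraints.append(optimize.NonlinearConstraint(
                (lambda x, ev=ev: ev(x)), -np.inf, con.bound,
                jac=(lambda x, ev=ev: ev.grad(x)[None, :]),
                hess=(lambda x, v, ev=ev: 2.0 * v[0] * ev.Q)))
        else:  # rational-ub as quadratic difference num - b*den <= 0
            num, den = ev
            b = con.bound
            constraints.append(optimize.NonlinearConstraint(
                (lambda x, num=num, den=den, b=b: num(x) - b * den(x)),
                -np.inf, 0.0,
                jac=(lambda x, num=num, den=den, b=b:
                     (num.grad(x) - b * den.grad(x))[None, :]),
                hess=(lambda x, v, num=num, den=den, b=b:
                      2.0 * v[0] * (num.Q - b * den.Q))))
    res = optimize.minimize(
        f, _equal_point(prob), jac=g, hess=hess, method="trust-constr",
        bounds=optimize.Bounds(prob.lb, prob.ub),
        constraints=constraints,
        options={"maxiter": maxiter, "gtol": 1e-12, "xtol": 1e-14,
                 "barrier_tol": 1e-12})
    x = _project_sex_sums(prob, res.x)
    info = validate(prob, prob.full_candidate_vector(x))
    return x, str(res.message), info


def _solve_dinkelbach(prob: OCSProblem, seed: int, n_starts: int,
                      max_outer: int = 50, tol: float = 1e-10):
    if prob.criterion_kind != "rational":
        raise OCSError("the 'dinkelbach' backend requires a rational "
                       "(native-kinship) objective")
    _, ev = _evaluator(prob, prob.criterion)
    num, den = ev
    sign = -1.0 if prob.direction == "max" else 1.0
    cons = _scipy_constraints(prob)
    bounds = list(zip(prob.lb, prob.ub))
    rng = np.random.default_rng(seed)
    starts = [_equal_point(prob)] + _random_points(prob, rng, n_starts - 1)
    best = None
    for x0 in starts:
        x = x0
        d = den(x)
        if d <= 0:
            continue
        lam = num(x) / d
        lambdas = [lam]
        for _ in range(max_outer):
            def fsub(z, lam=lam):
                return sign * (num(z) - lam * den(z))

            def gsub(z, lam=lam):
                return sign * (num.grad(z) - lam * den.grad(z))

            res = optimize.minimize(fsub, x, jac=gsub, bounds=bounds,
                                    constraints=cons, method="SLSQP",
                                    options={"maxiter": 300, "ftol": 1e-14})
            x = res.x
            d = den(x)
            if d <= 0:
                break
            new_lam = num(x) / d
            lambdas.append(new_lam)
            if abs(num(x) - lam * d) < tol or abs(new_lam - lam) < tol:
                lam = new_lam
                break
            lam = new_lam
        x = _project_sex_sums(prob, x)
        info = validate(prob, prob.full_candidate_vector(x))
        score = (not info["valid"], sign * lam if info["valid"]
                 else info["worst_violation"])
        if best is None or score < best[0]:
            best = (score, x, lambdas, info)
    if best is None:
        raise OCSError("no start with positive native denominator")
    _, x, lambdas, info = best
    info["lambdas"] = lambdas
    msg = (f"dinkelbach converged in {len(lambdas) - 1} iterations, "
           f"lambda={lambdas[-1]:.8g}")
    return x, msg, info


def _simplex_grid(k: int, t: int):
    """All length-k nonnegative integer vectors summing to t."""
    if k == 1:
        yield (t,)
        return
    for first in range(t + 1):
        for rest in _simplex_grid(k - 1, t - first):
            yield (first,) + rest


def _solve_brute(prob: OCSProblem, divisions: int = 6, refinements: int = 3):
    if prob.n_free > 5:
        raise OCSError("brute backend supports at most 5 free candidates")
    f, g, raw = _objective_funcs(prob)

    groups = [(np.flatnonzero(mask), total)
              for mask, total in prob.sex_groups]

    def candidates_at(steps):
        grids = []
        for (idx, total), step in zip(groups, steps):
            t = max(1, round(total / step))
            pts = [np.array(v) * (total / t) for v in
                   _simplex_grid(len(idx), t)]
            grids.append(pts)
        for combo in product(*grids):
            x = np.zeros(prob.n_free)
            for (idx, _), vals in zip(groups, combo):
                x[idx] = vals
            yield x

    def neighborhood(center, steps, span=4):
        grids = []
        for (idx, total), step in zip(groups, steps):
            base = center[idx]
            local = []
            for off in _offsets(len(idx), span):
                v = base + np.array(off) * step
                if np.all(v >= -1e-12):
                    local.append(np.clip(v, 0, None))
            grids.append(local)
        for combo in product(*grids):
            x = np.zeros(prob.n_free)
            for (idx, _), vals in zip(groups, combo):
                x[idx] = vals
            yield x

    def feasible(x):
        if np.any(x < prob.lb - BOUND_TOL) or np.any(x > prob.ub + BOUND_TOL):
            return False
        info = validate(prob, prob.full_candidate_vector(x))
        return info["valid"]

    steps = [total / divisions for _, total in groups]
    best_x, best_val = None, np.inf
    for x in candidates_at(steps):
        if feasible(x):
            val = f(x)
            if val < best_val:
                best_val, best_x = val, x
    for _ in range(refinements):
        if best_x is None:
            break
        steps = [s / 4.0 for s in steps]
        for x in neighborhood(best_x, steps):
            if feasible(x):
                val = f(x)
                if val < best_val:
                    best_val, best_x = val, x
    if best_x is None:
        info = {"valid": False, "violations": [("no feasible grid point", 0.0)],
                "worst_violation": np.inf}
        return _equal_point(prob), "brute: no feasible point found", info
    info = validate(prob, prob.full_candidate_vector(best_x))
    return best_x, "brute grid search", info


def _offsets(k: int, span: int):
    """Integer offset vectors summing to 0 with |d_i| <= span."""
    if k == 1:
        yield (0,)
        return
    for combo in product(range(-span, span + 1), repeat=k - 1):
        last = -sum(combo)
        if -span <= last <= span:
            yield combo + (last,)


_BACKENDS = {"slsqp", "ip", "dinkelbach", "brute"}


def solve(problem: OCSProblem, backend: str = "slsqp", seed: int = 0,
          n_starts: int = 5, **tuning) -> OCSSolution:
    """Solve an OCS problem with the given backend; the returned validity
    flag comes from an independent recheck of every constraint."""
    if backend not in _BACKENDS:
        raise OCSError(f"unknown backend {backend!r}; available: "
                       f"{sorted(_BACKENDS)}")
    if backend == "slsqp":
        x, status, info = _solve_slsqp(problem, seed, n_starts, **tuning)
    elif backend == "ip":
        x, status, info = _solve_ip(problem, **tuning)
    elif backend == "dinkelbach":
        x, status, info = _solve_dinkelbach(problem, seed, n_starts, **tuning)
    else:
        x, status, info = _solve_brute(problem, **tuning)

    _, _, raw = _objective_funcs(problem)
    c = problem.full_candidate_vector(x)
    state = problem.state

    means: dict[str, float] = {}
    for col in state.numeric_columns:
        means[col] = predicted_mean_linear(state, col, c)
    for name, obj in state.kinships.items():
        if isinstance(obj, NativeKinshipComponents):
            means[name] = predicted_mean_native_kinship(
                state, obj, c, problem.correction, problem.N0)
        else:
            means[name] = predicted_mean_kinship(
                state, obj, c, problem.correction, problem.N0)

    full_info = {"valid": info["valid"], "status": status,
                 "solver": backend,
                 "worst_violation": info["worst_violation"],
                 "violations": info["violations"]}
    if "lambdas" in info:
        full_info["lambdas"] = info["lambdas"]
    if not info["valid"]:
        full_info["diagnostics"] = diagnose_feasibility(problem)

    cser = pd.Series(c, index=problem.candidate_ids, name="oc")
    parent = state.candidates.copy()
    parent["oc"] = c
    return OCSSolution(c=cser, objective_value=float(raw(x)),
                       mean=means, info=full_info, parent=parent)
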