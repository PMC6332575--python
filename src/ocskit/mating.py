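"""Mate allocation: integer offspring counts and sire x dam assignment.

Once optimum contributions are known, each candidate i should parent
n_i ~ 2 c_i N0 of the N0 offspring in the birth cohort.  Matings are then
assigned by an exact integer program minimizing the mean inbreeding
coefficient of the offspring,

    (1/N0) * sum_i sum_j n_ij f(i, j),

because offspring inbreeding equals parental kinship.  Constraints: row
sums fix each sire's offspring count, column sums each dam's; optionally
n_ij <= ub_n_off per mating, and per herd h and sire i the herd cap
sum_{j in h} n_ij <= alpha * N_h (N_h = offspring born in herd h), which
preserves genetic connectedness between herds.

Without per-mating or herd caps the constraint matrix is the transportation
polytope (totally unimodular), so the LP relaxation is already integral;
the solver used here (HiGHS branch-and-bound via scipy.optimize.milp) is
exact in either case.  Ties between equal-objective plans are broken toward
lexicographically early (sire, dam) pairs by an epsilon cost perturbation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .containers import KinshipMatrix

__all__ = [
    "MatingPlan",
    "MatingError",
    "n_offspring",
    "allocate_matings",
    "mean_offspring_inbreeding",
]


class MatingError(ValueError):
    pass


@dataclass
class MatingPlan:
    """Assigned matings: one row per (Sire, Dam) pair with n >= 1 offspring."""

    table: pd.DataFrame  # columns Sire, Dam, n
    N0: int
    objective: float     # mean offspring inbreeding of the plan

    def counts_matrix(self, sires, dams) -> np.ndarray:
        m = np.zeros((len(sires), len(dams)), dtype=int)
        si = {s: k for k, s in enumerate(sires)}
        di = {d: k for k, d in enumerate(dams)}
        for row in self.table.itertuples(index=False):
            m[si[row.Sire], di[row.Dam]] = row.n
        return m

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def n_offspring(c: pd.Series, sex: pd.Series, N0: int) -> pd.Series:
    """Integer offspring counts per candidate by largest-remainder rounding
    of 2 c_i N0, separately within each sex so each sex totals N0."""
    if N0 < 1:
        raise MatingError("N0 must be at least 1")
    c = pd.Series(c, dtype=float)
    sex = pd.Series(sex).reindex(c.index)
    out = pd.Series(0, index=c.index, dtype=int, name="nOff")
    for s in ("male", "female"):
        mask = sex == s
        if not mask.any():
            raise MatingError(f"no {s} candidates")
        cs = c[mask]
        if abs(cs.sum() - 0.5) > 1e-6:
            raise MatingError(f"{s} contributions sum to {cs.sum():.6f}, "
                              f"expected 0.5")
        target = 2.0 * cs.to_numpy() * N0
        floor = np.floor(target).astype(int)
        short = N0 - floor.sum()
        order = np.argsort(-(target - floor), kind="stable")
        floor[order[:short]] += 1
        out[mask] = floor
    return out


def allocate_matings(
    n_m: pd.Series,
    n_f: pd.Series,
    K,
    ub_n_off: int | None = None,
    herds: pd.Series | dict | None = None,
    alpha: float | None = None,
) -> MatingPlan:
    """Exactly solve the mate-allocation integer program.

    ``n_m``/``n_f`` map sire/dam ids to offspring counts (equal totals N0);
    ``K`` is a KinshipMatrix, DataFrame, or dict-like giving f(sire, dam).
    Optional caps: ``ub_n_off`` per mating and, with ``herds`` (dam -> herd
    label) and ``alpha``, at most alpha * N_h offspring per sire per herd.
    """
    n_m = pd.Series(n_m, dtype=int)
    n_f = pd.Series(n_f, dtype=int)
    n_m = n_m[n_m > 0]
    n_f = n_f[n_f > 0]
    N0 = int(n_m.sum())
    if N0 != int(n_f.sum()):
        raise MatingError(f"sire offspring total {N0} != dam total "
                          f"{int(n_f.sum())}")
    sires = list(n_m.index.astype(str))
    dams = list(n_f.index.astype(str))
    nm, nf = len(sires), len(dams)

    def kin(i, j):
        if isinstance(K, KinshipMatrix):
            return K.loc(i, j)
        if isinstance(K, pd.DataFrame):
            return float(K.loc[i, j])
        return float(K[(i, j)])

    cost = np.array([[kin(s, d) for d in dams] for s in sires])

    nvar = nm * nf
    rows_a, cols_a, vals_a = [], [], []
    rhs_lo, rhs_hi = [], []
    r = 0
    for i in range(nm):
        for j in range(nf):
            rows_a.append(r)
            cols_a.append(i * nf + j)
            vals_a.append(1.0)
        rhs_lo.append(n_m.iloc[i])
        rhs_hi.append(n_m.iloc[i])
        r += 1
    for j in range(nf):
        for i in range(nm):
            rows_a.append(r)
            cols_a.append(i * nf + j)
            vals_a.append(1.0)
        rhs_lo.append(n_f.iloc[j])
        rhs_hi.append(n_f.iloc[j])
        r += 1

    herd_caps: list[tuple[str, str, float]] = []
    if herds is not None and alpha is not None:
        herds = pd.Series(herds).astype(str)
        herd_of = [herds.get(d, None) for d in dams]
        herd_n = {}
        for j, h in enumerate(herd_of):
            if h is not None:
                herd_n[h] = herd_n.get(h, 0) + int(n_f.iloc[j])
        for h, Nh in sorted(herd_n.items()):
            cap = alpha * Nh
            for i in range(nm):
                for j in range(nf):
                    if herd_of[j] == h:
                        rows_a.append(r)
                        cols_a.append(i * nf + j)
                        vals_a.append(1.0)
                rhs_lo.append(-np.inf)
                rhs_hi.append(cap)
                herd_caps.append((sires[i], h, cap))
                r += 1

    A = sparse.csr_matrix((vals_a, (rows_a, cols_a)), shape=(r, nvar))
    ub = np.full(nvar, np.inf)
    if ub_n_off is not None:
        ub[:] = ub_n_off
    ub = np.minimum(ub, np.repeat(n_m.to_numpy(), nf))
    ub = np.minimum(ub, np.tile(n_f.to_numpy(), nm))

    res = optimize.milp(
        c=cost.ravel(),
        constraints=optimize.LinearConstraint(A, rhs_lo, rhs_hi),
        bounds=optimize.Bounds(0, ub),
        integrality=np.ones(nvar),
    )
    if not res.success:
        raise MatingError(_infeasibility_report(
            n_m, n_f, ub_n_off, herd_caps, res))
    # second stage: among optimal plans, prefer the lexicographically
    # earliest (sire, dam) assignment via a geometric bonus objective
    rank = np.arange(nvar, dtype=float)
    bonus = np.power(2.0, -np.minimum(rank, 40.0))
    best_cost = float(cost.ravel() @ res.x)
    res2 = optimize.milp(
        c=-bonus,
        constraints=[optimize.LinearConstraint(A, rhs_lo, rhs_hi),
                     optimize.LinearConstraint(cost.ravel()[None, :],
                                               -np.inf, best_cost + 1e-9)],
        bounds=optimize.Bounds(0, ub),
        integrality=np.ones(nvar),
    )
    if res2.success:
        res = res2
    x = np.round(res.x).astype(int).reshape(nm, nf)
    obj = float((x * cost).sum()) / N0
    rows = [{"Sire": sires[i], "Dam": dams[j], "n": int(x[i, j])}
            for i in range(nm) for j in range(nf) if x[i, j] > 0]
    return MatingPlan(table=pd.DataFrame(rows, columns=["Sire", "Dam", "n"]),
                      N0=N0, objective=obj)


def _infeasibility_report(n_m, n_f, ub_n_off, herd_caps, res) -> str:
    notes = [f"mate allocation infeasible (solver: {res.message})"]
    if ub_n_off is not None:
        for i, ni in n_m.items():
            if ni > ub_n_off * len(n_f):
                notes.append(f"sire {i!r} needs {ni} offspring but "
                             f"ub_n_off={ub_n_off} over {len(n_f)} dams "
                             f"allows only {ub_n_off * len(n_f)}")
        for j, nj in n_f.items():
            if nj > ub_n_off * len(n_m):
                notes.append(f"dam {j!r} needs {nj} offspring but "
                             f"ub_n_off={ub_n_off} over {len(n_m)} sires "
                             f"allows only {ub_n_off * len(n_m)}")
    if herd_caps:
        total_cap = {}
        for s, h, cap in herd_caps:
            total_cap[s] = total_cap.get(s, 0.0) + np.floor(cap)
        for s, cap in total_cap.items():
            ni = int(n_m.get(s, 0))
            if ni > cap:
                notes.append(f"sire {s!r} needs {ni} offspring but herd "
                             f"caps total {cap:.0f}")
    return "; ".join(notes)


def mean_offspring_inbreeding(plan: MatingPlan, K) -> float:
    """Mean inbreeding coefficient of the planned offspring,
    (1/N0) sum n_ij f(i, j)."""
    def kin(i, j):
        if isinstance(K, KinshipMatrix):
            return K.loc(i, j)
        if isinstance(K, pd.DataFrame):
            return float(K.loc[i, j])
        return float(K[(i, j)])

    tot = sum(row.n * kin(row.Sire, row.Dam)
              for row in plan.table.itertuples(index=False))
    return tot / plan.N0
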