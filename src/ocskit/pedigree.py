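"""Pedigree ingestion, repair, and pedigree-based genetic parameters.

The central quantity is the geneological coancestry (pedigree kinship)
f_PED(i, j): the probability that one allele sampled from i and one from j
are copies of the same founder allele, computed by the tabular method in
topological order.  On top of the same recursion machinery this module
provides

* equivalent complete generations (pedigree completeness),
* breed composition: the genetic contribution of founder origin classes
  (native breed, foreign breeds, unknown) to every individual, and
* the two components of the pedigree-based native kinship: the probability
  that two sampled alleles are IBD *and* native, and the probability that
  both are native.  Their ratio is the kinship conditional on nativity.

Nativity is a property of founder alleles: a founder allele is native iff
its founder carries the breed of interest.  Founders labelled "unknown"
(including those relabelled because they were born after the base year
``last_native``) are non-native, as are alleles descending through a missing
parent link.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import BreedComposition, KinshipMatrix, NativeKinshipComponents

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "prepare_pedigree",
    "pedigree_kinship",
    "equivalent_complete_generations",
    "pedigree_breed_composition",
    "pedigree_native_kinship",
]

UNKNOWN_BREED = "unknown"
_MISSING_PARENT = {"", "0", "NA", "na", "NaN", "nan", "None", "<NA>"}


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Ancestry table with one record per individual.

    ``df`` columns: Indiv, Sire, Dam (None when missing), Sex in
    {"male", "female", "unknown"}, Born (nullable integer year), Breed.
    ``prepared`` is True after :func:`prepare_pedigree` has sorted and
    repaired the table; ``repairs`` lists every repair applied.
    """

    df: pd.DataFrame
    prepared: bool = False
    repairs: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df["Indiv"].tolist()

    def founders(self) -> pd.DataFrame:
        """Records with both parents unknown."""
        m = self.df["Sire"].isna() & self.df["Dam"].isna()
        return self.df[m]

    def require_prepared(self) -> None:
        if not self.prepared:
            raise PedigreeError("pedigree must be prepared first "
                                "(prepare_pedigree)")

    # index helpers used by the recursions -----------------------------------
    def _parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire_idx, dam_idx) arrays with -1 for missing; requires prepared."""
        pos = {ind: k for k, ind in enumerate(self.df["Indiv"])}
        sire = np.array([pos.get(s, -1) if s is not None else -1
                         for s in self.df["Sire"].where(self.df["Sire"].notna(), None)],
                        dtype=np.int64)
        dam = np.array([pos.get(d, -1) if d is not None else -1
                        for d in self.df["Dam"].where(self.df["Dam"].notna(), None)],
                       dtype=np.int64)
        return sire, dam


def _norm_sex(x) -> str:
    if pd.isna(x):
        return "unknown"
    s = str(x).strip().lower()
    if s in {"m", "male", "1"}:
        return "male"
    if s in {"f", "female", "2"}:
        return "female"
    return "unknown"


def _norm_parent(x):
    if pd.isna(x):
        return None
    s = str(x).strip()
    return None if s in _MISSING_PARENT else s


def read_pedigree(path, column_map: Mapping[str, str] | None = None) -> Pedigree:
    """Read a delimited pedigree file (comma or tab autodetected).

    ``column_map`` maps canonical names (Indiv, Sire, Dam, Sex, Born, Breed)
    to the file's column names; by default canonical names are matched
    case-insensitively.  Indiv, Sire, and Dam are required.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False, na_values=[])
    lower = {c.lower(): c for c in df.columns}
    cols = {}
    for canon in ["Indiv", "Sire", "Dam", "Sex", "Born", "Breed"]:
        if column_map and canon in column_map:
            name = column_map[canon]
            if name not in df.columns:
                raise PedigreeError(f"column {name!r} (mapped to {canon}) "
                                    f"not found in file")
            cols[canon] = name
        elif canon.lower() in lower:
            cols[canon] = lower[canon.lower()]
    for required in ["Indiv", "Sire", "Dam"]:
        if required not in cols:
            raise PedigreeError(f"required column {required!r} is not mapped "
                                f"and not present in the file")
    out = pd.DataFrame()
    out["Indiv"] = df[cols["Indiv"]].astype(str).str.strip()
    if (out["Indiv"] == "").any():
        raise PedigreeError("empty individual id")
    dup = out["Indiv"][out["Indiv"].duplicated()]
    if len(dup):
        raise PedigreeError(f"duplicate individual ids: {sorted(set(dup))}")
    out["Sire"] = df[cols["Sire"]].map(_norm_parent)
    out["Dam"] = df[cols["Dam"]].map(_norm_parent)
    out["Sex"] = (df[cols["Sex"]].map(_norm_sex) if "Sex" in cols
                  else "unknown")
    if "Born" in cols:
        born = pd.to_numeric(df[cols["Born"]].replace("", np.nan),
                             errors="coerce")
        out["Born"] = born.astype("Int64")
    else:
        out["Born"] = pd.array([pd.NA] * len(df), dtype="Int64")
    out["Breed"] = (df[cols["Breed"]].replace("", UNKNOWN_BREED)
                    if "Breed" in cols else UNKNOWN_BREED)
    return Pedigree(out.reset_index(drop=True))


def write_pedigree(ped: Pedigree, path) -> None:
    df = ped.df.copy()
    df["Sire"] = df["Sire"].fillna("")
    df["Dam"] = df["Dam"].fillna("")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preparation / repair
# ---------------------------------------------------------------------------

def prepare_pedigree(
    ped: Pedigree,
    this_breed: str | None = None,
    last_native: int | None = None,
    keep: Iterable[str] | None = None,
) -> Pedigree:
    """Sort, complete, and repair a raw pedigree.

    Repairs (all logged in ``repairs``):

    * founder rows are appended for every parent id without a record
      (sex from usage, breed taken from the referencing offspring);
    * an id used as both sire and dam has all its parent links severed;
    * recorded sex contradicting usage is corrected to the usage sex;
    * parent links forming a cycle are severed at the later-born (tie:
      later file order) individual;
    * records are topologically ordered (parents precede offspring).

    If ``this_breed`` and ``last_native`` are given, founders of
    ``this_breed`` born after ``last_native`` — or with missing birth year —
    are relabelled "unknown", which defines the native base population.
    If ``keep`` is given the result is pruned to ``keep`` and all ancestors.
    """
    df = ped.df.copy().reset_index(drop=True)
    repairs: list[str] = []

    ids = set(df["Indiv"])
    sire_use = set(df["Sire"].dropna())
    dam_use = set(df["Dam"].dropna())

    # both-sex usage: sever every link to the offending id
    both = sire_use & dam_use
    for bad in sorted(both):
        df.loc[df["Sire"] == bad, "Sire"] = None
        df.loc[df["Dam"] == bad, "Dam"] = None
        repairs.append(f"id {bad!r} used as both sire and dam; all parent "
                       f"links to it severed")
    sire_use -= both
    dam_use -= both

    # add founder rows for referenced parents without a record
    new_rows = []
    seen_new = set()
    for _, row in df.iterrows():
        for col, sex in (("Sire", "male"), ("Dam", "female")):
            p = row[col]
            if p is not None and p not in ids and p not in seen_new:
                new_rows.append({"Indiv": p, "Sire": None, "Dam": None,
                                 "Sex": sex, "Born": pd.NA,
                                 "Breed": row["Breed"]})
                seen_new.add(p)
                repairs.append(f"founder row added for {p!r}")
    if new_rows:
        add = pd.DataFrame(new_rows)
        add["Born"] = add["Born"].astype("Int64")
        df = pd.concat([df, add], ignore_index=True)
        df["Born"] = df["Born"].astype("Int64")

    # sex corrected from usage
    for use, sex in ((sire_use, "male"), (dam_use, "female")):
        m = df["Indiv"].isin(use) & (df["Sex"] != sex)
        for ind in df.loc[m, "Indiv"]:
            repairs.append(f"sex of {ind!r} set to {sex} (parental usage)")
        df.loc[m, "Sex"] = sex

    # break cycles: sever the parent link of the later-born individual
    pos = {ind: k for k, ind in enumerate(df["Indiv"])}
    born = df["Born"]

    def _later_key(ind: str):
        b = born.iloc[pos[ind]]
        return (int(b) if pd.notna(b) else 10**9, pos[ind])

    while True:
        cycle = _find_cycle(df)
        if cycle is None:
            break
        # cycle is a list of (parent, child) edges; sever at the latest child
        child = max((c for _, c in cycle), key=_later_key)
        parents = {p for p, c in cycle if c == child}
        for col in ("Sire", "Dam"):
            if df.loc[pos[child], col] in parents:
                bad = df.loc[pos[child], col]
                df.loc[pos[child], col] = None
                repairs.append(f"cycle broken: {col.lower()} link "
                               f"{bad!r} -> {child!r} severed")

    # topological order, stable by (born, file order)
    order = _topo_order(df)
    df = df.iloc[order].reset_index(drop=True)

    # native base population: relabel late/undated founders of this_breed
    if this_breed is not None and last_native is not None:
        is_founder = df["Sire"].isna() & df["Dam"].isna()
        late = df["Born"].isna() | (df["Born"] > last_native)
        m = is_founder & late & (df["Breed"] == this_breed)
        for ind in df.loc[m, "Indiv"]:
            repairs.append(f"founder {ind!r} of breed {this_breed!r} born "
                           f"after {last_native} (or undated): breed set to "
                           f"'{UNKNOWN_BREED}'")
        df.loc[m, "Breed"] = UNKNOWN_BREED

    if keep is not None:
        wanted = _with_ancestors(df, set(map(str, keep)))
        df = df[df["Indiv"].isin(wanted)].reset_index(drop=True)

    return Pedigree(df, prepared=True, repairs=repairs)


def _find_cycle(df: pd.DataFrame):
    """Return a list of (parent, child) edges forming a cycle, or None."""
    children: dict[str, list[str]] = {}
    parent_of: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        for col in ("Sire", "Dam"):
            p = row[col]
            if p is not None:
                children.setdefault(p, []).append(row["Indiv"])
    state: dict[str, int] = {}
    stack_edges: list[tuple[str, str]] = []

    for start in df["Indiv"]:
        if state.get(start):
            continue
        stack = [(start, iter(children.get(start, [])))]
        state[start] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for ch in it:
                if state.get(ch, 0) == 1:
                    # found a back edge: reconstruct cycle
                    cyc = [(node, ch)]
                    for k in range(len(stack) - 1, 0, -1):
                        cyc.insert(0, (stack[k - 1][0], stack[k][0]))
                    # trim to the part starting at ch
                    idx = next(i for i, (p, _) in enumerate(cyc) if p == ch)
                    return cyc[idx:]
                if state.get(ch, 0) == 0:
                    state[ch] = 1
                    stack.append((ch, iter(children.get(ch, []))))
                    advanced = True
                    break
            if not advanced:
                state[node] = 2
                stack.pop()
    return None


def _topo_order(df: pd.DataFrame) -> list[int]:
    """Kahn's algorithm; ties resolved by (born, file order)."""
    import heapq

    n = len(df)
    pos = {ind: k for k, ind in enumerate(df["Indiv"])}
    indeg = np.zeros(n, dtype=int)
    children: dict[int, list[int]] = {}
    for k, row in enumerate(df.itertuples(index=False)):
        for p in (row.Sire, row.Dam):
            if p is not None and p in pos:
                indeg[k] += 1
                children.setdefault(pos[p], []).append(k)
    born = df["Born"]

    def key(k: int):
        b = born.iloc[k]
        return (int(b) if pd.notna(b) else -(10**9), k)

    heap = [(key(k), k) for k in range(n) if indeg[k] == 0]
    heapq.heapify(heap)
    out: list[int] = []
    while heap:
        _, k = heapq.heappop(heap)
        out.append(k)
        for ch in children.get(k, []):
            indeg[ch] -= 1
            if indeg[ch] == 0:
                heapq.heappush(heap, (key(ch), ch))
    if len(out) != n:
        raise PedigreeError("pedigree still contains a cycle after repair")
    return out


def _with_ancestors(df: pd.DataFrame, keep: set[str]) -> set[str]:
    parent = {row.Indiv: (row.Sire, row.Dam)
              for row in df.itertuples(index=False)}
    out: set[str] = set()
    stack = [i for i in keep if i in parent]
    while stack:
        i = stack.pop()
        if i in out:
            continue
        out.add(i)
        for p in parent.get(i, (None, None)):
            if p is not None and p not in out:
                stack.append(p)
    return out


# ---------------------------------------------------------------------------
# pedigree kinship (tabular method)
# ---------------------------------------------------------------------------

def pedigree_kinship(
    ped: Pedigree, founder_kinship: KinshipMatrix | None = None
) -> KinshipMatrix:
    """Pedigree kinship matrix f_PED by the tabular method.

    Founders are unrelated and non-inbred by default (self-kinship 1/2);
    ``founder_kinship`` may supply a kinship matrix among (a subset of)
    founders instead.  The additive relationship matrix is
    ``result.additive`` (A = 2 f_PED).
    """
    ped.require_prepared()
    df = ped.df
    n = len(df)
    sire, dam = ped._parent_indices()
    is_founder = (sire < 0) & (dam < 0)

    fk_idx: dict[int, int] = {}
    fk = founder_kinship
    if fk is not None:
        pos = {ind: k for k, ind in enumerate(df["Indiv"])}
        for fid in fk.ids:
            if fid not in pos:
                raise PedigreeError(f"founder_kinship id {fid!r} not in "
                                    f"pedigree")
            k = pos[fid]
            if not is_founder[k]:
                raise PedigreeError(f"founder_kinship id {fid!r} is not a "
                                    f"founder")
            fk_idx[k] = fk.ids.index(fid)

    f = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if is_founder[i]:
            if i in fk_idx:
                for j in range(i):
                    if j in fk_idx:
                        f[i, :i][j] = fk.values[fk_idx[i], fk_idx[j]]
                f[i, i] = fk.values[fk_idx[i], fk_idx[i]]
            else:
                f[i, i] = 0.5
        else:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * f[s, :i]
            if d >= 0:
                row += 0.5 * f[d, :i]
            f[i, :i] = row
            fsd = f[s, d] if (s >= 0 and d >= 0) else 0.0
            f[i, i] = 0.5 * (1.0 + fsd)
        f[:i, i] = f[i, :i]
    return KinshipMatrix(df["Indiv"].tolist(), f, role="fPED")


def equivalent_complete_generations(ped: Pedigree) -> pd.Series:
    """Pedigree completeness: sum over generations of the proportion of
    known ancestors, equiGen(i) = sum_g #known(g) / 2^g."""
    ped.require_prepared()
    sire, dam = ped._parent_indices()
    n = len(ped.df)
    eg = np.zeros(n)
    for i in range(n):
        val = 0.0
        if sire[i] >= 0:
            val += 0.5 * (1.0 + eg[sire[i]])
        if dam[i] >= 0:
            val += 0.5 * (1.0 + eg[dam[i]])
        eg[i] = val
    return pd.Series(eg, index=ped.df["Indiv"], name="equiGen")


# ---------------------------------------------------------------------------
# breed composition and native kinship
# ---------------------------------------------------------------------------

def pedigree_breed_composition(ped: Pedigree, this_breed: str) -> BreedComposition:
    """Genetic contribution of founder origin classes to each individual.

    Founders of ``this_breed`` define the class "native"; founders of any
    other breed define one class per breed; founders labelled "unknown" and
    genome halves descending through missing parent links fall in class
    "unknown".  The native column is the pedigree native contribution
    N_PED(i).
    """
    ped.require_prepared()
    df = ped.df
    sire, dam = ped._parent_indices()
    is_founder = (sire < 0) & (dam < 0)

    breeds = sorted(set(df.loc[is_founder, "Breed"]))
    classes = ["native", UNKNOWN_BREED] + sorted(
        b for b in breeds if b not in (this_breed, UNKNOWN_BREED)
    )
    cls_idx = {c: k for k, c in enumerate(classes)}
    n, k = len(df), len(classes)
    comp = np.zeros((n, k))
    unknown = cls_idx[UNKNOWN_BREED]
    for i in range(n):
        if is_founder[i]:
            b = df["Breed"].iloc[i]
            comp[i, cls_idx["native" if b == this_breed else b]] = 1.0
        else:
            for p in (sire[i], dam[i]):
                if p >= 0:
                    comp[i] += 0.5 * comp[p]
                else:
                    comp[i, unknown] += 0.5
    table = pd.DataFrame(comp, index=df["Indiv"], columns=classes)
    return BreedComposition(table, this_breed=this_breed)


def pedigree_native_kinship(ped: Pedigree, this_breed: str) -> NativeKinshipComponents:
    """Components of the pedigree-based native kinship.

    Numerator f_IBD&N(i, j): probability the two sampled alleles are IBD and
    native.  Denominator f_N(i, j): probability both are native.  Native
    founders are unrelated and non-inbred; an allele is native iff it
    descends from a founder of ``this_breed``.  The diagonal uses
    with-replacement sampling, so the same-allele draw (probability 1/2) is
    always IBD and is native with probability N_PED(i).
    """
    ped.require_prepared()
    df = ped.df
    if not (df["Breed"] == this_breed).any():
        raise PedigreeError(f"breed {this_breed!r} absent from pedigree")
    n = len(df)
    sire, dam = ped._parent_indices()
    is_founder = (sire < 0) & (dam < 0)
    nat = (is_founder & (df["Breed"] == this_breed).to_numpy()).astype(float)
    n_ped = pedigree_breed_composition(ped, this_breed).native.to_numpy()

    fn = np.zeros((n, n))
    fin = np.zeros((n, n))  # IBD & native
    for i in range(n):
        s, d = sire[i], dam[i]
        if is_founder[i]:
            # independent of every non-descendant: P(both native) factorizes
            fn[i, :i] = nat[i] * n_ped[:i]
            fn[i, i] = nat[i]
            # unrelated to everything earlier: no IBD
            fin[i, i] = 0.5 * nat[i]
        else:
            row_n = np.zeros(i)
            row_f = np.zeros(i)
            if s >= 0:
                row_n += 0.5 * fn[s, :i]
                row_f += 0.5 * fin[s, :i]
            if d >= 0:
                row_n += 0.5 * fn[d, :i]
                row_f += 0.5 * fin[d, :i]
            fn[i, :i] = row_n
            fin[i, :i] = row_f
            fn_sd = fn[s, d] if (s >= 0 and d >= 0) else 0.0
            fin_sd = fin[s, d] if (s >= 0 and d >= 0) else 0.0
            fn[i, i] = 0.5 * n_ped[i] + 0.5 * fn_sd
            fin[i, i] = 0.5 * n_ped[i] + 0.5 * fin_sd
        fn[:i, i] = fn[i, :i]
        fin[:i, i] = fin[i, :i]

    ids = df["Indiv"].tolist()
    return NativeKinshipComponents(
        numerator=KinshipMatrix(ids, fin, role="fIBD&N"),
        denominator=KinshipMatrix(ids, fn, role="fN"),
    )
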