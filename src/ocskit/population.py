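"""Age x sex class contributions, population means, and kinship bounds.

In a population with overlapping generations, each age x sex class carries a
contribution to the gene pool proportional to the expected proportion of its
offspring that is not yet born, with the total contributions of non-juvenile
males and females assumed equal.  The contribution of the incoming birth
cohort is r0, and each evaluated individual carries weight v_i (its class
contribution divided by class size), so r0 + sum(v) = 1.

Predicted population means at the next evaluation time are functions of the
candidate contribution vector c: linear means (r0 c + v)' X for numeric
traits, quadratic forms (r0 c + v)' F (r0 c + v) for kinships, and ratios of
quadratic forms for native kinships.  Current means use the normalized
weights v / (1 - r0) over the existing classes; native-kinship means are
always ratios of weighted quadratic forms, never averages of per-pair
ratios.

The admissible yearly increase in a mean kinship follows from a target
effective population size Ne: the rate of increase per generation must
satisfy df_g <= 1/(2 Ne), hence per year df_y <= 1/(2 Ne L) with generation
interval L.  With the rate measured on the (1 - f) scale the per-generation
guarantee composes exactly over years, giving the upper bound
f + (1 - f) / (2 Ne L).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import KinshipMatrix, NativeKinshipComponents
from .pedigree import Pedigree

__all__ = [
    "ClassContributions",
    "PopulationState",
    "age_class_contributions",
    "generation_interval",
    "population_state",
    "kinship_bound",
]


class PopulationError(ValueError):
    pass


@dataclass
class ClassContributions:
    """Per (age, sex) class contributions to the population.

    ``table`` has columns age, male, female; the age-0 row is the incoming
    birth cohort.  All entries sum to 1 and the age >= 1 totals of the two
    sexes are equal.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if abs(float(t[["male", "female"]].to_numpy().sum()) - 1.0) > 1e-9:
            raise PopulationError("class contributions do not sum to 1")
        older = t[t["age"] >= 1]
        if abs(older["male"].sum() - older["female"].sum()) > 1e-9:
            raise PopulationError("non-juvenile male and female totals "
                                  "differ")

    @property
    def r0(self) -> float:
        """Contribution of the age-0 class (the unborn/incoming cohort)."""
        row = self.table[self.table["age"] == 0]
        return float(row[["male", "female"]].to_numpy().sum())

    def contribution(self, age: int, sex: str) -> float:
        row = self.table[self.table["age"] == age]
        if row.empty or sex not in ("male", "female"):
            return 0.0
        return float(row[sex].iloc[0])

    @classmethod
    def discrete(cls) -> "ClassContributions":
        """Discrete generations: one non-juvenile class per sex, r0 = 1/2."""
        return cls(pd.DataFrame({"age": [0, 1],
                                 "male": [0.25, 0.25],
                                 "female": [0.25, 0.25]}))


def age_class_contributions(ped: Pedigree, use=None) -> ClassContributions:
    """Estimate class contributions from parent ages at offspring birth.

    For each sex the empirical distribution p(a) of parent age at offspring
    birth is computed from the offspring in ``use`` (default: the youngest
    birth cohort in the pedigree).  The weight of the age-a class
    (a >= 1) is the survival sum S(a) = sum_{k >= a} p(k) — the proportion
    of the class's lifetime reproduction still ahead — and the age-0 class
    has weight 1.  Weights are normalized within sex; r0 is the mean of the
    two sexes' age-0 shares and each sex's age >= 1 classes are rescaled to
    total (1 - r0) / 2.
    """
    df = ped.df
    if use is None:
        if df["Born"].isna().all():
            raise PopulationError("no birth years in pedigree")
        last = df["Born"].max()
        use = set(df.loc[df["Born"] == last, "Indiv"])
    else:
        use = set(map(str, use))
    pos = {ind: k for k, ind in enumerate(df["Indiv"])}
    ages: dict[str, list[int]] = {"male": [], "female": []}
    for row in df.itertuples(index=False):
        if row.Indiv not in use or pd.isna(row.Born):
            continue
        for p, sex in ((row.Sire, "male"), (row.Dam, "female")):
            if p is None or p not in pos:
                continue
            pborn = df["Born"].iloc[pos[p]]
            if pd.isna(pborn):
                continue
            a = int(row.Born) - int(pborn)
            if a >= 1:
                ages[sex].append(a)
    if not ages["male"] or not ages["female"]:
        raise PopulationError("no usable parent ages for at least one sex")

    max_age = max(max(ages["male"]), max(ages["female"]))
    weights = {}
    for sex in ("male", "female"):
        counts = np.bincount(ages[sex], minlength=max_age + 1)[1:]
        p = counts / counts.sum()
        surv = p[::-1].cumsum()[::-1]  # S(a) = sum_{k >= a} p(k)
        weights[sex] = np.concatenate(([1.0], surv))
    q = {s: w / w.sum() for s, w in weights.items()}
    r0 = (q["male"][0] + q["female"][0]) / 2.0
    rows = {"age": np.arange(max_age + 1)}
    for sex in ("male", "female"):
        older = q[sex][1:]
        scaled = older / older.sum() * (1.0 - r0) / 2.0
        rows[sex] = np.concatenate(([r0 / 2.0], scaled))
    return ClassContributions(pd.DataFrame(rows))


def generation_interval(cont: ClassContributions) -> float:
    """Approximate generation interval L = 1/(4 c_m1) + 1/(4 c_f1), where
    c_m1 and c_f1 are the age-1 male and female class contributions."""
    c_m1 = cont.contribution(1, "male")
    c_f1 = cont.contribution(1, "female")
    if c_m1 <= 0 or c_f1 <= 0:
        raise PopulationError("age-1 class contribution is zero; cannot "
                              "approximate the generation interval")
    return 1.0 / (4.0 * c_m1) + 1.0 / (4.0 * c_f1)


@dataclass
class PopulationState:
    """Candidate table joined with class weights and current means.

    ``phen`` gains columns Age (years) and v (individual weight); ``mean``
    maps every registered parameter (numeric columns, kinships, native
    kinships) to its current population mean.
    """

    phen: pd.DataFrame
    kinships: dict[str, KinshipMatrix | NativeKinshipComponents]
    mean: dict[str, float]
    r0: float
    v: np.ndarray
    L: float
    cont: ClassContributions
    breed: str = ""
    numeric_columns: list[str] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return self.phen["Indiv"].tolist()

    @property
    def candidates(self) -> pd.DataFrame:
        return self.phen[self.phen["isCandidate"]]

    def candidate_mask(self) -> np.ndarray:
        return self.phen["isCandidate"].to_numpy(dtype=bool)

    def kinship_values(self, name: str) -> np.ndarray:
        """Dense matrix (or matrices) for parameter ``name`` aligned to phen."""
        obj = self.kinships[name]
        if isinstance(obj, NativeKinshipComponents):
            sub = obj.submatrix(self.ids)
            return sub.numerator.values, sub.denominator.values
        return obj.submatrix(self.ids).values

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": list(self.mean),
                             "mean": [self.mean[k] for k in self.mean]})


def population_state(
    phen: pd.DataFrame,
    kinships: dict[str, KinshipMatrix | NativeKinshipComponents] | None = None,
    cont: ClassContributions | None = None,
    breed: str = "",
) -> PopulationState:
    """Attach class weights to a candidate table and compute current means.

    ``phen`` needs columns Indiv, Sex, Born and optionally isCandidate; all
    other numeric columns are registered as parameters.  With ``cont`` None,
    discrete generations are assumed (equal sex totals, r0 = 1/2).  Means of
    kinships are weighted quadratic forms; means of native kinships are
    ratios of the numerator and denominator quadratic forms.
    """
    kinships = dict(kinships or {})
    phen = phen.copy().reset_index(drop=True)
    if "Indiv" not in phen.columns:
        raise PopulationError("phen table needs an Indiv column")
    phen["Indiv"] = phen["Indiv"].astype(str)
    if "Sex" not in phen.columns:
        phen["Sex"] = "unknown"
    if cont is None:
        cont = ClassContributions.discrete()
    r0 = cont.r0

    if "Born" in phen.columns and phen["Born"].notna().any():
        born = pd.to_numeric(phen["Born"], errors="coerce")
        current = int(born.max())
        phen["Age"] = current - born
        if not phen["Age"].ge(1).fillna(False).any():
            # table holds a single cohort of already-born adults
            phen["Age"] = phen["Age"] + 1
    else:
        phen["Age"] = 1  # ageless table: one class per sex
    if "isCandidate" not in phen.columns:
        phen["isCandidate"] = phen["Age"].ge(1).fillna(False)
    phen["isCandidate"] = phen["isCandidate"].fillna(False).astype(bool)

    sexes = phen["Sex"].fillna("unknown")
    known_sex = sexes.isin(["male", "female"]).any()
    v = np.zeros(len(phen))
    if known_sex:
        for (age, sex), grp in phen.groupby([phen["Age"], sexes]):
            if pd.isna(age) or age < 1:
                continue
            c = cont.contribution(int(age), str(sex))
            if c > 0:
                v[grp.index] = c / len(grp)
    else:
        older = phen.index[phen["Age"].ge(1).fillna(False)]
        if len(older):
            v[older] = (1.0 - r0) / len(older)
    tot = v.sum()
    if tot <= 0:
        raise PopulationError("no individuals fall in evaluated age classes")
    v *= (1.0 - r0) / tot  # renormalize over the classes actually present
    phen["v"] = v
    vt = v / (1.0 - r0)

    numeric_cols = [c for c in phen.columns
                    if c not in ("Indiv", "Sex", "Born", "Breed", "Age",
                                 "isCandidate", "v", "Herd")
                    and pd.api.types.is_numeric_dtype(phen[c])]
    mean: dict[str, float] = {}
    for col in numeric_cols:
        mean[col] = float(vt @ phen[col].to_numpy(dtype=float))
    ids = phen["Indiv"].tolist()
    for name, obj in kinships.items():
        try:
            if isinstance(obj, NativeKinshipComponents):
                sub = obj.submatrix(ids)
                num = vt @ sub.numerator.values @ vt
                den = vt @ sub.denominator.values @ vt
                if den <= 0:
                    raise PopulationError(
                        f"native kinship {name!r}: zero both-native mass")
                mean[name] = float(num / den)
            else:
                mean[name] = float(vt @ obj.submatrix(ids).values @ vt)
        except KeyError as exc:
            raise PopulationError(f"kinship {name!r} is missing phen "
                                  f"individuals: {exc}") from exc

    try:
        L = generation_interval(cont)
    except PopulationError:
        L = 1.0
    return PopulationState(phen=phen, kinships=kinships, mean=mean, r0=r0,
                           v=v, L=L, cont=cont, breed=breed,
                           numeric_columns=numeric_cols)


def kinship_bound(current_mean: float, Ne: float, L: float) -> float:
    """Upper bound for next year's mean kinship compatible with effective
    size Ne: f + (1 - f) / (2 Ne L)."""
    if not 0.0 <= current_mean < 1.0:
        raise PopulationError("current mean kinship must be in [0, 1)")
    if Ne <= 0 or L <= 0:
        raise PopulationError("Ne and L must be positive")
    return current_mean + (1.0 - current_mean) / (2.0 * Ne * L)
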