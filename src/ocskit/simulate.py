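"""Synthetic pedigrees, gene dropping, haplotypes, and breeding values.

This module generates the study material for the whole toolkit: multi-year
pedigrees of a native breed with planted introgression from foreign breeds,
gene-dropped haplotypes whose true per-marker origins are retained, and
additive breeding values.  It also provides a tagged gene-dropping
Monte-Carlo estimator that serves as an independent oracle for every
pedigree-based probability (kinship, both-native, IBD-and-native, native
contribution): alleles are dropped through the pedigree and the defining
probabilities are estimated by their empirical frequencies, with standard
errors.

Every generator is a pure function of its configuration and seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, prepare_pedigree
from .segments import HaplotypeSet, MarkerMap

__all__ = [
    "SimConfig",
    "GeneDropResult",
    "simulate_pedigree",
    "gene_drop",
    "simulate_haplotypes",
    "simulate_ebv",
    "default_marker_map",
]


@dataclass
class SimConfig:
    """Configuration of the synthetic breed.

    Defaults describe a small endangered cattle-like population: 40 native
    founders plus a Holstein-type foreign founder pool, 30 offspring per
    year, sires used at ages 1-4 (progeny-tested bulls breed older), dams
    at ages 1-3, and a 10% chance per offspring that its sire is a fresh
    foreign migrant (historic introgression).  The map is 2 chromosomes of
    120 markers at 0.5 Mb spacing; recombination follows Poisson crossovers
    at 0.01 Morgan/Mb (1 Morgan per 100 Mb).
    """

    n_founders: dict = field(default_factory=lambda: {"Angler": 40,
                                                      "Holstein": 12})
    this_breed: str = "Angler"
    years: int = 6
    n_offspring_per_year: int = 30
    male_age_dist: dict = field(default_factory=lambda: {1: 0.3, 2: 0.3,
                                                         3: 0.25, 4: 0.15})
    female_age_dist: dict = field(default_factory=lambda: {1: 0.5, 2: 0.3,
                                                           3: 0.2})
    migrant_fraction: float = 0.1
    n_chromosomes: int = 2
    n_markers_per_chrom: int = 120
    spacing_mb: float = 0.5
    recomb_rate_per_mb: float = 0.01
    mendelian_sd: float = float(np.sqrt(0.5))
    seed: int = 20200

    def foreign_breeds(self) -> list[str]:
        return [b for b in self.n_founders if b != self.this_breed]


def simulate_pedigree(cfg: SimConfig, seed: int | None = None) -> Pedigree:
    """Multi-year pedigree with breed-labelled founders and migrant sires."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    counter = [0]

    def new_id(prefix):
        counter[0] += 1
        return f"{prefix}{counter[0]:05d}"

    for breed, n in cfg.n_founders.items():
        for k in range(n):
            rows.append({"Indiv": new_id(breed[0].upper()),
                         "Sire": None, "Dam": None,
                         "Sex": "male" if k % 2 == 0 else "female",
                         "Born": 0, "Breed": breed})

    def sample_parent(sex, year, age_dist):
        pool = [r for r in rows if r["Sex"] == sex]
        ages = np.array([year - r["Born"] for r in pool])
        probs = np.array([age_dist.get(int(a), 0.0) for a in ages])
        if probs.sum() <= 0:
            probs = (ages >= 1).astype(float)
        if probs.sum() <= 0:
            raise ValueError("no eligible parents")
        probs = probs / probs.sum()
        return pool[rng.choice(len(pool), p=probs)]

    foreign = cfg.foreign_breeds()
    for year in range(1, cfg.years + 1):
        born = []
        for _ in range(cfg.n_offspring_per_year):
            if foreign and rng.random() < cfg.migrant_fraction:
                breed = foreign[rng.integers(len(foreign))]
                sire = {"Indiv": new_id(breed[0].upper() + "M"),
                        "Sire": None, "Dam": None, "Sex": "male",
                        "Born": year - 2, "Breed": breed}
                rows.append(sire)
            else:
                sire = sample_parent("male", year, cfg.male_age_dist)
            dam = sample_parent("female", year, cfg.female_age_dist)
            born.append({"Indiv": new_id("X"),
                         "Sire": sire["Indiv"], "Dam": dam["Indiv"],
                         "Sex": "male" if rng.random() < 0.5 else "female",
                         "Born": year, "Breed": cfg.this_breed})
        rows.extend(born)

    df = pd.DataFrame(rows)
    df["Born"] = df["Born"].astype("Int64")
    return prepare_pedigree(Pedigree(df))


# ---------------------------------------------------------------------------
# tagged gene dropping (Monte-Carlo oracle)
# ---------------------------------------------------------------------------

@dataclass
class GeneDropResult:
    """Empirical pedigree probabilities with standard errors.

    ``pairs`` has one row per evaluated pair with estimates and standard
    errors for f_PED, f_N (both native), and f_IBD&N (IBD and native);
    ``native`` has the per-individual native-contribution estimates.
    """

    pairs: pd.DataFrame
    native: pd.DataFrame
    n_rep: int


def gene_drop(
    ped: Pedigree,
    this_breed: str | None = None,
    tags: dict | None = None,
    pairs: list[tuple[str, str]] | None = None,
    n_rep: int = 100_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> GeneDropResult:
    """Monte-Carlo estimates of f_PED, f_N, f_IBD&N, and N_PED.

    Two uniquely tagged alleles are planted in every founder and dropped
    through the pedigree ``n_rep`` times.  A founder allele is *native* if
    its founder's tag is true: tags come from ``tags`` (founder id -> bool)
    or default to founder breed == ``this_breed``.  Pair probabilities
    average the four ordered allele draws (with replacement on the
    diagonal), matching the defining sampling conventions exactly.
    """
    ped.require_prepared()
    df = ped.df
    n = len(df)
    sire, dam = ped._parent_indices()
    is_founder = (sire < 0) & (dam < 0)
    ids = df["Indiv"].tolist()
    pos = {ind: k for k, ind in enumerate(ids)}

    if tags is None:
        if this_breed is None:
            raise ValueError("give either this_breed or tags")
        tag_vec = (df["Breed"] == this_breed).to_numpy() & is_founder
    else:
        tag_vec = np.array([bool(tags.get(i, False)) for i in ids])
        tag_vec &= is_founder

    if pairs is None:
        pairs = [(ids[i], ids[j]) for i in range(n) for j in range(i, n)]
    pidx = [(pos[str(a)], pos[str(b)]) for a, b in pairs]

    # founder allele ids: founder k carries alleles 2k and 2k+1
    founder_no = np.cumsum(is_founder) - 1
    # allele -> native flag lookup
    nat_of_allele = np.zeros(2 * int(is_founder.sum()) + 2, dtype=bool)
    for k in np.flatnonzero(is_founder):
        nat_of_allele[2 * founder_no[k]] = tag_vec[k]
        nat_of_allele[2 * founder_no[k] + 1] = tag_vec[k]
    rng = np.random.default_rng(seed)
    npairs = len(pidx)
    sum_f = np.zeros(npairs)
    sumsq_f = np.zeros(npairs)
    sum_n = np.zeros(npairs)
    sumsq_n = np.zeros(npairs)
    sum_fn = np.zeros(npairs)
    sumsq_fn = np.zeros(npairs)
    sum_nc = np.zeros(n)
    sumsq_nc = np.zeros(n)

    done = 0
    missing_counter = [0]
    while done < n_rep:
        m = min(chunk, n_rep - done)
        A1 = np.empty((n, m), dtype=np.int64)
        A2 = np.empty((n, m), dtype=np.int64)

        def parent_allele(p, m=m):
            if p < 0:
                # alleles through a missing link are unrelated & non-native:
                # give each draw a unique negative id
                missing_counter[0] += 1
                base = -(missing_counter[0] * (m + 1))
                return base - np.arange(m)
            pick = rng.integers(0, 2, size=m, dtype=np.int8)
            return np.where(pick == 0, A1[p], A2[p])

        for i in range(n):
            if is_founder[i]:
                A1[i] = 2 * founder_no[i]
                A2[i] = 2 * founder_no[i] + 1
            else:
                A1[i] = parent_allele(sire[i])
                A2[i] = parent_allele(dam[i])

        nat1 = np.where(A1 >= 0, nat_of_allele[np.where(A1 >= 0, A1, 0)],
                        False)
        nat2 = np.where(A2 >= 0, nat_of_allele[np.where(A2 >= 0, A2, 0)],
                        False)

        nc = (nat1.astype(float) + nat2.astype(float)) / 2.0
        sum_nc += nc.sum(axis=1)
        sumsq_nc += (nc ** 2).sum(axis=1)

        for k, (i, j) in enumerate(pidx):
            if i == j:
                eq = (A1[i] == A2[i]).astype(float)
                na, nb = nat1[i].astype(float), nat2[i].astype(float)
                f = (2.0 + 2.0 * eq) / 4.0
                fn = (na + nb + 2.0 * eq * na * nb) / 4.0
                bn = (na + nb + 2.0 * na * nb) / 4.0
            else:
                e11 = (A1[i] == A1[j]).astype(float)
                e12 = (A1[i] == A2[j]).astype(float)
                e21 = (A2[i] == A1[j]).astype(float)
                e22 = (A2[i] == A2[j]).astype(float)
                f = (e11 + e12 + e21 + e22) / 4.0
                b11 = (nat1[i] & nat1[j]).astype(float)
                b12 = (nat1[i] & nat2[j]).astype(float)
                b21 = (nat2[i] & nat1[j]).astype(float)
                b22 = (nat2[i] & nat2[j]).astype(float)
                bn = (b11 + b12 + b21 + b22) / 4.0
                fn = (e11 * b11 + e12 * b12 + e21 * b21 + e22 * b22) / 4.0
            sum_f[k] += f.sum()
            sumsq_f[k] += (f ** 2).sum()
            sum_n[k] += bn.sum()
            sumsq_n[k] += (bn ** 2).sum()
            sum_fn[k] += fn.sum()
            sumsq_fn[k] += (fn ** 2).sum()
        done += m

    def stats(s, sq):
        mean = s / n_rep
        var = np.maximum(sq / n_rep - mean ** 2, 0.0)
        se = np.sqrt(var / n_rep)
        return mean, se

    f_mean, f_se = stats(sum_f, sumsq_f)
    n_mean, n_se = stats(sum_n, sumsq_n)
    fn_mean, fn_se = stats(sum_fn, sumsq_fn)
    nc_mean, nc_se = stats(sum_nc, sumsq_nc)

    pairs_df = pd.DataFrame({
        "i": [ids[i] for i, _ in pidx],
        "j": [ids[j] for _, j in pidx],
        "fPED": f_mean, "fPED_se": f_se,
        "fN": n_mean, "fN_se": n_se,
        "fIBDN": fn_mean, "fIBDN_se": fn_se,
    })
    native_df = pd.DataFrame({"Indiv": ids, "NC": nc_mean, "NC_se": nc_se})
    return GeneDropResult(pairs=pairs_df, native=native_df, n_rep=n_rep)


# ---------------------------------------------------------------------------
# haplotype simulation
# ---------------------------------------------------------------------------

def default_marker_map(cfg: SimConfig) -> MarkerMap:
    rows = []
    for c in range(cfg.n_chromosomes):
        for k in range(cfg.n_markers_per_chrom):
            rows.append({"Name": f"c{c + 1}m{k + 1}", "Chr": str(c + 1),
                         "Position": k * cfg.spacing_mb})
    return MarkerMap(pd.DataFrame(rows))


def simulate_haplotypes(
    ped: Pedigree,
    cfg: SimConfig,
    recomb_rate: float | None = None,
    seed: int | None = None,
) -> tuple[HaplotypeSet, np.ndarray]:
    """Gene-drop binary haplotypes through the pedigree.

    Founder haplotypes are drawn from breed-specific allele-frequency
    profiles (Beta(2, 2) per marker per breed), so breeds carry private
    allele-frequency structure while IBD segments are identical by
    construction.  Meiosis places Poisson crossovers along each chromosome
    at ``recomb_rate`` Morgan/Mb.

    Returns the haplotype set and the true origin mask: an integer array
    (marker x 2 per individual) giving the breed index (order of
    ``cfg.n_founders``) of the founder allele at each position.
    """
    ped.require_prepared()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    rate = cfg.recomb_rate_per_mb if recomb_rate is None else recomb_rate
    mmap = default_marker_map(cfg)
    pos = mmap.positions
    m = len(mmap)
    df = ped.df
    n = len(df)
    sire, dam = ped._parent_indices()
    is_founder = (sire < 0) & (dam < 0)

    breeds = list(cfg.n_founders)
    breed_idx = {b: k for k, b in enumerate(breeds)}
    freqs = {b: rng.beta(2.0, 2.0, size=m) for b in breeds}

    H = np.zeros((m, 2 * n), dtype=np.uint8)
    origin = np.zeros((m, 2 * n), dtype=np.int8)
    chrom_slices = mmap.chrom_slices()

    def meiosis(h1, h2, o1, o2):
        out_h = np.empty(m, dtype=np.uint8)
        out_o = np.empty(m, dtype=np.int8)
        for _, sl in chrom_slices:
            p = pos[sl]
            length = p[-1] - p[0]
            n_x = rng.poisson(rate * length)
            cuts = np.sort(rng.uniform(p[0], p[-1], size=n_x))
            phase = int(rng.integers(2))
            seg = phase + np.searchsorted(cuts, p)
            use1 = seg % 2 == 0
            out_h[sl] = np.where(use1, h1[sl], h2[sl])
            out_o[sl] = np.where(use1, o1[sl], o2[sl])
        return out_h, out_o

    for i in range(n):
        if is_founder[i]:
            b = df["Breed"].iloc[i]
            b = b if b in breed_idx else breeds[0]
            for w in (0, 1):
                H[:, 2 * i + w] = rng.random(m) < freqs[b]
                origin[:, 2 * i + w] = breed_idx[b]
        else:
            for w, p in ((0, sire[i]), (1, dam[i])):
                if p < 0:
                    # unknown parent: draw a fresh native-pool haplotype
                    b = breeds[0]
                    H[:, 2 * i + w] = rng.random(m) < freqs[b]
                    origin[:, 2 * i + w] = breed_idx[b]
                else:
                    h, o = meiosis(H[:, 2 * p], H[:, 2 * p + 1],
                                   origin[:, 2 * p], origin[:, 2 * p + 1])
                    H[:, 2 * i + w] = h
                    origin[:, 2 * i + w] = o

    haps = HaplotypeSet(mmap, H, df["Indiv"].tolist(),
                        df["Breed"].tolist())
    return haps, origin


def simulate_ebv(ped: Pedigree, cfg: SimConfig,
                 seed: int | None = None) -> pd.Series:
    """Additive breeding values: founders ~ N(0, 1), offspring = parent
    average plus Mendelian-sampling noise (sd = cfg.mendelian_sd); a
    missing parent contributes the population mean 0."""
    ped.require_prepared()
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    df = ped.df
    sire, dam = ped._parent_indices()
    n = len(df)
    ebv = np.zeros(n)
    for i in range(n):
        if sire[i] < 0 and dam[i] < 0:
            ebv[i] = rng.normal()
        else:
            pa = ((ebv[sire[i]] if sire[i] >= 0 else 0.0)
                  + (ebv[dam[i]] if dam[i] >= 0 else 0.0)) / 2.0
            ebv[i] = pa + cfg.mendelian_sd * rng.normal()
    return pd.Series(ebv, index=df["Indiv"], name="EBV")
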