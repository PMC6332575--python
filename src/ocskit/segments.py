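"""Phased-haplotype I/O, shared-segment detection, and segment-based
kinship, breed composition, and native kinship.

Two haplotypes share a *segment* at a marker when the maximal run of
marker-wise identity covering that marker has at least ``min_snp`` markers
and spans at least ``min_l`` Mb (first to last marker position).  Runs never
cross chromosome boundaries.  Defaults min_snp=20 and min_l=1.0 Mb guard
against short chance identity; larger min_l restricts attention to more
recent common ancestry.

The segment-based kinship f_SEG(i, j) is the probability that two alleles,
one sampled from each individual at a uniformly random genome position,
lie in identical shared segments.  Genome position is discretized to
markers weighted by half-interval lengths (the interval between midpoints
of adjacent markers; chromosome-end markers carry their single half
interval), so a full chromosome's weights sum to its first-to-last length.
Self-kinship samples with replacement: the same-haplotype draw always lies
in an identical segment, giving f_SEG(i, i) = 1/2 + (shared length between
the two own haplotypes) / (2 G).

Haplotype origin classification: a marker in a haplotype of the breed of
interest is assigned to a reference breed B when the fraction of B's
haplotypes sharing a qualifying segment covering that marker reaches
``ub_freq``; otherwise the marker is native.  Segment-based native kinship
then conditions the kinship on both sampled alleles being native.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import BreedComposition, KinshipMatrix, NativeKinshipComponents

__all__ = [
    "MarkerMap",
    "HaplotypeSet",
    "SharedSegment",
    "OriginTrack",
    "read_marker_map",
    "read_haplotypes",
    "write_haplotypes",
    "detect_shared_segments",
    "segment_kinship",
    "haplotype_origin",
    "segment_breed_composition",
    "segment_native_kinship",
]

NATIVE = "native"


class SegmentError(ValueError):
    pass


@dataclass
class MarkerMap:
    """Marker map: name, chromosome, position in Mb.

    Positions must be strictly increasing within a chromosome and
    chromosome blocks contiguous.  Positions looking like base pairs
    (max > 10000) are auto-converted to Mb.
    """

    table: pd.DataFrame  # columns Name, Chr, Position

    def __post_init__(self) -> None:
        t = self.table
        for col in ("Name", "Chr", "Position"):
            if col not in t.columns:
                raise SegmentError(f"marker map lacks column {col!r}")
        t = t.copy()
        t["Position"] = t["Position"].astype(float)
        if t["Position"].max() > 10000:
            t["Position"] = t["Position"] / 1e6
        chrs = t["Chr"].astype(str)
        seen: list[str] = []
        for c in chrs:
            if not seen or seen[-1] != c:
                if c in seen:
                    raise SegmentError(f"chromosome {c!r} block is not "
                                       f"contiguous in map")
                seen.append(c)
        t["Chr"] = chrs
        for c, grp in t.groupby("Chr", sort=False):
            if not np.all(np.diff(grp["Position"].to_numpy()) > 0):
                raise SegmentError(f"positions not strictly increasing on "
                                   f"chromosome {c}")
        self.table = t.reset_index(drop=True)
        self.chromosomes = seen

    def __len__(self) -> int:
        return len(self.table)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        out = []
        chrs = self.table["Chr"].to_numpy()
        start = 0
        for k in range(1, len(chrs) + 1):
            if k == len(chrs) or chrs[k] != chrs[start]:
                out.append((chrs[start], slice(start, k)))
                start = k
        return out

    @property
    def positions(self) -> np.ndarray:
        return self.table["Position"].to_numpy()

    def marker_weights(self) -> np.ndarray:
        """Half-interval weight of each marker in Mb; sums to genome_length."""
        w = np.zeros(len(self))
        pos = self.positions
        for _, sl in self.chrom_slices():
            p = pos[sl]
            if len(p) == 1:
                continue
            wk = np.empty(len(p))
            mid = (p[1:] + p[:-1]) / 2.0
            wk[0] = mid[0] - p[0]
            wk[-1] = p[-1] - mid[-1]
            if len(p) > 2:
                wk[1:-1] = mid[1:] - mid[:-1]
            w[sl] = wk
        return w

    @property
    def genome_length(self) -> float:
        """Total map length G: sum over chromosomes of last - first (Mb)."""
        pos = self.positions
        return float(sum(pos[sl][-1] - pos[sl][0]
                         for _, sl in self.chrom_slices()))


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes for a set of individuals.

    ``alleles`` has one row per marker and two columns (haplotype 1 and 2)
    per individual, in the order of ``indiv``.  ``breed`` gives the breed
    label of each individual.
    """

    map: MarkerMap
    alleles: np.ndarray  # (n_markers, 2 * n_indiv) uint8
    indiv: list[str]
    breed: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.indiv = [str(i) for i in self.indiv]
        if self.alleles.shape[0] != len(self.map):
            raise SegmentError("allele row count does not match marker map")
        if self.alleles.shape[1] != 2 * len(self.indiv):
            raise SegmentError("allele matrix must have two columns per "
                               "individual")
        if len(self.breed) != len(self.indiv):
            raise SegmentError("breed labels do not match individuals")
        if not np.isin(self.alleles, (0, 1)).all():
            raise SegmentError("non-binary allele values")

    @property
    def n_indiv(self) -> int:
        return len(self.indiv)

    def hap(self, i: int, which: int) -> np.ndarray:
        """Haplotype ``which`` (0 or 1) of the i-th individual."""
        return self.alleles[:, 2 * i + which]

    def hap_columns(self, breed: str) -> list[int]:
        return [2 * i + w for i, b in enumerate(self.breed) if b == breed
                for w in (0, 1)]

    def subset(self, ids: Sequence[str]) -> "HaplotypeSet":
        pos = {ind: k for k, ind in enumerate(self.indiv)}
        idx = [pos[str(i)] for i in ids]
        cols = [c for i in idx for c in (2 * i, 2 * i + 1)]
        return HaplotypeSet(self.map, self.alleles[:, cols],
                            [self.indiv[i] for i in idx],
                            [self.breed[i] for i in idx])


@dataclass
class SharedSegment:
    chromosome: str
    start: int  # marker index into the map (inclusive)
    end: int    # marker index (inclusive)
    length: float  # Mb, position(end) - position(start)
    n_markers: int


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep=None, engine="python")
    lower = {c.lower(): c for c in df.columns}
    ren = {}
    for canon in ("Name", "Chr", "Position"):
        if canon.lower() not in lower:
            raise SegmentError(f"marker map lacks column {canon!r}")
        ren[lower[canon.lower()]] = canon
    return MarkerMap(df.rename(columns=ren)[["Name", "Chr", "Position"]])


def read_haplotypes(
    geno_paths, map_path, breed_of: Mapping[str, str]
) -> HaplotypeSet:
    """Assemble a HaplotypeSet from one or more genotype files plus a map.

    Genotype file dialect: a header line with haplotype column ids
    ``<indiv>.1 <indiv>.2``, then one whitespace-delimited row per marker:
    marker name followed by 0/1 alleles.  With one file per chromosome the
    files are concatenated in map order.
    """
    mmap = read_marker_map(map_path)
    if isinstance(geno_paths, (str, Path)):
        geno_paths = [geno_paths]
    frames = []
    indiv: list[str] | None = None
    for p in geno_paths:
        with open(p) as fh:
            header = fh.readline().split()
            rows = [line.split() for line in fh if line.strip()]
        cols = header[1:] if header and "." not in header[0] else header
        this_indiv = []
        for k in range(0, len(cols), 2):
            a, b = cols[k], cols[k + 1]
            if not (a.endswith(".1") and b.endswith(".2")
                    and a[:-2] == b[:-2]):
                raise SegmentError(f"haplotype columns {a!r}/{b!r} do not "
                                   f"pair as <indiv>.1 <indiv>.2")
            this_indiv.append(a[:-2])
        if indiv is None:
            indiv = this_indiv
        elif this_indiv != indiv:
            raise SegmentError("individuals differ between haplotype files")
        names = [r[0] for r in rows]
        mat = np.empty((len(rows), len(cols)), dtype=np.uint8)
        for r, row in enumerate(rows):
            vals = row[1:]
            if len(vals) != len(cols):
                raise SegmentError(f"marker {row[0]!r}: expected "
                                   f"{len(cols)} alleles, got {len(vals)}")
            for c, v in enumerate(vals):
                if v not in ("0", "1"):
                    raise SegmentError(f"non-binary allele {v!r} at marker "
                                       f"{row[0]!r}")
                mat[r, c] = v == "1"
        frames.append(pd.DataFrame(mat, index=names))
    combined = pd.concat(frames)
    want = mmap.table["Name"].astype(str).tolist()
    if len(combined) != len(want):
        raise SegmentError(f"haplotype files have {len(combined)} markers, "
                           f"map has {len(want)}")
    missing = set(want) - set(combined.index)
    if missing:
        raise SegmentError(f"markers in map but not in haplotype files: "
                           f"{sorted(missing)[:5]}")
    combined = combined.loc[want]
    breeds = []
    for ind in indiv:
        if ind not in breed_of:
            raise SegmentError(f"no breed label for individual {ind!r}")
        breeds.append(breed_of[ind])
    return HaplotypeSet(mmap, combined.to_numpy(), indiv, breeds)


def write_haplotypes(haps: HaplotypeSet, path, chromosome: str | None = None) -> None:
    """Write haplotypes in the dialect read by :func:`read_haplotypes`."""
    cols = " ".join(f"{i}.1 {i}.2" for i in haps.indiv)
    sl = slice(None)
    names = haps.map.table["Name"]
    if chromosome is not None:
        for c, s in haps.map.chrom_slices():
            if c == chromosome:
                sl = s
                break
        else:
            raise SegmentError(f"chromosome {chromosome!r} not in map")
    with open(path, "w") as fh:
        fh.write(f"Name {cols}\n")
        block = haps.alleles[sl]
        for name, row in zip(names[sl], block):
            fh.write(name + " " + " ".join("1" if v else "0" for v in row)
                     + "\n")


# ---------------------------------------------------------------------------
# shared-segment detection
# ---------------------------------------------------------------------------

def _equal_runs(eq: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector, as (start, end) inclusive."""
    if not eq.any():
        return []
    x = eq.astype(np.int8)
    d = np.diff(x)
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if x[0]:
        starts.insert(0, 0)
    if x[-1]:
        ends.append(len(x) - 1)
    return list(zip(starts, ends))


def detect_shared_segments(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    mmap: MarkerMap,
    min_snp: int = 20,
    min_l: float = 1.0,
) -> list[SharedSegment]:
    """Maximal qualifying runs of marker-wise identity between two haplotypes."""
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    if hap_a.shape != hap_b.shape or len(hap_a) != len(mmap):
        raise SegmentError("haplotypes must be equal-length and aligned to "
                           "the map")
    pos = mmap.positions
    out: list[SharedSegment] = []
    eq_all = hap_a == hap_b
    for chrom, sl in mmap.chrom_slices():
        off = sl.start
        for s, e in _equal_runs(eq_all[sl]):
            n = e - s + 1
            length = pos[off + e] - pos[off + s]
            if n >= min_snp and length >= min_l:
                out.append(SharedSegment(chrom, off + s, off + e,
                                         float(length), n))
    return out


def _shared_mask(hap_a, hap_b, mmap, min_snp, min_l) -> np.ndarray:
    """Boolean marker mask covered by qualifying shared segments."""
    mask = np.zeros(len(mmap), dtype=bool)
    for seg in detect_shared_segments(hap_a, hap_b, mmap, min_snp, min_l):
        mask[seg.start:seg.end + 1] = True
    return mask


# ---------------------------------------------------------------------------
# segment kinship
# ---------------------------------------------------------------------------

def segment_kinship(
    haps: HaplotypeSet, min_snp: int = 20, min_l: float = 1.0
) -> KinshipMatrix:
    """Segment-based kinship matrix f_SEG."""
    mmap = haps.map
    if len(mmap) == 0:
        raise SegmentError("empty marker map")
    G = mmap.genome_length
    if G <= 0:
        raise SegmentError("marker map has zero total length")
    w = mmap.marker_weights()
    n = haps.n_indiv
    H = haps.alleles
    nh = 2 * n

    # shared qualifying length between every pair of haplotype columns
    sh = np.zeros((nh, nh))
    for a in range(nh):
        for b in range(a + 1, nh):
            m = _shared_mask(H[:, a], H[:, b], mmap, min_snp, min_l)
            sh[a, b] = sh[b, a] = w[m].sum()

    f = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                f[i, i] = 0.5 + sh[2 * i, 2 * i + 1] / (2.0 * G)
            else:
                tot = (sh[2 * i, 2 * j] + sh[2 * i, 2 * j + 1]
                       + sh[2 * i + 1, 2 * j] + sh[2 * i + 1, 2 * j + 1])
                f[i, j] = f[j, i] = tot / (4.0 * G)
    return KinshipMatrix(haps.indiv, f, role="fSEG")


# ---------------------------------------------------------------------------
# haplotype origin and native quantities
# ---------------------------------------------------------------------------

@dataclass
class OriginTrack:
    """Per-marker origin of each haplotype of the breed of interest.

    ``origin`` holds, for every marker (rows) and focal haplotype (columns),
    the index into ``breeds`` of the assigned reference breed, or -1 for
    native.  ``freq[b]`` is the matching marker x haplotype matrix of
    segment frequencies in reference breed ``b``: the fraction of that
    breed's haplotypes sharing a qualifying segment covering the marker.
    """

    indiv: list[str]
    breeds: list[str]  # sorted reference breed labels
    origin: np.ndarray  # (n_markers, 2 * n_focal) int8, -1 = native
    freq: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def native_mask(self) -> np.ndarray:
        return self.origin < 0

    def origin_labels(self) -> np.ndarray:
        labels = np.array([NATIVE] + self.breeds, dtype=object)
        return labels[self.origin + 1]

    def write(self, out_dir) -> dict[str, Path]:
        """One marker x haplotype character file per origin breed (first
        letter of the breed name marks assigned markers, '.' elsewhere),
        plus one frequency matrix per breed."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cols = [f"{i}.{w}" for i in self.indiv for w in (1, 2)]
        paths = {}
        for k, b in enumerate(self.breeds):
            letter = b[0].upper()
            chars = np.where(self.origin == k, letter, ".")
            df = pd.DataFrame(chars, columns=cols)
            p = out_dir / f"origin_{b}.txt"
            df.to_csv(p, sep=" ", index=False)
            fq = out_dir / f"freq_{b}.txt"
            pd.DataFrame(self.freq[b], columns=cols).to_csv(
                fq, sep=" ", index=False, float_format="%.4f")
            paths[b] = p
        return paths


def haplotype_origin(
    haps: HaplotypeSet,
    this_breed: str,
    ref_breeds: Sequence[str],
    min_snp: int = 20,
    min_l: float = 1.0,
    ub_freq: float = 0.01,
) -> OriginTrack:
    """Classify each marker of each focal haplotype as native or introgressed.

    For each haplotype h of ``this_breed`` and reference breed B, the
    segment frequency at marker m is the fraction of B's haplotypes sharing
    a qualifying segment with h that covers m.  The marker's origin is the
    highest-frequency breed if that frequency reaches ``ub_freq`` (ties go
    to the first breed in sorted label order), otherwise native.
    """
    ref_breeds = sorted(set(map(str, ref_breeds)))
    if not ref_breeds:
        raise SegmentError("no reference breeds given")
    present = set(haps.breed)
    for b in [this_breed] + ref_breeds:
        if b not in present:
            raise SegmentError(f"breed {b!r} has no haplotypes in the set")

    focal_idx = [i for i, b in enumerate(haps.breed) if b == this_breed]
    focal_cols = [c for i in focal_idx for c in (2 * i, 2 * i + 1)]
    mmap = haps.map
    m = len(mmap)
    H = haps.alleles

    freq = {b: np.zeros((m, len(focal_cols))) for b in ref_breeds}
    for b in ref_breeds:
        cols = haps.hap_columns(b)
        for kf, fc in enumerate(focal_cols):
            cov = np.zeros(m)
            for rc in cols:
                cov += _shared_mask(H[:, fc], H[:, rc], mmap, min_snp, min_l)
            freq[b][:, kf] = cov / len(cols)

    stack = np.stack([freq[b] for b in ref_breeds])  # (B, m, H)
    best = stack.argmax(axis=0)
    best_freq = stack.max(axis=0)
    origin = np.where(best_freq >= ub_freq, best, -1).astype(np.int8)
    return OriginTrack(indiv=[haps.indiv[i] for i in focal_idx],
                       breeds=ref_breeds, origin=origin, freq=freq)


def segment_breed_composition(track: OriginTrack, mmap: MarkerMap) -> BreedComposition:
    """Length-weighted genome fraction per origin class, per individual.

    The native column is the segment-based native contribution N_SEG(i).
    """
    w = mmap.marker_weights()
    G = w.sum()
    classes = [NATIVE] + track.breeds
    rows = {}
    for k, ind in enumerate(track.indiv):
        o = track.origin[:, 2 * k:2 * k + 2]
        vals = []
        for ci, cls in enumerate(classes):
            code = ci - 1  # native = -1
            vals.append(((o == code) * w[:, None]).sum() / (2.0 * G))
        rows[ind] = vals
    table = pd.DataFrame.from_dict(rows, orient="index", columns=classes)
    table = table.rename(columns={NATIVE: "native"})
    return BreedComposition(table)


def segment_native_kinship(
    haps: HaplotypeSet,
    track: OriginTrack,
    min_snp: int = 20,
    min_l: float = 1.0,
) -> NativeKinshipComponents:
    """Components of the segment-based native kinship.

    Numerator f_SEG&N: probability that two sampled alleles lie in identical
    shared segments *and* both are native.  Denominator f_N: probability
    both are native.  The with-replacement same-haplotype draw on the
    diagonal contributes its native length to both matrices.
    """
    sub = haps.subset(track.indiv)
    mmap = sub.map
    w = mmap.marker_weights()
    G = w.sum()
    n = sub.n_indiv
    H = sub.alleles
    nat = track.native_mask()  # (m, 2n) aligned with track.indiv order
    nh = 2 * n

    nat_len = np.array([w[nat[:, a]].sum() for a in range(nh)])
    both_nat = np.zeros((nh, nh))
    shared_nat = np.zeros((nh, nh))
    for a in range(nh):
        both_nat[a, a] = nat_len[a]
        shared_nat[a, a] = nat_len[a]
        for b in range(a + 1, nh):
            bn = nat[:, a] & nat[:, b]
            both_nat[a, b] = both_nat[b, a] = w[bn].sum()
            m = _shared_mask(H[:, a], H[:, b], mmap, min_snp, min_l)
            shared_nat[a, b] = shared_nat[b, a] = w[m & bn].sum()

    fn = np.zeros((n, n))
    fsn = np.zeros((n, n))
    for i in range(n):
        a1, a2 = 2 * i, 2 * i + 1
        for j in range(i, n):
            b1, b2 = 2 * j, 2 * j + 1
            if i == j:
                # with replacement: 2 same-allele draws + 2 cross draws
                fn[i, i] = (nat_len[a1] + nat_len[a2]
                            + 2 * both_nat[a1, a2]) / (4.0 * G)
                fsn[i, i] = (nat_len[a1] + nat_len[a2]
                             + 2 * shared_nat[a1, a2]) / (4.0 * G)
            else:
                fn[i, j] = fn[j, i] = (
                    both_nat[a1, b1] + both_nat[a1, b2]
                    + both_nat[a2, b1] + both_nat[a2, b2]) / (4.0 * G)
                fsn[i, j] = fsn[j, i] = (
                    shared_nat[a1, b1] + shared_nat[a1, b2]
                    + shared_nat[a2, b1] + shared_nat[a2, b2]) / (4.0 * G)

    return NativeKinshipComponents(
        numerator=KinshipMatrix(sub.indiv, fsn, role="fSEG&N"),
        denominator=KinshipMatrix(sub.indiv, fn, role="fN"),
    )
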