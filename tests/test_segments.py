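"""Shared-segment detection, segment kinship, origin classification."""
import numpy as np
import pandas as pd
import pytest

from ocskit import (detect_shared_segments, haplotype_origin,
                    read_haplotypes, segment_breed_composition,
                    segment_kinship, segment_native_kinship,
                    write_haplotypes)
from ocskit.segments import (HaplotypeSet, MarkerMap, SegmentError,
                             _shared_mask)


def uniform_map(n_markers=40, spacing=0.1, n_chrom=1):
    rows = []
    for c in range(n_chrom):
        for k in range(n_markers):
            rows.append({"Name": f"c{c}m{k}", "Chr": str(c + 1),
                         "Position": k * spacing})
    return MarkerMap(pd.DataFrame(rows))


def hapset(mmap, columns, breeds=None):
    """columns: list of 0/1 vectors, two per individual."""
    alleles = np.column_stack(columns).astype(np.uint8)
    n = alleles.shape[1] // 2
    ids = [f"I{k}" for k in range(n)]
    return HaplotypeSet(mmap, alleles, ids, breeds or ["B"] * n)


# ---------------------------------------------------------------------------
# naive oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def naive_shared_weight(a, b, mmap, min_snp, min_l):
    """Brute-force qualifying-run weight by scanning every marker window."""
    pos = mmap.positions
    w = mmap.marker_weights()
    total = 0.0
    for _, sl in mmap.chrom_slices():
        i = sl.start
        while i < sl.stop:
            if a[i] == b[i]:
                j = i
                while j + 1 < sl.stop and a[j + 1] == b[j + 1]:
                    j += 1
                if (j - i + 1) >= min_snp and pos[j] - pos[i] >= min_l:
                    total += w[i:j + 1].sum()
                i = j + 1
            else:
                i += 1
    return total


def naive_segment_kinship(haps, min_snp, min_l):
    G = haps.map.genome_length
    n = haps.n_indiv
    f = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                s = naive_shared_weight(haps.hap(i, 0), haps.hap(i, 1),
                                        haps.map, min_snp, min_l)
                f[i, i] = 0.5 + s / (2 * G)
            else:
                tot = sum(
                    naive_shared_weight(haps.hap(i, a), haps.hap(j, b),
                                        haps.map, min_snp, min_l)
                    for a in (0, 1) for b in (0, 1))
                f[i, j] = tot / (4 * G)
    return f


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def test_identical_haplotypes_form_one_segment():
    mmap = uniform_map(40, 0.1)  # 3.9 Mb chromosome
    h = np.ones(40, dtype=np.uint8)
    segs = detect_shared_segments(h, h, mmap, min_snp=20, min_l=1.0)
    assert len(segs) == 1
    assert (segs[0].start, segs[0].end, segs[0].n_markers) == (0, 39, 40)
    assert segs[0].length == pytest.approx(3.9)


def test_periodic_mismatch_leaves_no_segment():
    mmap = uniform_map(100, 0.1)
    a = np.zeros(100, dtype=np.uint8)
    b = a.copy()
    b[::10] = 1  # runs of 9 < min_snp = 20
    assert detect_shared_segments(a, b, mmap, 20, 1.0) == []


def test_planted_run_respects_min_length():
    rng = np.random.default_rng(5)
    mmap = uniform_map(100, 0.1)  # planted run of 25 markers = 2.4 Mb
    a = rng.integers(0, 2, 100).astype(np.uint8)
    b = 1 - a
    a[40:65] = b[40:65] = 1
    segs = detect_shared_segments(a, b, mmap, min_snp=20, min_l=2.5)
    assert segs == []
    segs = detect_shared_segments(a, b, mmap, min_snp=20, min_l=1.0)
    assert len(segs) == 1
    assert (segs[0].start, segs[0].end) == (40, 64)
    assert segs[0].length == pytest.approx(2.4)


def test_runs_do_not_cross_chromosomes():
    mmap = uniform_map(30, 0.1, n_chrom=2)
    h = np.ones(60, dtype=np.uint8)
    segs = detect_shared_segments(h, h, mmap, min_snp=20, min_l=1.0)
    assert len(segs) == 2
    assert {s.chromosome for s in segs} == {"1", "2"}


# ---------------------------------------------------------------------------
# segment kinship
# ---------------------------------------------------------------------------

def test_identical_individuals_have_kinship_one():
    mmap = uniform_map(40, 0.1)
    h = np.ones(40, dtype=np.uint8)
    haps = hapset(mmap, [h, h, h, h])
    f = segment_kinship(haps, 20, 1.0)
    assert np.allclose(f.values, 1.0)


def test_self_kinship_of_unshared_haplotypes_is_half():
    rng = np.random.default_rng(0)
    mmap = uniform_map(60, 0.1)
    a = rng.integers(0, 2, 60).astype(np.uint8)
    haps = hapset(mmap, [a, 1 - a])  # fully heterozygous
    f = segment_kinship(haps, 20, 1.0)
    assert f.values[0, 0] == pytest.approx(0.5)


def test_segment_kinship_matches_naive_scan(sim_haps):
    haps, _ = sim_haps
    sub = haps.subset(haps.indiv[-10:])  # gene-dropped, related individuals
    f = segment_kinship(sub, 20, 1.0)
    expected = naive_segment_kinship(sub, 20, 1.0)
    assert np.allclose(f.values, expected, atol=1e-12)
    assert f.values.max() <= 1 + 1e-12
    assert np.diag(f.values).min() >= 0.5 - 1e-12


@pytest.mark.parametrize("tighter", [{"min_snp": 40}, {"min_l": 2.0}])
def test_tightening_thresholds_never_increases_fseg(sim_haps, tighter):
    haps, _ = sim_haps
    sub = haps.subset(haps.indiv[-8:])
    base = dict(min_snp=20, min_l=1.0)
    loose = segment_kinship(sub, **base).values
    base.update(tighter)
    tight = segment_kinship(sub, **base).values
    assert (tight <= loose + 1e-12).all()


def test_fseg_correlates_with_fped_on_genedropped_data(sim_haps, sim_ped):
    from scipy.stats import spearmanr

    from ocskit import pedigree_kinship
    haps, _ = sim_haps
    ids = [i for i in haps.indiv if i.startswith("X")][:30]
    fs = segment_kinship(haps.subset(ids), 20, 1.0)
    fp = pedigree_kinship(sim_ped).submatrix(ids)
    iu = np.triu_indices(len(ids), 1)
    rho = spearmanr(fs.values[iu], fp.values[iu]).statistic
    assert rho > 0.8


# ---------------------------------------------------------------------------
# haplotype origin
# ---------------------------------------------------------------------------

def planted_reference_fixture():
    """Focal haplotype carries a 3-Mb foreign block shared with 5 of 50
    reference haplotypes; truth known by construction."""
    rng = np.random.default_rng(21)
    mmap = uniform_map(120, 0.1)  # 11.9 Mb
    block = slice(40, 71)  # 31 markers, 3.0 Mb
    foreign_block = rng.integers(0, 2, 31).astype(np.uint8)
    focal = rng.integers(0, 2, 120).astype(np.uint8)
    focal[block] = foreign_block
    focal2 = rng.integers(0, 2, 120).astype(np.uint8)  # second focal hap
    cols = [focal, focal2]
    breeds = ["Angler"]
    for r in range(25):  # 50 Holstein haplotypes
        h1 = rng.integers(0, 2, 120).astype(np.uint8)
        h2 = rng.integers(0, 2, 120).astype(np.uint8)
        for h, carries in ((h1, r < 3), (h2, r < 2)):
            if carries:  # 5 of 50 carry the block, with pinned boundaries
                h[block] = foreign_block
                h[block.start - 1] = 1 - focal[block.start - 1]
                h[block.stop] = 1 - focal[block.stop]
        cols += [h1, h2]
        breeds.append("Holstein")
    haps = hapset(mmap, cols, breeds)
    return haps, block


def test_origin_frequency_and_assignment():
    haps, block = planted_reference_fixture()
    track = haplotype_origin(haps, "Angler", ["Holstein"], min_snp=20,
                             min_l=1.0, ub_freq=0.01)
    freq = track.freq["Holstein"][:, 0]
    inside = np.arange(block.start, block.stop)
    assert freq[inside].max() == pytest.approx(5 / 50)
    labels = track.origin_labels()[:, 0]
    assert (labels[inside] == "Holstein").all()
    outside = np.setdiff1d(np.arange(120), inside)
    assert (labels[outside] == "native").all()


def test_origin_native_when_no_qualifying_run():
    rng = np.random.default_rng(3)
    mmap = uniform_map(60, 0.1)
    cols = [rng.integers(0, 2, 60).astype(np.uint8) for _ in range(6)]
    # make reference disagree with focal everywhere (no long runs)
    cols[2] = 1 - cols[0]
    haps = hapset(mmap, cols, ["Angler", "Holstein", "Holstein"])
    track = haplotype_origin(haps, "Angler", ["Holstein"], 20, 1.0, 0.01)
    assert (track.origin[:, 0] == -1).all()
    assert track.freq["Holstein"][:, 0].max() == 0.0


def test_origin_unknown_breed_errors():
    haps, _ = planted_reference_fixture()
    with pytest.raises(SegmentError, match="Jersey"):
        haplotype_origin(haps, "Angler", ["Jersey"], 20, 1.0, 0.01)


# ---------------------------------------------------------------------------
# composition and native kinship
# ---------------------------------------------------------------------------

def test_composition_all_native_and_half_foreign():
    haps, block = planted_reference_fixture()
    track = haplotype_origin(haps, "Angler", ["Holstein"], 20, 1.0, 0.01)
    comp = segment_breed_composition(track, haps.map)
    G = haps.map.genome_length
    w = haps.map.marker_weights()
    expected = w[block].sum() / (2 * G)  # block on one of two haplotypes
    est = comp.table.loc["I0", "Holstein"]
    assert est == pytest.approx(expected, abs=1e-9)
    assert comp.table.loc["I0"].sum() == pytest.approx(1.0)


def test_native_kinship_reduces_to_segment_kinship(sim_haps):
    from ocskit.segments import OriginTrack
    haps, _ = sim_haps
    sub = haps.subset(haps.indiv[-6:])
    all_native = OriginTrack(indiv=sub.indiv, breeds=["Holstein"],
                             origin=np.full((len(sub.map), 12), -1,
                                            dtype=np.int8))
    comp = segment_native_kinship(sub, all_native, 20, 1.0)
    f = segment_kinship(sub, 20, 1.0)
    assert np.allclose(comp.denominator.values, 1.0)
    assert np.allclose(comp.numerator.values, f.values, atol=1e-12)


def test_disjoint_native_regions_flagged_undefined():
    mmap = uniform_map(60, 0.1)
    rng = np.random.default_rng(9)
    cols = [rng.integers(0, 2, 60).astype(np.uint8) for _ in range(4)]
    from ocskit.segments import OriginTrack
    origin = np.full((60, 4), 0, dtype=np.int8)
    origin[:30, :2] = -1   # individual 0 native on first half only
    origin[30:, 2:] = -1   # individual 1 native on second half only
    track = OriginTrack(indiv=["I0", "I1"], breeds=["Holstein"],
                        origin=origin)
    haps = HaplotypeSet(mmap, np.column_stack(cols), ["I0", "I1"],
                        ["Angler", "Angler"])
    comp = segment_native_kinship(haps, track, 20, 1.0)
    assert comp.denominator.loc("I0", "I1") == 0.0
    assert np.isnan(comp.ratio().loc["I0", "I1"])


def test_native_kinship_matches_masked_naive_scan(sim_haps):
    """Masked-overlap oracle: recompute both matrices marker by marker."""
    haps, origin = sim_haps
    focal = [k for k, b in enumerate(haps.breed) if b == "Angler"]
    take = focal[-6:]
    ids = [haps.indiv[k] for k in take]
    sub = haps.subset(ids)
    track = haplotype_origin(haps, "Angler", ["Holstein"], 20, 1.0, 0.01)
    keep = [track.indiv.index(i) for i in ids]
    cols = [c for k in keep for c in (2 * k, 2 * k + 1)]
    from ocskit.segments import OriginTrack
    sub_track = OriginTrack(indiv=ids, breeds=track.breeds,
                            origin=track.origin[:, cols])
    comp = segment_native_kinship(sub, sub_track, 20, 1.0)

    w = sub.map.marker_weights()
    G = w.sum()
    nat = sub_track.native_mask()
    n = len(ids)
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for a in (2 * i, 2 * i + 1):
                for b in (2 * j, 2 * j + 1):
                    both = nat[:, a] & nat[:, b]
                    if a == b:
                        den += w[both].sum()
                        num += w[both].sum()
                    else:
                        shared = _shared_mask(sub.alleles[:, a],
                                              sub.alleles[:, b],
                                              sub.map, 20, 1.0)
                        den += w[both].sum()
                        num += w[shared & both].sum()
            assert comp.denominator.values[i, j] == pytest.approx(
                den / (4 * G), abs=1e-12)
            assert comp.numerator.values[i, j] == pytest.approx(
                num / (4 * G), abs=1e-12)
    assert (comp.numerator.values
            <= segment_kinship(sub, 20, 1.0).values + 1e-12).all()


def test_composition_consistent_with_denominator_diagonal(sim_haps):
    haps, _ = sim_haps
    track = haplotype_origin(haps, "Angler", ["Holstein"], 20, 1.0, 0.01)
    comp = segment_breed_composition(track, haps.map)
    ids = track.indiv[:8]
    sub = haps.subset(ids)
    from ocskit.segments import OriginTrack
    cols = [c for i in ids for c in
            (2 * track.indiv.index(i), 2 * track.indiv.index(i) + 1)]
    nk = segment_native_kinship(
        sub, OriginTrack(indiv=ids, breeds=track.breeds,
                         origin=track.origin[:, cols]), 20, 1.0)
    w = haps.map.marker_weights()
    G = w.sum()
    nat = track.native_mask()
    for i, ind in enumerate(ids):
        k = track.indiv.index(ind)
        both = w[nat[:, 2 * k] & nat[:, 2 * k + 1]].sum() / G
        expected = 0.5 * comp.native[ind] + 0.5 * both
        assert nk.denominator.loc(ind, ind) == pytest.approx(expected,
                                                             abs=1e-12)


# ---------------------------------------------------------------------------
# I/O round trip
# ---------------------------------------------------------------------------

def test_haplotype_roundtrip(tmp_path, sim_haps):
    haps, _ = sim_haps
    sub = haps.subset(haps.indiv[:5])
    map_path = tmp_path / "map.txt"
    sub.map.table.to_csv(map_path, sep="\t", index=False)
    paths = []
    for chrom in sub.map.chromosomes:
        p = tmp_path / f"chr{chrom}.txt"
        write_haplotypes(sub, p, chrom)
        paths.append(p)
    breed_of = dict(zip(sub.indiv, sub.breed))
    back = read_haplotypes(paths[::-1], map_path, breed_of)  # out of order
    assert back.indiv == sub.indiv
    assert np.array_equal(back.alleles, sub.alleles)


def test_read_rejects_marker_count_mismatch(tmp_path, sim_haps):
    haps, _ = sim_haps
    sub = haps.subset(haps.indiv[:2])
    map_path = tmp_path / "map.txt"
    sub.map.table.to_csv(map_path, sep="\t", index=False)
    p = tmp_path / "geno.txt"
    write_haplotypes(sub, p, sub.map.chromosomes[0])  # only chromosome 1
    with pytest.raises(SegmentError, match="markers"):
        read_haplotypes([p], map_path, dict(zip(sub.indiv, sub.breed)))
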