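"""Pedigree ingestion, repair, kinship recursions, and native components."""
import io

import numpy as np
import pandas as pd
import pytest

from ocskit import (equivalent_complete_generations,
                    pedigree_breed_composition, pedigree_kinship,
                    pedigree_native_kinship, prepare_pedigree, read_pedigree)
from ocskit.containers import KinshipMatrix
from ocskit.pedigree import Pedigree, PedigreeError
from ocskit.simulate import gene_drop

from conftest import make_pedigree


# ---------------------------------------------------------------------------
# reading and preparation
# ---------------------------------------------------------------------------

def test_read_minimal_file(tmp_path):
    p = tmp_path / "ped.csv"
    p.write_text("Indiv,Sire,Dam,Sex,Born,Breed\n"
                 "A,,,male,2000,Angler\n"
                 "B,0,NA,female,2000,Angler\n"
                 "C,A,B,male,2001,Angler\n")
    ped = read_pedigree(p)
    assert len(ped) == 3
    assert ped.df["Sire"].isna().tolist() == [True, True, False]


def test_read_rejects_duplicate_id(tmp_path):
    p = tmp_path / "ped.csv"
    p.write_text("Indiv,Sire,Dam\nA,,\nA,,\n")
    with pytest.raises(PedigreeError, match="A"):
        read_pedigree(p)


def test_read_requires_sire_column(tmp_path):
    p = tmp_path / "ped.csv"
    p.write_text("id,father,mother\nA,,\n")
    with pytest.raises(PedigreeError, match="Sire"):
        read_pedigree(p, column_map={"Indiv": "id", "Dam": "mother"})
    ped = read_pedigree(p, column_map={"Indiv": "id", "Sire": "father",
                                       "Dam": "mother"})
    assert ped.ids == ["A"]


def test_prepare_sorts_parents_first():
    df = pd.DataFrame({
        "Indiv": ["C", "A", "B"], "Sire": ["A", None, None],
        "Dam": ["B", None, None], "Sex": ["male", "male", "female"],
        "Born": pd.array([2001, 2000, 2000], dtype="Int64"),
        "Breed": "Angler"})
    ped = prepare_pedigree(Pedigree(df))
    order = ped.ids
    assert order.index("A") < order.index("C")
    assert order.index("B") < order.index("C")


def test_prepare_adds_founder_rows():
    df = pd.DataFrame({"Indiv": ["C"], "Sire": ["A"], "Dam": ["B"],
                       "Sex": ["male"],
                       "Born": pd.array([2001], dtype="Int64"),
                       "Breed": ["Angler"]})
    ped = prepare_pedigree(Pedigree(df))
    assert set(ped.ids) == {"A", "B", "C"}
    added = ped.df.set_index("Indiv")
    assert added.loc["A", "Sex"] == "male"
    assert added.loc["B", "Sex"] == "female"
    assert any("founder row added" in r for r in ped.repairs)


def test_prepare_breaks_cycle():
    df = pd.DataFrame({
        "Indiv": ["A", "B"], "Sire": ["B", "A"], "Dam": [None, None],
        "Sex": ["male", "male"],
        "Born": pd.array([2000, 2001], dtype="Int64"), "Breed": "Angler"})
    ped = prepare_pedigree(Pedigree(df))
    assert any("cycle broken" in r for r in ped.repairs)
    # the later-born individual (B) lost its parent link
    assert ped.df.set_index("Indiv").loc["B", "Sire"] is None or \
        pd.isna(ped.df.set_index("Indiv").loc["B", "Sire"])
    pedigree_kinship(ped)  # recursion must now terminate


def test_prepare_severs_both_sex_usage():
    df = pd.DataFrame({
        "Indiv": ["P", "X", "Y"], "Sire": [None, "P", None],
        "Dam": [None, None, "P"], "Sex": ["male", "male", "female"],
        "Born": pd.array([2000, 2001, 2001], dtype="Int64"),
        "Breed": "Angler"})
    ped = prepare_pedigree(Pedigree(df))
    sub = ped.df.set_index("Indiv")
    assert pd.isna(sub.loc["X", "Sire"]) and pd.isna(sub.loc["Y", "Dam"])
    assert any("both sire and dam" in r for r in ped.repairs)


@pytest.mark.parametrize("born,expected", [(1960, "Angler"),
                                           (1975, "unknown"),
                                           (None, "unknown")])
def test_last_native_relabels_late_founders(born, expected):
    df = pd.DataFrame({"Indiv": ["F"], "Sire": [None], "Dam": [None],
                       "Sex": ["male"],
                       "Born": pd.array([born], dtype="Int64"),
                       "Breed": ["Angler"]})
    ped = prepare_pedigree(Pedigree(df), this_breed="Angler",
                           last_native=1970)
    assert ped.df["Breed"].iloc[0] == expected


def test_keep_prunes_to_ancestors(full_sibs):
    pruned = prepare_pedigree(full_sibs, keep={"S1"})
    assert set(pruned.ids) == {"A", "B", "S1"}


# ---------------------------------------------------------------------------
# kinship: closed forms
# ---------------------------------------------------------------------------

def test_parent_offspring_kinship(trio):
    f = pedigree_kinship(trio)
    assert f.loc("A", "C") == pytest.approx(0.25)
    assert f.loc("C", "C") == pytest.approx(0.5)
    assert f.loc("A", "B") == 0.0


def test_full_sib_and_inbred_offspring(full_sibs):
    f = pedigree_kinship(full_sibs)
    assert f.loc("S1", "S2") == pytest.approx(0.25)
    # offspring of full sibs: F = 0.25, diagonal (1 + F)/2 = 0.625
    assert f.loc("O", "O") == pytest.approx(0.625)


def test_additive_matrix_and_diagonal_bounds(sim_ped):
    f = pedigree_kinship(sim_ped)
    assert np.allclose(f.additive, 2 * f.values)
    d = np.diag(f.values)
    assert np.all(d >= 0.5 - 1e-12) and np.all(d <= 1.0 + 1e-12)
    assert np.allclose(f.values, f.values.T)


def test_offspring_inbreeding_equals_parent_kinship(sim_ped):
    f = pedigree_kinship(sim_ped)
    df = sim_ped.df
    pos = {i: k for k, i in enumerate(df["Indiv"])}
    for row in df.itertuples(index=False):
        if row.Sire is not None and row.Dam is not None:
            F_off = 2 * f.values[pos[row.Indiv], pos[row.Indiv]] - 1
            assert F_off == pytest.approx(f.loc(row.Sire, row.Dam), abs=1e-12)


def test_founder_kinship_matrix_is_honoured(trio):
    fk = KinshipMatrix(["A", "B"], np.array([[0.5, 0.25], [0.25, 0.5]]))
    f = pedigree_kinship(trio, founder_kinship=fk)
    assert f.loc("A", "B") == pytest.approx(0.25)
    # offspring of related parents is inbred
    assert f.loc("C", "C") == pytest.approx(0.5 * (1 + 0.25))


def test_founder_kinship_rejects_non_founder(trio):
    fk = KinshipMatrix(["C"], np.array([[0.5]]))
    with pytest.raises(PedigreeError, match="not a founder"):
        pedigree_kinship(trio, founder_kinship=fk)


# ---------------------------------------------------------------------------
# equivalent complete generations
# ---------------------------------------------------------------------------

def test_equigen_closed_forms():
    ped = make_pedigree([
        ("F1", None, None, "male", 2000, "Angler"),
        ("F2", None, None, "female", 2000, "Angler"),
        ("P1", "F1", "F2", "male", 2001, "Angler"),    # both parents known
        ("P2", None, None, "female", 2001, "Angler"),  # founder dam
        ("K", "P1", "P2", "male", 2002, "Angler"),
    ])
    eg = equivalent_complete_generations(ped)
    assert eg["F1"] == 0.0
    assert eg["P1"] == 1.0           # parents known, grandparents unknown
    # K: both parents known (1), two of four grandparents known (2/4)
    assert eg["K"] == pytest.approx(1.5)


def test_equigen_monotone_in_known_grandparents():
    base = [("P", None, None, "male", 2000, "Angler"),
            ("Q", None, None, "female", 2000, "Angler"),
            ("K", "P", "Q", "male", 2002, "Angler")]
    eg0 = equivalent_complete_generations(make_pedigree(base))
    richer = [("G", None, None, "male", 1998, "Angler"),
              ("H", None, None, "female", 1998, "Angler"),
              ("P", "G", "H", "male", 2000, "Angler"),
              ("Q", None, None, "female", 2000, "Angler"),
              ("K", "P", "Q", "male", 2002, "Angler")]
    eg1 = equivalent_complete_generations(make_pedigree(richer))
    assert eg1["K"] > eg0["K"]


# ---------------------------------------------------------------------------
# breed composition and native kinship
# ---------------------------------------------------------------------------

def test_breed_composition_closed_forms():
    ped = make_pedigree([
        ("N", None, None, "male", 1960, "Angler"),
        ("H", None, None, "female", 1960, "Holstein"),
        ("C", "N", "H", "male", 1965, "Angler"),
    ])
    comp = pedigree_breed_composition(ped, "Angler")
    assert comp.native["N"] == 1.0
    assert comp.table.loc["C", "native"] == pytest.approx(0.5)
    assert comp.table.loc["C", "Holstein"] == pytest.approx(0.5)
    assert np.allclose(comp.table.sum(axis=1), 1.0)


def test_missing_parent_counts_as_unknown_origin():
    ped = make_pedigree([
        ("N", None, None, "male", 1960, "Angler"),
        ("C", "N", None, "male", 1965, "Angler"),
    ])
    comp = pedigree_breed_composition(ped, "Angler")
    assert comp.table.loc["C", "native"] == pytest.approx(0.5)
    assert comp.table.loc["C", "unknown"] == pytest.approx(0.5)


def test_native_kinship_reduces_to_kinship_when_all_native(sim_ped):
    # relabel everything native: numerator must equal fPED, denominator 1
    df = sim_ped.df.copy()
    df["Breed"] = "Angler"
    ped = Pedigree(df, prepared=True)
    comp = pedigree_native_kinship(ped, "Angler")
    f = pedigree_kinship(ped)
    assert np.allclose(comp.numerator.values, f.values, atol=1e-12)
    assert np.allclose(comp.denominator.values, 1.0)


def test_native_kinship_mixed_founder_closed_form():
    ped = make_pedigree([
        ("N", None, None, "male", 1960, "Angler"),
        ("U", None, None, "female", 1960, "unknown"),
        ("I", "N", "U", "male", 1965, "Angler"),
    ])
    comp = pedigree_native_kinship(ped, "Angler")
    # f_N(I, I) = 1/2 * N(I) + 1/2 * f_N(N, U) = 1/2 * 1/2 + 0 = 0.25
    assert comp.denominator.loc("I", "I") == pytest.approx(0.25)
    assert comp.numerator.loc("I", "I") == pytest.approx(0.25)
    assert comp.ratio().loc["I", "I"] == pytest.approx(1.0)


def test_native_kinship_error_when_breed_absent(trio):
    with pytest.raises(PedigreeError, match="absent"):
        pedigree_native_kinship(trio, "NoSuchBreed")


def test_component_inequalities(sim_ped):
    f = pedigree_kinship(sim_ped)
    comp = pedigree_native_kinship(sim_ped, "Angler")
    num, den = comp.numerator.values, comp.denominator.values
    assert (num <= den + 1e-12).all()
    assert (num <= f.values + 1e-12).all()
    ratio = comp.ratio().to_numpy()
    ok = ~np.isnan(ratio)
    assert (ratio[ok] >= -1e-12).all() and (ratio[ok] <= 1 + 1e-12).all()


# ---------------------------------------------------------------------------
# gene-dropping oracle agreement
# ---------------------------------------------------------------------------

def test_recursions_match_gene_dropping(sim_ped):
    """All four pedigree probabilities agree with tagged gene dropping."""
    f = pedigree_kinship(sim_ped)
    comp = pedigree_native_kinship(sim_ped, "Angler")
    nc = pedigree_breed_composition(sim_ped, "Angler").native
    ids = sim_ped.ids
    rng = np.random.default_rng(42)
    ii = rng.integers(0, len(ids), 30)
    jj = rng.integers(0, len(ids), 30)
    pairs = [(ids[i], ids[j]) for i, j in zip(ii, jj)]
    pairs += [(i, i) for i in rng.choice(ids, 8, replace=False)]
    gd = gene_drop(sim_ped, this_breed="Angler", pairs=pairs,
                   n_rep=40_000, seed=11)
    for row in gd.pairs.itertuples():
        assert abs(row.fPED - f.loc(row.i, row.j)) <= 3 * row.fPED_se + 1e-9
        assert abs(row.fN - comp.denominator.loc(row.i, row.j)) \
            <= 3 * row.fN_se + 1e-9
        assert abs(row.fIBDN - comp.numerator.loc(row.i, row.j)) \
            <= 3 * row.fIBDN_se + 1e-9
    est = gd.native.set_index("Indiv")
    for ind in rng.choice(ids, 20, replace=False):
        assert abs(est.loc[ind, "NC"] - nc[ind]) \
            <= 3 * max(est.loc[ind, "NC_se"], 1e-9)
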