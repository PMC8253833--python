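"""The staged DE cascade and hypergeometric enrichment."""

import numpy as np
import pytest

from ctcflow import markers as mk
from ctcflow.datamodel import ExpressionMatrix, GeneSetCollection, UnitMismatchError


def _matrix(values, genes=None, cells=None, unit="FPKM"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        genes or [f"g{i}" for i in range(values.shape[0])],
        cells or [f"c{j}" for j in range(values.shape[1])],
        unit=unit,
    )


# ---------------------------------------------------------------------------
# CPM prefilter
# ---------------------------------------------------------------------------

def test_cpm_prefilter_boundaries():
    values = np.ones((3, 10)) * 5.0
    values[0, :3] = 0.5   # CPM < 1 in 3 samples -> removed
    values[1, :2] = 0.5   # exactly 2 -> kept
    m = _matrix(values, unit="CPM")
    mask = mk.cpm_prefilter(m)
    assert mask.tolist() == [False, True, True]


def test_cpm_prefilter_requires_cpm_unit():
    with pytest.raises(UnitMismatchError):
        mk.cpm_prefilter(_matrix(np.ones((2, 4)), unit="FPKM"))


def test_as_cpm_columns_sum_to_million(default_cohort):
    cpm = mk.as_cpm(default_cohort[0])
    assert cpm.unit == "CPM"
    assert np.allclose(cpm.values.sum(axis=0), 1e6)


# ---------------------------------------------------------------------------
# differential test and cascade
# ---------------------------------------------------------------------------

def test_identical_gene_p_one_stage_tested():
    rng = np.random.default_rng(0)
    values = np.abs(rng.normal(4, 1, size=(5, 8)))
    values[0] = 3.0  # identical in both groups
    m = _matrix(values)
    table = mk.differential_test(m, m.cell_ids[:4], m.cell_ids[4:])
    row = table.table.set_index("gene_id").loc["g0"]
    assert row["p"] == pytest.approx(1.0)
    assert row["stage"] == "tested"


def test_planted_de_gene_reaches_initial(two_group):
    matrix, ga, gb, de = two_group
    table = mk.differential_test(matrix, ga, gb)
    stages = table.table.set_index("gene_id")["stage"]
    frac_initial = (stages.loc[de] == "initial").mean()
    assert frac_initial >= 0.95


def test_label_swap_negates_log2fc(two_group):
    matrix, ga, gb, _ = two_group
    t_ab = mk.differential_test(matrix, ga, gb).table.set_index("gene_id")
    t_ba = mk.differential_test(matrix, gb, ga).table.set_index("gene_id")
    assert np.allclose(t_ab["log2fc"], -t_ba["log2fc"], atol=1e-12)
    assert np.allclose(t_ab["p"], t_ba["p"], atol=1e-12)


def test_cascade_invariant_to_gene_order(two_group):
    matrix, ga, gb, _ = two_group
    t1 = mk.run_cascade(matrix, ga, gb)
    perm = np.random.default_rng(1).permutation(matrix.n_genes)
    shuffled = ExpressionMatrix(matrix.values[perm],
                                [matrix.gene_ids[i] for i in perm],
                                matrix.cell_ids)
    t2 = mk.run_cascade(shuffled, ga, gb)
    s1 = t1.table.set_index("gene_id")["stage"].sort_index()
    s2 = t2.table.set_index("gene_id")["stage"].sort_index()
    assert (s1 == s2).all()


def test_stage_nesting(two_group):
    matrix, ga, gb, _ = two_group
    table = mk.run_cascade(matrix, ga, gb)
    final = set(table.at_stage("final"))
    potential = set(table.at_stage("potential"))
    initial = set(table.at_stage("initial"))
    tested = set(table.at_stage("tested"))
    assert final <= potential <= initial <= tested


def test_refine_90_percent_rule_boundary():
    """Initial gene expressed in 89% of the up-group stays initial."""
    rng = np.random.default_rng(5)
    n_a = 100
    values = np.abs(rng.lognormal(2, 0.2, size=(2, n_a + 20)))
    # gene g0: strongly up in A but expressed in only 89/100 A cells
    values[0, :n_a] = 40.0
    values[0, 89:n_a] = 0.5  # 11 A cells below the expressed threshold
    values[0, n_a:] = 0.9
    # gene g1: up in A and expressed in 100%
    values[1, :n_a] = 40.0
    values[1, n_a:] = 0.9
    m = _matrix(values)
    ga, gb = m.cell_ids[:n_a], m.cell_ids[n_a:]
    table = mk.differential_test(m, ga, gb)
    assert set(table.at_stage("initial")) == {"g0", "g1"}
    refined = mk.refine_upregulated(table, m)
    stages = refined.table.set_index("gene_id")["stage"]
    assert stages["g0"] == "initial"
    assert stages["g1"] == "final"


def test_cascade_hand_built_toy_against_walkthrough_oracle():
    """Six genes crafted so each cascade stage filters exactly one pattern.

    Expected stages were derived by an independent step-by-step walk of the
    rules (rank-sum enumeration for p, BH by hand, boundary checks):
      g_up     strong clean DE           -> final
      g_weakfc significant, |lfc| <= 1   -> tested
      g_flat   identical groups          -> tested
      g_sparse strong DE, low expression in up-group -> initial
      g_cpmlow CPM < 1 in many samples   -> filtered_out
      g_null   noise                     -> tested
    """
    n = 12  # 6 vs 6
    a, b = 6, 6
    values = np.zeros((6, n))
    values[0] = [64, 60, 70, 66, 58, 72, 2, 3, 2.5, 3.5, 2, 3]          # g_up
    values[1] = [6, 6.4, 5.8, 6.2, 6.1, 5.9, 3.6, 3.8, 3.5, 3.9, 3.4, 3.7]  # g_weakfc (~0.7 lfc)
    values[2] = [5] * 12                                                 # g_flat
    # g_sparse: clean separation (exact rank-sum p = 2/924) but one up-group
    # cell below the FPKM > 1 expressed threshold -> 5/6 = 83% < 90%
    values[3] = [40, 0.9, 44, 46, 38, 42, 0.2, 0.4, 0.3, 0.1, 0.2, 0.4]
    values[4] = [0.2] * 12                                               # g_cpmlow
    values[5] = [4, 5, 3.8, 4.4, 5.2, 4.1, 4.3, 4.9, 4.0, 4.6, 4.2, 4.8]  # g_null
    genes = ["g_up", "g_weakfc", "g_flat", "g_sparse", "g_cpmlow", "g_null"]
    m = _matrix(values, genes=genes)
    ga, gb = m.cell_ids[:a], m.cell_ids[a:]
    keep = np.array([True, True, True, True, False, True])  # CPM prefilter outcome
    table = mk.refine_upregulated(
        mk.differential_test(m, ga, gb, gene_mask=keep), m
    ).table.set_index("gene_id")["stage"]
    assert table["g_up"] == "final"
    assert table["g_weakfc"] == "tested"
    assert table["g_flat"] == "tested"
    assert table["g_sparse"] == "initial"
    assert table["g_cpmlow"] == "filtered_out"
    assert table["g_null"] == "tested"


def test_empty_initial_set_gives_empty_final():
    rng = np.random.default_rng(7)
    m = _matrix(np.abs(rng.lognormal(2, 0.3, size=(50, 12))))
    table = mk.run_cascade(m, m.cell_ids[:6], m.cell_ids[6:])
    assert table.at_stage("initial") == []
    assert table.at_stage("final") == []


def test_group_too_small_raises(two_group):
    matrix, ga, gb, _ = two_group
    with pytest.raises(ValueError):
        mk.differential_test(matrix, ga[:1], gb)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_enrich_whole_set_exact_p():
    sets = GeneSetCollection(sets={"S": [f"m{i}" for i in range(5)]})
    query = [f"m{i}" for i in range(5)]
    df = mk.enrich(query, sets, universe=10)
    assert df.loc[0, "p"] == pytest.approx(1 / 252, abs=1e-12)  # 1 / C(10,5)


def test_enrich_disjoint_query_p_one():
    sets = GeneSetCollection(sets={"S": ["a", "b", "c"]})
    df = mk.enrich(["x", "y"], sets, universe=20)
    assert df.loc[0, "overlap"] == 0
    assert df.loc[0, "p"] == pytest.approx(1.0)


def test_enrich_empty_query_raises():
    sets = GeneSetCollection(sets={"S": ["a"]})
    with pytest.raises(ValueError):
        mk.enrich([], sets, universe=10)


def test_planted_program_ranks_first(default_cohort):
    matrix, _, _, sets, truth = default_cohort
    df = mk.enrich(truth.program_genes["HV"], sets, universe=list(matrix.gene_ids))
    assert df.loc[0, "set_name"] == "PROGRAM_HV"
    assert df.loc[0, "q"] < 1e-10
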