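"""Relative-expression scoring and cycling classification."""

import numpy as np
import pytest

from ctcflow import cell_cycle as cc
from ctcflow.datamodel import CellClass, ExpressionMatrix
from ctcflow.simulate import SyntheticSpec, generate_cohort


def _matrix(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        genes or [f"g{i}" for i in range(values.shape[0])],
        cells or [f"c{j}" for j in range(values.shape[1])],
    )


def test_relative_expression_hand_case():
    # FPKM (1, 3, 7) -> log2 (1, 2, 3) -> centered (-1, 0, +1)
    m = _matrix([[1.0, 3.0, 7.0]])
    e = cc.relative_expression(m, ["g0"])
    assert np.allclose(e.to_numpy(), [[-1.0, 0.0, 1.0]])


def test_constant_gene_row_is_zero():
    m = _matrix([[5.0, 5.0, 5.0], [1.0, 3.0, 7.0]])
    e = cc.relative_expression(m, ["g0", "g1"])
    assert np.allclose(e.loc["g0"], 0.0)


def test_rows_center_to_zero(default_cohort):
    matrix, _, _, sets, _ = default_cohort
    e = cc.relative_expression(matrix, sets["G1S"])
    assert np.all(np.abs(e.to_numpy().sum(axis=1)) < 1e-9)


def test_cell_permutation_equivariance():
    rng = np.random.default_rng(0)
    m = _matrix(np.abs(rng.normal(4, 2, size=(6, 5))))
    e = cc.relative_expression(m, list(m.gene_ids))
    perm = [3, 1, 4, 0, 2]
    m2 = ExpressionMatrix(m.values[:, perm], m.gene_ids,
                          [m.cell_ids[i] for i in perm])
    e2 = cc.relative_expression(m2, list(m.gene_ids))
    assert np.allclose(e[ [m.cell_ids[i] for i in perm] ].to_numpy(), e2.to_numpy())


def test_missing_genes_dropped_with_warning(caplog):
    m = _matrix([[1.0, 2.0, 4.0]])
    with caplog.at_level("WARNING", logger="ctcflow"):
        e = cc.relative_expression(m, ["g0", "absent"])
    assert list(e.index) == ["g0"]
    with pytest.raises(ValueError):
        cc.relative_expression(m, ["absent"])


def test_scores_zero_for_identical_cells():
    profile = np.abs(np.random.default_rng(1).normal(4, 2, size=100))
    m = _matrix(np.tile(profile[:, None], (1, 4)))
    scores = cc.cycle_scores(m, g1s_set=list(m.gene_ids[:40]), g2m_set=list(m.gene_ids[40:]))
    assert all(s.g1s_score == pytest.approx(0.0) and s.g2m_score == pytest.approx(0.0)
               for s in scores)


def test_scores_invariant_to_gene_order(default_cohort):
    matrix, _, _, sets, _ = default_cohort
    scores = cc.cycle_scores(matrix, sets["G1S"], sets["G2M"])
    perm = np.random.default_rng(2).permutation(matrix.n_genes)
    shuffled = ExpressionMatrix(matrix.values[perm],
                                [matrix.gene_ids[i] for i in perm], matrix.cell_ids)
    scores2 = cc.cycle_scores(shuffled, sets["G1S"], sets["G2M"])
    assert np.allclose([s.g1s_score for s in scores], [s.g1s_score for s in scores2])


def test_builtin_signature_sizes():
    sets = cc.builtin_cycle_sets()
    assert len(sets["G1S"]) == 42
    assert len(sets["G2M"]) == 54


def test_boosted_cells_score_above_unboosted(default_cohort):
    matrix, cells, _, sets, truth = default_cohort
    ctc = [c.cell_id for c in cells if c.cell_class is CellClass.CTC]
    scores = cc.cycle_scores(matrix.subset(cells=ctc), sets["G1S"], sets["G2M"])
    by_cell = {s.cell_id: s for s in scores}
    g1s_cycling = [by_cell[c].g1s_score for c in ctc if truth.cycling_phase[c] == "G1S"]
    noncycling = [by_cell[c].max_score for c in ctc if not truth.cycling[c]]
    assert min(g1s_cycling) > max(noncycling)
    # direction and magnitude: boost of 2 shrunk by centering
    assert np.mean(g1s_cycling) > 1.0


@pytest.mark.parametrize("method", ["hclust2", "threshold"])
def test_classification_recovers_planted_cycling(method):
    spec = SyntheticSpec(
        seed=21,
        cycling_fraction={"HV": 0.25, "PA": 0.25, "PV": 0.25, "PoV": 0.25},
    )
    matrix, cells, _, sets, truth = generate_cohort(spec)
    ctc = [c.cell_id for c in cells if c.cell_class is CellClass.CTC]
    scores = cc.cycle_scores(matrix.subset(cells=ctc), sets["G1S"], sets["G2M"], cells=cells)
    scores = cc.classify_cycling(scores, method=method)
    pred = {s.cell_id: s.cycling for s in scores}
    tp = sum(pred[c] and truth.cycling[c] for c in ctc)
    fn = sum(not pred[c] and truth.cycling[c] for c in ctc)
    fp = sum(pred[c] and not truth.cycling[c] for c in ctc)
    tn = sum(not pred[c] and not truth.cycling[c] for c in ctc)
    assert tp / (tp + fn) >= 0.9
    assert tn / (tn + fp) >= 0.9


def test_zero_cycling_cohort_threshold_mode_calls_none():
    spec = SyntheticSpec(
        seed=6, cycling_fraction={"HV": 0.0, "PA": 0.0, "PV": 0.0, "PoV": 0.0}
    )
    matrix, cells, _, sets, _ = generate_cohort(spec)
    ctc = [c.cell_id for c in cells if c.cell_class is CellClass.CTC]
    scores = cc.cycle_scores(matrix.subset(cells=ctc), sets["G1S"], sets["G2M"])
    scores = cc.classify_cycling(scores, method="threshold", threshold=1.0)
    assert not any(s.cycling for s in scores)


def test_identical_cells_hclust2_all_noncycling(caplog):
    profile = np.abs(np.random.default_rng(3).normal(4, 2, size=100))
    m = _matrix(np.tile(profile[:, None], (1, 5)))
    scores = cc.cycle_scores(m, list(m.gene_ids[:40]), list(m.gene_ids[40:]))
    with caplog.at_level("WARNING", logger="ctcflow"):
        out = cc.classify_cycling(scores, method="hclust2")
    assert not any(s.cycling for s in out)


def test_classification_invariant_to_cell_relabeling(default_cohort):
    matrix, cells, _, sets, _ = default_cohort
    ctc = [c.cell_id for c in cells if c.cell_class is CellClass.CTC]
    scores = cc.cycle_scores(matrix.subset(cells=ctc), sets["G1S"], sets["G2M"])
    out1 = cc.classify_cycling(scores)
    out2 = cc.classify_cycling(list(reversed(scores)))
    m1 = {s.cell_id: s.cycling for s in out1}
    m2 = {s.cell_id: s.cycling for s in out2}
    assert m1 == m2


def test_site_proportions_one_decimal(default_cohort):
    matrix, cells, _, sets, _ = default_cohort
    ctc = [c.cell_id for c in cells if c.cell_class is CellClass.CTC]
    scores = cc.classify_cycling(
        cc.cycle_scores(matrix.subset(cells=ctc), sets["G1S"], sets["G2M"], cells=cells)
    )
    props = cc.site_proportions(scores)
    assert set(props) == {"HV", "PA", "PV", "PoV"}
    for v in props.values():
        assert v == round(v, 1)
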