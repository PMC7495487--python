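"""Batch adjustment, Welch testing, BH adjustment and the volcano rule."""

import numpy as np
import pandas as pd
import pytest

from netpharm.diffexpr import ExpressionStudy, batch_adjust, de_test, volcano_filter
from netpharm.synthetic_data import gen_expression


def _study(values, groups, batches):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    genes = [f"G{i:06d}" for i in range(1, values.shape[0] + 1)]
    return ExpressionStudy(
        matrix=pd.DataFrame(values, index=genes, columns=samples),
        groups=pd.Series(groups, index=samples),
        batches=pd.Series(batches, index=samples),
    )


def test_batch_adjust_shifts_means_to_pooled():
    # one gene, batch means 5 and 7 -> both batches moved to the pooled 6
    study = _study(
        [[5.0, 5.0, 7.0, 7.0]],
        ["case", "control", "case", "control"],
        ["b1", "b1", "b2", "b2"],
    )
    adj = batch_adjust(study)
    assert adj.matrix.iloc[0].tolist() == pytest.approx([6, 6, 6, 6])


def test_batch_adjust_single_batch_is_identity():
    study = _study(
        [[1.0, 2.0, 3.0, 4.0]],
        ["case", "control", "case", "control"],
        ["b1", "b1", "b1", "b1"],
    )
    adj = batch_adjust(study)
    pd.testing.assert_frame_equal(adj.matrix, study.matrix)


def test_batch_adjust_removes_simulated_batch_difference():
    study, _ = gen_expression(300, 20, 20, 0, 0.0, 0.5, 1.0, 2, seed=11)
    adj = batch_adjust(study)
    b = adj.batches
    cols1 = list(b.index[b == "batch1"])
    cols2 = list(b.index[b == "batch2"])
    delta = adj.matrix[cols1].mean(axis=1) - adj.matrix[cols2].mean(axis=1)
    assert delta.abs().max() < 0.05


def test_batch_adjust_preserves_group_difference_when_balanced():
    study, de_genes = gen_expression(200, 20, 20, 40, 2.0, 0.5, 1.0, 2, seed=13)
    adj = batch_adjust(study)
    diff = adj.matrix[adj.case_samples].mean(axis=1) - adj.matrix[
        adj.control_samples
    ].mean(axis=1)
    assert diff.loc[de_genes].mean() == pytest.approx(2.0, abs=0.2)


def test_identical_groups_give_zero_lfc_and_p_one():
    study = _study(
        [[3.0, 3.0, 3.0, 3.0]],
        ["case", "case", "control", "control"],
        ["b1", "b1", "b1", "b1"],
    )
    de = de_test(study)
    assert de["log2fc"].iloc[0] == 0.0
    assert de["p_raw"].iloc[0] == 1.0


def test_bh_step_up_hand_example():
    """p = (.01, .02, .03, .04) with m = 4 adjusts to .04 across the board.

    Hand step-up: p_(i) * m / i = (.04, .04, .04, .04); the running minimum
    from the largest rank down leaves every value at .04.
    """
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])
    # monotone in the p_raw ordering on the library path
    study, _ = gen_expression(50, 3, 3, 0, 0.0, 0.5, 0.0, 1, seed=1)
    de = de_test(study).sort_values("p_raw")
    assert de["p_adj"].is_monotonic_increasing


def test_null_type_one_error_rate():
    study, _ = gen_expression(1000, 20, 20, 0, 0.0, 0.5, 0.0, 1, seed=23)
    de = de_test(study)
    frac = float((de["p_raw"] < 0.05).mean())
    assert 0.03 <= frac <= 0.07


def test_de_test_requires_two_per_group():
    study = _study(
        [[1.0, 2.0, 3.0]], ["case", "control", "control"], ["b1", "b1", "b1"]
    )
    with pytest.raises(ValueError):
        de_test(study)


@pytest.mark.parametrize(
    "lfc,p_adj,kept",
    [
        (1.5, 0.01, True),
        (0.9, 0.001, False),  # fold-change clause
        (-1.2, 0.04, True),  # negative branch
        (1.0, 0.01, False),  # strict inequality at the boundary
        (1.5, 0.05, False),  # strict p cutoff
    ],
)
def test_volcano_rule_strict(lfc, p_adj, kept):
    de = pd.DataFrame(
        {"log2fc": [lfc], "p_raw": [p_adj], "p_adj": [p_adj]}, index=["G000001"]
    )
    result = volcano_filter(de)
    assert ("G000001" in result.symbols) is kept


def test_volcano_output_shrinks_with_stricter_thresholds():
    study, _ = gen_expression(500, 10, 10, 50, 1.5, 0.5, 0.0, 1, seed=3)
    de = de_test(study)
    base = volcano_filter(de, p_max=0.05, lfc_min=1.0).symbols
    assert volcano_filter(de, p_max=0.01, lfc_min=1.0).symbols <= base
    assert volcano_filter(de, p_max=0.05, lfc_min=1.2).symbols <= base


def test_planted_recovery_single_seed():
    study, de_genes = gen_expression(1000, 20, 20, 50, 2.0, 0.5, 1.0, 2, seed=42)
    degs = volcano_filter(de_test(batch_adjust(study))).symbols
    truth = set(de_genes)
    sens = len(degs & truth) / len(truth)
    fdp = len(degs - truth) / max(len(degs), 1)
    assert sens >= 0.9 and fdp <= 0.1


def test_study_validation():
    with pytest.raises(ValueError):
        _study([[1.0, 2.0]], ["case", "mystery"], ["b1", "b1"])
    with pytest.raises(ValueError):
        _study([[np.nan, 2.0]], ["case", "control"], ["b1", "b1"])
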