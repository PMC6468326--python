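"""Regression layer: linear relations, LOO, accuracy, and the (a, b) search."""

import dataclasses

import numpy as np
import pytest

from crowdnn.crowdfit import (
    DEFAULT_DG_EXCLUSIONS,
    DEFAULT_TM_EXCLUSIONS,
    GridSpec,
    StudyDataset,
    fit_ab,
    fit_relation,
    leave_one_out,
    prediction_accuracy,
)
from crowdnn.nnpredict import DILUTE_1M_DG37


def test_fit_relation_exact_line():
    x = np.arange(10.0)
    res = fit_relation(x, x)
    assert res.slope == pytest.approx(1.0, abs=1e-12)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)


def test_fit_relation_permutation_invariant():
    rng = np.random.default_rng(5)
    x = rng.normal(size=15)
    y = 2 * x + rng.normal(size=15)
    perm = rng.permutation(15)
    a = fit_relation(x, y)
    b = fit_relation(x[perm], y[perm])
    assert a.slope == pytest.approx(b.slope, rel=1e-12)
    assert a.intercept == pytest.approx(b.intercept, rel=1e-12)


def test_fit_relation_exclusions_require_labels():
    with pytest.raises(ValueError, match="labels"):
        fit_relation([1, 2, 3, 4], [1, 2, 3, 4], exclusions={"a"})


def test_fit_relation_too_few_points():
    with pytest.raises(ValueError, match=">= 3"):
        fit_relation([1, 2], [1, 2])


def test_dG_relation_recovers_published_coefficients(dataset):
    res = fit_relation(
        [r.predicted_dG37_dilute for r in dataset],
        [r.measured_dG37 for r in dataset],
        labels=[r.id for r in dataset],
        exclusions=DEFAULT_DG_EXCLUSIONS,
    )
    assert res.n_points == 24
    assert res.slope == pytest.approx(0.99, abs=0.01)
    assert res.intercept == pytest.approx(2.32, abs=0.05)
    assert res.r_squared == pytest.approx(0.981, abs=0.005)


def test_tm_relation_recovers_published_coefficients(dataset):
    res = fit_relation(
        [r.predicted_Tm_dilute for r in dataset],
        [r.measured_Tm for r in dataset],
        labels=[r.id for r in dataset],
        exclusions=DEFAULT_TM_EXCLUSIONS,
    )
    assert res.n_points == 23
    assert res.slope == pytest.approx(0.90, abs=0.01)
    assert res.intercept == pytest.approx(-3.39, abs=0.05)
    assert res.r_squared == pytest.approx(0.971, abs=0.005)


def test_relation_shifts_without_exclusions(dataset):
    """Dropping the outlier exclusions moves the ΔG°37 coefficients."""
    res = fit_relation(
        [r.predicted_dG37_dilute for r in dataset],
        [r.measured_dG37 for r in dataset],
    )
    assert res.n_points == 28
    assert abs(res.intercept - 2.32) > 0.05 or abs(res.slope - 0.99) > 0.01


def test_leave_one_out_counts_and_determinism(dataset):
    preds_dg, preds_tm, summary = leave_one_out(dataset)
    assert summary.n_dG == 24 and summary.n_Tm == 23
    assert set(preds_dg) == {r.id for r in dataset} - DEFAULT_DG_EXCLUSIONS
    _, _, again = leave_one_out(dataset)
    assert again == summary


def test_leave_one_out_needs_enough_points(dataset):
    all_but_three = {r.id for r in dataset.rows[:-3]}
    with pytest.raises(ValueError, match=">= 4"):
        leave_one_out(dataset, dg_exclusions=all_but_three)


def test_prediction_accuracy_perfect_predictions(dataset):
    preds_dg = {r.id: r.measured_dG37 for r in dataset}
    preds_tm = {r.id: r.measured_Tm for r in dataset}
    acc = prediction_accuracy(dataset, preds_dg, preds_tm, round_decimals=None)
    assert acc.mean_pct_dG37 == 0.0
    assert acc.mean_abs_dTm == 0.0


def _with_measured(dataset, values):
    rows = tuple(
        dataclasses.replace(r, measured_dG37=v) for r, v in zip(dataset.rows, values)
    )
    return StudyDataset(rows=rows)


def _dilute_sums(dataset):
    inc = DILUTE_1M_DG37.dG_increments
    u, v = [], []
    for r in dataset:
        u.append(
            sum(n * inc[s] for s, n in r.freqs.as_dict().items())
            + DILUTE_1M_DG37.initiation(r.freqs.initiation_class)
        )
        v.append(r.freqs.total + 1)
    return np.array(u), np.array(v)


def test_fit_ab_identity_recovery(dataset):
    """measured ≡ Σ nᵢDᵢ + I_d ⇒ optimum (a, b) = (1, 0)."""
    u, _ = _dilute_sums(dataset)
    synthetic = _with_measured(dataset, u)
    coeffs = fit_ab(synthetic, DILUTE_1M_DG37, GridSpec(a_min=0.5, a_max=1.2, step=5e-3))
    assert coeffs.a == pytest.approx(1.0, abs=5e-3)
    assert coeffs.b == pytest.approx(0.0, abs=5e-3)
    assert coeffs.r_squared == pytest.approx(1.0, abs=1e-9)


def test_fit_ab_planted_truth_recovery(dataset):
    u, v = _dilute_sums(dataset)
    synthetic = _with_measured(dataset, 0.7 * u + 0.1 * v)
    coeffs = fit_ab(synthetic, DILUTE_1M_DG37)
    assert coeffs.a == pytest.approx(0.7, abs=5e-4)
    assert coeffs.b == pytest.approx(0.1, abs=5e-4)


def test_fit_ab_noisy_planted_truth(dataset):
    """Planted (a, b) recovered within ±0.02 / ±0.05 under 0.1 kcal/mol noise."""
    u, v = _dilute_sums(dataset)
    rng = np.random.default_rng(11)
    grid = GridSpec(step=2e-3)  # coarser grid keeps 20 searches quick
    for _ in range(20):
        a_true = rng.uniform(0.55, 0.75)
        b_true = rng.uniform(-0.1, 0.3)
        noisy = a_true * u + b_true * v + rng.normal(0.0, 0.1, size=len(u))
        coeffs = fit_ab(_with_measured(dataset, noisy), DILUTE_1M_DG37, grid)
        assert coeffs.a == pytest.approx(a_true, abs=0.02)
        assert coeffs.b == pytest.approx(b_true, abs=0.05)


def test_fit_ab_study_dataset(dataset):
    coeffs = fit_ab(dataset, DILUTE_1M_DG37)
    assert coeffs.a == pytest.approx(0.666, abs=5.1e-4)
    assert coeffs.b == pytest.approx(0.117, abs=5.1e-4)
    assert coeffs.slope == pytest.approx(1.0, abs=1e-3)
    assert coeffs.intercept == pytest.approx(0.0, abs=1e-3)
    assert coeffs.r_squared == pytest.approx(0.977, abs=0.005)


def test_fit_ab_optimum_beats_grid_neighbors(dataset):
    """The returned (a, b) is a local (hence grid-global) objective minimum."""
    grid = GridSpec()
    coeffs = fit_ab(dataset, DILUTE_1M_DG37, grid)
    y = np.array([m for _, _, m in dataset.design_rows()])
    u19 = np.fromiter(_design_u(dataset), float)
    v19 = np.fromiter(_design_v(dataset), float)

    def objective(a, b):
        x = a * u19 + b * v19
        slope, intercept = np.polyfit(x, y, 1)
        return (slope - 1.0) ** 2 + intercept**2

    best = objective(coeffs.a, coeffs.b)
    for da in (-grid.step, 0.0, grid.step):
        for db in (-grid.step, 0.0, grid.step):
            if da == db == 0.0:
                continue
            assert best <= objective(coeffs.a + da, coeffs.b + db) + 1e-15


def _design_u(dataset):
    inc = DILUTE_1M_DG37.dG_increments
    for _, f, _ in dataset.design_rows():
        yield sum(n * inc[s] for s, n in f.as_dict().items()) + DILUTE_1M_DG37.initiation(
            f.initiation_class
        )


def _design_v(dataset):
    for _, f, _ in dataset.design_rows():
        yield f.total + 1


def test_design_rows_pair_averaging(dataset):
    designs = dataset.design_rows()
    assert len(designs) == 19
    by_key = dict((k, m) for k, _, m in designs)
    # pair 2: (−5.3 + −5.4)/2
    assert by_key["2"] == pytest.approx(-5.35, abs=1e-9)
    # singleton 16 passes through unchanged
    assert by_key["16"] == pytest.approx(-7.2, abs=1e-9)


def test_grid_spec_validation():
    with pytest.raises(ValueError):
        GridSpec(a_min=-0.1)
    with pytest.raises(ValueError):
        GridSpec(b_min=0.5, b_max=-0.5)
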