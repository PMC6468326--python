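"""End-to-end reproduction of the study's derived tables.

``reproduce_tables`` re-runs the whole deterministic analysis from the
packaged inputs — condition-level regressions, prediction and
leave-one-out summaries, the (a, b) grid search, parameter scaling and
per-sequence NN calculations — and compares every regenerated number
with the corresponding printed fixture value, honouring the documented
exemptions (the pair-7 NN-calculated entry, which the printed table
rounds to −4.7 where the parameters give −4.8, and the leave-one-out
averages, which are not recoverable from the rounded inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from . import crowdfit, nnpredict
from .crowdfit import GridSpec, StudyDataset
from .fixtures import FixtureBundle, crowding_parameter_set, load_fixtures, study_dataset
from .nnpredict import DILUTE_1M_DG37, round_table

__all__ = ["Comparison", "ReproductionReport", "reproduce_tables"]

#: Design whose printed NN-calculated ΔG°37 (−4.7) disagrees with the
#: parameter arithmetic (−4.8); documented discrepancy, not enforced.
EXEMPT_DESIGNS: frozenset[str] = frozenset({"7"})


@dataclass(frozen=True)
class Comparison:
    name: str
    computed: float
    expected: float
    tolerance: float
    exempt: bool = False

    @property
    def ok(self) -> bool:
        return self.exempt or abs(self.computed - self.expected) <= self.tolerance + 1e-9


@dataclass
class ReproductionReport:
    comparisons: list[Comparison] = field(default_factory=list)
    dg_relation: crowdfit.RegressionResult | None = None
    tm_relation: crowdfit.RegressionResult | None = None
    scaling: Any = None

    def add(self, name: str, computed: float, expected: float,
            tolerance: float, exempt: bool = False) -> None:
        self.comparisons.append(Comparison(name, computed, expected, tolerance, exempt))

    @property
    def n_failed(self) -> int:
        return sum(not c.ok for c in self.comparisons)

    def failures(self) -> list[Comparison]:
        return [c for c in self.comparisons if not c.ok]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{**asdict(c), "ok": c.ok} for c in self.comparisons]
        )


def reproduce_tables(
    bundle: FixtureBundle | None = None,
    dg_exclusions=crowdfit.DEFAULT_DG_EXCLUSIONS,
    tm_exclusions=crowdfit.DEFAULT_TM_EXCLUSIONS,
    grid: GridSpec | None = None,
) -> ReproductionReport:
    """Regenerate every derived quantity and compare with the fixtures."""
    if bundle is None:
        bundle = load_fixtures()
    dataset = study_dataset(bundle)
    report = ReproductionReport()

    # condition-level linear relations
    ids = [r.id for r in dataset]
    dg_rel = crowdfit.fit_relation(
        [r.predicted_dG37_dilute for r in dataset],
        [r.measured_dG37 for r in dataset],
        labels=ids,
        exclusions=dg_exclusions,
    )
    tm_rel = crowdfit.fit_relation(
        [r.predicted_Tm_dilute for r in dataset],
        [r.measured_Tm for r in dataset],
        labels=ids,
        exclusions=tm_exclusions,
    )
    report.dg_relation, report.tm_relation = dg_rel, tm_rel
    report.add("dG_relation_slope", dg_rel.slope, 0.99, 0.01)
    report.add("dG_relation_intercept", dg_rel.intercept, 2.32, 0.05)
    report.add("dG_relation_r_squared", dg_rel.r_squared, 0.981, 0.005)
    report.add("tm_relation_slope", tm_rel.slope, 0.90, 0.01)
    report.add("tm_relation_intercept", tm_rel.intercept, -3.39, 0.05)
    report.add("tm_relation_r_squared", tm_rel.r_squared, 0.971, 0.005)

    # per-sequence predicted columns (condition-level relations, rounded)
    t4 = bundle.table4.set_index("id")
    for r in dataset:
        pred_dg = round_table(nnpredict.predict_dG_crowding_linear(r.predicted_dG37_dilute))
        pred_tm = round_table(nnpredict.predict_tm_crowding_linear(r.predicted_Tm_dilute))
        report.add(f"predicted_dG37[{r.id}]", pred_dg, float(t4.loc[r.id, "pred_dG37"]), 0.05)
        report.add(f"predicted_Tm[{r.id}]", pred_tm, float(t4.loc[r.id, "pred_Tm"]), 0.05)

    # accuracy and leave-one-out summaries
    pred_dg_map = {
        r.id: nnpredict.predict_dG_crowding_linear(r.predicted_dG37_dilute) for r in dataset
    }
    pred_tm_map = {
        r.id: nnpredict.predict_tm_crowding_linear(r.predicted_Tm_dilute) for r in dataset
    }
    acc = crowdfit.prediction_accuracy(
        dataset, pred_dg_map, pred_tm_map, dg_exclusions, tm_exclusions
    )
    report.add("prediction_accuracy_dG_pct", acc.mean_pct_dG37, 4.7, 0.05)
    report.add("prediction_accuracy_Tm", acc.mean_abs_dTm, 1.2, 0.05)
    _, _, loo = crowdfit.leave_one_out(dataset, dg_exclusions, tm_exclusions)
    # printed averages are not recoverable from the rounded inputs
    report.add("loo_dG_pct", loo.mean_pct_dG37, 4.6, 0.05, exempt=True)
    report.add("loo_Tm", loo.mean_abs_dTm, 1.1, 0.05, exempt=True)

    # scaling search, scaled parameter table, per-design NN calculations
    scaling = crowdfit.fit_ab(dataset, DILUTE_1M_DG37, grid=grid)
    report.scaling = scaling
    report.add("scaling_a", scaling.a, 0.666, 5.1e-4)
    report.add("scaling_b", scaling.b, 0.117, 5.1e-4)
    report.add("scaling_r_squared", scaling.r_squared, 0.977, 0.005)

    scaled = nnpredict.scale_parameters(DILUTE_1M_DG37, scaling)
    t5 = bundle.table5.set_index("set")
    for s, value in scaled.dG_increments.items():
        report.add(f"table5[{s}]", value, float(t5.loc[s, "dG37"]), 0.005)
    report.add("table5[init_GC]", scaled.init_GC, float(t5.loc["init_GC", "dG37"]), 0.005)
    report.add("table5[init_AT]", scaled.init_AT, float(t5.loc["init_AT", "dG37"]), 0.005)

    tabulated = crowding_parameter_set(bundle)
    calc_col = bundle.table4.set_index("id")["calc_dG37"]
    for r in dataset:
        expected = calc_col.get(r.id)
        if expected is None or (isinstance(expected, float) and np.isnan(expected)):
            continue
        calc = round_table(nnpredict.predict_dG_crowding_nn(r.freqs, tabulated))
        report.add(
            f"calculated_dG37[{r.id}]",
            calc,
            float(expected),
            0.1,
            exempt=r.design_key() in EXEMPT_DESIGNS,
        )
    return report
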