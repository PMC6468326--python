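"""Statistical layer: crowding-vs-dilute regressions and the (a, b) search.

Three analyses connect the measured crowding thermodynamics to dilute
nearest-neighbor predictions:

* condition-level OLS relations between measured (crowding) and predicted
  (dilute) ΔG°37 and Tm, with explicit outlier exclusions;
* leave-one-out validation and prediction-accuracy summaries of those
  relations;
* a grid search for the affine coefficients (a, b) mapping the dilute NN
  parameter set onto a crowding set, chosen so the regression of measured
  on NN-calculated ΔG°37 over the 19 pair-averaged duplex designs has
  slope 1 and intercept 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .nnpredict import NNParameterSet, ScalingCoefficients, DILUTE_1M
from .seqmodel import NN_SETS, NNFrequencyVector

__all__ = [
    "RegressionResult",
    "StudyRow",
    "StudyDataset",
    "DEFAULT_DG_EXCLUSIONS",
    "DEFAULT_TM_EXCLUSIONS",
    "fit_relation",
    "leave_one_out",
    "prediction_accuracy",
    "fit_ab",
    "GridSpec",
]

#: Sequence ids excluded from the ΔG°37 relation (identical-NN pairs whose
#: points fall far off the line: pair 1, pair 8).
DEFAULT_DG_EXCLUSIONS: frozenset[str] = frozenset({"1a", "1b", "8a", "8b"})
#: For the Tm relation, additionally d(CGATCGGCCGATCG) (sequence 15).
DEFAULT_TM_EXCLUSIONS: frozenset[str] = DEFAULT_DG_EXCLUSIONS | {"15"}


@dataclass(frozen=True)
class RegressionResult:
    """OLS line y = slope·x + intercept with r² over n_points."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    excluded: frozenset[str] = frozenset()

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class StudyRow:
    """One sequence's joined design and measurement record."""

    id: str
    sequence: str
    freqs: NNFrequencyVector
    measured_dG37: float
    measured_Tm: float
    predicted_dG37_dilute: float
    predicted_Tm_dilute: float
    pair: str | None = None  # design identifier shared by identical-NN pairs

    def design_key(self) -> str:
        return self.pair if self.pair else self.id


@dataclass(frozen=True)
class StudyDataset:
    """All 28 study sequences (9 identical-NN pairs + 10 singletons)."""

    rows: tuple[StudyRow, ...]

    def __post_init__(self) -> None:
        if len(self.rows) != 28:
            raise ValueError(f"expected 28 rows, got {len(self.rows)}")
        designs = {}
        for r in self.rows:
            designs.setdefault(r.design_key(), []).append(r)
        if len(designs) != 19:
            raise ValueError(f"expected 19 distinct designs, got {len(designs)}")
        for key, members in designs.items():
            if len({tuple(sorted(m.freqs.as_dict().items())) for m in members}) != 1:
                raise ValueError(f"design {key}: members differ in NN frequencies")

    def __iter__(self):
        return iter(self.rows)

    def subset(self, exclusions: Iterable[str]) -> list[StudyRow]:
        excl = set(exclusions)
        return [r for r in self.rows if r.id not in excl]

    def design_rows(self) -> list[tuple[str, NNFrequencyVector, float]]:
        """The 19 designs with pair-averaged measured ΔG°37."""
        order: list[str] = []
        members: dict[str, list[StudyRow]] = {}
        for r in self.rows:
            key = r.design_key()
            if key not in members:
                order.append(key)
            members.setdefault(key, []).append(r)
        return [
            (
                key,
                members[key][0].freqs,
                float(np.mean([m.measured_dG37 for m in members[key]])),
            )
            for key in order
        ]


def fit_relation(
    x: Sequence[float],
    y: Sequence[float],
    labels: Sequence[str] | None = None,
    exclusions: Iterable[str] = (),
) -> RegressionResult:
    """Unweighted OLS of y on x, dropping points whose label is excluded."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    excl = frozenset(exclusions)
    if excl:
        if labels is None:
            raise ValueError("exclusions given but no labels")
        keep = np.array([lab not in excl for lab in labels])
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 included points, got {len(x)}")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
        excluded=excl,
    )


class _AccuracySummary(NamedTuple):
    mean_pct_dG37: float
    mean_abs_dTm: float
    n_dG: int
    n_Tm: int


def leave_one_out(
    dataset: StudyDataset,
    dg_exclusions: Iterable[str] = DEFAULT_DG_EXCLUSIONS,
    tm_exclusions: Iterable[str] = DEFAULT_TM_EXCLUSIONS,
) -> tuple[dict[str, float], dict[str, float], _AccuracySummary]:
    """Leave-one-out validation of the ΔG°37 and Tm linear relations.

    Each included sequence is held out in turn, the relation refitted on
    the remainder, and the held-out value predicted. Returns the per-id
    ΔG°37 and Tm predictions and a summary with the mean relative ΔG°37
    difference (%) and mean |ΔTm| (°C).
    """
    preds_dg: dict[str, float] = {}
    preds_tm: dict[str, float] = {}
    errs_dg: list[float] = []
    errs_tm: list[float] = []
    for excl, x_attr, y_attr, preds, errs, rel in (
        (set(dg_exclusions), "predicted_dG37_dilute", "measured_dG37", preds_dg, errs_dg, True),
        (set(tm_exclusions), "predicted_Tm_dilute", "measured_Tm", preds_tm, errs_tm, False),
    ):
        rows = dataset.subset(excl)
        if len(rows) < 4:
            raise ValueError("leave-one-out needs >= 4 included sequences")
        x = np.array([getattr(r, x_attr) for r in rows])
        y = np.array([getattr(r, y_attr) for r in rows])
        for i, row in enumerate(rows):
            keep = np.arange(len(rows)) != i
            rr = stats.linregress(x[keep], y[keep])
            p = float(rr.slope * x[i] + rr.intercept)
            preds[row.id] = p
            errs.append(abs(p - y[i]) / abs(y[i]) * 100.0 if rel else abs(p - y[i]))
    summary = _AccuracySummary(
        mean_pct_dG37=float(np.mean(errs_dg)),
        mean_abs_dTm=float(np.mean(errs_tm)),
        n_dG=len(errs_dg),
        n_Tm=len(errs_tm),
    )
    return preds_dg, preds_tm, summary


def prediction_accuracy(
    dataset: StudyDataset,
    predicted_dG37: Mapping[str, float],
    predicted_Tm: Mapping[str, float],
    dg_exclusions: Iterable[str] = DEFAULT_DG_EXCLUSIONS,
    tm_exclusions: Iterable[str] = DEFAULT_TM_EXCLUSIONS,
    round_decimals: int | None = 1,
) -> _AccuracySummary:
    """Mean |predicted − measured| summaries over the fitted sequence sets.

    ΔG°37 differences are relative (% of |measured|); Tm differences are
    absolute (°C). Predictions are rounded to ``round_decimals`` first
    (default 1, the printed-table convention the published averages were
    computed from); pass ``None`` to compare unrounded values.
    """
    def _maybe_round(v: float) -> float:
        return round(v, round_decimals) if round_decimals is not None else v

    excl_dg, excl_tm = set(dg_exclusions), set(tm_exclusions)
    errs_dg = [
        abs(_maybe_round(predicted_dG37[r.id]) - r.measured_dG37) / abs(r.measured_dG37) * 100.0
        for r in dataset.subset(excl_dg)
    ]
    errs_tm = [
        abs(_maybe_round(predicted_Tm[r.id]) - r.measured_Tm)
        for r in dataset.subset(excl_tm)
    ]
    return _AccuracySummary(
        mean_pct_dG37=float(np.mean(errs_dg)),
        mean_abs_dTm=float(np.mean(errs_tm)),
        n_dG=len(errs_dg),
        n_Tm=len(errs_tm),
    )


@dataclass(frozen=True)
class GridSpec:
    """Search grid for the affine scaling coefficients."""

    a_min: float = 0.5
    a_max: float = 0.8
    b_min: float = -0.3
    b_max: float = 0.5
    step: float = 5e-4

    def __post_init__(self) -> None:
        if self.a_min <= 0 or self.a_max <= self.a_min:
            raise ValueError("need 0 < a_min < a_max")
        if self.b_max <= self.b_min or self.step <= 0:
            raise ValueError("invalid b range or step")

    def a_values(self) -> np.ndarray:
        n = int(round((self.a_max - self.a_min) / self.step))
        return self.a_min + self.step * np.arange(n + 1)

    def b_values(self) -> np.ndarray:
        n = int(round((self.b_max - self.b_min) / self.step))
        return self.b_min + self.step * np.arange(n + 1)


def fit_ab(
    dataset: StudyDataset,
    dilute_params: NNParameterSet,
    grid: GridSpec | None = None,
) -> ScalingCoefficients:
    """Grid search for (a, b) so that calculated matches measured ΔG°37.

    For each candidate (a, b) the crowding NN prediction of design j is
    the affine image a·(Σ nᵢDᵢ + I_d) + b·(Σ nᵢ + 1) of its dilute sum
    (no symmetry term), and the measured pair-averaged ΔG°37 values are
    regressed on these calculated values. The objective
    (slope − 1)² + intercept² is minimized over the grid; ties break
    toward higher r², then smaller (a, b). The returned coefficients
    carry the regression diagnostics at the optimum.
    """
    if dilute_params.condition != DILUTE_1M:
        raise ValueError("fit_ab scales a dilute 1 M NaCl parameter set")
    if grid is None:
        grid = GridSpec()
    designs = dataset.design_rows()

    inc = dilute_params.dG_increments
    u = np.array(
        [
            sum(n * inc[s] for s, n in f.as_dict().items())
            + dilute_params.initiation(f.initiation_class)
            for _, f, _ in designs
        ]
    )
    v = np.array([f.total + 1.0 for _, f, _ in designs])
    y = np.array([meas for _, _, meas in designs])

    a = grid.a_values()[:, None]
    b = grid.b_values()[None, :]
    # x = a·u + b·v; the OLS slope/intercept of y on x reduce to moments of
    # (u, v, y), so the whole grid is evaluated in closed form.
    mu_u, mu_v, mu_y = u.mean(), v.mean(), y.mean()
    c_uy = np.mean((u - mu_u) * (y - mu_y))
    c_vy = np.mean((v - mu_v) * (y - mu_y))
    var_u = u.var()
    var_v = v.var()
    c_uv = np.mean((u - mu_u) * (v - mu_v))
    var_y = y.var()

    cov_xy = a * c_uy + b * c_vy
    var_x = a**2 * var_u + 2 * a * b * c_uv + b**2 * var_v
    slope = cov_xy / var_x
    intercept = mu_y - slope * (a * mu_u + b * mu_v)
    objective = (slope - 1.0) ** 2 + intercept**2
    r_squared = cov_xy**2 / (var_x * var_y)

    best = np.min(objective)
    ties = np.argwhere(objective <= best * (1 + 1e-12))
    if len(ties) > 1:  # break ties: max r², then lexicographically smallest (a, b)
        ties = sorted(
            map(tuple, ties),
            key=lambda ij: (-r_squared[ij], grid.a_values()[ij[0]], grid.b_values()[ij[1]]),
        )
    i, j = ties[0]
    return ScalingCoefficients(
        a=float(grid.a_values()[i]),
        b=float(grid.b_values()[j]),
        slope=float(slope[i, j]),
        intercept=float(intercept[i, j]),
        r_squared=float(r_squared[i, j]),
    )


def regress_measured_on_calculated(
    dataset: StudyDataset,
    crowding_params: NNParameterSet,
) -> RegressionResult:
    """Regression of pair-averaged measured ΔG°37 on the crowding NN
    calculation over the 19 designs (the diagnostics plot)."""
    from .nnpredict import predict_dG_crowding_nn

    designs = dataset.design_rows()
    x = [predict_dG_crowding_nn(f, crowding_params) for _, f, _ in designs]
    y = [meas for _, _, meas in designs]
    return fit_relation(x, y)
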