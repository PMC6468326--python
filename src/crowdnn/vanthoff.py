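"""Van't Hoff analysis: ΔH°, ΔS°, ΔG°37 from Tm⁻¹ versus ln(Ct).

For a self-complementary duplex, 1/Tm is linear in ln Ct with slope
R/ΔH° and intercept ΔS°/ΔH°. An unweighted ordinary least-squares fit of
the concentration series therefore yields ΔH° = R/slope and
ΔS° = R·intercept/slope; standard errors follow by first-order (delta
method) propagation from the full slope–intercept covariance matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .thermo import GAS_CONSTANT, T37, ThermoParams

__all__ = ["ConcentrationSeries", "fit", "summarize_pair_differences", "PairDifference"]


class DegenerateFitError(RuntimeError):
    """The Tm⁻¹ vs ln(Ct) regression is not identifiable."""


@dataclass(frozen=True)
class ConcentrationSeries:
    """(Ct, Tm) points for one duplex; Ct in mol/L, Tm in kelvin."""

    points: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        pts = tuple((float(c), float(t)) for c, t in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise ValueError("need at least 2 (Ct, Tm) points")
        if any(c <= 0 or t <= 0 for c, t in pts):
            raise ValueError("all Ct and Tm must be positive")
        if len({c for c, _ in pts}) == 1:
            raise DegenerateFitError("all Ct equal: slope is not identifiable")

    @property
    def ln_ct(self) -> np.ndarray:
        return np.log([c for c, _ in self.points])

    @property
    def inv_tm(self) -> np.ndarray:
        return 1.0 / np.array([t for _, t in self.points])


def fit(series: ConcentrationSeries) -> ThermoParams:
    """Fit Tm⁻¹ = (R/ΔH°)·ln Ct + ΔS°/ΔH° by unweighted OLS.

    With fewer than 3 points the point estimates are returned with a
    warning and undefined (nan) standard errors.
    """
    x = series.ln_ct
    y = series.inv_tm
    n = len(x)
    X = np.column_stack([x, np.ones(n)])
    coeffs, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    if n < 3:
        warnings.warn(
            f"{series.label or 'series'}: only {n} points; standard errors "
            "are undefined",
            stacklevel=2,
        )
        cov = np.full((2, 2), np.nan)
    else:
        resid = y - X @ coeffs
        sigma2 = float(resid @ resid) / (n - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
    m, b = float(coeffs[0]), float(coeffs[1])
    if abs(m) < 1e-12:
        raise DegenerateFitError("slope of Tm^-1 vs ln Ct is numerically zero")

    dH = GAS_CONSTANT / m
    dS = GAS_CONSTANT * b / m

    # delta-method propagation; gradients of each quantity wrt (m, b)
    g_dH = np.array([-GAS_CONSTANT / m**2, 0.0])
    g_TdS = T37 * np.array([-GAS_CONSTANT * b / m**2, GAS_CONSTANT / m])
    g_dG = g_dH - g_TdS
    se = lambda g: float(math.sqrt(max(g @ cov @ g, 0.0))) if np.isfinite(cov).all() else float("nan")
    return ThermoParams(
        dH=dH,
        dS=dS,
        se_dH=se(g_dH),
        se_TdS37=se(g_TdS),
        se_dG37=se(g_dG),
        label=series.label,
    )


class PairDifference(NamedTuple):
    """Differences between the two members of an identical-NN pair."""

    label: str
    abs_dTm: float       # °C (or kelvin; differences are unit-identical)
    pct_dH: float
    pct_TdS37: float
    pct_dG37: float


def _pct(a: float, b: float) -> float:
    """Percentage difference, max-|value| denominator convention."""
    denom = max(abs(a), abs(b))
    return 0.0 if denom == 0 else abs(a - b) / denom * 100.0


def summarize_pair_differences(
    pairs: Sequence[tuple[ThermoParams, ThermoParams, float, float]],
    labels: Sequence[str] | None = None,
) -> tuple[list[PairDifference], PairDifference]:
    """Per-pair and average differences for identical-NN sequence pairs.

    Each entry is (params_a, params_b, Tm_a, Tm_b). Percentage differences
    use |a − b| / max(|a|, |b|) × 100; the Tm difference is absolute.
    Returns (per-pair rows, averages row).
    """
    if not pairs:
        raise ValueError("need at least one pair")
    rows = []
    for i, (pa, pb, tma, tmb) in enumerate(pairs):
        label = labels[i] if labels is not None else (pa.label or str(i + 1))
        rows.append(
            PairDifference(
                label=label,
                abs_dTm=abs(tma - tmb),
                pct_dH=_pct(pa.dH, pb.dH),
                pct_TdS37=_pct(pa.TdS37, pb.TdS37),
                pct_dG37=_pct(pa.dG37, pb.dG37),
            )
        )
    mean = PairDifference(
        label="average",
        abs_dTm=float(np.mean([r.abs_dTm for r in rows])),
        pct_dH=float(np.mean([r.pct_dH for r in rows])),
        pct_TdS37=float(np.mean([r.pct_TdS37 for r in rows])),
        pct_dG37=float(np.mean([r.pct_dG37 for r in rows])),
    )
    return rows, mean
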