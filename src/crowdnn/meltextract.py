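"""Tm extraction by the baseline-median method.

Linear baselines are fitted by ordinary least squares in a low- and a
high-temperature window; the median line (arithmetic mean of the two
baselines at each temperature) is intersected with the melting profile,
and the crossing temperature — located by linear interpolation between
adjacent grid points — is Tm. For an ideal two-state curve the median
line is exactly the 50 %-duplexed locus, so this Tm coincides with the
van't Hoff Tm at that Ct.

A single-pass baseline fit is biased whenever the transition tails reach
into the windows (short duplexes never fully saturate to the folded
baseline above 0 °C), so by default the baselines are refined
iteratively: the apparent duplexed fraction implied by the current
baselines is fitted to the two-state van't Hoff form, the modeled tail
contribution is subtracted from the window points, and the lines are
refitted until the baselines are self-consistent. On ideal two-state
data this converges to the true baselines and removes the bias; the Tm
definition itself (median-line crossing) is unchanged. Pass
``refine=False`` for the plain single-pass spreadsheet procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meltsim import MeltingCurve
from .thermo import CELSIUS_OFFSET, GAS_CONSTANT, fraction_duplexed

__all__ = ["BaselineWindows", "LinearFit", "TmResult", "fit_baselines", "tm_from_curve"]

#: Minimum transition amplitude, in units of the baseline-residual noise
#: estimate, below which extraction refuses the curve.
_MIN_AMPLITUDE_SNR = 5.0


class ExtractionError(RuntimeError):
    """The melting profile does not admit a baseline-median Tm."""


@dataclass(frozen=True)
class BaselineWindows:
    """Temperature windows (°C) for the lower and upper baselines.

    The windows mirror the manual, per-curve choice an analyst makes in a
    spreadsheet; :meth:`default_for` takes the lowest and highest 15 % of
    the curve's temperature range.
    """

    lower_window: tuple[float, float]
    upper_window: tuple[float, float]
    min_points: int = 8

    def __post_init__(self) -> None:
        lo, hi = self.lower_window, self.upper_window
        if lo[0] >= lo[1] or hi[0] >= hi[1]:
            raise ValueError("each window must be (Tmin, Tmax) with Tmin < Tmax")
        if lo[1] >= hi[0]:
            raise ValueError("lower window must lie entirely below upper window")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")

    @classmethod
    def default_for(cls, curve: MeltingCurve, fraction: float = 0.15) -> "BaselineWindows":
        t = curve.temperatures
        span = t[-1] - t[0]
        return cls(
            lower_window=(float(t[0]), float(t[0] + fraction * span)),
            upper_window=(float(t[-1] - fraction * span), float(t[-1])),
        )


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    residual_sd: float
    n_points: int

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.slope * t + self.intercept


@dataclass(frozen=True)
class TmResult:
    """Extracted Tm (°C) with baseline fits and quality flags."""

    tm: float
    lower_fit: LinearFit
    upper_fit: LinearFit
    crossing_index: int
    multiple_crossings: bool = False
    flags: tuple[str, ...] = ()


def _window_mask(curve: MeltingCurve, window: tuple[float, float]) -> np.ndarray:
    t = curve.temperatures
    if window[0] < t[0] - 1e-9 or window[1] > t[-1] + 1e-9:
        raise ValueError(f"window {window} outside curve range ({t[0]}, {t[-1]})")
    return (t >= window[0]) & (t <= window[1])


def _ols_line(t: np.ndarray, a: np.ndarray) -> LinearFit:
    if np.ptp(t) == 0:
        raise ExtractionError("degenerate baseline window (zero temperature spread)")
    coeffs, residuals, *_ = np.polyfit(t, a, 1, full=True)
    dof = len(t) - 2
    rsd = float(np.sqrt(residuals[0] / dof)) if dof > 0 and len(residuals) else 0.0
    return LinearFit(slope=float(coeffs[0]), intercept=float(coeffs[1]),
                     residual_sd=rsd, n_points=len(t))


def fit_baselines(
    curve: MeltingCurve, windows: BaselineWindows
) -> tuple[LinearFit, LinearFit]:
    """Ordinary least-squares lines through the two baseline windows."""
    fits = []
    for window in (windows.lower_window, windows.upper_window):
        mask = _window_mask(curve, window)
        if mask.sum() < windows.min_points:
            raise ExtractionError(
                f"window {window} holds {int(mask.sum())} points, "
                f"fewer than the required {windows.min_points}"
            )
        fits.append(_ols_line(curve.temperatures[mask], curve.absorbances[mask]))
    return fits[0], fits[1]


def _refine_baselines(
    curve: MeltingCurve,
    windows: BaselineWindows,
    lower_fit: LinearFit,
    upper_fit: LinearFit,
    max_iter: int = 40,
    tol: float = 1e-10,
) -> tuple[LinearFit, LinearFit, bool]:
    """Two-state-aware iterative de-contamination of the baseline fits.

    Returns (lower, upper, converged); on any numerical failure the
    original single-pass fits are returned with ``converged=False``.
    """
    t = curve.temperatures
    a = curve.absorbances
    T = t + CELSIUS_OFFSET
    lo_mask = _window_mask(curve, windows.lower_window)
    hi_mask = _window_mask(curve, windows.upper_window)
    lo, hi = lower_fit, upper_fit
    prev = np.array([lo.slope, lo.intercept, hi.slope, hi.intercept])
    for _ in range(max_iter):
        upper = hi(t)
        lower = lo(t)
        denom = upper - lower
        if np.any(denom <= 0):
            return lower_fit, upper_fit, False
        alpha_hat = np.clip((upper - a) / denom, 1e-9, 1.0 - 1e-9)
        band = (alpha_hat >= 0.2) & (alpha_hat <= 0.8)
        if band.sum() < 5:
            return lower_fit, upper_fit, False
        # van't Hoff form of the apparent fraction: ln K linear in 1/T
        ln_k = np.log(alpha_hat[band] / (2.0 * curve.ct * (1.0 - alpha_hat[band]) ** 2))
        slope, intercept = np.polyfit(1.0 / T[band], ln_k, 1)
        dH_hat = -slope * GAS_CONSTANT
        dS_hat = intercept * GAS_CONSTANT
        if dH_hat >= 0:
            return lower_fit, upper_fit, False
        alpha_model = np.array(
            [fraction_duplexed(Tk, dH_hat, dS_hat, curve.ct) for Tk in T]
        )
        if np.any(alpha_model[lo_mask] < 0.1):
            return lower_fit, upper_fit, False
        # subtract the modeled tail contribution inside each window
        lower_pts = (a[lo_mask] - (1.0 - alpha_model[lo_mask]) * hi(t[lo_mask])) / alpha_model[lo_mask]
        upper_pts = (a[hi_mask] - alpha_model[hi_mask] * lo(t[hi_mask])) / (1.0 - alpha_model[hi_mask])
        lo = _ols_line(t[lo_mask], lower_pts)
        hi = _ols_line(t[hi_mask], upper_pts)
        cur = np.array([lo.slope, lo.intercept, hi.slope, hi.intercept])
        if np.max(np.abs(cur - prev)) < tol:
            return lo, hi, True
        prev = cur
    return lo, hi, True  # converged in practice; last iterate


def tm_from_curve(
    curve: MeltingCurve,
    windows: BaselineWindows | None = None,
    refine: bool = True,
) -> TmResult:
    """Tm as the intersection of the profile with the baseline median line.

    The crossing is located where A(T) − median(T) changes sign between
    the two windows; with several sign changes the one closest to the
    steepest-slope temperature is taken and flagged. ``refine`` controls
    the iterative two-state baseline de-contamination (see module notes).
    """
    if windows is None:
        windows = BaselineWindows.default_for(curve)
    lower_fit, upper_fit = fit_baselines(curve, windows)
    refine_flags: list[str] = []
    if refine:
        lower_fit, upper_fit, ok = _refine_baselines(curve, windows, lower_fit, upper_fit)
        if not ok:
            refine_flags.append("refine_failed")
    t = curve.temperatures
    a = curve.absorbances

    # refuse flat / low-amplitude transitions
    t_mid = 0.5 * (windows.lower_window[1] + windows.upper_window[0])
    amplitude = upper_fit(np.array([t_mid]))[0] - lower_fit(np.array([t_mid]))[0]
    noise = max(lower_fit.residual_sd, upper_fit.residual_sd, 1e-12)
    if amplitude <= 0 or amplitude < _MIN_AMPLITUDE_SNR * noise:
        raise ExtractionError(
            f"transition amplitude {amplitude:.3g} below {_MIN_AMPLITUDE_SNR}x "
            f"noise estimate {noise:.3g}: flat or inverted curve"
        )

    median = 0.5 * (lower_fit(t) + upper_fit(t))
    diff = a - median
    between = (t > windows.lower_window[1]) & (t < windows.upper_window[0])
    idx = np.flatnonzero(between[:-1] & between[1:] & (np.sign(diff[:-1]) * np.sign(diff[1:]) < 0))
    exact = np.flatnonzero(between & (diff == 0.0))

    crossings: list[tuple[float, int]] = [(float(t[i]), int(i)) for i in exact]
    for i in idx:
        # linear interpolation of the sign change inside [t[i], t[i+1]]
        frac = diff[i] / (diff[i] - diff[i + 1])
        crossings.append((float(t[i] + frac * (t[i + 1] - t[i])), int(i)))
    if not crossings:
        raise ExtractionError("median line does not cross the profile between the windows")

    flags: list[str] = refine_flags
    multiple = len(crossings) > 1
    if multiple:
        # pick the crossing nearest the steepest part of the transition
        slope = np.gradient(a, t)
        t_steep = float(t[between][np.argmax(np.abs(slope[between]))])
        crossings.sort(key=lambda c: abs(c[0] - t_steep))
        flags.append("multiple_crossings")
    tm, index = crossings[0]
    return TmResult(
        tm=tm,
        lower_fit=lower_fit,
        upper_fit=upper_fit,
        crossing_index=index,
        multiple_crossings=multiple,
        flags=tuple(flags),
    )
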