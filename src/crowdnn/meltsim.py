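"""Synthetic UV melting curves for a two-state self-complementary duplex.

The generator produces the data the downstream analysis assumes: an
absorbance-vs-temperature profile that interpolates between a linear
lower (duplex) baseline and a linear upper (single-strand) baseline
according to the duplexed fraction α(T), plus i.i.d. Gaussian noise,

    A(T) = α(T)·lower(T) + (1 − α(T))·upper(T) + ε,  ε ~ N(0, noise_sd²),

together with concentration series spanning the 50–100-fold Ct range used
for van't Hoff analysis. Default baselines give a unit-amplitude
hyperchromic transition with gently sloping ends; real-instrument
artifacts (drift, hysteresis, condensation) are deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np

from .thermo import celsius_to_kelvin, fraction_duplexed

__all__ = [
    "MeltingCurve",
    "CurveModel",
    "default_grid",
    "default_ct_series",
    "simulate_curve",
    "simulate_concentration_series",
    "write_curve_tsv",
    "read_curve_tsv",
]

#: Per-curve seed offset within a series (one master seed per series).
_SEED_STRIDE = 1000


@dataclass(frozen=True)
class MeltingCurve:
    """One melting profile: temperatures (°C, ascending) vs absorbance."""

    temperatures: np.ndarray
    absorbances: np.ndarray
    ct: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "absorbances", a)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("temperatures and absorbances must be equal-length 1-D")
        if len(t) < 20:
            raise ValueError(f"melting curve needs >= 20 points (got {len(t)})")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.ct <= 0:
            raise ValueError(f"Ct must be positive (got {self.ct})")


@dataclass(frozen=True)
class CurveModel:
    """Ground-truth parameters behind a simulated melt.

    Baselines are absorbance-vs-°C lines; the upper (single-strand)
    baseline must exceed the lower (duplex) one over the simulated range
    (hyperchromicity).
    """

    dH: float
    dS: float
    lower_slope: float = 2e-4
    lower_intercept: float = 1.0
    upper_slope: float = 5e-4
    upper_intercept: float = 1.9865  # unit amplitude at 45 °C
    noise_sd: float = 0.0
    seed: int = 0

    def lower(self, t_celsius: np.ndarray) -> np.ndarray:
        return self.lower_slope * t_celsius + self.lower_intercept

    def upper(self, t_celsius: np.ndarray) -> np.ndarray:
        return self.upper_slope * t_celsius + self.upper_intercept


def default_grid(start: float = 0.0, stop: float = 90.0, step: float = 0.5) -> np.ndarray:
    """Temperature grid in °C mirroring a 0–90 °C melt ramp."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def default_ct_series(n: int = 12, lo: float = 2e-6, hi: float = 2e-4) -> np.ndarray:
    """Log-spaced total strand concentrations (mol/L), 100-fold range."""
    return np.geomspace(lo, hi, n)


def simulate_curve(
    model: CurveModel,
    ct: float,
    grid: np.ndarray | None = None,
    label: str = "",
) -> MeltingCurve:
    """Simulate one melting curve; deterministic for a given model.seed."""
    t = default_grid() if grid is None else np.asarray(grid, dtype=float)
    lower = model.lower(t)
    upper = model.upper(t)
    if np.any(upper <= lower):
        raise ValueError(
            "upper baseline must exceed lower baseline over the whole grid "
            "(hyperchromicity)"
        )
    alpha = np.array(
        [fraction_duplexed(celsius_to_kelvin(tc), model.dH, model.dS, ct) for tc in t]
    )
    a = alpha * lower + (1.0 - alpha) * upper
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        a = a + rng.normal(0.0, model.noise_sd, size=a.shape)
    return MeltingCurve(t, a, ct=ct, label=label)


def simulate_concentration_series(
    model: CurveModel,
    ct_values: Sequence[float] | None = None,
    grid: np.ndarray | None = None,
    label: str = "",
) -> list[MeltingCurve]:
    """One curve per Ct with independent noise; seeds derived from model.seed.

    Curve i uses seed ``model.seed + i * 1000`` so a whole series is
    reproducible from the single master seed.
    """
    cts = default_ct_series() if ct_values is None else np.asarray(ct_values, float)
    if len(cts) < 2:
        raise ValueError("a concentration series needs at least 2 Ct values")
    if np.any(cts <= 0):
        raise ValueError("all Ct values must be positive")
    if len(cts) == 2:
        warnings.warn(
            "2-point concentration series: van't Hoff fit will have no "
            "error estimates",
            stacklevel=2,
        )
    return [
        simulate_curve(
            replace(model, seed=model.seed + i * _SEED_STRIDE),
            ct=float(ct),
            grid=grid,
            label=f"{label or 'curve'}_{i:02d}",
        )
        for i, ct in enumerate(cts)
    ]


def write_curve_tsv(curve: MeltingCurve, path: str | Path, model: CurveModel | None = None) -> None:
    """Write a curve as two-column TSV with a comment header carrying Ct
    (and, when known, the generating truth parameters)."""
    lines = [f"# label\t{curve.label}", f"# Ct_mol_per_L\t{curve.ct:.8g}"]
    if model is not None:
        lines += [
            f"# truth_dH_kcal_mol\t{model.dH:.8g}",
            f"# truth_dS_kcal_mol_K\t{model.dS:.8g}",
            f"# noise_sd\t{model.noise_sd:.8g}",
            f"# seed\t{model.seed}",
        ]
    lines.append("temperature_C\tabsorbance")
    lines += [f"{t:.4f}\t{a:.6f}" for t, a in zip(curve.temperatures, curve.absorbances)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve_tsv(path: str | Path) -> MeltingCurve:
    """Read a two-column TSV melting curve written by :func:`write_curve_tsv`."""
    ct = None
    label = ""
    temps: list[float] = []
    abss: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if len(parts) == 2 and parts[0] == "Ct_mol_per_L":
                ct = float(parts[1])
            elif len(parts) == 2 and parts[0] == "label":
                label = parts[1]
            continue
        if line[0].isalpha():  # column header
            continue
        t_s, a_s = line.split("\t")
        temps.append(float(t_s))
        abss.append(float(a_s))
    if ct is None:
        raise ValueError(f"{path}: missing '# Ct_mol_per_L' header")
    return MeltingCurve(np.array(temps), np.array(abss), ct=ct, label=label)
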