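"""Nearest-neighbor ΔG°37 and Tm prediction: dilute and crowding conditions.

Dilute 1 M NaCl predictions sum the standard NN ΔG°37 increments over the
step frequencies, plus the initiation term for the terminal base-pair
class and the self-complementary symmetry penalty. Physiological-salt
(0.1 M NaCl) values follow from the empirical linear salt corrections

    ΔG°37(0.1 M) = 0.63·ΔG°37(1 M) − 1.67
    Tm(0.1 M)    = 0.88·Tm(1 M)   − 5.15

and crowding (40 wt% PEG 200) values either from the condition-level
linear free-energy relations

    ΔG°37(crowding) = 0.99·ΔG°37(dilute) + 2.32
    Tm(crowding)    = 0.90·Tm(dilute)    − 3.39

or from a crowding NN parameter set obtained by the affine scaling
C_i = a·D_i + b (a = 0.666, b = 0.117) of the dilute increments and
initiations. Crowding NN predictions omit the symmetry term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .seqmodel import NN_SETS, DuplexSequence, NNFrequencyVector, count_nn_steps

__all__ = [
    "NNParameterSet",
    "ScalingCoefficients",
    "DILUTE_1M_DG37",
    "SYMMETRY_DG37",
    "predict_dG_dilute_1M",
    "salt_correct_dG",
    "salt_correct_tm",
    "predict_dG_crowding_linear",
    "predict_tm_crowding_linear",
    "predict_dG_crowding_nn",
    "scale_parameters",
    "round_table",
]

# condition tags
DILUTE_1M = "dilute_1M"
DILUTE_01M = "dilute_0.1M"
CROWDING = "crowding_40PEG200"

#: Self-complementary symmetry penalty, kcal·mol⁻¹ (dilute predictions only).
SYMMETRY_DG37: float = 0.43


@dataclass(frozen=True)
class NNParameterSet:
    """A ΔG°37 NN parameter set: 10 increments plus two initiation terms.

    ``symmetry_term`` is the self-complementary penalty where the
    convention applies (dilute sets); ``None`` marks sets defined without
    one (the crowding set). Optional per-entry standard errors share the
    increment keys plus ``init_GC``/``init_AT``.
    """

    condition: str
    dG_increments: Mapping[str, float]
    init_GC: float
    init_AT: float
    symmetry_term: float | None = None
    errors: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        missing = set(NN_SETS) - set(self.dG_increments)
        if missing:
            raise ValueError(f"missing NN increments: {sorted(missing)}")
        if any(v >= 0 for v in self.dG_increments.values()):
            raise ValueError("all propagation increments must be stabilizing (< 0)")
        if self.init_GC <= 0 or self.init_AT <= 0:
            raise ValueError("initiation terms must be penalties (> 0)")

    def initiation(self, initiation_class: str) -> float:
        if initiation_class == "GC":
            return self.init_GC
        if initiation_class == "AT":
            return self.init_AT
        raise ValueError(f"unknown initiation class {initiation_class!r}")


@dataclass(frozen=True)
class ScalingCoefficients:
    """Affine map C = a·D + b between dilute and crowding NN parameters,
    with the measured-vs-calculated regression diagnostics at (a, b)."""

    a: float
    b: float
    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"scaling coefficient a must be positive (got {self.a})")


#: Standard dilute 1 M NaCl NN ΔG°37 set, kcal·mol⁻¹.
DILUTE_1M_DG37 = NNParameterSet(
    condition=DILUTE_1M,
    dG_increments={
        "AA": -1.02, "AT": -0.73, "TA": -0.60, "CA": -1.38, "GT": -1.44,
        "CT": -1.16, "GA": -1.46, "CG": -2.09, "GC": -2.28, "GG": -1.77,
    },
    init_GC=1.82,
    init_AT=2.80,
    symmetry_term=SYMMETRY_DG37,
)


def _freqs(seq_or_freqs: NNFrequencyVector | DuplexSequence | str) -> NNFrequencyVector:
    if isinstance(seq_or_freqs, NNFrequencyVector):
        return seq_or_freqs
    return count_nn_steps(seq_or_freqs)


def predict_dG_dilute_1M(
    freqs: NNFrequencyVector | DuplexSequence | str,
    params: NNParameterSet = DILUTE_1M_DG37,
) -> float:
    """ΔG°37 (kcal·mol⁻¹) in dilute 1 M NaCl: Σ nᵢDᵢ + initiation + symmetry."""
    if params.condition != DILUTE_1M:
        raise ValueError(f"expected a {DILUTE_1M} parameter set, got {params.condition}")
    f = _freqs(freqs)
    total = sum(n * params.dG_increments[s] for s, n in f.as_dict().items())
    total += params.initiation(f.initiation_class)
    if params.symmetry_term is not None:
        total += params.symmetry_term
    return total


def salt_correct_dG(dG_1M: float) -> float:
    """ΔG°37 at 0.1 M NaCl from the 1 M value (kcal·mol⁻¹)."""
    return 0.63 * dG_1M - 1.67


def salt_correct_tm(tm_1M: float) -> float:
    """Tm at 0.1 M NaCl from the 1 M value (°C in, °C out)."""
    return 0.88 * tm_1M - 5.15


def predict_dG_crowding_linear(dG_dilute_01M: float) -> float:
    """ΔG°37 under 40 wt% PEG 200 from the dilute 0.1 M NaCl prediction."""
    return 0.99 * dG_dilute_01M + 2.32


def predict_tm_crowding_linear(tm_dilute_01M: float) -> float:
    """Tm (°C) under 40 wt% PEG 200 from the dilute 0.1 M NaCl prediction."""
    return 0.90 * tm_dilute_01M - 3.39


def predict_dG_crowding_nn(
    freqs: NNFrequencyVector | DuplexSequence | str,
    params: NNParameterSet,
) -> float:
    """ΔG°37 (kcal·mol⁻¹) in crowding from the crowding NN set: Σ nᵢCᵢ + I_c.

    No symmetry term: the crowding parameters are defined without one
    because they were derived from self-complementary sequences only.
    """
    if params.condition != CROWDING:
        raise ValueError(f"expected a {CROWDING} parameter set, got {params.condition}")
    f = _freqs(freqs)
    total = sum(n * params.dG_increments[s] for s, n in f.as_dict().items())
    return total + params.initiation(f.initiation_class)


def scale_parameters(
    dilute: NNParameterSet, coeffs: ScalingCoefficients
) -> NNParameterSet:
    """Crowding NN set from a dilute set by x → a·x + b on every increment
    and both initiations; errors scale as σ → a·σ; the symmetry term is
    dropped."""
    a, b = coeffs.a, coeffs.b
    return NNParameterSet(
        condition=CROWDING,
        dG_increments={s: a * v + b for s, v in dilute.dG_increments.items()},
        init_GC=a * dilute.init_GC + b,
        init_AT=a * dilute.init_AT + b,
        symmetry_term=None,
        errors=(
            {k: a * v for k, v in dilute.errors.items()}
            if dilute.errors is not None
            else None
        ),
    )


def round_table(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of the printed tables."""
    scale = 10**decimals
    import math

    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)
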