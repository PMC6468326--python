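"""Nearest-neighbor predictions: dilute, salt-corrected and crowding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdnn.nnpredict import (
    CROWDING,
    DILUTE_1M,
    DILUTE_1M_DG37,
    NNParameterSet,
    ScalingCoefficients,
    predict_dG_crowding_linear,
    predict_dG_crowding_nn,
    predict_dG_dilute_1M,
    predict_tm_crowding_linear,
    round_table,
    salt_correct_dG,
    salt_correct_tm,
    scale_parameters,
)
from crowdnn.seqmodel import NN_SETS, NNFrequencyVector


def test_dilute_prediction_GCGAATTCGC():
    # 2·(−1.02) + 1·(−0.73) + 2·(−1.46) + 2·(−2.09) + 2·(−2.28) + 1.82 + 0.43
    assert predict_dG_dilute_1M("GCGAATTCGC") == pytest.approx(-12.18, abs=1e-9)


def test_dilute_prediction_CCGCGG():
    # 2·(−2.09) + 1·(−2.28) + 2·(−1.77) + 1.82 + 0.43
    assert predict_dG_dilute_1M("CCGCGG") == pytest.approx(-7.75, abs=1e-9)


def test_dilute_set_validated_by_inverting_crowding_table(bundle):
    """Each embedded dilute value equals (C − 0.117)/0.666 of the crowding
    table within the crowding table's rounding half-width (scaled)."""
    t5 = bundle.table5.set_index("set")
    for s in NN_SETS:
        inverted = (t5.loc[s, "dG37"] - 0.117) / 0.666
        assert DILUTE_1M_DG37.dG_increments[s] == pytest.approx(
            inverted, abs=0.005 / 0.666
        ), s
    assert DILUTE_1M_DG37.init_GC == pytest.approx(
        (t5.loc["init_GC", "dG37"] - 0.117) / 0.666, abs=0.005 / 0.666
    )
    assert DILUTE_1M_DG37.init_AT == pytest.approx(
        (t5.loc["init_AT", "dG37"] - 0.117) / 0.666, abs=0.005 / 0.666
    )


@pytest.mark.parametrize(
    "x,expected", [(0.0, -1.67), (-10.0, -7.97), (-12.18, -9.3434)]
)
def test_salt_correct_dG(x, expected):
    assert salt_correct_dG(x) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("x,expected", [(0.0, -5.15), (50.0, 38.85), (54.15, 42.502)])
def test_salt_correct_tm(x, expected):
    assert salt_correct_tm(x) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "x,expected", [(-10.0, -7.58), (-6.9, -4.511), (0.0, 2.32)]
)
def test_crowding_relation_dG(x, expected):
    assert predict_dG_crowding_linear(x) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("x,expected", [(53.0, 44.31), (38.2, 30.99), (0.0, -3.39)])
def test_crowding_relation_tm(x, expected):
    assert predict_tm_crowding_linear(x) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("GCGAATTCGC", -7.22),   # G·C initiation
        ("GACGACGTCGTC", -9.28),
        ("AGTCATGACT", -4.71),   # A·T initiation
    ],
)
def test_crowding_nn_prediction(seq, expected, crowding_params):
    assert predict_dG_crowding_nn(seq, crowding_params) == pytest.approx(
        expected, abs=1e-9
    )


def test_condition_tags_enforced(crowding_params):
    with pytest.raises(ValueError, match="dilute_1M"):
        predict_dG_dilute_1M("AT", crowding_params)
    with pytest.raises(ValueError, match="crowding"):
        predict_dG_crowding_nn("AT", DILUTE_1M_DG37)


def test_scale_identity_drops_symmetry_only():
    scaled = scale_parameters(DILUTE_1M_DG37, ScalingCoefficients(a=1.0, b=0.0))
    assert scaled.dG_increments == DILUTE_1M_DG37.dG_increments
    assert scaled.init_GC == DILUTE_1M_DG37.init_GC
    assert scaled.symmetry_term is None
    assert scaled.condition == CROWDING


def test_scaled_parameters_match_crowding_table(bundle):
    """a = 0.666, b = 0.117 maps the dilute set onto every tabulated
    crowding entry within the table's rounding half-width."""
    scaled = scale_parameters(DILUTE_1M_DG37, ScalingCoefficients(a=0.666, b=0.117))
    t5 = bundle.table5.set_index("set")
    for s in NN_SETS:
        assert scaled.dG_increments[s] == pytest.approx(
            t5.loc[s, "dG37"], abs=0.005
        ), s
    assert scaled.init_GC == pytest.approx(t5.loc["init_GC", "dG37"], abs=0.005)
    assert scaled.init_AT == pytest.approx(t5.loc["init_AT", "dG37"], abs=0.005)


def test_affine_round_trip():
    coeffs = ScalingCoefficients(a=0.666, b=0.117)
    scaled = scale_parameters(DILUTE_1M_DG37, coeffs)
    for s, v in scaled.dG_increments.items():
        back = (v - coeffs.b) / coeffs.a
        assert back == pytest.approx(DILUTE_1M_DG37.dG_increments[s], abs=0.01)


def test_error_scaling():
    dilute = NNParameterSet(
        condition=DILUTE_1M,
        dG_increments=DILUTE_1M_DG37.dG_increments,
        init_GC=1.82,
        init_AT=2.80,
        errors={"AA": 0.10, "init_GC": 0.2},
    )
    scaled = scale_parameters(dilute, ScalingCoefficients(a=0.5, b=0.1))
    assert scaled.errors == {"AA": 0.05, "init_GC": 0.1}


@given(
    counts=st.lists(st.integers(min_value=0, max_value=6), min_size=10, max_size=10),
    init=st.sampled_from(["AT", "GC"]),
    a=st.floats(min_value=0.5, max_value=1.5),
    b=st.floats(min_value=-0.3, max_value=0.25),  # keeps a·D + b stabilizing
)
@settings(max_examples=100, derandomize=True)
def test_affine_consistency(counts, init, a, b):
    """predict(scale(params)) = a·(Σ nᵢDᵢ + I_d) + b·(Σ nᵢ + 1) identically."""
    freqs = NNFrequencyVector(
        counts=dict(zip(NN_SETS, counts)),
        initiation_class=init,
        terminal_5prime_pair="A·T" if init == "AT" else "G·C",
    )
    scaled = scale_parameters(DILUTE_1M_DG37, ScalingCoefficients(a=a, b=b))
    lhs = predict_dG_crowding_nn(freqs, scaled)
    inc = DILUTE_1M_DG37.dG_increments
    dilute_sum = sum(n * inc[s] for s, n in freqs.as_dict().items())
    dilute_sum += DILUTE_1M_DG37.initiation(init)
    rhs = a * dilute_sum + b * (freqs.total + 1)
    assert lhs == pytest.approx(rhs, abs=1e-9)


def test_parameter_set_validation():
    with pytest.raises(ValueError, match="missing"):
        NNParameterSet(condition=DILUTE_1M, dG_increments={"AA": -1.0}, init_GC=1.0, init_AT=2.0)
    with pytest.raises(ValueError, match="stabilizing"):
        NNParameterSet(
            condition=DILUTE_1M,
            dG_increments={s: 0.5 for s in NN_SETS},
            init_GC=1.0,
            init_AT=2.0,
        )


@pytest.mark.parametrize(
    "x,expected", [(-7.575, -7.6), (-4.45, -4.5), (2.345, 2.3), (-14.238, -14.2)]
)
def test_round_half_away_from_zero(x, expected):
    assert round_table(x) == pytest.approx(expected, abs=1e-12)
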