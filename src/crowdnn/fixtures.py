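"""Packaged study tables and their validated loading.

Five CSV tables transcribed from the study ship with the package:

* ``table1`` — the 28 self-complementary sequences with their NN-step
  frequencies (9 identical-NN pairs 1a/1b … 9a/9b plus sequences 10–19;
  19 distinct designs);
* ``table2`` — measured crowding (40 wt% PEG 200) thermodynamics with
  standard errors, plus dilute-condition predicted ΔG°37/Tm;
* ``table3`` — dextran 70 / Ficoll 70 measurements for pairs 6 and 7;
* ``table4`` — measured / predicted / NN-calculated comparison columns;
* ``table5`` — the crowding NN ΔG°37 parameter set with errors.

Loading validates shapes, cross-checks every table1 frequency row
against fresh NN-step counting, and checks ΔG°37 = ΔH° − TΔS° row by row.
Typographic minus signs (U+2212) are normalized to ASCII on ingestion.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .crowdfit import StudyDataset, StudyRow
from .nnpredict import CROWDING, NNParameterSet
from .seqmodel import NN_SETS, NNFrequencyVector, count_nn_steps

__all__ = ["FixtureBundle", "load_fixtures", "study_dataset", "crowding_parameter_set"]

_EXPECTED_ROWS = {"table1": 28, "table2": 28, "table3": 8, "table4": 28, "table5": 12}
_N_DESIGNS = 19

#: Rows transcribed as printed even though ΔH° − TΔS° disagrees with the
#: printed ΔG°37 (row 8b: −61.8 − (−54.5) = −7.3 vs printed −9.3; the
#: ΔG°37/Tm values are the ones consistent with its identical-NN partner
#: 8a and with every downstream table, so the misprint is in ΔH° or TΔS°).
KNOWN_INCONSISTENT_ROWS: frozenset[str] = frozenset({"8b"})


class CorruptFixtureError(RuntimeError):
    """A packaged table failed shape or consistency validation."""


@dataclass(frozen=True)
class FixtureBundle:
    """The five study tables as DataFrames."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame


def _read_csv(name: str, path: Path | None) -> pd.DataFrame:
    if path is not None:
        text = (path / f"{name}.csv").read_text()
    else:
        text = resources.files("crowdnn.data").joinpath(f"{name}.csv").read_text()
    text = text.replace("−", "-")  # typographic minus -> ASCII
    return pd.read_csv(io.StringIO(text), dtype={"id": str, "pair": str}, keep_default_na=False, na_values=[""])


def load_fixtures(path: str | Path | None = None) -> FixtureBundle:
    """Load and validate the packaged tables (or a directory of overrides)."""
    path = Path(path) if path is not None else None
    tables = {name: _read_csv(name, path) for name in _EXPECTED_ROWS}
    for name, df in tables.items():
        if len(df) != _EXPECTED_ROWS[name]:
            raise CorruptFixtureError(
                f"{name}: expected {_EXPECTED_ROWS[name]} rows, found {len(df)}"
            )

    t1 = tables["table1"]
    missing = ({"id", "sequence"} | set(NN_SETS)) - set(t1.columns)
    if missing:
        raise CorruptFixtureError(f"table1: missing columns {sorted(missing)}")
    for _, row in t1.iterrows():
        counted = count_nn_steps(row["sequence"]).as_dict()
        tabulated = {s: int(row[s]) for s in NN_SETS}
        if counted != tabulated:
            raise CorruptFixtureError(
                f"table1 id {row['id']}: tabulated frequencies {tabulated} "
                f"disagree with counted {counted}"
            )

    t2 = tables["table2"]
    resid = (t2["dH"] - t2["TdS37"] - t2["dG37"]).abs()
    bad = set(t2.loc[resid > 0.05 + 1e-9, "id"]) - KNOWN_INCONSISTENT_ROWS
    if bad:
        raise CorruptFixtureError(
            f"table2 rows {sorted(bad)}: dG37 != dH - TdS37 beyond rounding half-width"
        )
    if list(t1["id"]) != list(t2["id"]) or list(t1["id"]) != list(tables["table4"]["id"]):
        raise CorruptFixtureError("tables 1/2/4 disagree on sequence ids or order")
    return FixtureBundle(**tables)


def study_dataset(bundle: FixtureBundle | None = None) -> StudyDataset:
    """Join tables 1 and 2 into the per-sequence analysis dataset."""
    if bundle is None:
        bundle = load_fixtures()
    t1 = bundle.table1.set_index("id")
    rows = []
    for rid, r2 in bundle.table2.set_index("id").iterrows():
        r1 = t1.loc[rid]
        pair = r1["pair"] if isinstance(r1["pair"], str) and r1["pair"] else None
        rows.append(
            StudyRow(
                id=str(rid),
                sequence=r1["sequence"],
                freqs=count_nn_steps(r1["sequence"]),
                measured_dG37=float(r2["dG37"]),
                measured_Tm=float(r2["Tm"]),
                predicted_dG37_dilute=float(r2["pred_dG37_dilute"]),
                predicted_Tm_dilute=float(r2["pred_Tm_dilute"]),
                pair=pair,
            )
        )
    return StudyDataset(rows=tuple(rows))


def crowding_parameter_set(bundle: FixtureBundle | None = None) -> NNParameterSet:
    """The tabulated crowding NN ΔG°37 parameter set (table 5)."""
    if bundle is None:
        bundle = load_fixtures()
    t5 = bundle.table5.set_index("set")
    return NNParameterSet(
        condition=CROWDING,
        dG_increments={s: float(t5.loc[s, "dG37"]) for s in NN_SETS},
        init_GC=float(t5.loc["init_GC", "dG37"]),
        init_AT=float(t5.loc["init_AT", "dG37"]),
        symmetry_term=None,
        errors={k: float(v) for k, v in t5["err"].items()},
    )
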