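"""Validation arithmetic for measured vs computed pair currents, and QA reports.

The pulse generator records the delivered current of every electrode pair;
comparing it with the current predicted by the field model is the standard
validation of an ECT treatment plan.  Two summaries are used: the signed
relative error per pair, ``(I_comp - I_meas) / I_meas`` reported as a
rounded percent, and the root-mean-square error over the pairs of one
lesion, reported in amperes to one decimal.  Internal values are never
rounded; rounding happens only at the reporting boundary.

A transcription of the reference clinical measured/computed current table ships with
the package (``data/table1.csv``) for tests and the demo report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CurrentRecord:
    """Measured vs computed current for one electrode pair."""

    pair: str
    voltage: float
    i_meas: float
    i_comp: float

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ValueError("voltage must be > 0")
        if self.i_meas <= 0 or self.i_comp <= 0:
            raise ValueError("currents must be > 0")


def current_error(record: CurrentRecord) -> int:
    """Signed relative error ``100 * (i_comp - i_meas) / i_meas``, percent.

    Rounded to the nearest integer percent (reporting convention); positive
    when the model overpredicts.  Use :func:`current_error_raw` for the
    unrounded value.
    """
    return int(np.rint(current_error_raw(record)))


def current_error_raw(record: CurrentRecord) -> float:
    if record.i_meas == 0:
        raise ValueError("measured current is zero; relative error undefined")
    return 100.0 * (record.i_comp - record.i_meas) / record.i_meas


def current_rmse(records: list[CurrentRecord]) -> float:
    """Root-mean-square error (A) of computed vs measured currents."""
    if not records:
        raise ValueError("no current records given")
    diffs = np.array([r.i_comp - r.i_meas for r in records])
    return float(np.sqrt(np.mean(diffs**2)))


def load_table1() -> pd.DataFrame:
    """The reference clinical measured/computed current table, as transcribed."""
    with resources.files("ectplan.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def table1_records(metastasis: int) -> list[CurrentRecord]:
    """Current records of one lesion from the packaged table."""
    df = load_table1()
    sub = df[df["metastasis"] == metastasis]
    if sub.empty:
        raise ValueError("metastasis must be 1 or 2")
    return [
        CurrentRecord(pair=row.pair, voltage=row.voltage_v,
                      i_meas=row.i_meas_a, i_comp=row.i_comp_a)
        for row in sub.itertuples()
    ]


def plan_report(plan, solutions, coverage_report) -> dict:
    """Structured, JSON-serializable QA report for a solved plan.

    Per pair: voltage, predicted current and the voltage-to-distance ratio;
    plus plan-level coverage, CVH and (if computed) robustness, and the
    constraint checks a clinician would look at first.
    """
    from ectplan.electrodes import voltage_to_distance_ratio

    pairs = []
    for entry, sol in zip(plan.schedule, solutions):
        pairs.append(
            {
                "pair": list(entry.pair),
                "voltage_v": entry.voltage,
                "predicted_current_a": sol.current,
                "voltage_to_distance_vcm": voltage_to_distance_ratio(entry, plan.array),
                "n_pulses": entry.n_pulses,
                "converged": sol.converged,
            }
        )
    report = {
        "n_pairs": len(pairs),
        "total_pulses": plan.schedule.total_pulses,
        "per_pair": pairs,
        "coverage": coverage_report.to_dict(),
    }
    # round-trip safety: everything must be plain JSON types
    json.dumps(report)
    return report
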