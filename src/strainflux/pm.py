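"""Phenotype-microarray (PM) quantitation and model concordance.

Biolog PM plates report dye-reduction kinetics per well over ~48 h.  The
quantitation pipeline is: trapezoidal area beneath each growth-time
curve (unitless), averaging over replicate plates, subtraction of the
negative-control area (floored at 0), qualitative grading of the net
area into -, + and ++ tiers, and binarized concordance against FBA
growth predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from strainflux.models import GrowthCall


class PMDataError(Exception):
    """Malformed or inconsistent PM kinetic data."""


MINUS = "minus"
PLUS = "plus"
PLUS_PLUS = "plus_plus"
GRADES = (MINUS, PLUS, PLUS_PLUS)

#: negative-control well under standard Biolog plate layout
DEFAULT_CONTROL_WELL = "A01"


@dataclass
class PMWell:
    """Kinetics of one well of one replicate plate: unitless OmniLog-style
    signal over time (hours)."""

    plate: str
    well: str
    substrate: str
    replicate: int
    time: list[float] = field(default_factory=list)
    signal: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.time) != len(self.signal):
            raise PMDataError(
                f"{self.plate}/{self.well} rep {self.replicate}: "
                f"{len(self.time)} times vs {len(self.signal)} signals"
            )
        if len(self.time) < 2:
            raise PMDataError(f"{self.plate}/{self.well}: need >= 2 time points")
        t = np.asarray(self.time)
        if not np.all(np.diff(t) > 0):
            raise PMDataError(f"{self.plate}/{self.well}: times must strictly increase")
        if np.any(np.asarray(self.signal) < 0):
            raise PMDataError(f"{self.plate}/{self.well}: negative signal")


def curve_area(well: PMWell) -> float:
    """Unitless trapezoidal area beneath one growth-time curve."""
    return float(np.trapezoid(well.signal, well.time))


def summarize_wells(
    replicates: list[PMWell], negative_control: list[PMWell]
) -> float:
    """Mean replicate area minus mean negative-control area, floored at 0."""
    if not replicates:
        raise PMDataError("no replicate wells supplied")
    mean_area = float(np.mean([curve_area(w) for w in replicates]))
    control = float(np.mean([curve_area(w) for w in negative_control])) if negative_control else 0.0
    return max(mean_area - control, 0.0)


def pm_call(net_area: float, cutoffs: tuple[float, float]) -> str:
    """Grade a net area: ``minus`` if <= low, ``plus`` if <= high,
    else ``plus_plus``."""
    low, high = cutoffs
    if not 0 <= low < high:
        raise ValueError(f"cutoffs must satisfy 0 <= low < high, got {cutoffs}")
    if net_area <= low:
        return MINUS
    if net_area <= high:
        return PLUS
    return PLUS_PLUS


def default_cutoffs(net_areas: list[float]) -> tuple[float, float]:
    """Data-driven grade cutoffs: low = 10th percentile of the plate's
    net areas, high = median.  Biolog's own grading thresholds are
    proprietary, so the defaults are quantiles and always overridable."""
    arr = np.asarray(net_areas, dtype=float)
    low = float(np.percentile(arr, 10))
    high = float(np.median(arr))
    if not low < high:  # degenerate plates (all areas equal)
        high = low + max(abs(low), 1.0)
    return low, high


def binarize_grade(grade: str) -> GrowthCall:
    """minus -> no_growth; plus/plus_plus -> growth."""
    if grade == MINUS:
        return GrowthCall.NO_GROWTH
    if grade in (PLUS, PLUS_PLUS):
        return GrowthCall.GROWTH
    raise ValueError(f"unknown PM grade {grade!r}")


def concordance(
    pm: pd.DataFrame,
    predictions: dict[str, GrowthCall],
    strain: str,
) -> tuple[float, pd.DataFrame]:
    """Fraction of conditions where the binarized PM grade agrees with
    the FBA call, plus a per-condition agreement table.

    ``pm`` has columns strain, condition, call (grades as written by
    :func:`save_calls`).  Only conditions present in both inputs are
    compared; an empty overlap raises :class:`PMDataError`.
    """
    mine = pm[pm["strain"] == strain]
    rows = []
    n_agree = 0
    compared = 0
    for _, rec in mine.iterrows():
        cond = rec["condition"]
        if cond not in predictions:
            continue
        experimental = binarize_grade(str(rec["call"]))
        predicted = predictions[cond]
        agree = experimental == predicted
        compared += 1
        n_agree += agree
        rows.append(
            {
                "condition": cond,
                "pm_grade": rec["call"],
                "experimental": experimental.value,
                "predicted": predicted.value,
                "agree": agree,
            }
        )
    if compared == 0:
        raise PMDataError(
            f"no overlapping conditions between PM table and predictions for {strain!r}"
        )
    table = pd.DataFrame(rows)
    return n_agree / compared, table


# ---------------------------------------------------------------------------
# IO: long-format kinetics CSV and calls TSV
# ---------------------------------------------------------------------------

def load_pm_kinetics(path: str | Path) -> list[PMWell]:
    """Long CSV (plate, well, substrate, replicate, time_h, signal) -> wells."""
    df = pd.read_csv(path)
    required = {"plate", "well", "substrate", "replicate", "time_h", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise PMDataError(f"{path}: missing column(s) {sorted(missing)}")
    wells = []
    for (plate, well, substrate, rep), grp in df.groupby(
        ["plate", "well", "substrate", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        wells.append(
            PMWell(
                plate=str(plate),
                well=str(well),
                substrate=str(substrate),
                replicate=int(rep),
                time=grp["time_h"].tolist(),
                signal=grp["signal"].tolist(),
            )
        )
    return wells


def save_pm_kinetics(wells: list[PMWell], path: str | Path) -> None:
    records = []
    for w in wells:
        for t, s in zip(w.time, w.signal):
            records.append(
                {
                    "plate": w.plate,
                    "well": w.well,
                    "substrate": w.substrate,
                    "replicate": w.replicate,
                    "time_h": t,
                    "signal": s,
                }
            )
    pd.DataFrame(records).to_csv(path, index=False)


def quantitate_plate(
    wells: list[PMWell],
    strain: str,
    control_well: str = DEFAULT_CONTROL_WELL,
    cutoffs: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Replicate-averaged, control-subtracted net area and grade per
    substrate of one strain's plate set.

    Returns a calls table (strain, condition, area, call).  With
    ``cutoffs=None`` the plate-quantile defaults are used.
    """
    by_substrate: dict[str, list[PMWell]] = {}
    controls: list[PMWell] = []
    for w in wells:
        if w.well == control_well:
            controls.append(w)
        else:
            by_substrate.setdefault(w.substrate, []).append(w)
    if not by_substrate:
        raise PMDataError("no non-control wells found")
    net = {
        substrate: summarize_wells(reps, controls)
        for substrate, reps in sorted(by_substrate.items())
    }
    if cutoffs is None:
        cutoffs = default_cutoffs(list(net.values()))
    return pd.DataFrame(
        [
            {
                "strain": strain,
                "condition": substrate,
                "area": area,
                "call": pm_call(area, cutoffs),
            }
            for substrate, area in net.items()
        ]
    )


def load_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"strain", "condition", "call"} - set(df.columns)
    if missing:
        raise PMDataError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def save_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)
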