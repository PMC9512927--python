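"""Leachate time-series summaries and the XRF normalization.

These are the numeric series behind the study-level readouts of a
bioleaching column experiment: run-averaged concentrations (computed by
pooling survey intensities before inversion), the absolute change between
the last and first sampling, the relative deviation between the
biostimulation (BS) and bioaugmentation (BA) treatments, and the
normalization of XRF solid-residue abundances to the last measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import ElementCalibration
from .io import CalibrationDesign, IntensityMatrix
from .quantification import ConcentrationEstimate, quantify_mean_intensity

__all__ = [
    "ConcentrationSeries",
    "time_averaged",
    "delta_last_first",
    "relative_deviation",
    "normalize_to_last",
    "series_from_frame",
]


@dataclass
class ConcentrationSeries:
    """Ordered (time, ĉ, sd) triples for one element under one condition."""

    element: str
    condition: tuple
    times: np.ndarray
    concentrations: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.times.size == 0:
            raise ValueError("a concentration series needs at least one point")
        if not (self.times.shape == self.concentrations.shape == self.sds.shape):
            raise ValueError("times, concentrations and sds must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def series_from_frame(
    conc: pd.DataFrame,
    meta: pd.DataFrame,
    element: str,
    condition: dict,
) -> ConcentrationSeries:
    """Assemble a series from a Concentrations File + sample-metadata table.

    ``meta`` must carry ``sample_id`` and ``time`` columns plus the columns
    named in ``condition`` (e.g. medium, treatment, water_type); primary
    estimates of ``element`` matching the condition are ordered by time.
    """
    sel = meta.copy()
    for key, val in condition.items():
        sel = sel[sel[key] == val]
    rows = conc[(conc["element"] == element) & conc["primary"]].merge(
        sel[["sample_id", "time"]], on="sample_id"
    )
    rows = rows.sort_values("time")
    return ConcentrationSeries(
        element=element,
        condition=tuple(sorted(condition.items())),
        times=rows["time"].to_numpy(dtype=float),
        concentrations=rows["concentration"].to_numpy(dtype=float),
        sds=rows["sd"].to_numpy(dtype=float),
    )


def time_averaged(
    calibs: Iterable[ElementCalibration],
    assay: IntensityMatrix,
    sample_ids: Sequence[str],
    label: str | None = None,
    design: CalibrationDesign | None = None,
) -> list[ConcentrationEstimate]:
    """Run-averaged concentrations, pooled at the intensity level.

    Averages are taken directly on the survey intensities of the selected
    samples and then translated once through the calibration curves, so the
    propagated SD carries the σ̂²/m pooling gain.
    """
    if not sample_ids:
        raise ValueError("empty sample set for time averaging")
    return quantify_mean_intensity(
        calibs, assay, sample_ids=sample_ids, label=label, design=design
    )


def delta_last_first(series: ConcentrationSeries) -> tuple[float, float]:
    """Absolute change between the last and first measurements.

    Δ = ĉ_last − ĉ_first with sd_Δ = sqrt(sd_last² + sd_first²), the two
    samplings being independent measurements.
    """
    if len(series) < 2:
        raise ValueError("need at least two points for a last-first difference")
    delta = float(series.concentrations[-1] - series.concentrations[0])
    sd = float(np.hypot(series.sds[-1], series.sds[0]))
    return delta, sd


def relative_deviation(
    bs: ConcentrationSeries, ba: ConcentrationSeries
) -> pd.DataFrame:
    """Per-timestamp relative deviation (ĉ_BS − ĉ_BA)/ĉ_BA with delta-method sd.

    Positive values mean the biostimulated concentration exceeds the
    bioaugmented one.  Series are compared on the intersection of their
    timestamps (with a warning when points are dropped); timestamps where
    ĉ_BA ≤ 0 yield NaN and are flagged ``undefined_reference``.
    """
    common = np.intersect1d(bs.times, ba.times)
    if common.size == 0:
        raise KeyError("the two series share no timestamps")
    if common.size < max(len(bs), len(ba)):
        warnings.warn(
            f"comparing on {common.size} shared timestamps "
            f"(BS has {len(bs)}, BA has {len(ba)})",
            stacklevel=2,
        )
    i_bs = np.searchsorted(bs.times, common)
    i_ba = np.searchsorted(ba.times, common)
    c_s, sd_s = bs.concentrations[i_bs], bs.sds[i_bs]
    c_a, sd_a = ba.concentrations[i_ba], ba.sds[i_ba]
    rho = np.full(common.size, np.nan)
    sd = np.full(common.size, np.nan)
    ok = c_a > 0
    rho[ok] = (c_s[ok] - c_a[ok]) / c_a[ok]
    # delta method on f(cS, cA) = cS/cA - 1
    sd[ok] = np.sqrt(sd_s[ok] ** 2 / c_a[ok] ** 2 + (c_s[ok] ** 2) * sd_a[ok] ** 2 / c_a[ok] ** 4)
    return pd.DataFrame(
        {
            "time": common,
            "relative_deviation": rho,
            "sd": sd,
            "flag": np.where(ok, "ok", "undefined_reference"),
        }
    )


def normalize_to_last(values: Sequence[float]) -> np.ndarray:
    """Divide an ordered abundance series by its last value.

    Used for XRF relative abundances when the first measurement sits below
    the detection limit; the final element of the result is exactly 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    if not (arr[-1] > 0):
        raise ValueError(f"last value {arr[-1]} must be > 0 to normalize")
    return arr / arr[-1]
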