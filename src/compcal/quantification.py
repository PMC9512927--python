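"""Inverse prediction: from assay intensities back to concentrations.

A fitted channel gives r̂ = (I − b̂)/ŝ, the sample's dilution-equivalent with
respect to the main calibration mixture, and ĉ = r̂·C0.  The standard
deviation comes from first-order (delta-method) propagation, treating the
calibration estimates (b̂, ŝ) and the sample intensity as mutually
independent while keeping the b̂–ŝ covariance:

    sd_r² = (σ̂²/m + var_b + r̂²·var_s + 2·r̂·cov_bs) / ŝ²

where m is the number of intensity replicates averaged into I.  The sample
intensity's own error uses the calibration-estimated σ̂ of the channel.
Negative concentrations are reported as-is (flag ``below_background``) so
that downstream averaging stays unbiased; r̂ > 1 is allowed and flagged
``extrapolated_above_standard`` — such results remain usable, with small
relative SDs, because the survey intensities stay linear above d = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import ElementCalibration
from .exceptions import MissingCalibrationError, NonPositiveSensitivityError
from .io import CalibrationDesign, IntensityMatrix

__all__ = [
    "ConcentrationEstimate",
    "invert_intensity",
    "quantify_sample",
    "quantify_mean_intensity",
    "estimates_to_frame",
]

FLAG_OK = "ok"
FLAG_BELOW_BACKGROUND = "below_background"
FLAG_NON_POSITIVE_SENSITIVITY = "non_positive_sensitivity"
FLAG_EXTRAPOLATED = "extrapolated_above_standard"


@dataclass(frozen=True)
class ConcentrationEstimate:
    """One estimated concentration with its propagated standard deviation."""

    sample_id: str
    element: str
    channel: str
    dilution_estimate: float
    concentration: float
    sd: float
    m: int = 1
    flag: str = FLAG_OK
    primary: bool = True


def invert_intensity(
    calib: ElementCalibration, intensity: float, m: int = 1
) -> tuple[float, float]:
    """Invert one (possibly replicate-averaged) intensity to (r̂, sd_r).

    ``m`` is the replicate count behind ``intensity``; pooling shrinks only
    the sample-noise term σ̂²/m, not the calibration-parameter terms.  If the
    propagated variance goes negative through sampling noise in cov_bs the
    SD is clipped to zero with a warning.
    """
    if calib.non_positive_sensitivity:
        raise NonPositiveSensitivityError(
            f"channel {calib.channel or '?'} has sensitivity {calib.sensitivity} <= 0"
        )
    if m < 1:
        raise ValueError(f"replicate count m = {m} must be >= 1")
    r = (intensity - calib.background) / calib.sensitivity
    bracket = (
        calib.sigma2 / m
        + calib.var_background
        + r * r * calib.var_sensitivity
        + 2.0 * r * calib.cov_bg_sens
    )
    if bracket < 0:
        warnings.warn(
            f"negative propagated variance ({bracket:.3g}) on channel "
            f"{calib.channel or '?'}; clipping sd to 0",
            stacklevel=2,
        )
        return r, 0.0
    return r, float(np.sqrt(bracket)) / calib.sensitivity


def _estimate(
    calib: ElementCalibration,
    sample_id: str,
    intensity: float,
    m: int,
    primary: bool,
) -> ConcentrationEstimate:
    if calib.non_positive_sensitivity:
        return ConcentrationEstimate(
            sample_id=sample_id, element=calib.element, channel=calib.channel,
            dilution_estimate=float("nan"), concentration=float("nan"),
            sd=float("nan"), m=m, flag=FLAG_NON_POSITIVE_SENSITIVITY, primary=primary,
        )
    r, sd_r = invert_intensity(calib, intensity, m=m)
    conc = r * calib.c0
    if conc < 0:
        flag = FLAG_BELOW_BACKGROUND
    elif r > 1:
        flag = FLAG_EXTRAPOLATED
    else:
        flag = FLAG_OK
    return ConcentrationEstimate(
        sample_id=sample_id, element=calib.element, channel=calib.channel,
        dilution_estimate=float(r), concentration=float(conc),
        sd=float(sd_r * calib.c0), m=m, flag=flag, primary=primary,
    )


def _calib_index(calibs: Iterable[ElementCalibration]) -> dict[str, ElementCalibration]:
    return {c.channel: c for c in calibs}


def quantify_sample(
    calibs: Iterable[ElementCalibration],
    assay: IntensityMatrix,
    design: CalibrationDesign | None = None,
) -> list[ConcentrationEstimate]:
    """Estimate ĉ = r̂·C0 and sd = sd_r·C0 for every (sample, channel).

    Channels with non-positive sensitivity yield NaN estimates flagged
    ``non_positive_sensitivity``.  When a design is given, its
    ``primary_channel`` map marks which isotopic channel reports each
    element; estimates from other channels are retained but marked
    secondary.
    """
    by_channel = _calib_index(calibs)
    missing = [ch for ch in assay.channels if ch not in by_channel]
    if missing:
        raise MissingCalibrationError(f"no calibration for channels {missing}")
    out: list[ConcentrationEstimate] = []
    for i, sid in enumerate(assay.sample_ids):
        for j, ch in enumerate(assay.channels):
            calib = by_channel[ch]
            primary = design.is_primary(ch, calib.element) if design is not None else True
            out.append(_estimate(calib, sid, assay.intensities[i, j], m=1, primary=primary))
    return out


def quantify_mean_intensity(
    calibs: Iterable[ElementCalibration],
    assay: IntensityMatrix,
    sample_ids: Sequence[str] | None = None,
    label: str | None = None,
    design: CalibrationDesign | None = None,
) -> list[ConcentrationEstimate]:
    """Pool samples by averaging intensities first, then invert once.

    Averaging m intensities before inversion equals averaging the m
    per-sample ĉ (the model is linear) but carries the correct, smaller
    σ̂²/m sample-noise term.  This is how run-averaged concentrations are
    computed directly from the survey intensities.
    """
    ids = list(sample_ids) if sample_ids is not None else list(assay.sample_ids)
    if not ids:
        raise ValueError("empty sample subset")
    sub = assay.select_samples(ids)
    m = sub.n_samples
    label = label or f"pooled[{m}]"
    by_channel = _calib_index(calibs)
    missing = [ch for ch in sub.channels if ch not in by_channel]
    if missing:
        raise MissingCalibrationError(f"no calibration for channels {missing}")
    means = sub.intensities.mean(axis=0)
    out = []
    for j, ch in enumerate(sub.channels):
        calib = by_channel[ch]
        primary = design.is_primary(ch, calib.element) if design is not None else True
        out.append(_estimate(calib, label, float(means[j]), m=m, primary=primary))
    return out


def estimates_to_frame(estimates: Iterable[ConcentrationEstimate]) -> pd.DataFrame:
    """Long-format DataFrame view of a set of estimates."""
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id, "element": e.element, "channel": e.channel,
                "dilution_estimate": e.dilution_estimate,
                "concentration": e.concentration, "sd": e.sd,
                "m": e.m, "flag": e.flag, "primary": e.primary,
            }
            for e in estimates
        ]
    )
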