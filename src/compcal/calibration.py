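"""Per-channel linear calibration of intensity against dilution factor.

The calibration model for each mass channel is the straight line

    I = b + s·d + ε,      ε ~ (0, σ²)

with d the dilution factor of the external standard relative to the
undiluted main calibration mixture, b the background intensity (absorbing
blank-borne signal), s the sensitivity and σ the element-specific error SD
of intensity measurements, assumed independent of d.  The error variance is
unknown and estimated alongside the line.  Using the dilution factor — not
the concentration — as the regressor makes the design matrix identical for
every channel, so all channels are fitted in a single vectorized pass.

Closed-form ordinary least squares:

    ŝ   = S_dI / S_dd,          b̂ = Ī − ŝ·d̄
    σ̂²  = RSS / (n − 2)
    var(ŝ) = σ̂²/S_dd
    var(b̂) = σ̂²(1/n + d̄²/S_dd)
    cov(b̂, ŝ) = −σ̂²·d̄/S_dd
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DegenerateDesignError, DesignError, InsufficientPointsError
from .io import (
    ASSAY_ROLE,
    CALIBRATION_ROLE,
    CalibrationDesign,
    IntensityMatrix,
)

__all__ = [
    "ElementCalibration",
    "split_survey",
    "fit_element_calibration",
    "fit_all",
]


@dataclass(frozen=True)
class ElementCalibration:
    """Fitted calibration line for one mass channel.

    Units: ``background`` and ``residual_sd`` in cps, ``sensitivity`` in cps
    per unit dilution factor, ``c0`` in µg/L (concentration of the element in
    the undiluted main calibration mixture).
    """

    background: float
    sensitivity: float
    residual_sd: float
    var_background: float
    var_sensitivity: float
    cov_bg_sens: float
    n_points: int
    channel: str = ""
    element: str = ""
    c0: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise InsufficientPointsError(f"n_points = {self.n_points} < 3")
        if self.residual_sd < 0 or self.var_background < 0 or self.var_sensitivity < 0:
            raise DesignError("negative variance in ElementCalibration")
        bound = np.sqrt(self.var_background * self.var_sensitivity)
        if abs(self.cov_bg_sens) > bound * (1 + 1e-9) + 1e-300:
            raise DesignError("cov_bg_sens violates the Cauchy-Schwarz bound")

    @property
    def sigma2(self) -> float:
        return self.residual_sd ** 2

    @property
    def non_positive_sensitivity(self) -> bool:
        """Channels with ŝ ≤ 0 are kept in the Calibration File but refused
        by inverse prediction."""
        return self.sensitivity <= 0


def split_survey(
    matrix: IntensityMatrix, design: CalibrationDesign
) -> tuple[IntensityMatrix, IntensityMatrix]:
    """Partition a survey into calibration and assay parts.

    Channels whose element is absent from the main mixture carry no
    calibration information and are dropped from both parts.  Every
    calibration-role sample must have a declared dilution factor.
    """
    kept = [ch for ch in matrix.channels if design.element_of(ch) in design.mixture_composition]
    cal_ids = matrix.samples_with_role(CALIBRATION_ROLE)
    assay_ids = matrix.samples_with_role(ASSAY_ROLE)
    missing = [s for s in cal_ids if s not in design.dilution_factors]
    if missing:
        raise DesignError(
            f"calibration samples with no declared dilution factor: {missing}"
        )
    reduced = matrix.select_channels(kept)
    return reduced.select_samples(cal_ids), reduced.select_samples(assay_ids)


def _ols_core(d: np.ndarray, I: np.ndarray):
    """Shared closed-form OLS kernel.

    ``I`` may be 1-D (one channel) or 2-D with shape (n_points, n_channels);
    the exact same numpy reduction sequence runs in both cases, which keeps
    the vectorized multi-channel fit bit-identical to a per-channel loop for
    the small designs (≤ 8 points) used in practice.
    """
    n = d.shape[0]
    dbar = d.mean()
    dc = d - dbar
    sdd = (dc * dc).sum()
    if I.ndim == 1:
        ibar = I.mean()
        sdi = (dc * (I - ibar)).sum()
    else:
        ibar = I.mean(axis=0)
        sdi = (dc[:, None] * (I - ibar)).sum(axis=0)
    s = sdi / sdd
    b = ibar - s * dbar
    resid = I - (b + np.multiply.outer(d, s) if I.ndim == 2 else b + s * d)
    rss = (resid * resid).sum(axis=0)
    sigma2 = rss / (n - 2)
    var_s = sigma2 / sdd
    var_b = sigma2 * (1.0 / n + dbar * dbar / sdd)
    cov_bs = -sigma2 * dbar / sdd
    return b, s, sigma2, var_b, var_s, cov_bs


def fit_element_calibration(d, I) -> ElementCalibration:
    """Fit I = b + s·d + ε for one channel by closed-form OLS.

    Requires at least 3 points (so σ̂² = RSS/(n−2) is defined) and at least
    two distinct dilution factors (so the slope is identifiable); ties in d
    are otherwise allowed.
    """
    d = np.asarray(d, dtype=float)
    I = np.asarray(I, dtype=float)
    if d.shape != I.shape or d.ndim != 1:
        raise DesignError("d and I must be 1-D vectors of equal length")
    n = d.size
    if n < 3:
        raise InsufficientPointsError(f"need at least 3 calibration points, got {n}")
    if np.unique(d).size < 2:
        raise DegenerateDesignError("all dilution factors identical; slope unidentifiable")
    b, s, sigma2, var_b, var_s, cov_bs = _ols_core(d, I)
    return ElementCalibration(
        background=float(b),
        sensitivity=float(s),
        residual_sd=float(np.sqrt(sigma2)),
        var_background=float(var_b),
        var_sensitivity=float(var_s),
        cov_bg_sens=float(cov_bs),
        n_points=int(n),
    )


def fit_all(
    calib: IntensityMatrix,
    design: CalibrationDesign,
    vectorized: bool = True,
) -> list[ElementCalibration]:
    """Fit every retained channel of the calibration part of a survey.

    The vectorized pass fits all channels through one broadcast OLS; the
    per-channel loop exists as a cross-check and produces bit-identical
    numbers on the small dilution designs this method targets.
    """
    if calib.n_samples == 0:
        raise DesignError("no calibration samples in the survey")
    d = np.array([design.dilution_factors[s] for s in calib.sample_ids], dtype=float)
    n = d.size
    if n < 3:
        raise InsufficientPointsError(f"need at least 3 calibration points, got {n}")
    if np.unique(d).size < 2:
        raise DegenerateDesignError("all dilution factors identical; slope unidentifiable")

    def annotate(fit: ElementCalibration, ch: str) -> ElementCalibration:
        el = design.element_of(ch)
        return replace(fit, channel=ch, element=el, c0=design.mixture_composition[el])

    if vectorized:
        b, s, sigma2, var_b, var_s, cov_bs = _ols_core(d, calib.intensities)
        out = []
        for j, ch in enumerate(calib.channels):
            fit = ElementCalibration(
                background=float(b[j]),
                sensitivity=float(s[j]),
                residual_sd=float(np.sqrt(sigma2[j])),
                var_background=float(var_b[j]),
                var_sensitivity=float(var_s[j]),
                cov_bg_sens=float(cov_bs[j]),
                n_points=int(n),
            )
            out.append(annotate(fit, ch))
        return out
    out = []
    for j, ch in enumerate(calib.channels):
        try:
            fit = fit_element_calibration(d, calib.intensities[:, j])
        except DesignError as err:
            raise type(err)(f"channel {ch}: {err}") from err
        out.append(annotate(fit, ch))
    return out
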