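"""Model / Results interface over the compressed-calibration pipeline.

:class:`CompressedCalibration` is built from a survey-intensity matrix and
an external-standard design; :meth:`CompressedCalibration.fit` returns a
:class:`CalibrationResults` carrying the per-channel parameter estimates,
their (co)variances and residual SDs, with ``summary()``, ``conf_int()``,
file export, plotting and inverse prediction (``quantify``) hanging off it.

    >>> model = CompressedCalibration.from_files("survey.csv", "standards.yaml")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> conc = res.quantify()          # long-format concentration table
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import ElementCalibration, fit_all, split_survey
from .exceptions import DesignError
from .io import (
    CalibrationDesign,
    IntensityMatrix,
    RoleRule,
    read_standards_config,
    read_survey_intensities,
    write_calibration_file,
    write_concentrations_file,
)
from .quantification import (
    estimates_to_frame,
    quantify_mean_intensity,
    quantify_sample,
)

__all__ = ["CompressedCalibration", "CalibrationResults"]

_UNIT_SCALE = {"ug/L": 1.0, "ppb": 1.0, "mg/L": 1e-3, "ppm": 1e-3}


class CompressedCalibration:
    """Linear calibration model for one survey run.

    Splits the survey into its calibration and assay parts at construction
    (dropping channels whose element is absent from the standard mixture)
    and fits I = b + s·d + ε per retained channel on ``fit()``.
    """

    def __init__(self, survey: IntensityMatrix, design: CalibrationDesign):
        self.survey = survey
        self.design = design
        self.calibration_part, self.assay_part = split_survey(survey, design)
        if self.calibration_part.n_samples == 0:
            raise DesignError("survey contains no calibration-role samples")

    @classmethod
    def from_files(
        cls,
        survey_path: str | Path,
        standards_path: str | Path,
        role_rule: RoleRule | str | Sequence[str] = "cal*",
    ) -> "CompressedCalibration":
        survey = read_survey_intensities(survey_path, role_rule=role_rule)
        design = read_standards_config(standards_path)
        return cls(survey, design)

    @property
    def dilution_factors(self) -> np.ndarray:
        return np.array(
            [self.design.dilution_factors[s] for s in self.calibration_part.sample_ids]
        )

    def fit(self, vectorized: bool = True) -> "CalibrationResults":
        calibs = fit_all(self.calibration_part, self.design, vectorized=vectorized)
        return CalibrationResults(self, calibs)


class CalibrationResults:
    """Fitted per-channel calibrations plus inverse prediction."""

    def __init__(self, model: CompressedCalibration | None, calibrations: list[ElementCalibration]):
        self.model = model
        self.calibrations = list(calibrations)
        self._by_channel = {c.channel: c for c in self.calibrations}

    def __getitem__(self, channel: str) -> ElementCalibration:
        return self._by_channel[channel]

    @property
    def design(self) -> CalibrationDesign | None:
        return self.model.design if self.model is not None else None

    @property
    def params(self) -> pd.DataFrame:
        """One row per channel: estimates, (co)variances, n and C0."""
        return pd.DataFrame(
            [
                {
                    "channel": c.channel, "element": c.element, "C0": c.c0,
                    "background": c.background, "sensitivity": c.sensitivity,
                    "residual_sd": c.residual_sd,
                    "var_background": c.var_background,
                    "var_sensitivity": c.var_sensitivity,
                    "cov_bg_sens": c.cov_bg_sens, "n_points": c.n_points,
                }
                for c in self.calibrations
            ]
        ).set_index("channel")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """t-based confidence intervals for background and sensitivity.

        Uses the Student-t quantile on n − 2 degrees of freedom — with the
        short dilution series typical of this method the error variance is
        estimated on very few df, and normal quantiles would undercover.
        """
        rows = []
        for c in self.calibrations:
            q = stats.t.ppf(1 - alpha / 2, c.n_points - 2)
            se_b, se_s = np.sqrt(c.var_background), np.sqrt(c.var_sensitivity)
            rows.append({
                "channel": c.channel,
                "background_lo": c.background - q * se_b,
                "background_hi": c.background + q * se_b,
                "sensitivity_lo": c.sensitivity - q * se_s,
                "sensitivity_hi": c.sensitivity + q * se_s,
            })
        return pd.DataFrame(rows).set_index("channel")

    def summary(self) -> str:
        """Human-readable fit report, one line per channel."""
        lines = [
            "Compressed calibration fit",
            "==========================",
        ]
        if self.model is not None:
            d = np.asarray(sorted(set(self.model.dilution_factors), reverse=True))
            lines += [
                f"calibration samples : {self.model.calibration_part.n_samples}",
                f"dilution levels     : {', '.join(f'{x:g}' for x in d)}",
                f"assay samples       : {self.model.assay_part.n_samples}",
                f"channels retained   : {len(self.calibrations)}",
            ]
        lines.append("")
        lines.append(
            f"{'channel':>8} {'elem':>4} {'C0 ug/L':>9} {'bg cps':>11} {'(se)':>9} "
            f"{'sens cps/d':>12} {'(se)':>10} {'resid sd':>10}"
        )
        for c in self.calibrations:
            note = "  [s<=0]" if c.non_positive_sensitivity else ""
            lines.append(
                f"{c.channel:>8} {c.element:>4} {c.c0:>9.4g} {c.background:>11.5g} "
                f"{np.sqrt(c.var_background):>9.3g} {c.sensitivity:>12.6g} "
                f"{np.sqrt(c.var_sensitivity):>10.3g} {c.residual_sd:>10.4g}{note}"
            )
        return "\n".join(lines)

    # -- inverse prediction ------------------------------------------------

    def quantify(
        self,
        assay: IntensityMatrix | None = None,
        unit: str = "ug/L",
    ) -> pd.DataFrame:
        """Concentrations (long format) for the assay samples.

        Defaults to the assay part of the survey the model was built from;
        ``unit`` rescales the output (µg/L a.k.a. ppb, or mg/L a.k.a. ppm).
        """
        if assay is None:
            if self.model is None:
                raise ValueError("no assay data: pass an IntensityMatrix")
            assay = self.model.assay_part
        estimates = quantify_sample(self.calibrations, assay, design=self.design)
        return self._scaled(estimates_to_frame(estimates), unit)

    def quantify_mean(
        self,
        sample_ids: Sequence[str] | None = None,
        label: str | None = None,
        unit: str = "ug/L",
        assay: IntensityMatrix | None = None,
    ) -> pd.DataFrame:
        """Pooled (intensity-averaged) concentrations for a sample subset."""
        if assay is None:
            if self.model is None:
                raise ValueError("no assay data: pass an IntensityMatrix")
            assay = self.model.assay_part
        estimates = quantify_mean_intensity(
            self.calibrations, assay, sample_ids=sample_ids, label=label, design=self.design
        )
        return self._scaled(estimates_to_frame(estimates), unit)

    @staticmethod
    def _scaled(df: pd.DataFrame, unit: str) -> pd.DataFrame:
        try:
            scale = _UNIT_SCALE[unit]
        except KeyError:
            raise ValueError(f"unknown unit {unit!r}; choose from {sorted(_UNIT_SCALE)}") from None
        if scale != 1.0:
            df = df.assign(concentration=df["concentration"] * scale, sd=df["sd"] * scale)
        return df

    # -- persistence and plotting -----------------------------------------

    def save(self, path: str | Path) -> None:
        """Export the Calibration File (CSV, one row per channel)."""
        write_calibration_file(self.calibrations, path)

    @classmethod
    def from_file(cls, path: str | Path) -> "CalibrationResults":
        """Rebuild results from a Calibration File (no survey attached)."""
        from .io import read_calibration_file

        return cls(None, read_calibration_file(path))

    def save_concentrations(self, path: str | Path, assay: IntensityMatrix | None = None) -> None:
        """Quantify and export the Concentrations File."""
        if assay is None:
            if self.model is None:
                raise ValueError("no assay data: pass an IntensityMatrix")
            assay = self.model.assay_part
        estimates = quantify_sample(self.calibrations, assay, design=self.design)
        write_concentrations_file(estimates, path)

    def plot_channel(self, channel: str, ax=None):
        """Calibration points and fitted line for one channel."""
        import matplotlib.pyplot as plt

        if self.model is None:
            raise ValueError("plotting needs the survey the model was fitted on")
        calib = self._by_channel[channel]
        j = self.model.calibration_part.channels.index(channel)
        d = self.model.dilution_factors
        I = self.model.calibration_part.intensities[:, j]
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(d, I, label="standards", zorder=3)
        grid = np.linspace(0, max(1.0, d.max()), 50)
        ax.plot(grid, calib.background + calib.sensitivity * grid,
                label=f"fit: b={calib.background:.3g}, s={calib.sensitivity:.3g}")
        ax.set_xlabel("dilution factor d")
        ax.set_ylabel("intensity (cps)")
        ax.set_title(f"{channel} ({calib.element})")
        ax.legend()
        return ax
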