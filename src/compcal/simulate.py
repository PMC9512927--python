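"""Synthetic survey-scan datasets with known ground truth.

The generator emulates the structure of a column bioleaching study measured
by ICP-MS survey scans: one run per culture medium, biostimulation (BS) and
bioaugmentation (BA) treatments, effluent and pore-water sample types, five
sampling days each, plus a calibration dilution series of the main external
standard mixture at {1, 0.5, 0.1, 0.01, 0}.

Per channel the signal model is

    I(sample) = b* + s*·r(sample) + ε,   ε ~ Normal(0, σ*²) i.i.d.

with r equal to the dilution factor for calibration samples and to the
element's true dilution-equivalent for assay samples; σ* depends on the
element but not on the dilution factor.  Negative draws are floored at 0
(counts are physical) and the flooring events are counted, since flooring
biases blank channels.  One master seed derives per-channel substreams, so
adding a channel never perturbs the draws of existing channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import default_channel
from .io import (
    ASSAY_ROLE,
    CALIBRATION_ROLE,
    CalibrationDesign,
    IntensityMatrix,
    write_standards_config,
    write_survey_intensities,
)

__all__ = ["GroundTruth", "ELEMENT_POOL", "simulate_design", "simulate_survey", "write_dataset"]

#: Elements offered by the generator, panel-style: the nine interfering
#: components retained in the study first (Mg, Si, Al, K, Mn, Fe, Cu, Zn,
#: Se), then trace/critical metals and other common ICP-MS analytes.
ELEMENT_POOL = [
    "Mg", "Si", "Al", "K", "Mn", "Fe", "Cu", "Zn", "Se",
    "Li", "Co", "Cd", "Na", "Ca", "Ti", "V", "Cr", "Ni", "Ga", "Ge",
    "As", "Rb", "Sr", "Y", "Zr", "Nb", "Mo", "Ag", "Sn", "Sb",
    "Cs", "Ba", "La", "Ce", "Pr", "Nd", "W", "Pb", "Bi", "U",
    "Be", "B", "Sc", "Hf", "Ta", "Re", "Pt", "Au", "Tl", "Th",
]

DEFAULT_DILUTION_LEVELS = (1.0, 0.5, 0.1, 0.01, 0.0)
EFFLUENT_DAYS = (2, 9, 12, 16, 19)
PORE_DAYS = (3, 5, 8, 10, 17)


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline on a synthetic run."""

    design: CalibrationDesign
    channel_truth: pd.DataFrame  # index channel: element, background, sensitivity, sigma, c0
    assay_dilution: pd.DataFrame  # assay sample_id × element -> true r*
    layout: pd.DataFrame  # sample_id, role, medium, treatment, water_type, time
    medium: str = "R2Ab"

    def true_concentration(self, sample_id: str, element: str) -> float:
        c0 = self.design.mixture_composition[element]
        return float(self.assay_dilution.at[sample_id, element] * c0)

    @property
    def concentration_truth(self) -> pd.DataFrame:
        c0 = pd.Series(self.design.mixture_composition)
        return self.assay_dilution * c0[self.assay_dilution.columns]


def simulate_design(
    n_elements: int = 9,
    dilution_levels: tuple = DEFAULT_DILUTION_LEVELS,
    seed: int = 0,
    medium: str = "R2Ab",
    noise_cv: float | tuple[float, float] | None = (0.003, 0.015),
) -> tuple[CalibrationDesign, GroundTruth]:
    """Draw a calibration design plus ground truth for one medium run.

    The panel always contains one element leached beyond the main standard
    (true r* > 1, to exercise the extrapolation flag) and, for panels of two
    or more, one with true concentration exactly zero (to exercise the
    significance screen).  ``noise_cv`` is the per-element error SD as a
    fraction of the sensitivity: a (lo, hi) range sampled log-uniformly, a
    single number, or 0/None for noiseless data.
    """
    if n_elements < 1:
        raise ValueError(f"n_elements = {n_elements} must be >= 1")
    if n_elements > len(ELEMENT_POOL):
        raise ValueError(f"at most {len(ELEMENT_POOL)} elements available")
    levels = tuple(float(x) for x in dilution_levels)
    if len(set(levels)) < 3:
        raise ValueError(f"need at least 3 distinct dilution levels, got {levels}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    elements = ELEMENT_POOL[:n_elements]
    channels = [default_channel(el) for el in elements]

    # True instrument response: sensitivity spans decades across elements,
    # backgrounds are a few % to ~30% of the top-standard signal and the
    # error SD is sub-2% of the sensitivity, as in survey-mode counting.
    s_true = 10 ** rng.uniform(3.0, 5.5, n_elements)
    b_true = s_true * 10 ** rng.uniform(np.log10(0.05), np.log10(0.3), n_elements)
    if noise_cv is None:
        cv = np.zeros(n_elements)
    elif np.isscalar(noise_cv):
        cv = np.full(n_elements, float(noise_cv))
    else:
        lo, hi = noise_cv
        cv = 10 ** rng.uniform(np.log10(lo), np.log10(hi), n_elements)
    sigma_true = cv * s_true
    c0 = 10 ** rng.uniform(1.0, 3.0, n_elements)  # 10..1000 ug/L

    cal_ids = [f"cal_{i + 1}" for i in range(len(levels))]
    design = CalibrationDesign(
        mixture_composition=dict(zip(elements, map(float, c0))),
        dilution_factors=dict(zip(cal_ids, levels)),
        channel_map=dict(zip(channels, elements)),
        primary_channel=dict(zip(elements, channels)),
    )

    # Assay layout: BS/BA x effluent/pore x 5 sampling days.
    rows = []
    for treatment in ("BS", "BA"):
        for water, days in (("effluent", EFFLUENT_DAYS), ("pore", PORE_DAYS)):
            for t in days:
                rows.append({
                    "sample_id": f"{medium}_{treatment}_{water}_d{t:02d}",
                    "role": ASSAY_ROLE, "medium": medium,
                    "treatment": treatment, "water_type": water, "time": t,
                })
    assay_layout = pd.DataFrame(rows)
    cal_layout = pd.DataFrame({
        "sample_id": cal_ids, "role": CALIBRATION_ROLE, "medium": medium,
        "treatment": "", "water_type": "", "time": np.nan,
    })
    layout = pd.concat([cal_layout, assay_layout], ignore_index=True)

    # True dilution-equivalents: a smooth exponential time trend per
    # (element, treatment, water type) around an element-level amplitude.
    high_element = elements[2] if n_elements >= 3 else elements[0]
    zero_element = elements[-1] if n_elements >= 2 else None
    amp = 10 ** rng.uniform(np.log10(0.05), np.log10(0.6), n_elements)
    r = np.empty((len(assay_layout), n_elements))
    for j, el in enumerate(elements):
        base = 1.5 if el == high_element else amp[j]
        for cond, grp in assay_layout.groupby(["treatment", "water_type"], sort=True):
            growth = rng.uniform(-0.8, 0.8)
            scale = rng.uniform(0.6, 1.4)
            t = grp["time"].to_numpy(dtype=float)
            r[grp.index, j] = base * scale * np.exp(growth * (t / 20.0 - 0.5))
        if el == zero_element:
            r[:, j] = 0.0
    assay_dilution = pd.DataFrame(
        r, index=pd.Index(assay_layout["sample_id"], name="sample_id"), columns=elements
    )

    channel_truth = pd.DataFrame(
        {
            "element": elements, "background": b_true, "sensitivity": s_true,
            "sigma": sigma_true, "c0": c0,
        },
        index=pd.Index(channels, name="channel"),
    )
    truth = GroundTruth(
        design=design, channel_truth=channel_truth,
        assay_dilution=assay_dilution, layout=layout, medium=medium,
    )
    return design, truth


def simulate_survey(truth: GroundTruth, seed: int = 0) -> IntensityMatrix:
    """Draw one Survey Intensities matrix from a ground truth.

    Bit-reproducible for a fixed seed.  The returned matrix carries the
    number of zero-floored draws as ``matrix.n_floored``.
    """
    layout = truth.layout
    sample_ids = list(layout["sample_id"])
    roles = list(layout["role"])
    channels = list(truth.channel_truth.index)
    elements = list(truth.channel_truth["element"])

    # r per (sample, element): design dilution factors for calibration rows.
    r = np.empty((len(sample_ids), len(channels)))
    for i, (sid, role) in enumerate(zip(sample_ids, roles)):
        if role == CALIBRATION_ROLE:
            r[i, :] = truth.design.dilution_factors[sid]
        else:
            r[i, :] = truth.assay_dilution.loc[sid, elements].to_numpy(dtype=float)

    children = np.random.SeedSequence(seed).spawn(len(channels))
    I = np.empty_like(r)
    n_floored = 0
    for j, ch in enumerate(channels):
        row = truth.channel_truth.loc[ch]
        rng = np.random.default_rng(children[j])
        noise = rng.normal(0.0, row["sigma"], len(sample_ids)) if row["sigma"] > 0 else 0.0
        col = row["background"] + row["sensitivity"] * r[:, j] + noise
        n_floored += int(np.count_nonzero(col < 0))
        I[:, j] = np.maximum(col, 0.0)

    meta = layout.set_index("sample_id")[["medium", "treatment", "water_type", "time"]]
    matrix = IntensityMatrix(sample_ids, roles, channels, I, sample_meta=meta)
    matrix.n_floored = n_floored
    return matrix


def write_dataset(truth: GroundTruth, matrix: IntensityMatrix, outdir) -> dict:
    """Write survey CSV + standards YAML + truth/metadata CSVs into a directory."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "survey": outdir / "survey_intensities.csv",
        "standards": outdir / "standards.yaml",
        "truth": outdir / "truth_concentrations.csv",
        "meta": outdir / "sample_metadata.csv",
    }
    write_survey_intensities(matrix, paths["survey"])
    write_standards_config(truth.design, paths["standards"])
    truth.concentration_truth.to_csv(paths["truth"])
    truth.layout.to_csv(paths["meta"], index=False)
    return paths
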