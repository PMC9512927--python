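"""Screening of survey-scan estimates and cross-method validation.

Three steps: (1) quantify everything present in the external standards of
each run; (2) cross-check the two runs' element panels and drop elements not
present in both; (3) drop elements whose estimated SD is in the range of the
estimated concentration (they are detected but not quantifiable — typically
trace analytes sitting near the blank).  Surviving elements that were also
measured by the precise peak-hopping procedure are compared through

    z = (ĉ_CC − c_PH) / sd_CC

and accepted when |z| ≤ k (k = 3 by default, the usual three-standard-
deviation criterion).  Only the compressed-calibration SD enters z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .quantification import (
    FLAG_NON_POSITIVE_SENSITIVITY,
    ConcentrationEstimate,
    estimates_to_frame,
)

__all__ = [
    "ScreeningReport",
    "cross_check_elements",
    "significance_filter",
    "compare_methods",
    "screen",
]

DECISION_KEPT = "kept"
DECISION_NOT_COMMON = "excluded_not_common"
DECISION_INSIGNIFICANT = "excluded_insignificant"

_SUMMARIZERS: dict[str, Callable[[np.ndarray], float]] = {
    "median": lambda x: float(np.median(x)),
    "mean": lambda x: float(np.mean(x)),
}


def cross_check_elements(panel_a: Iterable[str], panel_b: Iterable[str]) -> set[str]:
    """Elements present in the external standards of both runs."""
    return set(panel_a) & set(panel_b)


def _frame(estimates) -> pd.DataFrame:
    if isinstance(estimates, pd.DataFrame):
        return estimates
    return estimates_to_frame(estimates)


def significance_filter(
    estimates: Iterable[ConcentrationEstimate] | pd.DataFrame,
    rho: float = 1.0,
    summarizer: str = "median",
) -> dict[str, str]:
    """Per-element keep/exclude decision for one run.

    Summarizes ĉ and sd over the run's samples (median by default) and
    excludes the element when sd ≥ ρ·|ĉ| or ĉ ≤ 0: its estimated SD is in
    the range of its estimated concentration.  Only primary-channel
    estimates enter; channels refused for non-positive sensitivity count as
    unquantifiable.
    """
    if rho <= 0:
        raise ValueError(f"rho = {rho} must be > 0")
    summarize = _SUMMARIZERS[summarizer]
    df = _frame(estimates)
    df = df[df["primary"]]
    decisions: dict[str, str] = {}
    for element, grp in df.groupby("element", sort=False):
        usable = grp[grp["flag"] != FLAG_NON_POSITIVE_SENSITIVITY]
        if usable.empty or usable["concentration"].isna().all():
            decisions[element] = DECISION_INSIGNIFICANT
            continue
        c = summarize(usable["concentration"].to_numpy())
        sd = summarize(usable["sd"].to_numpy())
        if c <= 0 or sd >= rho * abs(c):
            decisions[element] = DECISION_INSIGNIFICANT
        else:
            decisions[element] = DECISION_KEPT
    return decisions


def compare_methods(
    cc: Iterable[ConcentrationEstimate] | pd.DataFrame,
    ph: pd.DataFrame,
    k: float = 3.0,
) -> pd.DataFrame:
    """Cross-method z-scores against peak-hopping concentrations.

    ``ph`` is a long-format table (sample_id, element, concentration).
    Returns one row per matching (sample, element) with the z-score and the
    |z| ≤ k verdict; a zero sd with unequal concentrations reports an
    infinite z and fails.
    """
    if k <= 0:
        raise ValueError(f"k = {k} must be > 0")
    cc_df = _frame(cc)
    cc_df = cc_df[cc_df["primary"]][["sample_id", "element", "concentration", "sd"]]
    merged = cc_df.merge(
        ph[["sample_id", "element", "concentration"]],
        on=["sample_id", "element"],
        suffixes=("_cc", "_ph"),
    )
    diff = (merged["concentration_cc"] - merged["concentration_ph"]).to_numpy()
    sd = merged["sd"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / sd
    signed_inf = np.where(diff > 0, np.inf, -np.inf)
    z = np.where(sd == 0, np.where(diff == 0, 0.0, signed_inf), z)
    merged["z"] = z
    merged["passed"] = np.abs(z) <= k
    return merged


@dataclass
class ScreeningReport:
    """Outcome of the screening pipeline over two runs."""

    common_elements: set[str]
    decisions: dict[str, str]
    z_scores: pd.DataFrame | None = None
    k: float = 3.0
    rho: float = 1.0

    @property
    def kept(self) -> set[str]:
        return {el for el, d in self.decisions.items() if d == DECISION_KEPT}

    @property
    def pass_3sd(self) -> pd.Series | None:
        if self.z_scores is None:
            return None
        return self.z_scores.set_index(["sample_id", "element"])["passed"]

    def summary(self) -> str:
        lines = ["Screening report", "================",
                 f"common elements : {', '.join(sorted(self.common_elements)) or '(none)'}"]
        for decision in (DECISION_KEPT, DECISION_NOT_COMMON, DECISION_INSIGNIFICANT):
            els = sorted(el for el, d in self.decisions.items() if d == decision)
            lines.append(f"{decision:<24}: {', '.join(els) or '(none)'}")
        if self.z_scores is not None and not self.z_scores.empty:
            lines.append(f"cross-method check at |z| <= {self.k:g}:")
            per_el = self.z_scores.groupby("element")["z"].agg(lambda s: np.max(np.abs(s)))
            for el, zmax in per_el.items():
                n_fail = int((~self.z_scores[self.z_scores["element"] == el]["passed"]).sum())
                lines.append(f"  {el:<3} max|z| = {zmax:8.3f}  failures: {n_fail}")
        return "\n".join(lines)

    def to_csv(self, decisions_path, z_path=None) -> None:
        pd.DataFrame(
            sorted(self.decisions.items()), columns=["element", "decision"]
        ).to_csv(decisions_path, index=False)
        if z_path is not None and self.z_scores is not None:
            self.z_scores.to_csv(z_path, index=False)


def screen(
    run_a: Iterable[ConcentrationEstimate] | pd.DataFrame,
    run_b: Iterable[ConcentrationEstimate] | pd.DataFrame | None = None,
    ph: pd.DataFrame | None = None,
    rho: float = 1.0,
    k: float = 3.0,
    summarizer: str = "median",
) -> ScreeningReport:
    """Run the full screening pipeline.

    With a single run the cross-check step is a no-op (the panel is compared
    with itself).  An element is kept only if it is common to both runs and
    significant in each.
    """
    df_a = _frame(run_a)
    df_b = _frame(run_b) if run_b is not None else None
    panel_a = set(df_a["element"])
    panel_b = set(df_b["element"]) if df_b is not None else panel_a
    common = cross_check_elements(panel_a, panel_b)
    decisions: dict[str, str] = {
        el: DECISION_NOT_COMMON for el in (panel_a | panel_b) - common
    }
    sig_a = significance_filter(df_a[df_a["element"].isin(common)], rho=rho, summarizer=summarizer)
    sig_b = (
        significance_filter(df_b[df_b["element"].isin(common)], rho=rho, summarizer=summarizer)
        if df_b is not None
        else sig_a
    )
    for el in common:
        if sig_a.get(el) == DECISION_KEPT and sig_b.get(el) == DECISION_KEPT:
            decisions[el] = DECISION_KEPT
        else:
            decisions[el] = DECISION_INSIGNIFICANT
    z = None
    if ph is not None:
        kept = {el for el, d in decisions.items() if d == DECISION_KEPT}
        z = compare_methods(df_a[df_a["element"].isin(kept)], ph, k=k)
    return ScreeningReport(
        common_elements=common, decisions=decisions, z_scores=z, k=k, rho=rho
    )
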