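"""File formats: Survey Intensities, standards config, Calibration and Concentrations Files.

All tabular files are UTF-8 CSV with a mandatory header row, comma separator
and ``.`` decimal.  Floats are written in shortest round-trip representation,
so write → read is lossless (bit-exact for finite doubles).  The standards
configuration is YAML because it nests the mixture composition, the dilution
series and the channel maps.
"""

from __future__ import annotations

import csv
import fnmatch
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .channels import channel_element, parse_channel
from .exceptions import ConfigError, DesignError, FormatError

CALIBRATION_ROLE = "calibration"
ASSAY_ROLE = "assay"

#: Column order of the Calibration File.
CALIBRATION_COLUMNS = [
    "channel", "element", "background", "sensitivity", "residual_sd",
    "var_background", "var_sensitivity", "cov_bg_sens", "n_points", "C0",
]

#: Column order of the Concentrations File (long format).
CONCENTRATION_COLUMNS = [
    "sample_id", "element", "channel", "dilution_estimate",
    "concentration", "sd", "m", "flag", "primary",
]


@dataclass
class IntensityMatrix:
    """Samples × mass-channel intensities from one survey scan.

    ``intensities[i, j]`` is the counts-per-second reading of sample
    ``sample_ids[i]`` on channel ``channels[j]``.  Each sample carries a role
    (``calibration`` or ``assay``) and, optionally, metadata tags (medium,
    treatment, water type, timestamp index).
    """

    sample_ids: list[str]
    sample_roles: list[str]
    channels: list[str]
    intensities: np.ndarray
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.channels)) != len(self.channels):
            raise FormatError("duplicate mass channels")
        if self.intensities.shape != (len(self.sample_ids), len(self.channels)):
            raise FormatError(
                f"intensity block shape {self.intensities.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.channels)} channels"
            )
        if len(self.sample_roles) != len(self.sample_ids):
            raise FormatError("every sample needs a role")
        bad = set(self.sample_roles) - {CALIBRATION_ROLE, ASSAY_ROLE}
        if bad:
            raise FormatError(f"unknown sample roles: {sorted(bad)}")
        for j, ch in enumerate(self.channels):
            parse_channel(ch)
            col = self.intensities[:, j]
            if not np.all(np.isfinite(col)):
                i = int(np.flatnonzero(~np.isfinite(col))[0])
                raise FormatError(f"non-finite intensity at ({self.sample_ids[i]}, {ch})")
            if np.any(col < 0):
                i = int(np.flatnonzero(col < 0)[0])
                raise FormatError(f"negative intensity at ({self.sample_ids[i]}, {ch})")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.channels)

    def select_samples(self, ids: Sequence[str]) -> "IntensityMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[list(ids)]
        return IntensityMatrix(
            sample_ids=list(ids),
            sample_roles=[self.sample_roles[i] for i in idx],
            channels=list(self.channels),
            intensities=self.intensities[idx, :],
            sample_meta=meta,
        )

    def select_channels(self, channels: Sequence[str]) -> "IntensityMatrix":
        pos = {c: j for j, c in enumerate(self.channels)}
        idx = [pos[c] for c in channels]
        return IntensityMatrix(
            sample_ids=list(self.sample_ids),
            sample_roles=list(self.sample_roles),
            channels=list(channels),
            intensities=self.intensities[:, idx],
            sample_meta=self.sample_meta,
        )

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s, r in zip(self.sample_ids, self.sample_roles) if r == role]


@dataclass
class CalibrationDesign:
    """External-standard specification.

    ``mixture_composition`` gives C0, the concentration (µg/L) of each
    element in the undiluted main calibration standard mixture;
    ``dilution_factors`` gives each calibration sample's dilution factor d
    with respect to that mixture (d = 1 undiluted, d = 0 blank).
    ``channel_map`` may leave channels out, in which case the element is
    parsed from the channel label itself.
    """

    mixture_composition: dict[str, float]
    dilution_factors: dict[str, float]
    channel_map: dict[str, str] = field(default_factory=dict)
    primary_channel: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, c0 in self.mixture_composition.items():
            if not (c0 > 0):
                raise ConfigError(f"C0({el}) = {c0} must be > 0")
        dvals = list(self.dilution_factors.values())
        for sid, d in self.dilution_factors.items():
            if not (0.0 <= d <= 1.0):
                raise DesignError(f"dilution factor of {sid!r} is {d}, outside [0, 1]")
        if len(set(dvals)) < 3:
            raise DesignError(
                f"need at least 3 distinct dilution factors, got {sorted(set(dvals))}"
            )
        for el, ch in self.primary_channel.items():
            if el not in self.mixture_composition:
                raise ConfigError(
                    f"primary channel {ch!r} refers to element {el!r} absent from the mixture"
                )
            parse_channel(ch)
        for ch in self.channel_map:
            parse_channel(ch)

    def element_of(self, channel: str) -> str:
        """Element a channel quantifies: explicit map first, else the label."""
        return self.channel_map.get(channel) or channel_element(channel)

    def is_primary(self, channel: str, element: str | None = None) -> bool:
        el = element or self.element_of(channel)
        designated = self.primary_channel.get(el)
        return designated is None or designated == channel

    @property
    def elements(self) -> set[str]:
        return set(self.mixture_composition)


@dataclass
class RoleRule:
    """Machine-decidable sample → role assignment.

    Samples whose id matches any glob in ``calibration_globs`` are
    calibration samples; everything else is an assay sample.  ``overrides``
    wins over the globs for specific ids.
    """

    calibration_globs: tuple[str, ...] = ("cal*",)
    overrides: dict[str, str] = field(default_factory=dict)

    def role(self, sample_id: str) -> str:
        if sample_id in self.overrides:
            return self.overrides[sample_id]
        for pat in self.calibration_globs:
            if fnmatch.fnmatchcase(sample_id, pat):
                return CALIBRATION_ROLE
        return ASSAY_ROLE


def _as_role_rule(role_rule: RoleRule | str | Sequence[str]) -> RoleRule:
    if isinstance(role_rule, RoleRule):
        return role_rule
    if isinstance(role_rule, str):
        return RoleRule(calibration_globs=(role_rule,))
    return RoleRule(calibration_globs=tuple(role_rule))


def read_survey_intensities(
    path: str | Path,
    role_rule: RoleRule | str | Sequence[str] = "cal*",
    sample_meta: pd.DataFrame | None = None,
) -> IntensityMatrix:
    """Read a Survey Intensities CSV (first column sample id, header = channels).

    Order of samples and channels in the file is preserved.  Duplicate sample
    ids or channels raise :class:`FormatError`; a negative or non-numeric
    intensity raises :class:`FormatError` naming the offending cell.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    channels = [c.strip() for c in header[1:]]
    if len(set(channels)) != len(channels):
        dup = sorted({c for c in channels if channels.count(c) > 1})
        raise FormatError(f"duplicate mass channels in {path}: {dup}")
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    df.columns = channels
    ids = [str(s) for s in df.index]
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise FormatError(f"duplicate sample ids in {path}: {dup}")
    values = np.empty(df.shape, dtype=float)
    for i, sid in enumerate(ids):
        for j, ch in enumerate(channels):
            cell = df.iat[i, j]
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(f"non-numeric intensity {cell!r} at ({sid}, {ch}) in {path}") from None
            if not math.isfinite(v) or v < 0:
                raise FormatError(f"invalid intensity {v} at ({sid}, {ch}) in {path}")
            values[i, j] = v
    rule = _as_role_rule(role_rule)
    roles = [rule.role(s) for s in ids]
    return IntensityMatrix(ids, roles, channels, values, sample_meta=sample_meta)


def _float_repr(x: float) -> str:
    # shortest representation that round-trips a float64 exactly
    return repr(float(x))


def write_survey_intensities(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write a Survey Intensities CSV in the canonical wide layout."""
    matrix.to_frame().to_csv(Path(path), float_format=_float_repr)


def read_standards_config(path: str | Path) -> CalibrationDesign:
    """Read the standards YAML into a :class:`CalibrationDesign`.

    The ``mixture`` section accepts either a direct ``c0`` (µg/L) or the
    preparation pair ``stock`` (µg/L) and ``dilution`` (volume fraction of
    stock in the mixture), in which case C0 = stock × dilution.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise FormatError(f"standards config {path} is not a mapping")
    for key in ("mixture", "dilution_series"):
        if key not in cfg:
            raise FormatError(f"standards config {path} is missing the {key!r} section")
    mixture: dict[str, float] = {}
    for el, entry in cfg["mixture"].items():
        if isinstance(entry, Mapping):
            if "c0" in entry:
                c0 = float(entry["c0"])
            elif "stock" in entry and "dilution" in entry:
                c0 = float(entry["stock"]) * float(entry["dilution"])
            else:
                raise ConfigError(
                    f"mixture entry for {el!r} needs either 'c0' or 'stock' + 'dilution'"
                )
        else:
            c0 = float(entry)
        mixture[str(el)] = c0
    series = {str(k): float(v) for k, v in cfg["dilution_series"].items()}
    channel_map = {str(k): str(v) for k, v in (cfg.get("channel_map") or {}).items()}
    primary = {str(k): str(v) for k, v in (cfg.get("primary_channels") or {}).items()}
    return CalibrationDesign(
        mixture_composition=mixture,
        dilution_factors=series,
        channel_map=channel_map,
        primary_channel=primary,
    )


def write_standards_config(design: CalibrationDesign, path: str | Path) -> None:
    """Write a :class:`CalibrationDesign` back to the standards YAML layout."""
    cfg = {
        "mixture": {el: float(c0) for el, c0 in design.mixture_composition.items()},
        "dilution_series": {sid: float(d) for sid, d in design.dilution_factors.items()},
        "channel_map": dict(design.channel_map),
        "primary_channels": dict(design.primary_channel),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_calibration_file(calibs: Iterable, path: str | Path) -> None:
    """Export fitted calibrations (Calibration File, one row per channel)."""
    rows = [
        {
            "channel": c.channel, "element": c.element,
            "background": c.background, "sensitivity": c.sensitivity,
            "residual_sd": c.residual_sd, "var_background": c.var_background,
            "var_sensitivity": c.var_sensitivity, "cov_bg_sens": c.cov_bg_sens,
            "n_points": c.n_points, "C0": c.c0,
        }
        for c in calibs
    ]
    if not rows:
        raise FormatError("refusing to write an empty Calibration File")
    pd.DataFrame(rows, columns=CALIBRATION_COLUMNS).to_csv(
        Path(path), index=False, float_format=_float_repr
    )


def read_calibration_file(path: str | Path) -> list:
    """Read a Calibration File back into :class:`~compcal.calibration.ElementCalibration`s."""
    from .calibration import ElementCalibration

    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"Calibration File {path} is missing columns {missing}")
    return [
        ElementCalibration(
            channel=str(r.channel), element=str(r.element),
            background=float(r.background), sensitivity=float(r.sensitivity),
            residual_sd=float(r.residual_sd), var_background=float(r.var_background),
            var_sensitivity=float(r.var_sensitivity), cov_bg_sens=float(r.cov_bg_sens),
            n_points=int(r.n_points), c0=float(r.C0),
        )
        for r in df.itertuples(index=False)
    ]


def write_concentrations_file(estimates: Iterable, path: str | Path) -> None:
    """Export concentration estimates (Concentrations File, long format)."""
    rows = [
        {
            "sample_id": e.sample_id, "element": e.element, "channel": e.channel,
            "dilution_estimate": e.dilution_estimate, "concentration": e.concentration,
            "sd": e.sd, "m": e.m, "flag": e.flag, "primary": e.primary,
        }
        for e in estimates
    ]
    pd.DataFrame(rows, columns=CONCENTRATION_COLUMNS).to_csv(
        Path(path), index=False, float_format=_float_repr
    )


def read_concentrations_file(path: str | Path) -> pd.DataFrame:
    """Read a Concentrations File into a long-format DataFrame."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in CONCENTRATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"Concentrations File {path} is missing columns {missing}")
    return df
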