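"""Sample schema, CSV I/O, validation, and derived columns.

One row of the canonical table is a paired topsoil / wheat-grain observation:
total soil Cd and grain Cd (mg/kg dry wt), pH, organic matter (%), CaCO3
(g/kg), the clay/silt/sand texture split (%), totals for Ca/Fe/Mn/P (g/kg)
and Zn (mg/kg), and optionally the five Tessier Cd fractions (mg/kg):
exchangeable (ex_cd), carbonate-bound (ca_cd), Fe-Mn-oxide-bound (fm_cd),
organically bound (or_cd), and residual (re_cd).

Units are fixed as above; there is no automatic unit conversion.  Logarithms
are base 10 throughout the package (the convention under which published
transfer-model coefficients for this system are quoted).
"""

from __future__ import annotations

import json
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    MissingColumnError,
    SchemaError,
    UndefinedRatioError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Columns every dataset must carry.
MANDATORY_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "soil_cd",
    "grain_cd",
    "ph",
    "om",
    "caco3",
    "clay",
    "silt",
    "sand",
    "ca",
    "fe",
    "mn",
    "p",
    "zn",
)

#: Tessier sequential-extraction fractions; optional, but all-or-none.
FRACTION_COLUMNS: tuple[str, ...] = ("ex_cd", "ca_cd", "fm_cd", "or_cd", "re_cd")

ALL_COLUMNS: tuple[str, ...] = MANDATORY_COLUMNS + FRACTION_COLUMNS

#: Header aliases accepted on read (applied after lower-casing and stripping).
_ALIASES: dict[str, str] = {
    "id": "sample_id",
    "sample": "sample_id",
    "soil cd": "soil_cd",
    "total cd": "soil_cd",
    "cd_total": "soil_cd",
    "grain cd": "grain_cd",
    "wheat cd": "grain_cd",
    "cd_grain": "grain_cd",
    "caco_3": "caco3",
    "organic matter": "om",
    "soil ca": "ca",
    "soil fe": "fe",
    "soil mn": "mn",
    "soil p": "p",
    "soil zn": "zn",
    "ex-cd": "ex_cd",
    "ca-cd": "ca_cd",
    "fm-cd": "fm_cd",
    "carb-cd": "ca_cd",
    "fe/mn-cd": "fm_cd",
    "or-cd": "or_cd",
    "orga-cd": "or_cd",
    "re-cd": "re_cd",
    "resi-cd": "re_cd",
}

#: Default tolerance (percentage points) on clay + silt + sand = 100.
TEXTURE_TOLERANCE = 0.5
#: Relative tolerance on the Tessier fraction sum against total soil Cd;
#: mirrors a sequential-extraction recovery of 95 +/- 5 %.
RECOVERY_TOLERANCE = 0.10


def _canonical_name(raw: str) -> str:
    name = raw.strip().lower().replace("−", "-")
    name = _ALIASES.get(name, name)
    return name.replace("-", "_").replace(" ", "_")


@dataclass
class Dataset:
    """An ordered collection of paired soil-wheat samples.

    Thin wrapper around a :class:`pandas.DataFrame` in canonical column
    order, with free-text provenance (source file or generator config) and
    any per-row validation warnings collected in lenient mode.
    """

    frame: pd.DataFrame
    provenance: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frame) < 1:
            raise ValidationError("dataset must contain at least one record")
        ids = self.frame["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate sample_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def has_fractions(self) -> bool:
        return all(c in self.frame.columns for c in FRACTION_COLUMNS)


def _validate_row(row: Mapping[str, float], texture_tolerance: float) -> list[str]:
    problems: list[str] = []
    sid = row.get("sample_id", "?")
    for col in ("soil_cd", "grain_cd", "om", "caco3", "clay", "silt", "sand",
                "ca", "fe", "mn", "p", "zn"):
        v = row.get(col)
        if v is not None and not pd.isna(v) and v < 0:
            problems.append(f"sample {sid}: {col} negative ({v})")
    ph = row.get("ph")
    if ph is not None and not pd.isna(ph) and not (0 < ph < 14):
        problems.append(f"sample {sid}: ph outside (0, 14) ({ph})")
    texture = [row.get(c) for c in ("clay", "silt", "sand")]
    if all(v is not None and not pd.isna(v) for v in texture):
        total = float(sum(texture))
        if abs(total - 100.0) > texture_tolerance:
            problems.append(
                f"sample {sid}: clay+silt+sand = {total:.3f}, "
                f"outside 100 +/- {texture_tolerance}"
            )
    fracs = [row.get(c) for c in FRACTION_COLUMNS]
    if all(v is not None and not pd.isna(v) for v in fracs):
        soil_cd = row.get("soil_cd")
        if soil_cd is not None and not pd.isna(soil_cd) and soil_cd > 0:
            recovery = float(sum(fracs)) / float(soil_cd)
            if abs(recovery - 1.0) > RECOVERY_TOLERANCE:
                problems.append(
                    f"sample {sid}: fraction sum / soil_cd = {recovery:.3f}, "
                    f"outside 1 +/- {RECOVERY_TOLERANCE}"
                )
    return problems


def validate_frame(
    frame: pd.DataFrame,
    *,
    strict: bool = True,
    texture_tolerance: float = TEXTURE_TOLERANCE,
) -> list[str]:
    """Run per-row physical/bookkeeping checks; raise or return warnings."""
    problems: list[str] = []
    for row in frame.to_dict("records"):
        problems.extend(_validate_row(row, texture_tolerance))
    if problems and strict:
        raise ValidationError("; ".join(problems))
    return problems


def read_dataset(
    path: str | Path,
    schema_mode: str = "strict",
    *,
    texture_tolerance: float = TEXTURE_TOLERANCE,
) -> Dataset:
    """Read a canonical CSV into a validated :class:`Dataset`.

    Header matching is case-insensitive and accepts common aliases
    (``Ex-Cd`` for ``ex_cd``, ``Soil Cd`` for ``soil_cd``, ...).  In
    ``strict`` mode any non-numeric cell or invariant violation raises; in
    ``lenient`` mode violations are collected as warnings on the returned
    dataset.
    """
    if schema_mode not in ("strict", "lenient"):
        raise ValueError(f"schema_mode must be strict|lenient, got {schema_mode!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str)
    raw.columns = [_canonical_name(c) for c in raw.columns]

    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing} in {path}")
    present_fracs = [c for c in FRACTION_COLUMNS if c in raw.columns]
    if present_fracs and len(present_fracs) != len(FRACTION_COLUMNS):
        raise SchemaError(
            "Tessier fractions must be present as a group; found only "
            f"{present_fracs}"
        )

    keep = [c for c in ALL_COLUMNS if c in raw.columns]
    frame = raw[keep].copy()
    warnings: list[str] = []
    for col in keep:
        if col == "sample_id":
            continue
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            rows = (frame.index[bad] + 2).tolist()  # 1-based + header line
            msg = f"non-numeric value(s) in column {col!r} at file row(s) {rows}"
            if schema_mode == "strict":
                raise SchemaError(msg)
            warnings.append(msg)
        frame[col] = converted
    frame["sample_id"] = frame["sample_id"].astype(str)

    warnings.extend(
        validate_frame(
            frame, strict=(schema_mode == "strict"),
            texture_tolerance=texture_tolerance,
        )
    )
    for w in warnings:
        logger.warning("%s: %s", path.name, w)
    return Dataset(frame=frame, provenance=str(path), warnings=warnings)


def write_dataset(dataset: Dataset, path: str | Path) -> Path:
    """Write a dataset to CSV with full double precision (round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in ALL_COLUMNS if c in dataset.frame.columns]
    dataset.frame[cols].to_csv(path, index=False, float_format="%.17g")
    return path


def compute_bcf(grain_cd, soil_cd):
    """Bioconcentration factor: grain Cd / soil Cd (both mg/kg dry wt).

    Accepts scalars or aligned array-likes.  Scale-invariant by
    construction; a zero soil concentration is an error, not infinity.
    """
    soil = np.asarray(soil_cd, dtype=float)
    if np.any(soil <= 0):
        raise UndefinedRatioError(
            "soil_cd must be > 0 to form a bioconcentration factor"
        )
    out = np.asarray(grain_cd, dtype=float) / soil
    if out.ndim == 0:
        return float(out)
    return out


def log_transform(values, base: float = 10.0, *, labels: Iterable | None = None):
    """Base-10 logarithm (the package-wide convention) of positive values.

    ``labels`` (e.g. sample ids) are used to name offenders in the error
    message when a value is not strictly positive.
    """
    arr = np.asarray(values, dtype=float)
    bad = ~(arr > 0)
    if np.any(bad):
        if labels is not None:
            names = [str(l) for l, b in zip(labels, np.atleast_1d(bad)) if b]
            raise ValueError(f"log of non-positive value for sample(s): {names}")
        raise ValueError("log of non-positive value")
    out = np.log(arr) / math.log(base)
    if out.ndim == 0:
        return float(out)
    return out


def add_derived_columns(dataset: Dataset) -> Dataset:
    """Attach bcf, log_bcf and log_om columns, returning a new Dataset."""
    frame = dataset.frame.copy()
    frame["bcf"] = compute_bcf(frame["grain_cd"].to_numpy(),
                               frame["soil_cd"].to_numpy())
    frame["log_bcf"] = log_transform(frame["bcf"].to_numpy(),
                                     labels=frame["sample_id"])
    frame["log_om"] = log_transform(frame["om"].to_numpy(),
                                    labels=frame["sample_id"])
    return Dataset(frame=frame, provenance=dataset.provenance,
                   warnings=list(dataset.warnings))


def complete_cases(frame: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    """Rows complete in ``columns``; drops (with a logged count) the rest."""
    columns = list(columns)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise MissingColumnError(f"column(s) not in dataset: {missing}")
    mask = frame[columns].notna().all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("dropped %d incomplete row(s) for columns %s", dropped, columns)
    return frame.loc[mask]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write one CSV per named table plus a JSON manifest; return the manifest.

    Column order is taken as-is from each table (callers build tables in
    deterministic order), so reruns with identical inputs produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not tables:
        logger.warning("write_results called with an empty table set")
    manifest: dict = {
        "tables": {},
        "config": dict(config) if config else {},
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False, float_format="%.12g")
        manifest["tables"][name] = {"file": fname, "rows": int(len(table))}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
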