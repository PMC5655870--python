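"""Domain model and tabular I/O for fibroblast bioenergetic cohorts.

A cohort is a set of fibroblast cell lines (the unit of analysis), each
carrying a diagnostic group label and clinical covariates, together with
raw well-level plate-assay records from three assay families:

* extracellular flux time-courses (OCR/ECAR per well over the four
  mito-stress-test injection phases),
* TMRM / MitoTracker Green fluorescence wells with FCCP-depolarized
  background wells,
* luciferase ATP luminescence wells under baseline / 2-deoxyglucose /
  oligomycin conditions, plus an ATP standard curve.

All tables are long-format CSV with a header row, UTF-8, '.' decimal
separator; one record kind per file. Missing clinical values are empty
fields on disk and NaN in memory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "DISEASE_GROUPS",
    "FEATURES",
    "FLUX_PHASES",
    "ATP_CONDITIONS",
    "DYES",
    "SEXES",
    "ONSET_SITES",
    "MEDIA",
    "SchemaError",
    "CohortValidationError",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "validate_profiles",
    "assemble_feature_matrix",
]

GROUPS = ("control", "sALS", "PLS", "C9orf72")
DISEASE_GROUPS = ("sALS", "PLS", "C9orf72")

#: Canonical feature-matrix column order for the 12 bioenergetic features.
FEATURES = (
    "tmrm",
    "mtg",
    "ecar_base",
    "ecar_aarot",
    "ocr_base",
    "ocr_oligo_sens",
    "ocr_spare",
    "ocr_max",
    "ocr_ecar_ratio",
    "atp_base",
    "atp_2dg_delta",
    "atp_oligo_delta",
)

#: Injection order of the mito stress test.
FLUX_PHASES = ("baseline", "oligomycin", "FCCP", "AA_Rot")
ATP_CONDITIONS = ("baseline", "dg2", "oligo")
DYES = ("TMRM", "MTG")
SEXES = ("F", "M", "unknown")
ONSET_SITES = ("spinal", "bulbar", "NA")
MEDIA = ("glucose", "galactose")

#: Features that must be non-negative in a valid profile.
NONNEGATIVE_FEATURES = (
    "tmrm", "mtg", "ocr_base", "ocr_max", "ecar_base", "ecar_aarot", "atp_base",
)


class SchemaError(ValueError):
    """A CSV table is missing a required column."""


class CohortValidationError(ValueError):
    """A record violates a cohort invariant (bad enum, duplicate id, ...)."""


# ---------------------------------------------------------------------------
# table schemas: column name -> dtype kind ("str", "float", "int", "bool")
# ---------------------------------------------------------------------------

LINES_SCHEMA = {
    "line_id": "str",
    "group": "str",
    "sex": "str",
    "age_onset": "float",
    "age_biopsy": "float",
    "alsfrs": "float",
    "progression_rate": "float",
    "fvc_pct": "float",
    "bmi": "float",
    "onset_site": "str",
    "passage": "float",  # integer-valued; float to admit missing
}

FLUX_SCHEMA = {
    "line_id": "str",
    "plate_id": "str",
    "well_id": "str",
    "medium": "str",
    "phase": "str",
    "cycle": "int",
    "ocr_raw": "float",
    "ecar_raw": "float",
    "protein": "float",
}

FLUOR_SCHEMA = {
    "line_id": "str",
    "well_id": "str",
    "dye": "str",
    "fccp_treated": "bool",
    "rfu": "float",
    "protein": "float",
}

ATP_SCHEMA = {
    "line_id": "str",
    "well_id": "str",
    "condition": "str",
    "luminescence": "float",
    "protein": "float",
}

ATP_STANDARD_SCHEMA = {
    "atp_amount": "float",
    "luminescence": "float",
}

PROFILE_COLUMNS = ("line_id",) + FEATURES

_TABLE_SCHEMAS = {
    "lines": LINES_SCHEMA,
    "flux": FLUX_SCHEMA,
    "fluorescence": FLUOR_SCHEMA,
    "atp": ATP_SCHEMA,
    "atp_standard": ATP_STANDARD_SCHEMA,
}

_TABLE_FILENAMES = {
    "lines": "lines.csv",
    "flux": "flux_wells.csv",
    "fluorescence": "fluorescence_wells.csv",
    "atp": "atp_wells.csv",
    "atp_standard": "atp_standard.csv",
}


def _check_schema(df: pd.DataFrame, schema: Mapping[str, str], name: str) -> pd.DataFrame:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"table '{name}' is missing column(s): {', '.join(missing)}")
    out = df.copy()
    for col, kind in schema.items():
        if kind == "float":
            out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
        elif kind == "int":
            out[col] = pd.to_numeric(out[col], errors="raise").astype(int)
        elif kind == "bool":
            out[col] = out[col].map(
                {True: True, False: False, "True": True, "False": False,
                 "true": True, "false": False, 1: True, 0: False, "1": True, "0": False}
            )
            if out[col].isna().any():
                raise CohortValidationError(f"table '{name}': non-boolean value in column '{col}'")
            out[col] = out[col].astype(bool)
        else:
            out[col] = out[col].astype("string").astype(object)
    return out


def _check_enum(df: pd.DataFrame, col: str, allowed: Iterable[str], name: str,
                allow_missing: bool = False) -> None:
    values = df[col]
    if allow_missing:
        values = values.dropna()
    bad = set(values) - set(allowed)
    if bad:
        raise CohortValidationError(
            f"table '{name}', column '{col}': unknown value(s) {sorted(map(str, bad))!r}; "
            f"allowed: {tuple(allowed)}"
        )


@dataclass
class Cohort:
    """Validated in-memory cohort: cell-line metadata plus raw well tables."""

    lines: pd.DataFrame
    flux: pd.DataFrame = field(default_factory=lambda: _empty(FLUX_SCHEMA))
    fluorescence: pd.DataFrame = field(default_factory=lambda: _empty(FLUOR_SCHEMA))
    atp: pd.DataFrame = field(default_factory=lambda: _empty(ATP_SCHEMA))
    atp_standard: pd.DataFrame = field(default_factory=lambda: _empty(ATP_STANDARD_SCHEMA))

    def validate(self) -> "Cohort":
        self.lines = _check_schema(self.lines, LINES_SCHEMA, "lines")
        self.flux = _check_schema(self.flux, FLUX_SCHEMA, "flux")
        self.fluorescence = _check_schema(self.fluorescence, FLUOR_SCHEMA, "fluorescence")
        self.atp = _check_schema(self.atp, ATP_SCHEMA, "atp")
        self.atp_standard = _check_schema(self.atp_standard, ATP_STANDARD_SCHEMA, "atp_standard")

        _check_enum(self.lines, "group", GROUPS, "lines")
        _check_enum(self.lines, "sex", SEXES, "lines", allow_missing=True)
        _check_enum(self.lines, "onset_site", ONSET_SITES, "lines", allow_missing=True)
        dup = self.lines["line_id"][self.lines["line_id"].duplicated()]
        if len(dup):
            raise CohortValidationError(f"duplicate line_id(s): {sorted(set(dup))!r}")
        passages = self.lines["passage"].dropna()
        if len(passages) and not ((passages >= 5) & (passages <= 10)).all():
            bad = sorted(passages[(passages < 5) | (passages > 10)].unique())
            raise CohortValidationError(f"passage outside [5, 10]: {bad!r}")

        _check_enum(self.flux, "phase", FLUX_PHASES, "flux")
        _check_enum(self.flux, "medium", MEDIA, "flux")
        if not np.isfinite(self.flux["ocr_raw"]).all():
            raise CohortValidationError("flux: non-finite ocr_raw value")
        _check_enum(self.fluorescence, "dye", DYES, "fluorescence")
        if (self.fluorescence["rfu"] < 0).any():
            raise CohortValidationError("fluorescence: negative rfu")
        _check_enum(self.atp, "condition", ATP_CONDITIONS, "atp")
        if (self.atp["luminescence"] < 0).any():
            raise CohortValidationError("atp: negative luminescence")

        if len(self.atp_standard):
            std = self.atp_standard.sort_values("atp_amount")
            if len(std) < 2:
                raise CohortValidationError("atp_standard needs >= 2 points")
            if not (np.diff(std["luminescence"].to_numpy()) > 0).all():
                raise CohortValidationError("atp_standard luminescence not strictly increasing")

        known = set(self.lines["line_id"])
        for name, table in (("flux", self.flux), ("fluorescence", self.fluorescence),
                            ("atp", self.atp)):
            orphan = set(table["line_id"]) - known
            if orphan:
                raise CohortValidationError(
                    f"table '{name}' references unknown line_id(s): {sorted(orphan)[:5]!r}"
                )
        return self


def _empty(schema: Mapping[str, str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object if k == "str" else k)
                         for c, k in schema.items()})


def read_cohort(paths: Mapping[str, str | os.PathLike] | str | os.PathLike) -> Cohort:
    """Read and validate a cohort from CSV files.

    ``paths`` is either a directory containing the canonically named files
    (``lines.csv``, ``flux_wells.csv``, ``fluorescence_wells.csv``,
    ``atp_wells.csv``, ``atp_standard.csv``) or a mapping from table kind
    (``lines``/``flux``/``fluorescence``/``atp``/``atp_standard``) to file
    path. Only ``lines`` is mandatory.
    """
    if isinstance(paths, (str, os.PathLike)):
        root = Path(paths)
        paths = {kind: root / fname for kind, fname in _TABLE_FILENAMES.items()
                 if (root / fname).exists()}
    if "lines" not in paths:
        raise SchemaError("cohort requires a 'lines' table")
    tables = {}
    for kind, path in paths.items():
        if kind not in _TABLE_SCHEMAS:
            raise SchemaError(f"unknown table kind '{kind}'")
        # only empty fields are missing; the literal token "NA" is a valid
        # onset_site level and must survive the round trip
        tables[kind] = pd.read_csv(path, dtype={"line_id": str, "well_id": str,
                                                "plate_id": str},
                                   keep_default_na=False, na_values=[""])
    return Cohort(**tables).validate()


def write_cohort(cohort: Cohort, directory: str | os.PathLike) -> dict[str, Path]:
    """Write all cohort tables as CSV under ``directory``; returns the paths."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    written = {}
    for kind, fname in _TABLE_FILENAMES.items():
        table: pd.DataFrame = getattr(cohort, {"lines": "lines", "flux": "flux",
                                               "fluorescence": "fluorescence",
                                               "atp": "atp",
                                               "atp_standard": "atp_standard"}[kind])
        path = root / fname
        table.to_csv(path, index=False)
        written[kind] = path
    return written


def validate_profiles(profiles: pd.DataFrame, rtol: float = 1e-9) -> pd.DataFrame:
    """Assert the internal-consistency invariants of a profile table.

    Checks the derived identities ocr_spare = ocr_max - ocr_base and
    ocr_ecar_ratio = ocr_base / ecar_base (where ecar_base > 0), and
    non-negativity of the physically non-negative features.
    """
    missing = [c for c in PROFILE_COLUMNS if c not in profiles.columns]
    if missing:
        raise SchemaError(f"profile table missing column(s): {', '.join(missing)}")
    scale = np.maximum(np.abs(profiles["ocr_max"]), np.abs(profiles["ocr_base"])) + 1e-300
    bad = np.abs(profiles["ocr_spare"] - (profiles["ocr_max"] - profiles["ocr_base"])) > rtol * scale
    if bad.any():
        raise CohortValidationError(
            f"ocr_spare != ocr_max - ocr_base for line(s) {list(profiles.loc[bad, 'line_id'][:5])!r}"
        )
    pos = profiles["ecar_base"] > 0
    expected = profiles.loc[pos, "ocr_base"] / profiles.loc[pos, "ecar_base"]
    bad = np.abs(profiles.loc[pos, "ocr_ecar_ratio"] - expected) > rtol * np.abs(expected)
    if bad.any():
        raise CohortValidationError("ocr_ecar_ratio != ocr_base / ecar_base")
    for feat in NONNEGATIVE_FEATURES:
        if (profiles[feat].dropna() < 0).any():
            raise CohortValidationError(f"negative value in non-negative feature '{feat}'")
    return profiles


def assemble_feature_matrix(
    profiles: pd.DataFrame,
    lines: pd.DataFrame | None = None,
    exclude: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build the n_lines x 12 feature matrix and the group-label vector.

    Rows are sorted by ``line_id`` so the result is invariant to the input
    order. Profiles with any missing feature raise unless their line_id is
    listed in ``exclude`` (a mapping line_id -> reason; excluded rows are
    dropped). Returns ``(X, y)`` where ``X`` is indexed by line_id with
    columns in the canonical :data:`FEATURES` order and ``y`` holds group
    labels (aligned; requires ``lines`` or a ``group`` column in
    ``profiles``).
    """
    exclude = dict(exclude or {})
    df = profiles.copy()
    df = df[~df["line_id"].isin(exclude)]
    incomplete = df[list(FEATURES)].isna().any(axis=1)
    if incomplete.any():
        bad = list(df.loc[incomplete, "line_id"][:5])
        raise CohortValidationError(
            f"profile(s) with missing features and no exclusion flag: {bad!r}"
        )
    df = df.sort_values("line_id", kind="mergesort").set_index("line_id")
    X = df[list(FEATURES)].astype(float)
    if "group" in df.columns:
        y = df["group"]
    elif lines is not None:
        y = lines.set_index("line_id")["group"].reindex(X.index)
    else:
        raise CohortValidationError("group labels require 'lines' or a 'group' column")
    if y.isna().any():
        raise CohortValidationError("profiles reference line_ids with no group label")
    return X, y.rename("group")
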