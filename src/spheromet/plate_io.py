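"""Plate-level input/output: filename metadata parsing, CellProfiler CSV
ingest, and plate-layout spreadsheet export.

Well metadata (cell line, compound, concentration, replicate) is encoded in
image file names and recovered with a regular expression with named groups.
Concentrations are normalised to nanomolar; ``0`` marks the zero-dose
(control) wells.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns that identify a well rather than measure it.
META_COLUMNS = ["cell_line", "compound", "concentration_nM", "replicate", "well_id"]

#: Default filename pattern: ``<line>_<compound>_<conc><unit>_r<rep>.<ext>``
DEFAULT_FILENAME_PATTERN = (
    r"(?P<cell_line>[^_]+)_(?P<compound>[^_]+)_"
    r"(?P<conc>[\d.]+)(?P<unit>nM|uM|µM)_r(?P<rep>\d+)"
)

#: Conversion factors to nM.
_UNIT_TO_NM = {"nM": 1.0, "uM": 1000.0, "µM": 1000.0}

#: The six shape descriptors used downstream, in CellProfiler column dialect.
DEFAULT_FEATURE_WHITELIST = [
    "AreaShape_Area",
    "AreaShape_Perimeter",
    "AreaShape_FormFactor",
    "AreaShape_Compactness",
    "AreaShape_Solidity",
    "AreaShape_MedianRadius",
]


class FilenameParseError(ValueError):
    """A file name did not match the metadata pattern."""


class PatternError(ValueError):
    """The supplied pattern is unusable (missing or duplicated groups)."""


@dataclass(frozen=True)
class WellMetadata:
    """Identity of one well: who, what, how much, which replicate."""

    cell_line: str
    compound: str
    concentration_nM: float
    replicate: int
    well_id: str | None = None

    def __post_init__(self) -> None:
        if self.concentration_nM < 0:
            raise ValueError("concentration must be >= 0 nM")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")

    @property
    def is_control(self) -> bool:
        return self.concentration_nM == 0


@dataclass
class FeatureTable:
    """Per-well morphometric features joined to well metadata.

    ``data`` holds one row per well with the metadata columns from
    :data:`META_COLUMNS` (``well_id`` optional) followed by numeric feature
    columns.  Keys ``(cell_line, compound, concentration_nM, replicate)``
    must be unique and all feature values finite and strictly positive.
    """

    data: pd.DataFrame
    provenance: str = "native"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["cell_line", "compound", "concentration_nM", "replicate"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"FeatureTable missing metadata columns: {missing}")
        if self.data.duplicated(subset=required).any():
            raise ValueError("duplicate (cell_line, compound, concentration, replicate) keys")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    @property
    def meta(self) -> pd.DataFrame:
        cols = [c for c in META_COLUMNS if c in self.data.columns]
        return self.data[cols]

    def validate_values(self) -> None:
        feats = self.features.to_numpy(dtype=float)
        if not np.isfinite(feats).all():
            raise ValueError("non-finite feature values present")
        if (feats <= 0).any():
            raise ValueError("non-positive feature values present")


def _check_pattern(pattern: str) -> re.Pattern:
    try:
        rx = re.compile(pattern)
    except re.error as exc:  # pragma: no cover - message pass-through
        raise PatternError(f"invalid regular expression: {exc}") from exc
    needed = {"cell_line", "compound", "conc", "rep"}
    have = set(rx.groupindex)
    missing = needed - have
    if missing:
        raise PatternError(f"pattern lacks named groups: {sorted(missing)}")
    return rx


def parse_filename(name: str, pattern: str = DEFAULT_FILENAME_PATTERN) -> WellMetadata:
    """Extract well metadata from an image file name.

    The pattern must define named groups ``cell_line``, ``compound``,
    ``conc`` and ``rep``; an optional ``unit`` group (nM/uM/µM) converts the
    concentration to nM (default nM).
    """
    rx = _check_pattern(pattern)
    m = rx.search(Path(name).name)
    if m is None:
        raise FilenameParseError(f"file name {name!r} does not match metadata pattern")
    g = m.groupdict()
    unit = g.get("unit") or "nM"
    try:
        factor = _UNIT_TO_NM[unit]
    except KeyError:
        raise FilenameParseError(f"unknown concentration unit {unit!r} in {name!r}")
    conc = float(g["conc"]) * factor
    return WellMetadata(
        cell_line=g["cell_line"],
        compound=g["compound"],
        concentration_nM=conc,
        replicate=int(g["rep"]),
        well_id=g.get("well_id"),
    )


def read_cellprofiler_csv(
    path,
    feature_whitelist: list[str] | None = None,
    pattern: str = DEFAULT_FILENAME_PATTERN,
    filename_column: str | None = None,
) -> FeatureTable:
    """Read a CellProfiler object-export CSV into a :class:`FeatureTable`.

    Metadata linkage is via either explicit ``Metadata_CellLine`` /
    ``Metadata_Compound`` / ``Metadata_Concentration_nM`` /
    ``Metadata_Replicate`` columns or a file-name column (any column starting
    with ``FileName_``, or ``filename_column``) parsed with ``pattern``.
    When several objects share an image, the largest-area object is kept.
    Rows with missing or non-positive whitelisted features are dropped (count
    logged).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty table")
    whitelist = list(feature_whitelist) if feature_whitelist is not None else None
    if whitelist is None:
        whitelist = [c for c in DEFAULT_FEATURE_WHITELIST if c in df.columns]
        whitelist += sorted(c for c in df.columns if c.startswith("Granularity_"))
    missing = [c for c in whitelist if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns {missing}")
    if not whitelist:
        raise ValueError(f"{path}: no usable feature columns")

    meta_cols = {
        "Metadata_CellLine": "cell_line",
        "Metadata_Compound": "compound",
        "Metadata_Concentration_nM": "concentration_nM",
        "Metadata_Replicate": "replicate",
    }
    if set(meta_cols).issubset(df.columns):
        meta = df[list(meta_cols)].rename(columns=meta_cols)
    else:
        fn_col = filename_column
        if fn_col is None:
            candidates = [c for c in df.columns if c.startswith("FileName_")]
            fn_col = candidates[0] if candidates else None
        if fn_col is None or fn_col not in df.columns:
            raise ValueError(
                f"{path}: no metadata linkage (need Metadata_* columns or a FileName_* column)"
            )
        parsed = [parse_filename(str(n), pattern) for n in df[fn_col]]
        meta = pd.DataFrame(
            {
                "cell_line": [p.cell_line for p in parsed],
                "compound": [p.compound for p in parsed],
                "concentration_nM": [p.concentration_nM for p in parsed],
                "replicate": [p.replicate for p in parsed],
            }
        )

    out = pd.concat([meta.reset_index(drop=True), df[whitelist].reset_index(drop=True)], axis=1)
    out["concentration_nM"] = out["concentration_nM"].astype(float)
    out["replicate"] = out["replicate"].astype(int)

    # Multiple objects per image: keep the largest-area object per well.
    key = ["cell_line", "compound", "concentration_nM", "replicate"]
    if out.duplicated(subset=key).any():
        area_col = "AreaShape_Area" if "AreaShape_Area" in out.columns else whitelist[0]
        out = (
            out.sort_values(area_col, ascending=False, kind="stable")
            .drop_duplicates(subset=key, keep="first")
            .sort_index()
        )

    n_before = len(out)
    vals = out[whitelist].apply(pd.to_numeric, errors="coerce")
    ok = vals.notna().all(axis=1) & (vals > 0).all(axis=1)
    out = out.loc[ok].reset_index(drop=True)
    out[whitelist] = out[whitelist].astype(float)
    dropped = n_before - len(out)
    if dropped:
        logger.info("read_cellprofiler_csv: dropped %d rows with missing/non-positive features", dropped)
    if out.empty:
        raise ValueError(f"{path}: no rows with valid feature values")
    ft = FeatureTable(out, provenance="CellProfiler import")
    ft.validate_values()
    return ft


_ROW_LETTERS = string.ascii_uppercase


def assign_well_ids(table: FeatureTable, n_rows: int = 8, n_cols: int = 12) -> FeatureTable:
    """Derive plate coordinates from (compound, concentration, replicate).

    Each compound occupies a block of ``n_replicates`` consecutive rows;
    within a block the replicate selects the row and the concentration rank
    (ascending) selects the column.
    """
    df = table.data.copy()
    if "well_id" in df.columns and df["well_id"].notna().all():
        return table
    compounds = list(dict.fromkeys(df["compound"]))
    reps = sorted(df["replicate"].unique())
    concs = sorted(df["concentration_nM"].unique())
    if len(concs) > n_cols:
        raise ValueError(f"{len(concs)} concentrations exceed {n_cols} plate columns")
    if len(compounds) * len(reps) > n_rows:
        raise ValueError("compound blocks exceed plate rows")
    rep_ix = {r: i for i, r in enumerate(reps)}
    conc_ix = {c: i for i, c in enumerate(concs)}
    ids = []
    for _, row in df.iterrows():
        r = compounds.index(row["compound"]) * len(reps) + rep_ix[row["replicate"]]
        c = conc_ix[row["concentration_nM"]]
        ids.append(f"{_ROW_LETTERS[r]}{c + 1:02d}")
    df["well_id"] = ids
    return FeatureTable(df, provenance=table.provenance, extra=table.extra)


def write_plate_layout(table: FeatureTable, path, n_rows: int = 8, n_cols: int = 12) -> None:
    """Write an XLSX workbook with one sheet per feature laid out as a plate.

    Each sheet is an ``n_rows`` x ``n_cols`` grid (rows A.. / columns 1..);
    wells absent from the table stay blank.  Duplicate well assignment is an
    error.
    """
    table = assign_well_ids(table, n_rows=n_rows, n_cols=n_cols)
    df = table.data
    if df["well_id"].duplicated().any():
        dupes = df.loc[df["well_id"].duplicated(), "well_id"].tolist()
        raise ValueError(f"duplicate well assignment: {dupes}")
    index = list(_ROW_LETTERS[:n_rows])
    cols = list(range(1, n_cols + 1))
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for feat in table.feature_columns:
            grid = pd.DataFrame(np.nan, index=index, columns=cols)
            for _, row in df.iterrows():
                wid = row["well_id"]
                grid.loc[wid[0], int(wid[1:])] = row[feat]
            # Sheet names cap at 31 chars in xlsx.
            grid.to_excel(xl, sheet_name=feat[:31])


def read_plate_layout(path) -> dict[str, pd.DataFrame]:
    """Read back a plate-layout workbook as {feature: grid} (round-trip aid)."""
    sheets = pd.read_excel(path, sheet_name=None, index_col=0)
    return {name: g for name, g in sheets.items()}
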