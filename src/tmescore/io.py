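"""Delimited-text readers and writers for cell tables and patient tables.

Cell tables are the exchange format exported by digital-pathology tools: one
row per cell with coordinates in μm, an exclusive phenotype label, marker
flags and the owning core; a companion geometry table gives each core's disc
center and radius.  All files are tab-separated with a mandatory header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .spatial import PHENOTYPES, REGIONS, CellRecord, CorePattern, PatternError

CELL_COLUMNS = ("core_id", "tumor_id", "region", "marker_panel",
                "x_um", "y_um", "phenotype", "pd1", "pdl1")
GEOMETRY_COLUMNS = ("core_id", "center_x_um", "center_y_um", "radius_um")
MARKER_PANELS = ("CD3", "CD8", "multiplex")

PATIENT_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("<60", "60-80", ">80"),
    "sex": ("male", "female"),
    "cci_group": ("1-2", "3-4", ">=5"),
    "location": ("right", "left"),
    "t_stage": ("1", "2", "3", "4"),
    "n_stage": ("0", "1", "2"),
    "m_stage": ("0", "1"),
    "tnm_stage": ("I", "II", "III", "IV"),
    "lvi": ("no", "yes"),
    "budding_group": ("0-4", "5-9", ">=10"),
    "grade": ("low", "high"),
    "braf": ("no", "yes"),
    "necrosis_group": ("<10%", "10-<40%", ">=40%"),
    "stroma_group": ("<50%", ">=50%"),
    "lynch": ("no", "yes"),
    "adjuvant": ("no", "yes"),
    "metastatic": ("no", "yes"),
}


class TableValidationError(ValueError):
    """A delimited input file violates the schema."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing columns {missing}")


def write_cell_table(
    patterns: Iterable[CorePattern], cells_path, geometry_path, sep: str = "\t"
) -> None:
    cell_rows, geom_rows = [], []
    for p in patterns:
        geom_rows.append(
            dict(core_id=p.core_id, center_x_um=p.center[0],
                 center_y_um=p.center[1], radius_um=p.radius)
        )
        for c in p.cells:
            cell_rows.append(
                dict(core_id=p.core_id, tumor_id=p.tumor_id or "",
                     region=p.region or c.region, marker_panel=p.marker_panel or "",
                     x_um=c.x, y_um=c.y, phenotype=c.phenotype,
                     pd1=int(c.pd1_positive), pdl1=int(c.pdl1_positive))
            )
    pd.DataFrame(cell_rows, columns=list(CELL_COLUMNS)).to_csv(
        cells_path, sep=sep, index=False
    )
    pd.DataFrame(geom_rows, columns=list(GEOMETRY_COLUMNS)).to_csv(
        geometry_path, sep=sep, index=False
    )


def read_cell_table(
    cells_path, geometry_path, sep: str = "\t"
) -> dict[str, list[CorePattern]]:
    """Read and validate a cell table + geometry table.

    Returns patterns grouped by tumor_id.  Unknown phenotypes, unknown region
    labels and cells outside their core disc raise with the offending row.
    """
    cells = pd.read_csv(cells_path, sep=sep, dtype={"core_id": str, "tumor_id": str},
                        float_precision="round_trip")
    geom = pd.read_csv(geometry_path, sep=sep, dtype={"core_id": str},
                       float_precision="round_trip")
    _require_columns(cells, CELL_COLUMNS, cells_path)
    _require_columns(geom, GEOMETRY_COLUMNS, geometry_path)
    if geom["core_id"].duplicated().any():
        dups = geom.loc[geom["core_id"].duplicated(), "core_id"].tolist()
        raise TableValidationError(f"{geometry_path}: duplicate core_id {dups}")
    geom = geom.set_index("core_id")

    bad = ~cells["phenotype"].isin(PHENOTYPES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise TableValidationError(
            f"{cells_path}: row {row}: unknown phenotype "
            f"{cells.loc[bad].iloc[0]['phenotype']!r}"
        )
    bad = ~cells["region"].isin(REGIONS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise TableValidationError(
            f"{cells_path}: row {row}: unknown region "
            f"{cells.loc[bad].iloc[0]['region']!r}"
        )

    by_tumor: dict[str, list[CorePattern]] = {}
    for core_id, grp in cells.groupby("core_id", sort=False):
        if core_id not in geom.index:
            raise TableValidationError(
                f"{cells_path}: core {core_id!r} absent from geometry table"
            )
        g = geom.loc[core_id]
        center = (float(g["center_x_um"]), float(g["center_y_um"]))
        radius = float(g["radius_um"])
        recs = []
        for idx, r in grp.iterrows():
            try:
                recs.append(
                    CellRecord(
                        float(r["x_um"]), float(r["y_um"]), r["phenotype"],
                        pd1_positive=bool(int(r["pd1"])),
                        pdl1_positive=bool(int(r["pdl1"])),
                        region=r["region"],
                    )
                )
            except PatternError as exc:
                raise TableValidationError(
                    f"{cells_path}: row {int(idx) + 2}: {exc}"
                ) from exc
        regions = grp["region"].unique()
        panels = grp["marker_panel"].unique()
        tumor_id = str(grp["tumor_id"].iloc[0])
        try:
            pattern = CorePattern(
                core_id=str(core_id), center=center, radius=radius,
                cells=tuple(recs),
                region=str(regions[0]) if len(regions) == 1 else None,
                marker_panel=str(panels[0]) if len(panels) == 1 else None,
                tumor_id=tumor_id,
            )
        except PatternError as exc:
            raise TableValidationError(f"{cells_path}: core {core_id!r}: {exc}") from exc
        by_tumor.setdefault(tumor_id, []).append(pattern)
    return by_tumor


def write_patient_table(cohort: pd.DataFrame, path, sep: str = "\t") -> None:
    cohort.to_csv(path, sep=sep, index=False)


def read_patient_table(path, sep: str = "\t", strict_levels: bool = True) -> pd.DataFrame:
    """Read and validate a patient table.

    Category vocabularies are checked column by column; survival times must
    be non-negative and event flags 0/1.  The 30-day post-operative rule is
    applied downstream (analysis stage), never at read time.
    """
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    _require_columns(df, ("patient_id",), path)
    if strict_levels:
        for col, levels in PATIENT_LEVELS.items():
            if col not in df.columns:
                continue
            vals = df[col].dropna().astype(str)
            bad = ~vals.isin(levels)
            if bad.any():
                raise TableValidationError(
                    f"{path}: column {col!r}: unknown level "
                    f"{vals[bad].iloc[0]!r} (expected {levels})"
                )
    for col in ("dss_time", "os_time"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise TableValidationError(f"{path}: column {col!r}: negative time")
    for col in ("dss_event", "os_event"):
        if col in df.columns and not df[col].dropna().isin((0, 1)).all():
            raise TableValidationError(f"{path}: column {col!r}: flags must be 0/1")
    if "postoperative_death" in df.columns:
        df["postoperative_death"] = df["postoperative_death"].astype(bool)
    return df
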