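"""Tabular interchange formats.

Long/tidy CSV is the interchange format throughout: one row per
plate-well-field-day with columns
``plate, well, donor, group, treatment, dose_uM, day, field,
total_length_um, status``. Days are integer days of differentiation,
lengths µm, doses µM. ``status`` is ``ok`` or ``failed``; a well-day is
FAILED only when every field of that day failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .exceptions import InputError, SchemaError
from .phenocurves import DonorPhenotype, WellPhenotype, WellSeries

WELL_SERIES_COLUMNS = [
    "plate",
    "well",
    "donor",
    "group",
    "treatment",
    "dose_uM",
    "day",
    "field",
    "total_length_um",
    "status",
]


@dataclass
class PlateLayout:
    """Well → donor/group/treatment map for one (possibly virtual) plate."""

    plate_id: str
    n_rows: int = 16
    n_cols: int = 24
    wells: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["well", "donor", "group", "treatment", "dose_uM", "replicate"]
        )
    )

    def __post_init__(self) -> None:
        if self.wells["well"].duplicated().any():
            dupes = self.wells.loc[self.wells["well"].duplicated(), "well"].tolist()
            raise InputError(f"duplicate well addresses: {dupes}")


def well_address(index: int, n_cols: int = 24) -> str:
    """Row-major well address (A01, A02, …) for a 384-well plate by default."""
    row, col = divmod(index, n_cols)
    prefix = ""
    if row >= 26:
        prefix, row = "A", row - 26
    return f"{prefix}{chr(ord('A') + row)}{col + 1:02d}"


def read_well_series(path: Union[str, Path]) -> List[WellSeries]:
    """Read a long-format well-series CSV into per-well series.

    Field values for a well-day are averaged; the day is marked FAILED
    only when all fields of that day have ``status == failed``.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in WELL_SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(missing, path)
    bad = pd.to_numeric(df["total_length_um"], errors="coerce").isna() & (
        df["status"] == "ok"
    )
    if bad.any():
        # +2: header line and 1-based numbering
        lines = (df.index[bad] + 2).tolist()
        raise InputError(
            f"non-numeric total_length_um in {path} at line(s) {lines[:10]}"
        )
    df["total_length_um"] = pd.to_numeric(df["total_length_um"], errors="coerce")

    series: List[WellSeries] = []
    for (plate, well), g in df.groupby(["plate", "well"], sort=True):
        first = g.iloc[0]
        obs: Dict[int, Optional[float]] = {}
        for day, gd in g.groupby("day", sort=True):
            ok = gd[gd["status"] == "ok"]
            obs[int(day)] = float(ok["total_length_um"].mean()) if len(ok) else None
        treatment = first["treatment"]
        if pd.isna(treatment) or treatment == "":
            treatment = None
        series.append(
            WellSeries(
                well_id=f"{plate}:{well}",
                donor_id=str(first["donor"]),
                group=str(first["group"]),
                treatment=treatment,
                dose_uM=float(first["dose_uM"]) if pd.notna(first["dose_uM"]) else 0.0,
                observations=obs,
            )
        )
    return series


def well_series_frame(series_list: List[WellSeries]) -> pd.DataFrame:
    """Long-format frame (single field per well-day) for a list of series."""
    rows = []
    for s in series_list:
        plate, _, well = s.well_id.partition(":")
        for day in s.scheduled_days():
            v = s.observations[day]
            rows.append(
                {
                    "plate": plate or "P1",
                    "well": well or s.well_id,
                    "donor": s.donor_id,
                    "group": s.group,
                    "treatment": s.treatment if s.treatment is not None else "",
                    "dose_uM": s.dose_uM,
                    "day": day,
                    "field": 1,
                    "total_length_um": np.nan if v is None else v,
                    "status": "failed" if v is None else "ok",
                }
            )
    return pd.DataFrame(rows, columns=WELL_SERIES_COLUMNS)


def write_well_series(series_list: List[WellSeries], path: Union[str, Path]) -> None:
    well_series_frame(series_list).to_csv(path, index=False)


def write_well_phenotypes(phenos: List[WellPhenotype], path: Union[str, Path]) -> None:
    rows = [
        {
            "well_id": p.well_id,
            "donor_id": p.donor_id,
            "group": p.group,
            "treatment": p.treatment if p.treatment is not None else "",
            "dose_uM": p.dose_uM,
            "peak_um": p.peak_um,
            "peak_day": p.peak_day,
            "growth_rate_pct": p.growth_rate_pct,
            "decline_rate_pct": p.decline_rate_pct,
            "ld50_day": p.ld50_day,
            "qc_status": p.qc_status,
            "qc_reasons": ";".join(p.qc_reasons),
        }
        for p in phenos
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_donor_phenotypes(donors: List[DonorPhenotype], path: Union[str, Path]) -> None:
    rows = [
        {
            "donor_id": d.donor_id,
            "group": d.group,
            "treatment": d.treatment if d.treatment is not None else "",
            "mean_ld50": d.mean_ld50,
            "sem_ld50": d.sem_ld50,
            "n_wells_pass": d.n_wells_pass,
            "mean_growth_rate_pct": d.mean_growth_rate_pct,
            "mean_decline_rate_pct": d.mean_decline_rate_pct,
        }
        for d in donors
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
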