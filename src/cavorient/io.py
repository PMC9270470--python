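"""CSV readers/writers for the three record schemas.

All interchange is comma-separated UTF-8 with a header row. Each reader
accepts an optional ``column_map`` (``{canonical_name: actual_name}``) so
externally produced tables with different headers can be ingested without
editing the file.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from cavorient.errors import (
    ConsistencyError,
    DuplicateError,
    SchemaError,
    ValueRangeError,
)
from cavorient.records import BIOCLIM_VARS, CavityRecord, NestRecord, SiteMeta, normalize_bearing

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}

CAVITY_COLUMNS = ("site", "cavity_id", "stage", "is_nest", "orientation_deg")
SITE_COLUMNS = ("site", "latitude_deg", "longitude_deg")
NEST_COLUMNS = ("cluster_id", "year", "direction_deg", "adults", "eggs", "hatchlings", "fledglings")


def _parse_bool(raw: str, row_num: int) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueRangeError(f"row {row_num}: cannot interpret {raw!r} as a boolean")


def _load_table(path: str | Path, required: Sequence[str], column_map: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        rename = {actual: canonical for canonical, actual in column_map.items()}
        df = df.rename(columns=rename)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def read_cavities(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[CavityRecord]:
    """Read and validate cavity records; bearings are normalized into [0, 360)."""
    df = _load_table(path, CAVITY_COLUMNS, column_map)
    records: list[CavityRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            orientation = normalize_bearing(float(row.orientation_deg), context=f"row {i}")
        except ValueError as exc:
            raise ValueRangeError(f"row {i}: bad orientation {row.orientation_deg!r}") from exc
        records.append(
            CavityRecord(
                site=str(row.site),
                cavity_id=str(row.cavity_id),
                stage=str(row.stage).strip().lower(),
                is_nest=_parse_bool(row.is_nest, i),
                orientation_deg=orientation,
            )
        )
    return records


def write_cavities(records: Iterable[CavityRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CAVITY_COLUMNS)
        for r in records:
            w.writerow([r.site, r.cavity_id, r.stage, str(r.is_nest).lower(), repr(r.orientation_deg)])


def read_sites(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[SiteMeta]:
    """Read site metadata; bioclim columns bio1..bio19, when all present, become the climate vector."""
    df = _load_table(path, SITE_COLUMNS, column_map)
    has_climate = all(c in df.columns for c in BIOCLIM_VARS)
    sites: list[SiteMeta] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        site = str(row["site"])
        if site in seen:
            raise DuplicateError(f"row {i + 2}: duplicate site {site!r}")
        seen.add(site)
        climate = {c: float(row[c]) for c in BIOCLIM_VARS} if has_climate else None
        sites.append(
            SiteMeta(
                site=site,
                latitude_deg=float(row["latitude_deg"]),
                longitude_deg=float(row["longitude_deg"]),
                climate=climate,
            )
        )
    return sites


def write_sites(sites: Iterable[SiteMeta], path: str | Path) -> None:
    sites = list(sites)
    with_climate = all(s.climate is not None for s in sites) and len(sites) > 0
    header = list(SITE_COLUMNS) + (list(BIOCLIM_VARS) if with_climate else [])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for s in sites:
            row = [s.site, repr(s.latitude_deg), repr(s.longitude_deg)]
            if with_climate:
                row += [repr(s.climate[c]) for c in BIOCLIM_VARS]
            w.writerow(row)


def read_nests(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[NestRecord]:
    """Read and validate nest records; duplicate cluster-year pairs are rejected."""
    df = _load_table(path, NEST_COLUMNS, column_map)
    records: list[NestRecord] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        year = int(row.year)
        key = (str(row.cluster_id), year)
        if key in seen:
            raise DuplicateError(f"row {i}: duplicate cluster-year {key} (only first brood attempts allowed)")
        seen.add(key)
        records.append(
            NestRecord(
                cluster_id=str(row.cluster_id),
                year=year,
                direction_deg=normalize_bearing(float(row.direction_deg), context=f"row {i}"),
                adults=int(row.adults),
                eggs=int(row.eggs),
                hatchlings=int(row.hatchlings),
                fledglings=int(row.fledglings),
            )
        )
    return records


def write_nests(records: Iterable[NestRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(NEST_COLUMNS)
        for r in records:
            w.writerow(
                [r.cluster_id, r.year, repr(r.direction_deg), r.adults, r.eggs, r.hatchlings, r.fledglings]
            )


def read_climate_table(path: str | Path) -> pd.DataFrame:
    """Read a site x 19 bioclim table, indexed by site, columns bio1..bio19 in order."""
    df = pd.read_csv(path)
    if "site" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'site'")
    missing = [c for c in BIOCLIM_VARS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing bioclim columns {missing}")
    out = df.set_index("site")[list(BIOCLIM_VARS)].astype(float)
    if out.isna().any().any():
        raise ConsistencyError(f"{path}: climate table contains missing values")
    return out
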