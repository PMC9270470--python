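"""Domain record types and their validation rules.

Bearings are decimal degrees clockwise from north, stored half-open in
[0, 360). A single modulo-360 normalization is applied on ingest; raw
values at or above 720 (i.e. more than one full extra turn) are rejected
rather than silently wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cavorient.errors import ConsistencyError, ValueRangeError

#: Fixed order of the 19 bioclim variable names used in climate tables.
BIOCLIM_VARS = tuple(f"bio{i}" for i in range(1, 20))

STAGES = ("start", "complete")


def normalize_bearing(value: float, *, context: str = "") -> float:
    """Map a raw compass bearing into [0, 360) with one modulo pass.

    Values in [0, 720) are accepted (one wrap allowed); anything else is
    a range error, since a double wrap usually signals corrupted input.
    """
    v = float(value)
    if not (0.0 <= v < 720.0):
        raise ValueRangeError(
            f"orientation {value!r} outside [0, 720){': ' + context if context else ''}"
        )
    v = v % 360.0
    return 0.0 if v == 360.0 else v


@dataclass(frozen=True)
class CavityRecord:
    """One excavation: site, stage, nest flag, and entrance bearing."""

    site: str
    cavity_id: str
    stage: str  # "start" | "complete"
    is_nest: bool
    orientation_deg: float

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueRangeError(f"unknown stage {self.stage!r} (expected start/complete)")
        if self.is_nest and self.stage != "complete":
            raise ConsistencyError(
                f"cavity {self.cavity_id!r}: is_nest=true requires stage=complete"
            )
        if not (0.0 <= self.orientation_deg < 360.0):
            raise ValueRangeError(
                f"cavity {self.cavity_id!r}: orientation {self.orientation_deg} not in [0, 360)"
            )


@dataclass(frozen=True)
class SiteMeta:
    """Site coordinates plus an optional 19-entry bioclim vector."""

    site: str
    latitude_deg: float
    longitude_deg: float
    climate: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude_deg <= 90.0):
            raise ValueRangeError(f"site {self.site!r}: latitude {self.latitude_deg} outside [-90, 90]")
        if self.climate is not None:
            if tuple(self.climate.keys()) != BIOCLIM_VARS:
                raise ConsistencyError(
                    f"site {self.site!r}: climate vector must have exactly the 19 "
                    f"bioclim entries bio1..bio19 in order"
                )


@dataclass(frozen=True)
class NestRecord:
    """One first-brood nesting attempt for a cluster-year."""

    cluster_id: str
    year: int
    direction_deg: float
    adults: int
    eggs: int
    hatchlings: int
    fledglings: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.direction_deg < 360.0):
            raise ValueRangeError(
                f"cluster {self.cluster_id!r} year {self.year}: direction "
                f"{self.direction_deg} not in [0, 360)"
            )
        if self.adults < 2:
            raise ValueRangeError(
                f"cluster {self.cluster_id!r} year {self.year}: adults={self.adults} < 2 "
                f"(a breeding pair is the minimum group)"
            )
        for name in ("eggs", "hatchlings", "fledglings"):
            if getattr(self, name) < 0:
                raise ValueRangeError(
                    f"cluster {self.cluster_id!r} year {self.year}: negative {name}"
                )
        if not (self.fledglings <= self.hatchlings <= self.eggs):
            raise ConsistencyError(
                f"cluster {self.cluster_id!r} year {self.year}: requires "
                f"fledglings <= hatchlings <= eggs, got "
                f"{self.fledglings}/{self.hatchlings}/{self.eggs}"
            )
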