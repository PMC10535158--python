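"""Record-vs-process scheduling from GPS speed and port proximity.

While the vessel fishes (slow, away from port) the device records; when it
travels at or above 4 knots, or sits within the port geofence, it switches
to processing the stored footage.
"""

from __future__ import annotations

import csv
import enum
import math
import warnings
from dataclasses import dataclass

__all__ = [
    "GpsFix",
    "SchedulerConfig",
    "OperatingState",
    "haversine_m",
    "speed_knots",
    "operating_state",
    "track_states",
    "read_track_csv",
]

EARTH_RADIUS_M = 6371008.8
METERS_PER_NM = 1852.0


class OperatingState(enum.Enum):
    RECORD = "record"
    PROCESS = "process"


@dataclass(frozen=True)
class GpsFix:
    timestamp: float  # seconds
    lat: float  # degrees
    lon: float  # degrees

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of range")


@dataclass(frozen=True)
class SchedulerConfig:
    speed_threshold_knots: float = 4.0
    port_center: tuple[float, float] | None = None  # (lat, lon)
    port_radius_m: float | None = None

    def __post_init__(self) -> None:
        if self.speed_threshold_knots <= 0:
            raise ValueError("speed threshold must be positive")
        if self.port_radius_m is not None and self.port_radius_m <= 0:
            raise ValueError("port radius must be positive")


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


def speed_knots(a: GpsFix, b: GpsFix) -> float:
    """Great-circle speed between consecutive fixes, in knots."""
    dt = b.timestamp - a.timestamp
    if dt <= 0:
        raise ValueError("timestamps must be strictly increasing")
    dist = haversine_m(a.lat, a.lon, b.lat, b.lon)
    return dist / dt * 3600.0 / METERS_PER_NM


def _in_port(fix: GpsFix, config: SchedulerConfig) -> bool:
    if config.port_center is None or config.port_radius_m is None:
        return False
    dist = haversine_m(fix.lat, fix.lon, *config.port_center)
    return dist <= config.port_radius_m


def operating_state(
    a: GpsFix, b: GpsFix, config: SchedulerConfig = SchedulerConfig()
) -> OperatingState:
    """RECORD while fishing (< threshold knots, outside port); PROCESS when
    moving at/above the threshold or inside the port geofence."""
    if config.port_center is None or config.port_radius_m is None:
        warnings.warn("no port configured; applying the speed rule only")
    speed = speed_knots(a, b)
    if speed >= config.speed_threshold_knots or _in_port(b, config):
        return OperatingState.PROCESS
    return OperatingState.RECORD


def track_states(
    fixes: list[GpsFix],
    config: SchedulerConfig = SchedulerConfig(),
    smooth_k: int = 3,
) -> list[OperatingState]:
    """Per-fix states for a track, with median-of-k speed smoothing.

    Speeds come from consecutive fix pairs; a centred median over ``smooth_k``
    speeds resists GPS jitter.  Returns one state per fix after the first.
    """
    if len(fixes) < 2:
        raise ValueError("need at least two fixes")
    if smooth_k < 1 or smooth_k % 2 == 0:
        raise ValueError("smooth_k must be a positive odd integer")
    speeds = [speed_knots(a, b) for a, b in zip(fixes[:-1], fixes[1:])]
    half = smooth_k // 2
    states = []
    for i, fix in enumerate(fixes[1:]):
        window = speeds[max(0, i - half) : i + half + 1]
        med = sorted(window)[len(window) // 2]
        if med >= config.speed_threshold_knots or _in_port(fix, config):
            states.append(OperatingState.PROCESS)
        else:
            states.append(OperatingState.RECORD)
    return states


def read_track_csv(path) -> list[GpsFix]:
    """Read (timestamp, lat, lon) rows; timestamps must strictly increase."""
    fixes = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            fixes.append(
                GpsFix(
                    timestamp=float(row["timestamp"]),
                    lat=float(row["lat"]),
                    lon=float(row["lon"]),
                )
            )
    for a, b in zip(fixes[:-1], fixes[1:]):
        if b.timestamp <= a.timestamp:
            raise ValueError("track timestamps must be strictly increasing")
    return fixes
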