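"""Per-match activity profiles: distance per movement category, max speed.

Distance is integrated from instantaneous velocity with the rectangle rule
at the sampling rate (each sample contributes v / sample_hz metres), and
each sample's distance accrues to the zone containing its velocity.  Zones
are half-open [lower, upper) with the last zone closed above at 10 m/s,
mirroring the bin convention of the clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import VelocityTrace

__all__ = ["ZoneScheme", "ZoneProfile", "GENERIC_RUGBY_SCHEME", "profile_trace", "cohort_profiles"]

V_TOP = 10.0


@dataclass(frozen=True)
class ZoneScheme:
    """A named set of movement categories over [0, 10] m/s."""

    name: str
    boundaries: tuple[float, ...]
    zone_names: tuple[str, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if len(self.zone_names) != len(b) + 1:
            raise ValueError("zone count must be boundary count + 1")
        if len(set(self.zone_names)) != len(self.zone_names):
            raise ValueError("zone names must be unique")
        if len(b) and (b[0] <= 0 or np.any(np.diff(b) <= 0) or b[-1] >= V_TOP):
            raise ValueError("boundaries must be strictly increasing inside (0, 10)")

    @property
    def n_zones(self) -> int:
        return len(self.zone_names)

    def zone_of(self, v: np.ndarray) -> np.ndarray:
        """Zone index per velocity; half-open zones, top zone closed at 10."""
        return np.searchsorted(np.asarray(self.boundaries), v, side="right")

    def merged(self, names: tuple[str, str], new_name: str) -> "ZoneScheme":
        """Merge two adjacent zones (e.g. HSR + sprint) into one."""
        i, j = (self.zone_names.index(n) for n in names)
        if abs(i - j) != 1:
            raise ValueError("can only merge adjacent zones")
        lo = min(i, j)
        boundaries = self.boundaries[:lo] + self.boundaries[lo + 1:]
        zone_names = self.zone_names[:lo] + (new_name,) + self.zone_names[lo + 2:]
        return ZoneScheme(f"{self.name}-merged", boundaries, zone_names)


#: the legacy arbitrary rugby-sevens scheme the derived zones are compared to
GENERIC_RUGBY_SCHEME = ZoneScheme(
    name="generic-rugby",
    boundaries=(2.0, 3.5, 5.5, 6.0),
    zone_names=("standing_walking", "jogging", "cruising", "high_speed_running", "sprinting"),
)


@dataclass(frozen=True)
class ZoneProfile:
    """One match's external-load summary under one zone scheme."""

    match_id: str
    player_id: str
    sex: str
    scheme: str
    distance_per_zone: dict[str, float]
    total_distance_m: float
    duration_min: float
    relative_distance_m_per_min: float
    max_velocity_mps: float


def profile_trace(trace: VelocityTrace, scheme: ZoneScheme) -> ZoneProfile:
    """Absolute/relative distance per zone and max speed for one cleaned trace."""
    if len(trace) == 0:
        raise ValueError("cannot profile an empty trace")
    v = trace.velocities
    dist = v / trace.sample_hz
    zone_idx = scheme.zone_of(v)
    per_zone = {
        name: float(dist[zone_idx == z].sum()) for z, name in enumerate(scheme.zone_names)
    }
    total = float(dist.sum())
    duration_min = len(v) / (trace.sample_hz * 60.0)
    return ZoneProfile(
        match_id=trace.match_id,
        player_id=trace.player_id,
        sex=trace.sex,
        scheme=scheme.name,
        distance_per_zone=per_zone,
        total_distance_m=total,
        duration_min=duration_min,
        relative_distance_m_per_min=total / duration_min,
        max_velocity_mps=float(v.max()),
    )


def profiles_frame(profiles: list[ZoneProfile]) -> pd.DataFrame:
    """Flatten profiles to one row per match (zone columns prefixed ``dist_``)."""
    rows = []
    for p in profiles:
        row = {
            "match_id": p.match_id,
            "player_id": p.player_id,
            "sex": p.sex,
            "scheme": p.scheme,
            "total_distance_m": p.total_distance_m,
            "duration_min": p.duration_min,
            "relative_distance_m_per_min": p.relative_distance_m_per_min,
            "max_velocity_mps": p.max_velocity_mps,
        }
        row.update({f"dist_{k}": v for k, v in p.distance_per_zone.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_profiles(
    traces: list[VelocityTrace], scheme: ZoneScheme
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profile every trace and summarise mean +/- sample SD by sex.

    Returns (per-match table, summary).  The summary has one row per
    (sex, metric) with columns ``mean``, ``sd`` and ``n``; SD uses the n-1
    denominator and is NaN when a cohort holds a single match.
    """
    if not traces:
        raise ValueError("no traces to profile")
    table = profiles_frame([profile_trace(t, scheme) for t in traces])
    metrics = [c for c in table.columns if c.startswith("dist_")] + [
        "total_distance_m",
        "relative_distance_m_per_min",
        "max_velocity_mps",
    ]
    summary = (
        table.groupby("sex")[metrics]
        .agg(["mean", "std", "count"])
        .stack(level=0, future_stack=True)
        .rename(columns={"std": "sd", "count": "n"})
        .rename_axis(["sex", "metric"])
        .reset_index()
    )
    return table, summary
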