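"""GPS telemetry cleaning.

Three screens are applied to raw hourly fixes, in order:

1. **Elevation residual** — a fix whose recorded elevation differs from the
   DEM at its location by strictly more than ``max_elev_error`` (25 m) is an
   altimetry blunder and is removed.
2. **Speed / spike** — iteratively, (a) any fix whose incoming speed exceeds
   ``max_speed`` (300 m/hr, beyond the animal's locomotion) is removed; (b)
   any interior fix whose incoming AND outgoing legs both exceed
   ``spike_speed`` (100 m/hr) with a turn metric above ``spike_turn`` (300°)
   is an out-and-back GPS spike and is removed.  Speeds are recomputed after
   every pass until a pass removes nothing.
3. **Season gate** — only (animal, year) blocks covering the whole active
   season (>=1 fix in every month, April–October by default) are retained.

The turn metric is ``(bearing_out - bearing_in) mod 360`` in [0°, 360°): the
only convention under which a 300° threshold is attainable.  All thresholds
are strict inequalities.  Speeds use distance / elapsed *hours*, so gaps in
the fix record are handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Grid

__all__ = ["CleaningConfig", "elevation_filter", "speed_turn_filter", "season_gate", "clean_telemetry"]

FIX_COLUMNS = ["animal_id", "timestamp", "x", "y", "elev"]


@dataclass
class CleaningConfig:
    max_elev_error: float = 25.0   # m
    max_speed: float = 300.0       # m/hr
    spike_speed: float = 100.0     # m/hr
    spike_turn: float = 300.0      # degrees, on the mod-360 turn metric
    require_full_season: bool = True
    season: tuple[int, int] = (4, 10)  # month range, inclusive

    def __post_init__(self) -> None:
        if min(self.max_elev_error, self.max_speed, self.spike_speed, self.spike_turn) <= 0:
            raise ValueError("all cleaning thresholds must be > 0")
        if self.spike_speed > self.max_speed:
            raise ValueError("spike_speed must not exceed max_speed")


def _check_sorted(fixes: pd.DataFrame) -> None:
    for animal, grp in fixes.groupby("animal_id", sort=False):
        dt = grp["timestamp"].diff().dropna()
        if (dt <= pd.Timedelta(0)).any():
            idx = int(np.argmax((dt <= pd.Timedelta(0)).to_numpy()))
            raise ValueError(
                f"timestamps not strictly increasing for animal {animal!r} "
                f"(first violation at ordinal position {idx + 1})"
            )


def elevation_filter(
    fixes: pd.DataFrame, dem: Grid, cfg: CleaningConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove fixes with |recorded elevation - DEM| strictly above the cap.

    Fixes without a recorded elevation pass untouched; fixes outside the DEM
    extent are kept but flagged ``outside_dem`` for the report.
    """
    cfg = cfg or CleaningConfig()
    fixes = fixes.copy()
    dem_z = dem.sample_nearest(fixes["x"].to_numpy(), fixes["y"].to_numpy())
    inside = dem.contains(fixes["x"].to_numpy(), fixes["y"].to_numpy())
    elev = fixes["elev"].to_numpy(dtype=float) if "elev" in fixes else np.full(len(fixes), np.nan)
    resid = np.abs(elev - dem_z)
    bad = inside & ~np.isnan(resid) & (resid > cfg.max_elev_error)
    removed = fixes.loc[bad].copy()
    removed["reason"] = "elevation_error"
    kept = fixes.loc[~bad].copy()
    kept["outside_dem"] = ~inside[~bad]
    return kept, removed


def _bearings(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan2(np.diff(x), np.diff(y))) % 360.0


def speed_turn_filter(
    fixes: pd.DataFrame, cfg: CleaningConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iterative speed and spike screens, per animal, to a fixed point.

    One fix is removed per iteration and all speeds/turns are recomputed, so
    a single mislocated point never drags its (innocent) neighbours out with
    it.  Priority within an iteration: a fix whose incoming AND outgoing
    legs are both impossible is the clear outlier and goes first; then the
    worst incoming-speed violation; then the worst fast-sharp-turn spike.
    """
    cfg = cfg or CleaningConfig()
    _check_sorted(fixes)
    kept_parts, removed_parts = [], []
    for _, grp in fixes.groupby("animal_id", sort=False):
        grp = grp.copy()
        live = grp.index.to_numpy()
        reasons: dict[int, str] = {}
        while len(live) >= 2:
            sub = grp.loc[live]
            x = sub["x"].to_numpy(float)
            y = sub["y"].to_numpy(float)
            t = sub["timestamp"].to_numpy()
            hours = np.diff(t).astype("timedelta64[s]").astype(float) / 3600.0
            speed = np.hypot(np.diff(x), np.diff(y)) / hours  # m/hr per leg
            # both adjoining legs impossible: the fix itself is mislocated
            both = (speed[:-1] > cfg.max_speed) & (speed[1:] > cfg.max_speed)
            if both.any():
                i = int(np.argmax(np.minimum(speed[:-1], speed[1:]) * both)) + 1
                reasons[live[i]] = "speed"
                live = np.delete(live, i)
                continue
            over = speed > cfg.max_speed
            if over.any():
                i = int(np.argmax(np.where(over, speed, -np.inf))) + 1
                reasons[live[i]] = "speed"
                live = np.delete(live, i)
                continue
            if len(live) >= 3:
                brg = _bearings(x, y)
                turn = (brg[1:] - brg[:-1]) % 360.0
                spike = (
                    (speed[:-1] > cfg.spike_speed)
                    & (speed[1:] > cfg.spike_speed)
                    & (turn > cfg.spike_turn)
                )
                if spike.any():
                    i = int(np.argmax(np.where(spike, turn, -np.inf))) + 1
                    reasons[live[i]] = "spike"
                    live = np.delete(live, i)
                    continue
            break
        rem = grp.loc[list(reasons)].copy()
        rem["reason"] = [reasons[i] for i in rem.index]
        removed_parts.append(rem)
        kept_parts.append(grp.loc[live])
    kept = pd.concat(kept_parts) if kept_parts else fixes.iloc[0:0].copy()
    removed = (
        pd.concat(removed_parts)
        if removed_parts
        else fixes.iloc[0:0].assign(reason=pd.Series(dtype=str))
    )
    return kept, removed


def season_gate(fixes: pd.DataFrame, cfg: CleaningConfig | None = None) -> pd.DataFrame:
    """Keep only (animal, year) blocks with >=1 fix in every season month."""
    cfg = cfg or CleaningConfig()
    if not cfg.require_full_season or fixes.empty:
        return fixes.copy()
    months = set(range(cfg.season[0], cfg.season[1] + 1))
    ts = pd.DatetimeIndex(fixes["timestamp"])
    year = ts.year
    month = ts.month
    key = pd.MultiIndex.from_arrays([fixes["animal_id"], year])
    ok_blocks = set()
    covered = pd.DataFrame({"animal": fixes["animal_id"].to_numpy(), "year": year, "month": month})
    for (animal, yr), grp in covered.groupby(["animal", "year"]):
        if months.issubset(set(grp["month"])):
            ok_blocks.add((animal, yr))
    mask = np.array([k in ok_blocks for k in key])
    return fixes.loc[mask].copy()


def clean_telemetry(
    fixes: pd.DataFrame, dem: Grid, cfg: CleaningConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cleaning chain: elevation -> speed/spike -> season gate.

    Returns (kept, removal_report); the report holds one row per removed fix
    with a ``reason`` code (``elevation_error`` | ``speed`` | ``spike`` |
    ``partial_season``)."""
    cfg = cfg or CleaningConfig()
    _check_sorted(fixes)
    kept, rem_elev = elevation_filter(fixes, dem, cfg)
    kept, rem_speed = speed_turn_filter(kept, cfg)
    gated = season_gate(kept, cfg)
    rem_season = kept.loc[~kept.index.isin(gated.index)].copy()
    rem_season["reason"] = "partial_season"
    report = pd.concat([rem_elev, rem_speed, rem_season], ignore_index=False)
    return gated.drop(columns=["outside_dem"], errors="ignore"), report
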