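"""Segment cleaned trajectories into qualifying movement paths.

A *path* is a maximal run of consecutive fixes in which every adjacent pair
is one hour apart (within tolerance) and strictly more than ``min_step``
(10 m, the GPS error budget) apart; the run must have at least ``min_points``
(3) fixes and a total length strictly above ``min_total`` (100 m).  Animals
contribute to the selection analysis only if they yield at least
``min_paths_per_animal`` (6, i.e. "more than 5") observed paths.

Turn angles on a path are stored *signed* in (-180°, 180°] for distribution
fitting — a different convention from the 0–360° screening metric used by
the cleaning module, which exists only to apply the spike threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Path", "PathConfig", "segment_paths", "eligible_animals", "pooled_steps_turns", "step_stats"]


@dataclass
class Path:
    animal_id: str
    coords: np.ndarray                    # (n, 2) metres
    times: np.ndarray | None = None       # optional fix timestamps
    is_observed: bool = True
    path_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2 or len(self.coords) < 2:
            raise ValueError("a path needs >= 2 (x, y) fixes")

    @property
    def n_points(self) -> int:
        return len(self.coords)

    @property
    def n_steps(self) -> int:
        return len(self.coords) - 1

    @property
    def step_lengths(self) -> np.ndarray:
        d = np.diff(self.coords, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def bearings(self) -> np.ndarray:
        d = np.diff(self.coords, axis=0)
        return np.degrees(np.arctan2(d[:, 0], d[:, 1])) % 360.0

    @property
    def turn_angles(self) -> np.ndarray:
        """Signed turns in (-180°, 180°], length n_steps - 1."""
        t = (np.diff(self.bearings) + 180.0) % 360.0 - 180.0
        t[t == -180.0] = 180.0
        return t

    @property
    def total_length(self) -> float:
        return float(self.step_lengths.sum())

    @property
    def start(self) -> np.ndarray:
        return self.coords[0]


@dataclass
class PathConfig:
    min_points: int = 3
    fix_interval_hours: float = 1.0
    interval_tolerance_minutes: float = 5.0
    min_step: float = 10.0       # m, strict
    min_total: float = 100.0     # m, strict
    min_paths_per_animal: int = 6

    def __post_init__(self) -> None:
        vals = (self.min_points, self.fix_interval_hours, self.interval_tolerance_minutes,
                self.min_step, self.min_total, self.min_paths_per_animal)
        if any(v <= 0 for v in vals):
            raise ValueError("all path-construction parameters must be positive")


def segment_paths(trajectory: pd.DataFrame, cfg: PathConfig | None = None) -> list[Path]:
    """Split each animal's cleaned fix sequence at any adjacent pair that is
    not hourly or not > min_step apart, then keep runs meeting the point and
    total-length criteria. A fix belongs to at most one path; a violating
    pair breaks the run (segmentation, not further cleaning)."""
    cfg = cfg or PathConfig()
    out: list[Path] = []
    tol = pd.Timedelta(minutes=cfg.interval_tolerance_minutes)
    target = pd.Timedelta(hours=cfg.fix_interval_hours)
    for animal, grp in trajectory.groupby("animal_id", sort=False):
        x = grp["x"].to_numpy(float)
        y = grp["y"].to_numpy(float)
        t = pd.DatetimeIndex(grp["timestamp"])
        if len(grp) < 2:
            continue
        dt = np.diff(t.asi8) / 1e9  # seconds
        ok_time = np.abs(dt - target.total_seconds()) <= tol.total_seconds()
        step = np.hypot(np.diff(x), np.diff(y))
        ok = ok_time & (step > cfg.min_step)
        # maximal runs of consecutive qualifying pairs
        idx = 0
        n_pairs = len(ok)
        k = 0
        while idx < n_pairs:
            if not ok[idx]:
                idx += 1
                continue
            j = idx
            while j < n_pairs and ok[j]:
                j += 1
            coords = np.column_stack([x[idx : j + 1], y[idx : j + 1]])
            p = Path(
                animal_id=str(animal),
                coords=coords,
                times=t[idx : j + 1].to_numpy(),
                path_id=f"{animal}:{k}",
            )
            if p.n_points >= cfg.min_points and p.total_length > cfg.min_total:
                out.append(p)
                k += 1
            idx = j
    return out


def eligible_animals(paths: list[Path], cfg: PathConfig | None = None) -> set[str]:
    """Animals with at least ``min_paths_per_animal`` observed paths."""
    cfg = cfg or PathConfig()
    counts: dict[str, int] = {}
    for p in paths:
        if p.is_observed:
            counts[p.animal_id] = counts.get(p.animal_id, 0) + 1
    return {a for a, n in counts.items() if n >= cfg.min_paths_per_animal}


def pooled_steps_turns(paths: list[Path]) -> tuple[np.ndarray, np.ndarray]:
    """Pool all step lengths and all signed turns across observed paths."""
    obs = [p for p in paths if p.is_observed]
    steps = np.concatenate([p.step_lengths for p in obs]) if obs else np.array([])
    turns = (
        np.concatenate([p.turn_angles for p in obs if p.n_steps >= 2])
        if obs
        else np.array([])
    )
    return steps, turns


def step_stats(paths: list[Path]):
    """Population step/turn distributions fitted over ALL observed paths
    (pooled across animals, so availability is not circular per individual).
    Returns a :class:`pathsel.randomwalk.StepDistributions`."""
    from .randomwalk import fit_step_distributions

    steps, turns = pooled_steps_turns(paths)
    return fit_step_distributions(steps, turns)
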