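"""Population step/turn distributions and correlated-random-walk null paths.

Step lengths are gamma distributed; turning angles are wrapped normal.  Both
are fitted once over the *pooled* steps and turns of every observed path (the
population fit avoids circularity that per-individual fits would introduce).
Each observed path is then matched with ``n_random`` (10) correlated random
walks that start at the observed path's first fix and take the same number
of steps, giving the "available" side of each choice set.

Availability is deliberately unconstrained by fences or other barriers: the
selection model, not the availability sample, is what measures avoidance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import Grid
from .paths import Path

__all__ = [
    "StepDistributions",
    "RandomPathSet",
    "fit_gamma",
    "fit_wrapped_normal",
    "fit_step_distributions",
    "generate_random_paths",
]


@dataclass
class StepDistributions:
    gamma_shape: float
    gamma_scale: float        # metres
    wn_mu: float              # degrees
    wn_rho: float             # mean resultant length in [0, 1)
    n_steps_fitted: int = 0
    n_turns_fitted: int = 0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma parameters must be > 0")
        if not 0 <= self.wn_rho < 1:
            raise ValueError("wn_rho must lie in [0, 1)")

    @property
    def wn_sd_degrees(self) -> float:
        """Equivalent wrapped-normal standard deviation, degrees."""
        return float(np.degrees(np.sqrt(-2.0 * np.log(self.wn_rho)))) if self.wn_rho > 0 else np.inf


@dataclass
class RandomPathSet:
    observed: Path
    random_paths: list[Path]
    stratum_id: str = ""

    @property
    def all_paths(self) -> list[Path]:
        return [self.observed, *self.random_paths]


def fit_gamma(steps: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood gamma (shape, scale) for step lengths, metres."""
    steps = np.asarray(steps, dtype=float)
    if len(steps) < 10:
        raise ValueError(f"need >= 10 step lengths to fit, got {len(steps)}")
    if np.any(steps <= 0):
        raise ValueError("all step lengths must be > 0 (pipeline misuse: segmentation guarantees > 10 m)")
    if np.ptp(steps) == 0:
        raise ValueError("degenerate step sample: zero variance")
    shape, _, scale = stats.gamma.fit(steps, floc=0)
    return float(shape), float(scale)


def fit_wrapped_normal(turns_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean (degrees) and mean resultant length for turning angles."""
    turns_deg = np.asarray(turns_deg, dtype=float)
    if len(turns_deg) < 5:
        raise ValueError(f"need >= 5 turning angles, got {len(turns_deg)}")
    rad = np.radians(turns_deg)
    c, s = np.cos(rad).mean(), np.sin(rad).mean()
    mu = float(np.degrees(np.arctan2(s, c)))
    rho = float(min(np.hypot(c, s), 1.0 - 1e-12))  # rho = 1 would imply sd = 0 exactly
    return mu, rho


def fit_step_distributions(steps: np.ndarray, turns_deg: np.ndarray) -> StepDistributions:
    shape, scale = fit_gamma(steps)
    mu, rho = fit_wrapped_normal(turns_deg)
    return StepDistributions(
        gamma_shape=shape,
        gamma_scale=scale,
        wn_mu=mu,
        wn_rho=rho,
        n_steps_fitted=len(steps),
        n_turns_fitted=len(turns_deg),
    )


def _draw_walk(
    start: np.ndarray,
    n_steps: int,
    dists: StepDistributions,
    rng: np.random.Generator,
    extent: Grid | None,
    retry_cap: int,
) -> np.ndarray:
    """One CRW realisation; out-of-extent steps are redrawn up to retry_cap,
    after which the walk is truncated with a warning."""
    sd_rad = np.radians(dists.wn_sd_degrees)
    mu_rad = np.radians(dists.wn_mu)
    coords = [np.asarray(start, dtype=float)]
    bearing = rng.uniform(0.0, 2 * np.pi)
    first = True
    for _ in range(n_steps):
        placed = False
        for _try in range(retry_cap):
            if first:
                b = bearing
            else:
                b = bearing + mu_rad + sd_rad * rng.standard_normal()
            L = rng.gamma(dists.gamma_shape, dists.gamma_scale)
            nxt = coords[-1] + L * np.array([np.sin(b), np.cos(b)])
            if extent is None or bool(extent.contains(nxt[0], nxt[1])):
                coords.append(nxt)
                bearing = b
                first = False
                placed = True
                break
        if not placed:
            if len(coords) < 2:
                # never emit a degenerate (point) path: clip one step inside
                xmin, ymin, xmax, ymax = extent.bounds  # type: ignore[union-attr]
                eps = 1e-6 * (xmax - xmin)
                nxt = np.clip(nxt, [xmin + eps, ymin + eps], [xmax - eps, ymax - eps])
                coords.append(nxt)
            warnings.warn(
                "random walk stuck at raster edge; truncating path "
                f"at {len(coords) - 1} of {n_steps} steps",
                stacklevel=3,
            )
            break
    return np.array(coords)


def generate_random_paths(
    observed: Path,
    dists: StepDistributions,
    n_random: int = 10,
    rng: np.random.Generator | int | None = None,
    extent: Grid | None = None,
    retry_cap: int = 20,
) -> RandomPathSet:
    """Matched CRW availability set for one observed path.

    Each random path shares the observed start point and step count; its
    first bearing is uniform on [0°, 360°), subsequent bearings accumulate
    wrapped-normal turns, and step lengths are independent gamma draws.
    Generation depends on the observed path only through its start point and
    step count. A seed (or Generator) is required for reproducibility.
    """
    if observed.n_steps < 2:
        raise ValueError("observed path must have >= 2 steps")
    if rng is None:
        raise ValueError("pass an explicit seed or numpy Generator")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    rand = []
    for j in range(n_random):
        coords = _draw_walk(observed.start, observed.n_steps, dists, rng, extent, retry_cap)
        rand.append(
            Path(
                animal_id=observed.animal_id,
                coords=coords,
                is_observed=False,
                path_id=f"{observed.path_id}/r{j}",
            )
        )
    return RandomPathSet(observed=observed, random_paths=rand, stratum_id=observed.path_id)
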