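"""Synthetic landscapes, strata, and telemetry with known ground truth.

Three generators, each a pure function of its seed:

* :func:`make_landscape` — correlated random fields for vegetation, habitat
  suitability and wash intensity, a DEM with ridge structure (slope is
  derived from it), linear features, and the log-flattened
  distance-to-feature rasters.
* :func:`simulate_strata` / :func:`simulate_design` — direct draws from the
  conditional-logistic likelihood (choice sets with a known generating
  coefficient vector), for exact parameter-recovery and model-ranking tests.
* :func:`simulate_telemetry` — an agent-based GPS logger stand-in: at each
  hourly step the agent proposes K candidate steps (gamma length,
  wrapped-normal turn) and picks one with probability proportional to
  exp(x' beta) of the covariates at the candidate endpoint, then GPS noise,
  elevation noise and fix dropout are applied.  Cleaning violations can be
  planted with a truth ledger.

Default coefficient signs follow the biology: movement away from steep
slopes, toward vegetation, habitat and moderate washes, away from road
proximity, along fences and berms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .features import LinearFeature
from .grid import Grid
from .landscape import DistanceTransformConfig, distance_grid, log_flatten, slope_from_dem
from .model import ModelSpec, StratumData

__all__ = [
    "LandscapeConfig",
    "TruthParams",
    "make_landscape",
    "simulate_strata",
    "simulate_design",
    "simulate_telemetry",
]

FULL_MODEL_TERMS = [
    "slope", "slope^2", "wash", "wash^2", "veg", "veg^2", "habitat",
    "road", "fence", "floodcontrol", "rail",
]


@dataclass
class LandscapeConfig:
    n_rows: int = 150
    n_cols: int = 150
    cell_size: float = 30.0
    origin_x: float = 600000.0
    origin_y: float = 3940000.0
    crs_tag: str = "EPSG:32611"
    smoothness: dict[str, float] = field(
        default_factory=lambda: {"veg": 6.0, "habitat": 10.0, "wash": 4.0, "dem": 12.0}
    )
    dem_base: float = 900.0
    dem_relief: float = 120.0
    ridge_amplitude: float = 250.0
    ridge_width_cells: float = 10.0
    seed: int = 0


@dataclass
class TruthParams:
    beta: dict[str, float] = field(
        default_factory=lambda: {
            "slope": -0.5, "slope^2": -0.25,
            "wash": 0.4, "wash^2": -0.2,
            "veg": 0.4, "veg^2": -0.15,
            "habitat": 0.5,
            "road": 0.4, "fence": -0.4, "floodcontrol": -0.3, "rail": -0.1,
        }
    )
    between_animal_sd: dict[str, float] = field(default_factory=dict)
    gamma_shape: float = 1.5
    gamma_scale: float = 30.0   # metres
    wn_mu: float = 0.0          # degrees
    wn_rho: float = 0.6
    gps_noise_sd: float = 8.0   # m, under the 10 m logger error budget
    elevation_noise_sd: float = 8.0
    fix_miss_prob: float = 0.15
    n_animals: int = 30
    season: tuple[int, int] = (4, 10)
    k_candidates: int = 20

    @property
    def wn_sd_rad(self) -> float:
        return float(np.sqrt(-2.0 * np.log(self.wn_rho)))


def _random_field(shape, sigma, rng) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def make_landscape(cfg: LandscapeConfig | None = None):
    """Named covariate grids plus linear features, deterministic per seed.

    Returns (grids, features): grids holds dem, slope, wash, veg, habitat
    and the log-flattened distance rasters road/fence/floodcontrol/rail.
    """
    cfg = cfg or LandscapeConfig()
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_rows, cfg.n_cols)
    tmpl = Grid(
        np.zeros(shape), origin_x=cfg.origin_x, origin_y=cfg.origin_y,
        cell_size=cfg.cell_size, crs_tag=cfg.crs_tag,
    )
    # DEM: smooth base + a north-south mountain ridge near the east edge
    base = _random_field(shape, cfg.smoothness["dem"], rng)
    cols = np.arange(cfg.n_cols)
    ridge_col = 0.8 * cfg.n_cols
    ridge = np.exp(-(((cols - ridge_col) / cfg.ridge_width_cells) ** 2))
    dem_vals = cfg.dem_base + cfg.dem_relief * base + cfg.ridge_amplitude * ridge[None, :]
    dem = tmpl.like(dem_vals)
    slope = slope_from_dem(dem)
    veg = tmpl.like(np.clip(0.3 + 0.15 * _random_field(shape, cfg.smoothness["veg"], rng), 0, None))
    habitat = tmpl.like(1.0 / (1.0 + np.exp(-_random_field(shape, cfg.smoothness["habitat"], rng))))
    wash = tmpl.like(20.0 * np.clip(_random_field(shape, cfg.smoothness["wash"], rng) + 0.5, 0, None))

    xmin, ymin, xmax, ymax = tmpl.bounds
    w = xmax - xmin
    h = ymax - ymin
    features = [
        LinearFeature("road", [[xmin + 0.30 * w, ymin], [xmin + 0.33 * w, ymax]], id="road-1"),
        LinearFeature("fence", [[xmin + 0.60 * w, ymin + 0.1 * h], [xmin + 0.60 * w, ymin + 0.9 * h]], id="fence-1"),
        LinearFeature(
            "floodcontrol",
            [[xmin + 0.15 * w, ymin + 0.70 * h], [xmin + 0.28 * w, ymin + 0.72 * h]],
            id="berm-1",
        ),
        LinearFeature("rail", [[xmin, ymin + 0.85 * h], [xmax, ymin + 0.80 * h]], id="rail-1"),
    ]
    dcfg = DistanceTransformConfig()
    grids = {"dem": dem, "slope": slope, "wash": wash, "veg": veg, "habitat": habitat}
    for ftype in ("road", "fence", "floodcontrol", "rail"):
        grids[ftype] = log_flatten(distance_grid(features, tmpl, ftype), dcfg)
    return grids, features


# ---------------------------------------------------------------------------
# direct likelihood-level generators


def simulate_strata(
    beta: np.ndarray,
    n_strata: int,
    n_random: int = 10,
    seed: int = 0,
    n_animals: int = 20,
    between_sd: np.ndarray | None = None,
    terms: list[str] | None = None,
) -> tuple[StratumData, dict]:
    """Choice sets drawn exactly from the conditional-logistic model.

    Covariates are iid standard normal; the observed row is drawn with
    probability proportional to exp(x' beta_animal), where beta_animal =
    beta + a per-animal normal deviation (sd ``between_sd``, default 0).
    Returns fit-ready strata plus a truth record.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    P = len(beta)
    terms = terms or [f"x{i + 1}" for i in range(P)]
    M = 1 + n_random
    X = rng.standard_normal((n_strata, M, P))
    animals = rng.integers(0, n_animals, size=n_strata)
    sd = np.zeros(P) if between_sd is None else np.asarray(between_sd, dtype=float)
    dev = rng.standard_normal((n_animals, P)) * sd
    beta_a = beta[None, :] + dev
    eta = np.einsum("smp,sp->sm", X, beta_a[animals])
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.uniform(size=n_strata)
    obs = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    labels = [f"a{i}" for i in range(n_animals)]
    strata = StratumData(
        X=X, obs_idx=obs, animal_codes=animals, animal_labels=labels,
        terms=terms, stratum_ids=[f"s{i}" for i in range(n_strata)],
    )
    truth = {"beta": beta, "between_sd": sd, "beta_by_animal": beta_a}
    return strata, truth


def simulate_design(
    truth: TruthParams,
    n_strata: int,
    n_random: int = 10,
    seed: int = 0,
    n_animals: int = 20,
) -> pd.DataFrame:
    """Design-table analogue of :func:`simulate_strata` for the model
    ladder: base covariates are iid standard normal per path-row and the
    observed row follows the full generating model (quadratics included)."""
    rng = np.random.default_rng(seed)
    bases = ["slope", "wash", "veg", "habitat", "road", "fence", "floodcontrol", "rail"]
    M = 1 + n_random
    Z = rng.standard_normal((n_strata, M, len(bases)))
    cols = {b: Z[:, :, i] for i, b in enumerate(bases)}
    eta = np.zeros((n_strata, M))
    for term, b in truth.beta.items():
        if term.endswith("^2"):
            eta += b * cols[term[:-2]] ** 2
        elif ":" in term:
            a, c = term.split(":")
            eta += b * cols[a] * cols[c]
        else:
            eta += b * cols[term]
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.uniform(size=n_strata)
    obs = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    animals = rng.integers(0, n_animals, size=n_strata)
    rows = []
    for s in range(n_strata):
        for m in range(M):
            rows.append(
                {
                    "stratum_id": f"s{s}",
                    "animal_id": f"a{animals[s]}",
                    "role": "observed" if m == obs[s] else "random",
                    **{b: Z[s, m, i] for i, b in enumerate(bases)},
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# agent-based telemetry


def simulate_telemetry(
    landscape,
    truth: TruthParams | None = None,
    seed: int = 0,
    n_animals: int | None = None,
    season: tuple[int, int] | None = None,
    year: int = 2017,
    n_spike_violations: int = 0,
    n_elevation_violations: int = 0,
):
    """Hourly GPS fixes for habitat-selecting agents on a landscape.

    ``landscape`` is the (grids, features) pair from :func:`make_landscape`
    (features are unused here; selection acts through the distance rasters).
    Selection operates on z-scored covariate values at the K candidate-step
    endpoints.  Returns (fixes DataFrame, ledger dict) where the ledger
    records per-animal coefficients and the planted violations that cleaning
    is expected to remove.
    """
    truth = truth or TruthParams()
    grids, _features = landscape if isinstance(landscape, tuple) else (landscape, [])
    rng = np.random.default_rng(seed)
    n_animals = n_animals if n_animals is not None else truth.n_animals
    season = season if season is not None else truth.season

    sel_names = sorted(
        {p for t in truth.beta for p in (t.split(":") if ":" in t else [t[:-2] if t.endswith("^2") else t])}
    )
    zgrids = {}
    for name in sel_names:
        v = grids[name].values
        m, s = np.nanmean(v), np.nanstd(v)
        zgrids[name] = (grids[name], m, s if s > 0 else 1.0)
    dem = grids["dem"]
    xmin, ymin, xmax, ymax = dem.bounds

    # per-animal coefficients
    terms = list(truth.beta)
    beta = np.array([truth.beta[t] for t in terms])
    sd = np.array([truth.between_animal_sd.get(t, 0.0) for t in terms])
    beta_animals = beta[None, :] + rng.standard_normal((n_animals, len(terms))) * sd

    start = pd.Timestamp(f"{year}-{season[0]:02d}-01 06:00:00")
    end = pd.Timestamp(f"{year}-{season[1]:02d}-28 23:00:00")
    times = pd.date_range(start, end, freq="h")
    K = truth.k_candidates

    pad = 0.1
    pos = np.column_stack(
        [
            rng.uniform(xmin + pad * (xmax - xmin), xmax - pad * (xmax - xmin), n_animals),
            rng.uniform(ymin + pad * (ymax - ymin), ymax - pad * (ymax - ymin), n_animals),
        ]
    )
    heading = rng.uniform(0, 2 * np.pi, n_animals)
    sd_turn = truth.wn_sd_rad
    mu_turn = np.radians(truth.wn_mu)

    def utilities(pts: np.ndarray) -> np.ndarray:
        """x' beta_animal at candidate endpoints; (A, K)."""
        u = np.zeros(pts.shape[:2])
        zcache = {}
        for name, (g, m, s) in zgrids.items():
            zcache[name] = (g.sample_nearest(pts[..., 0], pts[..., 1]) - m) / s
        for j, t in enumerate(terms):
            if t.endswith("^2"):
                val = zcache[t[:-2]] ** 2
            elif ":" in t:
                a, c = t.split(":")
                val = zcache[a] * zcache[c]
            else:
                val = zcache[t]
            u += beta_animals[:, j][:, None] * np.nan_to_num(val)
        return u

    recs_x = np.empty((len(times), n_animals))
    recs_y = np.empty((len(times), n_animals))
    for ti in range(len(times)):
        turns = mu_turn + sd_turn * rng.standard_normal((n_animals, K))
        bearings = heading[:, None] + turns
        # cap below the 300 m/hr locomotion limit so that true movement plus
        # GPS noise on both fix ends cannot mimic an impossible speed
        lengths = np.minimum(
            rng.gamma(truth.gamma_shape, truth.gamma_scale, (n_animals, K)), 240.0
        )
        cand = pos[:, None, :] + np.stack(
            [lengths * np.sin(bearings), lengths * np.cos(bearings)], axis=-1
        )
        inside = (
            (cand[..., 0] >= xmin) & (cand[..., 0] < xmax)
            & (cand[..., 1] > ymin) & (cand[..., 1] <= ymax)
        )
        u = utilities(cand)
        u = np.where(inside, u, -1e9)
        u -= u.max(axis=1, keepdims=True)
        p = np.exp(u)
        p /= p.sum(axis=1, keepdims=True)
        pick = (p.cumsum(axis=1) < rng.uniform(size=(n_animals, 1))).sum(axis=1)
        any_inside = inside.any(axis=1)
        idx = np.arange(n_animals)
        new_pos = np.where(any_inside[:, None], cand[idx, pick], pos)
        heading = np.where(any_inside, bearings[idx, pick], heading)
        pos = new_pos
        recs_x[ti] = pos[:, 0]
        recs_y[ti] = pos[:, 1]

    rows = []
    for a in range(n_animals):
        keep = rng.uniform(size=len(times)) >= truth.fix_miss_prob
        x = recs_x[keep, a] + rng.standard_normal(keep.sum()) * truth.gps_noise_sd
        y = recs_y[keep, a] + rng.standard_normal(keep.sum()) * truth.gps_noise_sd
        elev = dem.sample_nearest(x, y) + rng.standard_normal(keep.sum()) * truth.elevation_noise_sd
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": f"t{a:03d}",
                    "timestamp": times[keep],
                    "x": x,
                    "y": y,
                    "elev": elev,
                }
            )
        )
    fixes = pd.concat(rows, ignore_index=True)

    ledger: dict = {
        "terms": terms,
        "beta": beta,
        "beta_by_animal": beta_animals,
        "spike_fix_ids": [],
        "elevation_fix_ids": [],
    }
    # planted violations: super-speed mislocations and altimetry blunders.
    # Planted indices are interior fixes with short (<= 2 h) gaps to both
    # neighbours and pairwise separation >= 3, so each violation is isolated
    # and its expected removal set is exactly the planted set.
    n_plant = n_spike_violations + n_elevation_violations
    if n_plant:
        same_prev = fixes["animal_id"].eq(fixes["animal_id"].shift(1))
        same_next = fixes["animal_id"].eq(fixes["animal_id"].shift(-1))
        gap_prev = fixes["timestamp"].diff().dt.total_seconds() / 3600.0
        gap_next = (-fixes["timestamp"].diff(-1)).dt.total_seconds() / 3600.0
        ok = (same_prev & same_next & (gap_prev <= 2.0) & (gap_next <= 2.0)).to_numpy()
        pool = np.nonzero(ok)[0]
        rng.shuffle(pool)
        chosen: list[int] = []
        for i in pool:
            if len(chosen) >= n_plant:
                break
            if all(abs(i - j) >= 3 for j in chosen):
                chosen.append(int(i))
        if len(chosen) < n_plant:
            raise ValueError("telemetry too short to plant the requested violations")
        for i in chosen[:n_spike_violations]:
            resid = fixes.loc[i, "elev"] - dem.sample_nearest(fixes.loc[i, "x"], fixes.loc[i, "y"])
            fixes.loc[i, "x"] = fixes.loc[i, "x"] + 800.0  # both legs >> 300 m/hr
            # keep the elevation residual unchanged so the displaced fix is
            # caught by the speed screen, not the elevation screen
            new_dem = dem.sample_nearest(fixes.loc[i, "x"], fixes.loc[i, "y"])
            if np.isfinite(new_dem) and np.isfinite(resid):
                fixes.loc[i, "elev"] = new_dem + resid
            ledger["spike_fix_ids"].append(i)
        for i in chosen[n_spike_violations:]:
            fixes.loc[i, "elev"] = fixes.loc[i, "elev"] + 60.0  # residual >> 25 m
            ledger["elevation_fix_ids"].append(i)
    return fixes, ledger
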