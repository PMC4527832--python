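"""Seeded synthetic watersheds with the statistical structure the
vulnerability pipeline assumes.

The generator stands in for the GIS stack a regional application would use
(flow-routed elevation models, gridded climate normals, soil and geology
surveys).  It emulates the features the downstream stages rely on:

* dendritic topology built as a random binary-merge tree over headwater
  catchments of at least 0.5 km^2, with incremental drainage areas drawn
  from a log-normal calibrated to mean 0.9 / median 0.7 km^2;
* July mean daily maximum air temperature (JMMAT) declining with elevation
  at a lapse rate, tightly enough that an elevation regression explains
  roughly 90 percent of its variance;
* acid neutralizing capacity (ANC) declining toward high-elevation
  headwaters and boosted by carbonate lithology, spanning the 50 and 300
  ueq/L thresholds;
* paired daily maximum air/stream temperature series in which stream
  temperature tracks air temperature with a site-specific coupling slope
  drawn from a truncated normal (mean 0.42, SD 0.15 on [0.02, 0.96]).

True generating parameters (site slopes, ANC surfaces) are returned
alongside the data so recovery tests need no re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sensitivity import DailyTemperatureSeries
from .stream_network import (
    COVARIATE_IDS,
    LITHOLOGY_IDS,
    Reach,
    StreamNetwork,
    compute_twi,
)

# Log-normal ln-scale parameters for incremental areas at the default
# 0.9 km^2 target mean.  Calibrated jointly with the 0.5 km^2 headwater
# floor (rejection sampling) so the mixture of truncated headwater and
# untruncated junction reaches hits mean ~0.9, median ~0.7, IQR ~0.47-1.09.
_AREA_LOG_MU = -0.7551
_AREA_LOG_SIGMA = 0.8526
_AREA_CALIB_MEAN = 0.9

# JMMAT lapse model: intercept at sea level and additive noise (deg C).
# The noise SD is set so an elevation regression on generated reaches has
# squared correlation near 0.92.
_JMMAT_SEA_LEVEL_C = 34.0
_JMMAT_NOISE_SD_C = 0.85

# Stream temperature anchor as air-water coupling -> 0: groundwater runs a
# couple of degrees above mean annual air temperature, hence declines with
# elevation like TANN does.
_GROUNDWATER_OFFSET_C = 2.0


@dataclass
class ANCProfile:
    """Monotone-decreasing-with-elevation mean ANC surface (ueq/L).

    mean ANC = anc_at_base + slope_per_m * (elevation - base elevation)
               + lithcar_coeff * percent carbonate lithology
    """

    anc_at_base_ueq_l: float = 470.0
    slope_per_m: float = -0.30
    lithcar_coeff: float = 1.5
    noise_sd_ueq_l: float = 40.0

    def __post_init__(self) -> None:
        if self.slope_per_m >= 0:
            raise ValueError("ANC must decline with elevation (slope < 0)")


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_headwaters: int = 5000
    target_incremental_area_km2: float = 0.9
    min_headwater_area_km2: float = 0.5
    elevation_range_m: tuple[float, float] = (200.0, 1700.0)
    beta_mean: float = 0.42
    beta_sd: float = 0.15
    beta_range: tuple[float, float] = (0.02, 0.96)
    noise_sd_stream_temp_C: float = 1.0
    jmmat_elevation_slope: float = -0.0065  # deg C per m, lapse rate
    anc_elevation_profile: ANCProfile = field(default_factory=ANCProfile)
    n_days: int = 92  # Jun 1 - Aug 31
    n_sites: int = 201
    n_forests: int = 3
    n_districts_per_forest: int = 3

    def __post_init__(self) -> None:
        if self.n_headwaters < 1:
            raise ValueError("n_headwaters must be a positive count")
        if self.min_headwater_area_km2 <= 0:
            raise ValueError("min_headwater_area_km2 must be > 0")
        if self.target_incremental_area_km2 <= 0:
            raise ValueError("target incremental area must be > 0")
        lo, hi = self.beta_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("beta_range must be within [0, 1] with lo < hi")
        if self.n_days < 2:
            raise ValueError("need at least 2 days of series")
        if self.noise_sd_stream_temp_C < 0:
            raise ValueError("noise SD must be nonnegative")
        if self.elevation_range_m[0] >= self.elevation_range_m[1]:
            raise ValueError("elevation range must be increasing")
        if self.jmmat_elevation_slope >= 0:
            raise ValueError("JMMAT must decline with elevation (slope < 0)")


# ----------------------------------------------------------------------
# topology
# ----------------------------------------------------------------------

def _draw_incremental_areas(
    rng: np.random.Generator, n: int, target: float, floor: float | None
) -> np.ndarray:
    mu = _AREA_LOG_MU + np.log(target / _AREA_CALIB_MEAN)
    areas = np.exp(rng.normal(mu, _AREA_LOG_SIGMA, n))
    if floor is not None:
        while True:
            bad = areas < floor
            if not bad.any():
                break
            areas[bad] = np.exp(rng.normal(mu, _AREA_LOG_SIGMA, int(bad.sum())))
    return areas


def _subtree_nodes(root: int, members: set[int], children: dict[int, list[int]]):
    out, stack = [], [root]
    while stack:
        v = stack.pop()
        out.append(v)
        stack.extend(c for c in children[v] if c in members)
    return out


def _carve(
    members: set[int], root: int, children: dict[int, list[int]], k: int
) -> list[set[int]]:
    """Split a rooted tree into k contiguous parts by detaching subtrees."""
    parts: list[set[int]] = []
    cur = set(members)
    k = min(k, len(cur))
    for i in range(k - 1):
        target = len(cur) / (k - i)
        sizes: dict[int, int] = {}
        for v in sorted(cur):  # deterministic order
            if v not in sizes:
                for node in reversed(_subtree_nodes(v, cur, children)):
                    sizes[node] = 1 + sum(
                        sizes[c] for c in children[node] if c in cur
                    )
        best, best_err = None, np.inf
        for v in sorted(cur):
            if v == root:
                continue
            err = abs(sizes[v] - target)
            if err < best_err:
                best, best_err = v, err
        if best is None:
            break
        sub = set(_subtree_nodes(best, cur, children))
        parts.append(sub)
        cur -= sub
    parts.append(cur)
    return parts


def generate_network(config: GeneratorConfig) -> StreamNetwork:
    """Random binary-merge dendritic network with management-unit labels.

    Headwater catchments are merged pairwise downstream until a single
    outlet remains, giving ``2 * n_headwaters - 1`` reaches.  Contributing
    areas are accumulated exactly; national-forest and ranger-district
    labels are assigned by carving the tree into contiguous subtrees.
    """
    rng = np.random.default_rng(config.seed)
    h = config.n_headwaters
    n_total = 2 * h - 1

    incr = np.empty(n_total)
    incr[:h] = _draw_incremental_areas(
        rng, h, config.target_incremental_area_km2, config.min_headwater_area_km2
    )
    if h > 1:
        incr[h:] = _draw_incremental_areas(
            rng, h - 1, config.target_incremental_area_km2, None
        )

    downstream = np.full(n_total, -1, dtype=int)
    active = list(range(h))
    next_id = h
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        downstream[a] = next_id
        downstream[b] = next_id
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(next_id)
        next_id += 1
    root = active[0]

    children: dict[int, list[int]] = {i: [] for i in range(n_total)}
    for i in range(n_total):
        if downstream[i] >= 0:
            children[downstream[i]].append(i)

    # contributing areas by post-order accumulation
    contrib = incr.copy()
    order: list[int] = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(children[v])
    for v in reversed(order):
        contrib[v] = incr[v] + sum(contrib[c] for c in children[v])

    # elevation from topological depth (edges to outlet), descending
    # toward the outlet.  Depths are mapped through their empirical ranks
    # (random tie-breaking within a depth class) so elevations spread
    # uniformly over the configured range while staying monotone in depth.
    depth = np.zeros(n_total)
    for v in order:  # order is root-first, so parent depth is ready
        if downstream[v] >= 0:
            depth[v] = depth[downstream[v]] + 1
    emin, emax = config.elevation_range_m
    jitter = rng.uniform(0.0, 0.5, n_total)  # < 1, preserves depth order
    rel = np.argsort(np.argsort(depth + jitter)) / max(n_total - 1, 1)
    elevation = emin + (emax - emin) * rel

    length = 1.6 * np.sqrt(incr) * np.exp(rng.normal(0.0, 0.25, n_total))

    # contiguous-subtree management units: forests first, districts nested
    unit_forest = np.empty(n_total, dtype=object)
    unit_district = np.empty(n_total, dtype=object)
    forest_parts = _carve(set(range(n_total)), root, children, config.n_forests)
    for fi, fpart in enumerate(forest_parts, start=1):
        fname = f"F{fi}"
        # local root: the member whose downstream is outside the part
        local_root = next(
            v for v in sorted(fpart)
            if downstream[v] < 0 or downstream[v] not in fpart
        )
        d_parts = _carve(fpart, local_root, children, config.n_districts_per_forest)
        for di, dpart in enumerate(d_parts, start=1):
            for v in dpart:
                unit_forest[v] = fname
                unit_district[v] = f"{fname}-D{di}"

    reaches = [
        Reach(
            reach_id=i,
            downstream_id=None if downstream[i] < 0 else int(downstream[i]),
            length_km=float(length[i]),
            incremental_area_km2=float(incr[i]),
            contributing_area_km2=float(contrib[i]),
            elevation_m=float(elevation[i]),
            unit_forest=str(unit_forest[i]),
            unit_district=str(unit_district[i]),
        )
        for i in range(n_total)
    ]
    return StreamNetwork(reaches)


# ----------------------------------------------------------------------
# covariates
# ----------------------------------------------------------------------

def generate_covariates(
    network: StreamNetwork, config: GeneratorConfig
) -> pd.DataFrame:
    """Populate every landscape covariate per reach.

    Returns a DataFrame indexed by reach id with all covariate columns and
    stores the same values on each reach's ``covariates`` mapping.  JMMAT
    declines with elevation at the configured lapse rate; lithology shares
    are drawn on a simplex so the five classes sum to at most 100 percent.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = sorted(network.reaches)
    n = len(ids)
    elev = np.array([network[i].elevation_m for i in ids])
    contrib = np.array([network[i].contributing_area_km2 for i in ids])
    incr = np.array([network[i].incremental_area_km2 for i in ids])
    length = np.array([network[i].length_km for i in ids])

    cov = pd.DataFrame(index=pd.Index(ids, name="reach_id"))
    cov["JMMAT"] = (
        _JMMAT_SEA_LEVEL_C
        + config.jmmat_elevation_slope * elev
        + rng.normal(0.0, _JMMAT_NOISE_SD_C, n)
    )
    cov["TANN"] = 18.0 - 0.0055 * elev + rng.normal(0.0, 0.5, n)
    cov["PPTANN"] = np.clip(
        1.0 + 4.0e-4 * elev + rng.normal(0.0, 0.08, n), 0.5, None
    )
    cov["PPTJUL"] = np.clip(
        0.10 + 3.0e-5 * elev + rng.normal(0.0, 0.012, n), 0.02, None
    )
    cov["RUNOFF"] = np.clip(
        0.45 * cov["PPTANN"] + rng.normal(0.0, 0.05, n), 0.05, None
    )

    cov["WSAREA"] = contrib
    cov["SLOPE"] = np.clip(
        28.0 - 3.0 * np.log(contrib) + rng.normal(0.0, 5.0, n), 0.5, 45.0
    )
    cov["BFI"] = np.clip(rng.normal(55.0, 12.0, n), 5.0, 95.0)
    cov["TWI"] = compute_twi(contrib, cov["SLOPE"].to_numpy())
    cov["DRAINDENS"] = (length * 1e3) / (incr * 1e6)

    lith = rng.dirichlet((2.0, 1.5, 2.0, 0.8, 1.0, 2.7), size=n) * 100.0
    for k, lid in enumerate(LITHOLOGY_IDS):
        cov[lid] = lith[:, k]
    cov["SOILCLAY"] = rng.uniform(5.0, 40.0, n)

    cov["FOREST"] = np.clip(rng.normal(85.0, 10.0, n), 1.0, 100.0)
    cov["FORESTRIP"] = np.clip(cov["FOREST"] + rng.normal(2.0, 5.0, n), 1.0, 100.0)
    cov["GRASS"] = np.clip(rng.normal(5.0, 5.0, n), 0.0, 100.0)
    cov["GRASSRIP"] = np.clip(rng.normal(4.0, 4.0, n), 0.0, 100.0)
    cov["CC"] = np.clip(rng.normal(75.0, 12.0, n), 1.0, 100.0)
    cov["CCRIP"] = np.clip(cov["CC"] + rng.normal(3.0, 6.0, n), 1.0, 100.0)
    cov["EVH"] = np.clip(rng.normal(20.0, 6.0, n), 0.5, 45.0)
    cov["EVHRIP"] = np.clip(cov["EVH"] + rng.normal(1.0, 3.0, n), 0.5, 45.0)

    cov["SOL57"] = np.clip(rng.normal(6.0e5, 5.0e4, n), 3.0e5, None)
    cov["SOL57FST"] = cov["SOL57"] / cov["FOREST"]
    cov["SOL57CC"] = cov["SOL57"] / cov["CC"]
    cov["SOL57EVH"] = cov["SOL57"] / cov["EVH"]
    cov["SOL57RIP"] = np.clip(
        cov["SOL57"] * rng.normal(0.9, 0.05, n), 2.0e5, None
    )
    cov["SOL57FSTRIP"] = cov["SOL57RIP"] / cov["FORESTRIP"]
    cov["SOL57CCRIP"] = cov["SOL57RIP"] / cov["CCRIP"]
    cov["SOL57EVHRIP"] = cov["SOL57RIP"] / cov["EVHRIP"]

    cov = cov[list(COVARIATE_IDS)]
    for rid in ids:
        network[rid].covariates = {
            c: float(cov.at[rid, c]) for c in COVARIATE_IDS
        }
    return cov


# ----------------------------------------------------------------------
# ANC truth
# ----------------------------------------------------------------------

def generate_anc_truth(
    network: StreamNetwork, config: GeneratorConfig
) -> pd.Series:
    """True ANC (ueq/L) per reach, declining toward high-elevation
    headwaters and elevated where carbonate lithology is abundant.

    Requires covariates to have been generated (uses LITHCAR).  Values
    span the 50 and 300 ueq/L thresholds at default settings; acidified
    reaches may be negative.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    prof = config.anc_elevation_profile
    ids = sorted(network.reaches)
    elev = np.array([network[i].elevation_m for i in ids])
    lithcar = np.array(
        [network[i].covariates.get("LITHCAR", 0.0) for i in ids]
    )
    emin = config.elevation_range_m[0]
    mean = (
        prof.anc_at_base_ueq_l
        + prof.slope_per_m * (elev - emin)
        + prof.lithcar_coeff * lithcar
    )
    anc = mean + rng.normal(0.0, prof.noise_sd_ueq_l, len(ids))
    return pd.Series(anc, index=pd.Index(ids, name="reach_id"), name="anc_ueq_l")


# ----------------------------------------------------------------------
# daily air/stream temperature series
# ----------------------------------------------------------------------

def generate_daily_series(
    network: StreamNetwork, config: GeneratorConfig
) -> tuple[list[DailyTemperatureSeries], pd.DataFrame]:
    """Paired daily MDAT/MDST series for a uniform sample of reaches.

    Per site: MDST_t = beta * MDAT_t + intercept + noise, with beta drawn
    from a truncated normal on ``beta_range`` and the intercept anchored
    to a groundwater temperature so weakly coupled streams stay cold.
    Returns the series plus a truth table (site_id, reach_id, beta_true,
    intercept_true) for recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    ids = sorted(network.reaches)
    n_sites = min(config.n_sites, len(ids))
    site_reaches = rng.choice(ids, size=n_sites, replace=False)

    lo, hi = config.beta_range
    a = (lo - config.beta_mean) / config.beta_sd
    b = (hi - config.beta_mean) / config.beta_sd
    betas = stats.truncnorm.rvs(
        a, b, loc=config.beta_mean, scale=config.beta_sd,
        size=n_sites, random_state=rng,
    )

    dates = pd.date_range("2012-06-01", periods=config.n_days, freq="D")
    t = np.arange(config.n_days)
    seasonal = 4.0 * np.sin(np.pi * t / max(config.n_days - 1, 1))

    series: list[DailyTemperatureSeries] = []
    rows = []
    for sid, (rid, beta) in enumerate(zip(site_reaches, betas)):
        reach = network[int(rid)]
        base = reach.covariates.get(
            "JMMAT",
            _JMMAT_SEA_LEVEL_C + config.jmmat_elevation_slope * reach.elevation_m,
        )
        groundwater = (
            reach.covariates.get("TANN", 18.0 - 0.0055 * reach.elevation_m)
            + _GROUNDWATER_OFFSET_C
        )
        mdat = base + seasonal + rng.normal(0.0, 2.0, config.n_days)
        intercept = (1.0 - beta) * groundwater
        mdst = (
            beta * mdat
            + intercept
            + rng.normal(0.0, config.noise_sd_stream_temp_C, config.n_days)
        )
        series.append(
            DailyTemperatureSeries(
                site_id=sid, dates=dates, mdat_c=mdat, mdst_c=mdst
            )
        )
        rows.append(
            {
                "site_id": sid,
                "reach_id": int(rid),
                "beta_true": float(beta),
                "intercept_true": float(intercept),
            }
        )
    return series, pd.DataFrame(rows)


def series_to_frame(series: Sequence[DailyTemperatureSeries]) -> pd.DataFrame:
    """Long-format daily series table (site_id, date, mdat_c, mdst_c)."""
    frames = [
        pd.DataFrame(
            {
                "site_id": s.site_id,
                "date": pd.DatetimeIndex(s.dates).strftime("%Y-%m-%d"),
                "mdat_c": s.mdat_c,
                "mdst_c": s.mdst_c,
            }
        )
        for s in series
    ]
    return pd.concat(frames, ignore_index=True)


def series_from_frame(df: pd.DataFrame) -> list[DailyTemperatureSeries]:
    out = []
    for sid, grp in df.groupby("site_id", sort=True):
        out.append(
            DailyTemperatureSeries(
                site_id=int(sid),
                dates=pd.DatetimeIndex(pd.to_datetime(grp["date"])),
                mdat_c=grp["mdat_c"].to_numpy(dtype=float),
                mdst_c=grp["mdst_c"].to_numpy(dtype=float),
            )
        )
    return out
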