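"""Dendritic stream-network data model and accounting primitives.

A stream network is a forest of rooted trees: every reach drains to exactly
one downstream reach or is an outlet.  Each reach carries its own incremental
drainage area (the new catchment area gained moving downstream past the last
junction) and the contributing area accumulated over its upstream closure.
Reaches are the unit of analysis for temperature, acid-base chemistry, and
habitat accounting, and are tagged with the nested management units
(national forest / ranger district) over which stream lengths are summarized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

#: Landscape covariate vocabulary (climate, hydrogeomorphology, lithology,
#: soils, vegetation, and solar radiation watershed summaries).
COVARIATE_IDS: tuple[str, ...] = (
    "PPTANN", "PPTJUL", "TANN", "JMMAT", "RUNOFF",
    "WSAREA", "SLOPE", "BFI", "TWI", "DRAINDENS",
    "LITHSIL", "LITHARG", "LITHFEL", "LITHMAF", "LITHCAR",
    "SOILCLAY",
    "FOREST", "FORESTRIP", "GRASS", "GRASSRIP",
    "CC", "CCRIP", "EVH", "EVHRIP",
    "SOL57", "SOL57FST", "SOL57CC", "SOL57EVH",
    "SOL57RIP", "SOL57FSTRIP", "SOL57CCRIP", "SOL57EVHRIP",
)

LITHOLOGY_IDS: tuple[str, ...] = (
    "LITHSIL", "LITHARG", "LITHFEL", "LITHMAF", "LITHCAR",
)


class NetworkValidationError(ValueError):
    """Raised for topological defects that make a network unusable."""


@dataclass
class Reach:
    """One stream segment with its incremental watershed attributes."""

    reach_id: int
    downstream_id: int | None
    length_km: float
    incremental_area_km2: float
    contributing_area_km2: float
    elevation_m: float
    unit_forest: str
    unit_district: str
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_km < 0:
            raise ValueError(f"reach {self.reach_id}: negative length")
        if self.incremental_area_km2 <= 0:
            raise ValueError(f"reach {self.reach_id}: non-positive incremental area")
        unknown = set(self.covariates) - set(COVARIATE_IDS)
        if unknown:
            raise ValueError(
                f"reach {self.reach_id}: unknown covariate ids {sorted(unknown)}"
            )


class StreamNetwork:
    """A forest of reaches linked by ``downstream_id``."""

    def __init__(self, reaches: Iterable[Reach]):
        self.reaches: dict[int, Reach] = {}
        for r in reaches:
            if r.reach_id in self.reaches:
                raise NetworkValidationError(f"duplicate reach id {r.reach_id}")
            self.reaches[r.reach_id] = r

    def __len__(self) -> int:
        return len(self.reaches)

    def __iter__(self):
        return iter(self.reaches.values())

    def __getitem__(self, reach_id: int) -> Reach:
        return self.reaches[reach_id]

    @property
    def outlets(self) -> set[int]:
        return {r.reach_id for r in self if r.downstream_id is None}

    def upstream_index(self) -> dict[int, list[int]]:
        """Map each reach id to the ids draining directly into it."""
        idx: dict[int, list[int]] = {rid: [] for rid in self.reaches}
        for r in self:
            if r.downstream_id is not None and r.downstream_id in idx:
                idx[r.downstream_id].append(r.reach_id)
        return idx

    def headwaters(self) -> set[int]:
        idx = self.upstream_index()
        return {rid for rid, ups in idx.items() if not ups}

    # ------------------------------------------------------------------
    # table round-trip
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self:
            row = {
                "reach_id": r.reach_id,
                "downstream_id": -1 if r.downstream_id is None else r.downstream_id,
                "length_km": r.length_km,
                "incr_area_km2": r.incremental_area_km2,
                "contrib_area_km2": r.contributing_area_km2,
                "elevation_m": r.elevation_m,
                "unit_forest": r.unit_forest,
                "unit_district": r.unit_district,
            }
            row.update(r.covariates)
            rows.append(row)
        return pd.DataFrame(rows).sort_values("reach_id").reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StreamNetwork":
        cov_cols = [c for c in df.columns if c in COVARIATE_IDS]
        reaches = []
        for rec in df.to_dict("records"):
            ds = int(rec["downstream_id"])
            reaches.append(
                Reach(
                    reach_id=int(rec["reach_id"]),
                    downstream_id=None if ds < 0 else ds,
                    length_km=float(rec["length_km"]),
                    incremental_area_km2=float(rec["incr_area_km2"]),
                    contributing_area_km2=float(rec["contrib_area_km2"]),
                    elevation_m=float(rec["elevation_m"]),
                    unit_forest=str(rec["unit_forest"]),
                    unit_district=str(rec["unit_district"]),
                    covariates={c: float(rec[c]) for c in cov_cols},
                )
            )
        return cls(reaches)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "StreamNetwork":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class NetworkDiagnostics:
    """Outcome of :func:`validate`."""

    n_reaches: int
    n_outlets: int
    dangling: list[int]
    conservation_violations: list[int]

    @property
    def ok(self) -> bool:
        return not self.dangling and not self.conservation_violations


def validate(network: StreamNetwork, atol: float = 1e-6) -> NetworkDiagnostics:
    """Check a network for cycles, dangling links, and area conservation.

    Cycles are a hard failure (raises :class:`NetworkValidationError` naming
    a reach on the cycle); dangling downstream links and contributing areas
    that do not equal the sum of upstream incremental areas are reported in
    the returned diagnostics.
    """
    g = nx.DiGraph()
    g.add_nodes_from(network.reaches)
    dangling = []
    for r in network:
        if r.downstream_id is None:
            continue
        if r.downstream_id == r.reach_id:
            raise NetworkValidationError(
                f"cycle detected at reach {r.reach_id} (self link)"
            )
        if r.downstream_id not in network.reaches:
            dangling.append(r.reach_id)
        else:
            g.add_edge(r.reach_id, r.downstream_id)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise NetworkValidationError(f"cycle detected at reach {cycle[0][0]}")

    expected = accumulate_area(network)
    violations = [
        rid
        for rid, area in expected.items()
        if not math.isclose(network[rid].contributing_area_km2, area, abs_tol=atol,
                            rel_tol=1e-9)
    ]
    return NetworkDiagnostics(
        n_reaches=len(network),
        n_outlets=len(network.outlets),
        dangling=sorted(dangling),
        conservation_violations=sorted(violations),
    )


def accumulate_area(network: StreamNetwork) -> dict[int, float]:
    """Contributing area per reach: its own incremental area plus the
    incremental areas of every reach upstream of it (topological sweep)."""
    idx = network.upstream_index()
    area: dict[int, float] = {}

    for root in network.outlets | {
        r.reach_id for r in network
        if r.downstream_id is not None and r.downstream_id not in network.reaches
    }:
        # iterative post-order to survive deep chains
        stack = [(root, False)]
        while stack:
            rid, done = stack.pop()
            if done:
                area[rid] = network[rid].incremental_area_km2 + sum(
                    area[u] for u in idx[rid]
                )
            else:
                stack.append((rid, True))
                stack.extend((u, False) for u in idx[rid])
    return area


def compute_twi(contributing_area, slope_deg):
    """Topographic wetness index ln(a / tan(slope)).

    ``slope_deg`` values of exactly zero are replaced by 0.001 degrees to
    avoid division by zero.  Accepts scalars or arrays.
    """
    a = np.asarray(contributing_area, dtype=float)
    s = np.asarray(slope_deg, dtype=float)
    if np.any(a <= 0):
        raise ValueError("contributing area must be positive")
    if np.any(s < 0):
        raise ValueError("slope must be nonnegative")
    s = np.where(s == 0, 0.001, s)
    out = np.log(a / np.tan(np.radians(s)))
    return float(out) if out.ndim == 0 else out


def length_by_category(
    network: StreamNetwork,
    category_map: Mapping[int, str],
    unit_level: str = "district",
) -> pd.DataFrame:
    """Sum reach lengths (km) by category within management units.

    ``unit_level`` is ``"forest"``, ``"district"``, or ``"all"`` (one row).
    Returns a unit x category table with a ``TOTAL`` row equal to the column
    sums.  Every reach must be categorized.
    """
    missing = [r.reach_id for r in network if r.reach_id not in category_map]
    if missing:
        raise ValueError(f"uncategorized reaches: {missing[:5]} ...")
    if unit_level not in ("forest", "district", "all"):
        raise ValueError(f"unknown unit level {unit_level!r}")

    def unit_of(r: Reach) -> str:
        if unit_level == "forest":
            return r.unit_forest
        if unit_level == "district":
            return r.unit_district
        return "ALL"

    df = pd.DataFrame(
        {
            "unit": [unit_of(r) for r in network],
            "category": [category_map[r.reach_id] for r in network],
            "length_km": [r.length_km for r in network],
        }
    )
    table = df.pivot_table(
        index="unit", columns="category", values="length_km",
        aggfunc="sum", fill_value=0.0,
    )
    table.loc["TOTAL"] = table.sum(axis=0)
    table.columns.name = None
    table.index.name = "unit"
    return table
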