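"""Study geography: region identifiers, planar coordinates, and adjacency.

A :class:`Geography` is the minimal spatial substrate the downstream models
need: an ordered list of region identifiers, a projected planar point (km) per
region, and a symmetric adjacency structure.  Islands that share no land
border are linked through ``extra_edges`` (ferry/bridge connections), so the
graph used by the spatially structured random effect is always connected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = ["Geography", "generate_lattice_geography"]


def _normalize_edges(edges: Iterable[tuple[str, str]]) -> frozenset[frozenset]:
    out = set()
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-edge on region {a!r}")
        out.add(frozenset((a, b)))
    return frozenset(out)


@dataclass(frozen=True)
class Geography:
    """Regions with planar coordinates and a connected adjacency graph.

    Parameters
    ----------
    region_ids
        Ordered region identifiers; the order fixes the index used by the
        adjacency matrix and by all model vectors.
    coords
        Mapping region id -> (x_km, y_km), projected planar coordinates.
    adjacency
        Unordered pairs of region ids sharing a border.
    extra_edges
        Additional unordered pairs (e.g. ferry or bridge links for islands).
    """

    region_ids: tuple[str, ...]
    coords: Mapping[str, tuple[float, float]]
    adjacency: frozenset = field(default_factory=frozenset)
    extra_edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        object.__setattr__(self, "coords", dict(self.coords))
        object.__setattr__(self, "adjacency", _normalize_edges(self.adjacency))
        object.__setattr__(self, "extra_edges", _normalize_edges(self.extra_edges))
        known = set(self.region_ids)
        if len(known) != len(self.region_ids):
            raise ValueError("duplicate region ids")
        missing = known - set(self.coords)
        if missing:
            raise ValueError(f"regions without coordinates: {sorted(missing)}")
        for edge in self.all_edges():
            for endpoint in edge:
                if endpoint not in known:
                    raise ValueError(f"edge endpoint {endpoint!r} is not a region")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def all_edges(self) -> frozenset:
        """Border edges united with the extra (island-link) edges."""
        return self.adjacency | self.extra_edges

    def index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.region_ids)}

    def coord_array(self) -> np.ndarray:
        """(n_regions, 2) array of coordinates in region order."""
        return np.array([self.coords[r] for r in self.region_ids], dtype=float)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        g.add_edges_from(tuple(e) for e in self.all_edges())
        return g

    def is_connected(self) -> bool:
        g = self.to_graph()
        return g.number_of_nodes() > 0 and nx.is_connected(g)

    def require_connected(self) -> None:
        if not self.is_connected():
            raise ValueError("geography graph is not connected (add extra_edges)")

    # ---------------------------------------------------------------- IO ---

    def to_geojson(self) -> dict:
        """Point FeatureCollection (one feature per region)."""
        features = []
        for rid in self.region_ids:
            x, y = self.coords[rid]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [x, y]},
                    "properties": {"region_id": rid},
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def adjacency_sidecar(self) -> dict:
        as_lists = lambda edges: sorted(sorted(e) for e in edges)
        return {
            "region_ids": list(self.region_ids),
            "adjacency": as_lists(self.adjacency),
            "extra_edges": as_lists(self.extra_edges),
        }

    def write(self, geojson_path: str | Path, adjacency_path: str | Path) -> None:
        Path(geojson_path).write_text(json.dumps(self.to_geojson(), indent=1))
        Path(adjacency_path).write_text(json.dumps(self.adjacency_sidecar(), indent=1))

    @classmethod
    def read(cls, geojson_path: str | Path, adjacency_path: str | Path) -> "Geography":
        gj = json.loads(Path(geojson_path).read_text())
        side = json.loads(Path(adjacency_path).read_text())
        coords = {}
        for feat in gj["features"]:
            rid = feat["properties"]["region_id"]
            x, y = feat["geometry"]["coordinates"]
            coords[rid] = (float(x), float(y))
        return cls(
            region_ids=tuple(side["region_ids"]),
            coords=coords,
            adjacency=frozenset(frozenset(e) for e in side["adjacency"]),
            extra_edges=frozenset(frozenset(e) for e in side["extra_edges"]),
        )


def generate_lattice_geography(
    n_rows: int, n_cols: int, cell_km: float, seed: int = 0
) -> Geography:
    """Rook-adjacency rectangular lattice of ``n_rows * n_cols`` regions.

    Region coordinates sit at cell centers spaced ``cell_km`` apart; the
    construction is deterministic (``seed`` is accepted for interface
    uniformity with the stochastic generators).
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("lattice dimensions must be positive")
    if n_rows * n_cols < 2:
        raise ValueError("need at least 2 regions")
    width = len(str(n_rows * n_cols))
    ids = []
    coords = {}
    for r in range(n_rows):
        for c in range(n_cols):
            rid = f"R{r * n_cols + c + 1:0{width}d}"
            ids.append(rid)
            coords[rid] = ((c + 0.5) * cell_km, (r + 0.5) * cell_km)
    edges = set()
    for r in range(n_rows):
        for c in range(n_cols):
            here = ids[r * n_cols + c]
            if c + 1 < n_cols:
                edges.add(frozenset((here, ids[r * n_cols + c + 1])))
            if r + 1 < n_rows:
                edges.add(frozenset((here, ids[(r + 1) * n_cols + c])))
    return Geography(region_ids=tuple(ids), coords=coords, adjacency=frozenset(edges))
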