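"""Kulldorff spatial scan statistic with the Bernoulli probability model.

Case/non-case points at projected planar (km) coordinates are scanned with
circular windows centred on each point, growing through the ordered
inter-point distances and truncated at a window constraint (a maximum
fraction of the population, or a maximum radius; the study's four presets
are 5%, 10%, 5 km and 10 km).  Only high-risk windows are scored (the
log-likelihood ratio is set to zero unless the rate inside exceeds the rate
outside).  Significance comes from Monte Carlo replication: case labels are
permuted over the fixed locations, conditioning on the numbers of cases and
points, and each cluster's p-value is the rank of its LLR among the
replicate maxima, p = (1 + #{max_rep >= llr}) / (1 + n_reps).

The numerical core exploits that the Bernoulli LLR depends only on the
window size n and its case count c: a (n, c) lookup table makes scanning a
replicate a cumulative sum plus a table gather.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

__all__ = [
    "LabeledPoint",
    "ScanWindowSpec",
    "ScanCluster",
    "bernoulli_llr",
    "candidate_windows",
    "scan",
    "report_clusters",
    "stratified_scan",
]


def _max_llr_batch_numpy(order, valid, labels, table):
    """Max window LLR per labeling (vectorized fallback)."""
    n_batch = labels.shape[0]
    C = table.shape[1] - 1
    kcap = order.shape[1]
    offsets = np.arange(1, kcap + 1) * (C + 1)
    best = np.zeros(n_batch)
    for i in range(order.shape[0]):
        c_in = np.cumsum(labels[:, order[i]], axis=1, dtype=np.int64)
        vals = np.take(table, c_in + offsets[None, :])
        vals *= valid[i]
        best = np.maximum(best, vals.max(axis=1))
    return best


try:  # tight scan loop: ~N^2 table lookups per replicate
    from numba import njit

    @njit(cache=False)
    def _max_llr_batch(order, valid, labels, table):
        n_batch = labels.shape[0]
        n, kcap = order.shape
        out = np.empty(n_batch)
        for b in range(n_batch):
            lab = labels[b]
            best = 0.0
            for i in range(n):
                c = 0
                row = order[i]
                ok = valid[i]
                for k in range(kcap):
                    c += lab[row[k]]
                    if ok[k]:
                        val = table[k + 1, c]
                        if val > best:
                            best = val
            out[b] = best
        return out

except ImportError:  # pragma: no cover - numba is an optional accelerator
    _max_llr_batch = _max_llr_batch_numpy


@dataclass(frozen=True)
class LabeledPoint:
    x_km: float
    y_km: float
    is_case: bool
    person_id: str | None = None


@dataclass(frozen=True)
class ScanWindowSpec:
    """Search-window constraint: exactly one of fraction or radius is set."""

    max_fraction: float | None = None
    max_radius_km: float | None = None

    def __post_init__(self):
        if (self.max_fraction is None) == (self.max_radius_km is None):
            raise ValueError("set exactly one of max_fraction / max_radius_km")
        if self.max_fraction is not None and not (0 < self.max_fraction <= 0.5):
            raise ValueError("max_fraction must lie in (0, 0.5]")
        if self.max_radius_km is not None and self.max_radius_km <= 0:
            raise ValueError("max_radius_km must be positive")

    @classmethod
    def preset(cls, name: str) -> "ScanWindowSpec":
        presets = {
            "frac5": cls(max_fraction=0.05),
            "frac10": cls(max_fraction=0.10),
            "km5": cls(max_radius_km=5.0),
            "km10": cls(max_radius_km=10.0),
        }
        try:
            return presets[name]
        except KeyError:
            raise ValueError(f"unknown window preset {name!r} (choose from {sorted(presets)})")


@dataclass(frozen=True)
class ScanCluster:
    """One candidate or reported high-risk cluster."""

    center: tuple[float, float]
    radius_km: float
    n_in: int
    c_in: int
    C: int
    N: int
    llr: float
    p_value: float | None = None
    high_risk: bool = True


def bernoulli_llr(c_in: int, n_in: int, C: int, N: int) -> float:
    """Bernoulli-model log-likelihood ratio of one window (high-risk only).

    Compares the two-rate alternative (inside vs outside) to the single-rate
    null, with the 0*log(0) := 0 convention; returns 0 when the inside rate
    does not exceed the outside rate, so only high-risk windows rank.
    """
    if not (0 <= c_in <= n_in and c_in <= C and C <= N and n_in < N):
        raise ValueError("impossible window counts")
    c_out = C - c_in
    n_out = N - n_in
    if c_out < 0 or c_out > n_out:
        raise ValueError("impossible window counts")
    if c_in * n_out <= c_out * n_in:  # inside rate <= outside rate
        return 0.0
    ll_alt = (
        xlogy(c_in, c_in / n_in)
        + xlogy(n_in - c_in, 1 - c_in / n_in)
        + xlogy(c_out, c_out / n_out)
        + xlogy(n_out - c_out, 1 - c_out / n_out)
    )
    ll_null = xlogy(C, C / N) + xlogy(N - C, 1 - C / N)
    return float(ll_alt - ll_null)


def _as_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a DataFrame or LabeledPoint sequence to (xy, is_case)."""
    if isinstance(points, pd.DataFrame):
        xy = points[["x_km", "y_km"]].to_numpy(dtype=float)
        is_case = points["is_case"].to_numpy(dtype=bool)
    else:
        xy = np.array([(p.x_km, p.y_km) for p in points], dtype=float)
        is_case = np.array([p.is_case for p in points], dtype=bool)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates")
    return xy, is_case


class _ScanGeometry:
    """Precomputed candidate-window structure for a fixed point set."""

    def __init__(self, xy: np.ndarray, spec: ScanWindowSpec):
        n = len(xy)
        if n < 2:
            raise ValueError("need at least 2 points")
        diff = xy[:, None, :] - xy[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        order = np.argsort(dist, axis=1, kind="stable")
        sorted_d = np.take_along_axis(dist, order, axis=1)
        # a window size k+1 is a genuine candidate only at a unique-radius
        # boundary: duplicate radii collapse to the largest tied size
        boundary = np.empty((n, n), dtype=bool)
        boundary[:, :-1] = sorted_d[:, :-1] < sorted_d[:, 1:]
        boundary[:, -1] = True
        candidate = boundary.copy()
        if spec.max_radius_km is not None:
            candidate &= sorted_d <= spec.max_radius_km
        else:
            kmax = int(np.floor(spec.max_fraction * n))
            candidate[:, kmax:] = False
        # the all-points window is a geometric candidate but cannot be
        # scored (no outside population), so it is masked for the LLR
        scorable = candidate.copy()
        scorable[:, -1] = False
        kcap = int(np.max(np.nonzero(scorable.any(axis=0))[0])) + 1 if scorable.any() else 0
        self.n = n
        self.xy = xy
        self.full_order = order
        self.full_radii = sorted_d
        self.candidate = candidate
        self.order = order[:, :kcap]
        self.radii = sorted_d[:, :kcap]
        self.valid = scorable[:, :kcap]
        self.kcap = kcap

    def llr_table(self, C: int) -> np.ndarray:
        """(kcap+1, C+1) lookup of the one-sided Bernoulli LLR by (n, c)."""
        n = np.arange(self.kcap + 1, dtype=float)[:, None]
        c = np.arange(C + 1, dtype=float)[None, :]
        N = float(self.n)
        c_out = C - c
        n_out = N - n
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_alt = (
                xlogy(c, c) - xlogy(c, n)
                + xlogy(n - c, n - c) - xlogy(n - c, n)
                + xlogy(c_out, c_out) - xlogy(c_out, n_out)
                + xlogy(n_out - c_out, n_out - c_out) - xlogy(n_out - c_out, n_out)
            )
        ll_null = xlogy(C, C / N) + xlogy(N - C, 1 - C / N)
        table = ll_alt - ll_null
        low_risk = c * n_out <= c_out * n  # inside rate <= outside rate
        impossible = (c > n) | (c_out > n_out) | (n_out <= 0)
        table[low_risk | impossible] = 0.0
        table[~np.isfinite(table)] = 0.0
        return table

    def window_llrs(self, labels: np.ndarray, table: np.ndarray) -> np.ndarray:
        """(n_centers, kcap) LLR matrix for one labeling."""
        c_in = np.cumsum(labels[self.order], axis=1)
        sizes = np.arange(1, self.kcap + 1)
        vals = table[sizes[None, :], c_in]
        return np.where(self.valid, vals, 0.0)

    def replicate_maxima(
        self, rng: np.random.Generator, C: int, n_reps: int, table: np.ndarray
    ) -> np.ndarray:
        """Max LLR of each of ``n_reps`` random relabelings (C cases of N)."""
        if self.kcap == 0:
            return np.zeros(n_reps)
        out = np.empty(n_reps)
        batch = max(1, int(2e7 // max(1, self.n * self.kcap)))
        done = 0
        order32 = np.ascontiguousarray(self.order, dtype=np.int32)
        while done < n_reps:
            b = min(batch, n_reps - done)
            # b random subsets of size C via partial argsort of uniforms
            keys = rng.random((b, self.n))
            case_idx = np.argpartition(keys, C - 1, axis=1)[:, :C]
            labels = np.zeros((b, self.n), dtype=np.uint8)
            np.put_along_axis(labels, case_idx, 1, axis=1)
            out[done : done + b] = _max_llr_batch(order32, self.valid, labels, table)
            done += b
        return out


def candidate_windows(points, spec: ScanWindowSpec):
    """Concentric candidate circles per center.

    Returns one (center_index, radii, sizes) triple per point: the unique
    window radii in increasing order and the number of points each contains,
    after applying the spec constraint and collapsing duplicate radii.
    """
    xy, _ = _as_arrays(points)
    geom = _ScanGeometry(xy, spec)
    out = []
    for i in range(geom.n):
        ks = np.nonzero(geom.candidate[i])[0]
        out.append((i, geom.full_radii[i, ks].copy(), ks + 1))
    return out


def scan(
    points,
    spec: ScanWindowSpec,
    n_reps: int = 999,
    seed: int | np.random.SeedSequence = 0,
) -> list[ScanCluster]:
    """Full Bernoulli scan: ranked high-risk clusters with Monte Carlo p-values.

    One candidate cluster (its best window) is retained per center whose best
    LLR is positive; clusters are returned sorted by decreasing LLR.  Null
    replicates permute the case labels over the fixed locations.
    """
    xy, is_case = _as_arrays(points)
    C = int(is_case.sum())
    N = len(is_case)
    if C == 0:
        raise ValueError("no cases among the points")
    if C == N:
        raise ValueError("all points are cases")
    geom = _ScanGeometry(xy, spec)
    table = geom.llr_table(C)
    vals = geom.window_llrs(is_case.astype(np.int32), table)
    best_k = np.argmax(vals, axis=1)
    best_llr = vals[np.arange(geom.n), best_k]

    rng = np.random.default_rng(seed)
    maxima = geom.replicate_maxima(rng, C, n_reps, table)

    clusters = []
    c_in_all = np.cumsum(is_case.astype(np.int32)[geom.order], axis=1)
    for i in np.argsort(-best_llr, kind="stable"):
        if best_llr[i] <= 0:
            continue
        k = best_k[i]
        p = float((1 + np.sum(maxima >= best_llr[i])) / (1 + n_reps))
        clusters.append(
            ScanCluster(
                center=(float(xy[i, 0]), float(xy[i, 1])),
                radius_km=float(geom.radii[i, k]),
                n_in=int(k + 1),
                c_in=int(c_in_all[i, k]),
                C=C,
                N=N,
                llr=float(best_llr[i]),
                p_value=p,
            )
        )
    return clusters


def report_clusters(clusters: Sequence[ScanCluster], alpha: float = 0.05) -> list[ScanCluster]:
    """Secondary-cluster rule: greedily keep significant clusters whose
    center does not lie inside any already-kept cluster's circle."""
    kept: list[ScanCluster] = []
    for cl in sorted(clusters, key=lambda c: -c.llr):
        if cl.p_value is None or cl.p_value >= alpha:
            continue
        cx, cy = cl.center
        inside = any(
            np.hypot(cx - k.center[0], cy - k.center[1]) <= k.radius_km for k in kept
        )
        if not inside:
            kept.append(cl)
    return kept


def stratified_scan(
    points: pd.DataFrame,
    spec: ScanWindowSpec,
    n_reps: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, list[ScanCluster]]:
    """Independent scans per age group; reports per-stratum clusters.

    ``points`` needs columns x_km, y_km, is_case, age_group.  A stratum with
    no cases or no non-cases is skipped with a warning; a stratum with no
    significant clusters maps to an empty list (a valid outcome).
    """
    results: dict[str, list[ScanCluster]] = {}
    strata = sorted(points["age_group"].unique())
    children = np.random.SeedSequence(seed).spawn(len(strata))
    for stratum, child in zip(strata, children):
        sub = points[points["age_group"] == stratum]
        n_cases = int(sub["is_case"].sum())
        if len(sub) < 2 or n_cases == 0 or n_cases == len(sub):
            warnings.warn(f"age group {stratum}: no scannable case/non-case mix; skipped")
            continue
        clusters = scan(sub, spec, n_reps=n_reps, seed=child)
        results[stratum] = report_clusters(clusters, alpha=alpha)
    return results


def clusters_to_frame(clusters: Sequence[ScanCluster]) -> pd.DataFrame:
    """Flat table of clusters (for CSV export)."""
    return pd.DataFrame(
        [
            {
                "x_km": c.center[0],
                "y_km": c.center[1],
                "radius_km": c.radius_km,
                "n_in": c.n_in,
                "c_in": c.c_in,
                "total_cases": c.C,
                "total_points": c.N,
                "llr": c.llr,
                "p_value": c.p_value,
            }
            for c in clusters
        ]
    )


def clusters_to_geojson(clusters: Sequence[ScanCluster], n_arc: int = 64) -> dict:
    """Cluster circles as a GeoJSON FeatureCollection of polygons (km plane)."""
    feats = []
    t = np.linspace(0, 2 * np.pi, n_arc, endpoint=False)
    for c in clusters:
        ring = np.column_stack(
            [c.center[0] + c.radius_km * np.cos(t), c.center[1] + c.radius_km * np.sin(t)]
        )
        ring = np.vstack([ring, ring[:1]])
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring.tolist()]},
                "properties": {"llr": c.llr, "p_value": c.p_value, "c_in": c.c_in, "n_in": c.n_in},
            }
        )
    return {"type": "FeatureCollection", "features": feats}
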