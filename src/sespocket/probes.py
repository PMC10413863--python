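"""Probe-sphere enumeration over a ladder of probe radii.

A *probe instance* is a sphere of probe radius r_p simultaneously tangent to
three protein atoms and free of clashes with every other atom.  These are the
generators of the concave (re-entrant) patches of the solvent-excluded
surface, and the raw material for pocket clustering.  The ladder of radii
spans 1.4 Å (water) to 3.0 Å in steps of 0.1 Å, 17 levels at the defaults.

The tangency system |x - c_i| = r_i + r_p, i = 1..3 is solved by
trilateration in a local orthonormal frame of the atom triplet; it has two
mirror solutions on opposite sides of the triplet plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import Structure

__all__ = [
    "RadiusLadder",
    "ProbeSphere",
    "tangent_sphere_centers",
    "enumerate_probes",
    "build_probe_series",
    "write_probe_tsv",
    "read_probe_tsv",
]


@dataclass(frozen=True)
class RadiusLadder:
    """Probe-radius ladder; defaults give 17 levels 1.4, 1.5, ..., 3.0 Å."""

    r_min: float = 1.4
    r_max: float = 3.0
    delta: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max and self.delta > 0):
            raise ValueError("require 0 < r_min < r_max and delta > 0")

    @property
    def radii(self) -> np.ndarray:
        n = int(round((self.r_max - self.r_min) / self.delta)) + 1
        return np.round(self.r_min + self.delta * np.arange(n), 10)

    @property
    def n_levels(self) -> int:
        return len(self.radii)


@dataclass(frozen=True)
class ProbeSphere:
    """A clash-free sphere tangent to the three atoms in ``triplet``.

    ``plane_normal`` is a canonical unit normal of the plane through the
    triplet's atom centers (deterministic per triplet); ``side`` is the sign
    of (center - plane_point)·plane_normal, so the two mirror solutions of a
    triplet carry opposite sides.
    """

    id: int
    center: np.ndarray
    radius: float
    level: int
    triplet: tuple[int, int, int]
    plane_point: np.ndarray
    plane_normal: np.ndarray
    side: int

    @property
    def outward_normal(self) -> np.ndarray:
        """Unit normal oriented from the triplet plane toward the probe."""
        return self.side * self.plane_normal


def tangent_sphere_centers(
    points: np.ndarray, dists: np.ndarray, eps: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve |x - p_i| = d_i for triplets of spheres (vectorised).

    Parameters
    ----------
    points : (n, 3, 3) triplet corner coordinates
    dists : (n, 3) required center distances (atom radius + probe radius)

    Returns
    -------
    centers_pos, centers_neg : (n, 3) the two mirror solutions
    valid : (n,) boolean; False for collinear triplets or when no real
        solution exists (the mirror solutions coincide or are imaginary)
    """
    p1, p2, p3 = points[:, 0], points[:, 1], points[:, 2]
    d1, d2, d3 = dists[:, 0], dists[:, 1], dists[:, 2]

    ex = p2 - p1
    d = np.linalg.norm(ex, axis=1)
    ok = d > eps
    d_safe = np.where(ok, d, 1.0)
    ex = ex / d_safe[:, None]

    v = p3 - p1
    i = np.einsum("ij,ij->i", ex, v)
    ey = v - i[:, None] * ex
    j = np.linalg.norm(ey, axis=1)
    ok &= j > eps
    j_safe = np.where(ok, j, 1.0)
    ey = ey / j_safe[:, None]
    ez = np.cross(ex, ey)

    X = (d_safe**2 + d1**2 - d2**2) / (2 * d_safe)
    Y = (d1**2 - d3**2 + i**2 + j_safe**2 - 2 * i * X) / (2 * j_safe)
    Z2 = d1**2 - X**2 - Y**2
    ok &= Z2 > eps
    Z = np.sqrt(np.where(ok, Z2, 0.0))

    base = p1 + X[:, None] * ex + Y[:, None] * ey
    return base + Z[:, None] * ez, base - Z[:, None] * ez, ok


def _canonical_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (centroid, unit normal) of the triplet plane."""
    n = np.cross(points[1] - points[0], points[2] - points[0])
    n = n / np.linalg.norm(n)
    for comp in n:
        if abs(comp) > 1e-12:
            if comp < 0:
                n = -n
            break
    return points.mean(axis=0), n


def _candidate_triplets(coords: np.ndarray, radii: np.ndarray, r_p: float) -> np.ndarray:
    """Atom triplets whose pairwise distances admit a common tangent probe:
    |c_i - c_j| < r_i + r_j + 2 r_p for every pair."""
    tree = cKDTree(coords)
    cut_max = 2 * radii.max() + 2 * r_p
    pairs = tree.query_pairs(cut_max, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 3), dtype=int)
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    keep = d < radii[pairs[:, 0]] + radii[pairs[:, 1]] + 2 * r_p
    pairs = pairs[keep]
    adj: dict[int, set[int]] = {}
    for a, b in pairs:
        adj.setdefault(int(a), set()).add(int(b))
        adj.setdefault(int(b), set()).add(int(a))
    triplets = []
    for a, b in pairs:
        a, b = int(min(a, b)), int(max(a, b))
        for c in adj[a] & adj[b]:
            if c > b:
                triplets.append((a, b, c))
    return np.array(sorted(triplets), dtype=int).reshape(-1, 3)


def enumerate_probes(
    structure: Structure,
    r_p: float,
    tol: float = 1e-3,
    level: int = 0,
    id_start: int = 0,
) -> list[ProbeSphere]:
    """All clash-free probes of radius ``r_p`` tangent to atom triplets.

    A candidate solution is kept iff |center - c_k| >= r_k + r_p - tol for
    every non-triplet atom k.  Probes whose centers coincide within ``tol``
    are merged, keeping the lexicographically smallest triplet.  Output is
    sorted by (triplet, side) and ids are assigned from ``id_start``.
    """
    if r_p <= 0:
        raise ValueError("probe radius must be positive")
    if len(structure) < 3:
        return []
    coords, radii = structure.coords, structure.radii

    triplets = _candidate_triplets(coords, radii, r_p)
    if len(triplets) == 0:
        return []

    pts = coords[triplets]           # (n, 3, 3)
    dd = radii[triplets] + r_p       # (n, 3)
    cpos, cneg, ok = tangent_sphere_centers(pts, dd)

    # clash test: nearest atom per vdW-radius group, full-structure check
    cand_centers = np.concatenate([cpos[ok], cneg[ok]])
    cand_trip = np.concatenate([triplets[ok], triplets[ok]])
    cand_sign = np.concatenate([np.ones(ok.sum(), dtype=int), -np.ones(ok.sum(), dtype=int)])
    if len(cand_centers) == 0:
        return []
    clashfree = np.ones(len(cand_centers), dtype=bool)
    for r_val in np.unique(radii):
        grp = np.nonzero(radii == r_val)[0]
        gtree = cKDTree(coords[grp])
        dmin, _ = gtree.query(cand_centers)
        clashfree &= dmin >= r_val + r_p - tol

    probes: list[ProbeSphere] = []
    order = np.lexsort((cand_sign, cand_trip[:, 2], cand_trip[:, 1], cand_trip[:, 0]))
    plane_cache: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]] = {}
    for k in order:
        if not clashfree[k]:
            continue
        trip = tuple(int(t) for t in cand_trip[k])
        if trip not in plane_cache:
            plane_cache[trip] = _canonical_plane(coords[list(trip)])
        pp, pn = plane_cache[trip]
        side = int(np.sign(np.dot(cand_centers[k] - pp, pn))) or 1
        probes.append(
            ProbeSphere(
                id=-1, center=cand_centers[k], radius=r_p, level=level,
                triplet=trip, plane_point=pp, plane_normal=pn, side=side,
            )
        )

    probes = _suppress_duplicates(probes, tol)
    probes.sort(key=lambda p: (p.triplet, p.side))
    return [
        ProbeSphere(id_start + i, p.center, p.radius, p.level, p.triplet,
                    p.plane_point, p.plane_normal, p.side)
        for i, p in enumerate(probes)
    ]


def _suppress_duplicates(probes: list[ProbeSphere], tol: float) -> list[ProbeSphere]:
    if len(probes) < 2:
        return probes
    centers = np.array([p.center for p in probes])
    tree = cKDTree(centers)
    parent = list(range(len(probes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in tree.query_pairs(tol):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[ProbeSphere]] = {}
    for k, p in enumerate(probes):
        groups.setdefault(find(k), []).append(p)
    return [min(g, key=lambda p: p.triplet) for g in groups.values()]


def build_probe_series(
    structure: Structure,
    ladder: RadiusLadder | None = None,
    tol: float = 1e-3,
) -> dict[int, list[ProbeSphere]]:
    """Run :func:`enumerate_probes` at every ladder level.

    Probe ids are unique across levels (level blocks are contiguous).
    """
    ladder = ladder or RadiusLadder()
    series: dict[int, list[ProbeSphere]] = {}
    next_id = 0
    for level, r_p in enumerate(ladder.radii):
        probes = enumerate_probes(structure, float(r_p), tol=tol, level=level,
                                  id_start=next_id)
        series[level] = probes
        next_id += len(probes)
    return series


def write_probe_tsv(path: str | Path, series: dict[int, list[ProbeSphere]]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlevel\tradius\tx\ty\tz\ta1\ta2\ta3\tnx\tny\tnz\tside\n")
        for level in sorted(series):
            for p in series[level]:
                x, y, z = p.center
                nx, ny, nz = p.plane_normal
                a1, a2, a3 = p.triplet
                fh.write(f"{p.id}\t{p.level}\t{p.radius:.4f}\t{x:.6f}\t{y:.6f}\t{z:.6f}"
                         f"\t{a1}\t{a2}\t{a3}\t{nx:.6f}\t{ny:.6f}\t{nz:.6f}\t{p.side}\n")


def read_probe_tsv(path: str | Path,
                   structure: Structure | None = None) -> dict[int, list[ProbeSphere]]:
    """Import probes from the TSV dump format (pluggable-backend contract)."""
    series: dict[int, list[ProbeSphere]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: not a probe TSV")
        for line in fh:
            rec = line.split()
            pid, level = int(rec[0]), int(rec[1])
            radius = float(rec[2])
            center = np.array([float(v) for v in rec[3:6]])
            trip = (int(rec[6]), int(rec[7]), int(rec[8]))
            normal = np.array([float(v) for v in rec[9:12]])
            side = int(rec[12])
            if structure is not None:
                pp, _ = _canonical_plane(structure.coords[list(trip)])
            else:
                pp = center - side * normal  # placeholder plane point
            series.setdefault(level, []).append(
                ProbeSphere(pid, center, radius, level, trip, pp, normal, side))
    return series
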