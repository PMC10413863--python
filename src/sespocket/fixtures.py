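"""Synthetic toy structures with known cavities, plus a grid oracle.

Four fixture kinds cover the geometries the pipeline must handle: a hollow
shell with a circular mouth (a deep pocket), an open-ended tube (a channel
with two mouths), a slab with a hemispherical dimple (a shallow pocket) and
a convex blob (no cavity; the pseudo-ligand is parked on the surface and
flagged shallow).  Atoms sit on jittered quasi-uniform lattices; residue
names cycle through the 20 amino acids so chemical descriptors are
exercised.  Generation is deterministic under the seed.

The grid oracle classifies space morphologically, independently of the
probe engine: a grid point is *outside* the r-SES iff some clash-free
sphere of radius r contains it (erosion of free space by r, then dilation
by r).  Points inside the 3.0 Å SES but outside the 1.4 Å SES mark pocket
interiors, and serve as ground truth for cross-checking detected pockets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .clustering import Pocket
from .features import AMINO_ACIDS
from .probes import ProbeSphere
from .structures import Atom, Structure

__all__ = [
    "FixtureSpec",
    "FixtureResult",
    "GridOracleResult",
    "CrossCheckReport",
    "make_structure",
    "grid_pocket_oracle",
    "cross_check",
]

FixtureKind = Literal["shell_with_mouth", "channel", "dimpled_slab", "convex_blob"]


@dataclass(frozen=True)
class FixtureSpec:
    kind: FixtureKind = "shell_with_mouth"
    atom_radius: float = 1.5
    lattice_spacing: float = 1.5
    cavity_radius: float = 2.7
    mouth_width: float = 3.6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.atom_radius, self.lattice_spacing, self.cavity_radius,
               self.mouth_width) <= 0:
            raise ValueError("fixture parameters must be positive")


@dataclass
class FixtureResult:
    structure: Structure
    ligand: np.ndarray                 # (M, 3) pseudo-ligand heavy atoms
    truth_region: frozenset[int]       # atoms within 5 Å of the ligand
    shallow: bool = False              # ligand could not be buried


@dataclass
class GridOracleResult:
    pocket_points: np.ndarray          # (K, 3) grid points inside the pocket
    spacing: float
    mask: np.ndarray                   # boolean grid
    origin: np.ndarray
    shape: tuple[int, int, int]

    @property
    def volume(self) -> float:
        return float(self.mask.sum()) * self.spacing**3


@dataclass
class CrossCheckReport:
    jaccard: float
    min_jaccard: float
    pocket_voxels: int
    oracle_voxels: int
    vacuous: bool = False

    @property
    def passed(self) -> bool:
        return self.vacuous or self.jaccard >= self.min_jaccard


def _fibonacci_shell(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _octahedron(scale: float) -> np.ndarray:
    eye = np.eye(3)
    return np.concatenate([scale * eye, -scale * eye])


def _to_structure(coords: np.ndarray, radius: float, name: str) -> Structure:
    atoms = [
        Atom(index=i, element="C", residue_name=AMINO_ACIDS[i % 20],
             residue_id=("A", i + 1), center=c.astype(float), radius=radius,
             is_heavy=True)
        for i, c in enumerate(coords)
    ]
    return Structure(atoms=atoms, name=name)


def make_structure(spec: FixtureSpec) -> FixtureResult:
    """Build the named fixture, its pseudo-ligand and the truth region."""
    rng = np.random.default_rng(spec.seed)
    a, h = spec.atom_radius, spec.lattice_spacing
    shallow = False

    if spec.kind == "shell_with_mouth":
        if spec.mouth_width >= 2 * spec.cavity_radius:
            raise ValueError("mouth wider than the cavity: shell self-intersects")
        # two concentric atom layers: a thick wall suppresses probes on the
        # material side of every surface triplet (as in a solid protein)
        coords_list = []
        cap_chord = spec.mouth_width / 2 + a
        for shell_r in (spec.cavity_radius + a, spec.cavity_radius + a + 1.2 * a):
            n = max(12, int(round(4 * np.pi * shell_r**2 / h**2)))
            dirs = _fibonacci_shell(n)
            cap_sin = min(cap_chord / shell_r, 1.0)
            keep = dirs[:, 2] < np.sqrt(max(0.0, 1 - cap_sin**2))
            coords_list.append(shell_r * dirs[keep])
        coords = np.concatenate(coords_list)
        lig = _octahedron(spec.cavity_radius / 2.0)
    elif spec.kind == "channel":
        # tube bore kept below the entrance-qualification radius (2.4 Å) so
        # that only the two open ends host wide terminal probes (the mouths)
        bore = min(spec.cavity_radius, 2.2)
        length = 6 * bore
        rows = []
        for tube_r in (bore + a, bore + a + 1.2 * a):
            n_ring = max(6, int(round(2 * np.pi * tube_r / h)))
            n_z = max(3, int(round(length / h)) + 1)
            zs = np.linspace(-length / 2, length / 2, n_z)
            for k, z in enumerate(zs):
                ang = 2 * np.pi * (np.arange(n_ring) + 0.5 * (k % 2)) / n_ring
                rows.append(np.column_stack([tube_r * np.cos(ang),
                                             tube_r * np.sin(ang),
                                             np.full(n_ring, z)]))
        coords = np.concatenate(rows)
        lig = np.concatenate([_octahedron(bore / 2.0),
                              [[0, 0, bore], [0, 0, -bore]]])
    elif spec.kind == "dimpled_slab":
        half = 3.0 * spec.cavity_radius
        xs = np.arange(-half, half + 1e-9, h)
        layers = np.arange(0.0, -2.1 * h, -h)
        gx, gy, gz = np.meshgrid(xs, xs, layers, indexing="ij")
        coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        dimple_center = np.array([0.0, 0.0, 0.0])
        d = np.linalg.norm(coords - dimple_center, axis=1)
        coords = coords[d > spec.cavity_radius]
        lig = _octahedron(spec.cavity_radius / 3.0) * np.array([1, 1, 0.5]) \
            + np.array([0, 0, -spec.cavity_radius / 3.0])
    elif spec.kind == "convex_blob":
        half = 1.5 * spec.cavity_radius
        xs = np.arange(-half, half + 1e-9, h)
        gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
        coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        coords = coords[np.linalg.norm(coords, axis=1) <= half]
        # no cavity: park the pseudo-ligand on the surface and flag it
        lig = np.array([[0.0, 0.0, half + a + 1.0],
                        [1.5, 0.0, half + a + 1.0],
                        [0.0, 1.5, half + a + 1.0]])
        shallow = True
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")

    coords = coords + rng.normal(scale=0.03 * h, size=coords.shape)
    structure = _to_structure(coords, a, name=spec.kind)
    tree = cKDTree(coords)
    truth = sorted({i for grp in tree.query_ball_point(lig, 5.0) for i in grp})
    if not truth and not shallow:
        raise ValueError("ligand placed outside contact range of the fixture")
    return FixtureResult(structure=structure, ligand=np.asarray(lig, float),
                         truth_region=frozenset(int(i) for i in truth),
                         shallow=shallow)


def _ball(radius_vox: float) -> np.ndarray:
    r = int(np.floor(radius_vox))
    if r < 1:
        return np.ones((1, 1, 1), dtype=bool)
    g = np.arange(-r, r + 1)
    gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
    return gx * gx + gy * gy + gz * gz <= radius_vox * radius_vox


def grid_pocket_oracle(
    structure: Structure,
    r_small: float = 1.4,
    r_large: float = 3.0,
    spacing: float = 0.5,
) -> GridOracleResult:
    """Grid points inside the large-probe SES but outside the small-probe SES.

    Accessibility to a probe of radius r is tested morphologically on the
    distance field D(x) = min_i (|x - c_i| - r_i): probe centers live where
    D >= r, and a point is outside the r-SES iff it lies within r of an
    allowed center (dilation of the eroded free space).
    """
    if spacing > 1.0:
        raise ValueError("oracle spacing must be <= 1.0 Å")
    coords, radii = structure.coords, structure.radii
    margin = r_large + 2 * spacing
    lo = (coords - radii[:, None]).min(axis=0) - margin
    hi = (coords + radii[:, None]).max(axis=0) + margin
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)

    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    D = np.full(len(pts), np.inf)
    # distance field via per-radius-group nearest neighbour
    for r_val in np.unique(radii):
        grp = coords[radii == r_val]
        gtree = cKDTree(grp)
        d, _ = gtree.query(pts)
        D = np.minimum(D, d - r_val)
    D = D.reshape(shape)

    def outside_ses(r: float) -> np.ndarray:
        # half-voxel compensation on both steps: a valid probe center can sit
        # anywhere within half a grid step of a sampled point
        allowed = D >= r - 0.5 * spacing
        return ndimage.binary_dilation(allowed,
                                       structure=_ball(r / spacing + 0.5))

    mask = outside_ses(r_small) & ~outside_ses(r_large) & (D > 0)
    idx = np.argwhere(mask)
    points = lo + spacing * idx
    return GridOracleResult(pocket_points=points, spacing=spacing, mask=mask,
                            origin=lo, shape=shape)


def voxelize_spheres(spheres, oracle: GridOracleResult) -> np.ndarray:
    """Boolean mask on the oracle grid covered by a union of spheres."""
    mask = np.zeros(oracle.shape, dtype=bool)
    lo, h = oracle.origin, oracle.spacing
    shape = np.array(oracle.shape)
    for c, r in spheres:
        c = np.asarray(c, float)
        i0 = np.maximum(((c - r - lo) / h).astype(int), 0)
        i1 = np.minimum(((c + r - lo) / h).astype(int) + 2, shape)
        if np.any(i0 >= i1):
            continue
        ax = [lo[k] + h * np.arange(i0[k], i1[k]) for k in range(3)]
        dx = ax[0][:, None, None] - c[0]
        dy = ax[1][None, :, None] - c[1]
        dz = ax[2][None, None, :] - c[2]
        inside = dx * dx + dy * dy + dz * dz <= r * r
        mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= inside
    return mask


def cross_check(
    pocket: Pocket,
    probes: dict[int, ProbeSphere],
    oracle: GridOracleResult,
    min_jaccard: float = 0.3,
) -> CrossCheckReport:
    """Jaccard overlap between a pocket's probe-sphere volume and the oracle.

    Both near-empty (convex fixture) counts as a vacuous pass.
    """
    spheres = [(probes[pid].center, probes[pid].radius) for pid in sorted(pocket.members)]
    pmask = voxelize_spheres(spheres, oracle)
    inter = int(np.sum(pmask & oracle.mask))
    union = int(np.sum(pmask | oracle.mask))
    if union == 0:
        return CrossCheckReport(jaccard=1.0, min_jaccard=min_jaccard,
                                pocket_voxels=0, oracle_voxels=0, vacuous=True)
    return CrossCheckReport(
        jaccard=inter / union, min_jaccard=min_jaccard,
        pocket_voxels=int(pmask.sum()), oracle_voxels=int(oracle.mask.sum()),
    )
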