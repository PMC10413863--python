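"""Pocket descriptors: 17 geometric/clustering and 22 chemical features.

The geometric block mixes mesh-derived quantities (volume, area, Wadell
sphericity) with scores harvested from the clustering history (aggregation,
persistence, bottlenecks, entrance depth).  The chemical block is the
residue composition of the pocket lining (one count per residue touching a
member probe) plus global hydrophobic/hydrophilic scores.

Volume and area of a pocket — the union of its member probe spheres — are
computed by extracting the zero isosurface of the signed-distance field on a
regular grid and measuring the resulting watertight mesh (the pocket
"mold"); the estimate converges to the analytic union values as the grid
spacing shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .clustering import Chain, ClusteringConfig, Entrance, Pocket
from .probes import ProbeSphere
from .structures import Structure

__all__ = [
    "AMINO_ACIDS",
    "HYDROPATHY",
    "PocketGeometry",
    "FeatureVector",
    "GEOMETRIC_FEATURE_NAMES",
    "CHEMICAL_FEATURE_NAMES",
    "union_volume_area",
    "sphericity",
    "geometric_features",
    "chemical_features",
    "compute_features",
]

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# binary hydropathy classification; glycine is neutral (counted in the
# normalisation but in neither class)
HYDROPATHY: dict[str, str] = {
    **{r: "hydrophobic" for r in
       ("ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "CYS")},
    **{r: "hydrophilic" for r in
       ("ARG", "LYS", "ASP", "GLU", "ASN", "GLN", "HIS", "SER", "THR", "TYR")},
    "GLY": "neutral",
}

GEOMETRIC_FEATURE_NAMES = (
    "n_entrances", "buried_flag", "avg_entrance_radius", "entrance_depth_score",
    "n_bottlenecks", "avg_bottleneck_radius", "avg_large_aggregation_radius",
    "volume", "size", "aggregation_score", "persistence_score",
    "clustering_score", "large_aggregation_score", "volume_ratio", "hw_index",
    "ramification", "protrusion",
)

CHEMICAL_FEATURE_NAMES = tuple(f"frac_{aa}" for aa in AMINO_ACIDS) + (
    "hydrophobic_score", "hydrophilic_score",
)


@dataclass
class PocketGeometry:
    """Volume (Å³), surface area (Å²) and triangulated mold of a sphere union."""

    V: float
    A: float
    mesh: trimesh.Trimesh


@dataclass
class FeatureVector:
    geometric: np.ndarray   # 17 entries, GEOMETRIC_FEATURE_NAMES order
    chemical: np.ndarray    # 22 entries, CHEMICAL_FEATURE_NAMES order

    def as_dict(self) -> dict[str, float]:
        d = dict(zip(GEOMETRIC_FEATURE_NAMES, self.geometric))
        d.update(zip(CHEMICAL_FEATURE_NAMES, self.chemical))
        return d


def union_volume_area(
    spheres: Sequence[tuple[np.ndarray, float]] | np.ndarray,
    spacing: float = 0.3,
) -> PocketGeometry:
    """Volume, area and mold mesh of a union of spheres.

    The signed distance to the union, f(x) = min_i(|x - c_i| - r_i), is
    sampled on a regular grid and its zero isosurface extracted by marching
    cubes; volume and area are those of the resulting closed mesh.
    """
    spheres = [(np.asarray(c, dtype=float), float(r)) for c, r in spheres]
    if not spheres:
        raise ValueError("empty sphere list")
    centers = np.array([c for c, _ in spheres])
    radii = np.array([r for _, r in spheres])

    margin = 2.5 * spacing
    lo = (centers - radii[:, None]).min(axis=0) - margin
    hi = (centers + radii[:, None]).max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1

    sdf = np.full(shape, np.inf)
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    for c, r in spheres:
        i0 = np.maximum(((c - r - margin - lo) / spacing).astype(int), 0)
        i1 = np.minimum(((c + r + margin - lo) / spacing).astype(int) + 2, shape)
        gx = axes[0][i0[0]:i1[0], None, None] - c[0]
        gy = axes[1][None, i0[1]:i1[1], None] - c[1]
        gz = axes[2][None, None, i0[2]:i1[2]] - c[2]
        d = np.sqrt(gx * gx + gy * gy + gz * gz) - r
        region = sdf[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        np.minimum(region, d, out=region)

    verts, faces, _, _ = marching_cubes(sdf, level=0.0,
                                        spacing=(spacing, spacing, spacing))
    verts = _project_to_union(verts + lo, centers, radii)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return PocketGeometry(V=float(abs(mesh.volume)), A=float(mesh.area), mesh=mesh)


def _project_to_union(verts: np.ndarray, centers: np.ndarray,
                      radii: np.ndarray) -> np.ndarray:
    """Snap marching-cubes vertices onto the exact union-of-spheres surface.

    Each vertex moves radially onto its nearest sphere's surface, removing
    the linear-interpolation bias of the isosurface extraction (the residual
    volume error is the chordal faceting term only).
    """
    from scipy.spatial import cKDTree

    def signed_and_nearest(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        best = np.full(len(pts), np.inf)
        idx = np.zeros(len(pts), dtype=int)
        for r_val in np.unique(radii):
            grp = np.nonzero(radii == r_val)[0]
            dist, j = cKDTree(centers[grp]).query(pts)
            better = dist - r_val < best
            best[better] = (dist - r_val)[better]
            idx[better] = grp[j[better]]
        return best, idx

    _, nearest = signed_and_nearest(verts)
    c = centers[nearest]
    v = verts - c
    norm = np.linalg.norm(v, axis=1)
    norm[norm < 1e-12] = 1.0
    projected = c + v * (radii[nearest] / norm)[:, None]
    # keep the projection only where it does not dive inside another sphere
    d_new, _ = signed_and_nearest(projected)
    out = verts.copy()
    ok = d_new >= -1e-9
    out[ok] = projected[ok]
    return out


def sphericity(V: float, A: float) -> float:
    """Wadell sphericity ψ = π^(1/3) (6V)^(2/3) / A.

    The surface area of a sphere with the object's volume, divided by the
    object's actual surface area; 1 for a perfect sphere, < 1 otherwise.
    """
    if V <= 0 or A <= 0:
        raise ValueError("V and A must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / A)


def _large_aggregations(pocket: Pocket) -> list:
    out = []
    for ev in pocket.node.aggregation_list:
        s1, s2 = ev.sizes_before
        if min(s1, s2) > 10 and min(s1, s2) / max(s1, s2) >= 0.2:
            out.append(ev)
    return out


def geometric_features(
    pocket: Pocket,
    geometry: PocketGeometry,
    config: ClusteringConfig,
) -> np.ndarray:
    """The 17-entry geometric/clustering block (entrances precomputed).

    Scores derived from the aggregation and persistence lists are normalised
    by cluster size; the entrance depth score is normalised by the
    significant-alignment threshold so that 1 marks the minimum pseudo-mouth
    requirement.  Persistence-derived features default to 0 when the
    persistence list is empty.
    """
    size = pocket.size
    entrances = pocket.entrances
    persistence = np.array(pocket.persistence_list, dtype=float)
    agg = pocket.node.aggregation_list
    bottlenecks = pocket.node.bottleneck_list
    large = _large_aggregations(pocket)

    if entrances:
        w = np.array([len(e.member_terminal_probes) for e in entrances], dtype=float)
        depths = np.array([e.avg_depth_index for e in entrances])
        entrance_depth = float((w * depths).sum() / w.sum()) / config.align_threshold
        avg_entrance_radius = float(np.mean([e.effective_radius for e in entrances]))
    else:
        entrance_depth = 0.0
        avg_entrance_radius = 0.0

    if large:
        lw = np.array([sum(ev.sizes_before) for ev in large], dtype=float)
        lr = np.array([ev.radius for ev in large])
        avg_large_radius = float((lw * lr).sum() / lw.sum())
    else:
        avg_large_radius = 0.0

    aggregation_score = len(agg) / size
    persistence_score = float(persistence.sum()) / size
    if persistence.size:
        mean_pers = float(persistence.mean())
        ramification = float(persistence.std())
    else:
        mean_pers = 0.0
        ramification = 0.0
    protrusion = entrance_depth * config.align_threshold - mean_pers - ramification

    return np.array([
        float(len(entrances)),
        1.0 if pocket.buried else 0.0,
        avg_entrance_radius,
        entrance_depth,
        float(len(bottlenecks)),
        float(np.mean([e.radius for e in bottlenecks])) if bottlenecks else 0.0,
        avg_large_radius,
        geometry.V,
        float(size),
        aggregation_score,
        persistence_score,
        aggregation_score + persistence_score,
        len(large) / size,
        geometry.V / size,
        sphericity(geometry.V, geometry.A),
        ramification,
        protrusion,
    ])


def chemical_features(
    pocket: Pocket,
    structure: Structure,
    hydropathy_table: Mapping[str, str] = HYDROPATHY,
) -> np.ndarray:
    """The 22-entry chemical block: 20 residue fractions + 2 hydropathy scores.

    A residue is represented once if any of its atoms is tangent to a member
    probe; fractions are normalised by the number of distinct residues in
    the pocket.  Glycine (and any residue outside both classes) enters the
    normalisation of the hydropathy scores but neither count.
    """
    residues: dict[tuple[str, int], str] = {}
    for i in pocket.tangent_atoms:
        a = structure.atoms[i]
        residues[a.residue_id] = a.residue_name
    total = len(residues)
    if total == 0:
        raise ValueError("pocket has no tangent atoms")

    counts = {aa: 0 for aa in AMINO_ACIDS}
    phob = phil = 0
    for resname in residues.values():
        if resname in counts:
            counts[resname] += 1
        cls = hydropathy_table.get(resname)
        if cls == "hydrophobic":
            phob += 1
        elif cls == "hydrophilic":
            phil += 1
    fractions = np.array([counts[aa] / total for aa in AMINO_ACIDS])
    return np.concatenate([fractions, [phob / total, phil / total]])


def compute_features(
    pocket: Pocket,
    structure: Structure,
    config: ClusteringConfig,
    probes: dict[int, ProbeSphere],
    grid_spacing: float = 0.3,
    hydropathy_table: Mapping[str, str] = HYDROPATHY,
) -> tuple[FeatureVector, PocketGeometry]:
    """Entrances (if absent) + mold geometry + both feature blocks."""
    from .clustering import detect_entrances

    if not pocket.entrances and not pocket.buried:
        pocket.entrances, pocket.buried = detect_entrances(pocket, config, probes)
    spheres = [(probes[pid].center, probes[pid].radius) for pid in sorted(pocket.members)]
    geometry = union_volume_area(spheres, spacing=grid_spacing)
    fv = FeatureVector(
        geometric=geometric_features(pocket, geometry, config),
        chemical=chemical_features(pocket, structure, hydropathy_table),
    )
    return fv, geometry
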