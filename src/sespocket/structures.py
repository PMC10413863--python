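"""Protein/ligand structure input, binding regions, and exposure.

Structures are read from PDB (via Biopython) or PQR files into a flat
:class:`Structure` of :class:`Atom` records carrying coordinates and van der
Waals radii.  Observed binding regions are defined as the protein heavy atoms
within a contact cutoff (default 5 Å, center-to-center) of any ligand heavy
atom; heavily overlapping regions from multiple co-crystallised ligands are
removed by an inclusion-ratio / Jaccard filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "BindingRegion",
    "StructureParseError",
    "VDW_RADII",
    "read_structure",
    "define_binding_regions",
    "deduplicate_binding_regions",
    "solvent_exposed_residues",
    "map_residues_to_apo",
    "write_ligand_xyz",
    "write_binding_region_table",
]

# Bondi-style van der Waals radii (Å) used when the input format carries none.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "B": 1.92, "ZN": 1.39, "FE": 1.40, "MG": 1.73,
    "CA": 2.31, "NA": 2.27, "K": 2.75, "MN": 1.61, "CU": 1.40,
    "NI": 1.63, "CO": 1.53, "CD": 1.58,
}

WATER_NAMES = {"HOH", "WAT", "DOD", "TIP", "SOL"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    """One atom: coordinates in Å, vdW radius in Å, residue bookkeeping."""

    index: int
    element: str
    residue_name: str
    residue_id: tuple[str, int]
    center: np.ndarray
    radius: float
    is_heavy: bool

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"atom {self.index}: radius must be positive")


@dataclass
class Structure:
    """A flat list of atoms plus cached coordinate/radius arrays."""

    atoms: list[Atom]
    name: str = "structure"
    _coords: np.ndarray | None = field(default=None, repr=False)
    _radii: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._coords = np.array([a.center for a in self.atoms], dtype=float)
        return self._coords

    @property
    def radii(self) -> np.ndarray:
        if self._radii is None:
            self._radii = np.array([a.radius for a in self.atoms], dtype=float)
        return self._radii

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.nonzero(self.heavy_mask)[0]

    def residues(self) -> dict[tuple[str, int], list[int]]:
        """Map residue_id -> atom indices, in file order."""
        out: dict[tuple[str, int], list[int]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a.index)
        return out

    def chain_sequence(self, chain: str) -> list[tuple[int, str]]:
        """Ordered (resid, residue_name) pairs for one chain."""
        seen: dict[int, str] = {}
        for a in self.atoms:
            c, i = a.residue_id
            if c == chain and i not in seen:
                seen[i] = a.residue_name
        return sorted(seen.items())

    def chains(self) -> list[str]:
        return sorted({a.residue_id[0] for a in self.atoms})


@dataclass
class BindingRegion:
    """Protein heavy atoms within the contact cutoff of a ligand."""

    ligand_id: str
    ligand_atoms: np.ndarray  # (M, 3) heavy-atom coordinates
    region_atoms: frozenset[int]
    region_residues: frozenset[tuple[str, int]]

    @property
    def empty(self) -> bool:
        return len(self.region_atoms) == 0


def _element_from_pdb_atom(name: str, element_field: str) -> str:
    el = element_field.strip().upper()
    if el:
        return el
    # fall back on the atom-name convention
    name = name.strip()
    if name[:2].upper() in VDW_RADII and not name[0].isdigit():
        return name[:2].upper()
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper()


def _radius_for(element: str, index: int, name: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise StructureParseError(
            f"no van der Waals radius for element {element!r} "
            f"(atom {index} {name!r}); extend VDW_RADII or supply a PQR file"
        ) from None


def _read_pdb(path: Path, include_waters: bool, include_hetero: bool) -> list[Atom]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        model = next(iter(parser.get_structure(path.stem, str(path))))
    except StopIteration:
        raise StructureParseError(f"{path}: no model records found")
    except Exception as exc:  # Biopython raises assorted errors on bad files
        raise StructureParseError(f"{path}: {exc}") from exc

    atoms: list[Atom] = []
    idx = 0
    for chain in model:
        for residue in chain:
            hetflag, resid, _icode = residue.id
            resname = residue.resname.strip()
            if resname in WATER_NAMES and not include_waters:
                continue
            if hetflag.strip() and not (resname in WATER_NAMES) and not include_hetero:
                continue
            for at in residue:
                element = _element_from_pdb_atom(at.get_name(), at.element or "")
                radius = _radius_for(element, idx, at.get_name())
                atoms.append(
                    Atom(
                        index=idx,
                        element=element,
                        residue_name=resname,
                        residue_id=(chain.id.strip() or "A", resid),
                        center=np.asarray(at.coord, dtype=float),
                        radius=radius,
                        is_heavy=element != "H",
                    )
                )
                idx += 1
    return atoms


def _read_pqr(path: Path, include_waters: bool) -> list[Atom]:
    atoms: list[Atom] = []
    idx = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            # ATOM serial name resname [chain] resid x y z charge radius
            try:
                if len(rec) == 11:
                    _, _, name, resname, chain, resid = rec[:6]
                    x, y, z, _q, radius = map(float, rec[6:11])
                elif len(rec) == 10:
                    _, _, name, resname, resid = rec[:5]
                    chain = "A"
                    x, y, z, _q, radius = map(float, rec[5:10])
                else:
                    raise ValueError("expected 10 or 11 fields")
                resid_i = int("".join(ch for ch in resid if ch not in "ABCDEFGHIJKLMNOPQRSTUVWXYZ") or resid)
            except ValueError as exc:
                raise StructureParseError(f"{path}:{lineno}: malformed PQR record ({exc})")
            if resname in WATER_NAMES and not include_waters:
                continue
            element = _element_from_pdb_atom(name, "")
            atoms.append(
                Atom(
                    index=idx,
                    element=element,
                    residue_name=resname,
                    residue_id=(chain, resid_i),
                    center=np.array([x, y, z]),
                    radius=radius,
                    is_heavy=element != "H",
                )
            )
            idx += 1
    return atoms


def read_structure(
    path: str | Path,
    format: str | None = None,
    include_waters: bool = False,
    include_hetero: bool = False,
) -> Structure:
    """Read a PDB or PQR file into a :class:`Structure`.

    PQR radii are taken from the file; PDB radii from :data:`VDW_RADII`.
    Waters (and, for PDB, other HETATM groups) are excluded by default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "pdb"
    if format == "pqr":
        atoms = _read_pqr(path, include_waters)
    elif format == "pdb":
        atoms = _read_pdb(path, include_waters, include_hetero)
    else:
        raise ValueError(f"unknown structure format {format!r}")
    if not atoms:
        raise StructureParseError(f"{path}: no atoms parsed")
    return Structure(atoms=atoms, name=path.stem)


def define_binding_regions(
    structure: Structure,
    ligands: Sequence[np.ndarray],
    cutoff: float = 5.0,
    ligand_ids: Sequence[str] | None = None,
) -> list[BindingRegion]:
    """One binding region per ligand: heavy atoms within ``cutoff`` Å
    (center-to-center) of any ligand heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy = structure.heavy_indices
    tree = cKDTree(structure.coords[heavy])
    regions = []
    for k, lig in enumerate(ligands):
        lig = np.atleast_2d(np.asarray(lig, dtype=float))
        if lig.size == 0:
            raise ValueError(f"ligand {k} has no heavy atoms")
        hits = sorted({i for grp in tree.query_ball_point(lig, cutoff) for i in grp})
        atom_ids = frozenset(int(heavy[i]) for i in hits)
        res_ids = frozenset(structure.atoms[i].residue_id for i in atom_ids)
        lid = ligand_ids[k] if ligand_ids is not None else f"lig{k}"
        region = BindingRegion(lid, lig, atom_ids, res_ids)
        if region.empty:
            warnings.warn(f"ligand {lid}: no protein atom within {cutoff} Å")
        regions.append(region)
    return regions


def deduplicate_binding_regions(regions: Sequence[BindingRegion]) -> list[BindingRegion]:
    """Drop binding regions that heavily overlap a larger one.

    For each pair, the two inclusion ratios |A∩B|/|A| and |A∩B|/|B| are
    computed; if either exceeds 50% the region with the higher ratio (the
    mostly-included one) is dropped.  Otherwise a Jaccard index ≥ 30% also
    drops the region with the higher inclusion ratio.  Pairs are processed in
    (i, j) order, greedily, with ties keeping the lower-index region.
    """
    if not regions:
        raise ValueError("need at least one binding region")
    alive = list(range(len(regions)))
    changed = True
    while changed:
        changed = False
        for ii in range(len(alive)):
            for jj in range(ii + 1, len(alive)):
                i, j = alive[ii], alive[jj]
                A, B = regions[i].region_atoms, regions[j].region_atoms
                inter = len(A & B)
                if inter == 0 or not A or not B:
                    continue
                ra, rb = inter / len(A), inter / len(B)
                drop: int | None = None
                if ra > 0.5 or rb > 0.5:
                    drop = i if ra > rb else j  # tie -> drop higher index
                else:
                    union = len(A | B)
                    if inter / union >= 0.3:
                        drop = i if ra > rb else j
                if drop is not None:
                    alive.remove(drop)
                    changed = True
                    break
            if changed:
                break
    return [regions[i] for i in alive]


def solvent_exposed_residues(
    structure: Structure,
    probe_radius: float = 1.4,
    tol: float = 1e-3,
    n_directions: int = 42,
) -> set[tuple[str, int]]:
    """Residues with at least one atom touchable by a probe of the given radius.

    An atom is exposed if it is tangent to at least one accepted triplet probe
    at ``probe_radius``; atoms in fully convex neighbourhoods (no triplet
    probe) fall back to a direction-sampling test: the atom is exposed if a
    probe-sized sphere placed tangent along some direction is clash-free.
    """
    from .probes import enumerate_probes

    if len(structure) == 0:
        raise ValueError("empty structure")
    probes = enumerate_probes(structure, probe_radius, tol=tol)
    tangent: set[int] = set()
    for p in probes:
        tangent.update(p.triplet)

    exposed = {structure.atoms[i].residue_id for i in tangent}
    remaining = [a for a in structure.atoms if a.index not in tangent and a.residue_id not in exposed]
    if remaining:
        dirs = _fibonacci_sphere(n_directions)
        tree = cKDTree(structure.coords)
        radii = structure.radii
        reach = radii.max() + 2 * probe_radius
        for a in remaining:
            if a.residue_id in exposed:
                continue
            centers = a.center + (a.radius + probe_radius) * dirs
            neigh = tree.query_ball_point(a.center, reach + a.radius)
            for c in centers:
                d = np.linalg.norm(structure.coords[neigh] - c, axis=1)
                if np.all(d >= radii[neigh] + probe_radius - tol):
                    exposed.add(a.residue_id)
                    break
    return exposed


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def map_residues_to_apo(
    holo: Structure,
    apo: Structure,
    holo_residues: Iterable[tuple[str, int]],
    probe_radius: float = 1.4,
    require_exposed: bool = True,
) -> set[tuple[str, int]]:
    """Map binding residues from a holo structure onto an apo structure.

    Chains are aligned globally (affine gap penalties, exact residue match);
    only matched residues — optionally restricted to those with at least one
    solvent-exposed atom in the apo form — are returned.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5

    wanted = set(holo_residues)
    exposure = solvent_exposed_residues(apo, probe_radius) if require_exposed else None

    mapped: set[tuple[str, int]] = set()
    for hc in holo.chains():
        hseq = holo.chain_sequence(hc)
        hstr = "".join(THREE_TO_ONE.get(rn, "X") for _, rn in hseq)
        if not hstr:
            continue
        best = None
        for ac in apo.chains():
            aseq = apo.chain_sequence(ac)
            astr = "".join(THREE_TO_ONE.get(rn, "X") for _, rn in aseq)
            if not astr:
                continue
            score = aligner.score(hstr, astr)
            if best is None or score > best[0]:
                best = (score, ac, aseq, astr)
        if best is None:
            continue
        _, ac, aseq, astr = best
        aln = aligner.align(hstr, astr)[0]
        for (h0, h1), (a0, a1) in zip(*aln.aligned):
            for off in range(h1 - h0):
                h_resid = hseq[h0 + off][0]
                if (hc, h_resid) not in wanted:
                    continue
                if hseq[h0 + off][1] != aseq[a0 + off][1]:
                    continue  # exact residue match required
                target = (ac, aseq[a0 + off][0])
                if exposure is None or target in exposure:
                    mapped.add(target)
    return mapped


def write_pqr(path: str | Path, structure: Structure, charge: float = 0.0) -> None:
    with open(path, "w") as fh:
        for a in structure.atoms:
            x, y, z = a.center
            fh.write(f"ATOM {a.index + 1} {a.element} {a.residue_name} "
                     f"{a.residue_id[0]} {a.residue_id[1]} "
                     f"{x:.3f} {y:.3f} {z:.3f} {charge:.4f} {a.radius:.4f}\n")


def write_ligand_xyz(path: str | Path, coords: np.ndarray, comment: str = "") -> None:
    coords = np.atleast_2d(coords)
    with open(path, "w") as fh:
        fh.write(f"{len(coords)}\n{comment}\n")
        for x, y, z in coords:
            fh.write(f"X {x:.3f} {y:.3f} {z:.3f}\n")


def write_binding_region_table(path: str | Path, structure: Structure,
                               regions: Sequence[BindingRegion]) -> None:
    with open(path, "w") as fh:
        fh.write("ligand_id\tchain\tresid\tatom_indices\n")
        for reg in regions:
            by_res: dict[tuple[str, int], list[int]] = {}
            for i in sorted(reg.region_atoms):
                by_res.setdefault(structure.atoms[i].residue_id, []).append(i)
            for (chain, resid), idxs in sorted(by_res.items()):
                fh.write(f"{reg.ligand_id}\t{chain}\t{resid}\t{','.join(map(str, idxs))}\n")
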