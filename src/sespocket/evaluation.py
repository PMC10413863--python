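"""Coverage metrics and Top-N ranking protocols.

A predicted pocket matches an observed site when it scores at least 50% in
Ligand Coverage (LC) and at least 20% in Pocket Coverage (PC), with
'contact' meaning a center-to-center distance below 5 Å:

* LC — ligand heavy atoms in contact with the pocket, over ligand heavy
  atoms in contact with the whole protein (×100);
* PC — the symmetric score: pocket heavy atoms in contact with the ligand,
  over all pocket heavy atoms (×100).

Scores are rounded *up* to one decimal.  Rankings are summarised per
binding site: the rank of a site is the number of non-matching pockets
above the first matching one, and Top-N rates are normalised by the number
of structure–ligand pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import Structure

__all__ = [
    "coverage_scores",
    "residue_coverage",
    "is_hit",
    "RankedPocket",
    "ProtocolSummary",
    "protocol_summary",
]


def _ceil1(x: float) -> float:
    """Round up to one decimal (0.1% resolution), guarding float fuzz."""
    return math.ceil(round(x * 10.0, 6)) / 10.0


def coverage_scores(
    structure: Structure,
    pocket_atoms: Sequence[int] | frozenset[int],
    ligand_coords: np.ndarray,
    cutoff: float = 5.0,
    mode: Literal["atom", "residue"] = "atom",
) -> tuple[float | None, float]:
    """(LC %, PC %) of a pocket against one ligand.

    ``pocket_atoms`` are heavy-atom indices (the pocket's tangent atoms).
    In residue mode both scores count residues: a residue is in contact if
    any of its heavy atoms is within ``cutoff`` of a ligand heavy atom, and
    the ligand-side contact test uses every atom of the pocket's residues.
    LC is None (undefined) when the ligand contacts no protein atom.
    """
    ligand_coords = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
    if ligand_coords.size == 0:
        raise ValueError("ligand has no heavy atoms")
    heavy = set(int(i) for i in structure.heavy_indices)
    pocket = sorted(heavy.intersection(int(i) for i in pocket_atoms))
    ltree = cKDTree(ligand_coords)

    def in_contact(atom_idx: Sequence[int]) -> np.ndarray:
        if not len(atom_idx):
            return np.zeros(0, dtype=bool)
        d, _ = ltree.query(structure.coords[list(atom_idx)])
        return d < cutoff

    protein_idx = sorted(heavy)
    prot_contact = in_contact(protein_idx)

    if mode == "atom":
        # ligand atoms in contact with protein / pocket
        ptree = cKDTree(structure.coords[protein_idx])
        d_prot, _ = ptree.query(ligand_coords)
        lig_prot = d_prot < cutoff
        n_L = int(lig_prot.sum())
        if n_L == 0:
            warnings.warn("ligand does not contact the protein; LC undefined")
            lc = None
        else:
            if pocket:
                ktree = cKDTree(structure.coords[pocket])
                d_poc, _ = ktree.query(ligand_coords)
                lig_poc = (d_poc < cutoff) & lig_prot
            else:
                lig_poc = np.zeros(len(ligand_coords), dtype=bool)
            lc = _ceil1(100.0 * lig_poc.sum() / n_L)
        poc_contact = in_contact(pocket)
        pc = _ceil1(100.0 * poc_contact.sum() / len(pocket)) if pocket else 0.0
        return lc, pc

    # residue mode
    res_atoms = structure.residues()
    pocket_res = sorted({structure.atoms[i].residue_id for i in pocket})
    pocket_res_atoms = [i for r in pocket_res for i in res_atoms[r]
                        if structure.atoms[i].is_heavy]
    ptree_all = cKDTree(structure.coords[protein_idx])
    d_prot, _ = ptree_all.query(ligand_coords)
    lig_prot = d_prot < cutoff
    n_L = int(lig_prot.sum())
    if n_L == 0:
        warnings.warn("ligand does not contact the protein; LC undefined")
        lc = None
    else:
        if pocket_res_atoms:
            ktree = cKDTree(structure.coords[pocket_res_atoms])
            d_poc, _ = ktree.query(ligand_coords)
            lig_poc = (d_poc < cutoff) & lig_prot
        else:
            lig_poc = np.zeros(len(ligand_coords), dtype=bool)
        lc = _ceil1(100.0 * lig_poc.sum() / n_L)
    if pocket_res:
        touched = 0
        for r in pocket_res:
            idx = [i for i in res_atoms[r] if structure.atoms[i].is_heavy]
            if idx and bool(np.any(in_contact(idx))):
                touched += 1
        pc = _ceil1(100.0 * touched / len(pocket_res))
    else:
        pc = 0.0
    return lc, pc


def residue_coverage(
    pocket_residues: frozenset | set,
    site_residues: frozenset | set,
) -> tuple[float, float]:
    """Residue-set LC/PC for apo evaluation against mapped binding residues."""
    if not site_residues:
        raise ValueError("empty reference residue set")
    inter = len(set(pocket_residues) & set(site_residues))
    lc = _ceil1(100.0 * inter / len(site_residues))
    pc = _ceil1(100.0 * inter / len(pocket_residues)) if pocket_residues else 0.0
    return lc, pc


def is_hit(lc: float | None, pc: float,
           lc_min: float = 50.0, pc_min: float = 20.0) -> bool:
    """Thresholds are inclusive; undefined LC is never a hit."""
    if lc is None:
        return False
    return lc >= lc_min and pc >= pc_min


@dataclass
class RankedPocket:
    """One entry of a ranked prediction list for a single binding site."""

    pocket_id: int
    hit: bool
    lc: float | None = None
    pc: float | None = None
    sub_hits: tuple[bool, ...] = ()   # hit flags of the top-3 subpockets


@dataclass
class ProtocolSummary:
    top1: float
    top3: float
    top10: float
    mean_LC: float
    mean_PC: float
    mode: str
    n_sites: int = 0


def protocol_summary(
    predictions: Sequence[Sequence[RankedPocket]],
    mode: Literal["standard", "nested", "single_pocket"] = "standard",
) -> ProtocolSummary:
    """Top-1/3/10 hit rates and mean LC/PC of the first matching pockets.

    Each element of ``predictions`` is the ranked pocket list for one
    binding site (structure–ligand pair).  In nested mode a master pocket
    counts as matching when any of its top-3 subpockets matches; the
    single_pocket mode expects the already-expanded list and counts plainly.
    """
    n_sites = len(predictions)
    if n_sites == 0:
        raise ValueError("no binding sites to summarise")
    hits_at = {1: 0, 3: 0, 10: 0}
    lcs: list[float] = []
    pcs: list[float] = []
    for site in predictions:
        rank_of_hit = None
        misses = 0
        for p in site:
            matching = p.hit or (mode == "nested" and any(p.sub_hits[:3]))
            if matching:
                rank_of_hit = misses
                if p.lc is not None:
                    lcs.append(p.lc)
                if p.pc is not None:
                    pcs.append(p.pc)
                break
            misses += 1
        if rank_of_hit is not None:
            for N in hits_at:
                if rank_of_hit < N:
                    hits_at[N] += 1
    return ProtocolSummary(
        top1=100.0 * hits_at[1] / n_sites,
        top3=100.0 * hits_at[3] / n_sites,
        top10=100.0 * hits_at[10] / n_sites,
        mean_LC=float(np.mean(lcs)) if lcs else 0.0,
        mean_PC=float(np.mean(pcs)) if pcs else 0.0,
        mode=mode,
        n_sites=n_sites,
    )
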