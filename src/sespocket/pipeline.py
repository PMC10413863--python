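"""End-to-end orchestration: structure → probes → clusters → features → rank.

The deployment defaults reproduce the published operating point: probe
ladder 1.4–3.0 Å in 0.1 Å steps, clustering with γ = 0 and β = 0.9,
pocket thresholds of 100 spheres and 4 aligned probes, and four isolation
forests (geometric/chemical × large/small populations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import ranking
from .clustering import (ClusteringConfig, ClusterTree, Pocket,
                         detect_entrances, extract_pockets_subpockets,
                         run_hierarchical_clustering)
from .evaluation import coverage_scores, is_hit
from .features import FeatureVector, PocketGeometry, compute_features
from .probes import RadiusLadder, build_probe_series
from .ranking import EvaluatedRow, IsoForestModel, RankItem, build_training_set, fit_iforest
from .structures import BindingRegion, Structure, define_binding_regions

logger = logging.getLogger("sespocket")

__all__ = ["RunConfig", "PocketResult", "DetectionRun", "detect_pockets",
           "rank_pockets", "train_models"]


@dataclass
class RunConfig:
    """Single configuration object; serialisable to/from YAML."""

    ladder: RadiusLadder = field(default_factory=RadiusLadder)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    grid_spacing: float = 0.3
    oracle_spacing: float = 0.5
    contact_cutoff: float = 5.0
    lc_min: float = 50.0
    pc_min: float = 20.0
    replication_scale: int = 10
    n_trees: int = 10_000
    subsample: int = 256
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        blob = {
            "ladder": asdict(self.ladder),
            "clustering": asdict(self.clustering),
            **{k: getattr(self, k) for k in
               ("grid_spacing", "oracle_spacing", "contact_cutoff", "lc_min",
                "pc_min", "replication_scale", "n_trees", "subsample", "seed")},
        }
        Path(path).write_text(yaml.safe_dump(blob))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        blob = yaml.safe_load(Path(path).read_text())
        return cls(
            ladder=RadiusLadder(**blob.pop("ladder", {})),
            clustering=ClusteringConfig(**blob.pop("clustering", {})),
            **blob,
        )


@dataclass
class PocketResult:
    """A pocket (or subpocket) with its descriptors and mold geometry."""

    pocket: Pocket
    features: FeatureVector
    geometry: PocketGeometry
    subresults: list["PocketResult"] = field(default_factory=list)

    @property
    def volume(self) -> float:
        return self.geometry.V


@dataclass
class DetectionRun:
    structure: Structure
    tree: ClusterTree
    results: list[PocketResult]
    ranked: list[ranking.PocketScore] = field(default_factory=list)

    def result_by_id(self, pocket_id: int) -> PocketResult | None:
        for r in self.results:
            if r.pocket.pocket_id == pocket_id:
                return r
            for s in r.subresults:
                if s.pocket.pocket_id == pocket_id:
                    return s
        return None


def detect_pockets(structure: Structure, config: RunConfig | None = None) -> DetectionRun:
    """Probe series → clustering → pockets/subpockets → features."""
    config = config or RunConfig()
    series = build_probe_series(structure, config.ladder)
    counts = {lv: len(ps) for lv, ps in series.items()}
    logger.info("probes per level: %s", counts)
    tree = run_hierarchical_clustering(series, config.clustering,
                                       coords=structure.coords)
    pockets = extract_pockets_subpockets(tree)
    logger.info("roots=%d pockets=%d subpockets=%d", len(tree.roots),
                len(pockets), sum(len(p.subpockets) for p in pockets))

    results: list[PocketResult] = []
    for pocket in pockets:
        pocket.entrances, pocket.buried = detect_entrances(
            pocket, config.clustering, tree.probes)
        fv, geom = compute_features(pocket, structure, config.clustering,
                                    tree.probes, config.grid_spacing)
        res = PocketResult(pocket=pocket, features=fv, geometry=geom)
        for sub in pocket.subpockets:
            sub.entrances, sub.buried = detect_entrances(
                sub, config.clustering, tree.probes)
            sfv, sgeom = compute_features(sub, structure, config.clustering,
                                          tree.probes, config.grid_spacing)
            res.subresults.append(PocketResult(pocket=sub, features=sfv,
                                               geometry=sgeom))
        results.append(res)
    return DetectionRun(structure=structure, tree=tree, results=results)


def feature_table(run: DetectionRun):
    """One row per pocket/subpocket with all 39 named feature columns."""
    import pandas as pd

    rows = []
    for r in run.results:
        for res in [r] + r.subresults:
            row = {"structure": run.structure.name,
                   "pocket_id": res.pocket.pocket_id,
                   "is_subpocket": res.pocket.is_subpocket,
                   "is_master": res.pocket.is_master}
            row.update(res.features.as_dict())
            rows.append(row)
    from .features import CHEMICAL_FEATURE_NAMES, GEOMETRIC_FEATURE_NAMES

    columns = ["structure", "pocket_id", "is_subpocket", "is_master",
               *GEOMETRIC_FEATURE_NAMES, *CHEMICAL_FEATURE_NAMES]
    return pd.DataFrame(rows, columns=columns)


def _rank_items(run: DetectionRun) -> list[RankItem]:
    items = []
    for r in run.results:
        item = RankItem(pocket_id=r.pocket.pocket_id,
                        geometric=r.features.geometric,
                        chemical=r.features.chemical, volume=r.volume)
        for s in r.subresults:
            item.subitems.append(RankItem(
                pocket_id=s.pocket.pocket_id, geometric=s.features.geometric,
                chemical=s.features.chemical, volume=s.volume))
        items.append(item)
    return items


def rank_pockets(
    run: DetectionRun,
    models: dict[tuple[str, str], IsoForestModel] | None = None,
    rank_by_volume: bool = False,
) -> list[ranking.PocketScore]:
    """Rank a detection run with the four forests, or by volume as fallback."""
    if rank_by_volume:
        order = sorted(run.results, key=lambda r: -r.volume)
        scored = []
        for i, r in enumerate(order):
            ps = ranking.PocketScore(pocket_id=r.pocket.pocket_id, s_geo=0.0,
                                     s_chem=0.0, s=0.0, rank=i + 1,
                                     is_master=r.pocket.is_master,
                                     volume=r.volume)
            subs = sorted(r.subresults, key=lambda s: -s.volume)
            ps.subranks = [
                ranking.PocketScore(pocket_id=s.pocket.pocket_id, s_geo=0.0,
                                    s_chem=0.0, s=0.0, subrank=j + 1,
                                    parent_id=r.pocket.pocket_id, volume=s.volume)
                for j, s in enumerate(subs)]
            scored.append(ps)
        run.ranked = scored
        return scored
    if models is None:
        raise ValueError("no trained models supplied (use rank_by_volume=True "
                         "for the volume fallback)")
    run.ranked = ranking.score_and_rank(_rank_items(run), models)
    return run.ranked


def _hit_info(result: PocketResult, structure: Structure,
              regions: Sequence[BindingRegion], config: RunConfig):
    """Best (hit, pc fraction) of a pocket over all binding regions."""
    best = (False, 0.0)
    for reg in regions:
        lc, pc = coverage_scores(structure, result.pocket.tangent_atoms,
                                 reg.ligand_atoms, cutoff=config.contact_cutoff)
        if is_hit(lc, pc, config.lc_min, config.pc_min):
            if not best[0] or pc / 100.0 > best[1]:
                best = (True, pc / 100.0)
    return best


def train_models(
    dataset: Sequence[tuple[Structure, Sequence[np.ndarray]]],
    config: RunConfig | None = None,
    n_trees: int | None = None,
    runs: Sequence[DetectionRun] | None = None,
) -> tuple[dict[tuple[str, str], IsoForestModel], dict]:
    """Fit the four forests from structures with known ligand poses.

    Pockets are generated per structure (or taken from precomputed ``runs``,
    aligned with ``dataset``), labelled by the LC/PC hit criteria against
    the deduplicated binding regions, replicated in proportion to PC, split
    by population, and fed to per-block isolation forests.
    """
    config = config or RunConfig()
    n_trees = n_trees or config.n_trees
    rows: list[EvaluatedRow] = []
    for k, (structure, ligands) in enumerate(dataset):
        regions = define_binding_regions(structure, ligands,
                                         cutoff=config.contact_cutoff)
        run = runs[k] if runs is not None else detect_pockets(structure, config)
        for r in run.results:
            hit, pc = _hit_info(r, structure, regions, config)
            is_large = r.pocket.is_master and len(r.pocket.subpockets) > 1
            rows.append(EvaluatedRow(geometric=r.features.geometric,
                                     chemical=r.features.chemical,
                                     pc=pc, hit=hit, is_large=is_large))
            for s in r.subresults:
                shit, spc = _hit_info(s, structure, regions, config)
                rows.append(EvaluatedRow(geometric=s.features.geometric,
                                         chemical=s.features.chemical,
                                         pc=spc, hit=shit, is_large=False))
    tsets = build_training_set(rows, config.replication_scale)
    models: dict[tuple[str, str], IsoForestModel] = {}
    for population, tset in tsets.items():
        for block in ("geometric", "chemical"):
            models[(block, population)] = fit_iforest(
                tset.replicated(block), feature_block=block,
                population=population, n_trees=n_trees,
                subsample=config.subsample, seed=config.seed)
    # fall back to the large-population pair when a population is unpopulated
    for population in ("large", "small"):
        other = "small" if population == "large" else "large"
        for block in ("geometric", "chemical"):
            models.setdefault((block, population), models[(block, other)])
    manifest = {
        "seed": config.seed,
        "n_trees": n_trees,
        "subsample": config.subsample,
        "ladder": asdict(config.ladder),
        "clustering": asdict(config.clustering),
        "n_training_rows": len(rows),
        "n_hits": sum(r.hit for r in rows),
    }
    return models, manifest
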