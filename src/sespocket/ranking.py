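"""Isolation-forest scoring and ranking of putative pockets.

Ranking is a one-class problem: only observed (hitting) pockets are
available as training samples, so an ensemble of isolation trees scores
how *anomalous* a pocket looks relative to real binding sites,

    s(x) = 2^(-E(h(x)) / c(n)),

where h(x) is the path length of x in a tree (edges, extended below
unsplit leaves by the average unsuccessful-search depth of a binary search
tree, c(m)), E(h) the mean over the forest, and n the subsample size.  Low
scores mean "looks like a binding site".  Four forests are used: a
geometric and a chemical forest per population ("large" = master pockets
with more than one subpocket; "small" = everything else, subpockets
included); the large-population pair provides the main score and the
small-population pair orders subpockets within their master.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import IsolationForest

__all__ = [
    "IsoForestModel",
    "TrainingSet",
    "RankItem",
    "PocketScore",
    "average_path_length",
    "eq5_score",
    "fit_iforest",
    "anomaly_score",
    "build_training_set",
    "score_and_rank",
    "subpocket_penalty",
    "expand_single_pocket_list",
    "save_models",
    "load_models",
]

EULER_GAMMA = 0.5772156649015329

FeatureBlock = Literal["geometric", "chemical"]
Population = Literal["large", "small"]


def average_path_length(n: float) -> float:
    """c(n): average path length of an unsuccessful BST search.

    c(n) = 2 H(n-1) - 2 (n-1)/n with the harmonic number approximated as
    H(m) ≈ ln m + γ (Euler–Mascheroni); c(1) = 0, c(2) = 1.
    """
    if n <= 1:
        return 0.0
    if n == 2:
        return 1.0
    return 2.0 * (np.log(n - 1.0) + EULER_GAMMA) - 2.0 * (n - 1.0) / n


def eq5_score(mean_path: float, n: int) -> float:
    """Anomaly score s = 2^(-E(h)/c(n)) for a given mean path length."""
    c = average_path_length(n)
    if c <= 0:
        return 1.0
    return float(2.0 ** (-mean_path / c))


@dataclass
class IsoForestModel:
    """A fitted isolation forest for one (feature block, population) slot."""

    feature_block: FeatureBlock
    population: Population
    n_trees: int = 10_000
    subsample: int = 256
    bootstrap: bool = False
    seed: int = 0
    estimator: IsolationForest | None = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return 17 if self.feature_block == "geometric" else 22


@dataclass
class TrainingSet:
    """Deduplicated hit rows plus PC-derived replication counts."""

    geometric: np.ndarray
    chemical: np.ndarray
    weights: np.ndarray  # integer replication counts, >= 1

    def replicated(self, block: FeatureBlock) -> np.ndarray:
        rows = self.geometric if block == "geometric" else self.chemical
        return np.repeat(rows, self.weights, axis=0)


def fit_iforest(
    rows: np.ndarray,
    feature_block: FeatureBlock = "geometric",
    population: Population = "large",
    n_trees: int = 10_000,
    subsample: int = 256,
    bootstrap: bool = False,
    seed: int = 0,
) -> IsoForestModel:
    """Fit an isolation forest on the (replicated) hit rows.

    Trees are grown on random subsamples of size ``subsample`` (clipped to
    the number of rows) by uniform random feature/split choices down to the
    height limit ceil(log2 n) or singleton leaves; deterministic under a
    fixed seed.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or len(rows) == 0:
        raise ValueError("training set must be a non-empty 2-D matrix")
    est = IsolationForest(
        n_estimators=n_trees,
        max_samples=min(subsample, len(rows)),
        bootstrap=bootstrap,
        random_state=seed,
        contamination="auto",
    )
    est.fit(rows)
    return IsoForestModel(feature_block=feature_block, population=population,
                          n_trees=n_trees, subsample=subsample,
                          bootstrap=bootstrap, seed=seed, estimator=est)


def anomaly_score(model: IsoForestModel, x: np.ndarray) -> np.ndarray | float:
    """s(x) in (0, 1); near 1 for strong anomalies, near 0 for normal rows."""
    if model.estimator is None:
        raise ValueError("model is not fitted")
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != model.estimator.n_features_in_:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.estimator.n_features_in_})")
    s = -model.estimator.score_samples(X)
    return s if np.ndim(x) == 2 else float(s[0])


@dataclass
class EvaluatedRow:
    """One hit pocket ready for training: features + PC (as a fraction)."""

    geometric: np.ndarray
    chemical: np.ndarray
    pc: float              # fraction in [0, 1]
    hit: bool
    is_large: bool         # master pocket with more than one subpocket


def build_training_set(
    rows: Sequence[EvaluatedRow],
    replication_scale: int = 10,
) -> dict[Population, TrainingSet]:
    """Split hits into populations and derive PC-proportional replication.

    Replication count = max(1, round(replication_scale × PC)), biasing the
    forests toward high-PC (tight) pockets.
    """
    hits = [r for r in rows if r.hit]
    if not hits:
        raise ValueError("no hitting pockets: cannot build a training set")
    out: dict[Population, TrainingSet] = {}
    for population in ("large", "small"):
        sel = [r for r in hits if r.is_large == (population == "large")]
        if not sel:
            continue
        out[population] = TrainingSet(
            geometric=np.array([r.geometric for r in sel]),
            chemical=np.array([r.chemical for r in sel]),
            weights=np.array([max(1, round(replication_scale * r.pc)) for r in sel],
                             dtype=int),
        )
    return out


@dataclass
class RankItem:
    """Scoring input: one pocket's feature blocks plus its subpockets."""

    pocket_id: int
    geometric: np.ndarray
    chemical: np.ndarray
    volume: float
    subitems: list["RankItem"] = field(default_factory=list)

    @property
    def is_master(self) -> bool:
        return len(self.subitems) > 0


@dataclass
class PocketScore:
    pocket_id: int
    s_geo: float
    s_chem: float
    s: float
    rank: int = -1
    is_master: bool = False
    parent_id: int | None = None
    subrank: int | None = None
    volume: float = 0.0
    subranks: list["PocketScore"] = field(default_factory=list)


def _require(models: Mapping[tuple[str, str], IsoForestModel],
             block: str, population: str) -> IsoForestModel:
    try:
        return models[(block, population)]
    except KeyError:
        raise ValueError(f"missing isolation forest for ({block}, {population})")


def score_and_rank(
    items: Sequence[RankItem],
    models: Mapping[tuple[str, str], IsoForestModel],
) -> list[PocketScore]:
    """Score all top-level pockets with the large-population forests and
    order ascending in s = (s_geo + s_chem)/2; subpockets are sub-ranked
    within their master by the small-population forests.  Ties break by
    larger volume, then pocket id."""
    geo_l = _require(models, "geometric", "large")
    chem_l = _require(models, "chemical", "large")
    geo_s = models.get(("geometric", "small"), geo_l)
    chem_s = models.get(("chemical", "small"), chem_l)

    scored: list[PocketScore] = []
    for it in items:
        sg = float(anomaly_score(geo_l, it.geometric))
        sc = float(anomaly_score(chem_l, it.chemical))
        ps = PocketScore(pocket_id=it.pocket_id, s_geo=sg, s_chem=sc,
                         s=(sg + sc) / 2.0, is_master=it.is_master,
                         volume=it.volume)
        subs = []
        for sub in it.subitems:
            ssg = float(anomaly_score(geo_s, sub.geometric))
            ssc = float(anomaly_score(chem_s, sub.chemical))
            subs.append(PocketScore(pocket_id=sub.pocket_id, s_geo=ssg,
                                    s_chem=ssc, s=(ssg + ssc) / 2.0,
                                    parent_id=it.pocket_id, volume=sub.volume))
        subs.sort(key=lambda q: (q.s, -q.volume, q.pocket_id))
        for j, q in enumerate(subs):
            q.subrank = j + 1
        ps.subranks = subs
        scored.append(ps)

    scored.sort(key=lambda q: (q.s, -q.volume, q.pocket_id))
    for i, q in enumerate(scored):
        q.rank = i + 1
    return scored


def subpocket_penalty(s_master: float, R: int) -> float:
    """Penalised score of the R-th subpocket of a master with score s.

    Identity at R = 1; non-improving (non-decreasing) and bounded by 1 as R
    grows: s_R = 1 - (1 - s)/R.
    """
    if R < 1:
        raise ValueError("subrank R must be >= 1")
    if not (0.0 < s_master < 1.0):
        raise ValueError("master score must lie in (0, 1)")
    return 1.0 - (1.0 - s_master) / R


def expand_single_pocket_list(ranked: Sequence[PocketScore]) -> list[PocketScore]:
    """Single-pocket protocol: replace each master by its ≤3 top subpockets.

    Subpockets inherit a penalised version of the master's score
    (:func:`subpocket_penalty`); non-master pockets pass through unchanged
    and the list is re-sorted ascending by score.
    """
    out: list[PocketScore] = []
    for p in ranked:
        if p.is_master and p.subranks:
            for q in p.subranks[:3]:
                out.append(PocketScore(
                    pocket_id=q.pocket_id, s_geo=q.s_geo, s_chem=q.s_chem,
                    s=subpocket_penalty(p.s, q.subrank or 1),
                    parent_id=p.pocket_id, subrank=q.subrank, volume=q.volume))
        else:
            out.append(p)
    out.sort(key=lambda q: (q.s, -q.volume, q.pocket_id))
    for i, q in enumerate(out):
        q.rank = i + 1
    return out


def save_models(path: str | Path,
                models: Mapping[tuple[str, str], IsoForestModel],
                manifest: dict | None = None) -> None:
    joblib.dump({"models": dict(models), "manifest": manifest or {}}, path)


def load_models(path: str | Path) -> tuple[dict[tuple[str, str], IsoForestModel], dict]:
    blob = joblib.load(path)
    return blob["models"], blob.get("manifest", {})
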