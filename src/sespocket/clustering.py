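"""Hierarchical clustering of probe spheres into pockets and subpockets.

Probes are merged across the radius ladder through four event types:

* **bottleneck** — two probes of equal or δ-differing radius on opposite
  sides of the same trimming plane, with coincident in-plane projections
  falling inside the triangle of the tangent-atom centers (a narrowing of
  the surface sealed from both sides);
* **radial shift** — probes of radii r and r+δ tangent to the same atom
  triplet on the same side; maximal runs over consecutive levels form
  *chains*, whose length is the depth index (chains of depth ≥ 4 are
  *significant* and mark pseudo-mouths);
* **lateral aggregation** — equal-radius probes tangent to the same two
  atoms, on the same side of each trimming plane, with center distance
  ≤ γ (γ = 0 disables lateral merging, the published optimum);
* **pyramidal aggregation** — δ-differing probes not sharing a full
  triplet, with center distance ≤ β; γ and β bound how far aggregation
  can percolate across the surface.

A conventional pocket is a cluster of ≥ 100 probes owning at least one
significant chain; subpockets are the minimal descendant clusters meeting
the same two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .probes import ProbeSphere

__all__ = [
    "ClusteringConfig",
    "ClusterEvent",
    "ClusterNode",
    "ClusterTree",
    "Chain",
    "Entrance",
    "Pocket",
    "detect_events",
    "build_chains",
    "run_hierarchical_clustering",
    "extract_pockets_subpockets",
    "detect_entrances",
]

EventKind = Literal["bottleneck", "radial_shift", "pyramidal", "lateral"]


@dataclass(frozen=True)
class ClusteringConfig:
    """Clustering thresholds; γ = 0 and β = 0.9 are the deployment optimum."""

    gamma: float = 0.0
    beta: float = 0.9
    align_threshold: int = 4
    size_threshold: int = 100
    entrance_radius_min: float = 2.4
    buried_radius: float = 2.5
    bottleneck_proj_tol: float = 0.1
    delta: float = 0.1

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.beta < 0:
            raise ValueError("gamma and beta must be non-negative")
        if self.align_threshold < 1 or self.size_threshold < 1:
            raise ValueError("thresholds must be >= 1")


@dataclass(frozen=True)
class ClusterEvent:
    kind: EventKind
    probes: tuple[int, int]
    radius: float                      # mean radius of the pair
    sizes_before: tuple[int, int] = (1, 1)
    distance: float = 0.0
    extras: tuple = ()

    def with_sizes(self, sizes: tuple[int, int]) -> "ClusterEvent":
        return ClusterEvent(self.kind, self.probes, self.radius, sizes,
                            self.distance, self.extras)


@dataclass(frozen=True)
class Chain:
    """Maximal radial-shift run: same (triplet, side) over consecutive levels."""

    triplet: tuple[int, int, int]
    side: int
    levels: tuple[int, ...]
    probe_ids: tuple[int, ...]
    terminal_probe_id: int
    terminal_radius: float
    direction: np.ndarray

    @property
    def depth_index(self) -> int:
        return len(self.probe_ids)


@dataclass
class ClusterNode:
    """Binary merge-tree node; leaves hold a single probe id.

    After tree indexing each node covers a contiguous interval
    [start, end) of the in-order leaf sequence, making membership and
    subset tests O(1)/O(k) without per-node member sets.
    """

    leaf: int | None = None
    children: tuple["ClusterNode", "ClusterNode"] | None = None
    event: ClusterEvent | None = None
    start: int = -1
    end: int = -1
    _leaf_order: np.ndarray | None = field(default=None, repr=False)
    _leaf_pos: dict | None = field(default=None, repr=False)

    @property
    def size(self) -> int:
        if self.end >= 0:
            return self.end - self.start
        return 1 if self.leaf is not None else sum(c.size for c in self.children)

    @property
    def members(self) -> frozenset[int]:
        if self.leaf is not None and self.children is None:
            return frozenset((self.leaf,))
        if self._leaf_order is None:
            raise RuntimeError("cluster tree not indexed")
        return frozenset(int(i) for i in self._leaf_order[self.start:self.end])

    def member_ids(self) -> np.ndarray:
        if self.leaf is not None and self.children is None:
            return np.array([self.leaf])
        return self._leaf_order[self.start:self.end]

    def contains_all(self, probe_ids: Iterable[int]) -> bool:
        if self._leaf_pos is None:
            return set(probe_ids) <= self.members
        return all(self.start <= self._leaf_pos[p] < self.end for p in probe_ids)

    def preorder(self) -> Iterable["ClusterNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            if node.children is not None:
                stack.extend(reversed(node.children))

    def events(self) -> list[ClusterEvent]:
        """All merge events in the subtree, gathered by pre-order traversal."""
        return [n.event for n in self.preorder() if n.event is not None]

    @property
    def aggregation_list(self) -> list[ClusterEvent]:
        return [e for e in self.events() if e.kind in ("lateral", "pyramidal")]

    @property
    def bottleneck_list(self) -> list[ClusterEvent]:
        return [e for e in self.events() if e.kind == "bottleneck"]


@dataclass(frozen=True)
class Entrance:
    center: np.ndarray
    effective_radius: float
    avg_depth_index: float
    member_terminal_probes: tuple[int, ...]
    normal: np.ndarray


@dataclass
class Pocket:
    """A qualifying cluster with entrances, chains and tangent atoms."""

    node: ClusterNode
    chains: list[Chain]
    tangent_atoms: frozenset[int]
    subpockets: list["Pocket"] = field(default_factory=list)
    entrances: list[Entrance] = field(default_factory=list)
    buried: bool = False
    is_master: bool = False
    is_subpocket: bool = False
    parent: "Pocket | None" = None
    pocket_id: int = -1

    @property
    def members(self) -> set[int]:
        return self.node.members

    @property
    def size(self) -> int:
        return self.node.size

    @property
    def significant_chains(self) -> list[Chain]:
        return self.chains

    @property
    def persistence_list(self) -> list[int]:
        return [c.depth_index for c in self.chains]


@dataclass
class ClusterTree:
    """Forest of merge trees plus probe/chain lookup tables."""

    roots: list[ClusterNode]
    probes: dict[int, ProbeSphere]
    chains: list[Chain]
    config: ClusteringConfig

    @property
    def n_probes(self) -> int:
        return len(self.probes)


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def _center_distance(a: ProbeSphere, b: ProbeSphere) -> float:
    return float(np.linalg.norm(a.center - b.center))


def _projection(p: ProbeSphere) -> np.ndarray:
    off = np.dot(p.center - p.plane_point, p.plane_normal)
    return p.center - off * p.plane_normal


def _inside_triangle(point: np.ndarray, corners: np.ndarray, eps: float = 1e-9) -> bool:
    a, b, c = corners
    v0, v1, v2 = c - a, b - a, point - a
    d00, d01, d02 = v0 @ v0, v0 @ v1, v0 @ v2
    d11, d12 = v1 @ v1, v1 @ v2
    denom = d00 * d11 - d01 * d01
    if abs(denom) < eps:
        return False
    u = (d11 * d02 - d01 * d12) / denom
    v = (d00 * d12 - d01 * d02) / denom
    return u >= -eps and v >= -eps and u + v <= 1 + eps


def _bottleneck(a: ProbeSphere, b: ProbeSphere, config: ClusteringConfig,
                coords: np.ndarray | None) -> bool:
    if a.triplet != b.triplet or a.side == b.side:
        return False
    pa, pb = _projection(a), _projection(b)
    if np.linalg.norm(pa - pb) > config.bottleneck_proj_tol:
        return False
    if coords is not None:
        corners = coords[list(a.triplet)]
        mid = 0.5 * (pa + pb)
        if not _inside_triangle(mid, corners):
            return False
    return True


def _lateral(a: ProbeSphere, b: ProbeSphere, config: ClusteringConfig) -> bool:
    shared = set(a.triplet) & set(b.triplet)
    if len(shared) != 2:
        return False
    if _center_distance(a, b) > config.gamma:
        return False
    for p in (a, b):   # same side of each trimming plane
        sa = np.dot(a.center - p.plane_point, p.plane_normal)
        sb = np.dot(b.center - p.plane_point, p.plane_normal)
        if sa * sb < 0:
            return False
    return True


def _pyramidal(a: ProbeSphere, b: ProbeSphere, config: ClusteringConfig) -> bool:
    if a.triplet == b.triplet:
        return False
    return _center_distance(a, b) <= config.beta


def _make_event(kind: EventKind, a: ProbeSphere, b: ProbeSphere) -> ClusterEvent:
    if a.id > b.id:
        a, b = b, a
    extras: tuple = ()
    if kind == "bottleneck":
        extras = (tuple(a.plane_normal),)
    elif kind == "radial_shift":
        hi = a if a.level > b.level else b
        extras = (tuple(hi.outward_normal),)
    d = float(np.linalg.norm(a.center - b.center))
    return ClusterEvent(kind, (a.id, b.id), 0.5 * (a.radius + b.radius),
                        distance=d, extras=extras)


def detect_events(
    probes_lo: Sequence[ProbeSphere],
    probes_hi: Sequence[ProbeSphere] = (),
    config: ClusteringConfig = ClusteringConfig(),
    coords: np.ndarray | None = None,
) -> list[ClusterEvent]:
    """Pairwise clustering events, same-level or between consecutive levels.

    With ``probes_hi`` empty: same-radius bottlenecks and lateral events among
    ``probes_lo``.  Otherwise: cross-level bottlenecks, radial-shift links and
    pyramidal events between the two levels.  Events are sorted by pair
    distance (ties by probe ids).
    """
    events: list[ClusterEvent] = []
    if probes_lo and len({p.level for p in probes_lo}) > 1:
        raise ValueError("probes_lo spans multiple ladder levels")
    if probes_hi:
        lv_lo = {p.level for p in probes_lo}
        lv_hi = {p.level for p in probes_hi}
        if len(lv_hi) > 1 or (lv_lo and lv_hi and max(lv_hi) != max(lv_lo) + 1):
            raise ValueError("probes_hi must sit exactly one level above probes_lo")

    if not probes_hi:
        by_triplet: dict[tuple, list[ProbeSphere]] = {}
        for p in probes_lo:
            by_triplet.setdefault(p.triplet, []).append(p)
        for group in by_triplet.values():
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    if _bottleneck(group[i], group[j], config, coords):
                        events.append(_make_event("bottleneck", group[i], group[j]))
        # lateral: candidates share an atom pair
        by_pair: dict[tuple, list[ProbeSphere]] = {}
        for p in probes_lo:
            a, b, c = p.triplet
            for key in ((a, b), (a, c), (b, c)):
                by_pair.setdefault(key, []).append(p)
        seen: set[tuple[int, int]] = set()
        for group in by_pair.values():
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    key = tuple(sorted((group[i].id, group[j].id)))
                    if key in seen:
                        continue
                    seen.add(key)
                    if _lateral(group[i], group[j], config):
                        events.append(_make_event("lateral", group[i], group[j]))
    else:
        by_triplet_side = {(p.triplet, p.side): p for p in probes_hi}
        by_triplet_hi: dict[tuple, list[ProbeSphere]] = {}
        for p in probes_hi:
            by_triplet_hi.setdefault(p.triplet, []).append(p)
        for p in probes_lo:
            partner = by_triplet_side.get((p.triplet, p.side))
            if partner is not None:
                events.append(_make_event("radial_shift", p, partner))
            for q in by_triplet_hi.get(p.triplet, ()):
                if _bottleneck(p, q, config, coords):
                    events.append(_make_event("bottleneck", p, q))
        # pyramidal: KDTree over the upper level
        if probes_lo:
            hi_centers = np.array([p.center for p in probes_hi])
            tree = cKDTree(hi_centers)
            rmax_hi = max(p.radius for p in probes_hi)
            for p in probes_lo:
                cut = config.beta
                for j in tree.query_ball_point(p.center, cut):
                    q = probes_hi[j]
                    if _pyramidal(p, q, config):
                        events.append(_make_event("pyramidal", p, q))

    events.sort(key=lambda e: (e.distance, e.probes))
    return events


# ---------------------------------------------------------------------------
# chains and tree construction
# ---------------------------------------------------------------------------

def build_chains(series: dict[int, list[ProbeSphere]]) -> list[Chain]:
    """Maximal consecutive-level runs of probes with fixed (triplet, side)."""
    index: dict[tuple, dict[int, ProbeSphere]] = {}
    for level, probes in series.items():
        for p in probes:
            index.setdefault((p.triplet, p.side), {})[level] = p
    chains: list[Chain] = []
    for (triplet, side), by_level in index.items():
        levels = sorted(by_level)
        run: list[int] = []
        for lv in levels:
            if run and lv != run[-1] + 1:
                if len(run) >= 2:
                    chains.append(_chain_from_run(triplet, side, run, by_level))
                run = []
            run.append(lv)
        if len(run) >= 2:
            chains.append(_chain_from_run(triplet, side, run, by_level))
    chains.sort(key=lambda c: (c.triplet, c.side))
    return chains


def _chain_from_run(triplet, side, run, by_level) -> Chain:
    probes = [by_level[lv] for lv in run]
    term = probes[-1]
    return Chain(
        triplet=triplet, side=side, levels=tuple(run),
        probe_ids=tuple(p.id for p in probes),
        terminal_probe_id=term.id, terminal_radius=term.radius,
        direction=term.outward_normal,
    )


class _UnionFind:
    """Path-compressed union-find over probe ids; builds the merge forest."""

    def __init__(self, probe_ids: Iterable[int]):
        self.parent: dict[int, int] = {pid: pid for pid in probe_ids}
        self.count: dict[int, int] = {pid: 1 for pid in probe_ids}
        self.node_of: dict[int, ClusterNode] = {
            pid: ClusterNode(leaf=pid) for pid in probe_ids
        }

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def merge(self, a: int, b: int, event: ClusterEvent) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        sizes = (self.count[self.find(event.probes[0])],
                 self.count[self.find(event.probes[1])])
        node = ClusterNode(children=(self.node_of[ra], self.node_of[rb]),
                           event=event.with_sizes(sizes))
        if self.count[ra] < self.count[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.count[ra] += self.count[rb]
        self.node_of[ra] = node
        del self.node_of[rb]
        return True

    def roots(self) -> list[ClusterNode]:
        return list(self.node_of.values())


def run_hierarchical_clustering(
    series: dict[int, list[ProbeSphere]],
    config: ClusteringConfig = ClusteringConfig(),
    coords: np.ndarray | None = None,
) -> ClusterTree:
    """Grow the cluster forest across the ladder.

    Per level: same-radius bottleneck pass then lateral pass; between
    consecutive levels: bottleneck pass then pyramidal + radial-shift pass.
    Candidate pairs are processed in ascending pair distance (ties by ids).
    """
    probes: dict[int, ProbeSphere] = {p.id: p for lv in series.values() for p in lv}
    uf = _UnionFind(probes.keys())
    levels = sorted(series)
    for li, lv in enumerate(levels):
        same = detect_events(series[lv], (), config, coords)
        for ev in sorted(same, key=lambda e: ((e.kind != "bottleneck"), e.distance, e.probes)):
            uf.merge(*ev.probes, ev)
        if li + 1 < len(levels) and levels[li + 1] == lv + 1:
            cross = detect_events(series[lv], series[levels[li + 1]], config, coords)
            order = {"bottleneck": 0, "pyramidal": 1, "radial_shift": 1}
            for ev in sorted(cross, key=lambda e: (order[e.kind], e.distance, e.probes)):
                uf.merge(*ev.probes, ev)
    roots = uf.roots()
    _index_forest(roots)
    return ClusterTree(roots=roots, probes=probes,
                       chains=build_chains(series), config=config)


def _index_forest(roots: list[ClusterNode]) -> None:
    """Assign contiguous leaf intervals to every node (iterative DFS)."""
    leaf_order: list[int] = []
    for root in roots:
        stack: list[tuple[ClusterNode, bool]] = [(root, False)]
        while stack:
            node, done = stack.pop()
            if node.children is None:
                node.start = len(leaf_order)
                leaf_order.append(node.leaf)
                node.end = node.start + 1
            elif not done:
                stack.append((node, True))
                stack.extend((c, False) for c in reversed(node.children))
            else:
                node.start = node.children[0].start
                node.end = node.children[-1].end
    arr = np.array(leaf_order, dtype=int)
    pos = {int(p): i for i, p in enumerate(leaf_order)}
    for root in roots:
        for node in root.preorder():
            node._leaf_order = arr
            node._leaf_pos = pos


# ---------------------------------------------------------------------------
# pockets, subpockets, entrances
# ---------------------------------------------------------------------------

def _owned_significant_chains(node: ClusterNode, chains: Sequence[Chain],
                              config: ClusteringConfig) -> list[Chain]:
    return [
        c for c in chains
        if c.depth_index >= config.align_threshold
        and node.contains_all(c.probe_ids)
    ]


def _qualifies(node: ClusterNode, chains: Sequence[Chain],
               config: ClusteringConfig) -> bool:
    if node.size < config.size_threshold:
        return False
    return len(_owned_significant_chains(node, chains, config)) > 0


def extract_pockets_subpockets(tree: ClusterTree,
                               config: ClusteringConfig | None = None) -> list[Pocket]:
    """Maximal qualifying nodes become pockets; their minimal qualifying
    strict descendants become subpockets (masters carry ≥ 1 subpocket)."""
    config = config or tree.config
    sig_chains = [c for c in tree.chains if c.depth_index >= config.align_threshold]

    def make_pocket(node: ClusterNode, is_sub: bool) -> Pocket:
        chains = _owned_significant_chains(node, sig_chains, config)
        tangent = frozenset(a for pid in node.member_ids()
                            for a in tree.probes[int(pid)].triplet)
        return Pocket(node=node, chains=chains, tangent_atoms=tangent,
                      is_subpocket=is_sub)

    def minimal_qualifying(top: ClusterNode) -> list[ClusterNode]:
        """Minimal qualifying nodes strictly below ``top`` (iterative post-order)."""
        minimal: list[ClusterNode] = []
        found: dict[int, bool] = {}
        if top.children is None:
            return minimal
        stack: list[tuple[ClusterNode, bool]] = [(c, False) for c in top.children]
        while stack:
            node, done = stack.pop()
            if node.children is None:
                # a single probe can never qualify (size threshold >= 1 chain of >= 2)
                found[id(node)] = False
                continue
            if not done:
                # prune: a subtree smaller than the size threshold cannot qualify
                if node.size < config.size_threshold:
                    found[id(node)] = False
                    continue
                stack.append((node, True))
                stack.extend((c, False) for c in node.children)
            else:
                below = any(found[id(c)] for c in node.children)
                if below:
                    found[id(node)] = True
                elif _qualifies(node, sig_chains, config):
                    minimal.append(node)
                    found[id(node)] = True
                else:
                    found[id(node)] = False
        return minimal

    pockets: list[Pocket] = []
    for root in tree.roots:
        stack = [root]
        maximal: list[ClusterNode] = []
        while stack:
            node = stack.pop()
            if _qualifies(node, sig_chains, config):
                maximal.append(node)
            elif node.children is not None:
                stack.extend(node.children)
        for pnode in maximal:
            pocket = make_pocket(pnode, is_sub=False)
            for sn in minimal_qualifying(pnode):
                sub = make_pocket(sn, is_sub=True)
                sub.parent = pocket
                pocket.subpockets.append(sub)
            pocket.is_master = bool(pocket.subpockets)
            pockets.append(pocket)

    pockets.sort(key=lambda p: -p.size)
    for i, p in enumerate(pockets):
        p.pocket_id = i
        for j, s in enumerate(p.subpockets):
            s.pocket_id = 1000 * (i + 1) + j
    return pockets


def detect_entrances(pocket: Pocket,
                     config: ClusteringConfig,
                     probes: dict[int, ProbeSphere]) -> tuple[list[Entrance], bool]:
    """Group chain-terminal probes into entrances; flag buried pockets.

    Terminal probes of significant chains with radius > the entrance minimum
    (2.4 Å) are single-linkage clustered under the power-distance
    orthogonality rule d² ≤ r_i² + r_j².  A pocket with no qualifying
    terminal is buried; a subpocket is buried when its terminal radius is
    below the (separate) buried threshold of 2.5 Å.
    """
    terms = [(c, probes[c.terminal_probe_id]) for c in pocket.chains]
    qual = [(c, p) for c, p in terms if p.radius > config.entrance_radius_min]
    if pocket.is_subpocket:
        buried = not any(p.radius >= config.buried_radius for _, p in terms)
    else:
        buried = len(qual) == 0
    if not qual:
        return [], buried

    n = len(qual)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = qual[i][1], qual[j][1]
            d2 = float(np.sum((pi.center - pj.center) ** 2))
            if d2 <= pi.radius**2 + pj.radius**2:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[tuple[Chain, ProbeSphere]]] = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(qual[k])

    entrances = []
    for members in groups.values():
        centers = np.array([p.center for _, p in members])
        center = centers.mean(axis=0)
        eff = float(np.mean(np.linalg.norm(centers - center, axis=1))
                    + np.mean([p.radius for _, p in members]))
        depth = float(np.mean([c.depth_index for c, _ in members]))
        normal = np.sum([p.outward_normal for _, p in members], axis=0)
        nn = np.linalg.norm(normal)
        normal = normal / nn if nn > 1e-12 else members[0][1].outward_normal
        entrances.append(Entrance(
            center=center, effective_radius=eff, avg_depth_index=depth,
            member_terminal_probes=tuple(p.id for _, p in members),
            normal=normal,
        ))
    entrances.sort(key=lambda e: -len(e.member_terminal_probes))
    return entrances, buried
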