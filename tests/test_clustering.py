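import numpy as np
import pytest

from sespocket.clustering import (
    Chain,
    ClusterNode,
    ClusteringConfig,
    Pocket,
    build_chains,
    detect_entrances,
    detect_events,
    extract_pockets_subpockets,
    run_hierarchical_clustering,
)
from sespocket.probes import ProbeSphere, enumerate_probes

from conftest import toy_structure

CFG = ClusteringConfig()


def mkprobe(pid, center, radius, level, triplet=(0, 1, 2), side=1,
            normal=(0.0, 0.0, 1.0), plane_point=(0.0, 0.0, 0.0)):
    return ProbeSphere(id=pid, center=np.asarray(center, float), radius=radius,
                       level=level, triplet=tuple(triplet),
                       plane_point=np.asarray(plane_point, float),
                       plane_normal=np.asarray(normal, float), side=side)


class TestEventDetection:
    def test_mirror_pair_is_a_bottleneck(self, equilateral):
        probes = enumerate_probes(equilateral, 1.4)
        events = detect_events(probes, (), CFG, coords=equilateral.coords)
        kinds = [e.kind for e in events]
        assert kinds.count("bottleneck") == 1

    def test_single_probe_no_events(self):
        p = mkprobe(0, [0, 0, 1], 1.4, 0)
        assert detect_events([p], (), CFG) == []

    def test_mixed_levels_rejected(self):
        ps = [mkprobe(0, [0, 0, 1], 1.4, 0), mkprobe(1, [0, 0, 2], 1.5, 1)]
        with pytest.raises(ValueError):
            detect_events(ps, (), CFG)

    def test_radial_shift_same_triplet_and_side(self):
        lo = [mkprobe(0, [0, 0, 1.0], 1.4, 0)]
        hi = [mkprobe(1, [0, 0, 1.1], 1.5, 1)]
        (ev,) = detect_events(lo, hi, CFG)
        assert ev.kind == "radial_shift"

    def test_lateral_needs_two_shared_atoms_and_gamma(self):
        a = mkprobe(0, [0, 0, 1.0], 1.4, 0, triplet=(0, 1, 2))
        b = mkprobe(1, [1.0, 0, 1.0], 1.4, 0, triplet=(0, 1, 3))
        assert detect_events([a, b], (), ClusteringConfig(gamma=0.0)) == []
        (ev,) = detect_events([a, b], (), ClusteringConfig(gamma=2.0))
        assert ev.kind == "lateral"
        # opposite plane sides block the event even within gamma
        c = mkprobe(2, [1.0, 0, -1.0], 1.4, 0, triplet=(0, 1, 3), side=-1)
        assert detect_events([a, c], (), ClusteringConfig(gamma=3.0)) == []

    def test_pyramidal_respects_beta(self):
        lo = [mkprobe(0, [0, 0, 1.0], 1.4, 0, triplet=(0, 1, 2))]
        hi = [mkprobe(1, [0.5, 0, 1.0], 1.5, 1, triplet=(0, 1, 3))]
        (ev,) = detect_events(lo, hi, ClusteringConfig(beta=0.9))
        assert ev.kind == "pyramidal"
        assert detect_events(lo, hi, ClusteringConfig(beta=0.3)) == []

    def test_pyramidal_event_count_nondecreasing_in_beta(self, equilateral):
        st = toy_structure(np.vstack([equilateral.coords,
                                      [[1.0, 0.57, 3.0], [3.0, 1.0, 1.0]]]))
        lo = enumerate_probes(st, 1.4, level=0)
        hi = enumerate_probes(st, 1.5, level=1, id_start=len(lo))
        counts = []
        for beta in (0.3, 0.9, 1.5, 3.0):
            evs = detect_events(lo, hi, ClusteringConfig(beta=beta))
            counts.append(sum(e.kind == "pyramidal" for e in evs))
        assert counts == sorted(counts)


def chain_probes(n_levels, base_id=0, triplet=(0, 1, 2), x=0.0, r0=1.4):
    return [mkprobe(base_id + k, [x, 0, 1.0 + 0.1 * k], r0 + 0.1 * k, k,
                    triplet=triplet) for k in range(n_levels)]


def filler_probes(n, base_id):
    """A pyramidally linked string of probes with all-distinct triplets,
    starting within β of the origin (where the chain probes sit)."""
    out = []
    for i in range(n):
        out.append(mkprobe(base_id + i, [0.4 * (i + 1), 0.0, 1.0],
                           1.4 + 0.1 * (i % 2), i % 2,
                           triplet=(100 + i, 200 + i, 300 + i)))
    return out


def as_series(probes):
    series = {}
    for p in probes:
        series.setdefault(p.level, []).append(p)
    return series


class TestChains:
    def test_five_level_run_has_depth_index_five(self):
        series = as_series(chain_probes(5))
        (chain,) = build_chains(series)
        assert chain.depth_index == 5
        assert chain.terminal_radius == pytest.approx(1.8)

    def test_interrupted_run_splits(self):
        ps = chain_probes(6)
        del ps[2]            # break between levels 1 and 3
        chains = build_chains(as_series(ps))
        assert sorted(c.depth_index for c in chains) == [2, 3]


class TestHierarchy:
    def test_disjoint_clouds_stay_separate(self):
        a = chain_probes(2, base_id=0, triplet=(0, 1, 2), x=0.0)
        b = chain_probes(2, base_id=10, triplet=(3, 4, 5), x=50.0)
        tree = run_hierarchical_clustering(as_series(a + b), CFG)
        assert len(tree.roots) == 2

    def test_bridging_pyramidal_pair_merges_and_records_sizes(self):
        a = chain_probes(2, base_id=0, triplet=(0, 1, 2), x=0.0)
        b = chain_probes(2, base_id=10, triplet=(3, 4, 5), x=0.5)
        tree = run_hierarchical_clustering(as_series(a + b), CFG)
        assert len(tree.roots) == 1
        agg = tree.roots[0].aggregation_list
        assert agg and {sum(e.sizes_before) for e in agg} <= {2, 3, 4}

    def test_member_conservation(self, shell_run):
        total = sum(r.size for r in shell_run.tree.roots)
        assert total == shell_run.tree.n_probes

    def test_partition_equals_bruteforce_event_closure(self):
        # independent oracle: exhaustive pairwise predicate + connected comps
        rng = np.random.default_rng(2)
        st = toy_structure(rng.uniform(-4, 4, size=(12, 3)), radius=1.5)
        import sespocket as sp

        series = sp.build_probe_series(st, sp.RadiusLadder(r_min=1.4, r_max=1.9))
        probes = [p for lv in series.values() for p in lv]
        assert 0 < len(probes) <= 200
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(p.id for p in probes)
        for i, p in enumerate(probes):
            for q in probes[i + 1:]:
                if _oracle_event(p, q, st.coords, CFG):
                    g.add_edge(p.id, q.id)
        want = {frozenset(c) for c in nx.connected_components(g)}
        tree = run_hierarchical_clustering(series, CFG, coords=st.coords)
        got = {frozenset(int(i) for i in r.member_ids()) for r in tree.roots}
        assert got == want


def _oracle_event(p, q, coords, cfg):
    """Straight-line re-derivation of the four pairwise event predicates."""
    dlvl = abs(p.level - q.level)
    d = float(np.linalg.norm(p.center - q.center))
    if dlvl == 0:
        if p.triplet == q.triplet and p.side != q.side:
            return _oracle_bottleneck(p, q, coords, cfg)
        if len(set(p.triplet) & set(q.triplet)) == 2 and d <= cfg.gamma:
            for t in (p, q):
                sa = np.dot(p.center - t.plane_point, t.plane_normal)
                sb = np.dot(q.center - t.plane_point, t.plane_normal)
                if sa * sb < 0:
                    return False
            return True
        return False
    if dlvl == 1:
        if p.triplet == q.triplet and p.side == q.side:
            return True                       # radial shift
        if p.triplet == q.triplet and p.side != q.side:
            return _oracle_bottleneck(p, q, coords, cfg)
        if p.triplet != q.triplet and d <= cfg.beta:
            return True                       # pyramidal
    return False


def _oracle_bottleneck(p, q, coords, cfg):
    n = p.plane_normal
    proj_p = p.center - np.dot(p.center - p.plane_point, n) * n
    proj_q = q.center - np.dot(q.center - p.plane_point, n) * n
    if np.linalg.norm(proj_p - proj_q) > cfg.bottleneck_proj_tol:
        return False
    a, b, c = coords[list(p.triplet)]
    m = 0.5 * (proj_p + proj_q)
    v0, v1, v2 = c - a, b - a, m - a
    den = (v0 @ v0) * (v1 @ v1) - (v0 @ v1) ** 2
    if abs(den) < 1e-12:
        return False
    u = ((v1 @ v1) * (v0 @ v2) - (v0 @ v1) * (v1 @ v2)) / den
    v = ((v0 @ v0) * (v1 @ v2) - (v0 @ v1) * (v0 @ v2)) / den
    return u >= -1e-9 and v >= -1e-9 and u + v <= 1 + 1e-9


class TestPocketExtraction:
    def _tree_with(self, n_filler):
        probes = chain_probes(4) + filler_probes(n_filler, base_id=100)
        return run_hierarchical_clustering(as_series(probes), CFG)

    def test_size_99_with_deep_chain_is_not_a_pocket(self):
        tree = self._tree_with(95)           # 4 chain + 95 filler = 99 members
        assert max(r.size for r in tree.roots) == 99
        assert extract_pockets_subpockets(tree) == []

    def test_size_100_with_depth_4_chain_is_a_pocket(self):
        tree = self._tree_with(96)           # exactly 100 members
        assert max(r.size for r in tree.roots) == 100
        pockets = extract_pockets_subpockets(tree)
        assert len(pockets) == 1
        assert pockets[0].size == 100 and not pockets[0].is_master

    def test_subpockets_are_subsets_of_their_master(self, channel_run):
        masters = [r.pocket for r in channel_run.results if r.pocket.is_master]
        assert masters
        for m in masters:
            for s in m.subpockets:
                assert s.members <= m.members
                assert s.size >= CFG.size_threshold
                assert s.chains

    def test_channel_pocket_has_two_mouths(self, channel_run):
        pocket = max((r.pocket for r in channel_run.results), key=lambda p: p.size)
        assert len(pocket.entrances) >= 2


def entrance_pocket(term_specs, is_subpocket=False):
    """Pocket scaffold from (terminal center, radius, depth) triples."""
    chains, probes = [], {}
    for k, (center, radius, depth) in enumerate(term_specs):
        pid = 1000 + k
        probes[pid] = mkprobe(pid, center, radius, 10)
        chains.append(Chain(triplet=(k, k + 1, k + 2), side=1,
                            levels=tuple(range(10 - depth + 1, 11)),
                            probe_ids=tuple([pid] * depth),
                            terminal_probe_id=pid, terminal_radius=radius,
                            direction=np.array([0.0, 0.0, 1.0])))
    pocket = Pocket(node=ClusterNode(leaf=0), chains=chains,
                    tangent_atoms=frozenset({0, 1, 2}),
                    is_subpocket=is_subpocket)
    return pocket, probes


class TestEntrances:
    def test_power_distance_grouping(self):
        # d² = 9 ≤ 2.5² + 2.5² = 12.5: one entrance
        pocket, probes = entrance_pocket([([0, 0, 0], 2.5, 5),
                                          ([3.0, 0, 0], 2.5, 5)])
        ents, buried = detect_entrances(pocket, CFG, probes)
        assert len(ents) == 1 and not buried
        # d² = 16 > 12.5: two entrances
        pocket, probes = entrance_pocket([([0, 0, 0], 2.5, 5),
                                          ([4.0, 0, 0], 2.5, 5)])
        ents, _ = detect_entrances(pocket, CFG, probes)
        assert len(ents) == 2

    def test_singleton_entrance_values(self):
        pocket, probes = entrance_pocket([([0, 0, 0], 2.5, 6)])
        (ent,), buried = detect_entrances(pocket, CFG, probes)
        assert ent.effective_radius == pytest.approx(2.5)
        assert ent.avg_depth_index == pytest.approx(6.0)
        assert not buried

    def test_small_terminals_mean_buried(self):
        pocket, probes = entrance_pocket([([0, 0, 0], 2.4, 5),
                                          ([4, 0, 0], 2.0, 4)])
        ents, buried = detect_entrances(pocket, CFG, probes)
        assert ents == [] and buried

    def test_subpocket_buried_threshold_is_separate(self):
        pocket, probes = entrance_pocket([([0, 0, 0], 2.3, 5)],
                                         is_subpocket=True)
        _, buried = detect_entrances(pocket, CFG, probes)
        assert buried
        pocket, probes = entrance_pocket([([0, 0, 0], 2.6, 5)],
                                         is_subpocket=True)
        _, buried = detect_entrances(pocket, CFG, probes)
        assert not buried
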