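"""Resolution evaluation, balancing, compartments, TADs, cliques and PEIs."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from shortadapt import hic
from shortadapt.genio import ContactMap
from shortadapt.hic import DecayCurve
from shortadapt.simdata import SimulationConfig, simulate_contact_map


def symmetric(rng, n, low=1.0, high=10.0):
    m = rng.uniform(low, high, size=(n, n))
    return (m + m.T) / 2


class TestResolutionEvaluation:
    def test_returns_smallest_passing_window(self):
        # 100 base bins at 10 kb; 85 rows above the contact threshold
        counts = np.zeros((100, 100))
        np.fill_diagonal(counts, [1200.0] * 85 + [10.0] * 15)
        cmap = ContactMap("chr1", 10_000, counts)
        assert hic.evaluate_matrix_resolution(cmap) == 10_000

    def test_all_zero_matrix_rejected(self):
        cmap = ContactMap("chr1", 10_000, np.zeros((50, 50)))
        with pytest.raises(ValueError, match="no window passes"):
            hic.evaluate_matrix_resolution(cmap)

    def test_aggregation_matches_bruteforce_recount(self):
        rng = np.random.default_rng(2)
        counts = np.diag(rng.uniform(300, 700, 40))  # only 25-kb pooling passes
        cmap = ContactMap("chr1", 10_000, counts)
        chosen = hic.evaluate_matrix_resolution(
            cmap, window_sizes_bp=(10_000, 25_000, 50_000), min_contacts=1000
        )
        row_tot = counts.sum(axis=1)
        for w in (10_000, 25_000, 50_000):
            step = w // 10_000
            groups = [row_tot[i : i + step].sum() for i in range(0, 40, step)]
            frac = np.mean([g > 1000 for g in groups])
            if frac > 0.80:
                assert chosen == w
                break


class TestKRBalancing:
    def test_row_sum_cv_below_tolerance(self):
        rng = np.random.default_rng(0)
        cmap = ContactMap("chr1", 10_000, symmetric(rng, 300))
        bal = hic.kr_balance(cmap)
        r = bal.counts.sum(axis=1)
        assert r.std() / r.mean() < 1e-6
        assert bal.balanced and bal.bias_vector is not None

    def test_balanced_matrix_is_fixed_point(self):
        cmap = ContactMap("chr1", 10_000, np.ones((20, 20)))
        bal = hic.kr_balance(cmap)
        assert np.abs(bal.bias_vector - 1.0).max() < 1e-6
        assert np.allclose(bal.counts, cmap.counts, atol=1e-6)

    def test_total_count_preserved(self):
        rng = np.random.default_rng(1)
        cmap = ContactMap("chr1", 10_000, symmetric(rng, 50))
        bal = hic.kr_balance(cmap)
        assert bal.counts.sum() == pytest.approx(cmap.counts.sum(), rel=1e-9)

    def test_zero_row_masked_others_balanced(self):
        rng = np.random.default_rng(2)
        m = symmetric(rng, 30)
        m[7, :] = 0.0
        m[:, 7] = 0.0
        bal = hic.kr_balance(ContactMap("chr1", 10_000, m))
        assert 7 in bal.masked_bins
        keep = bal.unmasked()
        r = bal.counts[keep].sum(axis=1)
        assert r.std() / r.mean() < 1e-6


class TestDecayCurve:
    def test_flat_matrix_gives_constant_expected(self):
        bal = ContactMap("chr1", 10_000, np.full((30, 30), 4.0), balanced=True)
        decay = hic.fit_decay_curve(bal)
        dom = decay.domain
        assert np.allclose(decay.expected[dom], 4.0)

    def test_positive_on_domain_and_nonincreasing(self):
        cfg = SimulationConfig(seed=3, chrom_lengths={"chr1": 10_000_000}, n_compartment_blocks=0)
        cmap, _ = simulate_contact_map(cfg)
        decay = hic.fit_decay_curve(hic.kr_balance(cmap))
        vals = decay.expected[decay.domain]
        assert (vals > 0).all()
        assert np.all(np.diff(vals) <= 1e-12)

    def test_generating_exponent_recovered(self):
        cfg = SimulationConfig(
            seed=4, chrom_lengths={"chr1": 30_000_000}, n_compartment_blocks=0, decay_exponent=1.0
        )
        cmap, _ = simulate_contact_map(cfg)
        decay = hic.fit_decay_curve(hic.kr_balance(cmap))
        d = np.arange(2, 80)
        slope = np.polyfit(np.log(d + 1.0), np.log(decay.expected[d]), 1)[0]
        assert abs(slope - (-1.0)) < 0.15

    def test_short_chromosome_rejected(self):
        bal = ContactMap("chr1", 10_000, np.ones((5, 5)), balanced=True)
        with pytest.raises(ValueError, match="too short"):
            hic.fit_decay_curve(bal)


class TestCompartments:
    @staticmethod
    def checkerboard_call(seed):
        cfg = SimulationConfig(
            seed=seed,
            chrom_lengths={"chr1": 50_000_000},
            resolution_bp=100_000,
            n_compartment_blocks=10,
        )
        cmap, truth = simulate_contact_map(cfg)
        bal = hic.kr_balance(cmap)
        rng = np.random.default_rng(seed)
        density = np.where(truth.compartment_labels == "A", 5.0, 1.0) + rng.normal(
            0, 0.5, bal.n_bins
        )
        comp = hic.call_compartments(bal, density)
        return comp, truth, bal

    def test_checkerboard_recovered(self):
        comp, truth, bal = self.checkerboard_call(1)
        keep = bal.unmasked()
        acc = np.mean(comp.labels[keep] == truth.compartment_labels[keep])
        assert acc >= 0.95

    def test_orientation_follows_gene_density(self):
        comp, truth, bal = self.checkerboard_call(2)
        keep = bal.unmasked()
        density = np.where(truth.compartment_labels == "A", 5.0, 1.0)
        rho = stats.spearmanr(comp.pc1[keep], density[keep]).statistic
        assert rho > 0
        assert set(comp.labels[keep]) <= {"A", "B"}
        assert ((comp.pc1[keep] > 0) == (comp.labels[keep] == "A")).all()

    def test_labels_invariant_to_global_scaling(self):
        comp, _, bal = self.checkerboard_call(3)
        scaled = ContactMap(
            bal.chrom,
            bal.resolution_bp,
            bal.counts * 7.5,
            balanced=True,
            masked_bins=bal.masked_bins,
        )
        density = np.nan_to_num(comp.pc1, nan=0.0) + 2.0
        comp2 = hic.call_compartments(scaled, density)
        keep = bal.unmasked()
        assert (comp.labels[keep] == comp2.labels[keep]).all()

    def test_oe_transform_matches_direct_division(self):
        counts = np.array(
            [[0, 4, 2, 1], [4, 0, 4, 2], [2, 4, 0, 4], [1, 2, 4, 0]], dtype=float
        )
        cmap = ContactMap("chr1", 10_000, counts, balanced=True)
        decay = DecayCurve(expected=np.array([np.nan, 4.0, 2.0, 1.0]))
        oe = hic.observed_over_expected(cmap, decay)
        assert oe[0, 1] == pytest.approx(1.0)
        assert oe[0, 2] == pytest.approx(1.0)
        assert oe[1, 3] == pytest.approx(1.0)
        assert oe[0, 3] == pytest.approx(1.0)


class TestABIndex:
    def test_extremes_and_hand_sum(self):
        # 8 fine bins, coarse/fine ratio 2 -> parents [0,0,1,1,2,2,3,3]
        labels = np.array(["A", "B", "A", "B"], dtype=object)
        comp = hic.CompartmentTrack("chr1", 20_000, np.array([1.0, -1, 1, -1]), labels)
        counts = np.zeros((8, 8))
        # bin 1 (parent 0): contacts A-parent bins 4,5 only -> +1
        counts[1, 4] = counts[4, 1] = 3.0
        counts[1, 5] = counts[5, 1] = 2.0
        # bin 2 (parent 1): A mass 2+3 (bins 4,5), B mass 2+3 (bins 6,7) -> 0
        counts[2, 4] = counts[4, 2] = 2.0
        counts[2, 5] = counts[5, 2] = 3.0
        counts[2, 6] = counts[6, 2] = 2.0
        counts[2, 7] = counts[7, 2] = 3.0
        # bin 7 (parent 3): A mass 1 (bin 0, parent 0), B mass 3 (bin 2, parent 1);
        # the bin-6 contact shares bin 7's own parent and is excluded
        counts[7, 0] = counts[0, 7] = 1.0
        counts[7, 6] = counts[6, 7] = 5.0
        cmap = ContactMap("chr1", 10_000, counts, balanced=True)
        track = hic.compute_ab_index(cmap, comp)
        assert track.ab_index[1] == pytest.approx(1.0)
        assert track.ab_index[2] == pytest.approx(0.0)
        assert track.ab_index[7] == pytest.approx((1 - 3) / (1 + 3))

    def test_resolution_mismatch_rejected(self):
        comp = hic.CompartmentTrack(
            "chr1", 25_000, np.zeros(4), np.array(["A"] * 4, dtype=object)
        )
        cmap = ContactMap("chr1", 10_000, np.zeros((10, 10)))
        with pytest.raises(ValueError, match="multiple"):
            hic.compute_ab_index(cmap, comp)


class TestTADs:
    def test_di_formula_on_crafted_window_sums(self):
        counts = np.zeros((3, 3))
        counts[1, 0] = counts[0, 1] = 10.0
        counts[1, 2] = counts[2, 1] = 2.0
        cmap = ContactMap("chr1", 25_000, counts)
        di = hic.directionality_index(cmap, di_window_bp=25_000)
        assert di[1] == pytest.approx(-(16 / 6 + 16 / 6))
        assert di[1] == pytest.approx(-5.3333, rel=1e-4)

    def test_uniform_matrix_yields_single_tad(self):
        cmap = ContactMap("chr1", 25_000, np.full((60, 60), 5.0), balanced=True)
        tads = hic.call_tads(cmap, di_window_bp=250_000, seed=0)
        assert tads.tads == [(0, 60)]

    def test_planted_boundaries_recovered_one_seed(self):
        cfg = SimulationConfig(
            seed=2,
            chrom_lengths={"chr1": 5_000_000},
            resolution_bp=25_000,
            n_compartment_blocks=0,
            tad_sizes_bins=[10] * 20,
        )
        cmap, truth = simulate_contact_map(cfg)
        tads = hic.call_tads(hic.kr_balance(cmap), di_window_bp=500_000, seed=0)
        recovered = sum(
            any(abs(b - t) <= 1 for b in tads.boundaries) for t in truth.tad_boundaries
        )
        assert recovered / len(truth.tad_boundaries) >= 0.9
        # segments tile without overlap
        for (s1, e1), (s2, e2) in itertools.pairwise(tads.tads):
            assert e1 <= s2
        assert all(e - s >= 3 for s, e in tads.tads)


class TestIntactness:
    def test_log2_identity_and_doubling(self):
        counts = np.zeros((6, 6))
        expected = np.array([np.nan, 8.0, 4.0, 2.0, 1.0, 0.5])
        for d in range(1, 6):
            for i in range(6 - d):
                counts[i, i + d] = counts[i + d, i] = expected[d]
        cmap = ContactMap("chr1", 25_000, counts, balanced=True)
        tads = hic.TADSet("chr1", 25_000, [(0, 5)], np.zeros(6), np.zeros(6, dtype=int))
        decay = DecayCurve(expected=expected)
        val = hic.tad_intactness(cmap, tads, decay)
        assert val[0] == pytest.approx(0.0, abs=1e-12)
        doubled = ContactMap("chr1", 25_000, counts * 2, balanced=True)
        val2 = hic.tad_intactness(doubled, tads, decay)
        assert val2[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        m = symmetric(rng, 10, 1, 5)
        cmap = ContactMap("chr1", 25_000, m, balanced=True)
        expected = np.concatenate([[np.nan], rng.uniform(1, 3, 9)])
        expected[1:] = np.sort(expected[1:])[::-1]
        decay = DecayCurve(expected=expected)
        tads = hic.TADSet("chr1", 25_000, [(2, 7)], np.zeros(10), np.zeros(10, dtype=int))
        val = hic.tad_intactness(cmap, tads, decay)
        obs = sum(m[i, j] for i in range(2, 7) for j in range(i + 1, 7))
        exp = sum(expected[j - i] for i in range(2, 7) for j in range(i + 1, 7))
        assert val[0] == pytest.approx(np.log2(obs / exp), abs=1e-12)


def bruteforce_maximal_cliques(G):
    """All maximal cliques by subset enumeration (n <= 12)."""
    nodes = list(G.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(G.has_edge(u, v) for u, v in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    return [c for c in cliques if not any(c < d for d in cliques)]


class TestCliques:
    def test_k4_plus_pendant_matches_bruteforce(self):
        G = nx.Graph()
        G.add_nodes_from(range(5))
        G.add_edges_from(itertools.combinations(range(4), 2))  # K4
        G.add_edge(3, 4)  # pendant
        cliques, max_size = hic.clique_stats(G, 5)
        assert cliques == [(0, 1, 2, 3)]
        assert max_size.tolist() == [4, 4, 4, 4, 2]
        brute = bruteforce_maximal_cliques(G)
        got = [set(c) for c in nx.find_cliques(G)]
        assert sorted(map(sorted, brute)) == sorted(map(sorted, got))

    def test_empty_graph_gives_unit_sizes(self):
        G = nx.Graph()
        G.add_nodes_from(range(6))
        cliques, max_size = hic.clique_stats(G, 6)
        assert cliques == []
        assert (max_size == 1).all()

    def test_planted_tad_clique_recovered_one_seed(self):
        cfg = SimulationConfig(
            seed=1,
            chrom_lengths={"chr1": 6_000_000},
            resolution_bp=25_000,
            n_compartment_blocks=0,
            tad_sizes_bins=[8] * 30,
            clique_groups=[{2, 7, 12, 18, 25}],
            clique_fold=8.0,
        )
        cmap, truth = simulate_contact_map(cfg)
        bal = hic.kr_balance(cmap)
        decay = hic.fit_decay_curve(bal)
        tads = hic.call_tads(bal, di_window_bp=500_000, seed=0)
        cg = hic.tad_clique_analysis(bal, tads, decay)
        assert len(tads.tads) == 30
        assert all(cg.max_clique_size[t] >= 5 for t in (2, 7, 12, 18, 25))
        assert (cg.edges["q"] < 1e-4).all()

    def test_null_map_produces_no_cliques(self):
        cfg = SimulationConfig(
            seed=5,
            chrom_lengths={"chr1": 6_000_000},
            resolution_bp=25_000,
            n_compartment_blocks=0,
            tad_sizes_bins=[8] * 30,
        )
        cmap, _ = simulate_contact_map(cfg)
        bal = hic.kr_balance(cmap)
        decay = hic.fit_decay_curve(bal)
        tads = hic.call_tads(bal, di_window_bp=500_000, seed=0)
        cg = hic.tad_clique_analysis(bal, tads, decay)
        assert len(cg.cliques) == 0


class TestPEI:
    @staticmethod
    def pei_setup(seed, loops, tad_fold=1.0):
        # tad_fold 1 keeps the chromosome-wide decay expectation exact for
        # within-TAD candidates, isolating the loop signal
        cfg = SimulationConfig(
            seed=seed,
            chrom_lengths={"chr1": 3_000_000},
            resolution_bp=10_000,
            n_compartment_blocks=0,
            tad_sizes_bins=[60],
            tad_fold=tad_fold,
            loop_anchors=loops,
            base_count=200.0,
        )
        cmap, _ = simulate_contact_map(cfg)
        bal = hic.kr_balance(cmap)
        return bal, hic.fit_decay_curve(bal)

    def test_planted_loop_detected_and_short_range_excluded(self):
        bal, decay = self.pei_setup(1, [(10, 20, 10.0), (10, 15, 10.0)])
        peis = hic.call_peis(bal, [10], [(0, 600_000)], decay)
        assert ((peis["promoter_bin"] == 10) & (peis["enhancer_bin"] == 20)).any()
        assert not (peis["distance_bp"] < 60_000).any()

    def test_null_map_yields_no_interactions(self):
        bal, decay = self.pei_setup(2, [])
        peis = hic.call_peis(bal, [10, 30], [(0, 600_000)], decay)
        assert len(peis) <= 1  # BH at 5% on a null map

    def test_promoter_outside_tads_warns(self):
        bal, decay = self.pei_setup(3, [])
        with pytest.warns(UserWarning, match="outside all TADs"):
            hic.call_peis(bal, [250], [(0, 600_000)], decay)
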