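import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirnome import synthetic_data as sd, target_networks as tn
from mirnome._seq import Interval, random_seq, revcomp

from ._oracles import (
    naive_quantile_normalize,
    naive_seed_scan,
    union_find_components,
)


class TestDedupeTranscripts:
    def test_boundary_40_percent(self):
        annotated = {"e1": Interval(1, 1000)}
        kept = {"c40": Interval(961, 1060)}  # overlap 40 of 100
        dropped = {"c41": Interval(960, 1059)}  # overlap 41 of 100
        out = tn.dedupe_transcripts({**kept, **dropped}, annotated)
        assert set(out) == {"c40"}

    def test_disjoint_kept(self):
        out = tn.dedupe_transcripts(
            {"c": Interval(2000, 2100)}, {"e": Interval(1, 1000)}
        )
        assert set(out) == {"c"}

    def test_matches_brute_force(self):
        # oracle: direct pairwise interval arithmetic
        rng = np.random.default_rng(0)
        clusters = {
            f"c{i}": Interval(int(s), int(s) + int(l))
            for i, (s, l) in enumerate(
                zip(rng.integers(1, 5000, 40), rng.integers(50, 400, 40))
            )
        }
        annotated = {
            f"e{i}": Interval(int(s), int(s) + int(l))
            for i, (s, l) in enumerate(
                zip(rng.integers(1, 5000, 15), rng.integers(100, 800, 15))
            )
        }
        out = tn.dedupe_transcripts(clusters, annotated)
        for cid, civ in clusters.items():
            best = max(civ.overlap(aiv) / len(civ) for aiv in annotated.values())
            assert (cid in out) == (best * 100 <= 40.0)


class TestDeriveUtr:
    def test_single_short_block(self):
        genome = random_seq(np.random.default_rng(1), 2000)
        utr = tn.derive_utr("t1", [Interval(101, 600)], genome)
        assert utr.sequence == genome[100:600]
        assert len(utr.sequence) == 500

    def test_gap_rule(self):
        genome = random_seq(np.random.default_rng(2), 200_000)
        near = [Interval(1000, 1499), Interval(11_500, 11_999)]  # 10 kb gap
        far = [Interval(1000, 1499), Interval(111_500, 111_999)]  # 110 kb gap
        chained = tn.derive_utr("t1", near, genome)
        assert len(chained.sequence) == 894  # 1000 covered nt -> tail
        unchained = tn.derive_utr("t2", far, genome)
        assert len(unchained.sequence) == 500  # best single block only

    def test_tail_894_cap(self):
        genome = random_seq(np.random.default_rng(3), 5000)
        utr = tn.derive_utr("t1", [Interval(1, 2000)], genome)
        assert len(utr.sequence) == 894
        assert utr.sequence == genome[2000 - 894 : 2000]

    def test_strand_aware(self):
        genome = random_seq(np.random.default_rng(4), 3000)
        utr = tn.derive_utr("t1", [Interval(101, 1300)], genome, strand="-")
        assert utr.sequence == revcomp(genome[100:1300])[-894:]

    def test_chain_choice_matches_enumeration(self):
        # oracle: enumerate all co-linear chains and pick max covered
        rng = np.random.default_rng(5)
        genome = random_seq(rng, 400_000)
        starts = sorted(rng.choice(350_000, size=8, replace=False))
        blocks = [Interval(int(s) + 1, int(s) + int(rng.integers(100, 900))) for s in starts]
        max_gap = 20_000
        # enumeration over contiguous runs (chains are runs of
        # consecutive blocks with all gaps <= max_gap)
        best_cov = -1
        best_run = None
        for i in range(len(blocks)):
            for j in range(i, len(blocks)):
                run = blocks[i : j + 1]
                gaps_ok = all(
                    run[k + 1].start - run[k].end - 1 <= max_gap
                    for k in range(len(run) - 1)
                )
                if not gaps_ok:
                    continue
                cov = sum(len(b) for b in run)
                if cov > best_cov:
                    best_cov, best_run = cov, run
        expected = "".join(genome[b.start - 1 : b.end] for b in best_run)[-894:]
        utr = tn.derive_utr("t1", blocks, genome, max_gap=max_gap)
        assert utr.sequence == expected

    def test_no_blocks_error(self):
        with pytest.raises(ValueError):
            tn.derive_utr("t1", [], "ACGT")


class TestPredictTargets:
    def test_single_interior_site(self):
        mature = "TAGCTTATCAGACTGATGTTGA"
        seed = tn.seed_of(mature)
        utr = "C" * 50 + revcomp(seed) + "C" * 50
        sites = tn.predict_targets({"m1": mature}, {"t1": utr})
        assert len(sites) == 1
        assert sites[0].position == 51

    def test_end_exclusion(self):
        mature = "TAGCTTATCAGACTGATGTTGA"
        seed = tn.seed_of(mature)
        utr = "C" * 9 + revcomp(seed) + "C" * 50  # site at position 10
        assert tn.predict_targets({"m1": mature}, {"t1": utr}) == []
        assert len(
            tn.predict_targets({"m1": mature}, {"t1": utr}, end_exclusion=5)
        ) == 1

    def test_site_classes(self):
        mature = "TAGCTTATCAGACTGATGTTGA"
        seed_rc = revcomp(mature[1:7])
        m8 = {"A": "T", "C": "G", "G": "C", "T": "A"}[mature[7]]
        not_m8 = "C" if m8 != "C" else "G"
        utr8 = "C" * 30 + m8 + seed_rc + "A" + "C" * 30
        utr7m8 = "C" * 30 + m8 + seed_rc + "C" * 30
        utr7a1 = "C" * 30 + not_m8 + seed_rc + "A" + "C" * 30
        utr6 = "C" * 30 + not_m8 + seed_rc + "C" * 30
        for utr, cls in [
            (utr8, "8mer"), (utr7m8, "7mer-m8"), (utr7a1, "7mer-1A"), (utr6, "6mer")
        ]:
            sites = tn.predict_targets({"m1": mature}, {"t": utr})
            assert [s.site_class for s in sites] == [cls]

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(7)
        matures = {
            f"m{i}": random_seq(rng, 22) for i in range(4)
        }
        utrs = {f"t{i}": random_seq(rng, 400) for i in range(50)}
        sites = tn.predict_targets(matures, utrs)
        got = {
            (s.mirna_id, s.transcript_id, s.position, s.site_class) for s in sites
        }
        assert got == naive_seed_scan(matures, utrs)

    def test_degenerate_seed_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            tn.predict_targets({"m1": "ANNNNNNCATGCATGCATGCA"}, {"t": "ACGT" * 30})


class TestAnticorrelationFilter:
    def _matrices(self, r=-1.0, seed=0):
        cfg = sd.SimulationConfig(rng_seed=seed, planted_target_correlation=r)
        return sd.generate_tissue_expression(
            10, [("m1", "t1")], [], [], cfg, extra_mirnas=2, extra_mrnas=2
        )

    def _site(self, m="m1", t="t1"):
        return tn.TargetSite(m, t, 100, "6mer")

    def test_perfect_anticorrelation_passes(self):
        mi, mr, _, _ = self._matrices(r=-1.0)
        out = tn.anticorrelation_filter([self._site()], mi, mr, threshold=-0.01)
        assert len(out) == 1 and out[0].passes
        assert out[0].pearson_r == pytest.approx(-1.0)

    def test_constant_profile_excluded(self):
        mi, mr, _, _ = self._matrices()
        mr.loc["t1"] = 5.0
        out = tn.anticorrelation_filter([self._site()], mi, mr)
        assert out == []

    def test_r_matches_direct_covariance(self):
        # oracle: direct Pearson formula
        mi, mr, _, _ = self._matrices(r=-0.6, seed=3)
        out = tn.anticorrelation_filter(
            [self._site("m1", "t1")], mi, mr, threshold=0.0
        )
        x = mi.loc["m1"].to_numpy()
        y = mr.loc["t1"].to_numpy()
        expected = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert out[0].pearson_r == pytest.approx(expected)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        mi = pd.DataFrame(
            rng.normal(size=(10, 8)),
            index=[f"m{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(8)],
        )
        mr = pd.DataFrame(
            rng.normal(size=(10, 8)),
            index=[f"t{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(8)],
        )
        sites = [self._site(f"m{i}", f"t{j}") for i in range(10) for j in range(10)]
        prev = None
        for thr in (0.0, -0.3, -0.6, -0.9):
            passing = {
                (f.site.mirna_id, f.site.transcript_id)
                for f in tn.anticorrelation_filter(sites, mi, mr, threshold=thr)
                if f.passes
            }
            if prev is not None:
                assert passing <= prev
            prev = passing

    def test_tissue_mismatch_errors(self):
        mi, mr, _, _ = self._matrices()
        bad = mr.rename(columns={mr.columns[0]: "other"})
        with pytest.raises(ValueError):
            tn.anticorrelation_filter([self._site()], mi, bad)

    def test_multiple_sites_collapse(self):
        mi, mr, _, _ = self._matrices()
        sites = [
            tn.TargetSite("m1", "t1", 50, "6mer"),
            tn.TargetSite("m1", "t1", 200, "8mer"),
        ]
        out = tn.anticorrelation_filter(sites, mi, mr)
        assert len(out) == 1 and out[0].n_sites == 2


class TestBuildTissueNetwork:
    def _setup(self, flip=False):
        tissues = [f"s{i}" for i in range(6)]
        up = [4.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        down = [0.25, 1.0, 1.0, 1.0, 1.0, 1.0]
        mir = pd.DataFrame(
            {"m1": up if not flip else down}, index=tissues
        ).T
        mrna = pd.DataFrame({"t1": down if not flip else up}, index=tissues).T
        ft = tn.FilteredTarget(tn.TargetSite("m1", "t1", 50, "6mer"), -0.95, True)
        return ft, mir, mrna

    def test_repressive_edge(self):
        ft, mir, mrna = self._setup()
        net = tn.build_tissue_network([ft], [], mir, mrna, "s0")
        net.validate()
        assert net.graph.number_of_nodes() == 2
        assert net.graph.edges["m1", "t1"]["partition"] == "repressive"

    def test_permissive_edge(self):
        ft, mir, mrna = self._setup(flip=True)
        net = tn.build_tissue_network([ft], [], mir, mrna, "s0")
        net.validate()
        assert net.graph.edges["m1", "t1"]["partition"] == "permissive"

    def test_same_sign_pair_dropped(self):
        tissues = [f"s{i}" for i in range(6)]
        up = [4.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        mir = pd.DataFrame({"m1": up}, index=tissues).T
        mrna = pd.DataFrame({"t1": up}, index=tissues).T
        ft = tn.FilteredTarget(tn.TargetSite("m1", "t1", 50, "6mer"), -0.95, True)
        net = tn.build_tissue_network([ft], [], mir, mrna, "s0")
        assert net.graph.number_of_edges() == 0

    def test_below_detection_excluded(self):
        ft, mir, mrna = self._setup()
        mir.loc["m1", "s0"] = np.nan
        net = tn.build_tissue_network([ft], [], mir, mrna, "s0")
        assert "m1" not in net.graph

    def test_interaction_edges_between_expressed(self):
        ft, mir, mrna = self._setup()
        mrna.loc["t2"] = [2.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        net = tn.build_tissue_network(
            [ft], [("t1", "t2")], mir, mrna, "s0"
        )
        net.validate()
        assert net.graph.edges["t1", "t2"]["kind"] == "interaction"

    def test_missing_tissue_errors(self):
        ft, mir, mrna = self._setup()
        with pytest.raises(ValueError):
            tn.build_tissue_network([ft], [], mir, mrna, "nope")


class TestDecomposeModules:
    def _network(self, edges, n_nodes):
        import networkx as nx

        g = nx.Graph()
        nodes = [f"n{i}" for i in range(n_nodes)]
        g.add_nodes_from(nodes, kind="mRNA", log2_ratio=0.0, state=0)
        for a, b in edges:
            g.add_edge(a, b, kind="interaction", partition=None)
        return tn.RegulatoryNetwork("t", g), nodes

    def test_two_disjoint_components(self):
        net, _ = self._network([("n0", "n1"), ("n2", "n3")], 4)
        labels = tn.decompose_modules(net)
        assert len(set(labels.values())) == 2
        assert labels["n0"] == labels["n1"]
        assert labels["n2"] == labels["n3"]

    def test_fully_connected_single_module(self):
        edges = [(f"n{i}", f"n{j}") for i in range(5) for j in range(i + 1, 5)]
        net, _ = self._network(edges, 5)
        assert set(tn.decompose_modules(net).values()) == {1}

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(13)
        n = 30
        edges = [
            (f"n{int(a)}", f"n{int(b)}")
            for a, b in rng.integers(0, n, size=(25, 2))
            if a != b
        ]
        net, nodes = self._network(edges, n)
        labels = tn.decompose_modules(net)
        expected = union_find_components(nodes, edges)
        got = {}
        for node, lab in labels.items():
            got.setdefault(lab, set()).add(node)
        assert {frozenset(v) for v in got.values()} == set(expected)


class TestClusterTissues:
    def test_duplicated_columns_join_with_full_support(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(40, 3))
        X = np.column_stack([base, base[:, 0]])
        df = pd.DataFrame(X, columns=["a", "b", "c", "a2"])
        link, labels, support = tn.cluster_tissues(df, n_resamples=50, rng=0)
        assert support[frozenset({"a", "a2"})] == 1.0

    def test_separated_groups_high_support(self):
        rng = np.random.default_rng(2)
        n_feat = 60
        g1 = rng.normal(0, 1, size=(n_feat, 3)) + np.linspace(0, 5, n_feat)[:, None]
        g2 = rng.normal(0, 1, size=(n_feat, 3)) - np.linspace(0, 5, n_feat)[:, None]
        df = pd.DataFrame(
            np.column_stack([g1, g2]),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        _, _, support = tn.cluster_tissues(df, n_resamples=100, rng=3)
        split = frozenset({"a1", "a2", "a3"})
        other = frozenset({"b1", "b2", "b3"})
        assert support.get(split, support.get(other, 0.0)) >= 0.95

    def test_support_in_unit_interval(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 5)))
        _, _, support = tn.cluster_tissues(df, n_resamples=30, rng=5)
        assert all(0.0 <= v <= 1.0 for v in support.values())

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            tn.cluster_tissues(pd.DataFrame({"a": [1.0, 2.0]}), 10)


class TestArmRatios:
    def _matrix(self, five, three):
        cols = [f"s{i}" for i in range(len(five))]
        return pd.DataFrame(
            {
                "P_1_100_160_+_5p": five,
                "P_1_100_160_+_3p": three,
                "P_2_5_80_-_5p": [1.0] * len(five),  # partner arm missing
            },
            index=cols,
        ).T

    def test_identical_arms(self):
        m = self._matrix([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        ratios, corr = tn.arm_ratio_profiles(m)
        assert np.allclose(ratios.loc["P_1_100_160_+"], 0.0)
        assert corr["P_1_100_160_+"] == pytest.approx(1.0)
        assert "P_2_5_80_-" not in corr.index

    def test_anticorrelated_arms(self):
        five = [1.0, 2.0, 3.0, 4.0]
        three = [4.0, 3.0, 2.0, 1.0]
        _, corr = tn.arm_ratio_profiles(self._matrix(five, three))
        assert corr["P_1_100_160_+"] == pytest.approx(-1.0)

    def test_ratios_match_elementwise(self):
        # oracle: direct arithmetic
        rng = np.random.default_rng(6)
        five = rng.lognormal(0, 1, 5)
        three = rng.lognormal(0, 1, 5)
        ratios, _ = tn.arm_ratio_profiles(self._matrix(list(five), list(three)))
        assert np.allclose(
            ratios.loc["P_1_100_160_+"].to_numpy(), np.log2(five / three)
        )

    def test_nan_propagates(self):
        m = self._matrix([1.0, np.nan, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        ratios, _ = tn.arm_ratio_profiles(m)
        assert np.isnan(ratios.loc["P_1_100_160_+"].iloc[1])


class TestFamilyEnrichment:
    def test_family_equals_universe_p_one(self):
        universe = {f"m{i}" for i in range(10)}
        p = tn.family_enrichment(universe, {"fam": universe}, universe)
        assert p["fam"] == pytest.approx(1.0)

    def test_exact_combinatorial_count(self):
        # oracle: p = 1 / C(20, 5) for full overlap
        from math import comb

        universe = {f"m{i}" for i in range(20)}
        family = {f"m{i}" for i in range(5)}
        p = tn.family_enrichment(family, {"fam": family}, universe)
        assert p["fam"] == pytest.approx(1 / comb(20, 5))

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(8)
        universe = {f"m{i}" for i in range(50)}
        fams = {
            f"f{j}": set(rng.choice(sorted(universe), size=8, replace=False))
            for j in range(5)
        }
        subset = set(rng.choice(sorted(universe), size=12, replace=False))
        for p in tn.family_enrichment(subset, fams, universe).values():
            assert 0.0 < p <= 1.0

    def test_subset_outside_universe_errors(self):
        with pytest.raises(ValueError):
            tn.family_enrichment({"x"}, {"f": {"x"}}, {"y"})


class TestSpongeCandidates:
    def test_planted_sponge_reported(self, small_config):
        mi, _, li, _ = sd.generate_tissue_expression(
            10, [("m1", "g1")], [("lincA", "m1")], [], small_config
        )
        out = tn.sponge_candidates(li, mi, threshold=0.85)
        assert ("lincA", "m1") in {(l, m) for l, m, _ in out}

    def test_independent_profiles_null_rate(self, small_config):
        # oracle: permutation of tissue labels
        rng = np.random.default_rng(10)
        mi, _, li, _ = sd.generate_tissue_expression(
            8, [], [], [], small_config, extra_mirnas=15, extra_lincs=15
        )
        out = tn.sponge_candidates(li, mi, threshold=0.9)
        base = mi.iloc[0].to_numpy()
        other = li.iloc[0].to_numpy()
        null = sum(
            np.corrcoef(base, rng.permutation(other))[0, 1] >= 0.9
            for _ in range(2000)
        ) / 2000
        n_pairs = len(mi.index) * len(li.index)
        bound = null + 3 * np.sqrt(max(null, 1 / 2000) / n_pairs)
        assert len(out) / n_pairs <= bound + 5e-3

    def test_threshold_one_only_collinear(self, small_config):
        cfg = sd.SimulationConfig(rng_seed=2, planted_target_correlation=-1.0)
        mi, _, li, _ = sd.generate_tissue_expression(
            8, [], [("lincA", "m1")], [], cfg, extra_lincs=4
        )
        out = tn.sponge_candidates(li, mi, threshold=1.0 - 1e-12)
        assert {(l, m) for l, m, _ in out} == {("lincA", "m1")}


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=30)
        df = pd.DataFrame({"a": col, "b": col, "c": col})
        out = tn.quantile_normalize(df)
        assert np.allclose(out.to_numpy(), df.to_numpy())

    def test_columns_share_sorted_distribution(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(40, 5)))
        out = tn.quantile_normalize(df).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            assert np.array_equal(np.sort(out[:, j]), ref)

    def test_matches_naive_reference(self):
        # oracle: naive two-pass implementation (tie-free input)
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 4))
        df = pd.DataFrame(X)
        out = tn.quantile_normalize(df).to_numpy()
        assert np.allclose(out, naive_quantile_normalize(X))

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_property_shared_distribution(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(12, 3)))
        out = tn.quantile_normalize(df).to_numpy()
        for j in range(1, 3):
            assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, j]))
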