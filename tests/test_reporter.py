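"""Reporter-metabolite statistics: Z-scores, backgrounds, significance."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from tigsmm.reporter import (
    GeneStat,
    MetaboliteNeighborhood,
    build_neighborhoods,
    gene_zscore,
    read_gene_stats,
    reporter_scores,
    reporter_subnetwork,
    significant_reporters,
    write_gene_stats,
)


class TestGeneZscore:
    def test_aligned_direction_uses_half_p(self):
        # two-sided p = 0.05 moving with the direction of interest:
        # one-tailed p = 0.025, Z = inverse normal at 0.975
        z = gene_zscore(GeneStat("g", 0.05, "up"), "up")
        assert z == pytest.approx(1.9600, abs=5e-4)

    def test_opposing_direction_lands_in_lower_tail(self):
        z = gene_zscore(GeneStat("g", 0.01, "down"), "up")
        assert z == pytest.approx(-2.5758, abs=5e-4)

    def test_p_one_is_zero_either_way(self):
        assert gene_zscore(GeneStat("g", 1.0, "up"), "up") == pytest.approx(0.0)
        assert gene_zscore(GeneStat("g", 1.0, "down"), "up") == pytest.approx(0.0)

    def test_symmetry_between_directions(self):
        up = gene_zscore(GeneStat("g", 0.02, "up"), "up")
        down = gene_zscore(GeneStat("g", 0.02, "up"), "down")
        assert up == pytest.approx(-down, abs=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            GeneStat("g", 0.0, "up")
        with pytest.raises(ValueError):
            GeneStat("g", 1.5, "up")


class TestNeighborhoods:
    def test_union_of_gpr_leaves_over_touching_reactions(self, textbook):
        nbs = {nb.metabolite_id: nb.genes for nb in build_neighborhoods(textbook)}
        # B_c is made by R_HI (g1), R_LO (g2), R_BYP (g3); consumed by
        # BIOMASS and R_SPONT which have no GPR
        assert nbs["B_c"] == {"g1", "g2", "g3"}
        assert nbs["A_e"] == {"g4"}

    def test_gprless_metabolite_not_scorable(self, textbook):
        nbs = {nb.metabolite_id for nb in build_neighborhoods(textbook)}
        assert "D_c" not in nbs  # only spontaneous + exchange touch D_c

    def test_exclusion_list(self, textbook):
        nbs = {nb.metabolite_id for nb in build_neighborhoods(textbook, exclude=["B_c"])}
        assert "B_c" not in nbs


def _finite_population_oracle(z, k):
    """Closed-form mean/std of sum(sample k without replacement)/sqrt(k)."""
    n = len(z)
    mu = k * z.mean() / math.sqrt(k)
    var_sum = k * z.var(ddof=0) * (n - k) / (n - 1)
    return mu, math.sqrt(var_sum) / math.sqrt(k)


class TestBackground:
    def test_exact_enumeration_matches_closed_form(self):
        rng = np.random.default_rng(3)
        stats = [
            GeneStat(f"g{i}", float(p), "up" if i % 2 else "down")
            for i, p in enumerate(rng.uniform(0.01, 1.0, size=12))
        ]
        nbs = [MetaboliteNeighborhood("m", {"g0", "g1", "g2"})]
        res = reporter_scores(nbs, stats, seed=0, background="exact")
        z = np.array([gene_zscore(s, "up") for s in stats])
        mu, sd = _finite_population_oracle(z, 3)
        z_raw = (z[0] + z[1] + z[2]) / math.sqrt(3)
        expected = (z_raw - mu) / sd
        assert res.scores[0].z_corrected_up == pytest.approx(expected, rel=1e-9)

    def test_singleton_background_is_exact_standardization(self):
        # k = 1 over a 4-gene universe: enumeration covers all 4 sets
        ps = [0.9, 0.5, 0.2, 0.04]
        stats = [GeneStat(f"g{i}", p, "up") for i, p in enumerate(ps)]
        nbs = [MetaboliteNeighborhood(f"m{i}", {f"g{i}"}) for i in range(4)]
        res = reporter_scores(nbs, stats, seed=0)
        z = np.array([gene_zscore(s, "up") for s in stats])
        for i, score in enumerate(res.scores):
            expected = (z[i] - z.mean()) / z.std(ddof=0)
            assert score.z_corrected_up == pytest.approx(expected, rel=1e-9)

    def test_constant_universe_gives_zero_corrected_score(self):
        stats = [GeneStat(f"g{i}", 0.3173, "up") for i in range(5)]
        nbs = [MetaboliteNeighborhood("m", {"g0", "g1"})]
        res = reporter_scores(nbs, stats, seed=0)
        assert res.scores[0].z_corrected_up == pytest.approx(0.0, abs=1e-6)
        assert res.scores[0].p_up == pytest.approx(0.5, abs=1e-6)

    def test_sampler_rejects_k_larger_than_universe(self):
        from tigsmm.reporter import _sample_index_matrix

        with pytest.raises(ValueError):
            _sample_index_matrix(np.random.default_rng(0), 3, 5, 10)


class TestScoring:
    def test_planted_hot_metabolite_ranks_first(self):
        rng = np.random.default_rng(11)
        stats = [
            GeneStat(f"g{i}", float(rng.uniform(0.001, 1.0)),
                     "up" if rng.random() < 0.5 else "down")
            for i in range(200)
        ]
        hot_genes = {"h1", "h2", "h3"}
        stats += [GeneStat(g, 0.001, "up") for g in sorted(hot_genes)]
        nbs = [MetaboliteNeighborhood("hot", hot_genes)]
        for i in range(50):
            genes = {f"g{j}" for j in rng.choice(200, size=4, replace=False)}
            nbs.append(MetaboliteNeighborhood(f"null{i}", genes))
        res = reporter_scores(nbs, stats, seed=2)
        best = min(res.scores, key=lambda s: s.p_up)
        assert best.metabolite_id == "hot"

    def test_stronger_signal_never_weakens_call(self):
        rng = np.random.default_rng(4)
        null_stats = [
            GeneStat(f"g{i}", float(rng.uniform(0.01, 1.0)), "up" if i % 2 else "down")
            for i in range(60)
        ]
        nbs = [MetaboliteNeighborhood("planted", {"h1", "h2"})]
        p_ups = []
        for p_hot in (0.5, 0.1, 0.01, 0.001):
            stats = null_stats + [GeneStat("h1", p_hot, "up"), GeneStat("h2", p_hot, "up")]
            res = reporter_scores(nbs, stats, seed=9)
            p_ups.append(res.scores[0].p_up)
        assert all(b <= a + 1e-12 for a, b in zip(p_ups, p_ups[1:]))

    def test_identical_seed_is_bitwise_deterministic(self):
        rng = np.random.default_rng(5)
        stats = [
            GeneStat(f"g{i}", float(rng.uniform(0.01, 1.0)), "up") for i in range(40)
        ]
        nbs = [
            MetaboliteNeighborhood(f"m{i}", {f"g{j}" for j in range(i, i + 5)})
            for i in range(10)
        ]
        a = reporter_scores(nbs, stats, seed=123, background="sample")
        b = reporter_scores(nbs, stats, seed=123, background="sample")
        assert a.to_frame().equals(b.to_frame())


class TestSignificance:
    def test_alpha_cut_per_direction(self):
        stats = [GeneStat(f"g{i}", 0.5, "up") for i in range(30)]
        nbs = [MetaboliteNeighborhood(f"m{i}", {f"g{i}", f"g{i+1}"}) for i in range(5)]
        res = reporter_scores(nbs, stats, seed=0)
        sig = significant_reporters(res, alpha=0.05)
        assert set(sig) == {"up", "down"}
        # manual threshold application agrees
        assert sig["up"] == [s.metabolite_id for s in res.scores if s.p_up < 0.05]

    def test_all_null_gives_empty_at_tiny_alpha(self):
        stats = [GeneStat(f"g{i}", 0.9, "up") for i in range(10)]
        nbs = [MetaboliteNeighborhood("m", {"g0", "g1"})]
        res = reporter_scores(nbs, stats, seed=0)
        sig = significant_reporters(res, alpha=1e-6)
        assert sig["up"] == [] and sig["down"] == []


class TestSubnetworkAndIo:
    def test_edges_for_significant_metabolites(self, textbook):
        edges = reporter_subnetwork(textbook, ["B_c"])
        rxns = {r for _, r in edges}
        assert rxns == {"R_HI", "R_LO", "R_BYP", "R_SPONT", "BIOMASS"}
        assert all(m == "B_c" for m, _ in edges)

    def test_empty_set_gives_empty_graph(self, textbook):
        assert reporter_subnetwork(textbook, []) == []

    def test_shared_reaction_appears_per_metabolite(self, textbook):
        edges = reporter_subnetwork(textbook, ["B_c", "C_c"])
        biomass_edges = [e for e in edges if e[1] == "BIOMASS"]
        assert len(biomass_edges) == 2

    def test_gene_stats_roundtrip(self, tmp_path):
        stats = [GeneStat("g1", 0.05, "up"), GeneStat("g2", 0.9, "down")]
        write_gene_stats(stats, tmp_path / "gs.tsv")
        back = read_gene_stats(tmp_path / "gs.tsv")
        assert back == stats
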