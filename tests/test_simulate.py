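import numpy as np
import pytest

from crossdeg.enrichment import hypergeom_tail
from crossdeg.errors import ConfigError, ValidationError
from crossdeg.ppi import closeness, ppi_score
from crossdeg.simulate import (
    GroundTruth,
    QUADRANT_SIGNS,
    SynthConfig,
    nb_sample,
    simulate_annotations,
    simulate_assays,
    simulate_counts,
    simulate_ppi,
)


class TestConfig:
    def test_invalid_fields_named(self):
        with pytest.raises(ConfigError, match="n_orthologs"):
            SynthConfig(n_genes=10, n_orthologs=20).validate()
        with pytest.raises(ConfigError, match="planted_quadrant_counts"):
            SynthConfig(n_orthologs=10, planted_quadrant_counts=(5, 5, 5, 5)).validate()
        with pytest.raises(ConfigError, match="dispersion"):
            SynthConfig(dispersion=-1).validate()


class TestCounts:
    def test_determinism(self):
        cfg = SynthConfig(seed=42, n_genes=200, n_orthologs=150,
                          planted_quadrant_counts=(5, 5, 5, 5),
                          planted_specific_counts=(10, 10, 5, 5))
        a1, b1, m1, t1 = simulate_counts(cfg)
        a2, b2, m2, t2 = simulate_counts(cfg)
        assert a1.counts.equals(a2.counts) and b1.counts.equals(b2.counts)
        assert m1.pairs == m2.pairs
        assert t1.quadrants == t2.quadrants

    def test_zero_effect_empties_truth(self):
        cfg = SynthConfig(seed=1, n_genes=100, n_orthologs=80,
                          planted_quadrant_counts=(2, 2, 2, 2),
                          planted_specific_counts=(2, 2, 2, 2),
                          planted_effect_log2fc=0.0)
        _, _, _, truth = simulate_counts(cfg)
        assert not (truth.up_a | truth.down_a | truth.up_b | truth.down_b)
        assert not truth.quadrants

    def test_quadrant_labels_match_effect_signs(self):
        cfg = SynthConfig(seed=3, n_genes=300, n_orthologs=250,
                          planted_quadrant_counts=(10, 10, 10, 10),
                          planted_specific_counts=(0, 0, 0, 0))
        _, _, _, truth = simulate_counts(cfg)
        truth.validate()  # internal consistency check
        for (a, b), lab in truth.quadrants.items():
            sa, sb = QUADRANT_SIGNS[lab]
            assert (a in truth.up_a) == (sa > 0)
            assert (b in truth.up_b) == (sb > 0)

    def test_nb_moments(self, rng):
        """Monte-Carlo oracle: gamma-Poisson draws match NB mean/variance."""
        mu, alpha, n = 100.0, 0.1, 10_000
        y = nb_sample(rng, np.full(n, mu), alpha)
        true_var = mu + alpha * mu**2
        se_mean = np.sqrt(true_var / n)
        assert abs(y.mean() - mu) < 3 * se_mean
        # SE of the sample variance via the 4th moment of the sample
        m4 = np.mean((y - y.mean()) ** 4)
        se_var = np.sqrt((m4 - true_var**2) / n)
        assert abs(y.var(ddof=1) - true_var) < 3 * se_var

    def test_truth_json_round_trip(self, tmp_path):
        cfg = SynthConfig(seed=9, n_genes=100, n_orthologs=80,
                          planted_quadrant_counts=(3, 3, 3, 3),
                          planted_specific_counts=(5, 5, 5, 5))
        _, _, _, truth = simulate_counts(cfg)
        truth.hub = "gB00001"
        truth.to_json(tmp_path / "gt.json")
        back = GroundTruth.from_json(tmp_path / "gt.json")
        assert back.quadrants == truth.quadrants and back.up_a == truth.up_a
        assert back.hub == truth.hub


class TestAnnotations:
    def _setup(self, seed, rate):
        cfg = SynthConfig(seed=seed, n_genes=2000, n_orthologs=1500,
                          planted_term_enrichment=rate)
        genes = [f"gB{i:05d}" for i in range(2000)]
        truth = GroundTruth(up_b=set(genes[:50]))
        anno = simulate_annotations(cfg, truth, genes)
        return cfg, genes, truth, anno

    def test_determinism(self):
        _, _, t1, a1 = self._setup(7, 0.8)
        _, _, t2, a2 = self._setup(7, 0.8)
        assert a1.terms == a2.terms and t1.enriched_term == t2.enriched_term

    def test_empty_gene_list_rejected(self):
        cfg = SynthConfig(seed=1)
        with pytest.raises(ValidationError):
            simulate_annotations(cfg, GroundTruth(), [])

    def test_planted_term_is_strongly_enriched(self):
        """Power oracle: planted-term hypergeometric p < 1e-6 in >95% of runs."""
        hits = 0
        n_sim = 100
        for seed in range(n_sim):
            _, genes, truth, anno = self._setup(seed, 0.8)
            _, members = anno.terms[truth.enriched_term]
            k = len(members & truth.up_b)
            p = hypergeom_tail(k, 2000, len(members), 50)
            hits += p < 1e-6
        assert hits > 95

    def test_background_rate_plant_is_null(self):
        """At background annotation rate the planted term is unremarkable."""
        ps = []
        for seed in range(40):
            # null terms cover ~ mean(20..100)/2000 = 3% of the universe
            _, genes, truth, anno = self._setup(seed, 0.03)
            _, members = anno.terms[truth.enriched_term]
            k = len(members & truth.up_b)
            ps.append(hypergeom_tail(k, 2000, len(members), 50))
        assert np.mean(np.array(ps) < 0.05) < 0.25


class TestPPI:
    def test_no_hub_recorded_when_extra_degree_zero(self):
        cfg = SynthConfig(seed=1, graph_n_nodes=20, graph_n_edges=30,
                          hub_extra_degree=0)
        g, hub = simulate_ppi(cfg, [f"n{i}" for i in range(50)])
        assert hub is None

    def test_star_topology_forced(self):
        cfg = SynthConfig(seed=1, graph_n_nodes=10, graph_n_edges=0,
                          hub_extra_degree=9)
        g, hub = simulate_ppi(cfg, [f"n{i}" for i in range(10)])
        assert g.degree(hub) == 9
        assert all(d == 1 for v, d in g.degree if v != hub)

    def test_simple_graph_invariants(self):
        cfg = SynthConfig(seed=5, graph_n_nodes=50, graph_n_edges=120,
                          hub_extra_degree=10)
        g, hub = simulate_ppi(cfg, [f"n{i}" for i in range(80)])
        assert not any(a == b for a, b in g.edges)
        assert g.number_of_nodes() == 50

    def test_too_few_nodes_rejected(self):
        cfg = SynthConfig(seed=1)
        with pytest.raises(ConfigError, match="graph_n_nodes"):
            simulate_ppi(cfg, ["a"])

    def test_hub_recovery_rate(self):
        """Planted hub ranks first by PPI score in nearly all simulations."""
        wins = 0
        n_sim = 30
        genes = [f"n{i}" for i in range(400)]
        for seed in range(n_sim):
            cfg = SynthConfig(seed=seed, graph_n_nodes=300, graph_n_edges=600,
                              hub_extra_degree=60)
            g, hub = simulate_ppi(cfg, genes)
            c = closeness(g)
            scores = {v: ppi_score(g.degree(v), c[v]) for v in g.nodes}
            wins += max(scores, key=lambda v: (scores[v], g.degree(v))) == hub
        assert wins >= int(0.95 * n_sim)


class TestAssays:
    def test_determinism(self):
        cfg = SynthConfig(seed=2)
        ct1, pl1, abr1 = simulate_assays(cfg)
        ct2, pl2, abr2 = simulate_assays(cfg)
        assert ct1.equals(ct2) and pl1.equals(pl2) and abr1.equals(abr2)

    def test_noise_free_null_ddct_gives_rq_one(self):
        from crossdeg.assays import ddct_quantify

        cfg = SynthConfig(seed=1, ct_noise_sd=0.0, true_ddct=0.0)
        ct, _, _ = simulate_assays(cfg)
        per_sample, _ = ddct_quantify(ct)
        assert per_sample["rq"].to_numpy() == pytest.approx(np.ones(6))

    def test_planted_abr_threshold_is_step(self):
        cfg = SynthConfig(seed=1, abr_thresholds={"Pre-NE": {f: 45 for f in (4, 8, 16, 24, 32)}})
        _, _, abr = simulate_assays(cfg)
        sub = abr[(abr["frequency_khz"] == 16)]
        assert (sub.loc[sub["intensity_db"] >= 45, "detectable"]).all()
        assert (~sub.loc[sub["intensity_db"] < 45, "detectable"]).all()
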