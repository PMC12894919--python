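import numpy as np
import pytest
from scipy import stats

from co2fix import (
    SimulationConfig,
    assign_kos,
    detection_probability,
    generate_corpus,
    load_ruleset,
    minimal_satisfying_profile,
    near_miss_profile,
    parse_kofam_tsv,
    predict,
    predict_batch,
    write_corpus,
    write_mock_kofam_tsv,
)
from co2fix.simulate import DECOY_POOL


class TestMinimalProfiles:
    def test_wl_i(self, rules):
        p = minimal_satisfying_profile(rules, "WL", "WL-I")
        assert p.kos == {"K00198", "K14138"}

    def test_dc4hb_picks_first_alternative(self, rules):
        p = minimal_satisfying_profile(rules, "DC4HB", "DC4HB")
        assert p.kos == {"K01595", "K01676", "K18861", "K14534"}

    def test_rgly_uses_min_count_prefix(self, rules):
        p = minimal_satisfying_profile(rules, "rGly", "rGly")
        assert len(p.kos) == 8  # 3 cleavage + 5 reductase subunits

    def test_every_variant_satisfies_its_pathway(self, rules):
        for pathway in rules:
            for variant in pathway.variants:
                p = minimal_satisfying_profile(
                    rules, pathway.pathway_id, variant.variant_id
                )
                pred = predict(p, rules)
                assert pred.calls[pathway.pathway_id]
                assert variant.variant_id in pred.evidence[pathway.pathway_id]

    def test_unknown_variant(self, rules):
        with pytest.raises(KeyError, match="WL-I"):
            minimal_satisfying_profile(rules, "WL", "WL-IX")


class TestNearMiss:
    def test_every_variant_has_a_near_miss(self, rules, rng):
        for pathway in rules:
            for variant in pathway.variants:
                miss = near_miss_profile(
                    rules, pathway.pathway_id, variant.variant_id, rng
                )
                base = minimal_satisfying_profile(
                    rules, pathway.pathway_id, variant.variant_id
                )
                assert len(base.kos - miss.kos) == 1
                assert not predict(miss, rules).calls[pathway.pathway_id]

    def test_rgly_near_miss_drops_below_threshold(self, rules, rng):
        miss = near_miss_profile(rules, "rGly", "rGly", rng)
        assert len(miss.kos) == 7
        assert not predict(miss, rules).calls["rGly"]


class TestCorpus:
    def test_same_seed_reproduces_byte_identically(self, rules, tmp_path):
        cfg = SimulationConfig(seed=5, n_per_pathway=3, dropout_p=0.2)
        a = generate_corpus(cfg, rules)
        b = generate_corpus(cfg, rules)
        assert a.profiles == b.profiles
        assert a.truth.equals(b.truth)
        d1, d2 = tmp_path / "one", tmp_path / "two"
        write_corpus(a, d1)
        write_corpus(b, d2)
        for f in sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_noise_free_corpus_is_recovered_exactly(self, rules):
        cfg = SimulationConfig(seed=2, n_per_pathway=4, dropout_p=0.0)
        corpus = generate_corpus(cfg, rules)
        batch = predict_batch(corpus.profiles, rules)
        assert batch.matrix.equals(corpus.truth.loc[batch.matrix.index])

    def test_decoy_pool_disjoint_from_markers(self, rules):
        assert not set(DECOY_POOL) & rules.all_marker_kos

    def test_truth_records_intended_pathway_despite_dropout(self, rules):
        cfg = SimulationConfig(seed=9, n_per_pathway=5, dropout_p=0.5,
                               background_k=5)
        corpus = generate_corpus(cfg, rules)
        pos = corpus.metadata[corpus.metadata.role == "pos"]
        for gid, row in pos.iterrows():
            assert corpus.truth.loc[gid, row.pathway_id] == 1

    def test_no_false_positives_without_dropout_interference(self, rules):
        # dropout removes KOs only, and the truth ignores it: predictions can
        # miss intended pathways but never claim unintended ones
        cfg = SimulationConfig(seed=3, n_per_pathway=10, dropout_p=0.3)
        corpus = generate_corpus(cfg, rules)
        batch = predict_batch(corpus.profiles, rules)
        truth = corpus.truth.loc[batch.matrix.index]
        assert int((batch.matrix.values & ~truth.values.astype(bool)).sum()) == 0

    def test_combo_genomes_are_multilabel(self, rules):
        cfg = SimulationConfig(seed=1, n_per_pathway=2)
        corpus = generate_corpus(cfg, rules)
        combos = corpus.metadata[corpus.metadata.role == "combo"]
        assert set(combos.pathway_id) == {"CBB+WL", "WL+rGly"}
        for gid in combos.index:
            assert corpus.truth.loc[gid].sum() == 2

    def test_variant_choice_first_vs_all(self, rules):
        all_c = generate_corpus(SimulationConfig(seed=1, n_per_pathway=2), rules)
        first_c = generate_corpus(
            SimulationConfig(seed=1, n_per_pathway=2, variant_choice="first"), rules
        )
        all_variants = set(
            all_c.metadata[all_c.metadata.role == "pos"].variant_id
        )
        assert {"rTCA-II", "WL-II", "3HP4HB-II"} <= all_variants
        first_variants = set(
            first_c.metadata[first_c.metadata.role == "pos"].variant_id
        )
        assert not {"rTCA-II", "WL-II", "3HP4HB-II"} & first_variants

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(dropout_p=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(variant_choice="best")
        with pytest.raises(ValueError):
            SimulationConfig(n_per_pathway=0)


class TestDetectionProbability:
    def test_conjunctive_variant_closed_form(self, rules):
        # WL-I requires 2 markers: survival is (1-p)^2
        kos = minimal_satisfying_profile(rules, "WL", "WL-I").kos
        assert detection_probability(rules, "WL", kos, 0.1) == pytest.approx(0.81)

    def test_at_least_matches_binomial_tail(self):
        # single at_least(3 of 5) clause with all 5 markers present: the
        # closed form is the Binomial(5, 1-p) upper tail (scipy as oracle)
        doc = {
            "version": "t",
            "pathways": [{
                "pathway_id": "P", "display_name": "p",
                "variants": [{
                    "variant_id": "P",
                    "clauses": [{
                        "quantifier": "at_least",
                        "kos": ["K00001", "K00002", "K00003", "K00004", "K00005"],
                        "min_count": 3,
                    }],
                }],
            }],
        }
        mini = load_ruleset(doc)
        p = 0.2
        got = detection_probability(
            mini, "P", ["K00001", "K00002", "K00003", "K00004", "K00005"], p
        )
        expected = stats.binom.sf(2, 5, 1 - p)
        assert got == pytest.approx(expected)

    def test_monte_carlo_agreement(self, rules, rng):
        # simulate dropout directly and compare to the exact enumeration
        kos = sorted(minimal_satisfying_profile(rules, "rGly", "rGly").kos)
        p = 0.15
        q = detection_probability(rules, "rGly", kos, p)
        n = 4000
        keep = rng.random((n, len(kos))) >= p
        hits = sum(
            predict_pathway(rules, {k for k, kept in zip(kos, row) if kept})
            for row in keep
        )
        se = np.sqrt(q * (1 - q) / n)
        assert abs(hits / n - q) < 4 * se


def predict_pathway(rules, kos):
    from co2fix import KOProfile, predict as _predict

    return _predict(KOProfile("g", frozenset(kos)), rules).calls["rGly"]


class TestMockKofamTsv:
    def test_round_trip_recovers_profile(self, rules, rng):
        profile = minimal_satisfying_profile(rules, "rGly", "rGly")
        tsv = write_mock_kofam_tsv(profile, rng)
        recovered = assign_kos(parse_kofam_tsv(tsv), profile.genome_id)
        assert recovered.kos == profile.kos

    def test_single_ko(self, rules, rng):
        from co2fix import KOProfile

        tsv = write_mock_kofam_tsv(KOProfile("g", frozenset({"K00855"})), rng)
        data_rows = [l for l in tsv.splitlines() if l and not l.startswith("#")]
        assert len(data_rows) == 1 and data_rows[0].startswith("*")
        assert assign_kos(parse_kofam_tsv(tsv), "g").kos == {"K00855"}

    def test_fallback_gene_contributes_its_top_decoy(self, rules, rng):
        profile = minimal_satisfying_profile(rules, "CBB", "CBB")
        tsv = write_mock_kofam_tsv(profile, rng, fallback_kos=["K90007"])
        recovered = assign_kos(parse_kofam_tsv(tsv), "g")
        assert recovered.kos == profile.kos | {"K90007"}
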