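"""Ground-truth recovery from the synthetic generator."""

import numpy as np
import pytest

from tefp.expression import delta_delta_ct, densitometry_relative
from tefp.probemap import annotation_hits, sequence_hits
from tefp.synthetic_data import (
    FamilyModel,
    GroupConfig,
    ScenarioConfig,
    default_probes,
    evolve_individuals,
    make_genome,
    realize,
    simulate_expression,
    simulate_ladders,
    three_subline_scenario,
)
from tefp.vsouthern import match_ladders, predict_bands
from tefp.seqres import digest_genome


def small_scenario(seed=7, **kw):
    defaults = dict(
        chrom_lengths={"c1": 300_000, "c2": 200_000},
        families=[FamilyModel("I", 5371, p_full=0.2)],
        planted_copies={"I": 4},
        groups=[GroupConfig("G", 3, insertion_rates={"I": 0.5})],
        generations=6,
        seed=seed,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestMakeGenome:
    def test_full_length_copies_annotated(self):
        g = make_genome(small_scenario())
        _, insertions = realize(g, g.founder_copies)
        assert len(insertions) == 4
        assert all(i.consensus_span == (0, 5371) for i in insertions)
        assert all(i.completeness == "full" for i in insertions)

    def test_zero_copies_yield_no_bands(self):
        g = make_genome(small_scenario(planted_copies={"I": 0}))
        records, insertions = realize(g, g.founder_copies)
        frags = digest_genome(records, g.config.enzyme)
        hits = []
        for p in default_probes(g)["I"]:
            hits.extend(annotation_hits(insertions, p))
        assert predict_bands(frags, hits) == []

    def test_genome_too_small_rejected(self):
        with pytest.raises(ValueError, match="10x"):
            make_genome(small_scenario(chrom_lengths={"c1": 100_000}, planted_copies={"I": 4}))

    def test_planted_copies_recovered_by_sequence_search(self):
        g = make_genome(small_scenario(planted_copies={"I": 3}))
        records, insertions = realize(g, g.founder_copies)
        probe = default_probes(g)["I"][1]  # 3' probe, present in every copy
        hits = sequence_hits(records, probe)
        hit_intervals = {(h.genomic.seq_id, h.genomic.start, h.genomic.end) for h in hits}
        for ins in insertions:
            expected = annotation_hits([ins], probe)[0].genomic
            assert (expected.seq_id, expected.start, expected.end) in hit_intervals


class TestEvolveIndividuals:
    def test_zero_rates_identical_to_founder(self):
        cfg = small_scenario(groups=[GroupConfig("G", 3)])
        g = make_genome(cfg)
        evolved = evolve_individuals(g, cfg)
        for copies in evolved["G"]:
            assert copies == g.founder_copies

    def test_deterministic_under_seed(self):
        cfg = small_scenario()
        g1, g2 = make_genome(cfg), make_genome(cfg)
        assert g1.background == g2.background
        e1, e2 = evolve_individuals(g1, cfg), evolve_individuals(g2, cfg)
        assert e1 == e2

    def test_truncated_fraction_matches_p_full(self):
        cfg = small_scenario(
            chrom_lengths={"c1": 2_000_000},
            groups=[GroupConfig("G", 4, insertion_rates={"I": 2.0})],
            generations=10,
        )
        g = make_genome(cfg)
        evolved = evolve_individuals(g, cfg)
        new = [
            c
            for copies in evolved["G"]
            for c in copies
            if c not in g.founder_copies
        ]
        frac_trunc = np.mean([c.consensus_span[0] > 0 for c in new])
        n = len(new)
        assert n > 40
        # binomial 99% CI around 1 - p_full = 0.8
        half = 2.58 * np.sqrt(0.8 * 0.2 / n)
        assert abs(frac_trunc - 0.8) <= half + 0.02

    def test_truncations_keep_3prime_tail(self):
        cfg = small_scenario()
        g = make_genome(cfg)
        evolved = evolve_individuals(g, cfg)
        for copies in evolved["G"]:
            for c in copies:
                s, e = c.consensus_span
                assert e == 5371
                assert e - s >= 500  # min_tail retained


class TestSimulateLadders:
    def test_zero_noise_open_window_matches_predictions(self):
        cfg = small_scenario(gel_sd=0.0, lane_sd=0.0, detection_window=(0.0, np.inf))
        g = make_genome(cfg)
        records, insertions = realize(g, g.founder_copies)
        frags = digest_genome(records, cfg.enzyme)
        hits = []
        for p in default_probes(g)["I"]:
            hits.extend(annotation_hits(insertions, p))
        predicted = predict_bands(frags, hits)
        (lad,) = simulate_ladders(g, g.founder_copies, "f0")
        assert len(lad.bands) == len(predicted)
        m = match_ladders(lad, predicted, 0.01)
        assert len(m.pairs) == len(predicted)  # only 10 bp rounding separates them

    def test_band_outside_window_dropped(self):
        cfg = small_scenario(gel_sd=0.0, lane_sd=0.0)
        g = make_genome(cfg)
        (lad,) = simulate_ladders(g, g.founder_copies, "f0")
        assert all(1.5 <= b.size_estimate <= 12.0 for b in lad.bands)
        # the unwindowed ladder is a superset
        cfg_open = small_scenario(gel_sd=0.0, lane_sd=0.0, detection_window=(0.0, np.inf))
        g_open = make_genome(cfg_open)
        (lad_open,) = simulate_ladders(g_open, g_open.founder_copies, "f0")
        assert len(lad_open.bands) >= len(lad.bands)

    def test_noise_rarely_breaks_matching_tolerance(self):
        """Lognormal size noise at sd 0.02 leaves >=95% of bands within 5%."""
        rng = np.random.default_rng(11)
        noise = np.exp(rng.normal(0.0, 0.02, size=1000))
        assert np.mean(np.abs(noise - 1.0) <= 0.05) >= 0.95


class TestExpressionPresets:
    def test_adult_preset_densitometry_truth(self):
        _, dens = simulate_expression("adult_females", ct_noise_sd=0.0, seed=3)
        rel5 = densitometry_relative(dens, "Montpellier", "I5", "G6PD")
        rel3 = densitometry_relative(dens, "Montpellier", "I3", "G6PD")
        assert rel5["Seattle"] == pytest.approx(0.30)
        assert rel3["Seattle"] == pytest.approx(0.50)
        assert rel5["JA"] == 0.0  # no 5' transcripts in the reactive strain
        assert rel3["JA"] > 0.0

    def test_gonad_preset_ddct_truth(self):
        ct, _ = simulate_expression("gonads", ct_noise_sd=0.0, seed=3)
        rq = {
            r.sample_id: r.rq
            for r in delta_delta_ct(ct, "I3", "G6PD", "Bari_gonads")
        }
        assert rq["dysgenic_M_gonads"] / rq["dysgenic_S_gonads"] == pytest.approx(2.5)

    def test_gonad_preset_rank_order(self):
        ct, _ = simulate_expression("gonads", ct_noise_sd=0.0, seed=3)
        for target in ("I5", "I3"):
            rq = {r.sample_id: r.rq for r in delta_delta_ct(ct, target, "G6PD", "Bari_gonads")}
            assert rq["Montpellier_gonads"] > rq["dysgenic_M_gonads"]
            assert rq["Montpellier_gonads"] > rq["dysgenic_S_gonads"]
            assert min(rq["dysgenic_M_gonads"], rq["dysgenic_S_gonads"]) > rq["nondysgenic_gonads"]
            assert rq["nondysgenic_gonads"] >= rq["JA_gonads"]

    def test_undetected_targets_emitted_as_nan(self):
        ct, _ = simulate_expression("adult_females", seed=3)
        ja_i5 = ct[(ct.sample_id == "JA") & (ct.gene == "I5")]
        assert ja_i5["ct"].isna().all()

    def test_noisy_recovery_unbiased(self):
        """Monte-Carlo: sd 0.2, n=6, many seeds -> mean ratio within 5% of 2.5."""
        ratios = []
        for seed in range(200):
            ct, _ = simulate_expression("gonads", n_replicates=6, ct_noise_sd=0.2, seed=seed)
            rq = {r.sample_id: r.rq for r in delta_delta_ct(ct, "I3", "G6PD", "Bari_gonads")}
            ratios.append(rq["dysgenic_M_gonads"] / rq["dysgenic_S_gonads"])
        assert abs(np.mean(ratios) / 2.5 - 1.0) <= 0.05


def test_three_prime_only_sites_monotone_in_truncation():
    """Lowering p_full never lowers the count of 3'-only (truncation-signature) sites."""
    counts = []
    for p_full in (0.9, 0.5, 0.1):
        cfg = small_scenario(
            seed=5,
            chrom_lengths={"c1": 3_000_000},
            families=[FamilyModel("I", 5371, p_full=p_full)],
            groups=[GroupConfig("G", 2, insertion_rates={"I": 5.0})],
            generations=10,
        )
        g = make_genome(cfg)
        evolved = evolve_individuals(g, cfg)
        probes = default_probes(g)
        p5, p3 = probes["I"]
        n3only = 0
        for copies in evolved["G"]:
            _, insertions = realize(g, copies)
            # count copies hit by the 3' probe but not the 5' probe
            for ins in insertions:
                has3 = bool(annotation_hits([ins], p3))
                has5 = bool(annotation_hits([ins], p5))
                n3only += has3 and not has5
        counts.append(n3only)
    assert counts == sorted(counts)


def test_scenario_lane_table_deterministic():
    from tefp.synthetic_data import simulate_scenario_ladders

    cfg = three_subline_scenario(seed=2)
    g = make_genome(cfg)
    df1 = simulate_scenario_ladders(g, cfg)
    df2 = simulate_scenario_ladders(g, cfg)
    assert df1.equals(df2)
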