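"""Link-perturbation protocols, ranking metrics and baselines."""

import numpy as np
import pytest

from _oracles import random_hetnet
from dtwalk import (
    PerturbationPlan,
    RemovalRecord,
    WalkParams,
    auac,
    auc,
    auc_top,
    bedroc,
    compute_metrics,
    enrichment_factor,
    multi_link_removal,
    randomized_baseline,
    rank_held_out,
    recovered_fraction,
    sequence_baseline,
    shuffle_network,
    single_link_removal,
)


def rec(rank, n=100, drug="d", target="t"):
    return RemovalRecord(drug=drug, target=target, rank=rank, n_candidates=n)


def auc_pairwise_oracle(records):
    """Exhaustive Mann-Whitney count: every hit vs every non-hit pair."""
    wins = total = 0
    for r in records:
        for other_rank in range(1, r.n_candidates + 1):
            if other_rank == r.rank:
                continue
            wins += other_rank > r.rank
            total += 1
    return wins / total


class TestRecoveredFraction:
    def test_direct_count(self):
        assert recovered_fraction([rec(3), rec(60)], 10) == 0.5

    def test_saturates_at_one(self):
        assert recovered_fraction([rec(1), rec(9), rec(10)], 10) == 1.0

    def test_empty_top_list(self):
        assert recovered_fraction([rec(3)], 0) == 0.0

    def test_non_decreasing_in_n(self, rng):
        records = [rec(int(r)) for r in rng.integers(1, 101, size=30)]
        fracs = [recovered_fraction(records, n) for n in range(0, 101, 5)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))


class TestAUC:
    def test_single_record_exhaustive(self):
        # rank 3 of 10 candidates beats 7 of the 9 non-hits
        records = [rec(3, n=10)]
        assert auc(records) == pytest.approx(7 / 9)
        assert auc(records) == pytest.approx(auc_pairwise_oracle(records))

    def test_matches_pairwise_oracle_on_random_sets(self, rng):
        for _ in range(20):
            records = [
                rec(int(rng.integers(1, n + 1)), n=n, drug=f"d{k}")
                for k, n in enumerate(rng.integers(2, 21, size=rng.integers(1, 11)))
            ]
            assert auc(records) == pytest.approx(auc_pairwise_oracle(records))

    def test_perfect_ranking_scores_one(self):
        assert auc([rec(1, n=50)] * 5) == 1.0

    def test_uniform_ranks_score_half(self, rng):
        records = [
            rec(int(rng.integers(1, 201)), n=200) for _ in range(10_000)
        ]
        assert auc(records) == pytest.approx(0.5, abs=0.02)

    def test_degenerate_single_candidate_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            value = auc([rec(1, n=1), rec(2, n=10)])
        assert value == pytest.approx(8 / 9)


class TestAUAC:
    def test_perfect_ranking_approaches_one(self):
        # rank 1 of n gives 1 - 1/n, tending to 1 as the list grows
        assert auac([rec(1, n=10)]) == pytest.approx(0.9)
        assert auac([rec(1, n=10_000)]) >= 0.999

    def test_accumulation_area(self):
        # ranks 25 and 75 of 100: mean relative rank 0.5
        assert auac([rec(25), rec(75)]) == pytest.approx(0.5)


class TestAUCTop:
    def test_perfect_ranking_scores_one(self):
        assert auc_top([rec(1, n=100)], 0.1) == 1.0

    def test_hit_outside_window_scores_zero(self):
        assert auc_top([rec(50, n=100)], 0.1) == 0.0

    def test_random_expectation_is_half_the_window(self, rng):
        records = [
            rec(int(rng.integers(1, 201)), n=200) for _ in range(10_000)
        ]
        assert auc_top(records, 0.1) == pytest.approx(0.05, abs=0.01)


class TestBEDROC:
    def test_all_hits_first_reach_the_closed_form_maximum(self):
        assert bedroc([rec(1, n=50)] * 4, alpha=20.0) == pytest.approx(1.0)

    def test_all_hits_last_reach_the_closed_form_minimum(self):
        assert bedroc([rec(50, n=50)] * 4, alpha=20.0) == pytest.approx(0.0)

    def test_uniform_hits_near_analytic_expectation(self, rng):
        alpha = 20.0
        records = [
            rec(int(rng.integers(1, 201)), n=200) for _ in range(10_000)
        ]
        # uniform relative ranks: RIE = 1, hence (1 - RIE_min)/(RIE_max - RIE_min)
        um = (1 - np.exp(-alpha)) / alpha
        expected = (1 - np.exp(-alpha) / um) / (1 / um - np.exp(-alpha) / um)
        assert bedroc(records, alpha) == pytest.approx(expected, abs=0.01)

    def test_early_hits_always_beat_late_hits(self):
        early = [rec(5, n=100)] * 3
        late = [rec(60, n=100)] * 3
        for alpha in (2.0, 10.0, 30.0):
            assert bedroc(early, alpha) > bedroc(late, alpha)

    def test_bounds_and_alpha_validation(self, rng):
        records = [rec(int(r), n=40) for r in rng.integers(1, 41, size=20)]
        assert 0.0 <= bedroc(records, 20.0) <= 1.0
        with pytest.raises(ValueError):
            bedroc(records, alpha=0.0)


class TestEnrichmentFactor:
    def test_all_hits_in_window_saturate(self):
        assert enrichment_factor([rec(5, n=100)] * 3, 0.1) == pytest.approx(10.0)

    def test_no_hits_in_window(self):
        assert enrichment_factor([rec(90, n=100)], 0.1) == 0.0

    def test_random_expectation_is_one(self, rng):
        records = [
            rec(int(rng.integers(1, 201)), n=200) for _ in range(10_000)
        ]
        assert enrichment_factor(records, 0.1) == pytest.approx(1.0, abs=0.1)

    def test_never_exceeds_inverse_window(self, rng):
        for frac in (0.05, 0.1, 0.5):
            records = [rec(int(r), n=60) for r in rng.integers(1, 61, size=50)]
            assert enrichment_factor(records, frac) <= 1 / frac + 1e-12


class TestSingleLinkRemoval:
    def test_one_record_per_linked_drug(self, rng):
        net = random_hetnet(rng, 5, 6, p_link=0.3)
        records = single_link_removal(net, WalkParams(), rng_seed=3)
        linked = [d for d in net.drug_ids if net.interactions.targets_of(d)]
        assert len(records) == len(linked)
        assert {r.drug for r in records} == set(linked)

    def test_single_target_drug_loses_its_only_link(self, rng):
        net = random_hetnet(rng, 3, 4, p_link=0.0)
        net = net.interactions.with_links([("d0", "t0")])
        from dtwalk import rebuild_with_interactions

        net = rebuild_with_interactions(random_hetnet(rng, 3, 4, 0.0), net)
        records = single_link_removal(net, WalkParams(), rng_seed=0)
        assert len(records) == 1
        assert records[0].drug == "d0" and records[0].target == "t0"
        # the hidden target competes against all targets
        assert records[0].n_candidates == 4

    def test_same_seed_same_removals(self, rng):
        net = random_hetnet(rng, 5, 6, p_link=0.4)
        a = single_link_removal(net, WalkParams(), rng_seed=9)
        b = single_link_removal(net, WalkParams(), rng_seed=9)
        assert a == b


class TestMultiLinkRemoval:
    def test_infeasible_count_reports_eligible_links(self, rng):
        net = random_hetnet(rng, 4, 5, p_link=0.3)
        with pytest.raises(ValueError, match="degree"):
            multi_link_removal(
                net,
                WalkParams(),
                PerturbationPlan(n_remove=10_000, repeats=1, min_degree=1),
            )

    def test_repeats_resample_distinct_links(self, rng):
        net = random_hetnet(rng, 6, 8, p_link=0.5)
        per_repeat = multi_link_removal(
            net,
            WalkParams(),
            PerturbationPlan(n_remove=5, repeats=2, min_degree=2, rng_seed=1),
        )
        assert len(per_repeat) == 2
        sets = [frozenset((r.drug, r.target) for r in rep) for rep in per_repeat]
        assert sets[0] != sets[1]

    def test_removing_all_eligible_links(self, rng):
        net = random_hetnet(rng, 5, 6, p_link=0.5)
        eligible = [
            (d, t)
            for d, t in net.interactions.links
            if net.interactions.drug_degree(d) >= 2
        ]
        per_repeat = multi_link_removal(
            net,
            WalkParams(),
            PerturbationPlan(
                n_remove=len(eligible), repeats=1, min_degree=2, rng_seed=0
            ),
        )
        assert len(per_repeat[0]) == len(eligible)


class TestRandomizedBaseline:
    def test_shuffle_preserves_degrees(self, rng):
        net = random_hetnet(rng, 8, 9, p_link=0.3)
        null = shuffle_network(net, rng_seed=5)
        A, B = net.interactions.matrix(), null.interactions.matrix()
        np.testing.assert_array_equal(A.sum(axis=1), B.sum(axis=1))
        np.testing.assert_array_equal(A.sum(axis=0), B.sum(axis=0))

    def test_shuffle_is_seeded(self, rng):
        net = random_hetnet(rng, 8, 9, p_link=0.3)
        a = shuffle_network(net, rng_seed=5)
        b = shuffle_network(net, rng_seed=5)
        assert a.interactions.links == b.interactions.links
        np.testing.assert_array_equal(a.drug_layer.values, b.drug_layer.values)

    def test_baseline_report_is_deterministic(self, rng):
        net = random_hetnet(rng, 6, 8, p_link=0.4)
        a = randomized_baseline(net, WalkParams(), rng_seed=2)
        b = randomized_baseline(net, WalkParams(), rng_seed=2)
        assert a == b

    def test_planted_network_dominates_its_baseline(
        self, default_world, default_net, default_params, held_out_records
    ):
        """The real pipeline must beat the degree-preserving null on early
        recognition and recovery of the held-out links."""
        report = compute_metrics(held_out_records, top_ns=(10, 50))
        null = randomized_baseline(
            default_net,
            default_params,
            rng_seed=default_world.params.rng_seed,
            held_out=default_world.held_out_links,
            top_ns=(10, 50),
        )
        assert report.auc > null.auc
        assert report.bedroc > null.bedroc
        assert report.recovered[10] > null.recovered[10]
        assert report.recovered[50] > null.recovered[50]

    def test_removed_links_rank_far_better_than_null(
        self, default_net, default_params, default_world
    ):
        """Single-link removal on the planted world: the hidden targets'
        median rank is far below the null network's."""
        records = single_link_removal(
            default_net, default_params, rng_seed=11
        )
        null_net = shuffle_network(default_net, rng_seed=11)
        null_records = single_link_removal(null_net, default_params, rng_seed=11)
        med = np.median([r.rank for r in records])
        null_med = np.median([r.rank for r in null_records])
        assert med * 2 <= null_med


class TestSequenceBaseline:
    def test_identical_sequence_ranks_first(self, default_world, default_net):
        preds = sequence_baseline(default_net)
        # zero-mutation copies do not exist; check score monotone with T_s
        drug = next(iter(preds))
        pred = preds[drug]
        assert pred.scores == tuple(sorted(pred.scores, reverse=True))

    def test_single_known_target_follows_similarity_column(self, rng):
        net = random_hetnet(rng, 2, 6, p_link=0.0)
        from dtwalk import rebuild_with_interactions

        net = rebuild_with_interactions(
            net, net.interactions.with_links([("d0", "t0")])
        )
        preds = sequence_baseline(net, ["d0"])
        col = {
            t: net.target_layer.values[0, j]
            for j, t in enumerate(net.target_ids)
            if t != "t0"
        }
        expected = tuple(sorted(col, key=lambda t: (-col[t], t)))
        assert preds["d0"].targets == expected

    def test_drug_without_targets_is_skipped(self, rng, caplog):
        net = random_hetnet(rng, 3, 4, p_link=0.0)
        with caplog.at_level("WARNING"):
            preds = sequence_baseline(net)
        assert preds == {}


class TestRankHeldOut:
    def test_present_link_rejected(self, rng):
        net = random_hetnet(rng, 4, 4, p_link=1.0)
        with pytest.raises(ValueError):
            rank_held_out(net, [("d0", "t0")], WalkParams())
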