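"""Selection-frequency, single-propensity and pair-cooperation protocols."""

import numpy as np
import pytest

import gfsmlp as g
from gfsmlp.experiments import SelectionFrequencyTable, derive_run_seeds

FAST = g.TrainingConfig(iterations=60)


class TestSeedDerivation:
    def test_prefix_property(self):
        full = derive_run_seeds(123, 10)
        head = derive_run_seeds(123, 4)
        tail = derive_run_seeds(123, 6, run_offset=4)
        assert np.array_equal(full, np.concatenate([head, tail]))

    def test_distinct_runs_get_distinct_seeds(self):
        seeds = derive_run_seeds(0, 100)
        assert len(np.unique(seeds)) == 100
        assert np.all(seeds >= 0) and np.all(seeds < 2**31)


class TestRankPropensities:
    def test_counts_bounded_by_runs(self, small_model):
        tab = g.rank_propensities(small_model, FAST, runs=3, seed=1)
        assert np.all(tab.counts >= 0) and np.all(tab.counts <= 3)
        assert tab.runs == 3

    def test_single_run_on_separable_data(self, small_model):
        tab = g.rank_propensities(small_model, FAST, runs=1, seed=2)
        assert tab.counts.sum() >= 0
        assert tab.gates_per_run.shape == (1, 8)

    def test_identical_master_seed_reproduces_table(self, small_model):
        a = g.rank_propensities(small_model, FAST, runs=3, seed=5)
        b = g.rank_propensities(small_model, FAST, runs=3, seed=5)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.gates_per_run, b.gates_per_run)

    def test_split_experiments_merge_to_the_full_experiment(self, small_model):
        full = g.rank_propensities(small_model, FAST, runs=4, seed=9)
        first = g.rank_propensities(small_model, FAST, runs=2, seed=9)
        second = g.rank_propensities(small_model, FAST, runs=2, seed=9, run_offset=2)
        merged = SelectionFrequencyTable.merge([first, second])
        assert np.array_equal(merged.counts, full.counts)
        assert merged.runs == full.runs
        assert np.array_equal(merged.gates_per_run, full.gates_per_run)

    def test_zero_runs_rejected(self, small_model):
        with pytest.raises(ValueError):
            g.rank_propensities(small_model, FAST, runs=0)

    def test_ranking_orders_by_count(self):
        tab = SelectionFrequencyTable(
            counts=np.array([1, 5, 5, 0]), runs=10,
            group_names=list("abcd"), threshold=0.5, master_seed=0,
        )
        assert tab.ranking() == [2, 3, 1, 4]


class TestEvaluateSinglePropensity:
    def test_sd_is_zero_for_single_run(self, small_model):
        res = g.evaluate_single_propensity(small_model, 8, FAST, runs=1, seed=0)
        assert res.sd == 0.0
        assert res.runs == 1

    def test_informative_group_separates_small_data(self, small_model):
        res = g.evaluate_single_propensity(
            small_model, 8, g.TrainingConfig(iterations=200), runs=2, seed=1
        )
        assert res.mean < 10.0

    def test_invalid_group_rejected(self, small_model):
        with pytest.raises(ValueError):
            g.evaluate_single_propensity(small_model, 0, FAST)
        with pytest.raises(ValueError):
            g.evaluate_single_propensity(small_model, 9, FAST)

    def test_mu_is_forced_to_zero(self, small_model):
        # even with a config carrying mu > 0, gates must stay clamped
        res = g.evaluate_single_propensity(
            small_model, 2, g.TrainingConfig(iterations=30, mu=0.5), runs=1, seed=3
        )
        assert res.errors.shape == (1,)


class TestPairCooperation:
    def test_counts_bounded_and_seeded_gate_stays_open(self, small_model):
        tab = g.pair_cooperation(
            small_model, 8, g.TrainingConfig(iterations=200), runs=3, seed=2
        )
        assert np.all(tab.counts <= 3)
        # group 8 drives the labels in this dataset: its seeded gate stays open
        assert tab.counts[7] == 3
        assert tab.total_with_seed - tab.total_without_seed == tab.counts[7]

    def test_requires_trainable_gates(self, small_model):
        with pytest.raises(ValueError, match="mu > 0"):
            g.pair_cooperation(small_model, 1, g.TrainingConfig(mu=0.0))

    def test_invalid_seed_group(self, small_model):
        with pytest.raises(ValueError):
            g.pair_cooperation(small_model, 99, FAST)


def test_xor_pair_is_coselected_when_seeding_its_partner(orthogonal_scales):
    """Jointly-informative pair: seeding one group should open its partner.

    Uses constructed orthogonal scales so neither group is marginally
    informative on its own; the signal lives in the (1, 2) interaction.
    """
    spec = g.SyntheticSpec(
        n_per_class=120, informative_groups=(1, 2), joint_mode="xor",
        effect=3.0, noise=0.0, seed=11,
    )
    ds = g.generate(spec, orthogonal_scales)
    model = g.GFSMLP.from_dataset(ds, orthogonal_scales)
    tab = g.pair_cooperation(
        model, 1, g.TrainingConfig(iterations=300), runs=6, seed=4
    )
    others = np.delete(tab.counts, 0)
    assert tab.counts[1] == others.max()
    assert tab.counts[1] > 0


def test_summaries_render(small_model):
    tab = g.rank_propensities(small_model, FAST, runs=2, seed=0)
    assert "Selection frequency" in tab.summary()
    res = g.evaluate_single_propensity(small_model, 8, FAST, runs=2, seed=0)
    assert "+/-" in res.summary()
    pc = g.pair_cooperation(small_model, 8, g.TrainingConfig(iterations=60), runs=2, seed=0)
    assert "seeded" in pc.summary()
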