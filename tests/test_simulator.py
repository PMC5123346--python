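"""Simulator mechanics: coordinate mapping, deletion/merge bookkeeping,
replenishment, and the model's sampling laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fractionate import (
    INVISIBLE,
    VISIBLE,
    GenomeState,
    Segment,
    SimConfig,
    SweepParams,
    apply_deletion,
    collect_lengths,
    counter_census,
    map_concat_to_original,
    new_genome,
    overlap_histogram,
    overlap_pmf,
    replenish,
    run_fractionation,
    run_sweep,
    validate_genome_state,
)
from fractionate.errors import ConfigurationError
from fractionate.simulator import concat_coordinate


def three_segment_state():
    return GenomeState(
        [
            Segment(0.0, 10.0, VISIBLE),
            Segment(10.0, 20.0, INVISIBLE, 3),
            Segment(20.0, 30.0, VISIBLE),
        ],
        sweep_index=1,
        target_visible_length=20.0,
    )


class TestCoordinateMapping:
    def test_identity_on_fresh_genome(self):
        state = new_genome(100.0)
        assert map_concat_to_original(state, 7.0) == 7.0

    def test_skips_invisible_run(self):
        assert map_concat_to_original(three_segment_state(), 15.0) == 25.0

    def test_round_trip_is_inverse(self):
        state = three_segment_state()
        for y in [0.0, 3.7, 9.99, 20.0, 24.5, 29.9]:
            assert map_concat_to_original(state, concat_coordinate(state, y)) == (
                pytest.approx(y)
            )

    def test_strictly_increasing(self):
        state = three_segment_state()
        xs = np.linspace(0, 19.99, 50)
        ys = [map_concat_to_original(state, x) for x in xs]
        assert all(b > a for a, b in zip(ys, ys[1:]))

    def test_out_of_range(self):
        state = three_segment_state()
        with pytest.raises(ValueError, match="outside visible extent"):
            map_concat_to_original(state, 20.0)
        with pytest.raises(ValueError):
            map_concat_to_original(state, -1.0)


class TestApplyDeletion:
    def test_first_deletion_counter_one(self):
        state, event = apply_deletion(new_genome(100.0), 10.0, 5.0)
        validate_genome_state(state)
        assert event.q == 0 and event.merged_counter == 1
        inv = state.invisible_segments()
        assert len(inv) == 1
        assert (inv[0].start, inv[0].end, inv[0].counter) == (10.0, 15.0, 1)

    def test_merge_across_junction(self):
        # [8, 12) in concatenated coords swallows the run at junction 10
        state, event = apply_deletion(three_segment_state(), 8.0, 4.0)
        validate_genome_state(state)
        assert event.q == 1 and event.swallowed_counters == (3,)
        inv = state.invisible_segments()
        assert len(inv) == 1
        assert (inv[0].start, inv[0].end, inv[0].counter) == (8.0, 22.0, 4)

    def test_merge_two_runs(self):
        state = GenomeState(
            [
                Segment(0.0, 10.0, VISIBLE),
                Segment(10.0, 12.0, INVISIBLE, 1),
                Segment(12.0, 20.0, VISIBLE),
                Segment(20.0, 25.0, INVISIBLE, 2),
                Segment(25.0, 40.0, VISIBLE),
            ],
            sweep_index=2,
            target_visible_length=33.0,
        )
        # concat coords: [0,10) | [10,18) | [18,33); delete [9, 20) covers
        # both junctions (10 and 18)
        new_state, event = apply_deletion(state, 9.0, 11.0)
        validate_genome_state(new_state)
        assert event.q == 2 and sorted(event.swallowed_counters) == [1, 2]
        inv = new_state.invisible_segments()
        assert len(inv) == 1
        assert inv[0].counter == 4  # 1 + 1 + 2
        assert (inv[0].start, inv[0].end) == (9.0, 27.0)

    def test_overhang_truncated(self):
        state, event = apply_deletion(new_genome(100.0), 95.0, 50.0)
        validate_genome_state(state)
        assert state.segments[-1].state == INVISIBLE
        assert state.segments[-1].end == 100.0
        assert state.visible_length() == pytest.approx(95.0)

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            apply_deletion(new_genome(100.0), 10.0, 0.0)

    def test_span_conserved(self):
        state = three_segment_state()
        new_state, _ = apply_deletion(state, 4.0, 9.0)
        assert new_state.total_span() == pytest.approx(state.total_span())
        assert new_state.visible_length() + new_state.invisible_length() == (
            pytest.approx(state.total_span())
        )


class TestDeletionProperties:
    @staticmethod
    def build_state(lengths):
        segs = []
        pos = 0.0
        for k, ln in enumerate(lengths):
            if k % 2 == 0:
                segs.append(Segment(pos, pos + ln, VISIBLE))
            else:
                segs.append(Segment(pos, pos + ln, INVISIBLE, 1 + k))
            pos += ln
        state = GenomeState(segs, 1, sum(lengths[::2]))
        validate_genome_state(state)
        return state

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        lengths=st.lists(
            st.floats(0.5, 40.0, allow_nan=False), min_size=1, max_size=9
        ),
        frac=st.floats(0.0, 0.999),
        a=st.floats(0.01, 100.0),
    )
    def test_deletion_preserves_span_and_invariants(self, lengths, frac, a):
        """Any admissible deletion keeps the genome contiguous,
        alternating, and of unchanged total span; its merged counter is
        1 plus the swallowed counters."""
        state = self.build_state(lengths)
        x_conc = frac * state.visible_length()
        new_state, event = apply_deletion(state, x_conc, a)
        validate_genome_state(new_state)
        assert new_state.total_span() == pytest.approx(state.total_span())
        assert event.merged_counter == 1 + sum(event.swallowed_counters)
        assert new_state.visible_length() <= state.visible_length() + 1e-9


class TestSweep:
    def test_first_sweep_all_counters_one(self):
        state, events = run_sweep(
            new_genome(10_000.0), SweepParams(nu=3, mu=1), np.random.default_rng(5)
        )
        validate_genome_state(state)
        assert state.sweep_index == 1
        assert all(s.counter == 1 for s in state.invisible_segments())
        assert all(e.q == 0 for e in events)

    def test_tiny_mu_limit_retains_everything(self):
        state, _ = run_sweep(
            new_genome(10_000.0),
            SweepParams(nu=3, mu=1e-9),
            np.random.default_rng(5),
        )
        assert state.visible_length() / 10_000.0 > 0.999999

    def test_single_sweep_retained_fraction(self):
        # mean deleted fraction per sweep is mu/(nu+mu) = 0.25
        fracs = []
        for seed in range(20):
            state, _ = run_sweep(
                new_genome(10_000.0),
                SweepParams(nu=3, mu=1),
                np.random.default_rng(seed),
            )
            fracs.append(state.visible_length() / 10_000.0)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.75) < 3 * se


class TestTrajectory:
    def test_zero_sweeps_is_fresh_genome(self):
        res = run_fractionation(
            SweepParams(nu=3, mu=1), SimConfig(sweeps=0, replicates=2, seed=1)
        )
        assert len(res.states) == 1
        for st in res.states[0]:
            assert len(st.segments) == 1
            assert st.segments[0].length == pytest.approx(10_000.0)

    def test_invariants_hold_after_every_sweep(self, std_run_t5):
        for states in std_run_t5.states:
            for st in states:
                validate_genome_state(st)
                assert st.visible_length() + st.invisible_length() == pytest.approx(
                    st.total_span()
                )

    def test_replenished_visible_length_restored(self, std_run_t5):
        for states in std_run_t5.states[1:]:
            for st in states:
                assert st.visible_length() == pytest.approx(10_000.0, abs=1e-6)

    def test_determinism_bit_for_bit(self):
        def table(res):
            return [
                (s.start, s.end, s.state, s.counter)
                for st in res.final_states()
                for s in st.segments
            ]

        params = SweepParams(nu=3, mu=1)
        config = SimConfig(sweeps=3, replicates=3, seed=77)
        assert table(run_fractionation(params, config)) == table(
            run_fractionation(params, config)
        )

    def test_small_genome_warns(self):
        with pytest.warns(UserWarning, match="genome_length"):
            run_fractionation(
                SweepParams(nu=3, mu=10), SimConfig(sweeps=1, genome_length=500,
                                                    replicates=2, seed=1)
            )

    @pytest.mark.parametrize("mu,nu,t_max", [(1.0, 3.0, 5), (5.0, 15.0, 8)])
    def test_retained_fraction_law(self, mu, nu, t_max):
        """Mean visible fraction after t sweeps tracks (1 - mu/(nu+mu))^t."""
        n_seeds = 20
        fracs = np.empty((n_seeds, t_max))
        for s in range(n_seeds):
            res = run_fractionation(
                SweepParams(nu=nu, mu=mu),
                SimConfig(sweeps=t_max, replicates=1, seed=1000 + s,
                          replenish=False),
            )
            for t in range(1, t_max + 1):
                fracs[s, t - 1] = res.states[t][0].visible_length() / 10_000.0
        keep = 1.0 - mu / (nu + mu)
        for t in range(1, t_max + 1):
            col = fracs[:, t - 1]
            se = col.std(ddof=1) / np.sqrt(n_seeds)
            assert abs(col.mean() - keep**t) < 3 * se, f"t={t}"

    def test_spacing_law(self, std_run_t5):
        """Mean visible segment length after sweep t is nu/t."""
        for t in range(1, 6):
            sample = collect_lengths(std_run_t5.states[t])
            se = sample.visible.std(ddof=1) / np.sqrt(len(sample.visible))
            assert abs(sample.visible.mean() - 3.0 / t) < 3 * se, f"t={t}"

    def test_visible_lengths_exponential_ks(self, seeded_runs_t5):
        """Per-genome visible lengths pass KS vs Exponential(nu/t) at 0.01
        in at least 4 of 5 seeds."""
        passes = 0
        for res in seeded_runs_t5:
            sample = collect_lengths(res.final_states()[0])
            p = stats.kstest(sample.visible, "expon", args=(0, 3.0 / 5)).pvalue
            passes += p > 0.01
        assert passes >= 4

    def test_overlap_counts_follow_geometric_law(self, std_run_t5):
        """Pooled q-histograms of sweeps 2..5 match the geometric pmf with
        the sweep-specific spacing lambda_{t-1} = nu/(t-1)."""
        q_cap = 8
        obs = np.zeros(q_cap + 1)
        exp = np.zeros(q_cap + 1)
        for t in range(2, 6):
            lam = 3.0 / (t - 1)
            events = [e for rep in std_run_t5.events[t - 1] for e in rep]
            hist = overlap_histogram(events)
            assert sum(hist.values()) == len(events)
            for q, c in hist.items():
                obs[min(q, q_cap)] += c
            pmf = np.array([overlap_pmf(q, 1.0, lam) for q in range(q_cap)])
            pmf = np.append(pmf, 1.0 - pmf.sum())
            exp += len(events) * pmf
        exp *= obs.sum() / exp.sum()
        assert stats.chisquare(obs, exp).pvalue > 0.01

    def test_first_sweep_histogram_all_q_zero(self, std_run_t5):
        events = [e for rep in std_run_t5.events[0] for e in rep]
        assert overlap_histogram(events) == {0: len(events)}


class TestReplenish:
    def test_no_deficit_unchanged(self):
        state = new_genome(1000.0)
        donor = new_genome(1000.0)
        out = replenish(state, [donor])
        assert [(s.start, s.end, s.state) for s in out.segments] == [
            (s.start, s.end, s.state) for s in state.segments
        ]

    def test_restores_target_and_preserves_counters(self):
        rng = np.random.default_rng(3)
        params = SweepParams(nu=3, mu=1)
        swept, _ = run_sweep(new_genome(10_000.0), params, rng)
        donor, _ = run_sweep(new_genome(10_000.0), params, rng)
        out = replenish(swept, [donor])
        validate_genome_state(out)
        assert out.visible_length() == pytest.approx(10_000.0, abs=1e-6)
        # the copied invisible runs carry the donor counters verbatim
        donor_census = counter_census(donor)
        appended = [
            s.counter
            for s in out.segments
            if s.state == INVISIBLE and s.start >= swept.total_span()
        ]
        assert appended  # something was copied
        assert set(appended) <= set(donor_census)

    def test_empty_pool_rejected(self):
        rng = np.random.default_rng(3)
        swept, _ = run_sweep(new_genome(10_000.0), SweepParams(nu=3, mu=1), rng)
        with pytest.raises(ConfigurationError, match="pool"):
            replenish(swept, [])

    def test_mismatched_sweep_index_rejected(self):
        rng = np.random.default_rng(3)
        swept, _ = run_sweep(new_genome(10_000.0), SweepParams(nu=3, mu=1), rng)
        with pytest.raises(ConfigurationError, match="sweep_index"):
            replenish(swept, [new_genome(10_000.0)])


class TestObservables:
    def test_collect_lengths_fresh_genome(self):
        sample = collect_lengths(new_genome(500.0))
        assert list(sample.visible) == [500.0]
        assert len(sample.invisible) == 0

    def test_collect_lengths_counts_and_total(self, std_run_t5):
        for st in std_run_t5.final_states():
            sample = collect_lengths(st)
            assert abs(len(sample.visible) - len(sample.invisible)) <= 1
            assert sample.visible.sum() + sample.invisible.sum() == pytest.approx(
                st.total_span()
            )

    def test_collect_lengths_rejects_mixed_sweeps(self, std_run_t5):
        with pytest.raises(ValueError, match="sweep"):
            collect_lengths([std_run_t5.states[1][0], std_run_t5.states[2][0]])

    def test_counter_census_empty_signal(self):
        assert counter_census(new_genome(100.0)) == {}

    def test_counter_census_proportions(self, std_run_t5):
        census = counter_census(std_run_t5.final_states())
        assert sum(census.values()) == pytest.approx(1.0)
        assert all(i >= 1 for i in census)
        census1 = counter_census(std_run_t5.states[1])
        assert census1 == {1: 1.0}


class TestValidation:
    def test_rejects_adjacent_same_state(self):
        bad = GenomeState(
            [Segment(0, 1, VISIBLE), Segment(1, 2, VISIBLE)], 0, 2.0
        )
        with pytest.raises(ValueError, match="share state"):
            validate_genome_state(bad)

    def test_rejects_gap(self):
        bad = GenomeState(
            [Segment(0, 1, VISIBLE), Segment(1.5, 2, INVISIBLE, 1)], 0, 1.0
        )
        with pytest.raises(ValueError, match="gap"):
            validate_genome_state(bad)

    def test_rejects_missing_counter(self):
        bad = GenomeState(
            [Segment(0, 1, VISIBLE), Segment(1, 2, INVISIBLE)], 0, 1.0
        )
        with pytest.raises(ValueError, match="counter"):
            validate_genome_state(bad)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SweepParams(nu=0, mu=1)
        with pytest.raises(ValueError):
            SweepParams(nu=1, mu=-2)
        # nu > mu is NOT required
        SweepParams(nu=1, mu=5)
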