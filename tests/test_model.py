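import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnascout import (
    ArchiveExhausted,
    BatchResult,
    CoverageState,
    RunRecord,
    SelectionParams,
    choose_next_run,
    estimate_profile,
    expected_score_after_batch,
    score,
    update_state,
)
from oracles import naive_profile, naive_score


def make_state(per_run, n_tiles):
    state = CoverageState(n_tiles)
    for run_id, counts in per_run.items():
        counts = np.asarray(counts, dtype=np.int64)
        state.per_run[run_id] = counts.copy()
        state.c += counts
    return state


class TestScore:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((0, 0, 0), 0.0),
            ((1, 0), math.log(2)),
            ((3, 1, 0), math.log(4) + math.log(2)),
        ],
    )
    def test_closed_form(self, counts, expected):
        assert score(counts) == pytest.approx(expected, abs=1e-12)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            score([1, -1])

    @given(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=20),
        st.data(),
    )
    def test_strictly_monotone_in_every_tile(self, counts, data):
        j = data.draw(st.integers(0, len(counts) - 1))
        delta = data.draw(st.floats(min_value=1e-6, max_value=100.0))
        bumped = list(map(float, counts))
        bumped[j] += delta
        assert score(bumped) > score(counts)

    def test_matches_naive_loop(self, rng):
        counts = rng.integers(0, 50, size=30)
        assert score(counts) == pytest.approx(naive_score(counts), rel=1e-12)


class TestEstimateProfile:
    def test_no_data_gives_uniform(self):
        state = make_state({}, 2)
        profile = estimate_profile("r1", state, SelectionParams())
        np.testing.assert_allclose(profile, [0.5, 0.5])

    def test_worked_example_with_symmetric_pooled_profile(self):
        # pooled counts (4,4) -> pbar=(1/2,1/2); run counts (3,1), lambda=10,
        # a=1, T=2: weights (3+10+1, 1+10+1) = (14,12) -> (14/26, 12/26)
        state = make_state({"r1": [3, 1], "r2": [1, 3]}, 2)
        profile = estimate_profile("r1", state, SelectionParams())
        np.testing.assert_allclose(profile, [14 / 26, 12 / 26], atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_probability_vector_and_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(1, 30))
        n_runs = int(rng.integers(1, 5))
        per_run = {f"r{i}": rng.integers(0, 40, size=T) for i in range(n_runs)}
        state = make_state(per_run, T)
        params = SelectionParams(
            lambda_=float(rng.uniform(0, 20)), a=float(rng.uniform(0, 3))
        )
        profile = estimate_profile("r0", state, params)
        assert profile.sum() == pytest.approx(1.0, abs=1e-9)
        assert (profile >= 0).all()
        if params.a > 0:
            assert (profile > 0).all()
        expected = naive_profile(
            list(per_run["r0"]), list(state.c), params.lambda_, params.a
        )
        np.testing.assert_allclose(profile, expected, atol=1e-12)


class TestExpectedScore:
    def test_single_tile_closed_form(self):
        state = make_state({}, 1)
        params = SelectionParams(b=10, initial_q_hat=1.0)
        assert expected_score_after_batch("r1", state, params) == pytest.approx(
            math.log(11), abs=1e-12
        )

    def test_zero_quality_run_changes_nothing(self):
        state = make_state({"r1": [5, 2, 0]}, 3)
        params = SelectionParams(initial_q_hat=0.0)
        # r2 never sampled -> q_hat = initial = 0
        assert expected_score_after_batch("r2", state, params) == score(state.c)

    def test_identical_inputs_identical_values(self):
        state = make_state({}, 4)
        params = SelectionParams()
        a = expected_score_after_batch("r1", state, params)
        b = expected_score_after_batch("r2", state, params)
        assert a == b

    def test_blacklisted_and_exhausted_rejected(self):
        state = make_state({}, 2)
        run = RunRecord("r1", blacklisted=True)
        with pytest.raises(ValueError):
            expected_score_after_batch(run, state, SelectionParams())
        run2 = RunRecord("r2", total_spots=10, downloaded=[(0, 10)])
        with pytest.raises(ValueError):
            expected_score_after_batch(run2, state, SelectionParams())


class TestChooseNextRun:
    def test_empty_candidates_signal_exhaustion(self):
        with pytest.raises(ArchiveExhausted):
            choose_next_run([], make_state({}, 2), SelectionParams(), np.random.default_rng(0))

    def test_symmetric_tie_is_uniform(self):
        runs = [RunRecord(f"r{i}", avg_read_length=100.0) for i in range(3)]
        state = make_state({}, 4)
        params = SelectionParams(seed=0)
        rng = np.random.default_rng(99)
        counts = {r.run_id: 0 for r in runs}
        trials = 10_000
        for _ in range(trials):
            counts[choose_next_run(runs, state, params, rng)] += 1
        for run_id in counts:
            assert counts[run_id] / trials == pytest.approx(1 / 3, abs=0.02)

    def test_tie_break_biased_towards_longer_reads(self):
        runs = [RunRecord("long", avg_read_length=150.0),
                RunRecord("short", avg_read_length=50.0)]
        state = make_state({}, 4)
        rng = np.random.default_rng(7)
        trials = 10_000
        hits = sum(
            choose_next_run(runs, state, SelectionParams(), rng) == "long"
            for _ in range(trials)
        )
        # binomial(10000, 0.75): 5 sigma ~ 0.0217
        assert hits / trials == pytest.approx(0.75, abs=0.025)

    def test_missing_read_length_imputed_as_median(self):
        runs = [RunRecord("a", avg_read_length=100.0),
                RunRecord("b", avg_read_length=None),
                RunRecord("c", avg_read_length=100.0)]
        state = make_state({}, 4)
        rng = np.random.default_rng(11)
        counts = {r.run_id: 0 for r in runs}
        for _ in range(6000):
            counts[choose_next_run(runs, state, params=SelectionParams(), rng=rng)] += 1
        assert counts["b"] / 6000 == pytest.approx(1 / 3, abs=0.03)

    def test_never_sampled_runs_tie_exactly(self):
        # two sampled runs with data plus three fresh ones: the fresh ones
        # share p_hat and q_hat, hence one expected score
        state = make_state({"s1": [9, 0, 0, 0], "s2": [0, 7, 1, 0]}, 4)
        params = SelectionParams(b=10)
        fresh = [expected_score_after_batch(f"f{i}", state, params) for i in range(3)]
        assert fresh[0] == fresh[1] == fresh[2]


class TestUpdateState:
    def test_empty_batch_leaves_counts_unchanged(self):
        state = make_state({"r1": [1, 2]}, 2)
        before = state.c.copy()
        update_state(state, "r1", BatchResult(run_id="r1", spots_downloaded=0))
        np.testing.assert_array_equal(state.c, before)
        state.validate()

    def test_counts_and_fractions_from_one_batch(self):
        state = make_state({}, 5)
        batch = BatchResult(
            run_id="r1", spots_downloaded=100, spots_unique=80,
            spots_unmapped=20, tile_increments={3: 80},
        )
        update_state(state, "r1", batch)
        assert state.c[3] == 80
        assert state.quality["r1"].f_unique == pytest.approx(0.8)
        state.validate()

    def test_quality_pools_counts_not_per_batch_fractions(self):
        state = make_state({}, 2)
        b1 = BatchResult(run_id="r1", spots_downloaded=100, spots_unique=100,
                         tile_increments={0: 100})
        b2 = BatchResult(run_id="r1", spots_downloaded=300, spots_unique=0,
                         spots_unmapped=300)
        update_state(state, "r1", b1)
        update_state(state, "r1", b2)
        # pooled: 100/400, not mean(1.0, 0.0)
        assert state.quality["r1"].f_unique == pytest.approx(0.25)

    def test_wrong_run_rejected(self):
        state = make_state({}, 2)
        with pytest.raises(ValueError):
            update_state(state, "r1", BatchResult(run_id="r2", spots_downloaded=0))


class TestGreedyBehaviour:
    def test_disjoint_runs_alternate(self):
        """With two runs of disjoint tile support, diminishing returns make
        the greedy choice alternate rather than repeat one run."""
        T = 10
        profiles = {
            "A": np.array([0.25] * 4 + [0.0] * 6),
            "B": np.array([0.0] * 6 + [0.25] * 4),
        }
        state = make_state({"A": [0] * T, "B": [0] * T}, T)
        for run_id in profiles:  # mark as sampled, perfect quality
            update_state(state, run_id, BatchResult(run_id=run_id, spots_downloaded=0))
            state.quality[run_id].n_sampled = 1
            state.quality[run_id].n_unique = 1
            state.quality[run_id].n_spliced = 1
        params = SelectionParams(b=100)
        rng = np.random.default_rng(0)
        runs = [RunRecord("A", avg_read_length=100.0), RunRecord("B", avg_read_length=100.0)]
        chosen = []
        for _ in range(6):
            run_id = choose_next_run(runs, state, params, rng)
            chosen.append(run_id)
            counts = np.rint(params.b * profiles[run_id]).astype(np.int64)
            batch = BatchResult(
                run_id=run_id, spots_downloaded=params.b,
                spots_unique=int(counts.sum()),
                spots_unmapped=params.b - int(counts.sum()),
                tile_increments={j: int(n) for j, n in enumerate(counts) if n},
            )
            update_state(state, run_id, batch)
        assert chosen[2:] == ["A", "B", "A", "B"] or chosen[2:] == ["B", "A", "B", "A"]
        assert set(chosen) == {"A", "B"}

    def test_profile_recovery_improves_with_sample_size(self):
        """The smoothed profile estimate approaches the run's true tile
        profile as sampled spots grow 10x (median TV over 20 seeds)."""
        from rnascout import classify_batch
        from rnascout.simulate import GOOD, ArchiveConfig, build_archive

        def tv_distances(seed):
            config = ArchiveConfig(
                seed=seed, n_runs=2, n_genes=30, genome_length=150_000,
                spots_per_run=11_000, bad_run_fraction=0.0,
            )
            archive = build_archive(config)
            tiles = archive.tile_index()
            run = next(r for r in archive.runs if r.quality_class == GOOD)
            truth = archive.tile_profile(run.run_id, tiles)
            out = []
            for n_spots in (1000, 10_000):
                records = archive.sample_batch(run.run_id, (0, n_spots))
                batch = classify_batch(run.run_id, records, n_spots, tiles)
                state = CoverageState(len(tiles))
                update_state(state, run.run_id, batch)
                estimate = estimate_profile(run.run_id, state, SelectionParams())
                out.append(0.5 * np.abs(estimate - truth).sum())
            return out

        pairs = [tv_distances(seed) for seed in range(20)]
        small = np.median([p[0] for p in pairs])
        large = np.median([p[1] for p in pairs])
        assert large < small
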