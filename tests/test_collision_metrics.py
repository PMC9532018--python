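"""Synchronous events, collision recall and correlogram error."""

import numpy as np
import pandas as pd
import pytest

import spikecollide as sc
from spikecollide.collision_metrics import lag_bin_edges
from spikecollide.probe_templates import SimilarityMatrix


def _sim(values, ids):
    return SimilarityMatrix(values=np.asarray(values, dtype=float),
                            unit_ids=np.asarray(ids))


class TestFindSynchronousEvents:
    def test_pair_within_window(self, make_trains):
        gt = make_trains({0: [0.0], 1: [0.0015]}, 1.0)
        ev = sc.find_synchronous_events(gt, 2.0)
        assert len(ev) == 1
        assert ev.iloc[0]["lag_ms"] == pytest.approx(1.5)

    def test_pair_outside_window(self, make_trains):
        gt = make_trains({0: [0.0], 1: [0.0025]}, 1.0)
        assert len(sc.find_synchronous_events(gt, 2.0)) == 0

    def test_window_boundary_inclusive(self, make_trains):
        gt = make_trains({0: [0.0], 1: [0.002]}, 1.0)
        assert len(sc.find_synchronous_events(gt, 2.0)) == 1

    def test_three_way_coincidence_gives_three_events(self, make_trains):
        gt = make_trains({0: [0.100], 1: [0.1005], 2: [0.101]}, 1.0)
        ev = sc.find_synchronous_events(gt, 2.0)
        assert len(ev) == 3
        assert set(map(tuple, ev[["unit_i", "unit_j"]].to_numpy())) == {
            (0, 1), (0, 2), (1, 2)
        }

    def test_brute_force_pair_scan(self, correlated_trains):
        # subsample two units; every cross pair within 2 ms appears once
        sub = sc.SpikeTrainSet(
            unit_ids=np.array([0, 1]),
            times={0: correlated_trains.times[0][:200],
                   1: correlated_trains.times[1][:200]},
            duration=correlated_trains.duration,
        )
        ev = sc.find_synchronous_events(sub, 2.0)
        expected = sum(
            1
            for ti in sub.times[0]
            for tj in sub.times[1]
            if abs(tj - ti) <= 0.002
        )
        assert len(ev) == expected
        assert ev.duplicated(["unit_i", "unit_j", "index_i", "index_j"]).sum() == 0


class TestCollisionRecallByLag:
    def test_eleven_bins_over_pm_two_ms(self):
        edges = lag_bin_edges()
        assert len(edges) == 12
        assert edges[0] == -2.0 and edges[-1] == 2.0
        assert np.allclose(np.diff(edges), 4.0 / 11.0)

    def test_oracle_recall_one_everywhere(self, correlated_trains):
        srt = sc.oracle_sorter(correlated_trains)
        match = sc.compare_sorting(correlated_trains, srt)
        ev = sc.find_synchronous_events(correlated_trains)
        profiles = sc.collision_recall_by_lag(ev, match)
        assert len(profiles) > 0
        for p in profiles.values():
            r = p.recall
            assert np.all(r[p.n_events > 0] == 1.0)
            assert np.all(np.isnan(r[p.n_events == 0]))

    def test_all_collided_deleted_recall_zero(self, correlated_trains):
        ev = sc.find_synchronous_events(correlated_trains)
        model = sc.DegradationModel(p_drop=1.0, seed=0)
        srt = sc.degraded_oracle(correlated_trains, ev, model)
        match = sc.compare_sorting(correlated_trains, srt)
        profiles = sc.collision_recall_by_lag(ev, match)
        pooled = sum(p.n_tp.sum() for p in profiles.values())
        assert pooled == 0

    def test_binomial_deletion_recovered(self, correlated_trains):
        # independent deletion with p = 0.3: per-bin recall within 3 binomial
        # SE of 0.7 (SE computed on distinct collided spikes per bin)
        ev = sc.find_synchronous_events(correlated_trains)
        model = sc.DegradationModel(p_drop=0.3, seed=2)
        srt = sc.degraded_oracle(correlated_trains, ev, model)
        match = sc.compare_sorting(correlated_trains, srt)
        profiles = sc.collision_recall_by_lag(ev, match)
        pooled = None
        for p in profiles.values():
            pooled = p if pooled is None else sc.CollisionProfile(
                p.lag_bin_edges_ms, pooled.n_tp + p.n_tp,
                pooled.n_events + p.n_events)
        edges = pooled.lag_bin_edges_ms
        distinct = _distinct_spikes_per_bin(ev, edges)
        for b in range(pooled.n_bins):
            if distinct[b] < 50:
                continue
            se = np.sqrt(0.7 * 0.3 / distinct[b])
            assert abs(pooled.recall[b] - 0.7) <= 3 * se


def _distinct_spikes_per_bin(ev, edges):
    n_bins = len(edges) - 1
    b = np.clip(np.digitize(ev["lag_ms"], edges) - 1, 0, n_bins - 1)
    out = np.zeros(n_bins, dtype=int)
    for k in range(n_bins):
        sel = ev[b == k]
        spikes = set(zip(sel["unit_i"], sel["index_i"])) | set(
            zip(sel["unit_j"], sel["index_j"]))
        out[k] = len(spikes)
    return out


class TestPooling:
    def _profile(self, n_tp, n_ev, label):
        edges = lag_bin_edges()
        return sc.CollisionProfile(
            edges,
            np.full(11, n_tp, dtype=np.int64),
            np.full(11, n_ev, dtype=np.int64),
            label,
        )

    def test_identical_recalls_pool_to_same(self):
        profiles = {(0, 1): self._profile(3, 4, (0, 1)),
                    (0, 2): self._profile(6, 8, (0, 2))}
        sim = _sim([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]], [0, 1, 2])
        pooled = sc.pool_profiles_by_similarity(profiles, sim,
                                                np.array([0.0, 1.0]))
        assert np.allclose(list(pooled.values())[0].recall, 0.75)

    def test_equal_events_average(self):
        profiles = {(0, 1): self._profile(0, 10, (0, 1)),
                    (0, 2): self._profile(10, 10, (0, 2))}
        sim = _sim([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]], [0, 1, 2])
        pooled = sc.pool_profiles_by_similarity(profiles, sim,
                                                np.array([0.0, 1.0]))
        assert np.allclose(list(pooled.values())[0].recall, 0.5)

    def test_event_weighted_average(self):
        # recalls 1 and 0 with event counts 10 vs 30 -> pooled 0.25
        profiles = {(0, 1): self._profile(10, 10, (0, 1)),
                    (0, 2): self._profile(0, 30, (0, 2))}
        sim = _sim([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]], [0, 1, 2])
        pooled = sc.pool_profiles_by_similarity(profiles, sim,
                                                np.array([0.0, 1.0]))
        assert np.allclose(list(pooled.values())[0].recall, 0.25)

    def test_pooled_recall_between_min_and_max(self, correlated_trains,
                                               similarity):
        ev = sc.find_synchronous_events(correlated_trains)
        model = sc.DegradationModel(p_drop=0.3, seed=3)
        srt = sc.degraded_oracle(correlated_trains, ev, model)
        match = sc.compare_sorting(correlated_trains, srt)
        profiles = sc.collision_recall_by_lag(ev, match)
        pooled = sc.pool_profiles_by_similarity(profiles, similarity)
        for (lo, hi), p in pooled.items():
            members = [q for pair, q in profiles.items()
                       if lo <= similarity[pair] < hi
                       or (hi == 1.0 and similarity[pair] == 1.0)]
            ov = [m.overall_recall() for m in members]
            assert min(ov) - 1e-12 <= p.overall_recall() <= max(ov) + 1e-12


class TestRecallBySimilarity:
    def test_uniform_recall_integrates_to_itself(self):
        edges = lag_bin_edges()
        p = sc.CollisionProfile(edges, np.full(11, 3, dtype=np.int64),
                                np.full(11, 4, dtype=np.int64), (0, 1))
        assert p.overall_recall() == pytest.approx(0.75)

    def test_ten_of_eleven_bins(self):
        edges = lag_bin_edges()
        n_tp = np.full(11, 5, dtype=np.int64)
        n_tp[0] = 0
        p = sc.CollisionProfile(edges, n_tp, np.full(11, 5, dtype=np.int64),
                                (0, 1))
        assert p.overall_recall() == pytest.approx(10 / 11)

    def test_oracle_recall_one_at_every_similarity(self, correlated_trains,
                                                   similarity):
        srt = sc.oracle_sorter(correlated_trains)
        match = sc.compare_sorting(correlated_trains, srt)
        ev = sc.find_synchronous_events(correlated_trains)
        profiles = sc.collision_recall_by_lag(ev, match)
        curve = sc.collision_recall_by_similarity(profiles, similarity)
        assert len(curve) > 0
        assert np.allclose(curve["recall"], 1.0)


class TestCorrelogramError:
    def test_oracle_error_zero(self, correlated_trains, similarity):
        srt = sc.oracle_sorter(correlated_trains)
        match = sc.compare_sorting(correlated_trains, srt)
        prof = sc.correlogram_relative_error(
            correlated_trains, srt, match.assignment, similarity, 0.5)
        assert prof.n_pairs > 0
        assert np.allclose(prof.mean_relative_error, 0.0)

    def test_missing_central_coincidences(self, make_trains):
        # one pair, flat gt CCG; sorter misses all central coincidences ->
        # central-lag error ~ 100% of baseline for that pair
        rng = np.random.default_rng(4)
        t0 = np.sort(rng.uniform(0, 200, 2000))
        t0 = sc.prune_refractory(t0, 4.0)
        t1 = np.sort(rng.uniform(0, 200, 2000))
        t1 = sc.prune_refractory(t1, 4.0)
        gt = make_trains({0: t0, 1: t1}, 200.0)
        # sorted: unit 1 loses every spike within 1 ms of a unit-0 spike
        d = np.min(np.abs(t1[:, None] - t0[None, :]), axis=1)
        srt = make_trains({0: t0, 1: t1[d > 0.001]}, 200.0)
        prof = sc.correlogram_relative_error(
            gt, srt, {0: 0, 1: 1}, similarity=None,
            bin_size_ms=0.5, window_ms=10.0,
        )
        central = np.abs(prof.lags_ms) < 1.0
        outer = np.abs(prof.lags_ms) > 2.0
        assert prof.mean_relative_error[central].mean() == pytest.approx(1.0, abs=0.15)
        assert prof.mean_relative_error[outer].mean() < 0.2

    def test_mean_over_pairs(self, make_trains):
        # two contributing pairs, one perfect and one degraded: the mean
        # profile is half the degraded pair's error profile
        rng = np.random.default_rng(5)
        times = {u: sc.prune_refractory(np.sort(rng.uniform(0, 100, 800)), 4.0)
                 for u in range(4)}
        gt = make_trains(times, 100.0)
        degraded = dict(times)
        d = np.min(np.abs(times[3][:, None] - times[2][None, :]), axis=1)
        degraded[3] = times[3][d > 0.001]
        srt = make_trains(degraded, 100.0)
        # similarity gates the pair set: only (0,1) and (2,3) pass 0.5
        v = np.full((4, 4), 0.0)
        v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 0.9
        np.fill_diagonal(v, 1.0)
        sim = _sim(v, [0, 1, 2, 3])
        ident = {u: u for u in range(4)}
        both = sc.correlogram_relative_error(gt, srt, ident, sim, 0.5)
        only_bad = sc.correlogram_relative_error(
            make_trains({2: times[2], 3: times[3]}, 100.0),
            make_trains({2: times[2], 3: degraded[3]}, 100.0),
            {2: 2, 3: 3},
        )
        assert both.n_pairs == 2 and only_bad.n_pairs == 1
        assert np.allclose(both.mean_relative_error,
                           only_bad.mean_relative_error / 2)

    def test_empty_assignment_raises(self, correlated_trains):
        with pytest.raises(sc.ConfigurationError):
            sc.correlogram_relative_error(
                correlated_trains, correlated_trains, {})


def test_plot_exports_write_png(tmp_path, correlated_trains, similarity):
    from spikecollide import plots
    srt = sc.oracle_sorter(correlated_trains)
    match = sc.compare_sorting(correlated_trains, srt)
    ev = sc.find_synchronous_events(correlated_trains)
    profiles = sc.collision_recall_by_lag(ev, match)
    pooled = sc.pool_profiles_by_similarity(profiles, similarity)
    plots.plot_collision_profiles(pooled, tmp_path / "recall.png")
    prof = sc.correlogram_relative_error(
        correlated_trains, srt, match.assignment, similarity, 0.5)
    plots.plot_ccg_error(prof, tmp_path / "ccg.png")
    assert (tmp_path / "recall.png").stat().st_size > 0
    assert (tmp_path / "ccg.png").stat().st_size > 0
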