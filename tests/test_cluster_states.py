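"""State clustering, dwell/transition metrics, group contrasts, k sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynconn.cluster_states import (
    ClusterParams,
    fit_cluster_states,
    label_agreement,
    per_state_group_compare,
    run_lengths,
    state_metrics,
    sweep_k,
)
from dynconn.dynamic_fnc import WindowedFNC, WindowParams


def _wfnc_from_blobs(centers, counts, noise, seed=0, subjects=2):
    """Synthetic windowed FNC whose windows are Gaussian blobs around centers."""
    rng = np.random.default_rng(seed)
    z = {}
    truth = {}
    per = {c: n // subjects for c, n in zip(range(len(centers)), counts)}
    for si in range(subjects):
        rows, labs = [], []
        for ci, center in enumerate(centers):
            n = per[ci]
            rows.append(center + noise * rng.standard_normal((n, len(center))))
            labs += [ci] * n
        z[f"s{si}"] = np.vstack(rows)
        truth[f"s{si}"] = np.array(labs)
    starts = np.arange(next(iter(z.values())).shape[0])
    params = WindowParams(width=2, gauss_alpha=1.0, step=1)
    names = [f"p{i}" for i in range(len(centers[0]))]
    return WindowedFNC(z=z, window_starts=starts, params=params, pair_names=names), truth


class TestStateMetrics:
    def test_manual_run_length_enumeration(self):
        m = state_metrics(np.array([1, 1, 1, 2, 2, 1, 3]), k=4)
        assert m.mean_dwell[1] == 2.0  # runs of length 3 and 1
        assert m.mean_dwell[2] == 2.0
        assert m.mean_dwell[3] == 1.0
        assert m.fraction[1] == pytest.approx(4 / 7)
        assert m.fraction[2] == pytest.approx(2 / 7)
        assert m.fraction[3] == pytest.approx(1 / 7)
        assert m.n_transitions == 3
        assert m.mean_dwell[0] == 0.0 and not m.visited[0]

    def test_constant_sequence(self):
        m = state_metrics(np.zeros(371, dtype=int), k=1)
        assert m.n_transitions == 0
        assert m.mean_dwell[0] == 371.0

    def test_strict_alternation(self):
        m = state_metrics(np.array([0, 1, 0, 1]), k=2)
        assert m.n_transitions == 3
        assert m.mean_dwell[0] == 1.0 and m.mean_dwell[1] == 1.0

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=100)
    def test_nt_equals_runs_minus_one(self, seq):
        seq = np.asarray(seq)
        m = state_metrics(seq, k=5)
        assert m.n_transitions == len(run_lengths(seq)) - 1
        assert sum(m.fraction.values()) == pytest.approx(1.0, abs=1e-12)
        occupancy = sum(f * m.n_windows for f in m.fraction.values())
        assert occupancy == pytest.approx(m.n_windows)

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=40), st.permutations([0, 1, 2, 3]))
    @settings(deadline=None, max_examples=60)
    def test_relabeling_invariance(self, seq, perm):
        seq = np.asarray(seq)
        perm = np.asarray(perm)
        m1 = state_metrics(seq, k=4)
        m2 = state_metrics(perm[seq], k=4)
        assert m1.n_transitions == m2.n_transitions
        assert sorted(m1.mean_dwell.values()) == pytest.approx(sorted(m2.mean_dwell.values()))


class TestKmeansFit:
    def test_planted_partition_recovered_exactly(self):
        centers = [np.zeros(6), 10 * np.ones(6)]
        wfnc, truth = _wfnc_from_blobs(centers, [40, 40], noise=0.3, seed=1)
        model = fit_cluster_states(wfnc, ClusterParams(k=2, n_replicates=5, seed=2))
        est = np.concatenate([model.assignments[s] for s in wfnc.subject_ids])
        tru = np.concatenate([truth[s] for s in wfnc.subject_ids])
        assert label_agreement(est, tru, 2) == 1.0

    def test_duplicated_windows_double_cost_same_centroids(self):
        centers = [np.zeros(4), 8 * np.ones(4)]
        wfnc, _ = _wfnc_from_blobs(centers, [30, 30], noise=0.2, seed=3)
        model1 = fit_cluster_states(wfnc, ClusterParams(k=2, n_replicates=5, seed=4))
        doubled = WindowedFNC(
            z={**wfnc.z, **{f"dup_{s}": v.copy() for s, v in wfnc.z.items()}},
            window_starts=wfnc.window_starts, params=wfnc.params,
            pair_names=wfnc.pair_names,
        )
        model2 = fit_cluster_states(doubled, ClusterParams(k=2, n_replicates=5, seed=4))
        order = np.argsort(model1.centroids[:, 0]), np.argsort(model2.centroids[:, 0])
        assert np.allclose(model1.centroids[order[0]], model2.centroids[order[1]])
        assert model2.cost == pytest.approx(2 * model1.cost)

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(5)
        z = {"s0": rng.standard_normal((120, 8))}  # hard unstructured instance
        wfnc = WindowedFNC(
            z=z, window_starts=np.arange(120),
            params=WindowParams(width=2, gauss_alpha=1.0, step=1),
            pair_names=[f"p{i}" for i in range(8)],
        )
        cost1 = fit_cluster_states(wfnc, ClusterParams(k=4, n_replicates=1, seed=6)).cost
        cost20 = fit_cluster_states(wfnc, ClusterParams(k=4, n_replicates=20, seed=6)).cost
        assert cost20 <= cost1 + 1e-9

    def test_k_exceeding_distinct_windows_rejected(self):
        z = {"s0": np.tile(np.arange(4.0), (10, 1))}
        wfnc = WindowedFNC(
            z=z, window_starts=np.arange(10),
            params=WindowParams(width=2, gauss_alpha=1.0, step=1),
            pair_names=list("abcd"),
        )
        with pytest.raises(ValueError, match="distinct"):
            fit_cluster_states(wfnc, ClusterParams(k=2, n_replicates=1, seed=0))


class TestSweepK:
    @staticmethod
    def _three_state_wfnc(seed=7):
        rng = np.random.default_rng(seed)
        centers = [np.zeros(6), 6 * np.ones(6), -6 * np.ones(6)]
        return _wfnc_from_blobs(centers, [60, 60, 60], noise=0.5, seed=seed)

    def test_cost_decreases_and_agreement_peaks_at_true_k(self):
        wfnc, truth = self._three_state_wfnc()
        sweep = sweep_k(wfnc, (2, 3, 4), ClusterParams(k=3, n_replicates=10, seed=8))
        costs = [sweep[k]["cost"] for k in (2, 3, 4)]
        assert costs[0] > costs[1] > costs[2]
        tru = np.concatenate([truth[s] for s in wfnc.subject_ids])
        agree = {}
        for k in (2, 3, 4):
            est = np.concatenate(
                [sweep[k]["model"].assignments[s] for s in wfnc.subject_ids]
            )
            kk = max(k, 3)
            agree[k] = label_agreement(est, tru, kk)
        assert agree[3] == max(agree.values())

    def test_overclustering_merges_cleanly(self):
        # k=4 on 3 planted states: mapping each cluster to its majority truth
        # label recovers the partition
        wfnc, truth = self._three_state_wfnc(seed=9)
        model = fit_cluster_states(wfnc, ClusterParams(k=4, n_replicates=10, seed=10))
        est = np.concatenate([model.assignments[s] for s in wfnc.subject_ids])
        tru = np.concatenate([truth[s] for s in wfnc.subject_ids])
        merged = np.empty_like(est)
        for c in range(4):
            mask = est == c
            if mask.any():
                merged[mask] = np.bincount(tru[mask]).argmax()
        assert (merged == tru).mean() >= 0.9

    def test_sweep_deterministic(self):
        wfnc, _ = self._three_state_wfnc(seed=11)
        p = ClusterParams(k=3, n_replicates=5, seed=12)
        s1 = sweep_k(wfnc, (2, 3), p)
        s2 = sweep_k(wfnc, (2, 3), p)
        for k in (2, 3):
            assert np.array_equal(s1[k]["model"].centroids, s2[k]["model"].centroids)
            assert s1[k]["metrics"].equals(s2[k]["metrics"])


class TestGroupCompare:
    def test_planted_state_specific_coupling_detected(self):
        rng = np.random.default_rng(13)
        n_per = 20
        centers = [np.zeros(6), 5 * np.ones(6)]
        z, groups = {}, {}
        for gi, g in enumerate(["EP", "HC"]):
            for i in range(n_per):
                sid = f"{g}{i}"
                rows = np.vstack(
                    [
                        centers[0] + 0.5 * rng.standard_normal((30, 6)),
                        centers[1] + 0.5 * rng.standard_normal((30, 6)),
                    ]
                )
                if g == "EP":
                    rows[30:, 0] += 1.5  # pair 0 shifted in state 1 only
                z[sid] = rows
                groups[sid] = g
        wfnc = WindowedFNC(
            z=z, window_starts=np.arange(60),
            params=WindowParams(width=2, gauss_alpha=1.0, step=1),
            pair_names=[f"p{i}" for i in range(6)],
        )
        model = fit_cluster_states(wfnc, ClusterParams(k=2, n_replicates=5, seed=14))
        res = per_state_group_compare(wfnc, model, groups)
        # locate the planted state: the one where pair 0 differs
        hits = [
            (s, r) for s, lst in res.items() for r in lst
            if r.detail["pair"] == "p0" and r.p_value < 0.01
        ]
        assert hits and all(r.direction == 1 for _, r in hits)

    def test_subject_without_windows_in_state_excluded(self):
        rng = np.random.default_rng(15)
        z, groups = {}, {}
        for gi, g in enumerate(["A", "B"]):
            for i in range(3):
                sid = f"{g}{i}"
                z[sid] = gi * 5 + 0.1 * rng.standard_normal((20, 3))
                groups[sid] = g
        # one extra subject per group visits both blobs
        for g, gi in [("A", 0), ("B", 1)]:
            sid = f"{g}x"
            z[sid] = np.vstack(
                [0.1 * rng.standard_normal((10, 3)), 5 + 0.1 * rng.standard_normal((10, 3))]
            )
            groups[sid] = g
        wfnc = WindowedFNC(
            z=z, window_starts=np.arange(20),
            params=WindowParams(width=2, gauss_alpha=1.0, step=1),
            pair_names=list("abc"),
        )
        model = fit_cluster_states(wfnc, ClusterParams(k=2, n_replicates=5, seed=16))
        res = per_state_group_compare(wfnc, model, groups)
        for s, lst in res.items():
            for r in lst:
                na, nb = r.n
                assert na + nb <= 8  # the pure-opposite-blob subjects are excluded
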