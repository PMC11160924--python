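"""Preliminary criteria, consensus, training preparation and the
semi-supervised re-classification."""

import numpy as np
import pytest
from scipy import stats

from stimmap.containers import epoch_times_ms, spec_times_ms
from stimmap.activation import (
    connectivity_index, consensus, criterion_channel_adaptive,
    criterion_phase_locking, criterion_uniform, evaluate_labels, plausibility,
    prepare_training, semisupervised_classify,
)

T = epoch_times_ms()


def _trace(peaks):
    z = np.zeros_like(T)
    for t0, (height, width) in peaks.items():
        z += height * np.exp(-0.5 * ((T - t0) / width) ** 2)
    return z


# ------------------------------------------------------------ criterion 1


@pytest.mark.parametrize("trace,expect", [
    (_trace({100: (7.5, 20)}), True),
    (_trace({100: (6.9, 20)}), False),
    (_trace({5: (10.0, 1.5)}), False),  # outside the [10, 600] window
])
def test_uniform_cutoff_window_rule(trace, expect):
    assert criterion_uniform(trace) is expect


def test_uniform_cutoff_sees_negative_peaks():
    assert criterion_uniform(-_trace({80: (9.0, 15)}))


# ------------------------------------------------------------ criterion 2


def test_flat_ep_among_peaky_siblings_votes_false():
    sibs = [_trace({100: (10.0, 15)}) for _ in range(12)]
    assert criterion_channel_adaptive(np.zeros_like(T), sibs) is False


def test_outstanding_peak_votes_true():
    rng = np.random.default_rng(0)
    sibs = [_trace({100: (2.0, 15)}) + 0.3 * rng.standard_normal(len(T))
            for _ in range(15)]
    big = _trace({120: (20.0, 15)})
    assert criterion_channel_adaptive(big, sibs + [big]) is True


def test_adaptive_abstains_below_ten_siblings():
    assert criterion_channel_adaptive(np.zeros_like(T), [np.zeros_like(T)] * 9) is None


def test_adaptive_matches_bruteforce_pooled_statistics():
    from scipy.signal import find_peaks

    rng = np.random.default_rng(1)
    sibs = [rng.standard_normal(len(T)) * rng.uniform(0.5, 3.0)
            + _trace({int(rng.uniform(50, 500)): (rng.uniform(0, 12), 20)})
            for _ in range(20)]
    win = (T >= 10) & (T < 600)
    pooled_h, pooled_p = [], []
    for z in sibs:
        seg = z[win]
        for sign in (1, -1):
            idx, props = find_peaks(sign * seg, prominence=0.5)
            pooled_h += [abs(seg[i]) for i in idx]
            pooled_p += list(props["prominences"])
    h_thr = np.mean(pooled_h) + 2 * np.std(pooled_h)
    p_thr = np.mean(pooled_p) + 2 * np.std(pooled_p)
    for z in sibs:
        seg = z[win]
        expect = False
        for sign in (1, -1):
            idx, props = find_peaks(sign * seg, prominence=0.5)
            expect = expect or any(abs(seg[i]) > h_thr and p > p_thr
                                   for i, p in zip(idx, props["prominences"]))
        assert criterion_channel_adaptive(z, sibs) is expect


# ------------------------------------------------------------ criterion 3


def test_identical_indices_none_exceed_percentile():
    idx = np.full(40, 0.2)
    assert not any(criterion_phase_locking(i, idx) for i in idx)


def test_planted_phase_locked_burst_flagged_among_nulls():
    rng = np.random.default_rng(2)
    st = spec_times_ms()
    null_raw = rng.uniform(0.05, 0.2, (39, 59, len(st)))
    planted = rng.uniform(0.05, 0.2, (59, len(st)))
    planted[40:50, (st >= 20) & (st < 60)] = 0.9
    indices = np.array([connectivity_index(r) for r in null_raw]
                       + [connectivity_index(planted)])
    assert criterion_phase_locking(indices[-1], indices)


def test_percentile_admits_five_percent_of_null_indices():
    rng = np.random.default_rng(3)
    idx = rng.uniform(size=2000)
    frac = np.mean([criterion_phase_locking(i, idx) for i in idx])
    assert abs(frac - 0.05) < 0.01


def test_percentile_warns_on_few_pairs():
    with pytest.warns(UserWarning):
        criterion_phase_locking(0.5, np.arange(10) / 10)


# ----------------------------------------------------------- plausibility


def test_textbook_early_rise_is_plausible():
    assert plausibility(_trace({40: (10.0, 12)}))


def test_sustained_late_offset_is_implausible():
    z = _trace({40: (10.0, 12)})
    z[T >= 800] += 4.0
    assert not plausibility(z)


def test_late_only_peak_clause():
    assert plausibility(_trace({300: (6.0, 30)}))
    assert not plausibility(_trace({300: (3.0, 30)}))


# --------------------------------------------------------------- consensus


@pytest.mark.parametrize("votes,plaus,expect", [
    ((True, True, True), True, 1),
    ((True, True, True), False, -1),
    ((False, False, False), True, 0),
    ((False, False, False), False, 0),
    ((True, False, True), True, -1),
    ((True, None, True), True, -1),  # abstention counts as disagreement
])
def test_consensus_table(votes, plaus, expect):
    assert consensus(votes, plaus).value == expect


def test_label_one_requires_plausibility():
    from stimmap.activation import PreliminaryLabel

    with pytest.raises(ValueError):
        PreliminaryLabel(1, (True, True, True), False)


# ------------------------------------------------------ training matrix


def test_prepare_training_identity_without_missing():
    rng = np.random.default_rng(4)
    V = rng.standard_normal((50, 8))
    X, kept, log = prepare_training(V)
    assert X.shape == V.shape and not log
    # quantile transform preserves ranks per feature
    for j in range(8):
        np.testing.assert_array_equal(np.argsort(X[:, j]), np.argsort(V[:, j]))


def test_single_missing_cell_mean_imputed_and_allmissing_dropped():
    rng = np.random.default_rng(5)
    V = rng.standard_normal((30, 4))
    V[3, 1] = np.nan
    V[:, 2] = np.nan
    X, kept, log = prepare_training(V)
    assert list(kept) == [0, 1, 3] and len(log) == 1
    # the imputed value is the feature mean -> mid-rank after transform
    col = V[:, 1]
    assert abs(stats.rankdata(np.nan_to_num(col, nan=np.nanmean(col)))[3]
               - (len(col) + 1) / 2) <= len(col) * 0.2


def test_quantile_transform_yields_gaussian_marginals():
    rng = np.random.default_rng(6)
    V = rng.exponential(size=(500, 3)) ** 2
    X, _, _ = prepare_training(V)
    for j in range(3):
        ks = stats.kstest(X[:, j], "norm").statistic
        assert ks < 0.05


# --------------------------------------------------- semi-supervised UMAP


def _blobs(seed=0, n=60, d=12, sep=8.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    truth = np.arange(n) < n // 3
    X[truth] += sep / np.sqrt(d)
    prelim = np.full(n, -1)
    labeled = rng.choice(n, n // 2, replace=False)
    prelim[labeled] = truth[labeled].astype(int)
    return X, prelim, truth


def test_separable_blobs_recover_partial_labels_exactly():
    X, prelim, truth = _blobs(seed=7)
    results, diag = semisupervised_classify(X, prelim, seed=0)
    assert not diag["failed"]
    got = np.array([r.label == "activated" for r in results])
    ok = np.array([r.label != "outlier" for r in results])
    assert ok.mean() > 0.9
    assert (got[ok] == truth[ok]).mean() == 1.0


def test_relabeling_stable_across_embedding_seeds():
    X, prelim, truth = _blobs(seed=8)
    runs = []
    for s in range(5):
        results, diag = semisupervised_classify(X, prelim, seed=s)
        assert not diag["failed"]
        runs.append(np.array([r.label for r in results]))
    base = runs[0]
    for other in runs[1:]:
        assert (other == base).mean() >= 0.95


def test_identical_instances_flag_subject_failed():
    X = np.zeros((40, 6))
    prelim = np.r_[np.ones(5), np.zeros(20), -np.ones(15)].astype(int)
    _, diag = semisupervised_classify(X, prelim, seed=0)
    assert diag["failed"]


# ----------------------------------------------------------------- scoring


def test_evaluate_labels_identity_and_negation():
    bench = np.array([1, 0, 1, 1, 0], dtype=bool)
    out = evaluate_labels(bench, bench)
    assert out == {"correspondence": 1.0, "precision": 1.0, "sensitivity": 1.0}
    assert evaluate_labels(~bench, bench)["correspondence"] == 0.0


def test_evaluate_labels_contingency_arithmetic():
    """TP=53, FP=1, FN=47, TN=99 -> precision 53/54, sensitivity 0.53."""
    labels = np.r_[np.ones(53), np.ones(1), np.zeros(47), np.zeros(99)] > 0
    bench = np.r_[np.ones(53), np.zeros(1), np.ones(47), np.zeros(99)] > 0
    out = evaluate_labels(labels, bench)
    assert out["precision"] == pytest.approx(53 / 54)
    assert out["sensitivity"] == pytest.approx(0.53)
    assert out["correspondence"] == pytest.approx(152 / 200)
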