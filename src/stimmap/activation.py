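"""Activated / non-activated labelling of stimulating->recording instances.

Stage 1 produces a *preliminary* label per instance from the consensus of
three neurophysiological criteria — a uniform evoked-potential z cutoff, a
stimulation-channel-adaptive peak test, and a subject-level phase-locking
percentile — gated by a physiological-plausibility check.  When the criteria
disagree the instance stays unlabeled (-1).

Stage 2 embeds each subject's down-sampled spectral feature vectors with a
semi-supervised 2-D UMAP (local neighbourhood 5, minimum distance 0.01),
locates density clusters, and re-classifies every instance by the majority
preliminary label of its cluster's labeled members; unclustered points are
outliers.  Subjects whose clusters cannot be told apart are flagged failed
and excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .containers import epoch_times_ms, spec_times_ms
from .spectral import EvokedInstance

__all__ = [
    "PreliminaryLabel", "ActivationResult",
    "criterion_uniform", "criterion_channel_adaptive", "criterion_phase_locking",
    "connectivity_index", "plausibility", "consensus",
    "prepare_training", "semisupervised_classify", "label_subject",
    "evaluate_labels", "score_against_ground_truth",
]

RESPONSE_WINDOW_MS = (10.0, 600.0)
PEAK_PROMINENCE_MIN = 0.5  # z-units; generic peak-finder floor


@dataclass
class PreliminaryLabel:
    value: int  # 1 activated, 0 non-activated, -1 unlabeled
    criterion_votes: tuple
    plausibility: bool

    def __post_init__(self) -> None:
        if self.value == 1 and not (all(v is True for v in self.criterion_votes)
                                    and self.plausibility):
            raise ValueError("label 1 requires full criterion agreement and plausibility")


@dataclass
class ActivationResult:
    label: str  # activated | non-activated | outlier
    embedding: tuple
    cluster_id: int


# ------------------------------------------------------------- criteria


def _window_mask(times: np.ndarray, window) -> np.ndarray:
    return (times >= window[0]) & (times < window[1])


def criterion_uniform(ep_z: np.ndarray, z_cut: float = 7.0,
                      window=RESPONSE_WINDOW_MS) -> bool:
    """Hard cutoff: |z| of the evoked potential exceeds ``z_cut`` anywhere in
    the 10-600 ms response window."""
    m = _window_mask(epoch_times_ms(), window)
    return bool(np.abs(ep_z[m]).max() > z_cut)


def _signed_peaks(ep_z: np.ndarray, window=RESPONSE_WINDOW_MS):
    """All positive and negative peaks inside the window: (index, height,
    prominence), height = |z| at the peak."""
    t = epoch_times_ms()
    m = _window_mask(t, window)
    offset = np.flatnonzero(m)[0]
    seg = ep_z[m]
    out = []
    for sign in (1.0, -1.0):
        idx, props = find_peaks(sign * seg, prominence=PEAK_PROMINENCE_MIN)
        for i, p in zip(idx, props["prominences"]):
            out.append((offset + i, abs(seg[i]), p))
    return out


def criterion_channel_adaptive(ep_z: np.ndarray, sibling_ep_zs: list,
                               sd: float = 2.0, min_siblings: int = 10):
    """Stimulation-channel-specific peak test.

    Pools peak heights and prominences over all evoked potentials generated
    from the same bipolar stimulation, and votes True when this instance has
    a peak whose height *and* prominence both exceed the pooled mean + 2 SD.
    Abstains (returns None) with fewer than ``min_siblings`` siblings.
    """
    if len(sibling_ep_zs) < min_siblings:
        return None
    pooled = [pk for z in sibling_ep_zs for pk in _signed_peaks(z)]
    if not pooled:
        return False
    heights = np.array([h for _, h, _ in pooled])
    proms = np.array([p for _, _, p in pooled])
    h_thr = heights.mean() + sd * heights.std()
    p_thr = proms.mean() + sd * proms.std()
    return bool(any(h > h_thr and p > p_thr for _, h, p in _signed_peaks(ep_z)))


def connectivity_index(itpc_raw: np.ndarray, window=RESPONSE_WINDOW_MS) -> float:
    """Per-pair phase-locking scalar: maximum over the response window of the
    frequency-averaged raw ITPC trace."""
    m = _window_mask(spec_times_ms(), window)
    return float(itpc_raw[:, m].mean(axis=0).max())


def criterion_phase_locking(index: float, subject_indices: np.ndarray,
                            percentile: float = 95.0) -> bool:
    """Subject-specific threshold: the pair's connectivity index exceeds the
    95th percentile of the index distribution over all pairs of the subject."""
    subject_indices = np.asarray(subject_indices, dtype=float)
    if len(subject_indices) < 20:
        warnings.warn("fewer than 20 pairs; phase-locking percentile is unstable")
    return bool(index > np.percentile(subject_indices, percentile))


def plausibility(ep_z: np.ndarray, late_z: float = 5.0, tail_z: float = 2.0) -> bool:
    """Physiological-plausibility gate.

    True iff (a smooth fast early rise — a monotone >= 10 ms climb into a
    local peak within 10-60 ms — OR a later (> 250 ms) peak with |z| > 5)
    AND the trace approximates baseline after 800 ms (mean |z| < 2).
    """
    t = epoch_times_ms()
    tail = np.abs(ep_z[t >= 800]).mean() < tail_z
    if not tail:
        return False
    early = False
    for i, _, _ in _signed_peaks(ep_z, window=(10.0, 60.0)):
        seg = ep_z[i - 10:i + 1]
        d = np.diff(seg if ep_z[i] > 0 else -seg)
        if len(d) == 10 and np.all(d >= 0):
            early = True
            break
    late = any(h > late_z for i, h, _ in _signed_peaks(ep_z) if t[i] > 250)
    return early or late


def consensus(votes, plausible: bool) -> PreliminaryLabel:
    """All-true + plausible -> 1; all-false -> 0; anything else (including an
    abstention, which counts as disagreement) -> -1."""
    votes = tuple(votes)
    if all(v is True for v in votes) and plausible:
        value = 1
    elif all(v is False for v in votes):
        value = 0
    else:
        value = -1
    return PreliminaryLabel(value=value, criterion_votes=votes, plausibility=plausible)


# -------------------------------------------------------- training matrix


def prepare_training(vectors: np.ndarray, random_state: int = 0):
    """Mean-impute missing entries and quantile-transform each feature to a
    normal target distribution.  All-missing features are dropped (logged).

    Returns ``(X, kept_columns, log)``.
    """
    from sklearn.impute import SimpleImputer
    from sklearn.preprocessing import QuantileTransformer

    V = np.asarray(vectors, dtype=float)
    if V.ndim != 2 or V.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 instances")
    kept = ~np.all(np.isnan(V), axis=0)
    log = [f"dropped all-missing feature {i}" for i in np.flatnonzero(~kept)]
    V = V[:, kept]
    V = SimpleImputer(strategy="mean").fit_transform(V)
    n_q = min(V.shape[0], 1000)
    X = QuantileTransformer(output_distribution="normal", n_quantiles=n_q,
                            random_state=random_state).fit_transform(V)
    return X, np.flatnonzero(kept), log


# ------------------------------------------------------------- embedding


def _cluster_embedding(emb: np.ndarray, min_cluster_size: int):
    from sklearn.cluster import HDBSCAN

    k = min(min_cluster_size, max(2, len(emb) // 4))
    return HDBSCAN(min_cluster_size=k).fit(emb).labels_


def semisupervised_classify(X: np.ndarray, prelim: np.ndarray, seed: int = 0,
                            n_neighbors: int = 5, min_dist: float = 0.01,
                            min_cluster_size: int = 5):
    """Semi-supervised 2-D UMAP + density clustering.

    Each density cluster is labeled activated/non-activated from its labeled
    members (clusters with none inherit from the nearest labeled cluster
    centroid); every instance is then assigned its cluster's label, and
    unclustered points become outliers.  Returns ``(results, diagnostics)``;
    ``diagnostics["failed"]`` is set when the clusters' labels cannot be told
    apart (no separation between activation and non-activation).
    """
    import umap

    prelim = np.asarray(prelim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=seed)
        emb = reducer.fit_transform(X, y=prelim)
    labs = _cluster_embedding(emb, min_cluster_size)

    # Label each cluster by *enrichment* of its labeled members in 1s
    # relative to the subject-wide labeled-1 rate.  Label-1 instances are
    # rare by construction (the phase-locking criterion admits only the top
    # 5% of pairs), so a plain within-cluster majority of labeled members is
    # dominated by the plentiful 0s even inside a correct activation cluster.
    cluster_ids = [c for c in np.unique(labs) if c >= 0]
    n1_all = int((prelim == 1).sum())
    n0_all = int((prelim == 0).sum())
    global_rate = n1_all / max(n1_all + n0_all, 1)
    maj, centroids = {}, {}
    for c in cluster_ids:
        members = labs == c
        centroids[c] = emb[members].mean(axis=0)
        votes = prelim[members & (prelim >= 0)]
        if len(votes):
            rate = float((votes == 1).mean())
            maj[c] = 1 if rate > global_rate else 0
    labeled = [c for c in maj]
    for c in cluster_ids:
        if c not in maj:
            if not labeled:
                break
            near = min(labeled, key=lambda d: np.linalg.norm(centroids[c] - centroids[d]))
            maj[c] = maj[near]

    diag = {"failed": False, "reason": "", "seed": seed,
            "n_clusters": len(cluster_ids), "labeled_1_rate": global_rate}
    values = set(maj.values())
    if not cluster_ids or values != {0, 1}:
        diag["failed"] = True
        diag["reason"] = ("no density clusters" if not cluster_ids else
                          "activation and non-activation clusters cannot be "
                          f"told apart (cluster labels {sorted(values) if values else 'undefined'})")
    results = []
    for i in range(len(X)):
        c = int(labs[i])
        if c < 0:
            results.append(ActivationResult("outlier", tuple(emb[i]), -1))
        else:
            lab = "activated" if maj.get(c) == 1 else "non-activated"
            results.append(ActivationResult(lab, tuple(emb[i]), c))
    return results, diag


# ----------------------------------------------------------- per subject


@dataclass
class SubjectLabels:
    """Per-instance labelling table plus diagnostics for one subject."""

    subject: str
    table: pd.DataFrame
    failed: bool = False
    reason: str = ""
    diagnostics: dict = field(default_factory=dict)


def label_subject(instances: list, seed: int = 0, *, z_cut: float = 7.0,
                  adaptive_sd: float = 2.0, percentile: float = 95.0,
                  n_neighbors: int = 5, min_dist: float = 0.01) -> SubjectLabels:
    """Full activation labelling of one subject's evoked instances."""
    if not instances:
        raise ValueError("no instances")
    subject = instances[0].subject

    by_stim: dict[str, list[EvokedInstance]] = {}
    for inst in instances:
        by_stim.setdefault(inst.stim.name, []).append(inst)
    indices = np.array([connectivity_index(i.itpc.raw) for i in instances])

    rows, prelim = [], []
    for inst, ci in zip(instances, indices):
        sibs = [s.ep_z for s in by_stim[inst.stim.name]]
        votes = (
            criterion_uniform(inst.ep_z, z_cut=z_cut),
            criterion_channel_adaptive(inst.ep_z, sibs, sd=adaptive_sd),
            criterion_phase_locking(ci, indices, percentile=percentile),
        )
        plaus = plausibility(inst.ep_z)
        lab = consensus(votes, plaus)
        prelim.append(lab.value)
        rows.append(dict(subject=subject, stim=inst.stim.name, rec=inst.rec.name,
                         uniform=votes[0], adaptive=votes[1], phase_locking=votes[2],
                         plausible=plaus, prelim=lab.value,
                         connectivity_index=ci))
    table = pd.DataFrame(rows)

    X, _, log = prepare_training(np.stack([i.features.values for i in instances]),
                                 random_state=seed)
    results, diag = semisupervised_classify(X, np.array(prelim), seed=seed,
                                            n_neighbors=n_neighbors, min_dist=min_dist)
    diag["prepare_log"] = log
    # consensus-labeled instances keep their label; the embedding decides
    # for the unlabeled (-1) remainder, whose unclustered points are outliers
    table["cluster_label"] = [r.label for r in results]
    table["label"] = [
        ("activated" if p == 1 else "non-activated") if p >= 0 else r.label
        for p, r in zip(prelim, results)
    ]
    table["cluster"] = [r.cluster_id for r in results]
    table["emb_x"] = [r.embedding[0] for r in results]
    table["emb_y"] = [r.embedding[1] for r in results]
    return SubjectLabels(subject=subject, table=table, failed=diag["failed"],
                         reason=diag["reason"], diagnostics=diag)


# -------------------------------------------------------------- scoring


def evaluate_labels(labels: np.ndarray, benchmark: np.ndarray) -> dict:
    """Correspondence, precision and sensitivity of a binary labelling
    against a benchmark labelling of the same instances."""
    labels = np.asarray(labels, dtype=bool)
    benchmark = np.asarray(benchmark, dtype=bool)
    if labels.shape != benchmark.shape or labels.size == 0:
        raise ValueError("labelings must cover the same, non-empty instance set")
    tp = int((labels & benchmark).sum())
    return {
        "correspondence": float((labels == benchmark).mean()),
        "precision": tp / max(int(labels.sum()), 1),
        "sensitivity": tp / max(int(benchmark.sum()), 1),
    }


def score_against_ground_truth(tables: pd.DataFrame, ground_truth) -> dict:
    """Sensitivity / false-positive rate of final activation labels against
    planted connections.

    ``tables`` must carry subject, stim, rec, label columns;
    ``ground_truth`` maps subject -> GroundTruth.  Recording pairs sharing a
    contact with a planted pair of the same stimulation inherit the planted
    waveform through the bipolar derivation (sign-flipped), so they are
    excluded from both the positive and the null sets.
    """
    planted, leaky = set(), set()
    for subject, gt in ground_truth.items():
        for c in gt.connections:
            planted.add((subject, c.stim_pair_id, c.rec_pair_id))
            a, b = c.rec_pair_id.split("-")
            leaky.add((subject, c.stim_pair_id, frozenset((a, b))))
    tp = fn = fp = tn = 0
    for row in tables.itertuples():
        key = (row.subject, row.stim, row.rec)
        active = row.label == "activated"
        if key in planted:
            tp += active
            fn += not active
            continue
        contacts = set(row.rec.split("-"))
        if any(subj == row.subject and stim == row.stim and (planted_contacts & contacts)
               for subj, stim, planted_contacts in leaky):
            continue
        fp += active
        tn += not active
    return {
        "sensitivity": tp / max(tp + fn, 1),
        "fpr": fp / max(fp + tn, 1),
        "n_planted_evaluated": tp + fn,
        "n_null_evaluated": fp + tn,
    }
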