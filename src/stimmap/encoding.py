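"""Group-level feature discovery on activated instances.

Activated spectrograms are denoised by subtracting a per-stimulation-channel
template built from that channel's non-activated pairs (mostly volume-
conducted artifact), embedded with a supervised 2-D UMAP using the four
anatomical categories (stimulating cortex/thalamus x recording ipsi/contra
hemisphere) as labels, clustered density-wise, and checked for
generalisability with a linear support-vector classifier on held-out data.
Category-specific time-frequency effects are assessed with cluster-based
sign-flip permutation tests, and the three recurring spectral features are
cut out as decoding templates:

* F1 from the [10, 50] ms window of the COR-ipsi category mean,
* F2 from [70, 160] ms of COR-contr,
* F3 from [165, 280] ms of THAL-contr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats as sp_stats

from .containers import BipolarChannel, morlet_freqs, spec_times_ms
from .spectral import EvokedInstance

__all__ = [
    "CATEGORIES", "categorize", "nonactivated_template", "denoise_activated",
    "supervised_embed", "holdout_check", "subject_t_map", "cluster_permutation",
    "SignificantCluster", "FeatureTemplate", "TEMPLATE_WINDOWS_MS",
    "extract_templates",
]

CATEGORIES = ("COR-ipsi", "COR-contr", "THAL-ipsi", "THAL-contr")

TEMPLATE_WINDOWS_MS = {"F1": (10.0, 50.0), "F2": (70.0, 160.0), "F3": (165.0, 280.0)}
TEMPLATE_SOURCES = {"F1": "COR-ipsi", "F2": "COR-contr", "F3": "THAL-contr"}


def categorize(stim: BipolarChannel, rec: BipolarChannel) -> str:
    """Anatomical category of an instance: stimulating from thalamus or
    cortex, recording ipsi- or contralateral to the stimulation."""
    seed = "THAL" if stim.thalamic else "COR"
    side = "ipsi" if stim.hemisphere == rec.hemisphere else "contr"
    return f"{seed}-{side}"


# ----------------------------------------------------------- denoising


def nonactivated_template(instances: list, min_count: int = 10):
    """Cell-wise mean (power, ITPC) over the non-activated instances of one
    stimulation channel; fewer than ``min_count`` instances is an error (the
    stimulation channel is then excluded from group analysis)."""
    if len(instances) < min_count:
        raise ValueError(f"only {len(instances)} non-activated instances (< {min_count})")
    power = np.mean([i.power.values for i in instances], axis=0)
    itpc = np.mean([i.itpc.values for i in instances], axis=0)
    return power, itpc


def denoise_activated(instance: EvokedInstance, template):
    """Subtract the stimulation channel's non-activated template cell-wise
    from both spectrograms.  Returns ``(power, itpc)`` arrays."""
    t_power, t_itpc = template
    if t_power.shape != instance.power.values.shape or t_itpc.shape != instance.itpc.values.shape:
        raise ValueError("template grid does not match instance grid")
    return instance.power.values - t_power, instance.itpc.values - t_itpc


# ------------------------------------------------------------ embedding


def supervised_embed(X: np.ndarray, categories, seed: int = 0,
                     n_neighbors: int = 15, min_dist: float = 0.1,
                     min_cluster_size: int = 5, min_per_category: int = 5):
    """Supervised 2-D UMAP on the prepared matrix with anatomical-category
    labels, followed by hierarchical density clustering to draw cluster
    boundaries against background noise.

    Categories with fewer than ``min_per_category`` instances are excluded
    from supervision (left unlabeled) with a warning.  Returns
    ``(embedding, cluster_labels, info)``.
    """
    import umap
    from sklearn.cluster import HDBSCAN

    categories = np.asarray(categories)
    codes = np.full(len(categories), -1)
    for k, cat in enumerate(CATEGORIES):
        m = categories == cat
        if 0 < m.sum() < min_per_category:
            warnings.warn(f"category {cat} has {m.sum()} instances; excluded from supervision")
            continue
        codes[m] = k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed).fit_transform(X, y=codes)
    k = min(min_cluster_size, max(2, len(emb) // 4))
    labels = HDBSCAN(min_cluster_size=k).fit(emb).labels_
    # identical instances: the supervision alone can still split the
    # embedding by label, so cluster structure would be vacuous
    degenerate = bool(np.allclose(X.var(axis=0), 0.0))
    info = {"supervised_codes": codes, "n_clusters": int(labels.max() + 1),
            "flagged": bool(labels.max() < 0) or degenerate,
            "degenerate_input": degenerate}
    # majority category per cluster, for inspection output
    info["cluster_majorities"] = {}
    for c in np.unique(labels):
        if c < 0:
            continue
        vals, counts = np.unique(categories[labels == c], return_counts=True)
        info["cluster_majorities"][int(c)] = str(vals[np.argmax(counts)])
    return emb, labels, info


def holdout_check(X: np.ndarray, categories, seed: int = 0,
                  n_neighbors: int = 15, min_dist: float = 0.1,
                  min_per_category: int = 20) -> dict:
    """Generalisability check: stratified 3/4-1/4 split, supervised embedding
    fit on the training rows, linear support-vector classification of the
    held-out rows from their embedding coordinates.  Returns test accuracy
    and the chance rate (1 / number of categories)."""
    import umap
    from sklearn.model_selection import train_test_split
    from sklearn.svm import SVC

    categories = np.asarray(categories)
    counts = {c: int((categories == c).sum()) for c in np.unique(categories)}
    if min(counts.values()) < min_per_category:
        raise ValueError(f"need >= {min_per_category} instances per category, got {counts}")
    for attempt in range(10):
        idx_tr, idx_te = train_test_split(
            np.arange(len(X)), test_size=0.25, random_state=seed + attempt,
            stratify=categories)
        if set(categories[idx_te]) == set(categories):
            break
    codes = np.searchsorted(np.unique(categories), categories)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=seed)
        emb_tr = reducer.fit_transform(X[idx_tr], y=codes[idx_tr])
        emb_te = reducer.transform(X[idx_te])
    clf = SVC(kernel="linear").fit(emb_tr, categories[idx_tr])
    acc = float((clf.predict(emb_te) == categories[idx_te]).mean())
    return {"accuracy": acc, "chance": 1.0 / len(np.unique(categories)),
            "n_train": len(idx_tr), "n_test": len(idx_te)}


# --------------------------------------------- cluster permutation test


@dataclass
class SignificantCluster:
    """A 4-connected suprathreshold time-frequency cluster."""

    cells: np.ndarray  # boolean (freq x time) mask
    mass: float        # summed t-score
    p_cluster: float


def subject_t_map(patches: np.ndarray) -> np.ndarray:
    """Within-subject one-sample t-map over instances (cells x ...)."""
    patches = np.asarray(patches, dtype=float)
    n = patches.shape[0]
    if n < 2:
        raise ValueError("need >= 2 instances for a within-subject t-map")
    mean = patches.mean(axis=0)
    sd = patches.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _clusters_from_map(tmap: np.ndarray, threshold: float, tail: int):
    """(mask, mass) pairs of 4-connected suprathreshold clusters."""
    out = []
    signs = (1,) if tail == 1 else ((-1,) if tail == -1 else (1, -1))
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for s in signs:
        lab, n = ndimage.label(s * tmap > threshold, structure=structure)
        for c in range(1, n + 1):
            mask = lab == c
            out.append((mask, float(tmap[mask].sum())))
    return out


def _max_null_mass(tmap: np.ndarray, threshold: float, tail: int) -> float:
    cl = _clusters_from_map(tmap, threshold, tail)
    return max((abs(m) for _, m in cl), default=0.0)


def cluster_permutation(subject_maps: np.ndarray, threshold: float = 6.0,
                        n_permutations: int = 5000, alpha: float = 0.01,
                        tail: int = 0, seed: int = 0, min_subjects: int = 10):
    """Group-level cluster-based sign-flip permutation test.

    ``subject_maps`` is (n_subjects, n_freqs, n_times) of within-subject
    t-scores (or condition differences for a paired test — swapping the two
    conditions within a subject is a sign flip of the difference map).  Cells
    of the group one-sample t-map exceeding ``threshold`` (|t| for two-tailed,
    ``tail=+-1`` for one-sided) form 4-connected clusters whose mass (summed
    t) is compared against the permutation null of the maximum cluster mass.

    When 2**n_subjects <= n_permutations the null is enumerated exhaustively
    (p-values are then exact); otherwise ``n_permutations`` random sign
    flips are drawn and p = (1 + #{null >= observed}) / (n_permutations + 1).

    With fewer than ``min_subjects`` rows the test runs identically but is
    flagged as a contact-level fallback in ``info["level"]``.

    Returns ``(significant, tmap, info)``: clusters with p < ``alpha``, the
    group t-map, and diagnostics including every candidate cluster.
    """
    maps = np.asarray(subject_maps, dtype=float)
    n = maps.shape[0]
    info = {"level": "subject" if n >= min_subjects else "contact",
            "fallback": n < min_subjects, "n_subjects": n}
    if info["fallback"]:
        warnings.warn(f"only {n} maps; contact-level fallback (flagged)")
    tmap = subject_t_map(maps)
    observed = _clusters_from_map(tmap, threshold, tail)
    flat = maps.reshape(n, -1)

    if not observed:
        info["clusters"] = []
        return [], tmap, info

    exhaustive = 2 ** n <= n_permutations
    if exhaustive:
        signs = np.array(np.meshgrid(*([[1.0, -1.0]] * n), indexing="ij")
                         ).reshape(n, -1).T
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_permutations, n))
    null = np.empty(len(signs))
    for b, s in enumerate(signs):
        perm = (s[:, None] * flat)
        t = subject_t_map(perm).reshape(tmap.shape)
        null[b] = _max_null_mass(t, threshold, tail)

    clusters = []
    for mask, mass in observed:
        if exhaustive:
            p = float((null >= abs(mass) - 1e-12).mean())
        else:
            p = float((1 + (null >= abs(mass) - 1e-12).sum()) / (len(null) + 1))
        clusters.append(SignificantCluster(cells=mask, mass=mass, p_cluster=p))
    info["clusters"] = clusters
    info["exhaustive"] = exhaustive
    significant = [c for c in clusters if c.p_cluster < alpha]
    return significant, tmap, info


def null_cluster_false_positive_rate(n_datasets: int = 500, n_subjects: int = 12,
                                     shape: tuple = (20, 30), threshold: float = 6.0,
                                     n_permutations: int = 1000, alpha: float = 0.01,
                                     seed: int = 0) -> dict:
    """Error control of the cluster permutation test under a global null.

    Draws ``n_datasets`` cohorts of i.i.d. standard-normal subject maps, runs
    the group test on each, and returns the fraction of datasets that yield
    any cluster declared significant at ``alpha`` — which a valid test keeps
    at or below ``alpha``.  Also returns the Monte-Carlo standard error.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_datasets):
            maps = rng.standard_normal((n_subjects, *shape))
            sig, _, _ = cluster_permutation(
                maps, threshold=threshold, n_permutations=n_permutations,
                alpha=alpha, tail=0, seed=int(rng.integers(2 ** 31)))
            hits += bool(sig)
    rate = hits / n_datasets
    return {"rate": rate, "n_datasets": n_datasets,
            "mc_se": float(np.sqrt(max(rate * (1 - rate), 1e-9) / n_datasets)),
            "alpha": alpha}


# ------------------------------------------------------------- templates


@dataclass
class FeatureTemplate:
    """A time-frequency patch (power + ITPC) defining F1, F2 or F3."""

    feature_id: str
    window: tuple
    source_category: str
    power_patch: np.ndarray
    itpc_patch: np.ndarray
    freqs: np.ndarray
    times: np.ndarray

    @property
    def width(self) -> int:
        return self.power_patch.shape[1]

    def vector(self) -> np.ndarray:
        return np.concatenate([self.power_patch.ravel(), self.itpc_patch.ravel()])


def extract_templates(category_means: dict) -> dict:
    """Cut the F1/F2/F3 templates from the denoised category-mean
    spectrograms at their fixed windows; patches are jointly z-transformed
    (power and ITPC together) for storage."""
    t = spec_times_ms()
    out = {}
    for fid, (a, b) in TEMPLATE_WINDOWS_MS.items():
        cat = TEMPLATE_SOURCES[fid]
        if cat not in category_means:
            continue
        power, itpc = category_means[cat]
        m = (t >= a) & (t < b)
        if not m.any():
            raise ValueError("template window outside the spectrogram grid")
        pw, pc = power[:, m].copy(), itpc[:, m].copy()
        joint = np.concatenate([pw.ravel(), pc.ravel()])
        mu, sd = joint.mean(), joint.std()
        if sd > 0:
            pw, pc = (pw - mu) / sd, (pc - mu) / sd
        out[fid] = FeatureTemplate(feature_id=fid, window=(a, b),
                                   source_category=cat, power_patch=pw,
                                   itpc_patch=pc, freqs=morlet_freqs(),
                                   times=t[m])
    return out
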