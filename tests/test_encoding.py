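"""Denoising templates, supervised embedding, hold-out check, cluster-based
permutation tests and feature-template extraction."""

import itertools

import numpy as np
import pytest

from stimmap.containers import BipolarChannel, Spectrogram, spec_times_ms
from stimmap.spectral import EvokedInstance
from stimmap.encoding import (
    CATEGORIES, FeatureTemplate, TEMPLATE_WINDOWS_MS, categorize,
    cluster_permutation, denoise_activated, extract_templates, holdout_check,
    nonactivated_template, subject_t_map, supervised_embed,
)


def _chan(region="HPC", hemi="L"):
    return BipolarChannel("X01", "X02", region, hemi, (0, 0, 0), False)


def _inst(power, itpc_vals):
    from stimmap.containers import FeatureVector, N_FEATURES

    return EvokedInstance(
        subject="s", stim=_chan(), rec=_chan(), power=Spectrogram(power, "power"),
        itpc=Spectrogram(itpc_vals, "itpc"), ep_z=np.zeros(1500),
        features=FeatureVector(np.zeros(N_FEATURES)), n_trials=40)


# ------------------------------------------------------------- categories


@pytest.mark.parametrize("stim_region,stim_h,rec_h,expect", [
    ("HPC", "L", "L", "COR-ipsi"),
    ("HPC", "L", "R", "COR-contr"),
    ("antTH", "L", "L", "THAL-ipsi"),
    ("pstTH", "L", "R", "THAL-contr"),
])
def test_categorize(stim_region, stim_h, rec_h, expect):
    assert categorize(_chan(stim_region, stim_h), _chan("MTG", rec_h)) == expect


# --------------------------------------------------------------- template


def test_identical_nonactivated_instances_give_their_own_template():
    vals = np.random.default_rng(0).standard_normal((59, 300))
    insts = [_inst(vals.copy(), 2 * vals.copy()) for _ in range(12)]
    power, itpc_vals = nonactivated_template(insts)
    np.testing.assert_allclose(power, vals)
    np.testing.assert_allclose(itpc_vals, 2 * vals)


def test_nine_instances_excluded():
    insts = [_inst(np.zeros((59, 300)), np.zeros((59, 300))) for _ in range(9)]
    with pytest.raises(ValueError):
        nonactivated_template(insts)


def test_template_is_cellwise_mean():
    rng = np.random.default_rng(1)
    stack = rng.standard_normal((15, 59, 300))
    insts = [_inst(s, -s) for s in stack]
    power, itpc_vals = nonactivated_template(insts)
    np.testing.assert_allclose(power, stack.mean(axis=0))
    np.testing.assert_allclose(itpc_vals, -stack.mean(axis=0))


def test_denoise_identity_zero_and_linearity():
    rng = np.random.default_rng(2)
    a = rng.standard_normal((59, 300))
    b = rng.standard_normal((59, 300))
    t = (a.copy(), a.copy())
    p, c = denoise_activated(_inst(a, a), t)
    np.testing.assert_allclose(p, 0.0)
    p, c = denoise_activated(_inst(a, a), (np.zeros_like(a), np.zeros_like(a)))
    np.testing.assert_allclose(p, a)
    p1, _ = denoise_activated(_inst(a + b, a), t)
    p2, _ = denoise_activated(_inst(a, a), t)
    np.testing.assert_allclose(p1, p2 + b)
    with pytest.raises(ValueError):
        denoise_activated(_inst(a, a), (np.zeros((10, 10)), np.zeros((10, 10))))


# -------------------------------------------------------------- embedding


def _category_matrix(seed=0, n_per=30, d=16, sep=6.0):
    rng = np.random.default_rng(seed)
    X, cats = [], []
    for k, cat in enumerate(CATEGORIES):
        centre = np.zeros(d)
        centre[2 * k:2 * k + 2] = sep
        X.append(centre + rng.standard_normal((n_per, d)))
        cats += [cat] * n_per
    return np.vstack(X), np.array(cats)


def test_planted_category_patterns_form_matching_clusters():
    X, cats = _category_matrix(seed=3)
    emb, labels, info = supervised_embed(X, cats, seed=0)
    assert info["n_clusters"] >= 4
    majors = set(info["cluster_majorities"].values())
    assert majors == set(CATEGORIES)


def test_embedding_clusters_stable_across_seeds():
    from sklearn.metrics import adjusted_rand_score

    X, cats = _category_matrix(seed=4)
    runs = [supervised_embed(X, cats, seed=s)[1] for s in range(3)]
    for a, b in itertools.combinations(runs, 2):
        ok = (a >= 0) & (b >= 0)
        assert adjusted_rand_score(a[ok], b[ok]) >= 0.9


def test_identical_instances_flagged_or_degenerate():
    X = np.zeros((60, 8))
    cats = np.array(list(CATEGORIES) * 15)
    _, labels, info = supervised_embed(X, cats, seed=0)
    # identical rows: either all-noise (flagged) or a degenerate clustering
    # that cannot reflect the four categories
    assert info["flagged"] or len(set(info["cluster_majorities"].values())) < 4


def test_tiny_category_excluded_from_supervision():
    X, cats = _category_matrix(seed=5, n_per=30)
    cats[:30] = "COR-ipsi"
    cats[0:3] = "THAL-contr"
    cats[30:90] = np.repeat(["COR-contr", "THAL-ipsi"], 30)
    cats[90:] = "COR-ipsi"
    with pytest.warns(UserWarning):
        supervised_embed(X, cats, seed=0, min_per_category=5)


# ---------------------------------------------------------------- holdout


def test_holdout_perfectly_separated_categories():
    X, cats = _category_matrix(seed=6, sep=10.0)
    out = holdout_check(X, cats, seed=0)
    assert out["accuracy"] >= 0.95
    assert out["chance"] == pytest.approx(0.25)


def test_holdout_shuffled_labels_near_chance():
    rng = np.random.default_rng(7)
    X, cats = _category_matrix(seed=7, sep=0.0)  # no structure at all
    rng.shuffle(cats)
    out = holdout_check(X, cats, seed=0)
    n = out["n_test"]
    assert out["accuracy"] < 0.25 + 3 * np.sqrt(0.25 * 0.75 / n)


def test_holdout_requires_twenty_per_category():
    X, cats = _category_matrix(n_per=10)
    with pytest.raises(ValueError):
        holdout_check(X, cats)


# ----------------------------------------------- cluster permutation test


def test_all_zero_maps_produce_no_clusters():
    sig, tmap, info = cluster_permutation(np.zeros((12, 10, 10)), seed=0)
    assert sig == [] and info["clusters"] == []


def test_planted_block_recovered_as_single_significant_cluster():
    rng = np.random.default_rng(8)
    maps = rng.standard_normal((15, 20, 30))
    maps[:, 5:13, 10:18] += 10.0
    sig, tmap, info = cluster_permutation(maps, threshold=6.0,
                                          n_permutations=1000, seed=0)
    assert len(sig) == 1
    block = np.zeros((20, 30), dtype=bool)
    block[5:13, 10:18] = True
    overlap = (sig[0].cells & block).sum() / block.sum()
    assert overlap >= 0.8
    assert sig[0].p_cluster < 0.01
    assert info["level"] == "subject"


def test_exhaustive_pvalues_match_bruteforce_enumeration():
    """4 subjects, 2x2 maps: p equals full 2^4 sign-flip enumeration."""
    rng = np.random.default_rng(9)
    maps = rng.standard_normal((4, 2, 2)) + 1.5
    thr = 1.0
    with pytest.warns(UserWarning):  # contact-level fallback flag
        sig, tmap, info = cluster_permutation(maps, threshold=thr,
                                              n_permutations=5000, seed=0)
    assert info["exhaustive"] and info["fallback"]

    # oracle: direct enumeration with an independent clustering routine
    def masses(m):
        out = []
        for sign in (1, -1):
            ex = sign * m > thr
            seen = np.zeros_like(ex)
            for i in range(2):
                for j in range(2):
                    if ex[i, j] and not seen[i, j]:
                        stack, cells = [(i, j)], []
                        while stack:
                            a, b = stack.pop()
                            if 0 <= a < 2 and 0 <= b < 2 and ex[a, b] and not seen[a, b]:
                                seen[a, b] = True
                                cells.append((a, b))
                                stack += [(a + 1, b), (a - 1, b), (a, b + 1), (a, b - 1)]
                        out.append(sum(m[c] for c in cells))
        return out

    def tmap_of(m):
        mean, sd = m.mean(0), m.std(0, ddof=1)
        return np.where(sd > 0, mean / (sd / 2.0), 0.0)

    null = []
    for signs in itertools.product([1.0, -1.0], repeat=4):
        t = tmap_of(np.array(signs)[:, None, None] * maps)
        null.append(max((abs(x) for x in masses(t)), default=0.0))
    null = np.array(null)
    for c in info["clusters"]:
        expect = (null >= abs(c.mass) - 1e-12).mean()
        assert c.p_cluster == pytest.approx(expect)


def test_signflip_null_symmetric_under_global_flip():
    rng = np.random.default_rng(10)
    maps = rng.standard_normal((8, 6, 6)) + 1.0
    _, _, info1 = cluster_permutation(maps, threshold=2.0, seed=1)
    with np.errstate(all="ignore"):
        _, _, info2 = cluster_permutation(-maps, threshold=2.0, seed=1)
    p1 = sorted(c.p_cluster for c in info1["clusters"])
    p2 = sorted(c.p_cluster for c in info2["clusters"])
    assert p1 == p2


def test_subject_t_map_matches_scipy():
    from scipy import stats as sps

    rng = np.random.default_rng(11)
    patches = rng.standard_normal((9, 4, 5)) + 0.3
    t = subject_t_map(patches)
    ref = sps.ttest_1samp(patches, 0.0, axis=0).statistic
    np.testing.assert_allclose(t, ref, atol=1e-10)


# ---------------------------------------------------------------- templates


def test_template_windows_and_sources():
    assert TEMPLATE_WINDOWS_MS == {"F1": (10.0, 50.0), "F2": (70.0, 160.0),
                                   "F3": (165.0, 280.0)}
    rng = np.random.default_rng(12)
    means = {c: (rng.standard_normal((59, 300)), rng.standard_normal((59, 300)))
             for c in CATEGORIES}
    templates = extract_templates(means)
    assert set(templates) == {"F1", "F2", "F3"}
    t = spec_times_ms()
    for fid, tpl in templates.items():
        a, b = TEMPLATE_WINDOWS_MS[fid]
        assert tpl.times[0] >= a and tpl.times[-1] < b
        assert tpl.width == ((t >= a) & (t < b)).sum()


def test_template_slicing_round_trip():
    """Cutting, then re-embedding the patch into a zero grid reproduces the
    patch cells exactly (idempotent, grid-exact) modulo the stored z-shift."""
    rng = np.random.default_rng(13)
    power = rng.standard_normal((59, 300))
    means = {"THAL-contr": (power, power * 0.5)}
    tpl = extract_templates(means)["F3"]
    t = spec_times_ms()
    m = (t >= 165) & (t < 280)
    joint = np.concatenate([power[:, m].ravel(), (0.5 * power)[:, m].ravel()])
    mu, sd = joint.mean(), joint.std()
    np.testing.assert_allclose(tpl.power_patch, (power[:, m] - mu) / sd)
    grid = np.zeros((59, 300))
    grid[:, m] = tpl.power_patch
    np.testing.assert_allclose(grid[:, m], tpl.power_patch)


def test_constant_mean_gives_constant_patch():
    means = {"COR-ipsi": (np.full((59, 300), 2.0), np.full((59, 300), 2.0))}
    tpl = extract_templates(means)["F1"]
    assert np.ptp(tpl.power_patch) == 0.0 and np.ptp(tpl.itpc_patch) == 0.0
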