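"""Template decoding: feature strength (r*), latency, presence, and
region-level connectivity matrices.

Each feature template is slid across an instance's (power + ITPC)
spectrograms point by time point; the Pearson correlation r(t) between the
vectorised template and the instance patch starting at t yields a similarity
curve at 200 samples/s.  The maximum local peak of r(t) inside the feature's
admissible latency range is r*, its time is the latency, and presence is
binarised at r* > 0.4 for F1/F2 and r* > 0.5 for F3.  Region-level matrices
average r* (or latency) over connections where the feature is present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks

from .containers import spec_times_ms
from .encoding import FeatureTemplate

__all__ = [
    "PRESENCE_THRESHOLDS", "LATENCY_RANGES_MS", "ConnectionScore",
    "sliding_correlation", "peak_decode", "decode_instances",
    "region_matrix", "normalized_representation", "zeroed_contrast",
]

PRESENCE_THRESHOLDS = {"F1": 0.4, "F2": 0.4, "F3": 0.5}
LATENCY_RANGES_MS = {"F1": (10.0, 70.0), "F2": (70.0, 165.0), "F3": (200.0, 400.0)}


@dataclass
class ConnectionScore:
    """Decoded strength/latency/presence of one feature in one instance."""

    feature_id: str
    r_star: float
    latency_ms: float
    present: bool


def sliding_correlation(power: np.ndarray, itpc: np.ndarray,
                        template: FeatureTemplate):
    """Pearson r between the template and the instance patch starting at
    each time point.

    Returns ``(times_ms, r)`` where ``times_ms[k]`` is the *window centre*
    of the k-th placement (time measured from stimulation onset): the
    latency of a feature is the time around which the matched patch sits.
    Windows that would extend past the epoch end are not computed; constant
    patches give r = 0 by convention.  r is invariant to scaling or
    offsetting the instance.
    """
    w = template.width
    if w > power.shape[1]:
        raise ValueError("template wider than the epoch")
    tv = template.vector()
    tc = tv - tv.mean()
    t_norm = np.linalg.norm(tc)
    # (n_lags, n_cells): each row is the vectorised patch starting at lag k
    patches = np.concatenate([
        sliding_window_view(power, w, axis=1),
        sliding_window_view(itpc, w, axis=1),
    ], axis=0)                      # (2F, n_lags, w)
    n_half = patches.shape[0] // 2
    # a placement over constant power AND constant ITPC carries no pattern
    constant = ((patches[:n_half].max(axis=(0, 2)) - patches[:n_half].min(axis=(0, 2)) == 0)
                & (patches[n_half:].max(axis=(0, 2)) - patches[n_half:].min(axis=(0, 2)) == 0))
    patches = patches.transpose(1, 0, 2).reshape(patches.shape[1], -1)
    pc = patches - patches.mean(axis=1, keepdims=True)
    p_norm = np.linalg.norm(pc, axis=1)
    denom = p_norm * t_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((denom > 0) & ~constant, pc @ tc / denom, 0.0)
    times = spec_times_ms()
    centre_offset = (times[w - 1] - times[0]) / 2.0
    return times[:len(r)] + centre_offset, r


def peak_decode(r: np.ndarray, times_ms: np.ndarray, feature_id: str,
                thresholds: dict | None = None,
                latency_ranges: dict | None = None) -> ConnectionScore:
    """Peak similarity and time-to-peak within the feature's admissible
    latency range.

    r* is the highest *local peak* of r(t) in range (equal peaks: earliest
    wins); with no local peak in range the feature is absent and the maximum
    r in range is recorded.  Presence additionally requires r* to exceed the
    feature threshold.
    """
    thresholds = thresholds or PRESENCE_THRESHOLDS
    latency_ranges = latency_ranges or LATENCY_RANGES_MS
    lo, hi = latency_ranges[feature_id]
    in_range = (times_ms >= lo) & (times_ms < hi)
    if not in_range.any():
        raise ValueError("admissible latency range outside the r(t) trace")
    peaks, _ = find_peaks(r)
    peaks = peaks[in_range[peaks]]
    if len(peaks) == 0:
        k = int(np.argmax(np.where(in_range, r, -np.inf)))
        return ConnectionScore(feature_id, float(r[k]), float(times_ms[k]), False)
    best = peaks[np.argmax(np.round(r[peaks], 12))]  # argmax -> earliest on ties
    r_star = float(r[best])
    return ConnectionScore(feature_id, r_star, float(times_ms[best]),
                           bool(r_star > thresholds[feature_id]))


def decode_instances(records: list, templates: dict,
                     thresholds: dict | None = None,
                     latency_ranges: dict | None = None) -> pd.DataFrame:
    """Decode every feature in every instance.

    ``records`` is a list of dicts with keys subject, stim, rec,
    stim_region, rec_region, category, power, itpc (denoised spectrogram
    arrays).  Returns one row per instance with r*/latency/presence columns
    per feature.
    """
    rows = []
    for rec in records:
        row = {k: rec[k] for k in
               ("subject", "stim", "rec", "stim_region", "rec_region", "category")}
        for fid, tpl in templates.items():
            times, r = sliding_correlation(rec["power"], rec["itpc"], tpl)
            score = peak_decode(r, times, fid, thresholds, latency_ranges)
            row[f"{fid}_r"] = score.r_star
            row[f"{fid}_latency"] = score.latency_ms
            row[f"{fid}_present"] = score.present
        rows.append(row)
    return pd.DataFrame(rows)


def region_matrix(scores: pd.DataFrame, feature_id: str, kind: str = "R",
                  regions: list | None = None):
    """Region x region connectivity matrix.

    ``kind="R"`` averages r* over connections where the feature is present;
    ``kind="latency"`` averages latency over the same set.  Cells without a
    present connection are NaN (missing, not zero).  Returns
    ``(matrix, support)`` DataFrames with stimulated regions as rows.
    """
    if kind not in {"R", "latency"}:
        raise ValueError("kind must be 'R' or 'latency'")
    col = f"{feature_id}_r" if kind == "R" else f"{feature_id}_latency"
    present = scores[scores[f"{feature_id}_present"]]
    known = regions or sorted(set(scores["stim_region"]) | set(scores["rec_region"]))
    for r in pd.concat([scores["stim_region"], scores["rec_region"]]).unique():
        if r not in known:
            raise ValueError(f"unknown region label {r!r}")
    grouped = present.groupby(["stim_region", "rec_region"])[col]
    matrix = pd.DataFrame(np.nan, index=known, columns=known)
    support = pd.DataFrame(0, index=known, columns=known)
    for (sr, rr), vals in grouped:
        matrix.loc[sr, rr] = vals.mean()
        support.loc[sr, rr] = len(vals)
    return matrix, support


def normalized_representation(r_values: np.ndarray) -> np.ndarray:
    """z-score r* across all thalamic connections of one feature type (makes
    feature representations comparable between pathways)."""
    r_values = np.asarray(r_values, dtype=float)
    if len(r_values) < 2:
        raise ValueError("need >= 2 scores to normalise")
    sd = r_values.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate: all scores identical (SD = 0)")
    return (r_values - r_values.mean()) / sd


def zeroed_contrast(z_a: np.ndarray, z_b: np.ndarray) -> np.ndarray:
    """Contrast of normalised representations with negative z-scores zeroed
    first (avoids negative-minus-negative inflating the contrast)."""
    return np.maximum(z_a, 0.0) - np.maximum(z_b, 0.0)
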