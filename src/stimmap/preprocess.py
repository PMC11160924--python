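"""Denoising, channel/trial quality control, bipolar re-referencing, epoching
and pair-level exclusion rules.

The exclusion rules mirror the recording-side screening used for repeated
single-pulse stimulation data:

i.   both contacts of the recording pair in white matter;
ii.  bipolar contacts not within the same anatomical region;
iii. recording pair too close to the stimulation pair (midpoint distance
     <= 5 mm);
iv.  artifact-only responders: |z| >= 7 of baseline inside the < 10 ms
     artifact window and never >= 7 within 10-800 ms;
v.   pairs containing a rejected (noisy/pathological-surrogate) channel.

Every input pair appears exactly once in ``retained`` or in the exclusion log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import (
    BASELINE_MS, EPOCH_MS, FS, PAD_MS, BipolarChannel, EpochedPair, Session,
    epoch_samples, epoch_times_ms,
)

__all__ = [
    "notch_filter", "detect_bad_channels", "detect_bad_trials",
    "bipolar_rereference", "ep_zscore", "exclude_pairs",
    "preprocess_session", "SubjectData",
]

NOTCH_FREQS = (60.0, 120.0, 180.0)
NOTCH_Q = 30.0


def notch_filter(voltage: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase IIR notches at 60/120/180 Hz (Q = 30), applied along the
    last axis.  Requires fs = 1000 Hz."""
    if int(fs) != FS:
        raise ValueError(f"expected fs = {FS} Hz, got {fs}")
    out = np.asarray(voltage, dtype=float)
    for f0 in NOTCH_FREQS:
        b, a = signal.iirnotch(f0, NOTCH_Q, fs=fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


def _event_mask(n_samples: int, onsets: np.ndarray, half_width_ms: float) -> np.ndarray:
    """Boolean mask that is False within +-half_width_ms of any pulse."""
    mask = np.ones(n_samples, dtype=bool)
    half = int(half_width_ms * FS / 1000)
    for s in onsets:
        mask[max(0, s - half):s + half] = False
    return mask


def detect_bad_channels(session: Session, amp_sd: float = 5.0,
                        jump_uv: float = 80.0, jump_factor: float = 3.0,
                        jump_floor: int = 5, exclude_ms: float = 20.0):
    """Flag channels with extreme raw amplitude (> ``amp_sd`` SD of the
    cross-channel amplitude distribution) or a prevalence of consecutive-sample
    jumps > ``jump_uv`` uV exceeding ``jump_factor`` x the cross-channel median
    count.

    Samples within +-``exclude_ms`` of a pulse are ignored so the stimulation
    artifact does not register as jumps.  Returns ``(flags, stats)`` where
    ``flags`` is a boolean array aligned with ``session.channels``.
    """
    v = session.voltage
    if v.shape[0] < 3:
        raise ValueError("need >= 3 channels for cross-channel statistics")
    mask = _event_mask(v.shape[1], session.events["onset_sample"].to_numpy(), exclude_ms)
    amp = v[:, mask].std(axis=1)
    jumps = (np.abs(np.diff(v, axis=1)) > jump_uv)[:, mask[1:]].sum(axis=1)

    amp_spread = amp.std()
    if amp_spread == 0:
        if np.all(amp == 0):
            warnings.warn("all-constant recording; no channels flagged")
        amp_flag = np.zeros(len(amp), dtype=bool)
    else:
        amp_flag = amp > amp.mean() + amp_sd * amp_spread
    jump_thresh = max(jump_factor * np.median(jumps), float(jump_floor))
    jump_flag = jumps > jump_thresh
    stats = pd.DataFrame({
        "name": session.channels["name"], "amplitude_sd": amp,
        "jump_count": jumps, "amp_flag": amp_flag, "jump_flag": jump_flag,
    })
    return amp_flag | jump_flag, stats


def detect_bad_trials(trials: np.ndarray, mean_sd: float = 4.0,
                      var_sd: float = 3.5) -> np.ndarray:
    """Indices of trials to keep.

    Removes trials whose mean |voltage| exceeds ``mean_sd`` SD of that
    statistic's across-trial distribution, or whose within-trial variance
    exceeds ``var_sd`` SD of its distribution.  Both statistics are computed
    on the full nominal epoch.
    """
    if trials.shape[0] < 5:
        raise ValueError("need >= 5 trials for trial QC")
    m = np.abs(trials).mean(axis=1)
    v = trials.var(axis=1)
    keep = np.ones(trials.shape[0], dtype=bool)
    if m.std() > 0:
        keep &= m <= m.mean() + mean_sd * m.std()
    if v.std() > 0:
        keep &= v <= v.mean() + var_sd * v.std()
    return np.flatnonzero(keep)


def bipolar_rereference(session: Session, bad_channels: set[str] | None = None):
    """Adjacent-contact bipolar derivation per shaft (trace = a - b).

    Returns ``(pairs, traces)`` over *all* adjacent pairs (a shaft of n
    contacts yields n-1 channels); validity screening happens later in
    :func:`exclude_pairs` so every pair is accounted for in the exclusion log.
    ``pairs`` entries carry the common region (None when contacts straddle
    regions) and a white-matter flag true only when both contacts are.
    """
    bad_channels = bad_channels or set()
    tab = session.channels.set_index("name")
    index = {n: i for i, n in enumerate(session.channels["name"])}
    pairs, rows = [], []
    for _, grp in session.channels.groupby("shaft", sort=True):
        names = list(grp["name"])
        for a, b in zip(names[:-1], names[1:]):
            if a == b:
                raise ValueError("bipolar pair requires distinct contacts")
            region_a, region_b = tab.loc[a, "region"], tab.loc[b, "region"]
            mid = tuple((tab.loc[a, ["x", "y", "z"]].to_numpy(float)
                         + tab.loc[b, ["x", "y", "z"]].to_numpy(float)) / 2.0)
            pairs.append(BipolarChannel(
                contact_a=a, contact_b=b,
                region=region_a if region_a == region_b else None,
                hemisphere=tab.loc[a, "hemisphere"], midpoint=mid,
                white_matter=bool(tab.loc[a, "white_matter"] and tab.loc[b, "white_matter"]),
            ))
            rows.append(session.voltage[index[a]] - session.voltage[index[b]])
    return pairs, np.asarray(rows)


def _epoch(trace: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    pad = PAD_MS * FS // 1000
    start, stop = EPOCH_MS[0] * FS // 1000 - pad, EPOCH_MS[1] * FS // 1000 + pad
    n = stop - start
    out = np.zeros((len(onsets), n))
    for i, s in enumerate(onsets):
        lo, hi = s + start, s + stop
        if lo < 0 or hi > trace.shape[-1]:
            raise ValueError("epoch extends beyond the recording")
        out[i] = trace[lo:hi]
    return out


def ep_zscore(trials: np.ndarray, kept: np.ndarray) -> np.ndarray:
    """Trial-averaged evoked potential, z-scored against its own baseline
    (mean/SD of the averaged trace over the -300..-50 ms window)."""
    avg = trials[kept].mean(axis=0)
    t = epoch_times_ms()
    base = (t >= BASELINE_MS[0]) & (t < BASELINE_MS[1])
    mu, sd = avg[base].mean(), avg[base].std()
    if sd == 0:
        raise ValueError("degenerate baseline (zero variance)")
    return (avg - mu) / sd


def exclude_pairs(stim: BipolarChannel, candidates, bad_channels: set[str],
                  min_dist_mm: float = 5.0, artifact_z: float = 7.0):
    """Apply exclusion rules i-v to candidate recording pairs of one stim pair.

    ``candidates`` is a list of ``(BipolarChannel, epoch_fn)`` where
    ``epoch_fn()`` lazily returns the padded trial matrix (only evaluated for
    pairs that survive the metadata rules).  Returns
    ``(retained: list[EpochedPair], log: DataFrame)``.
    """
    retained, log = [], []
    t = epoch_times_ms()
    art_w = (t >= 0) & (t < 10)
    resp_w = (t >= 10) & (t < 800)
    for rec, epoch_fn in candidates:
        if {rec.contact_a, rec.contact_b} & bad_channels:
            log.append((stim.name, rec.name, "v_bad_channel", np.nan))
            continue
        if rec.white_matter:
            log.append((stim.name, rec.name, "i_white_matter", np.nan))
            continue
        if rec.region is None:
            log.append((stim.name, rec.name, "ii_cross_region", np.nan))
            continue
        d = float(np.linalg.norm(np.subtract(rec.midpoint, stim.midpoint)))
        if d <= min_dist_mm:
            log.append((stim.name, rec.name, "iii_too_close", d))
            continue
        trials = epoch_fn()
        try:
            kept = detect_bad_trials(EpochedPair(stim, rec, trials, np.arange(len(trials))).trials)
        except ValueError:
            log.append((stim.name, rec.name, "qc_too_few_trials", float(len(trials))))
            continue
        if len(kept) < 5:
            log.append((stim.name, rec.name, "qc_too_few_trials", float(len(kept))))
            continue
        pair = EpochedPair(stim, rec, trials, kept)
        z = ep_zscore(pair.trials, kept)
        zart = np.abs(z[art_w]).max()
        zresp = np.abs(z[resp_w]).max()
        if zart >= artifact_z and zresp < artifact_z:
            log.append((stim.name, rec.name, "iv_artifact_only", zart))
            continue
        pair.ep_z = z
        retained.append(pair)
    log = pd.DataFrame(log, columns=["stim", "rec", "rule", "value"])
    return retained, log


@dataclass
class SubjectData:
    """Preprocessed output of one session: retained epoched pairs + QC logs."""

    subject: str
    pairs: list = field(default_factory=list)
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)
    channel_stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    bad_channels: list = field(default_factory=list)


def preprocess_session(session: Session, *, amp_sd: float = 5.0,
                       min_dist_mm: float = 5.0, artifact_z: float = 7.0) -> SubjectData:
    """Full preprocessing of one session: notch -> channel QC -> bipolar
    re-reference -> epoch -> trial QC -> exclusion rules."""
    clean = notch_filter(session.voltage, session.fs)
    filtered = Session(session.subject, clean, session.fs, session.channels,
                       session.events)
    flags, stats = detect_bad_channels(filtered, amp_sd=amp_sd)
    bad = set(session.channels.loc[flags, "name"])
    pairs, traces = bipolar_rereference(filtered, bad)
    by_name = {p.name: (p, traces[i]) for i, p in enumerate(pairs)}

    out = SubjectData(subject=session.subject, channel_stats=stats,
                      bad_channels=sorted(bad))
    logs = []
    for stim_name, ev in filtered.events.groupby("stim_pair", sort=False):
        if stim_name not in by_name:
            raise ValueError(f"stimulation pair {stim_name} is not an adjacent bipolar pair")
        stim = by_name[stim_name][0]
        onsets = ev["onset_sample"].to_numpy()
        candidates = [
            (rec, (lambda tr=trace, on=onsets: _epoch(tr, on)))
            for rec, trace in by_name.values()
        ]
        retained, log = exclude_pairs(stim, candidates, bad,
                                      min_dist_mm=min_dist_mm, artifact_z=artifact_z)
        out.pairs.extend(retained)
        logs.append(log)
    out.exclusions = pd.concat(logs, ignore_index=True)
    return out
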