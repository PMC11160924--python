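"""Evoked power and inter-trial phase coherence spectrograms.

Continuous bipolar traces are decomposed with complex Morlet wavelets (59
log-spaced frequencies in [1, 256] Hz, width 5 cycles).  Per-trial power at
1000 Hz is decimated to 200 samples/s by averaging non-overlapping 5-sample
blocks; phase is taken at block centres.  Evoked power is baseline-ratioed,
trial-averaged, log-transformed and jointly z-scored across all
time-frequency cells; ITPC is square-root transformed and z-scored the same
way.  Both spectrograms are finally collapsed onto a fixed 60-time-point x
6-band feature grid for manifold learning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import (
    BASELINE_MS, EPOCH_MS, FS, N_CYCLES, N_FREQS, PAD_MS, BANDS, TIME_BINS,
    BipolarChannel, EpochedPair, FeatureVector, Spectrogram,
    epoch_samples, morlet_freqs, spec_times_ms,
)

__all__ = [
    "morlet_power", "wavelet_decompose", "evoked_power", "itpc",
    "downsample_features", "EvokedInstance", "compute_instance",
    "unreliable_freqs",
]

_DECIM = FS // 200  # 5-sample blocks -> 200 samples/s


def unreliable_freqs() -> np.ndarray:
    """Frequencies whose 5-cycle wavelet outlasts the nominal epoch; their
    lowest-frequency estimates lean on the padded data and are edge-dominated."""
    span_s = (EPOCH_MS[1] - EPOCH_MS[0]) / 1000.0
    return morlet_freqs() < N_CYCLES / span_s


def _pad_trials(trials: np.ndarray) -> np.ndarray:
    pad = PAD_MS * FS // 1000
    n_nominal = epoch_samples()
    if trials.shape[-1] == n_nominal + 2 * pad:
        return trials
    if trials.shape[-1] == n_nominal:
        return np.pad(trials, [(0, 0)] * (trials.ndim - 1) + [(pad, pad)], mode="reflect")
    raise ValueError("unexpected epoch length")


def _morlet_wavelet(freq: float, fs: float = FS) -> np.ndarray:
    """Complex Morlet atom: zero-mean, L2-normalised (x sqrt(2)), support
    +-5 sigma_t — the standard construction used by time-frequency toolboxes,
    so the bank can be cross-checked against them wherever they apply."""
    sigma_t = N_CYCLES / (2.0 * np.pi * freq)
    t = np.arange(0.0, 5.0 * sigma_t, 1.0 / fs)
    t = np.r_[-t[::-1], t[1:]]
    osc = np.exp(2j * np.pi * freq * t)
    osc -= np.exp(-2 * (np.pi * freq * sigma_t) ** 2)  # zero mean
    w = osc * np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    return w / (np.sqrt(0.5) * np.linalg.norm(w))


_BANK_CACHE: dict = {}


def _bank_plan(n: int, fs: float, single: bool):
    """Group frequencies by wavelet length so short atoms use small FFTs;
    wavelet spectra are cached per epoch length."""
    from scipy import fft as sp_fft

    key = (n, fs, single)
    if key in _BANK_CACHE:
        return _BANK_CACHE[key]
    freqs = morlet_freqs()
    wavelets = [_morlet_wavelet(f, fs) for f in freqs]
    lengths = np.array([len(w) for w in wavelets])
    plan = []
    prev_edge = 0
    for edge in (600, 1800, 3600, np.inf):
        sel = [i for i in range(len(freqs)) if prev_edge < lengths[i] <= edge]
        prev_edge = edge
        if not sel:
            continue
        n_fft = sp_fft.next_fast_len(n + int(max(lengths[sel])) - 1, real=False)
        fw = np.stack([sp_fft.fft(wavelets[i], n_fft) for i in sel])
        starts = np.array([(lengths[i] - 1) // 2 for i in sel])
        if single:
            fw = fw.astype(np.complex64)
        plan.append((sel, n_fft, fw, starts, edge))
    _BANK_CACHE[key] = plan
    return plan


def _morlet_bank(data: np.ndarray, fs: float = FS, single: bool = False) -> np.ndarray:
    """Filter ``data`` (n_signals, n_times) with the full wavelet bank via
    shared-FFT linear convolution ('same' alignment).  Wavelets may be longer
    than the signal (the 1 Hz atom spans ~8 s); outside-epoch contributions
    are zero-padded, which is why the lowest rows are flagged unreliable.
    ``single=True`` runs the bank in single precision (used by the batched
    pipeline path; ~1e-6 relative error)."""
    from scipy import fft as sp_fft

    n = data.shape[-1]
    if single:
        data = data.astype(np.float32)
    out = np.empty((data.shape[0], N_FREQS, n),
                   dtype=np.complex64 if single else complex)
    for sel, n_fft, fw, starts, _ in _bank_plan(n, fs, single):
        fdata = sp_fft.fft(data, n_fft, axis=-1)
        conv = sp_fft.ifft(fdata[:, None, :] * fw[None, :, :], axis=-1)
        for j, (i, start) in enumerate(zip(sel, starts)):
            out[:, i, :] = conv[:, j, start:start + n]
    return out


def wavelet_decompose(trials: np.ndarray, fs: float = FS, single: bool = False):
    """Complex Morlet decomposition of epoched trials.

    ``trials`` is (n_trials, n_times), either the nominal -500..1000 ms span
    (reflect-padded internally) or the padded span stored on
    :class:`~stimmap.containers.EpochedPair`.  Returns ``(power, phases)``:
    per-trial power (n_trials, 59, n_dec) block-averaged to 200 samples/s and
    the complex unit phase at block centres.
    """
    if int(fs) != FS:
        raise ValueError(f"expected fs = {FS} Hz")
    data = _pad_trials(np.atleast_2d(trials))
    w = _morlet_bank(data, fs, single=single)
    pad = PAD_MS * FS // 1000
    w = w[..., pad:pad + epoch_samples()]
    n_dec = epoch_samples() // _DECIM
    power = (np.abs(w) ** 2).reshape(w.shape[0], w.shape[1], n_dec, _DECIM).mean(-1)
    centre = w[..., _DECIM // 2::_DECIM][..., :n_dec]
    with np.errstate(invalid="ignore", divide="ignore"):
        phases = np.where(np.abs(centre) > 0, centre / np.abs(centre), 0.0)
    return power.astype(float), phases.astype(complex)


def morlet_power(trials: np.ndarray, fs: float = FS) -> np.ndarray:
    """Per-trial instantaneous power at the 59 analysis frequencies,
    decimated to 200 samples/s.  Lowest frequencies are edge-contaminated
    when the epoch is shorter than 5 cycles (warned once)."""
    if unreliable_freqs().any():
        warnings.warn("epoch shorter than 5 cycles at the lowest frequencies; "
                      "those rows are edge-dominated", stacklevel=2)
    return wavelet_decompose(trials, fs)[0]


def _baseline_mask() -> np.ndarray:
    t = spec_times_ms()
    return (t >= BASELINE_MS[0]) & (t < BASELINE_MS[1])


def _zscore_cells(values: np.ndarray) -> np.ndarray:
    # constant maps (e.g. perfectly coherent phases) z-score to zero
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def evoked_power(power_trials: np.ndarray, kept: np.ndarray,
                 baseline: np.ndarray | None = None) -> Spectrogram:
    """Trial-averaged evoked power: ratio to per-frequency baseline mean,
    log-transformed, then z-scored jointly over all time-frequency cells."""
    base_mask = _baseline_mask() if baseline is None else baseline
    p = power_trials[kept]
    base = p[:, :, base_mask].mean(axis=(0, 2))
    if np.any(base <= 0):
        raise ValueError("zero baseline power (degenerate input)")
    rel = p.mean(axis=0) / base[:, None]
    return Spectrogram(values=_zscore_cells(np.log(rel)), kind="power")


def itpc(phases: np.ndarray, kept: np.ndarray) -> Spectrogram:
    """Inter-trial phase coherence.

    ``phases`` are per-trial phase angles (radians) or complex phase values;
    raw ITPC(f, t) = |mean over trials of the unit phase vectors|, in [0, 1].
    The stored ``values`` are the square-root transformed, cell-z-scored
    version used by downstream learning.
    """
    if len(kept) < 2:
        raise ValueError("ITPC requires >= 2 trials")
    u = np.asarray(phases)[kept]
    if not np.iscomplexobj(u):
        u = np.exp(1j * u)
    else:
        mag = np.abs(u)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(mag > 0, u / mag, 0.0)
    raw = np.abs(u.mean(axis=0))
    return Spectrogram(values=_zscore_cells(np.sqrt(raw)), kind="itpc", raw=raw)


# ------------------------------------------------------------ feature grid


def _kernel_grid():
    """(time_mask, band_mask) index lists defining the 60 x 6 kernels."""
    t, f = spec_times_ms(), morlet_freqs()
    time_masks = []
    for a, b, n in TIME_BINS:
        edges = np.linspace(a, b, n + 1)
        for i in range(n):
            hi_closed = (i == n - 1)
            m = (t >= edges[i]) & ((t <= edges[i + 1]) if hi_closed else (t < edges[i + 1]))
            time_masks.append(m)
    band_masks = [(f >= lo) & (f < hi) for _, lo, hi in BANDS]
    return time_masks, band_masks


def downsample_features(power: Spectrogram, itpc_spec: Spectrogram) -> FeatureVector:
    """Average cells within each (time-kernel x band) block and concatenate
    the power and ITPC halves into one flat vector (length 720).  Kernels
    whose time window holds no spectrogram sample are NaN."""
    time_masks, band_masks = _kernel_grid()
    halves = []
    for spec in (power, itpc_spec):
        vals = np.empty((len(time_masks), len(band_masks)))
        for i, tm in enumerate(time_masks):
            if not tm.any():
                vals[i] = np.nan
                continue
            block = spec.values[:, tm]
            for j, bm in enumerate(band_masks):
                vals[i, j] = block[bm].mean()
        halves.append(vals.ravel())
    return FeatureVector(values=np.concatenate(halves))


# ---------------------------------------------------------------- instance


@dataclass
class EvokedInstance:
    """One stimulating-pair -> recording-pair record after spectral analysis."""

    subject: str
    stim: BipolarChannel
    rec: BipolarChannel
    power: Spectrogram
    itpc: Spectrogram
    ep_z: np.ndarray
    features: FeatureVector
    n_trials: int

    @property
    def name(self) -> str:
        return f"{self.stim.name}>{self.rec.name}"


def compute_instance(pair: EpochedPair, subject: str = "") -> EvokedInstance:
    """Spectral analysis of one epoched pair (power, ITPC, feature vector)."""
    power_trials, phases = wavelet_decompose(pair.trials_ext, single=True)
    pw = evoked_power(power_trials, pair.kept_trials)
    pc = itpc(phases, pair.kept_trials)
    if pair.ep_z is None:
        from .preprocess import ep_zscore
        pair.ep_z = ep_zscore(pair.trials, pair.kept_trials)
    return EvokedInstance(
        subject=subject, stim=pair.stim, rec=pair.rec, power=pw, itpc=pc,
        ep_z=pair.ep_z, features=downsample_features(pw, pc),
        n_trials=len(pair.kept_trials),
    )
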