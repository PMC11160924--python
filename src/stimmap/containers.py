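"""Shared containers and canonical grids for the stimulation-evoked pipeline.

All stages of the pipeline speak in terms of a few fixed grids:

* raw voltage sampled at 1000 Hz, epochs spanning -500..+1000 ms around each
  pulse (time 0 = pulse onset, half-open windows ``[a, b)`` in ms);
* spectrograms on 59 log-spaced frequencies between 1 and 256 Hz, decimated to
  200 samples/s (5 ms blocks, values indexed at block centres);
* a fixed down-sampled feature grid (60 time points x 6 conventional bands,
  power and phase-coherence halves concatenated -> 720 features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ----------------------------------------------------------------- constants

FS = 1000
"""Raw sampling rate in Hz (fixed by the recording system)."""

EPOCH_MS = (-500, 1000)
"""Nominal epoch span around pulse onset, ms, half-open [start, stop)."""

PAD_MS = 1000
"""Extra padding kept on each side of the epoch for wavelet filtering."""

BASELINE_MS = (-300, -50)
"""Pre-stimulation baseline window, ms (avoids filter edges and pulse lead-in)."""

SPEC_SR = 200
"""Spectrogram sampling rate (samples/s); 1000 Hz power is block-averaged 5:1."""

N_FREQS = 59
N_CYCLES = 5.0

ARTIFACT_MS = (0, 10)
"""Stimulation-artifact window, ms post pulse."""

BANDS = (
    ("delta", 0.5, 5.0),
    ("theta", 5.0, 8.0),
    ("alpha", 8.0, 15.0),
    ("beta", 15.0, 30.0),
    ("gamma", 30.0, 70.0),
    ("high", 70.0, np.inf),
)

TIME_BINS = ((-30, 10, 5), (11, 117, 25), (118, 283, 20), (284, 800, 10))
"""(start_ms, stop_ms, n_points) of the temporal down-sampling kernels."""

N_TIME_POINTS = sum(n for _, _, n in TIME_BINS)  # 60
N_FEATURES = 2 * N_TIME_POINTS * len(BANDS)  # 720

THALAMIC_REGIONS = ("antTH", "midTH", "pstTH")


def morlet_freqs() -> np.ndarray:
    """The 59 log-spaced analysis frequencies between 1 and 256 Hz."""
    return np.logspace(0.0, 8.0, N_FREQS, base=2.0)


def epoch_samples() -> int:
    return (EPOCH_MS[1] - EPOCH_MS[0]) * FS // 1000


def epoch_times_ms() -> np.ndarray:
    """Millisecond time stamps of the 1000 Hz epoch grid."""
    return np.arange(EPOCH_MS[0], EPOCH_MS[1], dtype=float)


def spec_times_ms() -> np.ndarray:
    """Block-centre time stamps (ms) of the 200 samples/s spectrogram grid."""
    step = 1000 // SPEC_SR
    return EPOCH_MS[0] + step * np.arange(epoch_samples() // step) + (step - 1) / 2.0


# --------------------------------------------------------------- dataclasses


@dataclass
class Session:
    """One subject's recording: continuous voltage plus metadata tables.

    ``voltage`` is (n_channels, n_samples) in microvolts at :data:`FS`.
    ``channels`` has columns name, shaft, region, hemisphere, white_matter,
    x, y, z.  ``events`` has columns onset_sample, stim_pair, amplitude_mA,
    with ``stim_pair`` formatted ``"<contact_a>-<contact_b>"``.
    """

    subject: str
    voltage: np.ndarray
    fs: float
    channels: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if self.voltage.ndim != 2:
            raise ValueError("voltage must be 2-D (channels x samples)")
        if len(self.channels) != self.voltage.shape[0]:
            raise ValueError("channel table does not match voltage shape")
        names = set(self.channels["name"])
        for pair in self.events["stim_pair"].unique():
            a, b = pair.split("-")
            if a not in names or b not in names:
                raise ValueError(f"events reference unknown channel in {pair!r}")

    @property
    def stim_pairs(self) -> list[str]:
        return list(dict.fromkeys(self.events["stim_pair"]))


@dataclass(frozen=True)
class BipolarChannel:
    """An adjacent-contact bipolar derivation (trace = contact_a - contact_b)."""

    contact_a: str
    contact_b: str
    region: str | None
    hemisphere: str
    midpoint: tuple[float, float, float]
    white_matter: bool

    @property
    def name(self) -> str:
        return f"{self.contact_a}-{self.contact_b}"

    @property
    def thalamic(self) -> bool:
        return self.region in THALAMIC_REGIONS


@dataclass
class EpochedPair:
    """Trial epochs of one stimulating -> recording bipolar instance.

    ``trials_ext`` spans the padded window (EPOCH_MS widened by PAD_MS on each
    side); the :attr:`trials` view is the nominal -500..+1000 ms span used by
    all quality-control statistics.  ``kept_trials`` indexes rows of
    ``trials_ext`` that survived trial QC.
    """

    stim: BipolarChannel
    rec: BipolarChannel
    trials_ext: np.ndarray
    kept_trials: np.ndarray
    ep_z: np.ndarray | None = None

    @property
    def trials(self) -> np.ndarray:
        pad = PAD_MS * FS // 1000
        return self.trials_ext[:, pad:pad + epoch_samples()]

    @property
    def name(self) -> str:
        return f"{self.stim.name}>{self.rec.name}"


@dataclass
class Spectrogram:
    """Frequency x time matrix on the canonical grid.

    ``kind`` is ``"power"`` or ``"itpc"``; ``values`` are z-units after the
    stage transforms.  For ITPC the pre-transform coherence is kept in
    ``raw`` (values in [0, 1]).
    """

    values: np.ndarray
    kind: str
    freqs: np.ndarray = field(default_factory=morlet_freqs)
    times: np.ndarray = field(default_factory=spec_times_ms)
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.freqs), len(self.times)):
            raise ValueError("spectrogram values do not match the grid")


@dataclass
class FeatureVector:
    """Flat 720-vector: power then ITPC, 60 time kernels x 6 bands each.

    Kernels whose time window contains no spectrogram sample are NaN; they are
    mean-imputed (or dropped when empty for every instance) during training
    preparation.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")
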