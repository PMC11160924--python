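"""Synthetic stimulation-evoked sessions with ground-truth connectivity.

The generator emulates the study conditions of a repeated single-pulse
stimulation (RSEPS) experiment: ~42 biphasic pulses per stimulated bipolar
pair at 2 s intervals, recorded on a multi-shaft depth-electrode montage at
1000 Hz.  Each planted connection carries up to three spectral features:

* **F1** — an early (10-60 ms) phase-locked gamma Gabor atom; produces both a
  power and an ITPC signature in the gamma band.
* **F2** — a theta-alpha burst at ~120 ms whose per-trial onset is jittered
  (carrier phase tied to the jittered onset), so trial-averaged power survives
  while inter-trial phase coherence collapses to chance.
* **F3** — a delayed (>200 ms) phase-locked ~5 Hz oscillation lasting >= 2
  cycles, planted identically on all of the stimulating pair's targets,
  including contralateral ones.

A broadband stimulation artifact confined to < 10 ms post pulse is added to
every channel with 1/(1+distance) scaling, on top of 1/f background noise.
Bad channels (amplitude-inflated), spiky channels and bad trials are planted
so the downstream quality-control path is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import FS, Session, THALAMIC_REGIONS

__all__ = [
    "ConnectionSpec",
    "CohortSpec",
    "GroundTruth",
    "default_layout",
    "make_channel_table",
    "make_session",
    "make_cohort",
    "write_cohort_tables",
]


# ------------------------------------------------------------------- specs


@dataclass
class ConnectionSpec:
    """One planted stimulating-pair -> recording-pair connection."""

    stim_pair_id: str
    rec_pair_id: str
    has_f1: bool
    has_f2: bool
    has_f3: bool
    f1_onset: float = 25.0     # ms
    f1_gain: float = 1.0       # unitless multiplier on the cohort F1 amplitude
    f1_freq: float = 65.0      # Hz carrier of the gamma atom
    f2_onset: float = 120.0    # ms
    f2_jitter_sd: float = 40.0  # ms
    f3_onset: float = 220.0    # ms
    f3_freq: float = 5.0       # Hz
    f3_cycles: float = 2.0
    f3_phase: float = 0.0      # rad, shared across a stim pair's targets
    noise_sd: float = 5.0      # uV background at the recording contacts

    def validate(self) -> None:
        if self.has_f1 and not (10 <= self.f1_onset <= 60):
            raise ValueError("f1_onset must lie in [10, 60] ms")
        if self.has_f2 and not (70 <= self.f2_onset <= 165):
            raise ValueError("f2_onset must lie in [70, 165] ms")
        if self.has_f3 and self.f3_onset < 200:
            raise ValueError("f3_onset must be >= 200 ms")
        if self.f3_cycles < 2:
            raise ValueError("f3 oscillations require >= 2 cycles")


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults are the conditions every acceptance-scale simulation runs at:
    42 trials per stimulated pair at 2 s intervals, a 24-contact three-shaft
    montage per subject (one ipsilateral cortical shaft with two white-matter
    contacts, one contralateral cortical shaft, one thalamic shaft split into
    antTH/midTH/pstTH), four stimulated pairs (two cortical, two thalamic) and
    a 0.2 connection probability per ordered stimulating->recording pair.
    """

    n_subjects: int = 12
    channels_per_subject: int = 32
    n_trials: int = 42
    trial_interval: float = 2.0    # s
    fs: int = 1000                 # Hz, fixed
    connection_density: float = 0.2
    seed: int = 0
    # signal amplitudes, uV
    noise_sd: float = 5.0
    f1_amp: float = 20.0
    f2_amp: float = 15.0
    f3_amp: float = 15.0
    artifact_amp: float = 300.0
    # QC plants
    n_bad_trials: int = 3
    f3_onset_range: tuple = (240.0, 285.0)  # ms, uniform per stimulated pair
    regions: tuple = ()            # filled from default_layout when empty

    def __post_init__(self) -> None:
        if self.fs != FS:
            raise ValueError(f"fs is fixed at {FS} Hz")
        if self.trial_interval < 1.0:
            raise ValueError("trial_interval must be >= 1 s so epochs never overlap")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        valid = {"HPC", "MTG", "LFC"} | set(THALAMIC_REGIONS)
        if not self.regions:
            self.regions = tuple(
                (shaft, hemi, tuple(r for r, _ in contacts))
                for shaft, hemi, contacts, _ in default_layout()
            )
        for _, _, region_labels in self.regions:
            for r in region_labels:
                if r not in valid:
                    raise ValueError(f"invalid region label {r!r}")


@dataclass
class GroundTruth:
    """Everything planted in one session, for downstream scoring."""

    connections: list = field(default_factory=list)
    bad_channels: list = field(default_factory=list)
    noise_channels: list = field(default_factory=list)
    bad_trials: list = field(default_factory=list)  # (channel, stim_pair, trial)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.connections],
                            columns=list(ConnectionSpec.__dataclass_fields__))


# ------------------------------------------------------------------ montage

CONTACT_SPACING_MM = 4.0


def default_layout():
    """Four 8-contact shafts: HPC-L (contacts 4-5 in white matter), MTG-R,
    a left thalamic shaft split antTH x3 / midTH x2 / pstTH x3, and LFC-R."""
    return [
        ("A", "L", [("HPC", False)] * 3 + [("HPC", True)] * 2 + [("HPC", False)] * 3,
         (0.0, 0.0, 0.0)),
        ("B", "R", [("MTG", False)] * 8, (0.0, 40.0, 0.0)),
        ("C", "L", [("antTH", False)] * 3 + [("midTH", False)] * 2 + [("pstTH", False)] * 3,
         (0.0, -40.0, 10.0)),
        ("D", "R", [("LFC", False)] * 8, (0.0, 80.0, 0.0)),
    ]


def make_channel_table() -> pd.DataFrame:
    rows = []
    for shaft, hemi, contacts, origin in default_layout():
        for i, (region, wm) in enumerate(contacts):
            rows.append(dict(
                name=f"{shaft}{i + 1:02d}", shaft=shaft, region=region,
                hemisphere=hemi, white_matter=bool(wm),
                x=origin[0] + CONTACT_SPACING_MM * i, y=origin[1], z=origin[2],
            ))
    return pd.DataFrame(rows)


DEFAULT_STIM_PAIRS = ("A01-A02", "B01-B02", "C01-C02", "C06-C07")
BAD_CHANNEL = "B08"     # amplitude-inflated ("pathological" surrogate)
NOISE_CHANNEL = "A08"   # spiky channel (jump prevalence)


def _adjacent_pairs(channels: pd.DataFrame):
    """All adjacent-contact bipolar pairs per shaft (8 contacts -> 7 pairs)."""
    pairs = []
    for _, grp in channels.groupby("shaft", sort=True):
        grp = grp.reset_index(drop=True)
        for i in range(len(grp) - 1):
            pairs.append((grp.loc[i, "name"], grp.loc[i + 1, "name"]))
    return pairs


def _pair_midpoint(channels: pd.DataFrame, a: str, b: str) -> np.ndarray:
    tab = channels.set_index("name")
    return (tab.loc[a, ["x", "y", "z"]].to_numpy(float)
            + tab.loc[b, ["x", "y", "z"]].to_numpy(float)) / 2.0


def plantable_pairs(channels: pd.DataFrame, stim_pair: str) -> list[str]:
    """Recording pairs a connection may be planted on for ``stim_pair``:
    same-region, not both white matter, no QC-planted channels, no contact
    shared with the stimulation pair, and midpoint > 5 mm away from it."""
    tab = channels.set_index("name")
    sa, sb = stim_pair.split("-")
    smid = _pair_midpoint(channels, sa, sb)
    out = []
    for a, b in _adjacent_pairs(channels):
        if {a, b} & {sa, sb, BAD_CHANNEL, NOISE_CHANNEL}:
            continue
        if tab.loc[a, "region"] != tab.loc[b, "region"]:
            continue
        if tab.loc[a, "white_matter"] and tab.loc[b, "white_matter"]:
            continue
        mid = _pair_midpoint(channels, a, b)
        if np.linalg.norm(mid - smid) <= 5.0:
            continue
        out.append(f"{a}-{b}")
    return out


# ------------------------------------------------------------------ signals


def _one_over_f_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / FS)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** -0.5
    x = np.fft.irfft(spec * shaping, n=n)
    return x * (sd / x.std())


def _gabor(freq: float, sigma_ms: float, phase: float = 0.0) -> np.ndarray:
    """Gaussian-windowed sinusoid; support truncated at +-3 sigma."""
    half = int(round(3 * sigma_ms * FS / 1000))
    t = np.arange(-half, half + 1) / FS
    return np.exp(-0.5 * (t / (sigma_ms / 1000.0)) ** 2) * np.cos(2 * np.pi * freq * t + phase)


def artifact_waveform(amp: float = 1.0) -> np.ndarray:
    """Deterministic damped 300 Hz transient strictly confined to [0, 8) ms."""
    t = np.arange(0, int(0.008 * FS)) / FS
    return amp * np.exp(-t / 0.002) * np.sin(2 * np.pi * 300.0 * t)


def _add(trace: np.ndarray, start: int, wave: np.ndarray) -> None:
    stop = min(start + len(wave), trace.shape[-1])
    if start < 0 or stop <= start:
        return
    trace[start:stop] += wave[:stop - start]


# ------------------------------------------------------------------ session


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject_index,)))


def _draw_connections(cohort: CohortSpec, channels: pd.DataFrame,
                      rng: np.random.Generator) -> list[ConnectionSpec]:
    tab = channels.set_index("name")
    conns = []
    for stim_pair in DEFAULT_STIM_PAIRS:
        thalamic = tab.loc[stim_pair.split("-")[0], "region"] in THALAMIC_REGIONS
        # F3 waveform is a property of the stimulating site: shared onset,
        # frequency and phase across all of its targets (bilateral).
        f3_onset = rng.uniform(*cohort.f3_onset_range)
        f3_freq = rng.uniform(4.5, 5.5)
        f3_phase = rng.uniform(0.0, 2 * np.pi)
        for rec_pair in plantable_pairs(channels, stim_pair):
            if rng.uniform() >= cohort.connection_density:
                continue
            has_f1 = rng.uniform() < 0.9
            has_f2 = rng.uniform() < 0.7
            has_f3 = rng.uniform() < (0.8 if thalamic else 0.05)
            if not (has_f1 or has_f2 or has_f3):
                has_f2 = True
            spec = ConnectionSpec(
                stim_pair_id=stim_pair, rec_pair_id=rec_pair,
                has_f1=has_f1, has_f2=has_f2, has_f3=has_f3,
                f1_onset=rng.uniform(15.0, 45.0),
                f1_gain=rng.uniform(0.8, 1.2),
                f1_freq=rng.uniform(55.0, 75.0),
                f2_onset=rng.uniform(90.0, 150.0),
                f2_jitter_sd=40.0,
                f3_onset=f3_onset, f3_freq=f3_freq, f3_cycles=2.0,
                f3_phase=f3_phase, noise_sd=cohort.noise_sd,
            )
            spec.validate()
            conns.append(spec)
    return conns


def make_session(cohort: CohortSpec, subject_index: int):
    """Generate one subject's synthetic session.

    Returns ``(Session, GroundTruth)``.  Deterministic: the subject seed is
    derived from ``cohort.seed`` and ``subject_index`` alone.
    """
    if subject_index >= cohort.n_subjects:
        raise ValueError("subject_index out of range")
    rng = _subject_rng(cohort.seed, subject_index)
    channels = make_channel_table()
    n_ch = len(channels)
    names = list(channels["name"])
    idx = {n: i for i, n in enumerate(names)}

    n_trials, interval = cohort.n_trials, cohort.trial_interval
    block = n_trials * interval
    gap, lead = 4.0, 5.0
    n_samp = int((lead + len(DEFAULT_STIM_PAIRS) * (block + gap) + lead) * FS)

    voltage = np.empty((n_ch, n_samp))
    for c in range(n_ch):
        voltage[c] = _one_over_f_noise(rng, n_samp, cohort.noise_sd)

    # events -------------------------------------------------------------
    rows = []
    for k, stim_pair in enumerate(DEFAULT_STIM_PAIRS):
        t0 = lead + k * (block + gap)
        for j in range(n_trials):
            rows.append(dict(onset_sample=int(round((t0 + j * interval) * FS)),
                             stim_pair=stim_pair, amplitude_mA=6.0))
    events = pd.DataFrame(rows)

    # stimulation artifact: identical transient each pulse, 1/(1+d) scaling --
    coords = channels[["x", "y", "z"]].to_numpy(float)
    art = artifact_waveform()
    for stim_pair, ev in events.groupby("stim_pair", sort=False):
        smid = _pair_midpoint(channels, *stim_pair.split("-"))
        dist = np.linalg.norm(coords - smid, axis=1)
        scale = cohort.artifact_amp / (1.0 + dist)
        onsets = ev["onset_sample"].to_numpy()
        for c in range(n_ch):
            wave = art * scale[c]
            for s in onsets:
                _add(voltage[c], s, wave)

    # planted connections -------------------------------------------------
    gt = GroundTruth(bad_channels=[BAD_CHANNEL], noise_channels=[NOISE_CHANNEL])
    gt.connections = _draw_connections(cohort, channels, rng)
    ev_by_pair = {p: g["onset_sample"].to_numpy() for p, g in events.groupby("stim_pair", sort=False)}
    for spec in gt.connections:
        target = idx[spec.rec_pair_id.split("-")[0]]
        onsets = ev_by_pair[spec.stim_pair_id]
        if spec.has_f1:
            # fast phase-locked response: gamma-band Gabor atom riding on an
            # N1-like slow deflection (evoked potentials are multi-component;
            # the gamma burst alone is not a realistic waveform)
            amp = cohort.f1_amp * spec.f1_gain
            gabor = amp * _gabor(spec.f1_freq, 8.0)
            tn = np.arange(0, int(0.080 * FS)) / FS
            tau = 0.015
            n1 = -amp * (tn / tau) * np.exp(1.0 - tn / tau)
            start_off = int(round(spec.f1_onset / 1000 * FS))
            for s in onsets:
                _add(voltage[target], s + start_off, gabor)
                _add(voltage[target], s + start_off, n1)
        if spec.has_f2:
            # onset jitter with carrier phase tied to the (jittered) onset:
            # trial-averaged power survives, phase coherence does not.
            f2_freq = rng.uniform(7.0, 10.0)
            jit = rng.normal(0.0, spec.f2_jitter_sd, size=len(onsets))
            wave = cohort.f2_amp * _gabor(f2_freq, 30.0)
            for s, j in zip(onsets, jit):
                _add(voltage[target], s + int(round((spec.f2_onset + j) / 1000 * FS)), wave)
        if spec.has_f3:
            # damped evoked oscillation: 20 ms raised-cosine attack, then
            # exponential ring-down over >= 2 full cycles.  Evoked rhythms
            # decay, which is also what makes their onset identifiable: the
            # power envelope peaks shortly after f3_onset rather than at the
            # burst midpoint.
            dur = spec.f3_cycles / spec.f3_freq
            t = np.arange(0, int(dur * FS)) / FS
            attack, tau = 0.020, 0.120
            env = np.where(t < attack, 0.5 - 0.5 * np.cos(np.pi * t / attack),
                           np.exp(-(t - attack) / tau))
            wave = cohort.f3_amp * env * np.sin(2 * np.pi * spec.f3_freq * t + spec.f3_phase)
            start_off = int(round(spec.f3_onset / 1000 * FS))
            for s in onsets:
                _add(voltage[target], s + start_off, wave)

    # QC plants ------------------------------------------------------------
    voltage[idx[BAD_CHANNEL]] *= 6.0  # amplitude-inflation surrogate
    spike_at = rng.choice(np.arange(int(lead * FS), n_samp - 10), size=200, replace=False)
    voltage[idx[NOISE_CHANNEL], spike_at] += 100.0  # jumps > 80 uV
    safe = [n for n in names if n not in
            {BAD_CHANNEL, NOISE_CHANNEL} | {c for p in DEFAULT_STIM_PAIRS for c in p.split("-")}]
    for _ in range(cohort.n_bad_trials):
        ch = str(rng.choice(safe))
        stim_pair = str(rng.choice(DEFAULT_STIM_PAIRS))
        trial = int(rng.integers(cohort.n_trials))
        s = ev_by_pair[stim_pair][trial]
        voltage[idx[ch], s + 50:s + 450] += 200.0
        gt.bad_trials.append((ch, stim_pair, trial))

    session = Session(subject=f"sub-{subject_index + 1:02d}", voltage=voltage,
                      fs=float(FS), channels=channels, events=events)
    return session, gt


def make_cohort(cohort: CohortSpec):
    """Generate all subjects; per-subject seeds derive from the cohort seed."""
    return [make_session(cohort, i) for i in range(cohort.n_subjects)]


# ---------------------------------------------------------------------- io


def write_cohort_tables(cohort: CohortSpec, out_dir) -> dict:
    """Write per-subject HDF5 recordings + channels/events TSVs and a
    cohort-wide ground-truth table.  Round-trips through cli_io.read_session."""
    import h5py
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"subjects": []}
    gt_frames = []
    for i in range(cohort.n_subjects):
        session, gt = make_session(cohort, i)
        sub = out / session.subject
        sub.mkdir(exist_ok=True)
        with h5py.File(sub / "recording.h5", "w") as h5:
            h5.create_dataset("voltage", data=session.voltage, track_times=False)
            h5["voltage"].attrs["fs"] = session.fs
            h5["voltage"].attrs["units"] = "uV"
            h5.create_dataset(
                "channel_names",
                data=np.array(session.channels["name"], dtype="S"),
                track_times=False)
        session.channels.to_csv(sub / "channels.tsv", sep="\t", index=False)
        session.events.to_csv(sub / "events.tsv", sep="\t", index=False)
        frame = gt.to_frame()
        frame.insert(0, "subject", session.subject)
        frame["bad_channels"] = ",".join(gt.bad_channels)
        frame["noise_channels"] = ",".join(gt.noise_channels)
        gt_frames.append(frame)
        paths["subjects"].append(sub)
    gt_path = out / "ground_truth.tsv"
    pd.concat(gt_frames, ignore_index=True).to_csv(gt_path, sep="\t", index=False)
    paths["ground_truth"] = gt_path
    return paths
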