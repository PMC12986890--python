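"""EEG-like multichannel trials with controllable graph and spectral structure.

Every pipeline stage is testable without external recordings because the
generator plants exactly the two kinds of structure the graph construction
extracts:

* class-dependent pairwise *phase coupling* inside a carrier band, which
  controls the PLV adjacency.  Each band's phase trajectory per channel is a
  phase random walk (drift ``2*pi*f_carrier/fs`` per sample plus Gaussian
  diffusion); a coupled pair (i, j, coupling c) replaces channel j's phase
  with the circular mixture ``angle(c*exp(i(phi_i + delta)) +
  (1-c)*exp(i*psi_j))`` of channel i's trajectory (with a fixed per-trial
  offset delta) and an independent walk — the pair's expected PLV grows
  monotonically with c, reaching 1 at c = 1;
* class-dependent per-band oscillation *amplitudes*, which control the
  filter-bank band-power node features.

Channels sum their band oscillations plus white Gaussian noise.  The phase
model is a mixture random walk rather than a coupled-oscillator integration:
the quantity under test is PLV structure, not biophysics.  Phase diffusion of
0.3 rad/sample at 250 Hz gives an approximately Lorentzian line of ~3.6 Hz
width — narrow enough to sit inside a 4 Hz analysis band, wide enough that
uncoupled channels decorrelate within a 4 s trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_eeg import EEGRecording, EpochSet, EpochedTrial

__all__ = [
    "SyntheticClassSpec",
    "SyntheticDatasetConfig",
    "default_class_specs",
    "generate_trial",
    "generate_epochs",
    "generate_dataset",
    "epochs_to_recording",
    "DEFAULT_BANDS",
]

DEFAULT_BANDS: tuple[tuple[float, float], ...] = tuple(
    (float(lo), float(lo + 4)) for lo in range(8, 40, 4)
)


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Ground truth for one class.

    ``coupled_pairs``: (i, j, coupling in [0, 1], carrier band (f_low,
    f_high)); pairs are applied in order, so chains (j coupled to i, k
    coupled to j) are allowed and produce a coupled clique.
    ``band_amp``: (C, B) oscillation amplitudes in microvolts, columns
    matching ``bands``.  ``noise_sd``: additive white-noise level.
    """

    coupled_pairs: tuple[tuple[int, int, float, tuple[float, float]], ...]
    band_amp: np.ndarray
    noise_sd: float = 1.0
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS

    def __post_init__(self):
        object.__setattr__(
            self, "band_amp", np.asarray(self.band_amp, dtype=np.float64)
        )
        if self.band_amp.shape[1] != len(self.bands):
            raise ValueError("band_amp columns must match the band list")
        for i, j, c, band in self.coupled_pairs:
            if i == j:
                raise ValueError(f"coupled pair ({i}, {j}) must join distinct channels")
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling {c} outside [0, 1]")
            if band not in self.bands:
                raise ValueError(f"carrier band {band} not in the band list")

    @property
    def n_channels(self) -> int:
        return self.band_amp.shape[0]


@dataclass(frozen=True)
class SyntheticDatasetConfig:
    """Cohort-level study conditions.

    ``subject_jitter`` multiplicatively perturbs coupling strengths and band
    amplitudes per subject (never pair identities), so cross-subject
    transfer is possible but imperfect.  All randomness flows from ``seed``.
    """

    class_specs: tuple[SyntheticClassSpec, ...]
    n_subjects: int = 3
    n_sessions: int = 2
    trials_per_class: int = 72
    fs: float = 250.0
    duration: float = 4.0
    subject_jitter: float = 0.1
    phase_diffusion: float = 0.3
    amp_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_class < 1:
            raise ValueError("need at least one trial per class")
        if len(self.class_specs) < 2:
            raise ValueError("need at least two classes")
        n_samples = self.duration * self.fs
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("duration * fs must be integral")
        if all(
            _specs_equal(self.class_specs[0], s) for s in self.class_specs[1:]
        ):
            warnings.warn(
                "all class specs are identical; classes are indistinguishable "
                "by design",
                stacklevel=2,
            )


def _specs_equal(a: SyntheticClassSpec, b: SyntheticClassSpec) -> bool:
    return (
        a.coupled_pairs == b.coupled_pairs
        and np.array_equal(a.band_amp, b.band_amp)
        and a.noise_sd == b.noise_sd
    )


def default_class_specs(
    n_channels: int = 22,
    n_classes: int = 4,
    coupling: float = 0.85,
    noise_sd: float = 1.0,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
) -> tuple[SyntheticClassSpec, ...]:
    """The canonical synthetic cohort conditions.

    Class q gets a dominant rhythm in band ``2q + 1`` (12-16, 20-24, 28-32,
    36-40 Hz for four classes) expressed on its own subset of ~5 channels,
    a shared alpha background on every channel, and three phase-coupled
    pairs chained through that subset in the dominant band.  Classes thus
    differ in both connectivity and spectral profile, the two feature
    families the decoder consumes.
    """
    n_bands = len(bands)
    specs = []
    for q in range(n_classes):
        dominant = (2 * q + 1) % n_bands
        subset = list(range(n_channels))[q::n_classes][:5]
        if len(subset) < 2:
            raise ValueError("too few channels for the default class layout")
        # Modest spectral contrast (~2 dB dominant-band power change on a
        # channel subset) over a shared broadband + alpha background: real
        # rhythm modulations are small against trial-to-trial variability,
        # so class information is carried chiefly by the coupling structure.
        amp = np.full((n_channels, n_bands), 0.5)
        amp[:, 0] += 0.2  # alpha background, all classes
        amp[subset, dominant] = 0.8
        pairs = []
        for a, b in zip(subset[:-1], subset[1:]):
            pairs.append((a, b, coupling, bands[dominant]))
            if len(pairs) == 3:
                break
        specs.append(
            SyntheticClassSpec(
                coupled_pairs=tuple(pairs),
                band_amp=amp,
                noise_sd=noise_sd,
                bands=bands,
            )
        )
    return tuple(specs)


def _phase_walks(
    n_channels: int,
    n_samples: int,
    freq: float,
    fs: float,
    diffusion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(C, T) independent phase random walks around carrier ``freq``."""
    steps = 2 * np.pi * freq / fs + diffusion * rng.standard_normal(
        (n_channels, n_samples)
    )
    phases = np.cumsum(steps, axis=1)
    phases += rng.uniform(0, 2 * np.pi, size=(n_channels, 1))
    return phases


def generate_trial(
    spec: SyntheticClassSpec,
    label: int,
    rng: np.random.Generator,
    fs: float = 250.0,
    duration: float = 4.0,
    phase_diffusion: float = 0.3,
    amp_jitter: float = 0.3,
) -> EpochedTrial:
    """Sample one trial under a class spec (see module docstring).

    ``amp_jitter`` applies mean-one lognormal multiplicative noise to every
    channel x band amplitude per trial, emulating the large trial-to-trial
    band-power variability of real EEG (0 disables it).
    """
    n_samples = int(round(duration * fs))
    c = spec.n_channels
    data = np.zeros((c, n_samples))
    if amp_jitter > 0:
        jitter = np.exp(
            amp_jitter * rng.standard_normal(spec.band_amp.shape)
            - 0.5 * amp_jitter**2
        )
        trial_amp = spec.band_amp * jitter
    else:
        trial_amp = spec.band_amp
    for k, band in enumerate(spec.bands):
        amps = trial_amp[:, k]
        pairs_k = [p for p in spec.coupled_pairs if p[3] == band]
        if not pairs_k and not np.any(amps):
            continue
        freq = 0.5 * (band[0] + band[1])
        phases = _phase_walks(c, n_samples, freq, fs, phase_diffusion, rng)
        for i, j, coupling, _ in pairs_k:
            delta = rng.uniform(0, 2 * np.pi)
            mixture = coupling * np.exp(1j * (phases[i] + delta)) + (
                1 - coupling
            ) * np.exp(1j * phases[j])
            phases[j] = np.angle(mixture)
        data += amps[:, None] * np.cos(phases)
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)
    return EpochedTrial(data=data, label=label, fs=fs)


def generate_epochs(
    class_specs,
    trials_per_class: int,
    rng: np.random.Generator,
    fs: float = 250.0,
    duration: float = 4.0,
    phase_diffusion: float = 0.3,
    amp_jitter: float = 0.3,
    subject_id: str = "S0",
    session_id: str = "0",
) -> EpochSet:
    """One session: ``trials_per_class`` i.i.d. trials per class, classes
    interleaved round-robin (deterministic trial order)."""
    trials = []
    for _ in range(trials_per_class):
        for label, spec in enumerate(class_specs):
            trials.append(
                generate_trial(
                    spec, label, rng, fs=fs, duration=duration,
                    phase_diffusion=phase_diffusion, amp_jitter=amp_jitter,
                )
            )
    return EpochSet(
        trials=trials,
        subject_id=subject_id,
        session_id=session_id,
        class_names=[f"class{q}" for q in range(len(class_specs))],
    )


def _jitter_spec(
    spec: SyntheticClassSpec, jitter: float, rng: np.random.Generator
) -> SyntheticClassSpec:
    if jitter == 0:
        return spec
    pairs = tuple(
        (i, j, float(np.clip(c * (1 + jitter * rng.standard_normal()), 0.0, 1.0)), band)
        for i, j, c, band in spec.coupled_pairs
    )
    amp = spec.band_amp * np.clip(
        1 + jitter * rng.standard_normal(spec.band_amp.shape), 0.1, None
    )
    return SyntheticClassSpec(
        coupled_pairs=pairs, band_amp=amp, noise_sd=spec.noise_sd, bands=spec.bands
    )


def generate_dataset(cfg: SyntheticDatasetConfig):
    """Cohort of subjects x sessions plus the ground-truth specs.

    Returns ``(data, ground_truth)`` where ``data[subject][session]`` is an
    :class:`EpochSet` and ``ground_truth[subject]`` the subject's perturbed
    class specs.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    data: dict[str, dict[str, EpochSet]] = {}
    ground_truth: dict[str, tuple[SyntheticClassSpec, ...]] = {}
    for s in range(cfg.n_subjects):
        subject = f"S{s + 1:02d}"
        subject_specs = tuple(
            _jitter_spec(spec, cfg.subject_jitter, rng) for spec in cfg.class_specs
        )
        ground_truth[subject] = subject_specs
        data[subject] = {
            str(sess): generate_epochs(
                subject_specs,
                cfg.trials_per_class,
                rng,
                fs=cfg.fs,
                duration=cfg.duration,
                phase_diffusion=cfg.phase_diffusion,
                amp_jitter=cfg.amp_jitter,
                subject_id=subject,
                session_id=str(sess),
            )
            for sess in range(cfg.n_sessions)
        }
    return data, ground_truth


def epochs_to_recording(
    epochs: EpochSet,
    pre_s: float = 2.0,
    gap_s: float = 1.0,
    background_sd: float = 0.1,
    seed: int = 0,
) -> EEGRecording:
    """Lay an epoch set out as a continuous recording with cue events.

    Each trial's samples are placed ``pre_s`` seconds after its event marker
    (matching the cue-to-task delay of the standard paradigm), separated by
    ``gap_s`` of low-amplitude background noise, so
    ``extract_epochs(rec, pre_s, pre_s + duration)`` recovers the trials
    bit-for-bit in event order.
    """
    if not epochs.trials:
        raise ValueError("no trials to lay out")
    rng = np.random.default_rng(seed)
    fs = epochs.trials[0].fs
    c, t = epochs.trials[0].data.shape
    pre = int(round(pre_s * fs))
    gap = int(round(gap_s * fs))
    stride = pre + t + gap
    total = stride * len(epochs.trials) + gap
    data = background_sd * rng.standard_normal((c, total))
    events = []
    for k, trial in enumerate(epochs.trials):
        onset = gap + k * stride
        data[:, onset + pre : onset + pre + t] = trial.data
        events.append((onset, trial.label))
    return EEGRecording(
        data=data,
        fs=fs,
        channel_labels=[f"ch{i}" for i in range(c)],
        events=events,
    )
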