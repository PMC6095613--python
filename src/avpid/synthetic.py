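"""Synthetic audiovisual-speech cohorts with planted information structure.

Emulates the data entering the entrainment analysis: per subject, an
auditory amplitude envelope and a lip-area trace that share a
band-limited (3-7 Hz, syllable-rate) common drive; a set of "neural"
nodes coupled to the stimuli with a known kind of information structure
(redundant, unique-auditory, unique-visual, synergistic, or null) at a
100 ms stimulus-to-brain lag; and a behavioral comprehension score
linearly linked across subjects to the redundant node's coupling gain.

The common drive is narrowband Gaussian noise (white noise band-pass
filtered to the configured band), not a sinusoid, so phase
distributions are non-degenerate.  Node noise is likewise band-limited
to the analysis band: the downstream pipeline filters every node into
that band, so only in-band noise constrains how well the stimuli
predict the node — broadband noise alone would make every planted node
look deterministic (hence spuriously synergistic) after filtering.

Seed policy: one master seed; per-subject streams are derived with a
counter-based ``SeedSequence`` split, so subjects are independent and
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_prep import TimeSeries, bandpass_analytic

__all__ = ["SynthConfig", "SubjectDataset", "NODE_KINDS", "gen_stimulus_pair", "gen_neural_node", "gen_cohort"]

NODE_KINDS = ("redundant", "unique_a", "unique_v", "synergistic", "null")


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions: 44 subjects, 250 Hz sampling,
    a 5 +/- 2 Hz analysis band, and a 100 ms stimulus-to-brain lag.
    Each stimulus is a shared narrowband drive (``stim_drive_gain``)
    plus independent broadband noise (``stim_noise_sd``); the defaults
    put the in-band audiovisual correlation near 0.85, high enough that
    a node driven by the common component is dominantly redundant
    rather than synergistic.  ``noise_sd`` scales the in-band noise of
    neural nodes.
    """

    n_subjects: int = 44
    duration: float = 120.0
    fs: float = 250.0
    band_center: float = 5.0
    band_halfwidth: float = 2.0
    neural_lag_ms: float = 100.0
    gain_redundant: float = 1.0
    gain_unique_a: float = 1.0
    gain_unique_v: float = 1.0
    gain_synergistic: float = 1.0
    gain_shape: float = 16.0
    noise_sd: float = 0.35
    stim_drive_gain: float = 1.0
    stim_noise_sd: float = 1.5
    visual_lag_ms: float = 0.0
    behavior_intercept: float = 0.6
    behavior_slope: float = 0.2
    behavior_noise_sd: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9 or round(n) < 2000:
            raise ValueError("duration * fs must be an integer sample count >= 2000")
        if self.band_center - self.band_halfwidth <= 0:
            raise ValueError("band must lie strictly above 0 Hz")
        for name in ("gain_redundant", "gain_unique_a", "gain_unique_v", "gain_synergistic",
                     "noise_sd", "behavior_noise_sd", "stim_drive_gain", "stim_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def gain_for(self, kind: str) -> float:
        if kind == "null":
            return 0.0
        return getattr(self, f"gain_{kind}")


@dataclass
class SubjectDataset:
    """One subject's stimuli, neural nodes and behavioral score."""

    audio_env: TimeSeries
    lip_area: TimeSeries
    nodes: dict[str, TimeSeries]
    node_kinds: dict[str, str]
    node_gains: dict[str, float]
    comprehension: float
    congruent: bool = True
    subject_id: int = 0
    seed_entropy: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {self.audio_env.n, self.lip_area.n} | {ts.n for ts in self.nodes.values()}
        rates = {self.audio_env.fs, self.lip_area.fs} | {ts.fs for ts in self.nodes.values()}
        if len(lengths) != 1 or len(rates) != 1:
            raise ValueError("all series in a subject must share length and sampling rate")
        bad = set(self.node_kinds.values()) - set(NODE_KINDS)
        if bad:
            raise ValueError(f"unknown node kinds: {sorted(bad)}")
        if not 0.0 <= self.comprehension <= 1.0:
            raise ValueError("comprehension must lie in [0, 1]")


def _band_noise(n: int, fs: float, center: float, halfwidth: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the analysis band."""
    sos = sps.butter(4, [center - halfwidth, center + halfwidth], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _positive(x: np.ndarray) -> np.ndarray:
    """Affine offset making a series strictly positive (envelope/area are magnitudes)."""
    return x - x.min() + 0.05 * x.std()


def gen_stimulus_pair(
    config: SynthConfig, matched: bool = True, rng: np.random.Generator | int | None = None
) -> tuple[TimeSeries, TimeSeries]:
    """An auditory-envelope / lip-area pair.

    Matched pairs share a band-limited common drive riding on
    independent broadband noise, so their coherence — and hence the
    phase-MI profile — peaks inside the configured band and falls to
    chance outside it; nonmatched pairs get independent drives with the
    same spectral content, so their phase MI is flat at null level.
    """
    audio, lip, _ = _gen_stimulus(config, matched, rng)
    return audio, lip


def _gen_stimulus(
    config: SynthConfig, matched: bool, rng: np.random.Generator | int | None
) -> tuple[TimeSeries, TimeSeries, np.ndarray]:
    """Stimulus pair plus the latent band-limited common drive."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n, fs, c, hw = config.n_samples, config.fs, config.band_center, config.band_halfwidth
    g = config.stim_drive_gain

    drive = _band_noise(n, fs, c, hw, rng)
    if matched:
        shift = int(round(config.visual_lag_ms * fs / 1000.0))
        a_band = g * drive
        v_band = g * (np.roll(drive, -shift) if shift else drive)
    else:
        a_band = g * _band_noise(n, fs, c, hw, rng)
        v_band = g * _band_noise(n, fs, c, hw, rng)

    audio = _positive(a_band + config.stim_noise_sd * rng.standard_normal(n))
    lip = _positive(v_band + config.stim_noise_sd * rng.standard_normal(n))
    return TimeSeries(audio, fs, "audio_env"), TimeSeries(lip, fs, "lip_area"), drive


def _band_z(ts: TimeSeries, center: float, halfwidth: float) -> np.ndarray:
    """Band-limited, mean-centred, unit-variance projection of a series."""
    x = np.real(bandpass_analytic(ts, center, halfwidth).values)
    return x / x.std()


def gen_neural_node(
    audio_env: TimeSeries,
    lip_area: TimeSeries,
    kind: str,
    gain: float,
    noise_sd: float,
    lag_ms: float = 100.0,
    rng: np.random.Generator | int | None = None,
    band_center: float = 5.0,
    band_halfwidth: float = 2.0,
    shared_drive: np.ndarray | None = None,
) -> TimeSeries:
    """A neural node with a planted coupling of the given kind.

    The drive is built from the band-limited stimuli: the shared
    syllable-rate component for a redundant node (the latent common
    drive when available, otherwise the normalized sum of the two
    band-limited signals — a region encoding the shared source rather
    than either measurement), one modality alone for a unique node,
    their normalized difference for a synergistic node (each modality
    alone is weakly informative about the difference, but jointly they
    determine it — the classic synergistic configuration), and zero for
    a null node.  The drive is delayed by ``lag_ms`` so the node LAGS
    the stimuli, then mixed with in-band noise of standard deviation
    ``noise_sd``.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if kind not in NODE_KINDS:
        raise ValueError(f"unknown node kind {kind!r}; expected one of {NODE_KINDS}")
    fs, n = audio_env.fs, audio_env.n
    za = _band_z(audio_env, band_center, band_halfwidth)
    zv = _band_z(lip_area, band_center, band_halfwidth)

    if kind == "redundant":
        drive = shared_drive.copy() if shared_drive is not None else za + zv
    elif kind == "unique_a":
        drive = za
    elif kind == "unique_v":
        drive = zv
    elif kind == "synergistic":
        drive = za - zv
    else:  # null
        drive = np.zeros(n)

    if kind != "null":
        drive = drive / drive.std()
        k = int(round(lag_ms * fs / 1000.0))
        drive = np.roll(drive, k)  # node[t] reflects the stimulus at t - lag

    noise = noise_sd * _band_noise(n, fs, band_center, band_halfwidth, rng)
    broadband = 0.5 * noise_sd * rng.standard_normal(n)
    return TimeSeries(gain * drive + noise + broadband, fs, label=kind)


def gen_cohort(config: SynthConfig, matched: bool = True) -> list[SubjectDataset]:
    """A cohort of subjects with per-subject gains and behavior scores.

    Per-subject coupling gains are drawn from a Gamma(k, g/k)
    distribution with shape k = ``gain_shape`` (mean g = the configured
    gain, CV = 1/sqrt(k), strictly positive); the comprehension score
    is an affine function of the redundant node's gain plus Gaussian
    noise, clipped to [0, 1].  The whole cohort is a pure function of
    ``config.rng_seed``.
    """
    if config.n_subjects < 3:
        raise ValueError("need at least 3 subjects for across-subject correlation")
    master = np.random.SeedSequence(config.rng_seed)
    subjects = []
    for sid, ss in enumerate(master.spawn(config.n_subjects)):
        rng = np.random.default_rng(ss)
        audio, lip, drive = _gen_stimulus(config, matched=matched, rng=rng)
        nodes: dict[str, TimeSeries] = {}
        kinds: dict[str, str] = {}
        gains: dict[str, float] = {}
        for kind in NODE_KINDS:
            g_mean = config.gain_for(kind)
            g = float(rng.gamma(config.gain_shape, g_mean / config.gain_shape)) if g_mean > 0 else 0.0
            nodes[kind] = gen_neural_node(
                audio, lip, kind, g, config.noise_sd, config.neural_lag_ms, rng,
                config.band_center, config.band_halfwidth,
                shared_drive=drive if (matched and kind == "redundant") else None,
            )
            kinds[kind] = kind
            gains[kind] = g
        score = config.behavior_intercept + config.behavior_slope * gains["redundant"]
        score += config.behavior_noise_sd * rng.standard_normal()
        subjects.append(
            SubjectDataset(
                audio_env=audio,
                lip_area=lip,
                nodes=nodes,
                node_kinds=kinds,
                node_gains=gains,
                comprehension=float(np.clip(score, 0.0, 1.0)),
                congruent=matched,
                subject_id=sid,
                seed_entropy=config.rng_seed,
            )
        )
    return subjects
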