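"""Synthetic study generator.

Emulates a two-condition neuroergonomic experiment in which operators solve a
task once with an unexplained AI advisory ("BB", black box) and once with a
visual-explanation advisory ("HM", heat map), while 8-channel prefrontal /
parietal EEG is recorded.  The generator produces, per subject:

* one task recording per condition -- pink-noise background plus
  amplitude-modulated oscillation bursts: frontal theta at (IAF - 4) Hz
  (workload carrier), parietal alpha at the subject's individual alpha
  frequency (IAF), and frontal alpha whose right-hemisphere amplitude may
  exceed the left (approach-withdrawal carrier) -- with biphasic blink
  transients on the prefrontal row and rare rectangular high-amplitude
  spikes;
* one eyes-closed rest segment with a boosted parietal alpha peak, from
  which the IAF can be recovered;
* 5-point Likert questionnaire responses driven by shared per-construct
  latent variables, so items of one construct correlate positively.

Condition effects are multiplicative gains on oscillation amplitudes and
additive shifts on the questionnaire latents; with all gains at 1 and shifts
at 0 the two conditions are exchangeable, which is what the type-I
calibration tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .montage import ChannelMontage, default_montage
from .recording import Recording
from .questionnaire import CompositeSpec, LikertTable, default_constructs

CONDITIONS = ("BB", "HM")
GROUPS = ("expert", "student")

#: amplitude scale of blink transients across the prefrontal row, relative
#: to AFz; parietal sites are unaffected (ocular artifacts are frontal).
BLINK_TOPOGRAPHY = {"AFz": 1.0, "AF3": 0.8, "AF4": 0.8, "AF7": 0.6, "AF8": 0.6}
BLINK_PEAK_UV = 120.0
BLINK_DURATION_S = 0.4

#: fraction of the parietal alpha amplitude used as the *frontal* alpha
#: carrier (frontal alpha is present but weaker than the posterior rhythm)
FRONTAL_ALPHA_FRACTION = 0.6
#: rest segments boost parietal alpha by this factor (eyes closed)
REST_ALPHA_BOOST = 2.0
#: sd of the per-subject random intercept on the questionnaire latent scale;
#: sized so items of one construct correlate around r ~ 0.7 in population
SUBJECT_INTERCEPT_SD = 0.6


@dataclass(frozen=True)
class SubjectProfile:
    """Stable per-subject parameters of the generative model."""

    subject_id: str
    group: str                   # "expert" | "student"
    true_iaf: float              # Hz, in [8, 12]
    base_theta_amp: float        # uV, frontal theta burst amplitude
    base_alpha_amp: float        # uV, parietal alpha burst amplitude
    asymmetry_offset: float      # uV, right-minus-left frontal alpha amplitude
    blink_rate: float            # events / minute
    noise_rms: float             # uV, pink-noise floor

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 8.0 <= self.true_iaf <= 12.0:
            raise ValueError("true_iaf must lie in [8, 12] Hz")
        for name in ("base_theta_amp", "base_alpha_amp", "blink_rate",
                     "noise_rms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EffectSpec:
    """Programmed condition effects.

    ``theta_gain`` / ``alpha_gain`` multiply the frontal-theta and
    parietal-alpha burst amplitudes per condition.  ``asym_shift`` adds to
    the right-minus-left frontal alpha amplitude; keys may be a condition
    name or a ``(group, condition)`` pair (the default shift applies to
    students under the explained condition only).  ``likert_shift`` moves the
    questionnaire latents per ``(construct, group, condition)``.
    """

    theta_gain: dict = field(default_factory=lambda: {"BB": 1.3, "HM": 1.0})
    alpha_gain: dict = field(default_factory=lambda: {"BB": 0.8, "HM": 1.0})
    asym_shift: dict = field(
        default_factory=lambda: {("student", "HM"): 0.5})
    likert_shift: dict = field(default_factory=lambda: {
        # explanation raises willingness to use in both groups; students
        # score higher overall and report a larger perceived impact on
        # work performance than experts
        ("willingness_to_use", "expert", "BB"): 0.0,
        ("willingness_to_use", "expert", "HM"): 0.5,
        ("willingness_to_use", "student", "BB"): 0.6,
        ("willingness_to_use", "student", "HM"): 1.1,
        ("work_performance", "expert", "BB"): -0.45,
        ("work_performance", "expert", "HM"): -0.45,
        ("work_performance", "student", "BB"): 0.45,
        ("work_performance", "student", "HM"): 0.45,
    })
    item_loading: dict = field(default_factory=dict)   # item_id -> (0, 1]
    default_loading: float = 0.9
    item_noise_sd: float = 0.35  # latent-scale units
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta_gain", "alpha_gain"):
            for cond, g in getattr(self, name).items():
                if g <= 0:
                    raise ValueError(f"{name}[{cond!r}] must be > 0")
        for item, w in self.item_loading.items():
            if not 0 < w <= 1:
                raise ValueError(f"item_loading[{item!r}] must be in (0, 1]")
        if not 0 < self.default_loading <= 1:
            raise ValueError("default_loading must be in (0, 1]")
        if self.item_noise_sd < 0:
            raise ValueError("item_noise_sd must be non-negative")

    def loading(self, item_id: str) -> float:
        return self.item_loading.get(item_id, self.default_loading)

    def asym(self, group: str, condition: str) -> float:
        if (group, condition) in self.asym_shift:
            return self.asym_shift[(group, condition)]
        return self.asym_shift.get(condition, 0.0)

    def shift(self, construct: str, group: str, condition: str) -> float:
        return self.likert_shift.get((construct, group, condition), 0.0)


def null_effects(seed: int = 0) -> EffectSpec:
    """An EffectSpec with every gain 1 and every shift 0 (exchangeable null)."""
    return EffectSpec(theta_gain={c: 1.0 for c in CONDITIONS},
                      alpha_gain={c: 1.0 for c in CONDITIONS},
                      asym_shift={}, likert_shift={}, seed=seed)


@dataclass(frozen=True)
class StudyConfig:
    """Top-level knobs of a simulated study (defaults mirror the modelled
    experiment: 11 experts, 10 students, two conditions per subject)."""

    n_expert: int = 11
    n_student: int = 10
    fs: float = 256.0            # Hz
    task_duration: float = 300.0  # s per condition
    rest_duration: float = 60.0   # s, eyes closed
    spike_rate: float = 1.0       # high-amplitude artifacts / minute
    effects: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0


@dataclass
class StudyDataset:
    """Everything the downstream pipeline consumes, plus ground truth."""

    config: StudyConfig
    profiles: list[SubjectProfile]
    recordings: dict          # (subject_id, condition) -> Recording
    rest_segments: dict       # subject_id -> Recording
    questionnaire: LikertTable
    ground_truth: pd.DataFrame

    def __post_init__(self) -> None:
        for p in self.profiles:
            if p.subject_id not in self.rest_segments:
                raise ValueError(f"missing rest segment for {p.subject_id}")
            for cond in CONDITIONS:
                if (p.subject_id, cond) not in self.recordings:
                    raise ValueError(
                        f"missing {cond} recording for {p.subject_id}")


# ---------------------------------------------------------------------------
# profiles


def make_profiles(n_expert: int, n_student: int, seed: int
                  ) -> list[SubjectProfile]:
    """Draw subject profiles: IAF from a truncated normal (mean 10 Hz, sd 1,
    bounds [8, 12]); oscillation amplitudes, blink rate and noise floor from
    ranges typical of scalp EEG."""
    if n_expert < 0 or n_student < 0:
        raise ValueError("subject counts must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_expert + n_student
    iafs = truncnorm.rvs(-2.0, 2.0, loc=10.0, scale=1.0, size=n,
                         random_state=rng)
    profiles = []
    for i in range(n):
        group = "expert" if i < n_expert else "student"
        idx = i + 1 if group == "expert" else i - n_expert + 1
        profiles.append(SubjectProfile(
            subject_id=f"{'E' if group == 'expert' else 'S'}{idx:02d}",
            group=group,
            true_iaf=float(iafs[i]),
            base_theta_amp=float(rng.uniform(5.0, 7.0)),
            base_alpha_amp=float(rng.uniform(6.0, 9.0)),
            asymmetry_offset=float(rng.normal(0.0, 0.2)),
            blink_rate=float(rng.uniform(8.0, 20.0)),
            noise_rms=float(rng.uniform(5.0, 8.0)),
        ))
    return profiles


# ---------------------------------------------------------------------------
# signal building blocks


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, rms: float) -> np.ndarray:
    """Band-limited pink noise: white noise spectrally shaped to a 1/sqrt(f)
    amplitude profile (power ~ 1/f) between 1 and 45 Hz, scaled to ``rms``."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    band = (freqs >= 1.0) & (freqs <= 45.0)
    shape[band] = 1.0 / np.sqrt(freqs[band])
    x = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    if rms > 0:
        std = x.std(axis=1, keepdims=True)
        std[std == 0] = 1.0
        x *= rms / std
    else:
        x[:] = 0.0
    return x


def _burst_train(rng: np.random.Generator, n_samples: int, fs: float,
                 freq: float) -> np.ndarray:
    """Unit-amplitude oscillation as a sequence of Hann-windowed sinusoid
    bursts (1-2 s each, independent phases).  The envelope modulation widens
    the spectral peak so the generated rhythm is not a degenerate line."""
    out = np.zeros(n_samples)
    pos = 0
    while pos < n_samples:
        m = int(rng.uniform(1.0, 2.0) * fs)
        m = min(m, n_samples - pos)
        if m < 8:
            break
        t = np.arange(m) / fs
        phase = rng.uniform(0, 2 * np.pi)
        out[pos:pos + m] = np.sin(2 * np.pi * freq * t + phase) \
            * np.hanning(m)
        pos += m
    return out


def _blink_waveform(fs: float) -> np.ndarray:
    """Biphasic 400 ms ocular transient: a dominant positive lobe (250 ms)
    followed by a smaller negative rebound (150 ms), unit peak amplitude."""
    n_pos = int(round(0.25 * fs))
    n_neg = int(round(BLINK_DURATION_S * fs)) - n_pos
    pos = np.sin(np.pi * np.arange(n_pos) / n_pos)
    neg = -0.3 * np.sin(np.pi * np.arange(n_neg) / max(n_neg, 1))
    return np.concatenate([pos, neg])


def _add_events(samples: np.ndarray, fs: float, times: np.ndarray,
                waveform: np.ndarray, channel_gains: np.ndarray) -> None:
    n = samples.shape[1]
    for t0 in times:
        start = int(round(t0 * fs))
        stop = min(start + waveform.size, n)
        if start >= n:
            continue
        seg = waveform[:stop - start]
        samples[:, start:stop] += channel_gains[:, None] * seg[None, :]


def _synthesize(profile: SubjectProfile, *, theta_amp: float,
                parietal_alpha_amp: float, frontal_alpha_left: float,
                frontal_alpha_right: float, duration: float, fs: float,
                blink_rate: float, spike_rate: float, seed: int,
                montage: ChannelMontage, meta: dict) -> Recording:
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    samples = _pink_noise(rng, montage.n_channels, n, fs, profile.noise_rms)

    theta = _burst_train(rng, n, fs, profile.true_iaf - 4.0)
    for ch in montage.frontal:
        samples[montage.index(ch)] += theta_amp * theta

    alpha_par = _burst_train(rng, n, fs, profile.true_iaf)
    for ch in montage.parietal:
        samples[montage.index(ch)] += parietal_alpha_amp * alpha_par

    alpha_fro = _burst_train(rng, n, fs, profile.true_iaf)
    a_left = max(frontal_alpha_left, 0.0)
    a_right = max(frontal_alpha_right, 0.0)
    for ch in montage.frontal_left:
        samples[montage.index(ch)] += a_left * alpha_fro
    for ch in montage.frontal_right:
        samples[montage.index(ch)] += a_right * alpha_fro
    if "AFz" in montage.frontal:
        samples[montage.index("AFz")] += 0.5 * (a_left + a_right) * alpha_fro

    # blink transients, Poisson arrivals on the prefrontal row
    n_blinks = rng.poisson(blink_rate * duration / 60.0)
    blink_times = np.sort(rng.uniform(0.5, max(duration - 0.5, 0.5),
                                      size=n_blinks))
    gains = np.array([BLINK_TOPOGRAPHY.get(ch, 0.0)
                      for ch in montage.ordered_labels]) * BLINK_PEAK_UV
    _add_events(samples, fs, blink_times, _blink_waveform(fs), gains)

    # rare rectangular high-amplitude spikes on random single channels
    n_spikes = rng.poisson(spike_rate * duration / 60.0)
    spike_times = np.sort(rng.uniform(0.0, max(duration - 0.1, 0.1),
                                      size=n_spikes))
    spike_len = max(int(round(0.05 * fs)), 1)
    for t0 in spike_times:
        ch = rng.integers(montage.n_channels)
        amp = rng.uniform(110.0, 150.0) * rng.choice([-1.0, 1.0])
        start = int(round(t0 * fs))
        samples[ch, start:start + spike_len] += amp

    meta = dict(meta)
    meta.update(subject_id=profile.subject_id, group=profile.group,
                blink_times=blink_times, spike_times=spike_times)
    return Recording(samples, fs, montage, meta)


# ---------------------------------------------------------------------------
# public synthesis operations


def synthesize_recording(profile: SubjectProfile, condition: str,
                         effects: EffectSpec, duration: float = 300.0,
                         fs: float = 256.0, seed: int = 0,
                         spike_rate: float = 1.0,
                         montage: ChannelMontage | None = None) -> Recording:
    """One task recording for ``profile`` under ``condition``."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"expected one of {CONDITIONS}")
    if duration < 10.0:
        raise ValueError("task duration must be at least 10 s")
    if fs < 128.0:
        raise ValueError("sampling rate must be at least 128 Hz")
    montage = montage or default_montage()
    theta_amp = profile.base_theta_amp * effects.theta_gain.get(condition, 1.0)
    alpha_amp = profile.base_alpha_amp * effects.alpha_gain.get(condition, 1.0)
    a_left = FRONTAL_ALPHA_FRACTION * profile.base_alpha_amp
    a_right = a_left + profile.asymmetry_offset \
        + effects.asym(profile.group, condition)
    return _synthesize(
        profile, theta_amp=theta_amp, parietal_alpha_amp=alpha_amp,
        frontal_alpha_left=a_left, frontal_alpha_right=a_right,
        duration=duration, fs=fs, blink_rate=profile.blink_rate,
        spike_rate=spike_rate, seed=seed, montage=montage,
        meta={"condition": condition, "kind": "task"})


def synthesize_rest(profile: SubjectProfile, duration: float = 60.0,
                    fs: float = 256.0, seed: int = 0,
                    spike_rate: float = 1.0,
                    montage: ChannelMontage | None = None) -> Recording:
    """Eyes-closed rest segment: parietal alpha boosted, no task modulation,
    so the parietal spectrum shows a clear peak at the subject's IAF."""
    if duration < 30.0:
        raise ValueError("rest duration must be at least 30 s")
    if fs < 128.0:
        raise ValueError("sampling rate must be at least 128 Hz")
    montage = montage or default_montage()
    a_left = FRONTAL_ALPHA_FRACTION * profile.base_alpha_amp
    return _synthesize(
        profile, theta_amp=profile.base_theta_amp,
        parietal_alpha_amp=REST_ALPHA_BOOST * profile.base_alpha_amp,
        frontal_alpha_left=a_left,
        frontal_alpha_right=a_left + profile.asymmetry_offset,
        duration=duration, fs=fs, blink_rate=profile.blink_rate,
        spike_rate=spike_rate, seed=seed, montage=montage,
        meta={"condition": None, "kind": "rest"})


def synthesize_questionnaire(profiles: list[SubjectProfile],
                             effects: EffectSpec,
                             items: list[CompositeSpec] | None = None,
                             seed: int = 0) -> LikertTable:
    """Likert responses from shared per-construct latents.

    Per subject x condition, each construct's latent is
    ``3.0 + likert_shift(construct, group, condition) + subject intercept``;
    each item response is ``loading * latent + noise`` rounded and clipped
    to the 1..5 scale.  Items of one construct therefore correlate
    positively in expectation.
    """
    items = items if items is not None else default_constructs()
    seen: dict[str, str] = {}
    for spec in items:
        for item in spec.items:
            if item in seen:
                raise ValueError(
                    f"item {item!r} assigned to both {seen[item]!r} "
                    f"and {spec.name!r}")
            seen[item] = spec.name
    rng = np.random.default_rng(seed)
    rows = []
    for profile in profiles:
        intercept = rng.normal(0.0, SUBJECT_INTERCEPT_SD)
        for condition in CONDITIONS:
            for spec in items:
                latent = 3.0 + effects.shift(spec.name, profile.group,
                                             condition) + intercept
                for item in spec.items:
                    raw = effects.loading(item) * latent \
                        + rng.normal(0.0, effects.item_noise_sd)
                    resp = int(np.clip(np.round(raw), 1, 5))
                    rows.append((profile.subject_id, profile.group,
                                 condition, item, resp))
    frame = pd.DataFrame(rows, columns=["subject_id", "group", "condition",
                                        "item_id", "response"])
    return LikertTable(frame)


def generate_study(config: StudyConfig | None = None) -> StudyDataset:
    """Assemble a full study: profiles, task recordings, rest segments,
    questionnaire and ground truth, reproducible from ``config.seed``."""
    config = config or StudyConfig()
    master = np.random.default_rng(config.seed)

    def child_seed() -> int:
        return int(master.integers(0, 2**31 - 1))

    profiles = make_profiles(config.n_expert, config.n_student, child_seed())
    effects = config.effects
    recordings, rests = {}, {}
    for profile in profiles:
        for condition in CONDITIONS:
            recordings[(profile.subject_id, condition)] = synthesize_recording(
                profile, condition, effects, config.task_duration, config.fs,
                seed=child_seed(), spike_rate=config.spike_rate)
        rests[profile.subject_id] = synthesize_rest(
            profile, config.rest_duration, config.fs, seed=child_seed(),
            spike_rate=config.spike_rate)
    questionnaire = synthesize_questionnaire(profiles, effects,
                                             seed=child_seed())

    bb_hm_power_ratio = (
        (effects.theta_gain.get("BB", 1.0) / effects.theta_gain.get("HM", 1.0))
        ** 2
        / (effects.alpha_gain.get("BB", 1.0)
           / effects.alpha_gain.get("HM", 1.0)) ** 2)
    truth_rows = []
    for profile in profiles:
        row = {
            "subject_id": profile.subject_id,
            "group": profile.group,
            "true_iaf": profile.true_iaf,
            "wl_bb_over_hm_expected": bb_hm_power_ratio,
            "wl_bb_gt_hm_expected": bb_hm_power_ratio > 1.0,
        }
        for condition in CONDITIONS:
            row[f"asym_total_{condition}"] = profile.asymmetry_offset \
                + effects.asym(profile.group, condition)
        truth_rows.append(row)
    return StudyDataset(config, profiles, recordings, rests, questionnaire,
                        pd.DataFrame(truth_rows))
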