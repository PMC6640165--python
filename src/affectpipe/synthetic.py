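"""Synthetic study-cohort generator.

Emulates a two-arm randomized writing-intervention study (positive /
"prosocial" vs. negative / "antisocial" recall prompts) with pre/post
self-report panels, cognitive task response logs (recognition memory,
situation construal, word find), raw scalp EEG with a photodiode sync
channel, and wristband autonomic streams (RR intervals, tonic/phasic skin
conductance, skin temperature).

Every generator is deterministic given :class:`SimConfig.seed` and returns
ground-truth parameters alongside the raw data so downstream stages can be
validated without access to any real recordings.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SELF_REPORT_EFFECTS",
    "NEGATIVE_KEYED",
    "SELF_REPORT_MEASURES",
    "SIGNIFICANT_SELF_REPORT",
    "COGNITIVE_MEASURES",
    "ConfigError",
    "SimConfig",
    "EEGParams",
    "ANSParams",
    "CohortTable",
    "EventTimeline",
    "WristbandStreams",
    "default_measure_correlation",
    "generate_cohort",
    "simulate_cognitive_logs",
    "build_timeline",
    "simulate_eeg",
    "simulate_wristband",
    "write_dataset",
    "read_cohort",
    "read_eeg_csv",
    "write_eeg_csv",
]

# ---------------------------------------------------------------------------
# Calibration defaults
# ---------------------------------------------------------------------------

#: Default per-arm standardized pre->post mean changes for the 14 self-report
#: measures: measure -> (negative-arm change, positive-arm change), in SD
#: units of the (unit-variance) pre-intervention score.
SELF_REPORT_EFFECTS: dict[str, tuple[float, float]] = {
    "Autonomy": (-0.016, 0.018),
    "Competence": (-0.033, 0.019),
    "Connectedness": (-0.024, 0.021),
    "Elevation": (-0.022, 0.166),
    "Gratitude": (-0.162, 0.037),
    "Meaning in Life: Presence": (-0.025, 0.003),
    "Meaning in Life: Search": (-0.027, 0.001),
    "Negative Affect": (0.068, -0.085),
    "Negative Social Emotions": (0.240, -0.033),
    "Optimism": (-0.023, 0.018),
    "Positive Affect": (-0.179, 0.081),
    "Self Esteem: Appearance": (0.011, 0.056),
    "Self Esteem: Performance": (-0.025, 0.042),
    "Self Esteem: Social": (-0.001, 0.062),
}

SELF_REPORT_MEASURES: tuple[str, ...] = tuple(SELF_REPORT_EFFECTS)

#: Measures keyed in the negative direction (higher = worse affect).
NEGATIVE_KEYED = frozenset({"Negative Affect", "Negative Social Emotions"})

#: Measures whose between-arm change difference survives familywise
#: correction under the default calibration, with the sign of the
#: positive-minus-negative arm contrast.
SIGNIFICANT_SELF_REPORT: dict[str, int] = {
    "Elevation": +1,
    "Gratitude": +1,
    "Negative Affect": -1,
    "Negative Social Emotions": -1,
    "Positive Affect": +1,
}

VALENCES = ("pos", "neg", "neu")

#: The 18 cognitive outcome measures (6 recognition, 6 construal, 6 word
#: find). Construal image valences are pos/neg/ambiguous; keys follow the
#: per-task scorer output names.
COGNITIVE_MEASURES: tuple[str, ...] = tuple(
    [f"{v.capitalize()} d-prime" for v in VALENCES]
    + [f"{v.capitalize()} c" for v in VALENCES]
    + [f"Response Normalized {v}" for v in ("Pos", "Neg", "Amb")]
    + [f"Response Time {v}" for v in ("Pos", "Neg", "Amb")]
    + [f"Order {v.capitalize()}" for v in VALENCES]
    + [f"Find Time {v.capitalize()}" for v in VALENCES]
)


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class EEGParams:
    """Raw-EEG generator settings.

    alpha_uv is the occipital 10 Hz alpha amplitude; the blink waveform is a
    100 uV, 400 ms raised cosine on frontal channels and the injected
    artifact a 600 uV, 1 s band-limited burst, i.e. unambiguously below /
    above the 400 uV rejection threshold.
    """

    sampling_rate: float = 128.0
    montage: tuple[str, ...] = (
        "F7", "F8", "Fz", "C3", "Cz", "C4",
        "P3", "P4", "P7", "P8", "Pz", "Oz",
    )
    alpha_uv: float = 10.0
    noise_uv: float = 5.0
    noise_exponent: float = 1.0
    blink_rate_hz: float = 0.2
    artifact_rate_hz: float = 0.01
    blink_uv: float = 100.0
    blink_duration_s: float = 0.4
    artifact_uv: float = 600.0
    artifact_duration_s: float = 1.0
    sync_uv: float = 200.0


@dataclass
class ANSParams:
    """Wristband stream generator settings (RR in ms, conductance in uS)."""

    rr_baseline_ms: float = 800.0
    lf_depth_ms: float = 25.0      # 0.1 Hz RR modulation amplitude
    hf_depth_ms: float = 25.0      # 0.25 Hz RR modulation amplitude
    rr_noise_ms: float = 5.0
    scr_rate_hz: float = 0.05
    scr_amp_us: float = 0.3
    tonic_baseline_us: float = 2.0
    temperature_baseline_c: float = 33.0
    gsr_rate_hz: float = 20.0
    temp_rate_hz: float = 4.0
    rr_interp_rate_hz: float = 4.0


@dataclass
class SimConfig:
    """Full synthetic-study configuration.

    ``self_report_effects`` maps measure name to the (negative-arm,
    positive-arm) standardized pre->post mean change; the default is the
    study calibration in :data:`SELF_REPORT_EFFECTS`. ``cognitive_effects``
    has the same shape over the 18 cognitive outcomes and defaults to no
    effect in either arm. ``physio_effect`` optionally shifts a physiological
    feature (currently ``"alpha_rms"``, ``"hf_hrv"``, ``"lf_hrv"``) in the
    positive arm's post session, in units of its between-subject SD.
    """

    n_participants: int = 245
    condition_ratio: float = 0.5
    seed: int = 0
    self_report_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SELF_REPORT_EFFECTS)
    )
    cognitive_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    measure_correlation: np.ndarray | None = None
    test_retest: float = 0.8
    physio_effect: dict[str, float] = field(default_factory=dict)
    eeg: EEGParams = field(default_factory=EEGParams)
    ans: ANSParams = field(default_factory=ANSParams)
    # Recognition generator: fixed per-valence (hit, false-alarm)
    # probabilities; None selects the latent signal-detection model.
    recognition_probs: dict[str, tuple[float, float]] | None = None
    block_duration_s: float = 600.0
    # events per task block on the physiological timeline:
    # (memory words, construal items, questionnaire items)
    timeline_sizes: tuple[int, int, int] = (48, 60, 28)

    def validate(self) -> None:
        if self.n_participants < 4:
            raise ConfigError("n_participants must be >= 4")
        if not 0.0 < self.condition_ratio < 1.0:
            raise ConfigError("condition_ratio must lie strictly in (0, 1)")
        if self.eeg.sampling_rate <= 0 or self.ans.gsr_rate_hz <= 0:
            raise ConfigError("sampling rates must be positive")
        if not 0.0 < self.test_retest <= 1.0:
            raise ConfigError("test_retest must lie in (0, 1]")
        R = self.correlation_matrix()
        if not np.allclose(np.diag(R), 1.0):
            raise ConfigError("measure_correlation must have unit diagonal")
        if not np.allclose(R, R.T):
            raise ConfigError("measure_correlation must be symmetric")
        eigmin = np.linalg.eigvalsh(R).min()
        if eigmin < -1e-10:
            raise ConfigError(
                "measure_correlation is not positive semi-definite "
                f"(smallest eigenvalue {eigmin:.3g})"
            )

    @property
    def measures(self) -> list[str]:
        return list(self.self_report_effects)

    def correlation_matrix(self) -> np.ndarray:
        if self.measure_correlation is not None:
            return np.asarray(self.measure_correlation, dtype=float)
        return default_measure_correlation(self.measures)


def default_measure_correlation(measures: Sequence[str], c: float = 0.3) -> np.ndarray:
    """Exchangeable correlation aligned with measure keying.

    ``R = (1-c) I + c s s^T`` where ``s`` is +1 for positively keyed
    measures and -1 for negative-affect measures: every same-keyed pair
    correlates at ``c`` and opposite-keyed pairs at ``-c``. Positive
    semi-definite for any 0 <= c < 1 by construction.
    """
    s = np.array([-1.0 if m in NEGATIVE_KEYED else 1.0 for m in measures])
    return (1.0 - c) * np.eye(len(measures)) + c * np.outer(s, s)


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    """Independent child stream for one generator invocation."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _stable_key(participant: int | str) -> int:
    """Process-independent integer key for a participant identifier."""
    return zlib.crc32(str(participant).encode())


# ---------------------------------------------------------------------------
# Cohort (self-report panels)
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Per-participant condition assignment plus pre/post measure panels.

    ``condition`` is dummy coded with positive arm = 1. ``pre`` and ``post``
    are participant x measure frames sharing index and columns.
    """

    condition: pd.Series
    pre: pd.DataFrame
    post: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.pre.columns) != list(self.post.columns):
            raise ValueError("pre and post panels must share measure columns")
        if not set(self.condition.unique()) <= {0, 1}:
            raise ValueError("condition must be coded 0/1")

    @property
    def measures(self) -> list[str]:
        return list(self.pre.columns)

    @property
    def participants(self) -> pd.Index:
        return self.pre.index

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"condition": self.condition})
        for m in self.measures:
            out[f"pre::{m}"] = self.pre[m]
            out[f"post::{m}"] = self.post[m]
        out.index.name = "participant_id"
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortTable":
        measures = [c[len("pre::"):] for c in frame.columns if c.startswith("pre::")]
        pre = frame[[f"pre::{m}" for m in measures]].set_axis(measures, axis=1)
        post = frame[[f"post::{m}" for m in measures]].set_axis(measures, axis=1)
        return cls(condition=frame["condition"].astype(int), pre=pre, post=post)


def generate_cohort(config: SimConfig) -> CohortTable:
    """Draw a cohort with the configured per-arm mean changes.

    Pre scores are correlated multivariate standard normal. Post scores are
    ``r * pre + delta_arm + sqrt(1 - r^2) * e`` with ``e`` drawn from the
    same correlation structure, so both sessions are unit variance, the
    pre/post correlation equals the test-retest reliability ``r``, and the
    population standardized mean change per arm equals the configured delta.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_participants
    measures = config.measures
    R = config.correlation_matrix()
    try:
        L = np.linalg.cholesky(R + 1e-12 * np.eye(len(measures)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - validate() catches
        raise ConfigError("measure_correlation is not positive semi-definite") from exc

    n_pos = int(round(config.condition_ratio * n))
    condition = np.zeros(n, dtype=int)
    condition[rng.permutation(n)[:n_pos]] = 1

    r = config.test_retest
    pre = rng.standard_normal((n, len(measures))) @ L.T
    noise = rng.standard_normal((n, len(measures))) @ L.T
    delta = np.array(
        [[config.self_report_effects[m][arm] for m in measures] for arm in (0, 1)]
    )
    post = r * pre + delta[condition] + np.sqrt(1.0 - r**2) * noise

    ids = pd.Index([f"P{i:03d}" for i in range(n)], name="participant_id")
    return CohortTable(
        condition=pd.Series(condition, index=ids, name="condition"),
        pre=pd.DataFrame(pre, index=ids, columns=measures),
        post=pd.DataFrame(post, index=ids, columns=measures),
    )


# ---------------------------------------------------------------------------
# Cognitive task logs
# ---------------------------------------------------------------------------

_CONSTRUAL_VALENCES = ("pos", "neg", "ambiguous")
_CONSTRUAL_MEASURE_KEY = {"pos": "Pos", "neg": "Neg", "ambiguous": "Amb"}

# Latent construal rating means by (image valence, item polarity).
_CONSTRUAL_MU = {
    ("pos", "positive"): 5.5,
    ("pos", "negative"): 2.5,
    ("neg", "positive"): 2.5,
    ("neg", "negative"): 5.5,
    ("ambiguous", "positive"): 4.0,
    ("ambiguous", "negative"): 4.0,
}


def _effect(config: SimConfig, measure: str, arm: int, session: str) -> float:
    """Configured post-session mean shift for one arm, zero at pre."""
    if session != "post":
        return 0.0
    pair = config.cognitive_effects.get(measure)
    return 0.0 if pair is None else float(pair[arm])


def simulate_cognitive_logs(
    cohort: CohortTable, config: SimConfig
) -> dict[str, pd.DataFrame]:
    """Generate pre/post response logs for the three cognitive tasks.

    Returns ``{"recognition": ..., "construal": ..., "word_find": ...}``.

    Recognition: 96 words per session (48 old / 48 new, 16 per valence per
    status). Clicks come either from fixed per-valence (hit, FA)
    probabilities (``config.recognition_probs``) or from a per-participant
    latent equal-variance signal-detection model (d' ~ N(1.35, 0.4),
    criterion ~ N(0, 0.3)) onto which ``cognitive_effects`` shifts are
    applied in latent-SD units at the post session.

    Construal: 6 images (2 per valence) x 10 items (5 positive / 5 negative
    polarity), integer ratings 1-7 from a clipped normal around valence- and
    polarity-dependent means, lognormal reaction times.

    Word find: 9 words (3 per valence); find order is the rank of latent
    per-word search times, find times are the cumulative search times in ms.
    """
    rng = _rng(config, 1)
    rec_rows: list[tuple] = []
    con_rows: list[tuple] = []
    wf_rows: list[tuple] = []

    for pid in cohort.participants:
        arm = int(cohort.condition[pid])
        # Stable participant traits.
        lat_d = {v: rng.normal(1.35, 0.1) for v in VALENCES}
        lat_c = {v: rng.normal(0.0, 0.1) for v in VALENCES}
        rt_scale = rng.normal(2.0, 0.3)
        for session in ("pre", "post"):
            _recognition_session(
                rec_rows, rng, config, pid, session, arm, lat_d, lat_c
            )
            _construal_session(con_rows, rng, config, pid, session, arm, rt_scale)
            _word_find_session(wf_rows, rng, config, pid, session, arm)

    recognition = pd.DataFrame(
        rec_rows,
        columns=["participant_id", "session", "word_id", "valence", "is_old", "clicked"],
    )
    construal = pd.DataFrame(
        con_rows,
        columns=[
            "participant_id", "session", "image_id", "image_valence",
            "item_polarity", "rating", "reaction_time_s",
        ],
    )
    word_find = pd.DataFrame(
        wf_rows,
        columns=["participant_id", "session", "word_id", "valence", "find_order", "find_time_ms"],
    )
    return {"recognition": recognition, "construal": construal, "word_find": word_find}


def _recognition_session(rows, rng, config, pid, session, arm, lat_d, lat_c) -> None:
    from scipy.stats import norm

    for v in VALENCES:
        if config.recognition_probs is not None:
            hit_p, fa_p = config.recognition_probs[v]
        else:
            d = lat_d[v] + rng.normal(0.0, 0.4) + _effect(
                config, f"{v.capitalize()} d-prime", arm, session
            ) * 0.4
            c = lat_c[v] + rng.normal(0.0, 0.3) + _effect(
                config, f"{v.capitalize()} c", arm, session
            ) * 0.3
            hit_p = float(norm.cdf(d / 2.0 - c))
            fa_p = float(norm.cdf(-d / 2.0 - c))
        for i in range(16):
            rows.append(
                (pid, session, f"{session}_{v}_old_{i}", v, True,
                 bool(rng.random() < hit_p))
            )
            rows.append(
                (pid, session, f"{session}_{v}_new_{i}", v, False,
                 bool(rng.random() < fa_p))
            )


def _construal_session(rows, rng, config, pid, session, arm, rt_scale) -> None:
    for img_idx, val in enumerate(v for v in _CONSTRUAL_VALENCES for _ in range(2)):
        key = _CONSTRUAL_MEASURE_KEY[val]
        mu_shift = _effect(config, f"Response Normalized {key}", arm, session)
        rt_shift = _effect(config, f"Response Time {key}", arm, session)
        for item in range(10):
            polarity = "positive" if item < 5 else "negative"
            mu = _CONSTRUAL_MU[(val, polarity)]
            # A positive construal shift raises positive-item and lowers
            # negative-item ratings (3 rating points ~ 1 normalized unit).
            signed = mu_shift if polarity == "positive" else -mu_shift
            rating = int(np.clip(round(rng.normal(mu + 3.0 * signed, 1.0)), 1, 7))
            rt = float(
                np.exp(rng.normal(np.log(max(rt_scale + rt_shift, 0.2)), 0.3))
            )
            rows.append((pid, session, f"{session}_img{img_idx}", val, polarity, rating, rt))


def _word_find_session(rows, rng, config, pid, session, arm) -> None:
    valences = [v for v in VALENCES for _ in range(3)]
    # Latent per-word search times (s); effects shift a valence group's
    # latent time, moving both its order and its find time.
    lat = rng.exponential(40.0, size=9)
    for i, v in enumerate(valences):
        lat[i] += _effect(config, f"Find Time {v.capitalize()}", arm, session) * 20.0
        lat[i] += _effect(config, f"Order {v.capitalize()}", arm, session) * 20.0
    order = np.argsort(np.argsort(lat)) + 1          # rank 1..9
    find_time = np.cumsum(np.sort(lat))              # cumulative, increasing
    time_of_word = find_time[order - 1] * 1000.0     # ms
    for i, v in enumerate(valences):
        rows.append((pid, session, f"{session}_wf_{i}", v, int(order[i]), float(time_of_word[i])))


# ---------------------------------------------------------------------------
# Event timelines
# ---------------------------------------------------------------------------


@dataclass
class EventTimeline:
    """Ordered stimulus-on events: half-open windows [onset, onset+duration)."""

    events: pd.DataFrame  # columns: onset, duration, trial_type, stimulus_valence

    def __post_init__(self) -> None:
        onsets = self.events["onset"].to_numpy()
        if len(onsets) and not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        if len(onsets) and not np.all(self.events["duration"].to_numpy() > 0):
            raise ValueError("event durations must be positive")

    @property
    def end(self) -> float:
        if self.events.empty:
            return 0.0
        last = self.events.iloc[-1]
        return float(last["onset"] + last["duration"])

    def for_task(self, trial_type: str) -> pd.DataFrame:
        return self.events[self.events["trial_type"] == trial_type].reset_index(drop=True)

    def write_tsv(self, path: str | Path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EventTimeline":
        return cls(pd.read_csv(path, sep="\t"))


def build_timeline(
    config: SimConfig,
    *,
    rng: np.random.Generator | None = None,
    n_memory_words: int | None = None,
    n_construal_items: int | None = None,
    n_questionnaire_items: int | None = None,
) -> EventTimeline:
    """Session timeline for the three analyzed event types.

    Memory words are shown for 1 s with a uniform 2.75-3.25 s jittered
    inter-stimulus interval; construal and questionnaire items are modeled
    as 2 s stimulus-on windows with a short gap.
    """
    if rng is None:
        rng = _rng(config, 2)
    sizes = config.timeline_sizes
    n_memory_words = sizes[0] if n_memory_words is None else n_memory_words
    n_construal_items = sizes[1] if n_construal_items is None else n_construal_items
    n_questionnaire_items = sizes[2] if n_questionnaire_items is None else n_questionnaire_items
    rows = []
    t = 5.0
    vals = [VALENCES[i % 3] for i in range(n_memory_words)]
    for v in vals:
        rows.append((round(t, 4), 1.0, "emotional_memory", v))
        t += 1.0 + rng.uniform(2.75, 3.25)
    t += 10.0
    for i in range(n_construal_items):
        rows.append((round(t, 4), 2.0, "situation_construal", "n/a"))
        t += 2.0 + rng.uniform(0.5, 1.0)
    t += 10.0
    for i in range(n_questionnaire_items):
        rows.append((round(t, 4), 2.0, "questionnaire", "n/a"))
        t += 2.0 + rng.uniform(0.5, 1.0)
    return EventTimeline(
        pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "stimulus_valence"])
    )


# ---------------------------------------------------------------------------
# Raw EEG
# ---------------------------------------------------------------------------


def _one_over_f_noise(rng, n, exponent, rms, fs) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum and given RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


# Relative source gains per channel-group prefix.
_ALPHA_GAIN = {"O": 1.0, "P": 0.7, "C": 0.3, "F": 0.15}
_BLINK_GAIN = {"F": 1.0, "C": 0.3, "P": 0.1, "O": 0.0}


def _group_of(channel: str) -> str:
    return channel[0].upper()


def simulate_eeg(
    participant: int | str,
    timeline: EventTimeline,
    config: SimConfig,
    *,
    duration_s: float | None = None,
    condition: int = 0,
    session: str = "pre",
):
    """Simulate one recording: (channels x samples uV, sync, ground truth).

    The scalp signal is 1/f background + a shared 10 Hz alpha source with
    posterior-dominant gains + frontal eyeblink transients (Poisson) +
    injected large-amplitude broadband bursts at returned ground-truth
    times. The sync channel carries one rectangular pulse per timeline
    event, edges aligned to event onsets.

    Returns
    -------
    (recording, truth) where recording is an ``eeg.EEGRecording`` and truth
    a dict with blink times, artifact segments, sync onsets (samples) and
    the realized alpha amplitude.
    """
    from .eeg import EEGRecording

    p = config.eeg
    pidx = _stable_key(participant)
    rng = _rng(config, 3, pidx, 0 if session == "pre" else 1)
    if duration_s is None:
        duration_s = timeline.end + 5.0
    if timeline.end > duration_s:
        raise ValueError(
            f"timeline extends to {timeline.end:.1f}s beyond requested {duration_s:.1f}s"
        )
    fs = p.sampling_rate
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    montage = list(p.montage)

    # Participant-level alpha amplitude; optional injected condition effect
    # (between-subject SD = 20% of the nominal amplitude).
    alpha_sd = 0.2 * p.alpha_uv
    alpha_amp = p.alpha_uv + alpha_sd * rng.standard_normal()
    if condition == 1 and session == "post":
        alpha_amp += config.physio_effect.get("alpha_rms", 0.0) * alpha_sd
    alpha_amp = max(alpha_amp, 0.0)
    alpha_src = alpha_amp * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))

    # Blink transients: raised-cosine pulses on frontal channels.
    blink_src = np.zeros(n)
    n_bl = int(p.blink_duration_s * fs)
    bl_wave = p.blink_uv * 0.5 * (1 - np.cos(2 * np.pi * np.arange(n_bl) / n_bl))
    blink_times = []
    if p.blink_rate_hz > 0:
        n_blinks = rng.poisson(p.blink_rate_hz * duration_s)
        for start in np.sort(rng.uniform(0, duration_s - p.blink_duration_s, n_blinks)):
            i = int(start * fs)
            blink_src[i : i + n_bl] += bl_wave[: n - i]
            blink_times.append(float(start))

    # Large-amplitude artifact bursts: 5 Hz tone under a Hann window, hitting
    # a random subset of channels (channel-specific, like real electrode
    # pops/movement, so the average reference cannot cancel them).
    art_per_channel = np.zeros((len(montage), n))
    n_ar = int(p.artifact_duration_s * fs)
    ar_wave = (
        p.artifact_uv
        * np.sin(2 * np.pi * 5.0 * np.arange(n_ar) / fs)
        * np.hanning(n_ar)
    )
    artifact_segments = []
    if p.artifact_rate_hz > 0:
        n_art = rng.poisson(p.artifact_rate_hz * duration_s)
        n_hit = max(1, len(montage) // 4)
        for start in np.sort(rng.uniform(0, duration_s - p.artifact_duration_s, n_art)):
            i = int(start * fs)
            hit = rng.choice(len(montage), size=n_hit, replace=False)
            art_per_channel[hit, i : i + n_ar] += ar_wave[: n - i]
            artifact_segments.append((float(start), float(start + p.artifact_duration_s)))

    data = np.empty((len(montage), n))
    for ci, ch in enumerate(montage):
        g = _group_of(ch)
        data[ci] = (
            _one_over_f_noise(rng, n, p.noise_exponent, p.noise_uv, fs)
            + _ALPHA_GAIN[g] * alpha_src
            + _BLINK_GAIN[g] * blink_src
            + art_per_channel[ci]
        )

    sync = np.zeros(n)
    onsets = []
    for _, ev in timeline.events.iterrows():
        i0 = int(round(ev["onset"] * fs))
        i1 = min(int(round((ev["onset"] + ev["duration"]) * fs)), n)
        sync[i0:i1] = p.sync_uv
        onsets.append(i0)

    rec = EEGRecording(data=data, channels=montage, sfreq=fs, sync=sync)
    truth = {
        "blink_times": blink_times,
        "artifact_segments": artifact_segments,
        "sync_onsets": onsets,
        "alpha_amp": float(alpha_amp),
    }
    return rec, truth


# ---------------------------------------------------------------------------
# Wristband streams
# ---------------------------------------------------------------------------


@dataclass
class WristbandStreams:
    """The five autonomic feature-signal sources on their native grids."""

    beat_times: np.ndarray        # s
    rr_ms: np.ndarray             # one RR interval per beat
    gsr_time: np.ndarray          # s, 20 Hz grid
    gsr_tonic: np.ndarray         # uS
    gsr_phasic: np.ndarray        # uS
    temp_time: np.ndarray         # s
    temperature: np.ndarray       # degC

    def write_csvs(self, outdir: str | Path, prefix: str = "") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        frames = {
            "rr": pd.DataFrame({"time_s": self.beat_times, "value": self.rr_ms}),
            "gsr_tonic": pd.DataFrame({"time_s": self.gsr_time, "value": self.gsr_tonic}),
            "gsr_phasic": pd.DataFrame({"time_s": self.gsr_time, "value": self.gsr_phasic}),
            "temperature": pd.DataFrame({"time_s": self.temp_time, "value": self.temperature}),
        }
        for name, df in frames.items():
            path = outdir / f"{prefix}{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        return written

    @classmethod
    def read_csvs(cls, outdir: str | Path, prefix: str = "") -> "WristbandStreams":
        outdir = Path(outdir)
        rr = pd.read_csv(outdir / f"{prefix}rr.csv")
        tonic = pd.read_csv(outdir / f"{prefix}gsr_tonic.csv")
        phasic = pd.read_csv(outdir / f"{prefix}gsr_phasic.csv")
        temp = pd.read_csv(outdir / f"{prefix}temperature.csv")
        return cls(
            beat_times=rr["time_s"].to_numpy(),
            rr_ms=rr["value"].to_numpy(),
            gsr_time=tonic["time_s"].to_numpy(),
            gsr_tonic=tonic["value"].to_numpy(),
            gsr_phasic=phasic["value"].to_numpy(),
            temp_time=temp["time_s"].to_numpy(),
            temperature=temp["value"].to_numpy(),
        )


def simulate_wristband(
    participant: int | str,
    timeline: EventTimeline,
    config: SimConfig,
    *,
    duration_s: float | None = None,
    condition: int = 0,
    session: str = "pre",
):
    """Simulate wristband streams; returns (WristbandStreams, truth dict).

    RR intervals follow baseline + LF sinusoid (0.1 Hz) + HF sinusoid
    (0.25 Hz) + white noise, with beat times accumulated from the intervals.
    Tonic skin conductance is a slow drift, phasic conductance a sum of
    exponentially decaying responses at Poisson times, temperature a bounded
    random walk.
    """
    p = config.ans
    if p.lf_depth_ms < 0 or p.hf_depth_ms < 0:
        raise ValueError("HRV modulation depths must be non-negative")
    pidx = _stable_key(participant)
    rng = _rng(config, 4, pidx, 0 if session == "pre" else 1)
    if duration_s is None:
        duration_s = timeline.end + 5.0
    if timeline.end > duration_s:
        raise ValueError("timeline extends beyond requested duration")

    hf_depth = p.hf_depth_ms
    lf_depth = p.lf_depth_ms
    if condition == 1 and session == "post":
        hf_depth = max(0.0, hf_depth + config.physio_effect.get("hf_hrv", 0.0) * 0.2 * hf_depth)
        lf_depth = max(0.0, lf_depth + config.physio_effect.get("lf_hrv", 0.0) * 0.2 * lf_depth)

    beat_times = []
    rr_ms = []
    t = 0.0
    while t < duration_s:
        rr = (
            p.rr_baseline_ms
            + lf_depth * np.sin(2 * np.pi * 0.1 * t)
            + hf_depth * np.sin(2 * np.pi * 0.25 * t)
            + (p.rr_noise_ms * rng.standard_normal() if p.rr_noise_ms > 0 else 0.0)
        )
        beat_times.append(t)
        rr_ms.append(rr)
        t += rr / 1000.0

    gsr_t = np.arange(0, duration_s, 1.0 / p.gsr_rate_hz)
    tonic = (
        p.tonic_baseline_us
        + 0.2 * np.sin(2 * np.pi * 0.005 * gsr_t + rng.uniform(0, 2 * np.pi))
        + 0.05 * rng.standard_normal()
    )
    phasic = np.zeros_like(gsr_t)
    scr_times = []
    if p.scr_rate_hz > 0:
        for start in np.sort(rng.uniform(0, duration_s, rng.poisson(p.scr_rate_hz * duration_s))):
            amp = rng.exponential(p.scr_amp_us)
            tau_rise, tau_decay = 1.0, 3.0
            dt = gsr_t - start
            m = dt > 0
            phasic[m] += amp * (1 - np.exp(-dt[m] / tau_rise)) * np.exp(-dt[m] / tau_decay)
            scr_times.append(float(start))

    temp_t = np.arange(0, duration_s, 1.0 / p.temp_rate_hz)
    steps = 0.002 * rng.standard_normal(len(temp_t))
    temperature = p.temperature_baseline_c + np.clip(np.cumsum(steps), -0.5, 0.5)

    streams = WristbandStreams(
        beat_times=np.array(beat_times),
        rr_ms=np.array(rr_ms),
        gsr_time=gsr_t,
        gsr_tonic=tonic if np.ndim(tonic) else np.full_like(gsr_t, tonic),
        gsr_phasic=phasic,
        temp_time=temp_t,
        temperature=temperature,
    )
    truth = {"hf_depth_ms": hf_depth, "lf_depth_ms": lf_depth, "scr_times": scr_times}
    return streams, truth


# ---------------------------------------------------------------------------
# Dataset writer / readers
# ---------------------------------------------------------------------------


def write_eeg_csv(rec, path: str | Path) -> None:
    """EEG recording as CSV: time_s, one column per channel, sync."""
    cols = {"time_s": np.arange(rec.data.shape[1]) / rec.sfreq}
    for i, ch in enumerate(rec.channels):
        cols[ch] = rec.data[i]
    if rec.sync is not None:
        cols["sync"] = rec.sync
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.4f")


def read_eeg_csv(path: str | Path, sfreq: float = 128.0):
    from .eeg import EEGRecording

    df = pd.read_csv(path)
    channels = [c for c in df.columns if c not in ("time_s", "sync")]
    sync = df["sync"].to_numpy() if "sync" in df.columns else None
    return EEGRecording(
        data=df[channels].to_numpy().T, channels=channels, sfreq=sfreq, sync=sync
    )


def read_cohort(path: str | Path) -> CohortTable:
    return CohortTable.from_frame(pd.read_csv(path, index_col="participant_id"))


def write_dataset(
    config: SimConfig,
    outdir: str | Path,
    *,
    physio_participants: int = 0,
) -> dict:
    """Write a complete synthetic dataset; returns a ground-truth manifest.

    Cohort and task logs cover all participants; raw EEG (CSV) + events.tsv
    and wristband streams are written for the first ``physio_participants``
    participants (both sessions each).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    cohort.to_frame().to_csv(outdir / "cohort.csv")
    logs = simulate_cognitive_logs(cohort, config)
    for name, df in logs.items():
        df.to_csv(outdir / f"{name}_log.csv", index=False)

    manifest: dict = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "files": ["cohort.csv"] + [f"{k}_log.csv" for k in logs],
        "physio": {},
    }
    pids = list(cohort.participants[:physio_participants])
    for pid in pids:
        cond = int(cohort.condition[pid])
        for session in ("pre", "post"):
            timeline = build_timeline(config, rng=_rng(config, 5, _stable_key(pid)))
            pdir = outdir / "physio" / f"{pid}_{session}"
            pdir.mkdir(parents=True, exist_ok=True)
            timeline.write_tsv(pdir / "events.tsv")
            rec, eeg_truth = simulate_eeg(
                pid, timeline, config, condition=cond, session=session
            )
            write_eeg_csv(rec, pdir / "eeg.csv")
            pd.DataFrame({"onset_sample": eeg_truth["sync_onsets"]}).to_csv(
                pdir / "sync_truth.tsv", sep="\t", index=False
            )
            streams, ans_truth = simulate_wristband(
                pid, timeline, config, condition=cond, session=session
            )
            streams.write_csvs(pdir)
            manifest["physio"][f"{pid}_{session}"] = {
                "artifact_segments": eeg_truth["artifact_segments"],
                "alpha_amp": eeg_truth["alpha_amp"],
                "hf_depth_ms": ans_truth["hf_depth_ms"],
                "lf_depth_ms": ans_truth["lf_depth_ms"],
            }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
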