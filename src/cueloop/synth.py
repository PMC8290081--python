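"""Synthetic cue-reactivity EEG and a virtual subject for closed-loop runs.

The generator plants a condition-dependent ERP (boxcar plateau over a
configurable post-stimulus window on centro-parietal channels) and a
condition-dependent alpha-power effect into 1/f Gaussian background noise,
with raised-cosine blink transients on VEOG that propagate to the scalp with
anterior-to-posterior decaying gains.  The virtual subject couples the
displayed picture level back into the amplitude of the planted pattern, so
the whole feedback loop can run without a human.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .io import RawRecording
from .montage import STANDARD_64, positions_2d

__all__ = [
    "ErpEffect",
    "BandEffect",
    "NoiseSpec",
    "BlinkSpec",
    "SimulationSpec",
    "Trial",
    "Block",
    "TaskSchedule",
    "VirtualSubject",
    "BLOCK_ORDER",
    "TRIALS_PER_BLOCK",
    "ANIMALS_PER_BLOCK",
    "make_schedule",
    "generate_recording",
    "window_template",
    "virtual_subject_step",
    "emit_window",
]

BLOCK_ORDER = ("neutral", "smoking", "smoking", "neutral", "smoking", "neutral")
TRIALS_PER_BLOCK = 55
ANIMALS_PER_BLOCK = 5

CODE_OF = {"neutral": 1, "smoking": 2, "animal": 3}

_ERP_CHANNELS = ["CZ", "C1", "C2", "CPZ", "CP1", "CP2", "PZ", "P1", "P2", "POZ"]
_ALPHA_CHANNELS = ["PZ", "POZ", "PO3", "PO4", "O1", "OZ", "O2"]


@dataclass
class ErpEffect:
    channels: list[str] = field(default_factory=lambda: list(_ERP_CHANNELS))
    window_ms: tuple[float, float] = (300.0, 550.0)
    amplitude_uv: float = 5.0


@dataclass
class BandEffect:
    band: str = "alpha"
    freq_hz: float = 10.0
    channels: list[str] = field(default_factory=lambda: list(_ALPHA_CHANNELS))
    neutral_amplitude_uv: float = 4.0
    power_ratio: float = 2.0  # smoking / neutral power

    def __post_init__(self) -> None:
        if self.power_ratio <= 0:
            raise ValueError("power_ratio must be positive")


@dataclass
class NoiseSpec:
    exponent: float = 1.0  # 1/f^exponent power spectrum
    amplitude_uv: float = 10.0  # RMS per channel


@dataclass
class BlinkSpec:
    rate_per_min: float = 8.0
    amplitude_uv: float = 150.0
    duration_ms: float = 400.0
    propagation_max: float = 0.5  # frontal scalp gain; decays to 0 posteriorly

    def __post_init__(self) -> None:
        if not np.isfinite(self.propagation_max):
            raise ValueError("propagation gain must be finite")


@dataclass
class SimulationSpec:
    """Everything needed to synthesize a recording and drive a subject."""

    channel_labels: list[str] = field(default_factory=lambda: list(STANDARD_64))
    sampling_rate: float = 250.0
    erp: ErpEffect = field(default_factory=ErpEffect)
    band_effects: list[BandEffect] = field(default_factory=lambda: [BandEffect()])
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    blink: BlinkSpec = field(default_factory=BlinkSpec)
    stimulus_s: float = 1.0
    iti_s: float = 1.0
    inter_block_rest_s: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lo, hi = self.erp.window_ms
        if not (0.0 <= lo < hi <= 1000.0):
            raise ValueError("ERP window must lie within 0-1000 ms")

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path=None) -> str:
        d = {
            "channel_labels": list(self.channel_labels),
            "sampling_rate": self.sampling_rate,
            "erp": {
                "channels": list(self.erp.channels),
                "window_ms": list(self.erp.window_ms),
                "amplitude_uv": self.erp.amplitude_uv,
            },
            "band_effects": [
                {
                    "band": b.band,
                    "freq_hz": b.freq_hz,
                    "channels": list(b.channels),
                    "neutral_amplitude_uv": b.neutral_amplitude_uv,
                    "power_ratio": b.power_ratio,
                }
                for b in self.band_effects
            ],
            "noise": {"exponent": self.noise.exponent, "amplitude_uv": self.noise.amplitude_uv},
            "blink": {
                "rate_per_min": self.blink.rate_per_min,
                "amplitude_uv": self.blink.amplitude_uv,
                "duration_ms": self.blink.duration_ms,
                "propagation_max": self.blink.propagation_max,
            },
            "stimulus_s": self.stimulus_s,
            "iti_s": self.iti_s,
            "inter_block_rest_s": self.inter_block_rest_s,
            "seed": self.seed,
        }
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path) -> "SimulationSpec":
        try:
            with open(text_or_path) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(text_or_path)
        erp = ErpEffect(
            channels=d["erp"]["channels"],
            window_ms=tuple(d["erp"]["window_ms"]),
            amplitude_uv=d["erp"]["amplitude_uv"],
        )
        bands = [BandEffect(**b) for b in d.get("band_effects", [])]
        return cls(
            channel_labels=d["channel_labels"],
            sampling_rate=d["sampling_rate"],
            erp=erp,
            band_effects=bands,
            noise=NoiseSpec(**d["noise"]),
            blink=BlinkSpec(**d["blink"]),
            stimulus_s=d.get("stimulus_s", 1.0),
            iti_s=d.get("iti_s", 1.0),
            inter_block_rest_s=d.get("inter_block_rest_s", 90.0),
            seed=d.get("seed", 0),
        )


# --------------------------------------------------------------------------
# Task schedule
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Trial:
    onset_sample: int
    code: int  # 1 neutral, 2 smoking, 3 animal

    @property
    def condition(self) -> str:
        return {v: k for k, v in CODE_OF.items()}[self.code]


@dataclass(frozen=True)
class Block:
    condition: str
    trials: tuple[Trial, ...]


@dataclass(frozen=True)
class TaskSchedule:
    blocks: tuple[Block, ...]
    sampling_rate: float

    @property
    def all_trials(self) -> list[Trial]:
        return [t for b in self.blocks for t in b.trials]

    @property
    def end_sample(self) -> int:
        return self.all_trials[-1].onset_sample if self.blocks else 0

    def events(self) -> np.ndarray:
        return np.array([[t.onset_sample, t.code] for t in self.all_trials], dtype=np.int64)

    def to_yaml(self, path=None) -> str:
        d = {
            "sampling_rate": self.sampling_rate,
            "blocks": [
                {
                    "condition": b.condition,
                    "trials": [[t.onset_sample, t.code] for t in b.trials],
                }
                for b in self.blocks
            ],
        }
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path) -> "TaskSchedule":
        try:
            with open(text_or_path) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(text_or_path)
        blocks = tuple(
            Block(
                condition=b["condition"],
                trials=tuple(Trial(int(s), int(c)) for s, c in b["trials"]),
            )
            for b in d["blocks"]
        )
        return cls(blocks=blocks, sampling_rate=float(d["sampling_rate"]))


def make_schedule(
    spec: SimulationSpec,
    seed: int | None = None,
    trials_per_block: int = TRIALS_PER_BLOCK,
    animals_per_block: int = ANIMALS_PER_BLOCK,
    lead_in_s: float = 5.0,
) -> TaskSchedule:
    """Build the 6-block pseudo-randomized task schedule (N,S,S,N,S,N).

    Only the positions of the attention-catch (animal) trials are random;
    they depend solely on ``seed`` (``spec.seed`` when None).  The
    ``trials_per_block``/``animals_per_block`` overrides exist for scaled-down
    test runs and deviate from the protocol.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    fs = spec.sampling_rate
    trial_len = int(round((spec.stimulus_s + spec.iti_s) * fs))
    block_len = trials_per_block * trial_len
    rest_len = int(round(spec.inter_block_rest_s * fs))
    cursor = int(round(lead_in_s * fs))

    blocks = []
    for cond in BLOCK_ORDER:
        animal_pos = set(rng.choice(trials_per_block, size=animals_per_block, replace=False))
        trials = tuple(
            Trial(
                onset_sample=cursor + i * trial_len,
                code=CODE_OF["animal"] if i in animal_pos else CODE_OF[cond],
            )
            for i in range(trials_per_block)
        )
        blocks.append(Block(condition=cond, trials=trials))
        cursor += block_len + rest_len
    return TaskSchedule(blocks=tuple(blocks), sampling_rate=fs)


# --------------------------------------------------------------------------
# Signal building blocks
# --------------------------------------------------------------------------


def _one_over_f(rng: np.random.Generator, n_ch: int, n_samp: int, exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, RMS-normalized."""
    if rms == 0:
        return np.zeros((n_ch, n_samp))
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samp, d=1.0)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shaping[None, :], n=n_samp, axis=1)
    std = shaped.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return shaped / std * rms


def _blink_template(spec: BlinkSpec, fs: float) -> np.ndarray:
    n = max(int(round(spec.duration_ms / 1000.0 * fs)), 2)
    t = np.arange(n) / (n - 1)
    return spec.amplitude_uv * 0.5 * (1.0 - np.cos(2.0 * math.pi * t))


def _blink_gains(labels: list[str], blink: BlinkSpec) -> np.ndarray:
    """Per-channel blink propagation gain; VEOG gets 1, scalp decays with y."""
    pos = positions_2d(labels)
    ys = np.array([pos[l][1] for l in labels])
    scalp_mask = np.array([l.upper() not in {"VEOG", "HEOG"} for l in labels])
    ymin, ymax = ys[scalp_mask].min(), ys[scalp_mask].max()
    norm = np.clip((ys - ymin) / (ymax - ymin), 0.0, 1.0)
    gains = blink.propagation_max * norm**2
    gains[~scalp_mask] = 0.0
    gains[[l.upper() for l in labels].index("VEOG")] = 1.0
    return gains


def _erp_sample_range(spec: SimulationSpec) -> tuple[int, int]:
    fs = spec.sampling_rate
    lo = int(math.ceil(spec.erp.window_ms[0] * fs / 1000.0))
    hi = int(math.ceil(spec.erp.window_ms[1] * fs / 1000.0))  # half-open
    return lo, hi


def generate_recording(
    spec: SimulationSpec,
    schedule: TaskSchedule,
    seed: int | None = None,
    duration_s: float | None = None,
) -> RawRecording:
    """Continuous synthetic EEG with the schedule's events embedded.

    Smoking trials carry the planted ERP plateau; both conditions carry the
    band oscillations (neutral amplitude vs neutral x sqrt(power_ratio) for
    smoking, random phase per trial).  Deterministic given (spec, seed).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    fs = spec.sampling_rate
    labels = list(spec.channel_labels)
    n_ch = len(labels)
    tail = int(round(2.0 * fs))
    n_samp = schedule.end_sample + int(round(1.0 * fs)) + tail
    if duration_s is not None:
        n_total = int(round(duration_s * fs))
        if n_total < n_samp - tail:
            raise ValueError("schedule does not fit within the requested duration")
        n_samp = n_total

    data = _one_over_f(rng, n_ch, n_samp, spec.noise.exponent, spec.noise.amplitude_uv)
    idx = {l.upper(): i for i, l in enumerate(labels)}

    erp_lo, erp_hi = _erp_sample_range(spec)
    erp_rows = [idx[c.upper()] for c in spec.erp.channels if c.upper() in idx]
    trial_n = int(round(1.0 * fs))  # stimulus-locked effect window 0-1000 ms
    t_axis = np.arange(trial_n) / fs

    for trial in schedule.all_trials:
        cond = trial.condition
        if cond == "animal":
            continue
        s0 = trial.onset_sample
        if cond == "smoking" and erp_rows and spec.erp.amplitude_uv != 0.0:
            data[np.ix_(erp_rows, range(s0 + erp_lo, s0 + erp_hi))] += spec.erp.amplitude_uv
        for be in spec.band_effects:
            rows = [idx[c.upper()] for c in be.channels if c.upper() in idx]
            if not rows:
                continue
            amp = be.neutral_amplitude_uv * (
                math.sqrt(be.power_ratio) if cond == "smoking" else 1.0
            )
            if amp == 0.0:
                continue
            phase = rng.uniform(0.0, 2.0 * math.pi)
            osc = amp * np.cos(2.0 * math.pi * be.freq_hz * t_axis + phase)
            data[rows, s0 : s0 + trial_n] += osc

    if spec.blink.amplitude_uv != 0.0 and spec.blink.rate_per_min > 0.0:
        template = _blink_template(spec.blink, fs)
        gains = _blink_gains(labels, spec.blink)
        n_blinks = rng.poisson(spec.blink.rate_per_min * n_samp / fs / 60.0)
        onsets = np.sort(rng.integers(0, max(n_samp - len(template), 1), size=n_blinks))
        for on in onsets:
            data[:, on : on + len(template)] += gains[:, None] * template[None, :]

    return RawRecording(
        data=data, sampling_rate=fs, channel_labels=labels, events=schedule.events()
    )


def window_template(spec: SimulationSpec, duration_s: float = 1.0) -> np.ndarray:
    """Deterministic smoking-pattern template for a 1-s window (channels x samples).

    ERP plateau plus the smoking-minus-neutral band oscillation amplitude at
    fixed (zero) phase; this is what ``emit_window`` scales by the subject's
    craving state.
    """
    fs = spec.sampling_rate
    n = int(round(duration_s * fs))
    labels = list(spec.channel_labels)
    idx = {l.upper(): i for i, l in enumerate(labels)}
    tpl = np.zeros((len(labels), n))
    lo, hi = _erp_sample_range(spec)
    rows = [idx[c.upper()] for c in spec.erp.channels if c.upper() in idx]
    tpl[np.ix_(rows, range(lo, min(hi, n)))] += spec.erp.amplitude_uv
    t_axis = np.arange(n) / fs
    for be in spec.band_effects:
        rows = [idx[c.upper()] for c in be.channels if c.upper() in idx]
        d_amp = be.neutral_amplitude_uv * (math.sqrt(be.power_ratio) - 1.0)
        if rows and d_amp != 0.0:
            tpl[rows, :] += d_amp * np.cos(2.0 * math.pi * be.freq_hz * t_axis)
    return tpl


# --------------------------------------------------------------------------
# Virtual subject
# --------------------------------------------------------------------------

PICTURE_LEVELS = 11
_MID_LEVEL = (PICTURE_LEVELS + 1) / 2.0  # 6


@dataclass
class VirtualSubject:
    """Latent craving state driven by feedback, with picture-coupled output.

    ``learning_rate`` is subtracted from the state whenever the displayed
    score just fell, modelling reinforcement of successful downregulation;
    zero-mean Gaussian noise is added each update and the state is clipped
    to [0, 1].  ``reactivity_gain`` couples the currently displayed picture
    level into the *amplitude of the emitted pattern* (higher-craving
    pictures transiently evoke more cue reactivity) without moving the
    latent state, so a non-learning subject shows no systematic trend.
    """

    craving_state: float = 0.7
    reactivity_gain: float = 0.05
    learning_rate: float = 0.02
    state_noise_sd: float = 0.02
    seed: int = 0
    last_picture_level: int = 6
    rng: np.random.Generator = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        self.craving_state = float(np.clip(self.craving_state, 0.0, 1.0))
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)

    def copy(self) -> "VirtualSubject":
        dup = replace(self)
        dup.rng = copy.deepcopy(self.rng)
        return dup


def virtual_subject_step(
    subject: VirtualSubject, picture_level: int, displayed_score_delta: float
) -> VirtualSubject:
    """Advance the subject one update; returns the updated subject.

    state -= learning_rate * [delta < 0]; state += N(0, state_noise_sd);
    state clipped to [0, 1].  The picture level is remembered and modulates
    the next emitted window via ``reactivity_gain``.
    """
    if not 1 <= picture_level <= PICTURE_LEVELS:
        raise ValueError(f"picture_level must be in 1..{PICTURE_LEVELS}")
    s = subject.craving_state
    if displayed_score_delta < 0:
        s -= subject.learning_rate
    if subject.state_noise_sd > 0:
        s += subject.rng.normal(0.0, subject.state_noise_sd)
    out = replace(
        subject,
        craving_state=float(np.clip(s, 0.0, 1.0)),
        last_picture_level=int(picture_level),
    )
    out.rng = subject.rng
    return out


def emit_window(
    subject: VirtualSubject,
    spec: SimulationSpec,
    duration_s: float = 1.0,
    template: np.ndarray | None = None,
) -> np.ndarray:
    """One window of ongoing EEG: pattern-scaled template plus noise + blinks.

    The pattern amplitude is ``craving_state`` plus the transient picture
    reactivity ``reactivity_gain * (level - 6) / 5``, clipped to [0, 1];
    with the mid picture level displayed it reduces to the craving state
    exactly.
    """
    fs = spec.sampling_rate
    n = int(round(duration_s * fs))
    tpl = window_template(spec, duration_s) if template is None else template
    amp = subject.craving_state + subject.reactivity_gain * (
        subject.last_picture_level - _MID_LEVEL
    ) / (_MID_LEVEL - 1.0)
    out = float(np.clip(amp, 0.0, 1.0)) * tpl
    if spec.noise.amplitude_uv > 0:
        out = out + _one_over_f(
            subject.rng, tpl.shape[0], n, spec.noise.exponent, spec.noise.amplitude_uv
        )
    if spec.blink.amplitude_uv != 0.0 and spec.blink.rate_per_min > 0.0:
        p_blink = spec.blink.rate_per_min * duration_s / 60.0
        if subject.rng.random() < p_blink:
            template = _blink_template(spec.blink, fs)
            gains = _blink_gains(list(spec.channel_labels), spec.blink)
            on = int(subject.rng.integers(0, max(n - len(template), 1)))
            seg = min(len(template), n - on)
            out[:, on : on + seg] += gains[:, None] * template[None, :seg]
    return out
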