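"""Real-time neurofeedback session engine (virtual clock, no wall-time).

Every 2-s update acquires a 1-s window, cleans it with the causal online
chain, scores it with the trained decoder, smooths the score (first two
updates of a session are pinned at 0.5, afterwards the mean of the current
and previous two raw scores), maps the displayed score onto one of 11
picture levels, and - when the source is a virtual subject - feeds the
picture level and the score change back into the subject's dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoder import TrainedDecoder, score as decoder_score
from .features import assemble_window_features
from .io import RawRecording
from .montage import MODEL60
from .preprocess import OnlineHighpass, RlsBlinkFilter, RlsConfig
from .synth import (
    PICTURE_LEVELS,
    SimulationSpec,
    VirtualSubject,
    emit_window,
    virtual_subject_step,
)

__all__ = [
    "SessionConfig",
    "FeedbackTrace",
    "ScoreSmoother",
    "smooth",
    "picture_for",
    "VirtualSubjectSource",
    "ReplaySource",
    "SourceExhaustedError",
    "run_cycle",
    "run_session",
]


@dataclass(frozen=True)
class SessionConfig:
    """Protocol constants of one neurofeedback session."""

    n_cycles: int = 8
    trials_per_cycle: int = 40
    update_period_s: float = 2.0
    inter_cycle_rest_s: float = 60.0
    picture_levels: int = PICTURE_LEVELS
    smooth_on: str = "raw"  # or "displayed"
    smoother_reset: str = "session"  # or "cycle"
    highpass_hz: float = 0.5
    use_rls: bool = True

    def __post_init__(self) -> None:
        if min(self.n_cycles, self.trials_per_cycle, self.picture_levels) <= 0:
            raise ValueError("all session counts must be positive")
        if self.update_period_s <= 0 or self.inter_cycle_rest_s < 0:
            raise ValueError("timing values must be positive")


class ScoreSmoother:
    """3-point moving average with the first two outputs pinned at 0.5."""

    def __init__(self, smooth_on: str = "raw"):
        if smooth_on not in {"raw", "displayed"}:
            raise ValueError("smooth_on must be 'raw' or 'displayed'")
        self.smooth_on = smooth_on
        self._raw: list[float] = []
        self._displayed: list[float] = []

    def reset(self) -> None:
        self._raw.clear()
        self._displayed.clear()

    def update(self, raw: float) -> float:
        self._raw.append(float(raw))
        n = len(self._raw)
        if n <= 2:
            out = 0.5
        elif self.smooth_on == "raw":
            out = float(np.mean(self._raw[-3:]))
        else:
            out = float(np.mean([raw] + self._displayed[-2:]))
        self._displayed.append(out)
        return out


def smooth(raw_history: list[float], new_raw: float) -> float:
    """Stateless helper: displayed value for the next update.

    ``raw_history`` holds the raw scores of all previous updates of the
    session line; updates 1 and 2 return the fixed 0.5.
    """
    n = len(raw_history) + 1
    if n <= 2:
        return 0.5
    return float(np.mean(list(raw_history[-2:]) + [new_raw]))


def picture_for(score_value: float, n_levels: int = PICTURE_LEVELS) -> int:
    """Map a displayed score in [0, 1] onto a picture level 1..n_levels.

    Uniform bins of width 1/n_levels, right-closed at 1; monotone
    non-decreasing.  Out-of-range scores are clipped with a warning.
    """
    if not 0.0 <= score_value <= 1.0:
        warnings.warn(f"score {score_value} outside [0, 1]; clipping")
        score_value = min(max(score_value, 0.0), 1.0)
    return min(int(score_value * n_levels) + 1, n_levels)


@dataclass
class FeedbackTrace:
    """Per-update log of a neurofeedback session."""

    rows: list[dict] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.rows.append(kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["cycle", "trial", "t_s", "raw_score", "displayed_score", "picture_level"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeedbackTrace":
        df = pd.read_csv(path)
        return cls(rows=df.to_dict("records"))

    def cycle_means(self) -> pd.Series:
        """Mean displayed score per cycle."""
        df = self.to_frame()
        return df.groupby("cycle")["displayed_score"].mean()

    def __len__(self) -> int:
        return len(self.rows)


class SourceExhaustedError(RuntimeError):
    """A window source ran out of data mid-cycle; carries the partial trace."""

    def __init__(self, message: str, partial_trace: FeedbackTrace):
        super().__init__(message)
        self.partial_trace = partial_trace


class VirtualSubjectSource:
    """Closes the loop around a :class:`VirtualSubject`."""

    def __init__(self, subject: VirtualSubject, spec: SimulationSpec):
        self.subject = subject
        self.spec = spec
        self.channel_labels = list(spec.channel_labels)
        self.sampling_rate = spec.sampling_rate
        self._template = None

    def next_window(self, duration_s: float = 1.0) -> np.ndarray:
        if self._template is None or self._template.shape[1] != int(
            round(duration_s * self.sampling_rate)
        ):
            from .synth import window_template

            self._template = window_template(self.spec, duration_s)
        return emit_window(self.subject, self.spec, duration_s, template=self._template)

    def feedback(self, picture_level: int, displayed_score_delta: float) -> None:
        self.subject = virtual_subject_step(
            self.subject, picture_level, displayed_score_delta
        )


class ReplaySource:
    """Serves consecutive 1-s windows from a recorded session; never adapts."""

    def __init__(self, rec: RawRecording):
        self.rec = rec
        self.channel_labels = list(rec.channel_labels)
        self.sampling_rate = rec.sampling_rate
        self._cursor = 0

    def next_window(self, duration_s: float = 1.0) -> np.ndarray:
        n = int(round(duration_s * self.sampling_rate))
        if self._cursor + n > self.rec.n_samples:
            raise StopIteration("recording exhausted")
        w = self.rec.data[:, self._cursor : self._cursor + n]
        self._cursor += n
        return w

    def feedback(self, picture_level: int, displayed_score_delta: float) -> None:
        pass


@dataclass
class _OnlineChain:
    """Persistent causal preprocessing shared across a session."""

    hp: OnlineHighpass
    rls: RlsBlinkFilter | None
    model_idx: list[int]
    model_labels: list[str]

    @classmethod
    def build(cls, labels: list[str], fs: float, cfg: SessionConfig) -> "_OnlineChain":
        upper = {l.upper(): i for i, l in enumerate(labels)}
        have_eog = all(r in upper for r in ("VEOG", "HEOG"))
        rls = RlsBlinkFilter(labels, RlsConfig()) if (cfg.use_rls and have_eog) else None
        model_idx = [i for i, l in enumerate(labels) if l.upper() in set(MODEL60)]
        if not model_idx:  # toy sources without standard labels: use everything
            model_idx = list(range(len(labels)))
        return cls(
            hp=OnlineHighpass(len(labels), fs, cfg.highpass_hz),
            rls=rls,
            model_idx=model_idx,
            model_labels=[labels[i] for i in model_idx],
        )

    def process(self, window: np.ndarray) -> np.ndarray:
        w = self.hp.process(window)
        if self.rls is not None:
            w = self.rls.process(w)
        return w[self.model_idx]


def _run_cycle_into(
    trace: FeedbackTrace,
    decoder: TrainedDecoder,
    source,
    cfg: SessionConfig,
    smoother: ScoreSmoother,
    chain: _OnlineChain,
    cycle: int,
    t0_s: float,
    last_displayed: list[float],
) -> None:
    for trial in range(1, cfg.trials_per_cycle + 1):
        try:
            window = source.next_window(1.0)
        except StopIteration as exc:
            raise SourceExhaustedError(
                f"source exhausted at cycle {cycle} trial {trial}", trace
            ) from exc
        clean = chain.process(np.asarray(window, dtype=np.float64))
        feats = assemble_window_features(
            clean,
            source.sampling_rate,
            chain.model_labels,
            decoder.clusters,
            decoder.bands,
        )
        raw = float(decoder_score(decoder, feats))
        displayed = smoother.update(raw)
        level = picture_for(displayed, cfg.picture_levels)
        delta = displayed - last_displayed[0]
        last_displayed[0] = displayed
        source.feedback(level, delta)
        trace.append(
            cycle=cycle,
            trial=trial,
            t_s=t0_s + (trial - 1) * cfg.update_period_s,
            raw_score=raw,
            displayed_score=displayed,
            picture_level=level,
        )


def run_cycle(
    decoder: TrainedDecoder,
    source,
    cfg: SessionConfig | None = None,
    smoother: ScoreSmoother | None = None,
) -> FeedbackTrace:
    """Run one feedback cycle (``trials_per_cycle`` updates) and log it."""
    cfg = cfg or SessionConfig()
    smoother = smoother or ScoreSmoother(cfg.smooth_on)
    chain = _OnlineChain.build(source.channel_labels, source.sampling_rate, cfg)
    trace = FeedbackTrace()
    _run_cycle_into(trace, decoder, source, cfg, smoother, chain, 1, 0.0, [0.5])
    return trace


def run_session(
    decoder: TrainedDecoder, source, cfg: SessionConfig | None = None
) -> FeedbackTrace:
    """Run a full session: ``n_cycles`` cycles with rest gaps in the timeline."""
    cfg = cfg or SessionConfig()
    smoother = ScoreSmoother(cfg.smooth_on)
    chain = _OnlineChain.build(source.channel_labels, source.sampling_rate, cfg)
    trace = FeedbackTrace()
    last = [0.5]
    t0 = 0.0
    for cycle in range(1, cfg.n_cycles + 1):
        if cfg.smoother_reset == "cycle":
            smoother.reset()
        _run_cycle_into(trace, decoder, source, cfg, smoother, chain, cycle, t0, last)
        t0 += cfg.trials_per_cycle * cfg.update_period_s + cfg.inter_cycle_rest_s
    return trace
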