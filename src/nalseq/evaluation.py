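"""Metrics and experiment runners.

Anticipation accuracy follows the any-of convention: a step counts as
correct when the event occurring at ``t+1`` is among the concepts the
learner anticipated at ``t``.  Accuracy is reported as a sliding-window
mean over the most recent 100 steps, over *all* positions (deterministic
and filler alike), so a stream with half random fillers caps the
achievable accuracy near 50%.  A secondary accuracy restricted to
deterministic positions is tracked as a diagnostic.

Steady-state summaries average over the final 5,000 recorded steps by
default.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datagen import (
    EpisodeSchedule,
    Event,
    Prototype,
    StreamConfig,
    forgetting_stream,
    generate_stream,
    make_prototypes,
)
from .learner import SequenceLearner, StepResult
from .network import ConceptNetwork, HyperParams

__all__ = [
    "MetricsWindow",
    "record_step",
    "ExperimentResult",
    "ForgettingResult",
    "run_capacity_experiment",
    "run_forgetting_experiment",
    "snapshot_links",
    "oracle_correctness",
]

STEADY_STATE_TAIL = 5_000


class MetricsWindow:
    """Sliding-window accuracy plus per-step anticipation/activity counts."""

    def __init__(self, window: int = 100) -> None:
        self.window = window
        self._ring: deque[bool] = deque(maxlen=window)
        self.correct: list[bool] = []
        self.accuracy: list[float] = []
        self.n_anticipated: list[int] = []
        self.n_active: list[int] = []
        self.deterministic: list[bool] = []
        self.episode: list[int] = []
        self.segment: list[int] = []
        self.touched: list[int] = []

    def record(
        self,
        result: StepResult,
        occurred_next: str,
        deterministic: bool = True,
        episode: int = 0,
        segment: int = 0,
    ) -> float:
        """Score the prediction made at ``result.t`` against the event
        observed at the following step; returns the updated window
        accuracy."""
        ok = occurred_next in result.anticipated_concepts
        self._ring.append(ok)
        acc = sum(self._ring) / len(self._ring)
        self.correct.append(ok)
        self.accuracy.append(acc)
        self.n_anticipated.append(len(result.anticipated_concepts))
        self.n_active.append(len(result.active_nodes))
        self.deterministic.append(deterministic)
        self.episode.append(episode)
        self.segment.append(segment)
        self.touched.append(result.touched)
        return acc


def record_step(
    metrics: MetricsWindow, result: StepResult, occurred_next: str
) -> MetricsWindow:
    """Functional wrapper around :meth:`MetricsWindow.record`."""
    metrics.record(result, occurred_next)
    return metrics


@dataclass
class ExperimentResult:
    """Full time series of one run plus its reproducibility echo."""

    config: dict
    seed: int
    accuracy: np.ndarray
    correct: np.ndarray
    n_anticipated: np.ndarray
    n_active: np.ndarray
    deterministic: np.ndarray
    episode: np.ndarray
    segment: np.ndarray
    touched: np.ndarray

    @classmethod
    def from_metrics(
        cls, metrics: MetricsWindow, config: dict, seed: int
    ) -> "ExperimentResult":
        return cls(
            config=config,
            seed=seed,
            accuracy=np.asarray(metrics.accuracy, dtype=float),
            correct=np.asarray(metrics.correct, dtype=bool),
            n_anticipated=np.asarray(metrics.n_anticipated, dtype=int),
            n_active=np.asarray(metrics.n_active, dtype=int),
            deterministic=np.asarray(metrics.deterministic, dtype=bool),
            episode=np.asarray(metrics.episode, dtype=int),
            segment=np.asarray(metrics.segment, dtype=int),
            touched=np.asarray(metrics.touched, dtype=int),
        )

    def __len__(self) -> int:
        return len(self.accuracy)

    def steady_state(self, tail: int = STEADY_STATE_TAIL) -> dict:
        """Means over the final ``tail`` recorded steps."""
        sl = slice(max(0, len(self) - tail), None)
        det = self.deterministic[sl]
        return {
            "accuracy": float(self.accuracy[sl].mean()) if len(self) else float("nan"),
            "accuracy_deterministic": float(self.correct[sl][det].mean())
            if det.any()
            else float("nan"),
            "n_anticipated": float(self.n_anticipated[sl].mean()) if len(self) else float("nan"),
            "n_active": float(self.n_active[sl].mean()) if len(self) else float("nan"),
            "steps": int(sl.indices(len(self))[1] - sl.indices(len(self))[0]),
        }

    def segment_summaries(self, tail: int = STEADY_STATE_TAIL) -> list[dict]:
        """Steady-state summary of each contiguous stream segment."""
        out = []
        for seg in np.unique(self.segment):
            mask = self.segment == seg
            idx = np.flatnonzero(mask)
            lo = idx[max(0, len(idx) - tail)]
            window = idx[idx >= lo]
            out.append(
                {
                    "segment": int(seg),
                    "episode": int(self.episode[idx[0]]),
                    "start": int(idx[0]),
                    "end": int(idx[-1]) + 1,
                    "accuracy": float(self.accuracy[window].mean()),
                    "n_anticipated": float(self.n_anticipated[window].mean()),
                    "n_active": float(self.n_active[window].mean()),
                }
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(len(self)),
                "correct": self.correct.astype(int),
                "accuracy_w100": self.accuracy,
                "n_anticipated": self.n_anticipated,
                "n_active": self.n_active,
                "deterministic": self.deterministic.astype(int),
                "episode": self.episode,
                "segment": self.segment,
                "touched": self.touched,
            }
        )


@dataclass
class ForgettingResult:
    """Episodic run: the series, per-segment summaries, link snapshots."""

    result: ExperimentResult
    summaries: list[dict]
    #: segment index -> canonical tuple of the watched link set, taken at
    #: the end of the segment (see :func:`snapshot_links`).
    snapshots: dict[int, tuple] = field(default_factory=dict)


def _run_stream(
    learner: SequenceLearner,
    events: Iterable[Event],
    metrics: MetricsWindow,
    on_segment_end=None,
) -> None:
    """Drive the learner over a stream, scoring each step against the
    next event's term."""
    prev: Optional[Event] = None
    prev_result: Optional[StepResult] = None
    for ev in events:
        if prev_result is not None:
            metrics.record(
                prev_result,
                ev.term,
                deterministic=ev.deterministic,
                episode=prev.episode,
                segment=prev.segment,
            )
            if on_segment_end is not None and ev.segment != prev.segment:
                on_segment_end(prev.segment)
        prev_result = learner.step(ev.term, ev.t)
        prev = ev
    if on_segment_end is not None and prev is not None:
        on_segment_end(prev.segment)


def run_capacity_experiment(
    cfg: StreamConfig,
    hp: Optional[HyperParams] = None,
    prototypes: Optional[Sequence[Prototype] | Sequence[Sequence[str]]] = None,
) -> ExperimentResult:
    """Train a fresh learner online on one synthetic stream.

    ``prototypes`` overrides the random draw (e.g. the fixed
    overlapping pair of the simple case); plain tuples of terms are
    accepted.
    """
    rng = np.random.default_rng(cfg.seed)
    if prototypes is None:
        protos = make_prototypes(cfg, rng)
    else:
        protos = [
            p if isinstance(p, Prototype) else Prototype(tuple(p))
            for p in prototypes
        ]
    learner = SequenceLearner(hp)
    metrics = MetricsWindow()
    _run_stream(learner, generate_stream(protos, cfg, rng), metrics)
    config = {
        "experiment": "capacity",
        "stream": cfg.to_dict(),
        "hyperparams": learner.hp.to_dict(),
        "prototypes": [list(p.events) for p in protos],
    }
    return ExperimentResult.from_metrics(metrics, config, cfg.seed)


def snapshot_links(
    network: ConceptNetwork, terms: Optional[Iterable[str]] = None
) -> tuple:
    """Canonical, order-independent image of the link set.

    Restricted, when ``terms`` is given, to links with *both* endpoints
    in ``terms``.  Evidence amounts are included verbatim, so equal
    snapshots mean bit-identical knowledge.
    """
    keep = set(terms) if terms is not None else None
    rows = []
    for link in network.iter_links():
        st, dt = link.src.column.term, link.dst.column.term
        if keep is not None and (st not in keep or dt not in keep):
            continue
        rows.append(
            (st, link.src.index, dt, link.dst.index, link.w_pos, link.w_neg)
        )
    return tuple(sorted(rows))


def run_forgetting_experiment(
    schedule: EpisodeSchedule,
    cfg: StreamConfig,
    hp: Optional[HyperParams] = None,
    snapshot_terms: Optional[Iterable[str]] = None,
) -> ForgettingResult:
    """Train one continuous learner across an episodic schedule.

    When ``snapshot_terms`` is given (typically episode 1's alphabet),
    the link set among those terms is snapshotted at the end of every
    segment, which lets callers verify that later episodes leave earlier
    knowledge untouched.
    """
    rng = np.random.default_rng(cfg.seed)
    learner = SequenceLearner(hp)
    metrics = MetricsWindow()
    snapshots: dict[int, tuple] = {}
    watch = list(snapshot_terms) if snapshot_terms is not None else None

    def on_segment_end(segment: int) -> None:
        if watch is not None:
            snapshots[segment] = snapshot_links(learner.network, watch)

    _run_stream(
        learner, forgetting_stream(schedule, cfg, rng), metrics, on_segment_end
    )
    config = {
        "experiment": "forgetting",
        "stream": cfg.to_dict(),
        "hyperparams": learner.hp.to_dict(),
        "segments": schedule.segments,
    }
    result = ExperimentResult.from_metrics(metrics, config, cfg.seed)
    return ForgettingResult(result, result.segment_summaries(), snapshots)


def oracle_correctness(events: Sequence[Event]) -> np.ndarray:
    """Upper-bound baseline: a predictor handed the generator's own
    labels.  It anticipates the next event exactly when the current one
    sits inside a prototype and has a successor there; on those
    positions it is always correct, elsewhere never."""
    out = np.zeros(max(len(events) - 1, 0), dtype=bool)
    for i in range(len(events) - 1):
        cur, nxt = events[i], events[i + 1]
        out[i] = (
            cur.pos is not None
            and nxt.pos is not None
            and nxt.proto_id == cur.proto_id
            and nxt.pos == cur.pos + 1
        )
    return out
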