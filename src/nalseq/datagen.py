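"""Seedable synthetic event streams for capacity and forgetting studies.

A stream is an endless concatenation of *samples*.  Each sample embeds
one of ``p`` fixed *prototype* sequences of ``m`` deterministic events
inside random filler events drawn uniformly from the alphabet::

    ($, ..., $, E_1, ..., E_m, $, ..., $)

With the default of ``m`` fillers per sample exactly half of all stream
positions are deterministic, which caps the achievable next-event
prediction accuracy at about 50%.  Within a prototype every successor is
uniquely determined by its predecessor context; fillers are independent
uniform draws and may coincide with prototype terms.

Episode schedules chain several such stream segments (each with its own
prototype set, optionally its own disjoint alphabet slice) and replay
earlier episodes afterwards — the protocol used to probe catastrophic
forgetting.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Event",
    "Prototype",
    "StreamConfig",
    "EpisodeSpec",
    "EpisodeSchedule",
    "make_alphabet",
    "make_prototypes",
    "generate_stream",
    "make_forgetting_schedule",
    "forgetting_stream",
    "SIMPLE_CASE_PROTOTYPES",
]

#: The two overlapping prototypes of the introductory "simple case":
#: (A,B,C,D,E) and (X,B,C,D,Y) share their middle (B,C,D), so after the
#: shared context either continuation is plausible without the opening
#: cue.
SIMPLE_CASE_PROTOTYPES = (
    ("A", "B", "C", "D", "E"),
    ("X", "B", "C", "D", "Y"),
)


@dataclass(frozen=True)
class Event:
    """One stream position.

    ``deterministic`` marks prototype positions (vs. random fillers);
    ``proto_id``/``pos`` locate the event inside its prototype, enabling
    oracle baselines in tests.  ``episode`` is the id of the episode the
    prototypes belong to; ``segment`` numbers the contiguous stream
    segments (a replayed episode is a new segment with an old episode
    id).
    """

    t: int
    term: str
    deterministic: bool
    episode: int = 0
    segment: int = 0
    proto_id: Optional[int] = None
    pos: Optional[int] = None


@dataclass(frozen=True)
class Prototype:
    """The fixed deterministic core ``(E_1, ..., E_m)`` of a sample."""

    events: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.events) < 2:
            raise ValueError("a prototype needs at least 2 events")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class StreamConfig:
    """Parameters of a synthetic stream.

    ``fillers_per_sample`` defaults to ``m``, which fixes the
    deterministic fraction at exactly one half per sample.
    """

    n_r: int = 26
    m: int = 5
    p: int = 2
    fillers_per_sample: Optional[int] = None
    seed: int = 0
    total_steps: int = 20_000

    def __post_init__(self) -> None:
        if self.n_r < 2:
            raise ValueError("need an alphabet of at least 2 event types")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.fillers_per_sample is None:
            self.fillers_per_sample = self.m
        if self.fillers_per_sample < 0:
            raise ValueError("fillers_per_sample must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_r": self.n_r,
            "m": self.m,
            "p": self.p,
            "fillers_per_sample": self.fillers_per_sample,
            "seed": self.seed,
            "total_steps": self.total_steps,
        }


def make_alphabet(n_r: int) -> list[str]:
    """Event-type names: single letters up to 26 types, ``e0000``-style
    strings beyond."""
    if n_r <= 26:
        return list(string.ascii_uppercase[:n_r])
    width = len(str(n_r - 1))
    return [f"e{i:0{width}d}" for i in range(n_r)]


def make_prototypes(
    cfg: StreamConfig,
    rng: np.random.Generator,
    alphabet: Optional[Sequence[str]] = None,
) -> list[Prototype]:
    """Draw ``p`` random prototypes of length ``m``.

    Terms within one prototype are unique whenever the alphabet allows
    (``n_r >= m``); otherwise sampling falls back to replacement.
    Distinct prototypes may share terms — with ``p*m`` exceeding the
    alphabet size they necessarily do.
    """
    if alphabet is None:
        alphabet = make_alphabet(cfg.n_r)
    alphabet = list(alphabet)
    replace = len(alphabet) < cfg.m
    protos: list[Prototype] = []
    seen: set[tuple[str, ...]] = set()
    for _ in range(cfg.p):
        for _attempt in range(100):
            idx = rng.choice(len(alphabet), size=cfg.m, replace=replace)
            events = tuple(alphabet[i] for i in idx)
            if events not in seen:
                break
        seen.add(events)
        protos.append(Prototype(events))
    return protos


def _iter_samples(
    prototypes: Sequence[Prototype],
    fillers: int,
    alphabet: Sequence[str],
    rng: np.random.Generator,
    episode: int,
    segment: int,
) -> Iterator[Event]:
    """Endless sample generator; ``t`` is filled in by the caller."""
    n_a = len(alphabet)
    while True:
        proto_id = int(rng.integers(len(prototypes))) if len(prototypes) > 1 else 0
        proto = prototypes[proto_id]
        n_before = int(rng.integers(fillers + 1)) if fillers else 0
        for _ in range(n_before):
            yield Event(-1, alphabet[int(rng.integers(n_a))], False, episode, segment)
        for pos, term in enumerate(proto.events):
            yield Event(-1, term, True, episode, segment, proto_id, pos)
        for _ in range(fillers - n_before):
            yield Event(-1, alphabet[int(rng.integers(n_a))], False, episode, segment)


def generate_stream(
    prototypes: Sequence[Prototype],
    cfg: StreamConfig,
    rng: np.random.Generator,
    alphabet: Optional[Sequence[str]] = None,
    episode: int = 0,
    segment: int = 0,
    start_t: int = 0,
    total_steps: Optional[int] = None,
) -> Iterator[Event]:
    """Emit ``total_steps`` events (``cfg.total_steps`` by default).

    Per sample a prototype is chosen uniformly and its
    ``fillers_per_sample`` random fillers are split uniformly at random
    before/after the deterministic block.
    """
    if not prototypes:
        raise ValueError("need at least one prototype")
    if alphabet is None:
        alphabet = make_alphabet(cfg.n_r)
    if total_steps is None:
        total_steps = cfg.total_steps
    src = _iter_samples(
        prototypes, cfg.fillers_per_sample, alphabet, rng, episode, segment
    )
    for t in range(start_t, start_t + total_steps):
        ev = next(src)
        yield Event(t, ev.term, ev.deterministic, ev.episode, ev.segment,
                    ev.proto_id, ev.pos)


@dataclass
class EpisodeSpec:
    """One episode: its prototype set, step budget, and alphabet."""

    prototypes: list[Prototype]
    steps: int
    alphabet: list[str]
    episode_id: int


@dataclass
class EpisodeSchedule:
    """Episodes played in order, then the listed episodes replayed."""

    episodes: list[EpisodeSpec]
    replay: list[int] = field(default_factory=list)
    replay_steps: Optional[int] = None  # defaults to the episode's own budget

    def __post_init__(self) -> None:
        for i in self.replay:
            if not 0 <= i < len(self.episodes):
                raise ValueError(f"replay index {i} out of range")
        sets = [tuple(ep.prototypes) for ep in self.episodes]
        if len(set(sets)) != len(sets):
            raise ValueError("prototype sets must differ across episodes")

    @property
    def segments(self) -> list[tuple[int, int]]:
        """(episode_id, steps) for every segment, replays included."""
        out = [(ep.episode_id, ep.steps) for ep in self.episodes]
        for i in self.replay:
            ep = self.episodes[i]
            out.append((ep.episode_id, self.replay_steps or ep.steps))
        return out


def make_forgetting_schedule(
    cfg: StreamConfig,
    rng: np.random.Generator,
    n_episodes: int = 3,
    steps_per_episode: int = 10_000,
    replay: Sequence[int] = (0,),
    replay_steps: Optional[int] = None,
    disjoint_alphabets: bool = False,
) -> EpisodeSchedule:
    """Build the episodic protocol: ``n_episodes`` fresh prototype sets,
    then replay of the listed episodes.

    With ``disjoint_alphabets`` the alphabet is cut into equal
    per-episode slices (prototypes *and* fillers stay inside the slice),
    so episodes share no concepts at all — the strictest setting for
    verifying that new learning leaves old knowledge untouched.
    """
    full = make_alphabet(cfg.n_r)
    episodes = []
    for e in range(n_episodes):
        if disjoint_alphabets:
            size = len(full) // n_episodes
            if size < cfg.m:
                raise ValueError(
                    "alphabet too small for disjoint per-episode slices"
                )
            alphabet = full[e * size : (e + 1) * size]
        else:
            alphabet = list(full)
        protos = make_prototypes(cfg, rng, alphabet)
        episodes.append(EpisodeSpec(protos, steps_per_episode, alphabet, e))
    return EpisodeSchedule(episodes, list(replay), replay_steps)


def forgetting_stream(
    schedule: EpisodeSchedule,
    cfg: StreamConfig,
    rng: np.random.Generator,
) -> Iterator[Event]:
    """Concatenate the schedule's segments into one continuous stream."""
    if len(schedule.episodes) < 2:
        raise ValueError("an episodic schedule needs at least 2 episodes")
    t = 0
    order = [(ep, ep.steps) for ep in schedule.episodes] + [
        (
            schedule.episodes[i],
            schedule.replay_steps or schedule.episodes[i].steps,
        )
        for i in schedule.replay
    ]
    for segment, (ep, steps) in enumerate(order):
        yield from generate_stream(
            ep.prototypes,
            cfg,
            rng,
            alphabet=ep.alphabet,
            episode=ep.episode_id,
            segment=segment,
            start_t=t,
            total_steps=steps,
        )
        t += steps
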