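"""File formats: streams, configs, snapshots, traces.

Streams are plain text (one event term per line) or JSONL with one
``{"t": ..., "term": ..., "deterministic": ..., "episode": ...}`` object
per line.  Configuration is YAML (JSON is a subset and accepted).
Learner snapshots are a single JSON document containing the network, the
hyper-parameters and the transient cycle state, so a reloaded learner
continues bit-for-bit identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, Union

import yaml

from .datagen import Event
from .learner import SequenceLearner, StepResult
from .network import HyperParams

__all__ = [
    "read_stream",
    "write_stream",
    "save_learner",
    "load_learner",
    "load_hyperparams",
    "save_config",
    "write_trace",
]

PathLike = Union[str, Path]


def write_stream(events: Iterable[Event], path: PathLike) -> int:
    """Write events to ``path``; ``.jsonl`` selects the labeled format,
    anything else plain text.  Returns the number of events written."""
    path = Path(path)
    n = 0
    with path.open("w") as fh:
        if path.suffix == ".jsonl":
            for ev in events:
                fh.write(
                    json.dumps(
                        {
                            "t": ev.t,
                            "term": ev.term,
                            "deterministic": ev.deterministic,
                            "episode": ev.episode,
                            "segment": ev.segment,
                        }
                    )
                    + "\n"
                )
                n += 1
        else:
            for ev in events:
                fh.write(ev.term + "\n")
                n += 1
    return n


def read_stream(path: PathLike) -> Iterator[Event]:
    """Read a stream file written by :func:`write_stream`."""
    path = Path(path)
    with path.open() as fh:
        if path.suffix == ".jsonl":
            for t, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                d = json.loads(line)
                yield Event(
                    t=d.get("t", t),
                    term=d["term"],
                    deterministic=d.get("deterministic", False),
                    episode=d.get("episode", 0),
                    segment=d.get("segment", 0),
                )
        else:
            t = 0
            for line in fh:
                term = line.strip()
                if not term:
                    continue
                yield Event(t=t, term=term, deterministic=False)
                t += 1


def save_learner(learner: SequenceLearner, path: PathLike) -> None:
    Path(path).write_text(json.dumps(learner.to_dict()))


def load_learner(path: PathLike) -> SequenceLearner:
    return SequenceLearner.from_dict(json.loads(Path(path).read_text()))


def load_hyperparams(path: PathLike) -> HyperParams:
    """Load hyper-parameters from a YAML/JSON config file; keys may sit
    at the top level or under a ``hyperparams`` section."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "hyperparams" in data:
        data = data["hyperparams"]
    return HyperParams.from_dict(data)


def save_config(config: dict, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def write_trace(results: Iterable[StepResult], path: PathLike) -> int:
    """Write a JSONL trace, one working cycle per line."""
    n = 0
    with Path(path).open("w") as fh:
        for res in results:
            fh.write(json.dumps(res.to_dict()) + "\n")
            n += 1
    return n
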