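"""The working cycle: online learning over one event per timestep.

Each cycle handles a single input event end to end:

1. fetch (or create) the event's column;
2. activate nodes against the anticipations left by the previous step;
3. collect evidence — one unit of positive evidence for the strongest
   known-cause link, negative evidence for anticipations that failed,
   and a contradiction charge for links whose consequent fired while
   their antecedent stayed silent in the antecedent's own column;
4. hypothesize a fresh weak link when no known cause explains the event;
5. recycle any queue pushed over capacity;
6. depolarize: derive anticipations for the next step by temporal
   deduction over strong outgoing links;
7. expire the previous step's anticipations (they last exactly one
   timestep).

Hypothesizing and revising are mutually exclusive within a cycle: a
known cause is revised, an unknown cause is hypothesized, never both.
All knowledge updates touch only links incident to nodes active or
anticipated at the current or previous step, so learning one stream
cannot disturb concepts that never take part in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .network import (
    Anticipation,
    ConceptNetwork,
    HyperParams,
    HYPOTHESIS_TRUTH,
    Link,
    Node,
    node_utility,
)
from .truth import TruthValue

__all__ = [
    "StepResult",
    "SequenceLearner",
    "select_revision_link",
    "apply_positive_evidence",
    "apply_negative_evidence",
    "apply_unverified_penalty",
    "hypothesize",
]


@dataclass
class StepResult:
    """Explainability trace of one working cycle."""

    t: int
    term: str
    active_nodes: tuple[tuple[str, int], ...]
    anticipated: dict[tuple[str, int], TruthValue]
    anticipated_concepts: frozenset[str]
    fallback: bool
    links_created: int = 0
    links_revised: int = 0
    links_removed: int = 0
    #: (link id, "w+"/"w-", amount) for every piece of evidence applied,
    #: including the birth evidence of a hypothesized link.
    evidence_log: list[tuple[str, str, float]] = field(default_factory=list)
    #: Number of nodes/links examined this cycle (resource-bound probe).
    touched: int = 0

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "term": self.term,
            "active_nodes": [list(x) for x in self.active_nodes],
            "anticipated": {
                f"{term}({idx})": [tv.f, tv.c]
                for (term, idx), tv in self.anticipated.items()
            },
            "anticipated_concepts": sorted(self.anticipated_concepts),
            "fallback": self.fallback,
            "links_created": self.links_created,
            "links_revised": self.links_revised,
            "links_removed": self.links_removed,
            "evidence_log": [list(e) for e in self.evidence_log],
            "touched": self.touched,
        }


def select_revision_link(
    active_nodes: list[Node], prev_active_ids: set[int]
) -> Optional[Link]:
    """Pick the known-cause link to revise: the highest-expectation
    pre-link of the activated nodes whose source was active at the
    previous step.  Ties resolve by lowest (source index, target index,
    age).  Returns ``None`` when no known cause exists.
    """
    best: Optional[Link] = None
    best_key: tuple = ()
    for node in active_nodes:
        for link in node.pre_links:
            if id(link.src) not in prev_active_ids:
                continue
            key = (-link.expectation, link.src.index, link.dst.index, link.seq)
            if best is None or key < best_key:
                best, best_key = link, key
    return best


def apply_positive_evidence(link: Link, p_pos: float) -> TruthValue:
    """Confirmations add ``p_pos`` units of positive evidence."""
    return link.add_evidence(w_pos=p_pos)


def apply_negative_evidence(link: Link, p_neg: float) -> TruthValue:
    """Contradictions add ``p_neg`` units of negative evidence."""
    return link.add_evidence(w_neg=p_neg)


def apply_unverified_penalty(
    node: Node, theta: float, b: float
) -> Optional[TruthValue]:
    """Charge a fallback-fired node's unverified speculative predictions.

    Each post-link with expectation above ``theta`` receives
    ``w- = (number of such links)/b``; with ``b`` infinite no penalty is
    applied.  Returns the last updated truth, or ``None`` if nothing
    changed.
    """
    import math

    if math.isinf(b):
        return None
    strong = [L for L in node.post_links if L.expectation > theta]
    if not strong:
        return None
    w_neg = len(strong) / b
    out = None
    for link in strong:
        out = link.add_evidence(w_neg=w_neg)
    return out


def hypothesize(
    network: ConceptNetwork,
    prev_active: list[Node],
    cur_active: list[Node],
) -> tuple[Optional[Link], list[Link]]:
    """Speculate an unknown cause: link the lowest-utility node of the
    previously active set to the lowest-utility node of the currently
    active set, with the weak initial truth ``<1.0; 0.1>``.

    Returns ``(None, [])`` when that pair is already linked (the pair is
    then a known cause waiting for confirmation, not a new hypothesis).
    """
    src = min(prev_active, key=lambda n: (node_utility(n), n.index))
    dst = min(cur_active, key=lambda n: (node_utility(n), n.index))
    if network.find_link(src, dst) is not None:
        return None, []
    link, evicted = network.add_link(src, dst, HYPOTHESIS_TRUTH)
    return link, evicted


class SequenceLearner:
    """Online, life-long learner over a stream of discrete events."""

    def __init__(self, hp: Optional[HyperParams] = None) -> None:
        self.hp = hp if hp is not None else HyperParams()
        self.network = ConceptNetwork(self.hp)
        self._t = -1
        self._prev_term: Optional[str] = None
        self._prev_active: list[Node] = []
        self._prev_active_ids: set[int] = set()
        self._pending: dict[Node, Anticipation] = {}

    @property
    def t(self) -> int:
        """Timestep of the last processed event (-1 before any input)."""
        return self._t

    @property
    def anticipated_concepts(self) -> frozenset[str]:
        return frozenset(n.column.term for n in self._pending)

    def step(self, term: str, t: Optional[int] = None) -> StepResult:
        """Process the event ``term`` occurring at timestep ``t``.

        ``t`` defaults to the next timestep and must be strictly
        increasing.
        """
        if not term:
            raise ValueError("event term must be a non-empty string")
        if t is None:
            t = self._t + 1
        elif t <= self._t:
            raise ValueError(
                f"timesteps must be strictly increasing (got {t} after {self._t})"
            )
        hp = self.hp
        net = self.network
        evidence_log: list[tuple[str, str, float]] = []
        links_revised = 0
        links_created = 0
        links_removed = 0

        # (1)-(2) column lookup and activation against pending anticipations
        col = net.get_or_create_column(term)
        active, fallback = net.activate_column(col, t)
        touched = len(col.nodes)

        # (3a) positive evidence for the strongest known cause
        rev_link = select_revision_link(active, self._prev_active_ids)
        for node in active:
            touched += len(node.pre_links)
        if rev_link is not None:
            apply_positive_evidence(rev_link, hp.p_pos)
            evidence_log.append((rev_link.id, "w+", hp.p_pos))
            links_revised += 1

        # (3b) negative evidence for anticipations that were not borne
        # out.  Any unverified anticipation costs its generating link
        # the mild penalty fixed at issue time (count of strong
        # post-links over b).  An anticipated node silenced by lateral
        # inhibition inside its own occurring column is a sharper
        # verdict — the recognized context contradicts it outright — and
        # costs the full p_neg instead.
        for node, ant in self._pending.items():
            touched += len(ant.sources)
            in_col = node.column is col
            if in_col and node.active:
                continue  # confirmed
            for link, w_fail, speculative in ant.sources:
                if not link.alive or link is rev_link:
                    continue
                w = hp.p_neg if in_col else w_fail
                if w <= 0.0:
                    continue
                link.add_evidence(w_neg=w)
                evidence_log.append((link.id, "w-ant", w))
                links_revised += 1

        # (3c) contradiction: when a node fires in a recognized context,
        # every pre-link whose antecedent sat silent at the previous
        # step is one-sidedly satisfied and collects negative evidence.
        # A whole-column fallback firing activates nodes
        # indiscriminately and passes no such verdict.
        if self._prev_term is not None and not fallback:
            for node in active:
                for link in list(node.pre_links):
                    if link is rev_link or not link.alive:
                        continue
                    if id(link.src) not in self._prev_active_ids:
                        apply_negative_evidence(link, hp.p_neg)
                        evidence_log.append((link.id, "w-con", hp.p_neg))
                        links_revised += 1

        # (4)-(5) hypothesize an unknown cause; recycle overflowing queues
        if rev_link is None and self._prev_active:
            new_link, evicted = hypothesize(net, self._prev_active, active)
            if new_link is not None:
                links_created += 1
                links_removed += len(evicted)
                if new_link.alive:
                    evidence_log.append((new_link.id, "w+", new_link.w_pos))

        # (6) depolarize: anticipations for t+1
        pending = net.depolarize(active, fallback)
        for node in active:
            touched += len(node.post_links)

        # (7) expire old anticipations; install the new ones
        for node in self._pending:
            node.anticipation = None
        for node, ant in pending.items():
            node.anticipation = ant.truth
        self._pending = pending

        self._prev_term = term
        self._prev_active = active
        self._prev_active_ids = {id(n) for n in active}
        self._t = t

        touched += links_created + links_removed
        return StepResult(
            t=t,
            term=term,
            active_nodes=tuple((term, n.index) for n in active),
            anticipated={
                (n.column.term, n.index): a.truth for n, a in pending.items()
            },
            anticipated_concepts=frozenset(
                n.column.term for n in pending
            ),
            fallback=fallback,
            links_created=links_created,
            links_revised=links_revised,
            links_removed=links_removed,
            evidence_log=evidence_log,
            touched=touched,
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        node_key = lambda n: [n.column.term, n.index]  # noqa: E731
        return {
            "network": self.network.to_dict(),
            "timestep": self._t,
            "prev_term": self._prev_term,
            "prev_active": [node_key(n) for n in self._prev_active],
            "pending": [
                {
                    "node": node_key(n),
                    "truth": [a.truth.f, a.truth.c],
                    "sources": [
                        {
                            "src": node_key(L.src),
                            "dst": node_key(L.dst),
                            "w_fail": w_fail,
                            "speculative": spec,
                        }
                        for L, w_fail, spec in a.sources
                    ],
                }
                for n, a in self._pending.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceLearner":
        net = ConceptNetwork.from_dict(d["network"])
        learner = cls(net.hp)
        learner.network = net

        def find_node(key: list) -> Node:
            return net.columns[key[0]].nodes[key[1] - 1]

        learner._t = d.get("timestep", -1)
        learner._prev_term = d.get("prev_term")
        learner._prev_active = [find_node(k) for k in d.get("prev_active", [])]
        learner._prev_active_ids = {id(n) for n in learner._prev_active}
        for n in learner._prev_active:
            n.active = True
        pending: dict[Node, Anticipation] = {}
        for pd in d.get("pending", []):
            node = find_node(pd["node"])
            truth = TruthValue(*pd["truth"])
            sources = []
            for sd in pd["sources"]:
                link = net.find_link(find_node(sd["src"]), find_node(sd["dst"]))
                if link is not None:
                    sources.append(
                        (link, sd["w_fail"], sd.get("speculative", False))
                    )
            pending[node] = Anticipation(truth, sources)
            node.anticipation = truth
        learner._pending = pending
        return learner
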