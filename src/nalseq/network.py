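"""The conceptual network: columns, context-sensitive nodes, bounded links.

The learner's memory is a graph.  Each distinct event term owns one
*column* (the concept); a column holds a fixed number ``n_c`` of *nodes*,
each standing for the concept in one temporal context — the same event
can mean different things in different sequences.  A *link* is a
predictive-equivalence statement between two nodes carrying an NAL truth
value; it is the unit of learned knowledge.

Resource bounds are enforced structurally: every node keeps at most
``xi`` incoming and at most ``xi`` outgoing links in utility-ordered
queues, and the lowest-utility links are recycled whenever a queue
overflows.  A working cycle therefore touches a number of objects
bounded by a function of ``n_c`` and ``xi`` alone, independent of how
many concepts the network has accumulated.

Node dynamics per timestep:

* *activation* — when a column's event occurs, the nodes whose
  anticipation expectation exceeds ``zeta`` fire; if none does (no
  recognized context) the whole column fires.
* *depolarization* (anticipation) — an active node primes the targets of
  its strong (expectation above ``theta``) outgoing links for the next
  timestep, with the anticipation truth derived by temporal deduction.
  Anticipations expire after exactly one timestep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .truth import (
    DEFAULT_K,
    TruthValue,
    Evidence,
    evidence_from_truth,
    expectation,
    deduction,
    revision,
)

__all__ = [
    "HYPOTHESIS_TRUTH",
    "HyperParams",
    "Link",
    "LinkQueue",
    "Node",
    "Column",
    "Anticipation",
    "ConceptNetwork",
    "LinkExistsError",
    "node_expectation",
    "node_utility",
    "link_utility",
]

#: Initial truth value of a hypothesized link: full frequency, very low
#: confidence (one ninth of a unit of positive evidence at k=1).  Its
#: expectation is 0.55 — too weak to trigger an anticipation.
HYPOTHESIS_TRUTH = TruthValue(1.0, 0.1)


class LinkExistsError(ValueError):
    """Raised when adding a link between an already-linked node pair."""


@dataclass
class HyperParams:
    """Model hyper-parameters.

    Attributes
    ----------
    n_c : int
        Nodes per column, i.e. how many distinct temporal contexts one
        concept can keep apart.  The default is sized for the heaviest
        workload studied here (20 prototypes of length 14 over a
        26-letter alphabet puts ~11 contexts on an average concept,
        with a tail approaching 18).
    xi : int
        Capacity of each node's pre- and post-link queue.
    theta : float
        Anticipation threshold on link expectation: only links with
        ``e(L) > theta`` propagate predictions.  Must exceed the
        expectation of a fresh hypothesis (0.55) so that unconfirmed
        links stay silent.
    zeta : float
        Activation threshold on node expectation: a node fires
        selectively when its anticipation expectation exceeds ``zeta``.
        Must exceed the neutral 0.5.
    p_pos, p_neg : float
        Units of positive / negative evidence per confirmation /
        contradiction.
    b : float
        Penalty divisor for unverified anticipations issued by a
        whole-column (context-free) firing; ``math.inf`` disables the
        penalty.
    k : float
        Evidential horizon used in all truth/evidence conversions.
    event_truth : TruthValue
        The constant truth value assigned to an observed event.
    """

    n_c: int = 20
    xi: int = 6
    theta: float = 0.7
    zeta: float = 0.6
    p_pos: float = 1.0
    p_neg: float = 1.0
    b: float = 40.0
    k: float = DEFAULT_K
    event_truth: TruthValue = field(default_factory=lambda: TruthValue(1.0, 0.9))

    def __post_init__(self) -> None:
        if self.n_c < 1:
            raise ValueError("n_c must be >= 1")
        if self.xi < 1:
            raise ValueError("xi must be >= 1")
        if not 0.0 < self.theta < 1.0 or not 0.0 < self.zeta < 1.0:
            raise ValueError("theta and zeta must lie in (0, 1)")
        if self.theta <= expectation(HYPOTHESIS_TRUTH):
            raise ValueError(
                "theta must exceed the expectation of a fresh hypothesis "
                f"({expectation(HYPOTHESIS_TRUTH)}), got {self.theta}"
            )
        if self.zeta <= 0.5:
            raise ValueError("zeta must exceed the neutral expectation 0.5")
        if self.p_pos <= 0.0 or self.p_neg <= 0.0:
            raise ValueError("p_pos and p_neg must be positive")
        if self.b <= 0.0:
            raise ValueError("b must be positive (math.inf disables the penalty)")
        if self.k <= 0.0:
            raise ValueError("k must be positive")

    def to_dict(self) -> dict:
        return {
            "n_c": self.n_c,
            "xi": self.xi,
            "theta": self.theta,
            "zeta": self.zeta,
            "p_pos": self.p_pos,
            "p_neg": self.p_neg,
            "b": "inf" if math.isinf(self.b) else self.b,
            "k": self.k,
            "event_truth": [self.event_truth.f, self.event_truth.c],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        d = dict(d)
        b = d.get("b", 40.0)
        if isinstance(b, str):
            b = math.inf if b in ("inf", "Infinity", ".inf") else float(b)
        et = d.get("event_truth", [1.0, 0.9])
        if isinstance(et, (list, tuple)):
            et = TruthValue(float(et[0]), float(et[1]))
        return cls(
            n_c=int(d.get("n_c", 20)),
            xi=int(d.get("xi", 6)),
            theta=float(d.get("theta", 0.7)),
            zeta=float(d.get("zeta", 0.6)),
            p_pos=float(d.get("p_pos", 1.0)),
            p_neg=float(d.get("p_neg", 1.0)),
            b=b,
            k=float(d.get("k", DEFAULT_K)),
            event_truth=et,
        )


class Link:
    """A predictive-equivalence statement ``src <=> dst`` with evidence.

    The link stores raw evidence amounts; frequency, confidence and
    expectation are derived on demand.  Storing evidence (rather than a
    truth value) makes repeated revision exact: every update is a plain
    addition.
    """

    __slots__ = ("src", "dst", "w_pos", "w_neg", "k", "seq", "alive")

    def __init__(
        self,
        src: "Node",
        dst: "Node",
        w_pos: float,
        w_neg: float,
        k: float,
        seq: int,
    ) -> None:
        self.src = src
        self.dst = dst
        self.w_pos = w_pos
        self.w_neg = w_neg
        self.k = k
        self.seq = seq  # global creation counter; deterministic tie-break
        self.alive = True

    @property
    def evidence(self) -> Evidence:
        return Evidence(self.w_pos, self.w_neg)

    @property
    def truth(self) -> TruthValue:
        w = self.w_pos + self.w_neg
        return TruthValue(min(self.w_pos / w, 1.0), w / (w + self.k))

    @property
    def expectation(self) -> float:
        w = self.w_pos + self.w_neg
        f = self.w_pos / w
        c = w / (w + self.k)
        return c * (f - 0.5) + 0.5

    @property
    def id(self) -> str:
        return (
            f"{self.src.column.term}({self.src.index})->"
            f"{self.dst.column.term}({self.dst.index})#{self.seq}"
        )

    def add_evidence(self, w_pos: float = 0.0, w_neg: float = 0.0) -> TruthValue:
        self.w_pos += w_pos
        self.w_neg += w_neg
        return self.truth

    def detach(self) -> None:
        """Remove this link from both endpoint queues."""
        self.src.post_links.discard(self)
        self.dst.pre_links.discard(self)
        self.alive = False

    def __repr__(self) -> str:  # pragma: no cover
        tv = self.truth
        return f"<Link {self.id} <{tv.f:.3f};{tv.c:.3f}>>"


class LinkQueue:
    """A bounded, utility-ordered collection of links.

    Order is maintained lazily: entries are kept in insertion order and
    sorted by utility only when the queue overflows and must be
    recycled.
    """

    __slots__ = ("capacity", "entries")

    def __init__(self, capacity: int) -> None:
        self.capacity = capacity
        self.entries: list[Link] = []

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Link]:
        return iter(self.entries)

    def add(self, link: Link) -> None:
        self.entries.append(link)

    def discard(self, link: Link) -> None:
        try:
            self.entries.remove(link)
        except ValueError:
            pass

    def recycle(self) -> list[Link]:
        """Drop the lowest-utility links until the queue fits its capacity.

        Exactly ``max(0, n_L - xi)`` links are removed; utility ties are
        broken by age (older links go first).  Removed links are
        detached from both endpoint queues.
        """
        n_over = len(self.entries) - self.capacity
        if n_over <= 0:
            return []
        victims = sorted(self.entries, key=lambda L: (L.expectation, L.seq))[:n_over]
        for link in victims:
            link.detach()
        return victims


class Node:
    """One context-sensitive sense of a concept.

    ``active`` and ``anticipation`` are per-timestep states managed by
    the learner; anticipations expire after one step.
    """

    __slots__ = (
        "column",
        "index",
        "pre_links",
        "post_links",
        "active",
        "anticipation",
        "last_active_t",
    )

    def __init__(self, column: "Column", index: int, xi: int) -> None:
        self.column = column
        self.index = index  # 1-based, per the column ordering
        self.pre_links = LinkQueue(xi)
        self.post_links = LinkQueue(xi)
        self.active = False
        self.anticipation: Optional[TruthValue] = None
        self.last_active_t: Optional[int] = None

    @property
    def name(self) -> str:
        return f"{self.column.term}({self.index})"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Node {self.name}>"


class Column:
    """A concept: a named mini-column of ``n_c`` nodes."""

    __slots__ = ("term", "nodes")

    def __init__(self, term: str, n_c: int, xi: int) -> None:
        self.term = term
        self.nodes: tuple[Node, ...] = tuple(
            Node(self, i + 1, xi) for i in range(n_c)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Column {self.term!r} ({len(self.nodes)} nodes)>"


def node_expectation(node: Node) -> float:
    """Expectation of a node's anticipation state; 0.5 when absent."""
    if node.anticipation is None:
        return 0.5
    return expectation(node.anticipation)


def node_utility(node: Node) -> float:
    """How unambiguous a node's meaning is: ``1 - (1-u1)(1-u2)`` with
    ``u1``/``u2`` the best pre-/post-link expectation (0 if none).

    High-utility nodes anchor well-established chains and should not be
    disturbed by new hypotheses; hypothesizing targets the lowest-utility
    node.
    """
    u1 = max((L.expectation for L in node.pre_links), default=0.0)
    u2 = max((L.expectation for L in node.post_links), default=0.0)
    return 1.0 - (1.0 - u1) * (1.0 - u2)


def link_utility(link: Link) -> float:
    """Priority of a link in its queues: the expectation of its truth."""
    return link.expectation


@dataclass
class Anticipation:
    """A node's anticipation for the next timestep.

    ``truth`` is the revision-merged truth of all contributing
    deductions; ``sources`` records each generating link, the amount of
    negative evidence a failure costs it, and whether the prediction was
    speculative (issued by a whole-column fallback firing) rather than
    grounded in a recognized context.
    """

    truth: TruthValue
    sources: list[tuple[Link, float, bool]]


class ConceptNetwork:
    """Registry of columns plus the activation/anticipation dynamics."""

    def __init__(self, hp: Optional[HyperParams] = None) -> None:
        self.hp = hp if hp is not None else HyperParams()
        self.columns: dict[str, Column] = {}
        self._link_seq = 0

    # -- structure ---------------------------------------------------------

    def get_or_create_column(self, term: str) -> Column:
        """Return the column for ``term``, creating it on first sight."""
        if not term:
            raise ValueError("event term must be a non-empty string")
        col = self.columns.get(term)
        if col is None:
            col = Column(term, self.hp.n_c, self.hp.xi)
            self.columns[term] = col
        return col

    def find_link(self, src: Node, dst: Node) -> Optional[Link]:
        for link in src.post_links:
            if link.dst is dst:
                return link
        return None

    def add_link(
        self,
        src: Node,
        dst: Node,
        truth: TruthValue = HYPOTHESIS_TRUTH,
    ) -> tuple[Link, list[Link]]:
        """Create the link ``src -> dst`` and recycle overflowing queues.

        Returns the new link together with any links evicted to make
        room (possibly including the new link itself, if it is the
        weakest).
        """
        if self.find_link(src, dst) is not None:
            raise LinkExistsError(
                f"link {src.name}->{dst.name} exists; revise instead"
            )
        ev = evidence_from_truth(truth, self.hp.k)
        self._link_seq += 1
        link = Link(src, dst, ev.w_pos, ev.w_neg, self.hp.k, self._link_seq)
        src.post_links.add(link)
        dst.pre_links.add(link)
        evicted = src.post_links.recycle()
        evicted += dst.pre_links.recycle()
        return link, evicted

    def iter_links(self) -> Iterator[Link]:
        for col in self.columns.values():
            for node in col.nodes:
                yield from node.post_links

    @property
    def n_links(self) -> int:
        return sum(1 for _ in self.iter_links())

    # -- dynamics ----------------------------------------------------------

    def activate_column(
        self, col: Column, t: Optional[int] = None
    ) -> tuple[list[Node], bool]:
        """Fire the column for an occurrence of its event.

        Nodes whose anticipation expectation strictly exceeds ``zeta``
        fire selectively (lateral inhibition silences the rest); if no
        node was anticipated strongly enough, the whole column fires —
        the system entertains every context at once.  Returns the active
        nodes and whether the whole-column fallback applied.  The result
        is never empty.
        """
        zeta = self.hp.zeta
        winners = [n for n in col.nodes if node_expectation(n) > zeta]
        fallback = not winners
        active = list(col.nodes) if fallback else winners
        for node in col.nodes:
            node.active = False
        for node in active:
            node.active = True
            if t is not None:
                node.last_active_t = t
        return active, fallback

    def depolarize(
        self,
        active_nodes: list[Node],
        fallback: bool,
    ) -> dict[Node, Anticipation]:
        """Prime next-step anticipations from the active nodes.

        Every post-link with expectation above ``theta`` deposits on its
        target an anticipation whose truth is the temporal deduction of
        the link truth with the (constant) event truth; multiple
        anticipations of one node merge by revision.

        Each anticipation also carries the mild negative evidence its
        generating link pays if the prediction goes unverified:
        ``(number of strong post-links of the generating node)/b``, zero
        when ``b`` is infinite.  A sharper verdict — the full ``p_neg``
        — is reserved for anticipated nodes silenced by lateral
        inhibition inside their own occurring column, and is decided by
        the learner, not here.
        """
        hp = self.hp
        pending: dict[Node, Anticipation] = {}
        for node in active_nodes:
            strong = [L for L in node.post_links if L.expectation > hp.theta]
            w_fail = 0.0 if math.isinf(hp.b) else len(strong) / hp.b
            for link in strong:
                tv = deduction(link.truth, hp.event_truth)
                ant = pending.get(link.dst)
                if ant is None:
                    pending[link.dst] = Anticipation(tv, [(link, w_fail, fallback)])
                else:
                    ant.truth = revision(ant.truth, tv, hp.k)
                    ant.sources.append((link, w_fail, fallback))
        return pending

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        cols = []
        for col in self.columns.values():
            nodes = []
            for node in col.nodes:
                links_out = [
                    {
                        "dst_term": L.dst.column.term,
                        "dst_index": L.dst.index,
                        "f": L.truth.f,
                        "c": L.truth.c,
                        "w_pos": L.w_pos,
                        "w_neg": L.w_neg,
                        "seq": L.seq,
                    }
                    for L in node.post_links
                ]
                nodes.append({"index": node.index, "links_out": links_out})
            cols.append({"term": col.term, "nodes": nodes})
        return {
            "hyperparams": self.hp.to_dict(),
            "link_seq": self._link_seq,
            "columns": cols,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConceptNetwork":
        net = cls(HyperParams.from_dict(d["hyperparams"]))
        for cd in d["columns"]:
            net.get_or_create_column(cd["term"])
        records = []
        for cd in d["columns"]:
            col = net.columns[cd["term"]]
            for nd in cd["nodes"]:
                src = col.nodes[nd["index"] - 1]
                for ld in nd["links_out"]:
                    records.append((ld.get("seq", 0), src, ld))
        records.sort(key=lambda r: r[0])
        for seq, src, ld in records:
            dst = net.columns[ld["dst_term"]].nodes[ld["dst_index"] - 1]
            if "w_pos" in ld:
                w_pos, w_neg = ld["w_pos"], ld["w_neg"]
            else:
                ev = evidence_from_truth(TruthValue(ld["f"], ld["c"]), net.hp.k)
                w_pos, w_neg = ev.w_pos, ev.w_neg
            link = Link(src, dst, w_pos, w_neg, net.hp.k, seq)
            src.post_links.add(link)
            dst.pre_links.add(link)
        net._link_seq = max(
            [d.get("link_seq", 0)] + [L.seq for L in net.iter_links()]
        )
        return net
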