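"""Render learned knowledge as Narsese statements.

Every link is a predictive-equivalence statement between two contextual
concepts and exports as one line, e.g.::

    <A(1) =|> B(2)>. %1.00;0.81%

The copula is rendered in plain ASCII and the truth value with two
decimals by default; the dialect is presentational only.

Beyond single links, maximal chains of strong links encode compound
knowledge: the chain ``A -> B -> C -> D`` simultaneously asserts
``<A =|> B>``, ``<(A, B) =|> C>`` and ``<(A, B, C) =|> D>``.  The chain
expansion walks strong links (expectation above ``theta``), starting
from chain heads (nodes without a strong incoming link) and following
the strongest outgoing link; cycles are walked once from their smallest
node.
"""

from __future__ import annotations

from typing import Optional

from .network import ConceptNetwork, Node

__all__ = ["export_narsese"]


def _link_line(link, decimals: int) -> str:
    tv = link.truth
    return (
        f"<{link.src.name} =|> {link.dst.name}>. "
        f"%{tv.f:.{decimals}f};{tv.c:.{decimals}f}%"
    )


def _strong_successor(node: Node, theta: float) -> Optional[Node]:
    best = None
    best_key = ()
    for link in node.post_links:
        e = link.expectation
        if e <= theta:
            continue
        key = (-e, link.dst.column.term, link.dst.index)
        if best is None or key < best_key:
            best, best_key = link.dst, key
    return best


def _chains(network: ConceptNetwork, theta: float) -> list[list[Node]]:
    strong_in: set[int] = set()
    nodes: list[Node] = []
    for col in network.columns.values():
        for node in col.nodes:
            nodes.append(node)
            for link in node.post_links:
                if link.expectation > theta:
                    strong_in.add(id(link.dst))
    heads = [
        n
        for n in nodes
        if id(n) not in strong_in and _strong_successor(n, theta) is not None
    ]
    if not heads:
        # purely cyclic chains (e.g. a periodic stream): walk each cycle
        # once, starting from its lexicographically smallest member
        heads = [n for n in nodes if _strong_successor(n, theta) is not None]
    chains: list[list[Node]] = []
    visited: set[int] = set()
    for head in sorted(heads, key=lambda n: (n.column.term, n.index)):
        if id(head) in visited:
            continue
        chain, cur, on_path = [], head, set()
        while (
            cur is not None and id(cur) not in on_path and id(cur) not in visited
        ):
            on_path.add(id(cur))
            chain.append(cur)
            cur = _strong_successor(cur, theta)
        visited.update(on_path)
        if len(chain) >= 2:
            chains.append(chain)
    return chains


def export_narsese(
    network: ConceptNetwork,
    include_chains: bool = True,
    decimals: int = 2,
    theta: Optional[float] = None,
) -> str:
    """Serialize the network's links (and optionally its strong chains)
    as Narsese text; empty network gives an empty string."""
    if theta is None:
        theta = network.hp.theta
    lines = [
        _link_line(link, decimals)
        for link in sorted(
            network.iter_links(),
            key=lambda L: (
                L.src.column.term,
                L.src.index,
                L.dst.column.term,
                L.dst.index,
            ),
        )
    ]
    if include_chains:
        for chain in _chains(network, theta):
            for i in range(2, len(chain)):
                antecedent = ", ".join(n.column.term for n in chain[:i])
                lines.append(f"<({antecedent}) =|> {chain[i].column.term}>.")
    return "\n".join(lines) + ("\n" if lines else "")
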