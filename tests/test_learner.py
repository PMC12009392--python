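"""The working cycle: hypothesizing, revising, recycling, anticipating."""

import itertools
import json

import numpy as np
import pytest

from nalseq import (
    HYPOTHESIS_TRUTH,
    HyperParams,
    Prototype,
    SequenceLearner,
    StreamConfig,
    TruthValue,
    generate_stream,
    snapshot_links,
)
from nalseq.learner import (
    apply_negative_evidence,
    apply_positive_evidence,
    apply_unverified_penalty,
    hypothesize,
    select_revision_link,
)


@pytest.fixture
def learner(hp_small):
    return SequenceLearner(hp_small)


def chain_learner(hp, sequence, repeats):
    """Train a learner on `sequence` repeated `repeats` times."""
    lr = SequenceLearner(hp)
    for term in itertools.chain.from_iterable([sequence] * repeats):
        lr.step(term)
    return lr


class TestStepBasics:
    def test_first_event_fires_whole_column_quietly(self, learner):
        res = learner.step("A", 0)
        assert res.fallback
        assert len(res.active_nodes) == learner.hp.n_c
        assert res.anticipated == {}
        assert res.links_created == res.links_revised == 0

    def test_second_event_hypothesizes_weak_link(self, learner):
        learner.step("A", 0)
        res = learner.step("B", 1)
        assert res.links_created == 1
        links = list(learner.network.iter_links())
        assert len(links) == 1
        link = links[0]
        assert link.src.column.term == "A" and link.dst.column.term == "B"
        # lowest-utility tie resolves to the first node on both sides
        assert link.src.index == 1 and link.dst.index == 1
        assert link.truth == HYPOTHESIS_TRUTH

    def test_trained_pair_anticipates_successor(self, learner):
        # first A,B hypothesizes the link; the second confirms it
        # (e: 0.55 -> 0.76 > theta), so the third A anticipates B
        for t, term in enumerate(["A", "B", "A", "B", "A"]):
            res = learner.step(term, t)
        assert "B" in res.anticipated_concepts

    def test_monotonic_time_enforced(self, learner):
        learner.step("A", 5)
        with pytest.raises(ValueError):
            learner.step("B", 5)

    def test_empty_term_rejected(self, learner):
        with pytest.raises(ValueError):
            learner.step("")


class TestEvidenceOperations:
    def test_positive_evidence_strengthens(self, network):
        a = network.get_or_create_column("A").nodes[0]
        b = network.get_or_create_column("B").nodes[0]
        link, _ = network.add_link(a, b)  # <1.0;0.1>, w+ = 1/9
        tv = apply_positive_evidence(link, 1.0)
        assert tv.f == pytest.approx(1.0)
        assert tv.c == pytest.approx(10.0 / 19.0, abs=1e-9)  # ~0.526
        tv = apply_positive_evidence(link, 1.0)
        assert tv.c == pytest.approx(19.0 / 28.0, abs=1e-9)  # ~0.679

    def test_zero_positive_evidence_is_noop(self, network):
        a = network.get_or_create_column("A").nodes[0]
        b = network.get_or_create_column("B").nodes[0]
        link, _ = network.add_link(a, b)
        before = link.truth
        apply_positive_evidence(link, 0.0)
        assert link.truth == before

    def test_negative_evidence_lowers_frequency(self, network):
        a = network.get_or_create_column("A").nodes[0]
        b = network.get_or_create_column("B").nodes[0]
        link, _ = network.add_link(a, b, TruthValue(1.0, 0.5))  # w+ = 1
        tv = apply_negative_evidence(link, 1.0)
        assert tv.f == pytest.approx(0.5)
        assert tv.c == pytest.approx(2.0 / 3.0)
        tv2 = apply_negative_evidence(link, 1.0)
        assert tv2.f < 0.5 and tv2.c > tv.c

    def test_unverified_penalty_divides_by_b(self, network):
        a = network.get_or_create_column("A").nodes[0]
        b = network.get_or_create_column("B").nodes[0]
        c = network.get_or_create_column("C").nodes[0]
        l1, _ = network.add_link(a, b, TruthValue(1.0, 0.81))
        l2, _ = network.add_link(a, c, TruthValue(1.0, 0.81))
        apply_unverified_penalty(a, theta=0.7, b=40.0)
        assert l1.w_neg == pytest.approx(0.05)
        assert l2.w_neg == pytest.approx(0.05)

    def test_unverified_penalty_disabled_at_infinite_b(self, network):
        a = network.get_or_create_column("A").nodes[0]
        b = network.get_or_create_column("B").nodes[0]
        link, _ = network.add_link(a, b, TruthValue(1.0, 0.81))
        assert apply_unverified_penalty(a, theta=0.7, b=float("inf")) is None
        assert link.w_neg == 0.0


class TestSelection:
    def test_argmax_expectation_wins(self, network):
        a = network.get_or_create_column("A")
        b = network.get_or_create_column("B")
        weak, _ = network.add_link(a.nodes[0], b.nodes[0])  # e = 0.55
        strong, _ = network.add_link(
            a.nodes[1], b.nodes[1], TruthValue(1.0, 0.81)
        )
        prev = {id(a.nodes[0]), id(a.nodes[1])}
        assert select_revision_link(list(b.nodes), prev) is strong

    def test_requires_previously_active_source(self, network):
        a = network.get_or_create_column("A")
        b = network.get_or_create_column("B")
        network.add_link(a.nodes[0], b.nodes[0], TruthValue(1.0, 0.81))
        assert select_revision_link(list(b.nodes), {id(a.nodes[1])}) is None

    def test_tie_breaks_on_lowest_indices(self, network):
        a = network.get_or_create_column("A")
        b = network.get_or_create_column("B")
        l23, _ = network.add_link(a.nodes[2], b.nodes[2])
        l11, _ = network.add_link(a.nodes[1], b.nodes[1])
        prev = {id(n) for n in a.nodes}
        assert select_revision_link(list(b.nodes), prev) is l11

    def test_hypothesize_avoids_high_utility_nodes(self, network):
        a = network.get_or_create_column("A")
        b = network.get_or_create_column("B")
        c = network.get_or_create_column("C")
        # give A(1) a strong post-link: utility ~0.9
        network.add_link(a.nodes[0], c.nodes[0], TruthValue(1.0, 0.81))
        link, _ = hypothesize(network, list(a.nodes), list(b.nodes))
        assert link.src is a.nodes[1]  # the busy node was spared
        assert link.dst is b.nodes[0]

    def test_hypothesize_existing_pair_returns_none(self):
        # with one node per column the argmin pair is forced, so a
        # second hypothesis lands on an already-linked pair
        from nalseq import ConceptNetwork

        net = ConceptNetwork(HyperParams(n_c=1))
        a = net.get_or_create_column("A")
        b = net.get_or_create_column("B")
        first, _ = hypothesize(net, list(a.nodes), list(b.nodes))
        assert first is not None
        link, evicted = hypothesize(net, list(a.nodes), list(b.nodes))
        assert link is None and evicted == []


class TestInvariants:
    def test_queue_bounds_after_every_cycle(self, hp_small):
        cfg = StreamConfig(n_r=8, m=3, p=2, seed=3, total_steps=400)
        rng = np.random.default_rng(cfg.seed)
        protos = [Prototype(("A", "B", "C")), Prototype(("D", "B", "E"))]
        lr = SequenceLearner(hp_small)
        for ev in generate_stream(protos, cfg, rng):
            lr.step(ev.term, ev.t)
            for col in lr.network.columns.values():
                for node in col.nodes:
                    assert len(node.pre_links) <= hp_small.xi
                    assert len(node.post_links) <= hp_small.xi

    def test_determinism_bit_for_bit(self, hp_small):
        cfg = StreamConfig(n_r=10, m=3, p=2, seed=7, total_steps=600)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(cfg.seed)
            protos = [Prototype(("A", "B", "C")), Prototype(("X", "B", "Y"))]
            lr = SequenceLearner(hp_small)
            trace = [
                lr.step(ev.term, ev.t).to_dict()
                for ev in generate_stream(protos, cfg, rng)
            ]
            runs.append((json.dumps(trace), json.dumps(lr.to_dict())))
        assert runs[0] == runs[1]

    def test_evidence_totals_only_grow(self, hp_small):
        cfg = StreamConfig(n_r=6, m=3, p=1, seed=0, total_steps=300)
        rng = np.random.default_rng(0)
        protos = [Prototype(("A", "B", "C"))]
        lr = SequenceLearner(hp_small)
        seen: dict[str, float] = {}
        for ev in generate_stream(protos, cfg, rng):
            lr.step(ev.term, ev.t)
            for link in lr.network.iter_links():
                total = link.w_pos + link.w_neg
                assert total >= seen.get(link.id, 0.0) - 1e-12
                seen[link.id] = total

    def test_evidence_log_replay_reproduces_truths(self, hp_small):
        """Replaying the per-cycle evidence log through a brute-force
        accumulator reproduces every surviving link's truth value."""
        from nalseq.truth import Evidence, truth_from_evidence

        cfg = StreamConfig(n_r=8, m=3, p=2, seed=11, total_steps=500)
        rng = np.random.default_rng(cfg.seed)
        protos = [Prototype(("A", "B", "C")), Prototype(("D", "E", "F"))]
        lr = SequenceLearner(hp_small)
        acc: dict[str, list[float]] = {}
        for ev in generate_stream(protos, cfg, rng):
            res = lr.step(ev.term, ev.t)
            for lid, kind, amount in res.evidence_log:
                w = acc.setdefault(lid, [0.0, 0.0])
                w[0 if kind.startswith("w+") else 1] += amount
        for link in lr.network.iter_links():
            w_pos, w_neg = acc[link.id]
            assert w_pos == pytest.approx(link.w_pos, abs=1e-9)
            assert w_neg == pytest.approx(link.w_neg, abs=1e-9)
            replayed = truth_from_evidence(Evidence(w_pos, w_neg), hp_small.k)
            assert replayed.f == pytest.approx(link.truth.f, abs=1e-9)
            assert replayed.c == pytest.approx(link.truth.c, abs=1e-9)

    def test_periodic_stream_reaches_perfect_accuracy(self, hp_small):
        """On a noiseless cycle every transition is deterministic, so
        the sliding-window accuracy must reach and hold 1.0."""
        from nalseq.evaluation import MetricsWindow

        lr = SequenceLearner(hp_small)
        metrics = MetricsWindow()
        seq = ["A", "B", "C"] * 200
        prev = None
        for t, term in enumerate(seq):
            if prev is not None:
                metrics.record(prev, term)
            prev = lr.step(term, t)
        assert metrics.accuracy[-1] == 1.0
        # and it stays there for the whole last window
        assert all(metrics.correct[-100:])

    def test_disjoint_stream_leaves_links_untouched(self, hp_small):
        """Learning a second stream over a disjoint alphabet must not
        alter any link among the first stream's concepts (locality):
        knowledge is only revised where its concepts take part."""
        lr = SequenceLearner(hp_small)
        t = 0
        for _ in range(60):
            for term in ("A", "B", "C"):
                lr.step(term, t)
                t += 1
        terms1 = ["A", "B", "C"]
        lr.step("X", t)  # boundary step settles the last anticipations
        t += 1
        frozen = snapshot_links(lr.network, terms1)
        for _ in range(60):
            for term in ("X", "Y", "Z"):
                lr.step(term, t)
                t += 1
        assert snapshot_links(lr.network, terms1) == frozen
        # and on re-exposure the first chain still predicts correctly
        lr.step("A", t)
        res = lr.step("B", t + 1)
        assert "C" in res.anticipated_concepts


class TestSerialization:
    def test_save_load_continues_identically(self, hp_small):
        cfg = StreamConfig(n_r=8, m=3, p=2, seed=5, total_steps=300)
        rng = np.random.default_rng(cfg.seed)
        protos = [Prototype(("A", "B", "C")), Prototype(("D", "B", "E"))]
        events = list(generate_stream(protos, cfg, rng))
        lr = SequenceLearner(hp_small)
        for ev in events[:200]:
            lr.step(ev.term, ev.t)
        clone = SequenceLearner.from_dict(
            json.loads(json.dumps(lr.to_dict()))
        )
        for ev in events[200:]:
            a = lr.step(ev.term, ev.t).to_dict()
            b = clone.step(ev.term, ev.t).to_dict()
            assert a == b
        assert json.dumps(lr.to_dict()) == json.dumps(clone.to_dict())
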