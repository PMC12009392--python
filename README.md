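# nalseq

An online, life-long sequence learner for streams of discrete events,
modeled on neocortical mini-columns and grounded in the truth-value
arithmetic of Non-Axiomatic Logic (NAL).  It is written for researchers
in brain-inspired AI and continual learning who want a sequence
predictor whose every internal step — prediction, learning, forgetting —
is inspectable as a logical inference.

## The model

Each distinct event term owns a *column* (a concept) of `n_c`
context-sensitive *nodes*: the same event means different things in
different sequences, the way "bank" does in different sentences.
Knowledge is a bounded set of *links* — predictive-equivalence
statements `E1 ⇔/ E2` between nodes — each carrying an NAL truth value
⟨f; c⟩, where frequency `f = w⁺/w` is the fraction of positive evidence
and confidence `c = w/(w+k)` measures total evidence (`k = 1` by
default).  Decisions use the expectation `e = c·(f−0.5) + 0.5`.

One event arrives per timestep and drives a working cycle:

* **Activation.**  Nodes of the event's column whose anticipation
  expectation exceeds `ζ` fire; with no recognized context the whole
  column fires (every contextual reading is entertained at once, and
  lateral inhibition will prune them on later steps).
* **Anticipation.**  Each active node primes the targets of its strong
  (`e > θ`) outgoing links for the next step, with the anticipation's
  truth derived by temporal deduction: `f = f1·f2`, `c = f1·f2·c1·c2`.
  Anticipations last exactly one timestep.
* **Learning** happens in three resource-bounded moves:
  *hypothesizing* — an unexplained event is linked to the
  lowest-utility node of the previous step's column with the weak truth
  ⟨1.0; 0.1⟩; *revising* — the strongest known-cause link collects one
  unit of positive evidence, failed predictions collect negative
  evidence (a mild `count/b` for speculative ones, the full `p⁻` when a
  recognized context contradicts them); *recycling* — every node keeps
  at most `ξ` incoming and `ξ` outgoing links, and the lowest-utility
  links are deleted on overflow.

Because a cycle touches only the objects incident to the active column,
work per step is a constant in `n_c` and `ξ` regardless of how many
concepts exist, and knowledge about concepts that never take part in a
stream is — exactly, bit for bit — never modified.  That locality is
what makes the learner immune to catastrophic forgetting.

## Worked example

Train on the classic two-prototype stream, where samples embed
`(A,B,C,D,E)` or `(X,B,C,D,Y)` — sharing their middle — among random
filler letters (half of all positions are fillers, so ~50% accuracy is
the structural ceiling):

```python
from nalseq import (StreamConfig, SIMPLE_CASE_PROTOTYPES,
                    run_capacity_experiment)

cfg = StreamConfig(n_r=26, m=5, p=2, seed=1, total_steps=20_000)
res = run_capacity_experiment(cfg, prototypes=SIMPLE_CASE_PROTOTYPES)
print(res.steady_state())
```

prints (means over the final 5,000 steps):

```
{'accuracy': 0.529, 'accuracy_deterministic': 0.816,
 'n_anticipated': 4.548, 'n_active': 11.685, 'steps': 5000}
```

Sliding-window accuracy sits at 0.53 — essentially the 50% ceiling, the
excess coming from accidental regularities the learner picks out of the
fillers.  On positions whose successor is deterministic it is right
81.6% of the time (the first event of a prototype is unpredictable, so
0.8 is the within-prototype ceiling).

What it learned is readable.  After 400 steps of the noiseless cycle
`A,B,C,D,A,…`:

```python
from nalseq import SequenceLearner, HyperParams, export_narsese

lr = SequenceLearner(HyperParams(n_c=5))
for t in range(400):
    lr.step("ABCD"[t % 4], t)
print(export_narsese(lr.network))
```

```
<A(1) =|> B(1)>. %1.00;0.89%
<A(2) =|> B(3)>. %1.00;0.92%
...
<(A, B) =|> C>.
<(A, B, C) =|> D>.
<(A, B, C, D) =|> A>.
```

Each line is a Narsese belief: a link between contextual nodes with its
⟨frequency; confidence⟩, and chains of strong links expanded into
compound-antecedent beliefs.

The same experiments are scriptable from the shell:

```bash
nalseq generate --n-r 26 --m 5 --p 2 --steps 20000 --seed 1 --out stream.jsonl
nalseq run --input stream.jsonl --metrics-out metrics.csv --export-narsese knowledge.nal
nalseq eval --experiment capacity --m 14 --p 20 --n-r 1000 --steps 50000 --seed 1 --out-dir out/
nalseq eval --experiment forgetting --m 14 --p 20 --n-r 1000 --disjoint-alphabets --steps 12000 --out-dir out-forget/
```

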