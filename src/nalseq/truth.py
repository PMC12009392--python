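"""Truth-value arithmetic of Non-Axiomatic Logic (NAL).

NAL quantifies the uncertainty of a statement by a *truth value*
``<f; c>``.  *Frequency* ``f`` is the fraction of positive evidence among
all evidence observed so far (``f = w+/w``), and *confidence* ``c``
measures how much total evidence backs the statement relative to a
personality constant ``k`` (``c = w/(w+k)``, typically ``k = 1``).
Confidence is strictly below 1: no finite amount of evidence yields
certainty.

This module provides the evidence/truth conversions and the six truth
functions the sequence learner relies on:

* ``deduction`` — forward prediction: from an implication and its
  antecedent, derive the consequent's truth.
* ``induction_forward`` / ``induction_backward`` / ``comparison`` —
  temporal induction: from two events observed in succession, derive a
  (weak) predictive implication, retrospective implication, or
  predictive equivalence.
* ``revision`` — pooling: add up the evidence of two derivations of the
  same statement.
* ``expectation`` — collapse ``<f; c>`` into a single decision-ready
  number ``e = c*(f - 0.5) + 0.5``, neutral (0.5) at zero confidence.

All functions are pure; the statement bookkeeping lives elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DEFAULT_K",
    "TruthValue",
    "Evidence",
    "NoEvidenceError",
    "truth_from_evidence",
    "evidence_from_truth",
    "expectation",
    "deduction",
    "induction_forward",
    "induction_backward",
    "comparison",
    "revision",
]

#: Default evidential horizon (personality constant) k.
DEFAULT_K = 1.0


class NoEvidenceError(ValueError):
    """Raised when a truth value is requested for zero total evidence."""


@dataclass(frozen=True)
class TruthValue:
    """An NAL truth value ``<f; c>``.

    Parameters
    ----------
    f : float
        Frequency, the ratio of positive to total evidence, in ``[0, 1]``.
    c : float
        Confidence, a measure of total evidence, in ``[0, 1)``.  ``c = 1``
        would imply infinite evidence and is rejected.
    """

    f: float
    c: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"frequency must lie in [0, 1], got {self.f!r}")
        if not 0.0 <= self.c < 1.0:
            raise ValueError(f"confidence must lie in [0, 1), got {self.c!r}")


@dataclass(frozen=True)
class Evidence:
    """Amounts of positive (``w_pos``) and negative (``w_neg``) evidence."""

    w_pos: float
    w_neg: float

    def __post_init__(self) -> None:
        if self.w_pos < 0.0 or self.w_neg < 0.0:
            raise ValueError("evidence amounts must be non-negative")

    @property
    def total(self) -> float:
        """Total evidence ``w = w+ + w-``."""
        return self.w_pos + self.w_neg


def truth_from_evidence(ev: Evidence, k: float = DEFAULT_K) -> TruthValue:
    """Convert evidence amounts to a truth value.

    ``f = w+/w`` and ``c = w/(w+k)``.

    Raises
    ------
    NoEvidenceError
        If the total evidence is zero, in which case no frequency is
        defined.
    """
    w = ev.w_pos + ev.w_neg
    if w <= 0.0:
        raise NoEvidenceError("no evidence; truth undefined")
    # Clamp against 1-ulp overshoot when w was assembled from products in
    # a different association order than w_pos.
    f = min(ev.w_pos / w, 1.0)
    return TruthValue(f, w / (w + k))


def evidence_from_truth(tv: TruthValue, k: float = DEFAULT_K) -> Evidence:
    """Invert :func:`truth_from_evidence`: ``w = k*c/(1-c)``, ``w+ = f*w``.

    A truth value with ``c = 0`` carries no evidence and maps to
    ``(0, 0)``.
    """
    w = k * tv.c / (1.0 - tv.c)
    w_pos = tv.f * w
    return Evidence(w_pos, w - w_pos)


def expectation(tv: TruthValue) -> float:
    """Expectation ``e = c*(f - 0.5) + 0.5`` of a truth value.

    With zero confidence the expectation is exactly the neutral 0.5,
    regardless of frequency; full-frequency, high-confidence statements
    approach 1.
    """
    return tv.c * (tv.f - 0.5) + 0.5


def deduction(tv_impl: TruthValue, tv_event: TruthValue) -> TruthValue:
    """Temporal deduction: from ``A => C <f1;c1>`` and ``A <f2;c2>``
    derive ``C``.

    ``f = f1*f2`` and ``c = f1*f2*c1*c2``; the conclusion is never more
    confident than either premise.
    """
    f = tv_impl.f * tv_event.f
    return TruthValue(f, f * tv_impl.c * tv_event.c)


def induction_forward(
    tv_consequent: TruthValue,
    tv_antecedent: TruthValue,
    k: float = DEFAULT_K,
) -> TruthValue:
    """Temporal induction of the predictive implication antecedent => consequent.

    The antecedent is the *earlier* event.  With consequent ``<f1;c1>``
    and antecedent ``<f2;c2>``, the conclusion's evidence is
    ``w+ = f1*f2*c1*c2`` and ``w = f2*c1*c2``, so its total evidence
    never exceeds 1 and its confidence never exceeds ``1/(1+k)`` — an
    inductive conclusion is always a weak hypothesis.
    """
    w = tv_antecedent.f * tv_consequent.c * tv_antecedent.c
    if w <= 0.0:
        raise NoEvidenceError("no evidence; truth undefined")
    w_pos = tv_consequent.f * w
    return truth_from_evidence(Evidence(w_pos, w - w_pos), k)


def induction_backward(
    tv_consequent: TruthValue,
    tv_antecedent: TruthValue,
    k: float = DEFAULT_K,
) -> TruthValue:
    """Temporal induction of the retrospective implication (consequent <= antecedent).

    As :func:`induction_forward` but with total evidence
    ``w = f1*c1*c2`` (weighted by the *later* event's frequency).
    """
    w = tv_consequent.f * tv_consequent.c * tv_antecedent.c
    if w <= 0.0:
        raise NoEvidenceError("no evidence; truth undefined")
    w_pos = tv_antecedent.f * w
    return truth_from_evidence(Evidence(w_pos, w - w_pos), k)


def comparison(
    tv1: TruthValue,
    tv2: TruthValue,
    k: float = DEFAULT_K,
) -> TruthValue:
    """Temporal comparison: derive the predictive *equivalence* of two
    events observed in succession.

    ``w+ = f1*f2*c1*c2`` and ``w = (1 - (1-f1)*(1-f2))*c1*c2``.  The
    function is symmetric in its premises.
    """
    q = tv1.c * tv2.c
    w = (1.0 - (1.0 - tv1.f) * (1.0 - tv2.f)) * q
    if w <= 0.0:
        raise NoEvidenceError("no evidence; truth undefined")
    w_pos = tv1.f * tv2.f * q
    return truth_from_evidence(Evidence(w_pos, max(w - w_pos, 0.0)), k)


def revision(
    tv1: TruthValue,
    tv2: TruthValue,
    k: float = DEFAULT_K,
) -> TruthValue:
    """Revision: pool the evidence of two truth values for one statement.

    Evidence adds componentwise (``w+ = w1+ + w2+``, ``w- = w1- + w2-``),
    so revision is commutative and confidence never decreases.  A
    zero-evidence premise (``c = 0``) is the identity.
    """
    e1 = evidence_from_truth(tv1, k)
    e2 = evidence_from_truth(tv2, k)
    if e2.total <= 0.0:
        return tv1
    if e1.total <= 0.0:
        return tv2
    return truth_from_evidence(
        Evidence(e1.w_pos + e2.w_pos, e1.w_neg + e2.w_neg), k
    )
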