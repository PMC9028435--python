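"""Two-hypothesis Dempster-Shafer evidence algebra.

A piece of *evidence* about a binary receptor status is a normalized mass
triple ``(alpha, beta, theta)``:

* ``alpha`` -- belief that the status is positive *by quality of the
  measurement* (not by chance),
* ``beta``  -- belief that it is negative by quality of measurement,
* ``theta`` -- mass left on "either", the explicit uncertainty of the source.

The three masses are non-negative and sum to one, so an evidence triple is a
point on the 2-simplex.  Two degenerate shapes are worth naming: *vacuous*
evidence ``(0, 0, 1)`` carries no information and is the identity of the
conjunctive combination rules, and *Bayesian* evidence has ``theta = 0`` and
reduces to an ordinary complementary probability pair.

This module implements the algebra only: construction, plausibility, the
Dempster rule (conflict renormalized away), the Yager rule (conflict routed
into uncertainty), the OR-rule used to merge the two receptors into one
hormone status, and the three-way decision rule with a reject option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "MASS_ATOL",
    "Call",
    "Evidence",
    "InvalidEvidenceError",
    "TotalConflictError",
    "VACUOUS",
    "classify",
    "combine_dempster",
    "combine_or",
    "combine_yager",
    "make_evidence",
    "plausibility",
]

#: Absolute tolerance for mass-sum validation; triples whose sum deviates
#: from 1 by more than this are rejected, smaller deviations are renormalized.
MASS_ATOL = 1e-9


class InvalidEvidenceError(ValueError):
    """Raised when masses are negative or do not sum to one."""


class TotalConflictError(ZeroDivisionError):
    """Dempster combination of totally conflicting evidence (conflict K = 1).

    The Dempster rule divides by ``1 - K``; for e.g. ``(1,0,0)`` against
    ``(0,1,0)`` the denominator vanishes and no combined evidence exists.
    """


class Call(str, Enum):
    """Three-valued receptor-status decision (positive / negative / reject)."""

    POS = "pos"
    NEG = "neg"
    INC = "inc"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Evidence:
    """Normalized mass triple (alpha, beta, theta) on the 2-simplex.

    Tiny negative masses from floating-point cancellation (within
    :data:`MASS_ATOL` of zero) are clamped to 0; the triple is then
    renormalized to sum exactly to one, provided the raw sum was within
    tolerance of one.  Anything further off is rejected.
    """

    alpha: float
    beta: float
    theta: float

    def __post_init__(self) -> None:
        masses = [float(self.alpha), float(self.beta), float(self.theta)]
        for i, m in enumerate(masses):
            if not math.isfinite(m):
                raise InvalidEvidenceError(f"non-finite mass {m!r}")
            if m < 0.0:
                if m < -MASS_ATOL:
                    raise InvalidEvidenceError(
                        f"negative mass {m!r} in (alpha, beta, theta)={masses}"
                    )
                masses[i] = 0.0
        total = sum(masses)
        if abs(total - 1.0) > MASS_ATOL:
            raise InvalidEvidenceError(
                f"masses must sum to 1, got {total!r} for {masses}"
            )
        a, b, t = (m / total for m in masses)
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "theta", t)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.theta)

    @property
    def is_bayesian(self) -> bool:
        """True when theta == 0 and the masses are plain probabilities."""
        return self.theta == 0.0

    def __iter__(self):
        return iter(self.as_tuple())


#: The fully uninformative triple (0, 0, 1); identity of both conjunctive rules.
VACUOUS = Evidence(0.0, 0.0, 1.0)


def make_evidence(alpha: float, beta: float) -> Evidence:
    """Build evidence from the two beliefs, with theta as the complement.

    ``theta = 1 - alpha - beta``; a tiny negative complement (floating-point
    cancellation) is clamped to zero.  Raises
    :class:`InvalidEvidenceError` if ``alpha + beta`` genuinely exceeds one
    or either belief is negative.
    """
    alpha = float(alpha)
    beta = float(beta)
    if alpha < 0.0 or beta < 0.0:
        raise InvalidEvidenceError(f"negative belief: alpha={alpha}, beta={beta}")
    theta = 1.0 - alpha - beta
    if theta < 0.0:
        if theta < -MASS_ATOL:
            raise InvalidEvidenceError(
                f"alpha + beta = {alpha + beta!r} exceeds 1"
            )
        theta = 0.0
    return Evidence(alpha, beta, theta)


def plausibility(e: Evidence) -> float:
    """Plausibility of the positive status: ``alpha + theta = 1 - beta``.

    Everything supportive of or neutral toward a positive call; only the
    mass committed to the negative status counts against it.
    """
    return e.alpha + e.theta


def conflict(e1: Evidence, e2: Evidence) -> float:
    """Conflict mass K between two sources: ``a1*b2 + b1*a2``.

    The probability, under independent random focal-set selection, that the
    two sources commit to strictly opposite statuses.
    """
    return e1.alpha * e2.beta + e1.beta * e2.alpha


def combine_dempster(e1: Evidence, e2: Evidence) -> Evidence:
    """Dempster's rule: conjunctive combination, conflict renormalized away.

    .. math::

        \\alpha = \\frac{\\alpha_1\\alpha_2 + \\theta_1\\alpha_2
                        + \\alpha_1\\theta_2}{1 - K}, \\qquad
        \\beta  = \\frac{\\beta_1\\beta_2 + \\theta_1\\beta_2
                        + \\beta_1\\theta_2}{1 - K}, \\qquad
        \\theta = \\frac{\\theta_1\\theta_2}{1 - K}

    with conflict ``K = a1*b2 + b1*a2``.  Dividing out the conflict makes the
    rule "sharp": even strongly contradicting inputs yield a combined triple
    with little uncertainty.  Raises :class:`TotalConflictError` when K = 1.
    """
    k = conflict(e1, e2)
    denom = 1.0 - k
    if denom <= MASS_ATOL:
        raise TotalConflictError(
            f"total conflict (K={k!r}) between {e1.as_tuple()} and {e2.as_tuple()}"
        )
    alpha = (e1.alpha * e2.alpha + e1.theta * e2.alpha + e1.alpha * e2.theta) / denom
    beta = (e1.beta * e2.beta + e1.theta * e2.beta + e1.beta * e2.theta) / denom
    theta = (e1.theta * e2.theta) / denom
    return Evidence(alpha, beta, theta)


def combine_yager(e1: Evidence, e2: Evidence) -> Evidence:
    """Yager's rule: conjunctive combination, conflict routed to uncertainty.

    Same product terms as Dempster's rule but the conflict mass
    ``a1*b2 + b1*a2`` is added to theta instead of being renormalized away.
    Contradicting sources therefore yield a *soft* result with large
    uncertainty.  Defined for every pair of inputs, including total conflict
    (which maps to total uncertainty).  Not associative.
    """
    alpha = e1.alpha * e2.alpha + e1.theta * e2.alpha + e1.alpha * e2.theta
    beta = e1.beta * e2.beta + e1.theta * e2.beta + e1.beta * e2.theta
    theta = e1.theta * e2.theta + e1.alpha * e2.beta + e1.beta * e2.alpha
    return Evidence(alpha, beta, theta)


def combine_or(e_er: Evidence, e_pgr: Evidence) -> Evidence:
    """OR-fusion of two receptor evidences into one hormone-status evidence.

    Mirrors the clinical rule "hormone-receptor positive if either receptor
    is positive" in mass-function terms:

    ``alpha = a1 + a2 - a1*a2`` (positive unless neither is),
    ``beta = b1*b2`` (negative only if both are), theta by complement
    (algebraically ``b1*t2 + t1*b2 + t1*t2 >= 0``).
    """
    alpha = e_er.alpha + e_pgr.alpha - e_er.alpha * e_pgr.alpha
    beta = e_er.beta * e_pgr.beta
    return make_evidence(alpha, beta)


def classify(e: Evidence, threshold: float = 0.5) -> Call:
    """Three-way decision: pos if alpha > threshold, neg if beta > threshold.

    Everything else -- including evidence exactly on the border -- is
    inconclusive (the reject option).  Strict inequality keeps border points
    undecided; with ``threshold >= 0.5`` at most one belief can exceed it,
    so the decision is unambiguous.
    """
    threshold = float(threshold)
    if not 0.5 <= threshold < 1.0:
        raise ValueError(f"threshold must lie in [0.5, 1), got {threshold}")
    if e.alpha > threshold:
        return Call.POS
    if e.beta > threshold:
        return Call.NEG
    return Call.INC
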