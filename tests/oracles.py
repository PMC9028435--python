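"""Independent brute-force reference implementations used only by tests.

Mass functions are represented literally as dictionaries over focal subsets
of the two-hypothesis frame {P, N}; combination enumerates all focal-set
pairs and assigns each product mass by set intersection (conjunctive rules)
or by elementwise disjunction (the OR rule).  Nothing here shares code with
the package's closed-form algebra.
"""

from __future__ import annotations

from dstcall.evidence import Evidence

P = frozenset({"P"})
N = frozenset({"N"})
PN = frozenset({"P", "N"})


def to_mass(e: Evidence) -> dict[frozenset, float]:
    return {P: e.alpha, N: e.beta, PN: e.theta}


def from_mass(m: dict[frozenset, float]) -> tuple[float, float, float]:
    return (m[P], m[N], m[PN])


def combine_conjunctive(m1, m2, rule: str) -> tuple[float, float, float]:
    """Dempster ('renormalize') or Yager ('to-theta') handling of conflict."""
    out = {P: 0.0, N: 0.0, PN: 0.0}
    conflict = 0.0
    for a, wa in m1.items():
        for b, wb in m2.items():
            inter = a & b
            if inter:
                out[inter] += wa * wb
            else:
                conflict += wa * wb
    if rule == "dempster":
        denom = 1.0 - conflict
        if denom <= 0.0:
            raise ZeroDivisionError("total conflict")
        return tuple(out[k] / denom for k in (P, N, PN))
    if rule == "yager":
        out[PN] += conflict
        return from_mass(out)
    raise ValueError(rule)


def _or_status(a: str, b: str) -> str:
    return "P" if "P" in (a, b) else "N"


def combine_or(m1, m2) -> tuple[float, float, float]:
    """Disjunctive combination: the joint status is the OR of the elements."""
    out = {P: 0.0, N: 0.0, PN: 0.0}
    for a, wa in m1.items():
        for b, wb in m2.items():
            result = frozenset(_or_status(x, y) for x in a for y in b)
            out[result] += wa * wb
    return from_mass(out)


def kappa_from_lists(calls_a, calls_b) -> float:
    """Cohen's kappa straight from the raw paired labels, no table."""
    n = len(calls_a)
    labels = sorted({*calls_a, *calls_b})
    p_o = sum(a == b for a, b in zip(calls_a, calls_b)) / n
    p_e = sum(
        (sum(a == lab for a in calls_a) / n) * (sum(b == lab for b in calls_b) / n)
        for lab in labels
    )
    return (p_o - p_e) / (1.0 - p_e)
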