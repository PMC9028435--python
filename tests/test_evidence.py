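"""Unit and property tests for the two-hypothesis evidence algebra."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from dstcall.evidence import (
    Call,
    Evidence,
    InvalidEvidenceError,
    TotalConflictError,
    VACUOUS,
    classify,
    combine_dempster,
    combine_or,
    combine_yager,
    make_evidence,
    plausibility,
)


@st.composite
def evidences(draw, min_theta: float = 0.0) -> Evidence:
    budget = 1.0 - min_theta
    a = draw(st.floats(0.0, 1.0)) * budget
    b = draw(st.floats(0.0, 1.0)) * (budget - a)
    return make_evidence(a, b)


def assert_close(e: Evidence, expected, atol=1e-12) -> None:
    np.testing.assert_allclose(e.as_tuple(), expected, atol=atol, rtol=0)


class TestConstruction:
    @pytest.mark.parametrize(
        "alpha,beta,expected",
        [
            (0.8, 0.1, (0.8, 0.1, 0.1)),
            (0.0, 0.0, (0.0, 0.0, 1.0)),  # vacuous: total uncertainty
            (0.6, 0.4, (0.6, 0.4, 0.0)),  # Bayesian: theta = 0
        ],
    )
    def test_theta_is_complement(self, alpha, beta, expected):
        assert_close(make_evidence(alpha, beta), expected)

    def test_tiny_negative_complement_clamped(self):
        e = make_evidence(0.7, 0.3 + 1e-13)
        assert e.theta == 0.0
        assert e.alpha + e.beta + e.theta == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("alpha,beta", [(0.7, 0.4), (-0.1, 0.2), (0.2, -0.1)])
    def test_invalid_masses_rejected(self, alpha, beta):
        with pytest.raises(InvalidEvidenceError):
            make_evidence(alpha, beta)

    def test_triple_off_simplex_rejected(self):
        with pytest.raises(InvalidEvidenceError):
            Evidence(0.5, 0.5, 0.5)
        with pytest.raises(InvalidEvidenceError):
            Evidence(float("nan"), 0.5, 0.5)

    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.8, 0.1, 0.1), 0.9),
            ((0.0, 0.0, 1.0), 1.0),  # vacuous is fully plausible
            ((0.0, 1.0, 0.0), 0.0),  # certain-negative: zero plausibility
        ],
    )
    def test_plausibility(self, triple, expected):
        e = Evidence(*triple)
        assert plausibility(e) == pytest.approx(expected, abs=1e-12)
        assert plausibility(e) == pytest.approx(1.0 - e.beta, abs=1e-12)


class TestDempster:
    def test_contradicting_sources_worked_example(self):
        """Strongly conflicting expression-vs-IHC evidence is combined
        sharply: most conflict mass is renormalized away."""
        e = combine_dempster(Evidence(0.8, 0.1, 0.1), Evidence(0.0, 0.7, 0.3))
        assert_close(e, (0.24 / 0.44, 0.17 / 0.44, 0.03 / 0.44))
        assert round(e.alpha, 4) == 0.5455
        assert round(e.theta, 4) == 0.0682

    def test_vacuous_is_identity(self):
        e = Evidence(0.3, 0.5, 0.2)
        assert_close(combine_dempster(e, VACUOUS), e.as_tuple())
        assert_close(combine_dempster(VACUOUS, e), e.as_tuple())

    def test_half_conflict_bayesian_fixed_point(self):
        assert_close(
            combine_dempster(Evidence(0.5, 0.5, 0.0), Evidence(0.5, 0.5, 0.0)),
            (0.5, 0.5, 0.0),
        )

    def test_total_conflict_raises(self):
        with pytest.raises(TotalConflictError):
            combine_dempster(Evidence(1, 0, 0), Evidence(0, 1, 0))


class TestYager:
    def test_contradicting_sources_worked_example(self):
        """The same conflicting pair combined softly: conflict mass moves
        into uncertainty instead of being renormalized away."""
        e = combine_yager(Evidence(0.8, 0.1, 0.1), Evidence(0.0, 0.7, 0.3))
        assert_close(e, (0.24, 0.17, 0.59))

    def test_vacuous_is_identity(self):
        e = Evidence(0.3, 0.5, 0.2)
        assert_close(combine_yager(e, VACUOUS), e.as_tuple())
        assert_close(combine_yager(VACUOUS, e), e.as_tuple())

    def test_total_conflict_becomes_total_uncertainty(self):
        assert_close(
            combine_yager(Evidence(1, 0, 0), Evidence(0, 1, 0)), (0.0, 0.0, 1.0)
        )


class TestOrFusion:
    @pytest.mark.parametrize(
        "e1,e2,expected",
        [
            ((1, 0, 0), (0, 1, 0), (1, 0, 0)),  # one certain positive wins
            ((0, 1, 0), (0, 1, 0), (0, 1, 0)),  # both certain negative
            ((0.5, 0.3, 0.2), (0.4, 0.6, 0.0), (0.7, 0.18, 0.12)),
        ],
    )
    def test_examples(self, e1, e2, expected):
        assert_close(combine_or(Evidence(*e1), Evidence(*e2)), expected)

    def test_subthreshold_positives_can_jointly_cross(self):
        e = combine_or(Evidence(0.4, 0.3, 0.3), Evidence(0.4, 0.3, 0.3))
        assert e.alpha == pytest.approx(0.64, abs=1e-12)
        assert classify(e) is Call.POS


class TestClassify:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.6, 0.3, 0.1), Call.POS),
            ((0.3, 0.6, 0.1), Call.NEG),
            ((0.5, 0.5, 0.0), Call.INC),  # border point stays undecided
            ((0.2, 0.2, 0.6), Call.INC),
        ],
    )
    def test_three_way_rule(self, triple, expected):
        assert classify(Evidence(*triple)) is expected

    def test_threshold_below_half_rejected(self):
        with pytest.raises(ValueError):
            classify(VACUOUS, threshold=0.4)

    def test_strict_border_at_custom_threshold(self):
        assert classify(Evidence(0.7, 0.3, 0.0), threshold=0.7) is Call.INC
        assert classify(Evidence(0.7, 0.3, 0.0), threshold=0.6) is Call.POS


class TestAlgebraicProperties:
    @given(evidences(), evidences())
    def test_outputs_normalized_and_commutative(self, e1, e2):
        for rule in (combine_yager, combine_or):
            a = rule(e1, e2)
            b = rule(e2, e1)
            assert abs(sum(a.as_tuple()) - 1.0) < 1e-9
            np.testing.assert_allclose(a.as_tuple(), b.as_tuple(), atol=1e-12)
        try:
            a = combine_dempster(e1, e2)
        except TotalConflictError:
            return
        b = combine_dempster(e2, e1)
        assert abs(sum(a.as_tuple()) - 1.0) < 1e-9
        np.testing.assert_allclose(a.as_tuple(), b.as_tuple(), atol=1e-12)

    @given(
        evidences(min_theta=0.05),
        evidences(min_theta=0.05),
        evidences(min_theta=0.05),
    )
    def test_dempster_associative(self, a, b, c):
        left = combine_dempster(combine_dempster(a, b), c)
        right = combine_dempster(a, combine_dempster(b, c))
        np.testing.assert_allclose(left.as_tuple(), right.as_tuple(), atol=1e-9)

    def test_yager_not_associative(self):
        # one explicit counterexample; no associativity claim for Yager
        a, b, c = Evidence(0.8, 0.1, 0.1), Evidence(0.0, 0.7, 0.3), Evidence(0.6, 0.2, 0.2)
        left = combine_yager(combine_yager(a, b), c)
        right = combine_yager(a, combine_yager(b, c))
        assert max(
            abs(x - y) for x, y in zip(left.as_tuple(), right.as_tuple())
        ) > 1e-3

    @given(evidences())
    def test_vacuous_identity_both_rules(self, e):
        for rule in (combine_dempster, combine_yager):
            np.testing.assert_allclose(
                rule(e, VACUOUS).as_tuple(), e.as_tuple(), atol=1e-12
            )
            np.testing.assert_allclose(
                rule(VACUOUS, e).as_tuple(), e.as_tuple(), atol=1e-12
            )

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_bayesian_closure(self, a1, a2):
        e1 = Evidence(a1, 1.0 - a1, 0.0)
        e2 = Evidence(a2, 1.0 - a2, 0.0)
        if e1.alpha * e2.beta + e1.beta * e2.alpha < 1.0 - 1e-9:
            assert combine_dempster(e1, e2).theta == pytest.approx(0.0, abs=1e-12)
        e_or = combine_or(e1, e2)
        assert e_or.theta == pytest.approx(0.0, abs=1e-12)
        assert e_or.alpha + e_or.beta == pytest.approx(1.0, abs=1e-12)


class TestOracleEquivalence:
    """Closed-form rules match the focal-set enumeration on the 0.1 grid."""

    def test_all_rules_match_brute_force(self, grid_evidences):
        for e1, e2 in itertools.product(grid_evidences, repeat=2):
            m1, m2 = oracles.to_mass(e1), oracles.to_mass(e2)
            try:
                expected = oracles.combine_conjunctive(m1, m2, "dempster")
            except ZeroDivisionError:
                with pytest.raises(TotalConflictError):
                    combine_dempster(e1, e2)
            else:
                np.testing.assert_allclose(
                    combine_dempster(e1, e2).as_tuple(), expected, atol=1e-12
                )
            np.testing.assert_allclose(
                combine_yager(e1, e2).as_tuple(),
                oracles.combine_conjunctive(m1, m2, "yager"),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                combine_or(e1, e2).as_tuple(),
                oracles.combine_or(m1, m2),
                atol=1e-12,
            )
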