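"""Evidence construction from gene expression and from IHC status.

Continuous route: a logistic *responsibility function*
``r+(x) = expit(c0 + c1 x)`` gives the probability of a positive receptor
status at expression level ``x``; ``r- = 1 - r+``.  Beliefs are the
responsibilities scaled by *belief caps* ``alpha_cap`` / ``beta_cap`` strictly
below one, so that no expression value, however extreme, can ever certify the
status -- the residual mass is explicit uncertainty.

Categorical route: immunohistochemistry (IHC) delivers one of three statuses
(+, -, unknown); each maps to a fixed evidence triple.  Unknown is vacuous.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .evidence import VACUOUS, Evidence, make_evidence

__all__ = [
    "FitResult",
    "IhcEvidenceTable",
    "IhcStatus",
    "ResponsibilityModel",
    "SeparationError",
    "default_ihc_table",
    "evidence_from_expression",
    "evidence_from_ihc",
    "fit_responsibility",
    "parse_ihc",
    "responsibility_pos",
]


class SeparationError(RuntimeError):
    """Logistic fit diverged: classes perfectly separable along expression."""


class IhcStatus(str, Enum):
    POS = "+"
    NEG = "-"
    UNKNOWN = "0"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


_IHC_ALIASES: Mapping[str, IhcStatus] = {
    "+": IhcStatus.POS,
    "pos": IhcStatus.POS,
    "1": IhcStatus.POS,
    "-": IhcStatus.NEG,
    "−": IhcStatus.NEG,  # unicode minus
    "neg": IhcStatus.NEG,
    "0": IhcStatus.UNKNOWN,
    "u": IhcStatus.UNKNOWN,
    "na": IhcStatus.UNKNOWN,
    "nan": IhcStatus.UNKNOWN,
    "unknown": IhcStatus.UNKNOWN,
}


def parse_ihc(token: object) -> IhcStatus:
    """Parse an IHC status token; '0', 'u', 'NA' all mean unknown."""
    if isinstance(token, IhcStatus):
        return token
    key = str(token).strip().lower()
    try:
        return _IHC_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognized IHC status token {token!r}") from None


@dataclass(frozen=True)
class ResponsibilityModel:
    """Logistic responsibility curve plus belief caps for one gene.

    Parameters
    ----------
    c0, c1
        Logistic intercept and slope (log-odds units per expression unit).
    alpha_cap, beta_cap
        Upper limits for the positive and negative beliefs, in (0, 1].
        ``beta_cap`` defaults to ``alpha_cap``, keeping the scaled form
        symmetric.  With both caps <= 1 the triple
        ``(alpha_cap*r+, beta_cap*r-, complement)`` is valid for every x.
    gene_label
        Identifier used in provenance and reports only.
    """

    c0: float
    c1: float
    alpha_cap: float = 0.9
    beta_cap: float | None = None
    gene_label: str = ""

    def __post_init__(self) -> None:
        if self.beta_cap is None:
            object.__setattr__(self, "beta_cap", self.alpha_cap)
        for name in ("c0", "c1"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("alpha_cap", "beta_cap"):
            cap = float(getattr(self, name))
            if 1.0 < cap <= 1.0 + 1e-9:  # FP noise from cap arithmetic
                cap = 1.0
                object.__setattr__(self, name, cap)
            if not 0.0 < cap <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {cap!r}")


def responsibility_pos(x: float, model: ResponsibilityModel) -> float:
    """P(status positive | expression x) = expit(c0 + c1*x)."""
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"expression value must be finite, got {x!r}")
    return float(expit(model.c0 + model.c1 * x))


def evidence_from_expression(x: float, model: ResponsibilityModel) -> Evidence:
    """Capped-responsibility evidence at expression level x.

    ``alpha = alpha_cap * r+(x)``, ``beta = beta_cap * r-(x)``, theta by
    complement.  With caps strictly below one, theta stays bounded away from
    zero for every finite x: expression alone never removes all uncertainty.
    """
    r_pos = responsibility_pos(x, model)
    return make_evidence(model.alpha_cap * r_pos, model.beta_cap * (1.0 - r_pos))


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood logistic coefficients with standard errors."""

    c0: float
    c1: float
    se_c0: float
    se_c1: float
    n: int

    def __iter__(self):
        return iter((self.c0, self.c1))


def fit_responsibility(x, y) -> FitResult:
    """Fit the logistic responsibility curve by maximum likelihood.

    Parameters
    ----------
    x : array-like of float
        Expression values.
    y : array-like of bool/int
        Binary status labels (1 = positive).  Samples with unknown status
        must be excluded by the caller before fitting.

    Raises
    ------
    ValueError
        Fewer than two samples per class, or constant x (no identifiable
        slope).
    SeparationError
        Perfectly separable classes; the MLE diverges and the direction of
        divergence is reported instead of a silently ridged fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if y.dtype != bool:
        y = y.astype(float) > 0.5
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not np.all(np.isfinite(x)):
        raise ValueError("expression values must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {n_pos} positive / {n_neg} negative"
        )
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant; slope not identifiable")

    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            warnings.simplefilter("error", category=ConvergenceWarning)
            res = sm.Logit(y.astype(float), design).fit(disp=0, maxiter=200)
    except (
        PerfectSeparationError,
        PerfectSeparationWarning,
        ConvergenceWarning,
        np.linalg.LinAlgError,
    ) as exc:
        direction = "+x" if np.mean(x[y]) >= np.mean(x[~y]) else "-x"
        raise SeparationError(
            f"logistic fit diverged (separable classes, direction {direction})"
        ) from exc
    c0, c1 = res.params
    se_c0, se_c1 = res.bse
    if not (np.isfinite(se_c0) and np.isfinite(se_c1)) or max(abs(c0), abs(c1)) > 1e4:
        direction = "+x" if c1 >= 0 else "-x"
        raise SeparationError(
            f"logistic fit diverged (separable classes, direction {direction})"
        )
    return FitResult(float(c0), float(c1), float(se_c0), float(se_c1), int(x.size))


@dataclass(frozen=True)
class IhcEvidenceTable:
    """Fixed evidence triple per categorical IHC status.

    The default constants are conservative reconstructions, not published
    values: the opposing belief is zero and theta = 0.15, so capped
    expression evidence can weaken but never flip an IHC call into the
    opposite definite call.  Unknown is always vacuous.
    """

    positive: Evidence = field(
        default_factory=lambda: Evidence(0.85, 0.0, 0.15)
    )
    negative: Evidence = field(
        default_factory=lambda: Evidence(0.0, 0.85, 0.15)
    )
    unknown: Evidence = field(default_factory=lambda: VACUOUS)

    def __getitem__(self, status: IhcStatus) -> Evidence:
        if status is IhcStatus.POS:
            return self.positive
        if status is IhcStatus.NEG:
            return self.negative
        if status is IhcStatus.UNKNOWN:
            return self.unknown
        raise KeyError(status)


def default_ihc_table() -> IhcEvidenceTable:
    return IhcEvidenceTable()


def evidence_from_ihc(status, table: IhcEvidenceTable | None = None) -> Evidence:
    """Look up the configured evidence triple for an IHC status."""
    if table is None:
        table = default_ihc_table()
    return table[parse_ihc(status)]
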