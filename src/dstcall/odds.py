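"""Reconstructed ODDS-score baseline: continuous per-receptor scores with
two decision thresholds and a crisp clinical OR.

The original score formulas come from prior work and are not reproduced
here; this module is an explicitly labeled, fully configurable reconstruction
that preserves the baseline's structure: a per-receptor score that is a
weighted log-odds of the gene and co-gene responsibilities plus an additive
IHC offset, a negative region below ``t_neg``, a positive region above
``t_pos``, an inconclusive band between, and a three-valued OR across
receptors.  None of the default constants are authoritative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .evidence import Call
from .responsibility import IhcStatus, ResponsibilityModel, parse_ihc

__all__ = [
    "OddsCall",
    "OddsReceptorConfig",
    "odds_hormone_call",
    "odds_receptor_call",
    "odds_score",
    "run_cohort_odds",
]


def _default_offsets() -> Mapping[IhcStatus, float]:
    return {IhcStatus.POS: 2.0, IhcStatus.NEG: -2.0, IhcStatus.UNKNOWN: 0.0}


@dataclass(frozen=True)
class OddsReceptorConfig:
    """Score weights, IHC offsets and thresholds for one receptor.

    ``gene_model``/``cogene_model`` supply the logistic coefficients whose
    linear predictor ``c0 + c1*x`` is the per-gene log-odds term.  All
    constants are placeholders meant to be overridden from config.
    """

    gene_model: ResponsibilityModel
    cogene_model: ResponsibilityModel | None = None
    gene_weight: float = 1.0
    cogene_weight: float = 0.5
    ihc_offsets: Mapping[IhcStatus, float] = field(default_factory=_default_offsets)
    t_neg: float = -1.0
    t_pos: float = 1.0

    def __post_init__(self) -> None:
        if not self.t_neg < self.t_pos:
            raise ValueError(
                f"thresholds must satisfy t_neg < t_pos, got {self.t_neg} >= {self.t_pos}"
            )


def odds_score(
    gene_x: float | None,
    cogene_x: float | None,
    ihc,
    cfg: OddsReceptorConfig,
) -> float:
    """Weighted log-odds of gene + co-gene responsibilities + IHC offset.

    The log-odds of ``r+(x)`` is exactly the linear predictor ``c0 + c1*x``.
    A missing expression value contributes a neutral term of zero (the
    log-odds of an uninformative r+ = 0.5).  The IHC term is additive by
    construction: two scores at the same expression differ exactly by the
    difference of their status offsets.
    """
    score = 0.0
    for x, model, w in (
        (gene_x, cfg.gene_model, cfg.gene_weight),
        (cogene_x, cfg.cogene_model, cfg.cogene_weight),
    ):
        if model is None or x is None:
            continue
        x = float(x)
        if math.isnan(x):
            continue
        if math.isinf(x):
            raise ValueError(f"expression value must be finite, got {x!r}")
        score += w * (model.c0 + model.c1 * x)
    return score + cfg.ihc_offsets[parse_ihc(ihc)]


def odds_receptor_call(score: float, cfg: OddsReceptorConfig) -> Call:
    """neg below t_neg, pos above t_pos, inconclusive in the band between."""
    if score < cfg.t_neg:
        return Call.NEG
    if score > cfg.t_pos:
        return Call.POS
    return Call.INC


def odds_hormone_call(er_call: Call, pgr_call: Call) -> Call:
    """Three-valued clinical OR: pos if either receptor is pos, neg only if
    both are neg, inconclusive otherwise."""
    if Call.POS in (er_call, pgr_call):
        return Call.POS
    if er_call is Call.NEG and pgr_call is Call.NEG:
        return Call.NEG
    return Call.INC


@dataclass(frozen=True)
class OddsCall:
    sample_id: str
    er_score: float
    pgr_score: float
    er_call: Call
    pgr_call: Call
    hormone_call: Call


def run_cohort_odds(
    samples: Sequence,
    er_cfg: OddsReceptorConfig,
    pgr_cfg: OddsReceptorConfig,
) -> list[OddsCall]:
    """Score and classify every sample; order preserved, deterministic."""
    out = []
    for rec in samples:
        er_score = odds_score(rec.er_gene_expr, rec.er_cogene_expr, rec.er_ihc, er_cfg)
        pgr_score = odds_score(
            rec.pgr_gene_expr, rec.pgr_cogene_expr, rec.pgr_ihc, pgr_cfg
        )
        er_call = odds_receptor_call(er_score, er_cfg)
        pgr_call = odds_receptor_call(pgr_score, pgr_cfg)
        out.append(
            OddsCall(
                sample_id=rec.sample_id,
                er_score=er_score,
                pgr_score=pgr_score,
                er_call=er_call,
                pgr_call=pgr_call,
                hormone_call=odds_hormone_call(er_call, pgr_call),
            )
        )
    return out
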