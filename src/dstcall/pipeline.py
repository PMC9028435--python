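"""Full evidence-fusion flow from per-sample measurements to hormone calls.

Per receptor (ER, then PGR): evidence from the receptor gene and from its
co-gene are combined with the Dempster rule, the result is combined with the
IHC evidence via the Yager rule, and the receptor call follows from the
three-way decision rule.  The two receptor evidences are then merged by the
OR-rule into a single hormone-status evidence and call.

The combination order (gene ⊕D co-gene first, IHC via ⊕Y second) is part of
the contract: the Yager rule is not associative, so reordering changes
results.  All intermediate triples are kept as provenance.  A missing
expression value contributes vacuous evidence -- the identity of both rules --
so the rest of the fusion is unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .evidence import (
    VACUOUS,
    Call,
    Evidence,
    classify,
    combine_dempster,
    combine_or,
    combine_yager,
)
from .responsibility import (
    IhcEvidenceTable,
    IhcStatus,
    ResponsibilityModel,
    default_ihc_table,
    evidence_from_expression,
    evidence_from_ihc,
    fit_responsibility,
    parse_ihc,
)

__all__ = [
    "CohortError",
    "HormoneCall",
    "PipelineConfig",
    "ReceptorCall",
    "ReceptorModels",
    "SampleRecord",
    "calls_frame",
    "fit_cohort_models",
    "hormone_call",
    "ihc_hormone_call",
    "read_samples",
    "receptor_evidence",
    "run_cohort",
    "write_calls",
]


@dataclass(frozen=True)
class SampleRecord:
    """One patient sample: four expression values and two IHC statuses."""

    sample_id: str
    er_gene_expr: float | None
    er_cogene_expr: float | None
    pgr_gene_expr: float | None
    pgr_cogene_expr: float | None
    er_ihc: IhcStatus
    pgr_ihc: IhcStatus

    def __post_init__(self) -> None:
        for name in (
            "er_gene_expr",
            "er_cogene_expr",
            "pgr_gene_expr",
            "pgr_cogene_expr",
        ):
            v = getattr(self, name)
            if v is not None and math.isinf(float(v)):
                raise ValueError(f"{name} must be finite or missing, got {v!r}")
        object.__setattr__(self, "er_ihc", parse_ihc(self.er_ihc))
        object.__setattr__(self, "pgr_ihc", parse_ihc(self.pgr_ihc))

    @property
    def any_ihc_unknown(self) -> bool:
        return (
            self.er_ihc is IhcStatus.UNKNOWN or self.pgr_ihc is IhcStatus.UNKNOWN
        )


@dataclass(frozen=True)
class ReceptorCall:
    """Fused evidence and decision for one receptor, with provenance."""

    receptor: str
    evidence: Evidence
    call: Call
    gene_evidence: Evidence
    cogene_evidence: Evidence
    ihc_evidence: Evidence


@dataclass(frozen=True)
class HormoneCall:
    """OR-fused hormone-status evidence and call for one sample."""

    sample_id: str
    evidence: Evidence
    call: Call
    er: ReceptorCall
    pgr: ReceptorCall
    any_ihc_unknown: bool = False


@dataclass(frozen=True)
class ReceptorModels:
    """Responsibility models and IHC evidence table for one receptor."""

    gene: ResponsibilityModel
    cogene: ResponsibilityModel | None
    ihc_table: IhcEvidenceTable


@dataclass(frozen=True)
class PipelineConfig:
    er: ReceptorModels
    pgr: ReceptorModels
    threshold: float = 0.5


class CohortError(ValueError):
    """Per-sample input failures, collected with their sample ids."""

    def __init__(self, failures: list[tuple[str, str]]):
        self.failures = failures
        lines = "; ".join(f"{sid}: {msg}" for sid, msg in failures)
        super().__init__(f"{len(failures)} sample(s) failed: {lines}")


def _expression_evidence(
    x: float | None, model: ResponsibilityModel | None
) -> Evidence:
    # Missing value or absent model -> vacuous, the identity of both rules.
    if model is None or x is None or (isinstance(x, float) and math.isnan(x)):
        return VACUOUS
    return evidence_from_expression(x, model)


def receptor_evidence(
    gene_x: float | None,
    cogene_x: float | None,
    ihc,
    models: ReceptorModels,
    threshold: float = 0.5,
    receptor: str = "",
) -> ReceptorCall:
    """gene ⊕D co-gene, then ⊕Y IHC; decision by the three-way rule.

    With belief caps strictly below one, the gene/co-gene conflict is
    strictly below one, so the Dempster step cannot fail.
    """
    e_gene = _expression_evidence(gene_x, models.gene)
    e_cogene = _expression_evidence(cogene_x, models.cogene)
    e_ihc = evidence_from_ihc(ihc, models.ihc_table)
    e_expr = combine_dempster(e_gene, e_cogene)
    e_rez = combine_yager(e_expr, e_ihc)
    return ReceptorCall(
        receptor=receptor,
        evidence=e_rez,
        call=classify(e_rez, threshold),
        gene_evidence=e_gene,
        cogene_evidence=e_cogene,
        ihc_evidence=e_ihc,
    )


def hormone_call(
    er: ReceptorCall,
    pgr: ReceptorCall,
    threshold: float = 0.5,
    sample_id: str = "",
    any_ihc_unknown: bool = False,
) -> HormoneCall:
    """OR-fuse the two receptor evidences and classify the result."""
    e_h = combine_or(er.evidence, pgr.evidence)
    return HormoneCall(
        sample_id=sample_id,
        evidence=e_h,
        call=classify(e_h, threshold),
        er=er,
        pgr=pgr,
        any_ihc_unknown=any_ihc_unknown,
    )


def run_cohort(
    samples: Sequence[SampleRecord], config: PipelineConfig
) -> list[HormoneCall]:
    """Apply the full fusion flow to every sample, order preserved.

    Per-sample failures are collected and raised together as a
    :class:`CohortError` carrying the offending sample ids; nothing is
    silently dropped.
    """
    calls: list[HormoneCall] = []
    failures: list[tuple[str, str]] = []
    for rec in samples:
        try:
            er = receptor_evidence(
                rec.er_gene_expr,
                rec.er_cogene_expr,
                rec.er_ihc,
                config.er,
                config.threshold,
                receptor="ER",
            )
            pgr = receptor_evidence(
                rec.pgr_gene_expr,
                rec.pgr_cogene_expr,
                rec.pgr_ihc,
                config.pgr,
                config.threshold,
                receptor="PGR",
            )
            calls.append(
                hormone_call(
                    er,
                    pgr,
                    config.threshold,
                    sample_id=rec.sample_id,
                    any_ihc_unknown=rec.any_ihc_unknown,
                )
            )
        except (ValueError, ZeroDivisionError) as exc:
            failures.append((rec.sample_id, str(exc)))
    if failures:
        raise CohortError(failures)
    return calls


def ihc_hormone_call(er_ihc, pgr_ihc) -> Call:
    """Crisp clinical OR on raw IHC alone (the conventional SOP baseline)."""
    er_ihc = parse_ihc(er_ihc)
    pgr_ihc = parse_ihc(pgr_ihc)
    if er_ihc is IhcStatus.POS or pgr_ihc is IhcStatus.POS:
        return Call.POS
    if er_ihc is IhcStatus.NEG and pgr_ihc is IhcStatus.NEG:
        return Call.NEG
    return Call.INC


def fit_cohort_models(
    samples: Sequence[SampleRecord],
    alpha_cap: float = 0.9,
    beta_cap: float | None = None,
    ihc_table: IhcEvidenceTable | None = None,
) -> PipelineConfig:
    """Fit all four responsibility models against the cohort's own IHC labels.

    Samples with unknown IHC for a receptor are excluded from that
    receptor's fits (they still flow through the pipeline as vacuous IHC
    evidence later).
    """
    if ihc_table is None:
        ihc_table = default_ihc_table()

    def _fit(expr_attr: str, ihc_attr: str, label: str) -> ResponsibilityModel:
        xs, ys = [], []
        for rec in samples:
            status = getattr(rec, ihc_attr)
            x = getattr(rec, expr_attr)
            if status is IhcStatus.UNKNOWN or x is None or math.isnan(float(x)):
                continue
            xs.append(float(x))
            ys.append(status is IhcStatus.POS)
        fit = fit_responsibility(np.asarray(xs), np.asarray(ys))
        return ResponsibilityModel(
            fit.c0, fit.c1, alpha_cap=alpha_cap, beta_cap=beta_cap, gene_label=label
        )

    er = ReceptorModels(
        gene=_fit("er_gene_expr", "er_ihc", "ER-gene"),
        cogene=_fit("er_cogene_expr", "er_ihc", "ER-cogene"),
        ihc_table=ihc_table,
    )
    pgr = ReceptorModels(
        gene=_fit("pgr_gene_expr", "pgr_ihc", "PGR-gene"),
        cogene=_fit("pgr_cogene_expr", "pgr_ihc", "PGR-cogene"),
        ihc_table=ihc_table,
    )
    return PipelineConfig(er=er, pgr=pgr)


# ---------------------------------------------------------------------------
# Tabular I/O (TSV with header, decimal point, UTF-8)

_EXPR_COLUMNS = (
    "er_gene_expr",
    "er_cogene_expr",
    "pgr_gene_expr",
    "pgr_cogene_expr",
)


def read_samples(path) -> list[SampleRecord]:
    """Read a sample table (TSV) into records; malformed cells are reported."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [
        c
        for c in ("sample_id", *_EXPR_COLUMNS, "er_ihc", "pgr_ihc")
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"input table lacks columns: {missing}")
    for col in _EXPR_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed expression value in column {col}: {exc}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                er_gene_expr=_none_if_nan(row.er_gene_expr),
                er_cogene_expr=_none_if_nan(row.er_cogene_expr),
                pgr_gene_expr=_none_if_nan(row.pgr_gene_expr),
                pgr_cogene_expr=_none_if_nan(row.pgr_cogene_expr),
                er_ihc=parse_ihc(row.er_ihc),
                pgr_ihc=parse_ihc(row.pgr_ihc),
            )
        )
    return records


def _none_if_nan(v):
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)


def calls_frame(calls: Iterable[HormoneCall]) -> pd.DataFrame:
    """Flatten hormone calls into the canonical output table."""
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "er_alpha": c.er.evidence.alpha,
                "er_beta": c.er.evidence.beta,
                "er_theta": c.er.evidence.theta,
                "er_call": c.er.call.value,
                "pgr_alpha": c.pgr.evidence.alpha,
                "pgr_beta": c.pgr.evidence.beta,
                "pgr_theta": c.pgr.evidence.theta,
                "pgr_call": c.pgr.call.value,
                "h_alpha": c.evidence.alpha,
                "h_beta": c.evidence.beta,
                "h_theta": c.evidence.theta,
                "h_call": c.call.value,
                "any_ihc_unknown": c.any_ihc_unknown,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "er_alpha",
            "er_beta",
            "er_theta",
            "er_call",
            "pgr_alpha",
            "pgr_beta",
            "pgr_theta",
            "pgr_call",
            "h_alpha",
            "h_beta",
            "h_theta",
            "h_call",
            "any_ihc_unknown",
        ],
    )


def write_calls(calls: Iterable[HormoneCall], path) -> None:
    calls_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.10g")
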