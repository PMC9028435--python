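"""YAML run configuration: model constants, evidence tables, generator and
baseline settings, with package defaults for anything omitted."""

from __future__ import annotations

import copy
import hashlib
from typing import Any, Mapping

import yaml

from .evidence import Evidence
from .odds import OddsReceptorConfig
from .pipeline import PipelineConfig, ReceptorModels, fit_cohort_models
from .responsibility import IhcEvidenceTable, IhcStatus, ResponsibilityModel
from .synthetic import CohortSpec, GeneSpec

__all__ = [
    "build_cohort_spec",
    "build_ihc_table",
    "build_odds_configs",
    "build_pipeline_config",
    "config_hash",
    "default_config",
    "load_config",
]


def default_config() -> dict[str, Any]:
    return {
        "seed": 0,
        "threshold": 0.5,
        "cohort": {
            "n": 2000,
            "er_prevalence": 0.70,
            "pgr_prevalence": 0.60,
            "er_pgr_odds_ratio": 4.0,
            "er_gene": {"mean_pos": 12.0, "mean_neg": 8.0, "sd_pos": 2.0, "sd_neg": 2.0},
            "er_cogene": {"mean_pos": 11.0, "mean_neg": 8.5, "sd_pos": 2.0, "sd_neg": 2.0},
            "pgr_gene": {"mean_pos": 10.5, "mean_neg": 7.5, "sd_pos": 2.0, "sd_neg": 2.0},
            "cogene_correlation": 0.6,
            "ihc_misclassification": 0.15,
            "ihc_unknown_rate": 0.05,
        },
        "caps": {"alpha_cap": 0.9, "beta_cap": None},
        # reconstructed defaults, not published constants; unknown is vacuous
        "ihc_evidence": {
            "positive": [0.85, 0.0, 0.15],
            "negative": [0.0, 0.85, 0.15],
        },
        # null -> fit the four logistic models from the input cohort's IHC
        "models": None,
        "odds": {
            "gene_weight": 1.0,
            "cogene_weight": 0.5,
            "ihc_offsets": {"+": 2.0, "-": -2.0, "0": 0.0},
            "t_neg": -1.0,
            "t_pos": 1.0,
        },
        "gene_labels": {
            "er_gene": "ESR1",
            "er_cogene": "AGR3",
            "pgr_gene": "PGR",
            "pgr_cogene": "ESR1",
        },
    }


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None) -> dict[str, Any]:
    """Load YAML config merged over the package defaults."""
    cfg = default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ValueError(f"config root must be a mapping, got {type(user)}")
        cfg = _deep_merge(cfg, user)
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a config for run logging."""
    canonical = yaml.safe_dump(cfg, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:12]


def build_cohort_spec(cfg: Mapping, seed: int | None = None, n: int | None = None) -> CohortSpec:
    c = dict(cfg["cohort"])
    for key in ("er_gene", "er_cogene", "pgr_gene"):
        c[key] = GeneSpec(**c[key])
    if n is not None:
        c["n"] = n
    c["seed"] = int(cfg.get("seed", 0) if seed is None else seed)
    return CohortSpec(**c)


def build_ihc_table(cfg: Mapping) -> IhcEvidenceTable:
    ev = cfg["ihc_evidence"]
    return IhcEvidenceTable(
        positive=Evidence(*ev["positive"]),
        negative=Evidence(*ev["negative"]),
    )


def build_pipeline_config(cfg: Mapping, samples=None) -> PipelineConfig:
    """Models from explicit constants if present, else fitted from `samples`."""
    table = build_ihc_table(cfg)
    caps = cfg["caps"]
    alpha_cap = float(caps["alpha_cap"])
    beta_cap = caps.get("beta_cap")
    beta_cap = None if beta_cap is None else float(beta_cap)
    labels = cfg.get("gene_labels", {})
    models = cfg.get("models")
    if models is None:
        if samples is None:
            raise ValueError(
                "config has no explicit model constants and no cohort to fit from"
            )
        fitted = fit_cohort_models(
            samples, alpha_cap=alpha_cap, beta_cap=beta_cap, ihc_table=table
        )
        return PipelineConfig(
            er=fitted.er, pgr=fitted.pgr, threshold=float(cfg["threshold"])
        )

    def _model(key: str) -> ResponsibilityModel:
        block = models[key]
        return ResponsibilityModel(
            c0=float(block["c0"]),
            c1=float(block["c1"]),
            alpha_cap=float(block.get("alpha_cap", alpha_cap)),
            beta_cap=block.get("beta_cap", beta_cap),
            gene_label=str(block.get("gene_label", labels.get(key, key))),
        )

    er = ReceptorModels(_model("er_gene"), _model("er_cogene"), table)
    pgr = ReceptorModels(_model("pgr_gene"), _model("pgr_cogene"), table)
    return PipelineConfig(er=er, pgr=pgr, threshold=float(cfg["threshold"]))


def build_odds_configs(
    cfg: Mapping, pipeline: PipelineConfig
) -> tuple[OddsReceptorConfig, OddsReceptorConfig]:
    o = cfg["odds"]
    offsets = {IhcStatus(k): float(v) for k, v in o["ihc_offsets"].items()}

    def _cfg(models: ReceptorModels) -> OddsReceptorConfig:
        return OddsReceptorConfig(
            gene_model=models.gene,
            cogene_model=models.cogene,
            gene_weight=float(o["gene_weight"]),
            cogene_weight=float(o["cogene_weight"]),
            ihc_offsets=offsets,
            t_neg=float(o["t_neg"]),
            t_pos=float(o["t_pos"]),
        )

    return _cfg(pipeline.er), _cfg(pipeline.pgr)
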