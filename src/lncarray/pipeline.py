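"""End-to-end orchestration of the lncRNA mining stages.

Stage order: re-annotation -> probe-to-transcript summarization ->
differential expression -> median split on the target transcript ->
clinicopathological association -> Kaplan-Meier/Cox survival -> GSEA ->
over-representation of the leading edge.  Each stage writes its TSV/JSON
outputs under the run directory, and a timestamped machine-parseable log
records versions, seeds and parameters.  All randomness flows from the
configured seed, so a rerun with the same config produces identical stage
outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__, io
from .association import association_table, median_split
from .enrichment import gsea_permutation, overrepresentation_test, rank_genes
from .expression import differential_expression, summarize_expression
from .reannotation import reannotate
from .survival import cox_univariate, km_estimate

__all__ = ["PipelineConfig", "run_pipeline", "run_paperlike"]

logger = logging.getLogger("lncarray")

STAGES = [
    "reannotate", "summarize", "de", "median_split",
    "association", "survival", "gsea", "overrepresentation",
]


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    Unknown keys are rejected by :meth:`from_dict`; parameter validity is
    checked before any stage executes.
    """

    out_dir: str
    reference_fasta: str
    probe_tab: str
    probe_expr_tsv: str
    clinical_tsv: str
    survival_tsv: str
    gmt: str
    biotype_tsv: Optional[str] = None
    target_transcript: Optional[str] = None  # default: best-q assigned DE feature
    covariates: List[str] = field(default_factory=list)
    continuous_covariates: List[str] = field(default_factory=list)
    de_group_column: str = "cohort"  # clinical column with the two DE groups
    min_probes: int = 4
    unique_scope: str = "whole_reference"
    allow_revcomp: bool = False
    word_size: int = 12
    summary_method: str = "median"
    de_paired: bool = False
    de_welch: bool = False
    q_cutoff: float = 0.05
    log2fc_cutoff: float = 0.0
    n_perm: int = 1000
    gsea_weight: float = 1.0
    min_set_size: int = 5
    cox_ties: str = "breslow"
    seed: int = 0

    def validate(self) -> None:
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.unique_scope not in ("whole_reference", "lncRNA_only"):
            raise ValueError(f"unknown unique_scope {self.unique_scope!r}")
        if self.summary_method not in ("median", "mean"):
            raise ValueError(f"unknown summary_method {self.summary_method!r}")
        if self.cox_ties not in ("breslow", "efron"):
            raise ValueError(f"unknown cox_ties {self.cox_ties!r}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0 < self.q_cutoff <= 1:
            raise ValueError("q_cutoff must be in (0, 1]")
        for key in ("reference_fasta", "probe_tab", "probe_expr_tsv",
                    "clinical_tsv", "survival_tsv", "gmt"):
            path = getattr(self, key)
            if not Path(path).exists():
                raise FileNotFoundError(f"{key}: {path} does not exist")

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _stage_log(log_lines: List[str], stage: str, **kv) -> None:
    ts = datetime.datetime.now(datetime.timezone.utc).isoformat()
    payload = " ".join(f"{k}={v}" for k, v in kv.items())
    line = f"{ts}\tstage={stage}\t{payload}"
    log_lines.append(line)
    logger.info(line)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: Union[PipelineConfig, Dict]) -> Dict[str, object]:
    """Execute every stage in order and write the report bundle.

    Returns a dict with per-stage in-memory results plus ``"paths"`` mapping
    stage names to output files.  Any stage failure raises
    :class:`StageError` naming the stage; outputs of completed stages remain
    on disk and are listed as partial in the summary JSON.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    else:
        config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: List[str] = []
    _stage_log(log_lines, "start", version=__version__, seed=config.seed)
    paths: Dict[str, Path] = {}
    results: Dict[str, object] = {"paths": paths}
    completed: List[str] = []

    def finish(stage: str, path: Optional[Path] = None, **kv) -> None:
        completed.append(stage)
        if path is not None:
            paths[stage] = path
        _stage_log(log_lines, stage, **kv)

    def fail(stage: str, exc: Exception) -> StageError:
        _stage_log(log_lines, stage, error=repr(exc))
        io.write_json(
            {"completed_stages": completed, "failed_stage": stage, "partial": True},
            out / "summary.json",
        )
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        return StageError(stage, exc)

    # 1. re-annotation
    try:
        transcripts = io.read_transcripts(config.reference_fasta, config.biotype_tsv)
        probes = io.read_probe_tab(config.probe_tab)
        assignments = reannotate(
            probes, transcripts,
            min_probes=config.min_probes,
            unique_scope=config.unique_scope,  # type: ignore[arg-type]
            allow_revcomp=config.allow_revcomp,
            word_size=config.word_size,
        )
        p = out / "assignments.tsv"
        io.write_assignments(assignments, p)
        status_counts = pd.Series([a.status for a in assignments]).value_counts().to_dict()
        io.write_json({"status_counts": status_counts}, out / "assignments_summary.json")
        finish("reannotate", p, **status_counts)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise fail("reannotate", exc)

    # 2. summarization
    try:
        probe_expr = io.read_expression_matrix(config.probe_expr_tsv)
        expr = summarize_expression(probe_expr, assignments, method=config.summary_method)
        p = out / "expression_transcripts.tsv"
        io.write_expression_matrix(expr, p)
        finish("summarize", p, n_transcripts=expr.shape[0], n_samples=expr.shape[1])
    except Exception as exc:
        raise fail("summarize", exc)

    # 3. differential expression
    try:
        clinical = io.read_clinical_table(config.clinical_tsv)
        de_groups = clinical.loc[expr.columns, config.de_group_column]
        de = differential_expression(
            expr, de_groups, paired=config.de_paired, welch=config.de_welch
        )
        de = de.sort_values("p_value", kind="stable").reset_index(drop=True)
        p = out / "differential_expression.tsv"
        de.to_csv(p, sep="\t", index=False)
        n_sig = int(
            (
                (de["q_value"] < config.q_cutoff)
                & (de["log2_fold_change"].abs() >= config.log2fc_cutoff)
            ).sum()
        )
        finish("de", p, n_features=len(de), n_significant=n_sig)
    except Exception as exc:
        raise fail("de", exc)

    # 4. median split on the target transcript (tumor-side samples only)
    try:
        target = config.target_transcript
        if target is None:
            assigned = set(expr.index)
            target = next(f for f in de["feature_id"] if f in assigned)
        tumor_mask = de_groups == de_groups.sort_values().iloc[-1]  # second group label
        split_samples = expr.columns[tumor_mask.to_numpy()]
        split = median_split(expr.loc[target, split_samples])
        p = out / "median_split.tsv"
        split.rename("group").to_frame().to_csv(p, sep="\t", index_label="sample_id")
        finish(
            "median_split", p, target=target,
            n_low=int((split == "low").sum()), n_high=int((split == "high").sum()),
        )
    except Exception as exc:
        raise fail("median_split", exc)

    # 5. association with clinicopathological covariates
    try:
        covs = config.covariates or [
            c for c in clinical.columns if c != config.de_group_column
        ]
        assoc = association_table(
            expr.loc[target, split_samples],
            clinical.loc[split_samples],
            covs,
            continuous=config.continuous_covariates or None,
        )
        p = out / "association.tsv"
        assoc.to_csv(p, sep="\t", index=False)
        finish("association", p, n_covariates=len(covs))
    except Exception as exc:
        raise fail("association", exc)

    # 6. survival
    try:
        surv = io.read_survival_table(config.survival_tsv)
        surv = surv.loc[[s for s in split_samples if s in surv.index]]
        groups = split.loc[surv.index]
        km = km_estimate(surv["time_months"], surv["event"], groups)
        indicator = (groups == "high").astype(float)
        cox = cox_univariate(
            surv["time_months"], surv["event"], indicator, ties=config.cox_ties
        )
        p = out / "survival_curves.tsv"
        pd.concat(
            [c.assign(group=g) for g, c in km["curves"].items()], ignore_index=True
        ).to_csv(p, sep="\t", index=False)
        io.write_json(
            {"logrank": km["logrank"], "cox": dataclasses.asdict(cox)},
            out / "survival.json",
        )
        finish(
            "survival", p,
            hr=round(cox.hazard_ratio, 4), logrank_p=round(km["logrank"]["p"], 6),
        )
    except Exception as exc:
        raise fail("survival", exc)

    # 7. GSEA between split groups
    try:
        symbol_expr = expr.loc[:, split_samples]
        symbols = _transcript_symbols(transcripts)
        symbol_expr = symbol_expr.rename(index=symbols)
        collection = io.read_gene_sets(config.gmt)
        gsea = gsea_permutation(
            symbol_expr, split, collection,
            n_perm=config.n_perm, seed=config.seed,
            weight=config.gsea_weight, min_set_size=config.min_set_size,
        )
        gsea_df = pd.DataFrame(
            [
                {
                    "set_name": r.set_name, "es": r.es, "nes": r.nes,
                    "p_perm": r.p_perm, "q_value": r.q_value,
                    "set_size_used": r.set_size_used,
                    "leading_edge": ",".join(r.leading_edge),
                }
                for r in gsea
            ]
        ).sort_values(["q_value", "p_perm"], kind="stable")
        p = out / "gsea.tsv"
        gsea_df.to_csv(p, sep="\t", index=False)
        finish("gsea", p, n_sets=len(gsea_df))
    except Exception as exc:
        raise fail("gsea", exc)

    # 8. over-representation of the best set's leading edge (top 10 members)
    try:
        best = gsea_df.iloc[0]
        query = best["leading_edge"].split(",")[:10]
        universe = list(symbol_expr.index)
        over = overrepresentation_test(query, collection, universe)
        p = out / "overrepresentation.tsv"
        over.to_csv(p, sep="\t", index=False)
        finish("overrepresentation", p, query_set=best["set_name"], query_size=len(query))
    except Exception as exc:
        raise fail("overrepresentation", exc)

    io.write_json(
        {
            "completed_stages": completed,
            "partial": False,
            "seed": config.seed,
            "target_transcript": target,
            "paths": {k: str(v) for k, v in paths.items()},
        },
        out / "summary.json",
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    results.update(
        assignments=assignments, expression=expr, de=de, split=split,
        association=assoc, km=km, cox=cox, gsea=gsea_df, overrepresentation=over,
        target_transcript=target,
    )
    return results


def _transcript_symbols(transcripts) -> Dict[str, str]:
    return {
        t.transcript_id: t.gene_symbol or t.transcript_id for t in transcripts
    }


def run_paperlike(seed: int, out_dir: Union[str, Path], n_perm: int = 200) -> Dict[str, object]:
    """Simulate the paper-shaped study and run the full pipeline on it."""
    from .synthetic_data import simulate_paperlike

    out = Path(out_dir)
    inputs = out / "inputs"
    reference, study, gene_sets = simulate_paperlike(seed=seed, out_dir=inputs)
    cfg = PipelineConfig(
        out_dir=str(out / "results"),
        reference_fasta=str(inputs / "reference.fasta"),
        biotype_tsv=str(inputs / "biotypes.tsv"),
        probe_tab=str(inputs / "probes.tsv"),
        probe_expr_tsv=str(inputs / "probe_expression.tsv"),
        clinical_tsv=str(inputs / "clinical.tsv"),
        survival_tsv=str(inputs / "survival.tsv"),
        gmt=str(inputs / "gene_sets.gmt"),
        target_transcript=study.truth.target_transcript,
        continuous_covariates=["age_years"],
        n_perm=n_perm,
        seed=seed,
    )
    return run_pipeline(cfg)
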