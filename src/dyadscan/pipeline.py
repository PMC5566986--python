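"""End-to-end pipeline: surfaceome -> screen -> dyad scan -> filters -> rank.

One :class:`RunConfig` fixes the inputs, cohort, thresholds and mode
flags; :func:`run_pipeline` executes the stages in order, writes the
stage TSVs plus a flat key=value summary (thresholds, modes, input
checksums, stage counts), and is deterministic: identical inputs and
config reproduce identical output bytes.  Any stage error aborts with a
stage-labelled message and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import dyad as dyad_mod
from . import surfaceome as surf_mod
from .de_screen import gene_stats, gene_stats_frame, screen
from .io_model import (
    DyadscanError,
    FormatError,
    Thresholds,
    log2_transform,
    read_evidence,
    read_expression,
    read_samples,
)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "annotate_targets",
    "read_config_file",
    "write_summary",
]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    expression_path: Path
    samples_path: Path
    evidence_path: Path
    cohort: str
    out_dir: Path
    risk_path: Optional[Path] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    test_mode: str = "welch"          # welch | moderated
    normals: str = "all"              # all | nonbrain
    require_positive_r: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("expression_path", "samples_path", "evidence_path", "risk_path"):
            p = getattr(self, name)
            if p is None:
                continue
            if not Path(p).exists():
                raise FormatError(f"{name}: no such file {p}")
        Path(self.out_dir).mkdir(parents=True, exist_ok=True)


@dataclass
class PipelineResult:
    ranked: list
    all_dyads: list
    summary: dict
    out_files: dict


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute every stage for one tumor cohort and write the artifacts.

    Outputs in ``cfg.out_dir``: ``surfaceome.tsv`` (consensus scores),
    ``screen.tsv`` (per-gene statistics), ``dyads.tsv`` (all evaluated
    pairs with filter outcomes and ranks), ``summary.txt``.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_files = {
        "surfaceome": out_dir / "surfaceome.tsv",
        "screen": out_dir / "screen.tsv",
        "dyads": out_dir / "dyads.tsv",
        "summary": out_dir / "summary.txt",
    }
    written = []
    stage = "configuration"
    try:
        th = cfg.thresholds
        stage = "input"
        matrix = read_expression(cfg.expression_path)
        samples = read_samples(cfg.samples_path)
        samples.validate_against(matrix)
        evidence = read_evidence(cfg.evidence_path)
        if th.consensus_votes_min > evidence.n_sources:
            raise FormatError(
                f"consensus_votes_min={th.consensus_votes_min} exceeds the "
                f"{evidence.n_sources} evidence sources"
            )

        stage = "surfaceome"
        scores = surf_mod.consensus_score(evidence, th.consensus_votes_min)
        surf_matrix = surf_mod.select_surfaceome(matrix, scores)
        surf_mod.scores_frame(scores).to_csv(
            out_files["surfaceome"], sep="\t", index=False
        )
        written.append(out_files["surfaceome"])

        stage = "screen"
        gstats = gene_stats(surf_matrix, samples, cfg.cohort, th, mode=cfg.test_mode)
        screened = screen(gstats, th)
        gene_stats_frame(gstats).to_csv(
            out_files["screen"], sep="\t", index=False, float_format=_FLOAT_FMT
        )
        written.append(out_files["screen"])

        stage = "dyad"
        if len(screened) < 2:
            raise DyadscanError(
                f"{len(screened)} screened gene(s); >=2 needed for pair testing"
            )
        m_log = log2_transform(surf_matrix.subset_genes(screened), th.pseudocount)
        dyads = dyad_mod.dyad_scan(m_log, samples, cfg.cohort, th, normals=cfg.normals)
        dyads = dyad_mod.apply_filters(
            dyads, gstats, th, require_positive_r=cfg.require_positive_r
        )
        ranked, rank_summary = dyad_mod.rank_dyads(dyads)
        # persist ranks into the full table
        rank_of = {d.pair: d.rank for d in ranked}
        for d in dyads:
            d.rank = rank_of.get(d.pair)
        dyad_mod.dyads_frame(dyads).to_csv(
            out_files["dyads"], sep="\t", index=False, float_format=_FLOAT_FMT
        )
        written.append(out_files["dyads"])

        stage = "summary"
        summary = {
            "cohort": cfg.cohort,
            "test_mode": cfg.test_mode,
            "normals": cfg.normals,
            "require_positive_r": int(cfg.require_positive_r),
            "seed": cfg.seed,
            "sha256_expression": _sha256(cfg.expression_path),
            "sha256_samples": _sha256(cfg.samples_path),
            "sha256_evidence": _sha256(cfg.evidence_path),
            "n_genes_input": matrix.shape[0],
            "n_samples_input": matrix.shape[1],
            "n_surface_genes": surf_matrix.shape[0],
            "n_screened_genes": len(screened),
            "n_dyads_attempted": len(m_log.gene_ids) * (len(m_log.gene_ids) - 1) // 2,
            "n_dyads_evaluated": len(dyads),
            "n_dyads_passing": rank_summary["n_pairs"],
            "n_unique_genes": rank_summary["n_unique_genes"],
        }
        for f in dataclasses.fields(th):
            summary[f"threshold_{f.name}"] = getattr(th, f.name)
        write_summary(summary, out_files["summary"])
        written.append(out_files["summary"])
    except Exception as exc:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise DyadscanError(f"[stage: {stage}] {exc}") from exc
    log.info("pipeline done: %s", {k: summary[k] for k in
                                   ("n_surface_genes", "n_screened_genes",
                                    "n_dyads_passing", "n_unique_genes")})
    return PipelineResult(
        ranked=ranked, all_dyads=dyads, summary=summary, out_files=out_files
    )


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        for k in sorted(summary):
            fh.write(f"{k}={summary[k]}\n")


def read_config_file(path) -> dict:
    """Parse a flat ``key = value`` config file (lines starting with '#'
    are comments); returns raw string values for the CLI to coerce."""
    out = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{ln}: expected key=value, got {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def annotate_targets(ranked: pd.DataFrame, risk: pd.DataFrame) -> pd.DataFrame:
    """Left-join per-gene risk categories onto a ranked dyad table.

    ``risk`` needs columns ``gene_id`` and ``category``; genes without a
    category are annotated "unclassified".
    """
    missing = {"gene_id", "category"} - set(risk.columns)
    if missing:
        raise FormatError(f"risk table missing column(s) {sorted(missing)}")
    if risk["gene_id"].duplicated().any():
        dup = risk.loc[risk["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"risk table: duplicate gene_id {dup!r}")
    lookup = dict(zip(risk["gene_id"], risk["category"].astype(str)))
    out = ranked.copy()
    out["category_a"] = [lookup.get(g, "unclassified") for g in out["gene_a"]]
    out["category_b"] = [lookup.get(g, "unclassified") for g in out["gene_b"]]
    return out
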