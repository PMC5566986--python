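"""Surfaceome selection by consensus voting over annotation sources.

A gene is called plasma-membrane resident ("surface") when at least
``min_votes`` of the independent evidence sources score it positive — the
consensus mechanism that defines which genes are candidate antibody / CAR
targets before any expression statistics are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io_model import DyadscanError, EvidenceTable, ExpressionMatrix

__all__ = ["ConsensusScore", "consensus_score", "select_surfaceome", "scores_frame"]

log = logging.getLogger(__name__)


class ConfigurationError(DyadscanError):
    pass


class NoSurfaceGenesError(DyadscanError):
    """Surfaceome selection produced an empty matrix; downstream stages are
    undefined on empty input."""


@dataclass(frozen=True)
class ConsensusScore:
    gene_id: str
    votes: int
    n_sources: int
    is_surface: bool


def consensus_score(ev: EvidenceTable, min_votes: int) -> list[ConsensusScore]:
    """Count positive source calls per gene and apply the consensus vote.

    Missing evidence is absence of evidence: only explicit positive calls
    count.  Deterministic; gene order follows the evidence table.
    """
    if min_votes > ev.n_sources:
        raise ConfigurationError(
            f"min_votes={min_votes} exceeds the {ev.n_sources} evidence sources"
        )
    votes = ev.table.sum(axis=1)
    return [
        ConsensusScore(
            gene_id=g,
            votes=int(v),
            n_sources=ev.n_sources,
            is_surface=bool(v >= min_votes),
        )
        for g, v in votes.items()
    ]


def scores_frame(scores: list[ConsensusScore]) -> pd.DataFrame:
    """Tabular form of consensus scores for TSV output."""
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "votes": [s.votes for s in scores],
            "n_sources": [s.n_sources for s in scores],
            "is_surface": [int(s.is_surface) for s in scores],
        }
    )


def select_surfaceome(
    m: ExpressionMatrix, scores: list[ConsensusScore]
) -> ExpressionMatrix:
    """Restrict the expression matrix to consensus surface genes.

    Genes in the matrix but absent from the evidence table are treated as
    non-surface and dropped with a logged warning.  Raises
    :class:`NoSurfaceGenesError` when nothing survives.
    """
    surface = {s.gene_id for s in scores if s.is_surface}
    scored = {s.gene_id for s in scores}
    unscored = [g for g in m.gene_ids if g not in scored]
    if unscored:
        log.warning(
            "%d gene(s) in the expression matrix have no evidence record "
            "and are treated as non-surface (e.g. %s)",
            len(unscored), unscored[:3],
        )
    keep = [g for g in m.gene_ids if g in surface]
    if not keep:
        raise NoSurfaceGenesError(
            "no surface genes: the consensus surfaceome does not intersect "
            "the expression matrix"
        )
    log.info("surfaceome: %d of %d genes retained", len(keep), len(m.gene_ids))
    return m.subset_genes(keep)
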