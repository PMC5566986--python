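"""Synthetic expression / design / evidence generator with planted dyads.

Emulates the study design the analysis targets: two tumor cohorts (32
MYCN-amplified and 70 MYCN-non-amplified samples by default) compared
against a 63-sample normal panel (17 brain, 46 other tissues including
heart, liver, lung and kidney groups).  Values are drawn on the log2
scale as

    value = baseline(gene) + tissue offset + delta(planted, tumor) + noise

with per-gene noise variances from a scaled inverse-chi-square prior
(sigma^2 = d0*s0^2 / chi^2_d0), enabling the variance-moderation mode to
be exercised, and back-transformed to FPKM = 2^value - pseudocount,
floored at zero.

Planted dyads are pairs of consensus-surface genes that behave like bona
fide immunotherapy targets: near-silent across the normal panel (low
baseline, small normal-tissue noise) and shifted up by ``delta`` log2
units in both tumor cohorts, with bivariate-Gaussian tumor noise
correlated at ``rho`` inside each cohort.  Normal-tissue values of all
genes are uncorrelated.  Optionally, the first ``n_vital_leak`` planted
genes "leak" into one vital organ at a controlled median FPKM so the
vital-organ filter is exercised non-trivially.

Determinism: every random draw comes from a stream keyed on (seed, block),
so identical parameters give byte-identical outputs and adding genes does
not perturb earlier genes' values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd

from .io_model import (
    VITAL_ORGANS,
    DesignError,
    EvidenceTable,
    ExpressionMatrix,
    SampleTable,
)

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "RecoveryReport",
    "EVIDENCE_SOURCES",
    "simulate_dataset",
    "evaluate_recovery",
]

log = logging.getLogger(__name__)

#: default nine localization evidence sources used for consensus voting
EVIDENCE_SOURCES = (
    "surfaceome_compendium",
    "conserved_domains",
    "go_plasma_membrane",
    "surface_evidence",
    "amigo",
    "loc_knowledge",
    "loc_experiments",
    "loc_prediction",
    "loc_textmining",
)


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults reproduce the emulated study design."""

    n_genes: int = 2000
    frac_surface: float = 0.3
    n_tumor_a: int = 32        # MYCN-amplified cohort
    n_tumor_na: int = 70       # MYCN-non-amplified cohort
    n_brain: int = 17
    n_other_normal: int = 46   # includes one sample group per vital organ
    n_planted_dyads: int = 20
    delta: float = 3.0         # planted tumor shift, log2 units
    rho: float = 0.7           # within-tumor correlation of planted pair members
    baseline_mean: float = 3.0     # log2 scale, background genes
    baseline_sd: float = 1.5
    planted_baseline_mean: float = 0.25  # planted targets are near-silent in normals
    planted_baseline_sd: float = 0.15
    planted_normal_sd: float = 0.2
    sigma_shape: float = 4.0       # d0 of the scaled inverse-chi-square noise prior
    sigma_scale: float = 0.25      # s0^2 of the prior
    tissue_offset_sd: float = 0.3  # per (gene, normal tissue) offset spread
    evidence_p_surface: float = 0.95
    evidence_p_nonsurface: float = 0.05
    consensus_votes_min: int = 7
    n_vital_leak: int = 0
    vital_leak_fpkm: float = 1.5
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tumor_a", "n_tumor_na", "n_brain",
                     "n_other_normal"):
            if getattr(self, name) < 1:
                raise DesignError(f"{name} must be positive")
        if not (0.0 < self.frac_surface <= 1.0):
            raise DesignError("frac_surface must lie in (0, 1]")
        if not (0.0 <= self.rho < 1.0):
            raise DesignError("rho must lie in [0, 1)")
        for name in ("evidence_p_surface", "evidence_p_nonsurface"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DesignError(f"{name} must lie in [0, 1]")
        if self.n_planted_dyads < 0 or self.n_vital_leak < 0:
            raise DesignError("counts must be non-negative")
        if self.n_vital_leak > 2 * self.n_planted_dyads:
            raise DesignError("more vital-leak genes than planted genes")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    surface_genes: tuple            # genes meeting the consensus vote
    planted_dyads: tuple            # canonical (gene_a, gene_b) pairs
    planted_shifts: dict            # gene -> tumor shift in log2 units
    vital_leak_genes: tuple         # planted genes leaking into a vital organ

    @property
    def planted_genes(self) -> set:
        out = set()
        for a, b in self.planted_dyads:
            out.update((a, b))
        return out


def _rng(seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def _sample_design(p: SimulationParams) -> pd.DataFrame:
    rows = []
    for i in range(p.n_tumor_a):
        rows.append(("T_A_%03d" % i, "tumor", "MYCN_A", "", 0, 0, "none"))
    for i in range(p.n_tumor_na):
        rows.append(("T_NA_%03d" % i, "tumor", "MYCN_NA", "", 0, 0, "none"))
    for i in range(p.n_brain):
        rows.append(("N_BRAIN_%03d" % i, "normal", "", "brain", 1, 0, "none"))
    per_vital = max(3, p.n_other_normal // 10)
    if 4 * per_vital > p.n_other_normal:
        raise DesignError(
            "n_other_normal too small to host the four vital-organ groups"
        )
    k = 0
    for organ in VITAL_ORGANS:
        for i in range(per_vital):
            rows.append((f"N_{organ.upper()}_%03d" % i, "normal", "", organ, 0, 1, organ))
            k += 1
    rest = p.n_other_normal - k
    group_size = 5
    for i in range(rest):
        t = f"tissue{i // group_size}"
        rows.append((f"N_{t.upper()}_%03d" % (i % group_size), "normal", "", t, 0, 0, "none"))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "cohort", "tissue",
                 "is_brain", "is_vital", "vital_organ"],
    )


def simulate_dataset(
    p: SimulationParams,
) -> tuple[ExpressionMatrix, SampleTable, EvidenceTable, SimulationTruth]:
    """Generate one complete synthetic dataset.

    Returns the FPKM expression matrix, sample design, evidence table and
    the ground truth needed to score recovery.  Identical parameters
    (including seed) give byte-identical outputs.
    """
    design = _sample_design(p)
    samples = SampleTable(design)
    sample_ids = list(samples.table["sample_id"])
    tissues = [t for t in dict.fromkeys(samples.table["tissue"]) if t]
    tissue_of = dict(zip(samples.table["sample_id"], samples.table["tissue"]))
    normal_mask = (samples.table["group"] == "normal").to_numpy()
    cohort_cols = {
        c: np.flatnonzero((samples.table["cohort"] == c).to_numpy())
        for c in ("MYCN_A", "MYCN_NA")
    }

    genes = ["G%05d" % i for i in range(p.n_genes)]
    n_sources = len(EVIDENCE_SOURCES)

    # evidence votes per gene, from each gene's own stream
    votes = np.zeros((p.n_genes, n_sources), dtype=int)
    intended_surface = np.zeros(p.n_genes, dtype=bool)
    for gi in range(p.n_genes):
        rg = _rng(p.seed, 0, gi)
        intended = rg.random() < p.frac_surface
        prob = p.evidence_p_surface if intended else p.evidence_p_nonsurface
        votes[gi] = rg.random(n_sources) < prob
        intended_surface[gi] = intended
    evidence = EvidenceTable(
        pd.DataFrame(votes, index=pd.Index(genes, name="gene_id"),
                     columns=list(EVIDENCE_SOURCES))
    )
    surface_idx = np.flatnonzero(votes.sum(axis=1) >= p.consensus_votes_min)
    n_needed = 2 * p.n_planted_dyads
    if len(surface_idx) < n_needed:
        raise DesignError(
            f"only {len(surface_idx)} consensus-surface genes; "
            f"{n_needed} needed for {p.n_planted_dyads} planted dyads"
        )
    plant_rng = _rng(p.seed, 1)
    chosen = plant_rng.choice(surface_idx, size=n_needed, replace=False)
    pairs_idx = [(int(chosen[2 * i]), int(chosen[2 * i + 1]))
                 for i in range(p.n_planted_dyads)]
    planted_set = {g for pr in pairs_idx for g in pr}
    leak_genes_idx = sorted(planted_set)[: p.n_vital_leak]
    leak_organ = {g: VITAL_ORGANS[i % len(VITAL_ORGANS)]
                  for i, g in enumerate(leak_genes_idx)}

    n_samples = len(sample_ids)
    V = np.zeros((p.n_genes, n_samples))

    # background genes: one stream per gene
    for gi in range(p.n_genes):
        if gi in planted_set:
            continue
        rg = _rng(p.seed, 2, gi)
        mu = p.baseline_mean + p.baseline_sd * rg.standard_normal()
        sigma = np.sqrt(p.sigma_shape * p.sigma_scale / rg.chisquare(p.sigma_shape))
        offs = dict(zip(tissues, p.tissue_offset_sd * rg.standard_normal(len(tissues))))
        eps = sigma * rg.standard_normal(n_samples)
        for si, sid in enumerate(sample_ids):
            off = offs[tissue_of[sid]] if normal_mask[si] else 0.0
            V[gi, si] = mu + off + eps[si]

    # planted dyads: one stream per pair (tumor noise is bivariate per cohort)
    for pi, (ga, gb) in enumerate(pairs_idx):
        rg = _rng(p.seed, 3, pi)
        for gi in (ga, gb):
            mu = p.planted_baseline_mean + p.planted_baseline_sd * rg.standard_normal()
            # near-silent in normals: small dedicated noise, damped offsets
            offs = dict(zip(
                tissues, 0.2 * p.tissue_offset_sd * rg.standard_normal(len(tissues))
            ))
            for si, sid in enumerate(sample_ids):
                if normal_mask[si]:
                    V[gi, si] = (mu + offs[tissue_of[sid]]
                                 + p.planted_normal_sd * rg.standard_normal())
                else:
                    V[gi, si] = mu + p.delta  # tumor noise added below
        sig_a = np.sqrt(p.sigma_shape * p.sigma_scale / rg.chisquare(p.sigma_shape))
        sig_b = np.sqrt(p.sigma_shape * p.sigma_scale / rg.chisquare(p.sigma_shape))
        cov = np.array([
            [sig_a**2, p.rho * sig_a * sig_b],
            [p.rho * sig_a * sig_b, sig_b**2],
        ])
        chol = np.linalg.cholesky(cov)
        for cols in cohort_cols.values():
            z = rg.standard_normal((2, len(cols)))
            noise = chol @ z
            V[ga, cols] += noise[0]
            V[gb, cols] += noise[1]

    # vital-organ leak: controlled median FPKM in one organ
    leak_level = np.log2(p.vital_leak_fpkm + p.pseudocount)
    for gi in leak_genes_idx:
        rg = _rng(p.seed, 4, gi)
        organ = leak_organ[gi]
        cols = np.flatnonzero((samples.table["vital_organ"] == organ).to_numpy())
        V[gi, cols] = leak_level + 0.05 * rg.standard_normal(len(cols))

    fpkm = np.maximum(np.exp2(V) - p.pseudocount, 0.0)
    matrix = ExpressionMatrix(
        pd.DataFrame(fpkm, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    )
    truth = SimulationTruth(
        surface_genes=tuple(genes[i] for i in surface_idx),
        planted_dyads=tuple(
            tuple(sorted((genes[a], genes[b]))) for a, b in pairs_idx
        ),
        planted_shifts={genes[g]: p.delta for g in sorted(planted_set)},
        vital_leak_genes=tuple(genes[g] for g in leak_genes_idx),
    )
    log.info(
        "simulated %d genes x %d samples; %d surface, %d planted dyads, %d leak",
        p.n_genes, n_samples, len(surface_idx), p.n_planted_dyads, len(leak_genes_idx),
    )
    return matrix, samples, evidence, truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    n_planted: int
    n_recovered: int
    sensitivity: float
    false_candidate_genes: tuple   # ranked-dyad genes outside any planted dyad
    extra_pairs: int               # ranked pairs that are not planted dyads

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["n_planted", "n_recovered", "sensitivity",
                           "n_false_candidate_genes", "extra_pairs"],
                "value": [self.n_planted, self.n_recovered, self.sensitivity,
                          len(self.false_candidate_genes), self.extra_pairs],
            }
        )


def evaluate_recovery(ranked, truth: SimulationTruth) -> RecoveryReport:
    """Score a ranked dyad list against the planted ground truth.

    Sensitivity is the fraction of planted dyads present among the ranked
    pairs; false-candidate genes are members of ranked pairs that belong
    to no planted dyad.
    """
    ranked_pairs = {(d.gene_a, d.gene_b) for d in ranked}
    planted = set(truth.planted_dyads)
    recovered = ranked_pairs & planted
    ranked_genes = {g for pr in ranked_pairs for g in pr}
    false_genes = tuple(sorted(ranked_genes - truth.planted_genes))
    sens = len(recovered) / len(planted) if planted else float("nan")
    return RecoveryReport(
        n_planted=len(planted),
        n_recovered=len(recovered),
        sensitivity=sens,
        false_candidate_genes=false_genes,
        extra_pairs=len(ranked_pairs - planted),
    )
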