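"""Pairwise ("dyad") co-overexpression testing, filtering and ranking.

Every unordered pair of screened surface genes is tested with a two-group
Hotelling's T^2: with d the difference of the two groups' mean vectors and
S the pooled covariance,

    T^2 = (n1*n2 / (n1+n2)) * d' S^{-1} d,
    F   = T^2 * (n1+n2-p-1) / (p * (n1+n2-2)),   df = (p, n1+n2-p-1),

which for two groups is equivalent to the Hotelling-Lawley MANOVA trace
T^2 / (n1+n2-2).  Linear dependence of the pair inside the tumor cohort is
scored with the Pearson correlation and its t-transform p-value.  Six
filters then decide candidacy:

  (a) Hotelling p <= 0.01,
  (b) tumor-only Pearson p <= 0.05,
  (c) tumor median log2(FPKM) >= 2 for both genes,
  (d) logFC vs all normals >= 2 for both genes,
  (e) logFC vs brain alone >= 2 for both genes,
  (f) median FPKM in every vital organ (heart/liver/lung/kidney) below a
      ceiling (1.0 by default, loosenable to 1.5 or 2.0) for both genes.

Survivors are ranked by F descending.  Raw p-values are primary, as in the
output table; a Benjamini-Hochberg column is appended for information only
and never affects filtering.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import DesignError, DyadscanError, ExpressionMatrix, SampleTable, Thresholds
from .de_screen import GeneStats

__all__ = [
    "HotellingResult",
    "CorrelationResult",
    "DyadResult",
    "NotEvaluableError",
    "hotelling_two_sample",
    "f_upper_tail",
    "pearson_tumor",
    "dyad_scan",
    "apply_filters",
    "rank_dyads",
    "compare_cohorts",
    "dyads_frame",
]

log = logging.getLogger(__name__)

_TINY_P = np.nextafter(0.0, 1.0)
#: condition-number ceiling beyond which a pooled covariance is treated as
#: singular (constant gene or collinear pair)
_COND_MAX = 1e12

FILTER_LABELS = ("a", "b", "c", "d", "e", "f")


class NotEvaluableError(DyadscanError):
    """A pair statistic is undefined (singular covariance, constant gene)."""


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n1: int
    n2: int
    hl_trace: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t_stat: float
    df: int
    p_value: float


@dataclass
class DyadResult:
    gene_a: str
    gene_b: str
    hotelling: HotellingResult
    correlation: CorrelationResult
    passed_filters: bool = False
    filter_failures: list = field(default_factory=list)
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise DesignError(
                f"dyad not canonical: {self.gene_a!r} must sort before {self.gene_b!r}"
            )

    @property
    def pair(self) -> str:
        return f"{self.gene_a}_{self.gene_b}"


def canonical_pair(g1: str, g2: str) -> tuple[str, str]:
    """Unordered pair stored canonically (lexicographic)."""
    if g1 == g2:
        raise DesignError(f"a dyad needs two distinct genes, got {g1!r} twice")
    return (g1, g2) if g1 < g2 else (g2, g1)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def hotelling_two_sample(xa: np.ndarray, xb: np.ndarray) -> HotellingResult:
    """Two-sample Hotelling T^2 for paired observations (rows = samples).

    Requires n1, n2 >= 3 so that df2 >= 2 for p = 2 variables, and a
    nonsingular pooled covariance; a constant gene or a perfectly collinear
    pair raises :class:`NotEvaluableError`.
    """
    xa = np.atleast_2d(np.asarray(xa, dtype=float))
    xb = np.atleast_2d(np.asarray(xb, dtype=float))
    if xa.shape[1] != xb.shape[1]:
        raise DesignError("groups must share the same variables")
    p = xa.shape[1]
    n1, n2 = xa.shape[0], xb.shape[0]
    if n1 < 3 or n2 < 3:
        raise DesignError(f"need >=3 observations per group, got {n1} and {n2}")
    if n1 + n2 - p - 1 < 1:
        raise DesignError("too few observations for the number of variables")
    d = xa.mean(axis=0) - xb.mean(axis=0)
    s1 = np.cov(xa, rowvar=False, ddof=1).reshape(p, p)
    s2 = np.cov(xb, rowvar=False, ddof=1).reshape(p, p)
    S = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    if not np.all(np.isfinite(S)) or np.linalg.cond(S) > _COND_MAX:
        raise NotEvaluableError("singular pooled covariance")
    t2 = float(n1 * n2 / (n1 + n2) * d @ np.linalg.solve(S, d))
    t2 = max(t2, 0.0)  # guard roundoff on near-zero shifts
    df1 = p
    df2 = n1 + n2 - p - 1
    f_stat = t2 * df2 / (df1 * (n1 + n2 - 2))
    return HotellingResult(
        t2=t2,
        f_stat=f_stat,
        df1=df1,
        df2=df2,
        p_value=f_upper_tail(f_stat, df1, df2),
        n1=n1,
        n2=n2,
        hl_trace=t2 / (n1 + n2 - 2),
    )


def f_upper_tail(x: float, df1: int, df2: int) -> float:
    """Upper-tail (survival) probability of the F distribution, in (0, 1]."""
    if x < 0:
        raise DesignError(f"F statistic must be >= 0, got {x}")
    if df1 < 1 or df2 < 1:
        raise DesignError("degrees of freedom must be >= 1")
    return float(max(stats.f.sf(x, df1, df2), _TINY_P))


def pearson_tumor(xa: np.ndarray, xb: np.ndarray) -> CorrelationResult:
    """Pearson correlation of a gene pair across tumor samples only.

    p is two-sided from t = r*sqrt((n-2)/(1-r^2)) on n-2 df.  Constant
    vectors raise :class:`NotEvaluableError`.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    n = xa.size
    if n < 3 or xb.size != n:
        raise DesignError("pearson_tumor needs two equal-length vectors, n >= 3")
    if np.ptp(xa) == 0.0 or np.ptp(xb) == 0.0:
        raise NotEvaluableError("constant vector: correlation undefined")
    r = float(np.corrcoef(xa, xb)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        return CorrelationResult(r=r, t_stat=np.sign(r) * np.inf, df=df, p_value=_TINY_P)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(max(2.0 * stats.t.sf(abs(t), df), _TINY_P))
    return CorrelationResult(r=r, t_stat=float(t), df=df, p_value=p)


# ---------------------------------------------------------------------------
# All-pairs scan
# ---------------------------------------------------------------------------

def dyad_scan(
    m_log: ExpressionMatrix,
    s: SampleTable,
    cohort: str,
    th: Thresholds,
    normals: str = "all",
) -> list[DyadResult]:
    """Test every unordered pair of genes in ``m_log`` (log2 scale).

    Each of the C(G, 2) canonical pairs gets a tumor-vs-normal Hotelling
    T^2 and a tumor-only Pearson correlation.  ``normals`` selects the
    comparison panel for the Hotelling test: ``"all"`` normals (default)
    or ``"nonbrain"``.  Pairs with a singular covariance or a constant
    member are skipped with a logged reason.
    """
    if m_log.scale != "log2":
        raise DesignError("dyad_scan expects a log2-scale matrix")
    genes = m_log.gene_ids
    if len(genes) < 2:
        raise DesignError(f"dyad_scan needs >=2 genes, got {len(genes)}")
    if normals not in ("all", "nonbrain"):
        raise DesignError(f"normals must be 'all' or 'nonbrain', got {normals!r}")
    tumor_ids = s.ids(group="tumor", cohort=cohort)
    normal_ids = (
        s.ids(group="normal") if normals == "all" else s.ids(group="normal", brain=False)
    )
    if len(tumor_ids) < 3 or len(normal_ids) < 3:
        raise DesignError("Hotelling test needs >=3 tumor and >=3 normal samples")

    T = m_log.values[tumor_ids].to_numpy()  # genes x tumor samples
    N = m_log.values[normal_ids].to_numpy()

    idx = {g: i for i, g in enumerate(genes)}
    results: list[DyadResult] = []
    n_skipped = 0
    for g1, g2 in itertools.combinations(genes, 2):
        ga, gb = canonical_pair(g1, g2)
        ia, ib = idx[ga], idx[gb]
        try:
            hot = hotelling_two_sample(T[[ia, ib]].T, N[[ia, ib]].T)
            cor = pearson_tumor(T[ia], T[ib])
        except NotEvaluableError as exc:
            n_skipped += 1
            log.warning("dyad %s_%s skipped: %s", ga, gb, exc)
            continue
        results.append(DyadResult(gene_a=ga, gene_b=gb, hotelling=hot, correlation=cor))
    log.info(
        "dyad_scan: %d pairs attempted, %d evaluated, %d skipped",
        len(genes) * (len(genes) - 1) // 2, len(results), n_skipped,
    )
    return results


# ---------------------------------------------------------------------------
# Filters (a)-(f)
# ---------------------------------------------------------------------------

def apply_filters(
    dyads: list[DyadResult],
    gstats: list[GeneStats],
    th: Thresholds,
    require_positive_r: bool = False,
) -> list[DyadResult]:
    """Evaluate filters (a)-(f) on every dyad; returns new result records.

    (a) and (b) read the pair statistics; (c)-(f) must hold for *both*
    member genes.  ``filter_failures`` lists every violated label.  A NaN
    gene statistic (brain or vital organs not evaluable) fails its filter:
    a candidate is never passed on an unverifiable safety criterion.
    """
    by_gene = {r.gene_id: r for r in gstats}
    out = []
    for dy in dyads:
        for g in (dy.gene_a, dy.gene_b):
            if g not in by_gene:
                raise DesignError(f"no gene statistics for {g!r}")
        ra, rb = by_gene[dy.gene_a], by_gene[dy.gene_b]
        fails = []
        if not dy.hotelling.p_value <= th.manova_p_max:
            fails.append("a")
        ok_b = dy.correlation.p_value <= th.pearson_p_max
        if require_positive_r:
            ok_b = ok_b and dy.correlation.r > 0
        if not ok_b:
            fails.append("b")
        if not (
            ra.median_log2_tumor >= th.median_log2_min
            and rb.median_log2_tumor >= th.median_log2_min
        ):
            fails.append("c")
        if not (
            ra.logfc_vs_normal >= th.logfc_vs_normal_min
            and rb.logfc_vs_normal >= th.logfc_vs_normal_min
        ):
            fails.append("d")
        if not (
            ra.logfc_vs_brain >= th.logfc_vs_brain_min
            and rb.logfc_vs_brain >= th.logfc_vs_brain_min
        ):
            fails.append("e")
        if not (
            ra.max_vital_fpkm <= th.vital_fpkm_max
            and rb.max_vital_fpkm <= th.vital_fpkm_max
        ):
            fails.append("f")
        out.append(
            replace(dy, passed_filters=not fails, filter_failures=fails, rank=None)
        )
    return out


# ---------------------------------------------------------------------------
# Ranking and reporting
# ---------------------------------------------------------------------------

def rank_dyads(dyads: list[DyadResult]) -> tuple[list[DyadResult], dict]:
    """Rank passing dyads by F descending (ties: p ascending, then pair name).

    Returns the ranked passing list and a summary with the pair count and
    the number of unique genes across ranked pairs.
    """
    passing = [d for d in dyads if d.passed_filters]
    passing.sort(key=lambda d: (-d.hotelling.f_stat, d.hotelling.p_value, d.pair))
    ranked = [replace(d, rank=i + 1) for i, d in enumerate(passing)]
    genes = set()
    for d in ranked:
        genes.update((d.gene_a, d.gene_b))
    summary = {"n_pairs": len(ranked), "n_unique_genes": len(genes)}
    log.info("rank_dyads: %(n_pairs)d pairs over %(n_unique_genes)d genes", summary)
    return ranked, summary


def compare_cohorts(
    ranked_a: list[DyadResult], ranked_b: list[DyadResult]
) -> pd.DataFrame:
    """Dyads shared between two ranked lists, with both ranks."""
    by_pair_b = {d.pair: d for d in ranked_b}
    rows = [
        {"pair": d.pair, "rank_a": d.rank, "rank_b": by_pair_b[d.pair].rank}
        for d in ranked_a
        if d.pair in by_pair_b
    ]
    return pd.DataFrame(rows, columns=["pair", "rank_a", "rank_b"])


def dyads_frame(dyads: list[DyadResult]) -> pd.DataFrame:
    """Tabular dyad report: pair, F-value, p-value, tumor r and its p,
    rank, filter failures, and an informational Benjamini-Hochberg column
    over the Hotelling p-values (never used for filtering)."""
    df = pd.DataFrame(
        {
            "pair": [d.pair for d in dyads],
            "gene_a": [d.gene_a for d in dyads],
            "gene_b": [d.gene_b for d in dyads],
            "t2": [d.hotelling.t2 for d in dyads],
            "f_value": [d.hotelling.f_stat for d in dyads],
            "p_value": [d.hotelling.p_value for d in dyads],
            "r": [d.correlation.r for d in dyads],
            "r_p_value": [d.correlation.p_value for d in dyads],
            "passed_filters": [int(d.passed_filters) for d in dyads],
            "filter_failures": ["".join(d.filter_failures) for d in dyads],
            "rank": [d.rank if d.rank is not None else "" for d in dyads],
        }
    )
    df["p_bh"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):
        running = min(running, p[order[i]] * n / (i + 1))
        adj[order[i]] = running
    return adj
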