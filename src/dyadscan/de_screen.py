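"""Single-gene overexpression screen of one tumor cohort against normals.

A gene passes the screen when, comparing the chosen tumor cohort to the
normal-tissue panel on the log2(FPKM + pseudocount) scale,

* its log fold-change (difference of group means) is >= ``screen_logfc_min``,
* its tumor-cohort median FPKM exceeds ``screen_fpkm_min``, and
* its two-sample p-value is <= ``screen_p_max``.

The two-sample test runs either as a plain Welch t (Satterthwaite df) or
in a variance-moderated mode that shrinks each gene's pooled variance
toward an empirical-Bayes prior estimated across all genes — the standard
shrinkage idea for stabilising small-sample variance estimates in
genome-wide screens.  The screen also records, per gene, the statistics
the later pair filters consume: tumor median on the log2 scale, log
fold-change against brain alone, and the worst-case vital-organ median
FPKM (max over the per-organ medians of heart, liver, lung and kidney).

Fields that cannot be evaluated (no brain samples, no vital-organ
samples) are set to NaN, logged, and treated as failing by the filters
that read them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_model import (
    VITAL_ORGANS,
    DesignError,
    ExpressionMatrix,
    SampleTable,
    Thresholds,
    log2_transform,
)

__all__ = [
    "GeneStats",
    "VariancePrior",
    "estimate_variance_prior",
    "two_sample_test",
    "gene_stats",
    "gene_stats_frame",
    "screen",
]

log = logging.getLogger(__name__)

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class GeneStats:
    """Per-gene screen statistics (log2 scale except ``*_fpkm`` fields)."""

    gene_id: str
    median_log2_tumor: float
    median_tumor_fpkm: float
    logfc_vs_normal: float
    logfc_vs_brain: float
    max_vital_fpkm: float
    t_stat: float
    df: float
    p_value: float
    passes_screen: bool


# ---------------------------------------------------------------------------
# Empirical-Bayes variance prior (moderated mode)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariancePrior:
    """Scaled inverse-chi-square prior (d0, s0^2) for gene-wise variances."""

    d0: float
    s0_sq: float


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on psi'(x) = y; psi' is decreasing and convex.
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> VariancePrior:
    """Moment-match (d0, s0^2) on the log sample variances.

    Under s^2 | sigma^2 ~ sigma^2 chi^2_df / df with sigma^2 drawn from a
    scaled inverse-chi-square(d0, s0^2), the shifted log variances
    e = log s^2 - psi(df/2) + log(df/2) have across-gene variance
    psi'(df/2) + psi'(d0/2) and mean log s0^2 + psi(d0/2) - log(d0/2);
    both moments are inverted in closed form (trigamma numerically).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        raise DesignError("variance prior needs >=2 genes with positive variance")
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # observed spread no larger than pure sampling noise: variances are
        # effectively common; use a very informative prior
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(
            np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    return VariancePrior(d0=float(d0), s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# Two-sample test
# ---------------------------------------------------------------------------

def _welch(mx, my, vx, vy, nx, ny):
    se2 = vx / nx + vy / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


def _moderated(mx, my, vx, vy, nx, ny, prior: VariancePrior):
    d = nx + ny - 2
    s2 = ((nx - 1) * vx + (ny - 1) * vy) / d
    if np.isinf(prior.d0):
        post = np.full_like(np.asarray(s2, dtype=float), prior.s0_sq)
        df = np.inf
    else:
        post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df = prior.d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(post * (1.0 / nx + 1.0 / ny))
    return t, df, post


def two_sample_test(
    x,
    y,
    mode: str = "welch",
    prior: Optional[VariancePrior] = None,
) -> tuple[float, float, float]:
    """Two-sided two-sample test of mean difference; returns (t, df, p).

    ``welch`` uses the unequal-variance t with Satterthwaite df.
    ``moderated`` shrinks the pooled variance toward the supplied
    empirical-Bayes prior: posterior variance
    (d0*s0^2 + d*s^2)/(d0 + d) on d0 + d df, where d = nx + ny - 2.
    Degenerate inputs with zero variance in both groups give p = 1 when the
    means agree and the smallest positive p (with a warning) when they do
    not.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DesignError("two_sample_test needs >=2 observations per group")
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return 0.0, float(x.size + y.size - 2), 1.0
        log.warning("zero variance in both groups with unequal means")
        return float(np.sign(mx - my) * np.inf), float(x.size + y.size - 2), _TINY_P
    if mode == "welch":
        t, df = _welch(mx, my, vx, vy, x.size, y.size)
    elif mode == "moderated":
        if prior is None:
            raise DesignError("moderated mode requires a VariancePrior")
        t, df, _ = _moderated(mx, my, vx, vy, x.size, y.size, prior)
    else:
        raise DesignError(f"unknown test mode {mode!r}")
    p = _p_from_t(t, df)
    return float(t), float(df), float(p)


def _p_from_t(t, df):
    t = np.asarray(t, dtype=float)
    if np.isscalar(df) or np.ndim(df) == 0:
        if np.isinf(df):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.maximum(p, _TINY_P)


# ---------------------------------------------------------------------------
# Gene-wise screen statistics
# ---------------------------------------------------------------------------

def gene_stats(
    m: ExpressionMatrix,
    s: SampleTable,
    cohort: str,
    th: Thresholds,
    mode: str = "welch",
) -> list[GeneStats]:
    """Compute per-gene screen statistics for one tumor cohort vs normals.

    All tests and fold-changes operate on log2(FPKM + pseudocount);
    ``median_tumor_fpkm`` and ``max_vital_fpkm`` stay on the FPKM scale.
    Deterministic; gene order follows the matrix.
    """
    if m.scale != "fpkm":
        raise DesignError("gene_stats expects an FPKM-scale matrix")
    s.validate_against(m)
    tumor_ids = s.ids(group="tumor", cohort=cohort)
    normal_ids = s.ids(group="normal")
    if len(tumor_ids) < 2:
        raise DesignError(
            f"cohort {cohort!r} has {len(tumor_ids)} sample(s); >=2 required"
        )
    if len(normal_ids) < 2:
        raise DesignError(f"{len(normal_ids)} normal sample(s); >=2 required")
    brain_ids = s.ids(group="normal", brain=True)
    organ_ids = {o: s.ids(vital_organ=o) for o in VITAL_ORGANS}
    if not brain_ids:
        log.warning("no brain samples: logfc_vs_brain not evaluable (NaN)")
    if not any(organ_ids.values()):
        log.warning("no vital-organ samples: max_vital_fpkm not evaluable (NaN)")

    fpkm = m.values
    L = log2_transform(m, th.pseudocount).values

    Lt = L[tumor_ids].to_numpy()
    Ln = L[normal_ids].to_numpy()
    Ft = fpkm[tumor_ids].to_numpy()

    med_log2_t = np.median(Lt, axis=1)
    med_fpkm_t = np.median(Ft, axis=1)
    mean_t = Lt.mean(axis=1)
    logfc_normal = mean_t - Ln.mean(axis=1)
    if brain_ids:
        logfc_brain = mean_t - L[brain_ids].to_numpy().mean(axis=1)
    else:
        logfc_brain = np.full(len(m.gene_ids), np.nan)
    organ_medians = [
        np.median(fpkm[ids].to_numpy(), axis=1) for ids in organ_ids.values() if ids
    ]
    if organ_medians:
        max_vital = np.max(np.column_stack(organ_medians), axis=1)
    else:
        max_vital = np.full(len(m.gene_ids), np.nan)

    t_arr, df_arr, p_arr = _vector_test(Lt, Ln, mode)

    out = []
    for i, g in enumerate(m.gene_ids):
        rec = GeneStats(
            gene_id=g,
            median_log2_tumor=float(med_log2_t[i]),
            median_tumor_fpkm=float(med_fpkm_t[i]),
            logfc_vs_normal=float(logfc_normal[i]),
            logfc_vs_brain=float(logfc_brain[i]),
            max_vital_fpkm=float(max_vital[i]),
            t_stat=float(t_arr[i]),
            df=float(df_arr[i]),
            p_value=float(p_arr[i]),
            passes_screen=bool(
                logfc_normal[i] >= th.screen_logfc_min
                and med_fpkm_t[i] > th.screen_fpkm_min
                and p_arr[i] <= th.screen_p_max
            ),
        )
        out.append(rec)
    return out


def _vector_test(Lt: np.ndarray, Ln: np.ndarray, mode: str):
    """Gene-vectorised version of :func:`two_sample_test` (same contract)."""
    nx, ny = Lt.shape[1], Ln.shape[1]
    mx, my = Lt.mean(axis=1), Ln.mean(axis=1)
    vx, vy = Lt.var(axis=1, ddof=1), Ln.var(axis=1, ddof=1)
    degen = (vx == 0.0) & (vy == 0.0)
    if mode == "welch":
        t, df = _welch(mx, my, vx, vy, nx, ny)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = _p_from_t(np.where(degen, 0.0, t), np.where(degen, 1.0, df))
    elif mode == "moderated":
        d = nx + ny - 2
        s2 = ((nx - 1) * vx + (ny - 1) * vy) / d
        prior = estimate_variance_prior(s2, d)
        t, df, _ = _moderated(mx, my, vx, vy, nx, ny, prior)
        p = _p_from_t(np.where(degen, 0.0, t), df)
        df = np.full_like(t, df)
    else:
        raise DesignError(f"unknown test mode {mode!r}")
    # degenerate genes: p = 1 when means equal, smallest positive p otherwise
    eq = degen & (mx == my)
    ne = degen & (mx != my)
    t = np.where(eq, 0.0, t)
    with np.errstate(invalid="ignore"):
        t = np.where(ne, np.sign(mx - my) * np.inf, t)
    p = np.where(eq, 1.0, p)
    p = np.where(ne, _TINY_P, p)
    if ne.any():
        log.warning("%d gene(s) with zero variance but unequal means", int(ne.sum()))
    df = np.where(degen, nx + ny - 2, df)
    return t, df, p


def gene_stats_frame(stats: list[GeneStats]) -> pd.DataFrame:
    """Tabular form for TSV output, one row per gene."""
    return pd.DataFrame([vars(r) for r in stats])


def screen(stats: list[GeneStats], th: Thresholds) -> set[str]:
    """Genes passing the overexpression gate under the given thresholds."""
    if not stats:
        raise DesignError("screen called with no gene statistics")
    passed = {
        r.gene_id
        for r in stats
        if r.logfc_vs_normal >= th.screen_logfc_min
        and r.median_tumor_fpkm > th.screen_fpkm_min
        and r.p_value <= th.screen_p_max
    }
    log.info("screen: %d of %d genes pass", len(passed), len(stats))
    return passed
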