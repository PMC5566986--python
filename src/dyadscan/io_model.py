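"""Shared data types and tabular I/O for the dyad-discovery pipeline.

Every table in the pipeline is plain TSV with a mandatory header row, "."
decimal, and opaque string identifiers in the first column.  Three tables
drive an analysis:

* an expression matrix (genes x samples) on the FPKM scale,
* a sample table assigning each sample to a tumor cohort or a normal
  tissue, with brain and vital-organ (heart/liver/lung/kidney) flags,
* an evidence table of boolean plasma-membrane calls, one column per
  annotation source, used for surfaceome consensus voting.

All thresholds the downstream stages apply live in a single
:class:`Thresholds` record so a run's stringency is one configurable
object.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "DyadscanError",
    "FormatError",
    "DesignError",
    "ExpressionMatrix",
    "SampleTable",
    "EvidenceTable",
    "Thresholds",
    "VITAL_ORGANS",
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "read_evidence",
    "write_evidence",
    "log2_transform",
]

VITAL_ORGANS = ("heart", "liver", "lung", "kidney")

#: float formatting used by every writer; round-trips IEEE doubles exactly.
_FLOAT_FMT = "%.17g"


class DyadscanError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DyadscanError):
    """A table violates its format contract (located in the message)."""


class DesignError(DyadscanError):
    """The sample design cannot support the requested analysis."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample expression values.

    ``scale`` is ``"fpkm"`` for raw non-negative FPKM input and ``"log2"``
    after :func:`log2_transform`; non-negativity is enforced only on the
    FPKM scale.
    """

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    scale: str = "fpkm"

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(v.index, "gene id")
        _check_unique(v.columns, "sample id")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise FormatError(
                f"expression matrix needs >=2 genes and >=2 samples, got {v.shape}"
            )
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric cells")
        bad = ~np.isfinite(arr)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise FormatError(
                f"non-finite value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if self.scale == "fpkm" and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative FPKM at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` preserving this matrix's row order."""
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], scale=self.scale)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if s in set(samples)]
        return ExpressionMatrix(self.values[keep], scale=self.scale)


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = [
    "sample_id", "group", "cohort", "tissue", "is_brain", "is_vital", "vital_organ",
]


@dataclass
class SampleTable:
    """Per-sample design: tumor cohort vs normal tissue with organ flags."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing = {"sample_id", "group"} - set(t.columns)
        if missing:
            raise FormatError(f"sample table missing required columns {sorted(missing)}")
        # optional columns default to inert values
        if "cohort" not in t:
            t["cohort"] = ""
        if "tissue" not in t:
            t["tissue"] = ""
        if "is_brain" not in t:
            t["is_brain"] = False
        if "is_vital" not in t:
            t["is_vital"] = False
        if "vital_organ" not in t:
            t["vital_organ"] = "none"
        t["cohort"] = t["cohort"].fillna("").astype(str)
        t["tissue"] = t["tissue"].fillna("").astype(str)
        t["vital_organ"] = t["vital_organ"].fillna("none").replace("", "none").astype(str)
        for c in ("is_brain", "is_vital"):
            t[c] = _coerce_bool(t[c], c)
        _check_unique(t["sample_id"], "sample id")
        bad_group = set(t["group"]) - {"tumor", "normal"}
        if bad_group:
            raise FormatError(f"unknown group value(s) {sorted(bad_group)}")
        bad_organ = set(t["vital_organ"]) - (set(VITAL_ORGANS) | {"none"})
        if bad_organ:
            raise FormatError(f"unknown vital_organ value(s) {sorted(bad_organ)}")
        for _, row in t.iterrows():
            if row["is_brain"] and row["group"] != "normal":
                raise FormatError(
                    f"sample {row['sample_id']!r}: is_brain set on a non-normal sample"
                )
            if row["is_vital"]:
                if row["group"] != "normal":
                    raise FormatError(
                        f"sample {row['sample_id']!r}: is_vital set on a non-normal sample"
                    )
                if row["vital_organ"] == "none":
                    raise FormatError(
                        f"sample {row['sample_id']!r}: is_vital requires a vital_organ"
                    )
        self.table = t[_SAMPLE_COLUMNS].reset_index(drop=True)

    def ids(self, *, group=None, cohort=None, brain=None, vital_organ=None) -> list:
        """Sample ids matching every given criterion."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        if group is not None:
            mask &= t["group"] == group
        if cohort is not None:
            mask &= t["cohort"] == cohort
        if brain is not None:
            mask &= t["is_brain"] == brain
        if vital_organ is not None:
            mask &= t["vital_organ"] == vital_organ
        return list(t.loc[mask, "sample_id"])

    @property
    def cohorts(self) -> list:
        t = self.table
        return sorted(set(t.loc[t["group"] == "tumor", "cohort"]))

    def validate_against(self, m: ExpressionMatrix) -> None:
        extra = set(self.table["sample_id"]) - set(m.sample_ids)
        if extra:
            raise FormatError(
                f"sample id(s) absent from expression matrix: {sorted(extra)[:5]}"
            )


def _coerce_bool(col: pd.Series, name: str) -> pd.Series:
    mapping = {
        True: True, False: False, 1: True, 0: False,
        "1": True, "0": False, "true": True, "false": False,
        "True": True, "False": False, "": False,
    }
    out = []
    for v in col:
        if isinstance(v, float) and np.isnan(v):
            v = ""
        if isinstance(v, (np.bool_, np.integer)):
            v = bool(v) if isinstance(v, np.bool_) else int(v)
        if v not in mapping:
            raise FormatError(f"column {name!r}: cannot interpret {v!r} as boolean")
        out.append(mapping[v])
    return pd.Series(out, index=col.index, dtype=bool)


# ---------------------------------------------------------------------------
# EvidenceTable
# ---------------------------------------------------------------------------

@dataclass
class EvidenceTable:
    """Gene x annotation-source boolean membership calls.

    Column names are arbitrary source labels; the default schema carries
    nine sources mirroring the consensus surfaceome annotation design.
    """

    table: pd.DataFrame  # index = gene ids, columns = source names, values 0/1

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "gene id")
        if t.shape[1] < 1:
            raise FormatError("evidence table has no source columns")
        arr = t.to_numpy()
        ok = np.isin(arr, (0, 1, True, False))
        if not ok.all():
            g, s = np.argwhere(~ok)[0]
            raise FormatError(
                f"non-boolean evidence cell at gene {t.index[g]!r}, "
                f"source {t.columns[s]!r}: {arr[g, s]!r}"
            )
        self.table = t.astype(int)

    @property
    def gene_ids(self) -> list:
        return list(self.table.index)

    @property
    def sources(self) -> list:
        return list(self.table.columns)

    @property
    def n_sources(self) -> int:
        return self.table.shape[1]


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Thresholds:
    """Every cutoff of the screen gates and the pair filters (a)-(f).

    Defaults are the stringent published settings: single-gene screen at
    logFC >= 2, tumor median FPKM > 2, p <= 1e-3; pair filters at Hotelling
    p <= 0.01, Pearson p <= 0.05, tumor median log2(FPKM) >= 2 per gene,
    logFC >= 2 vs all normals and vs brain alone, and a vital-organ median
    FPKM ceiling of 1.0 (loosenable to 1.5 or 2.0).
    """

    screen_logfc_min: float = 2.0
    screen_fpkm_min: float = 2.0
    screen_p_max: float = 0.001
    manova_p_max: float = 0.01
    pearson_p_max: float = 0.05
    median_log2_min: float = 2.0
    logfc_vs_normal_min: float = 2.0
    logfc_vs_brain_min: float = 2.0
    vital_fpkm_max: float = 1.0
    consensus_votes_min: int = 7
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise FormatError(f"threshold {f.name} must be finite, got {v!r}")
        for name in ("screen_p_max", "manova_p_max", "pearson_p_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise FormatError(f"{name} must lie in (0, 1), got {v!r}")
        if self.vital_fpkm_max <= 0:
            raise FormatError("vital_fpkm_max must be > 0")
        if self.consensus_votes_min < 1:
            raise FormatError("consensus_votes_min must be >= 1")
        if self.pseudocount < 0:
            raise FormatError("pseudocount must be >= 0")

    def replace(self, **kw) -> "Thresholds":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

PathLike = Union[str, Path, io.IOBase]


def _read_table(path: PathLike, dialect: str = "\t") -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep=dialect, header=0, dtype={0: str}, index_col=0,
            float_precision="round_trip",
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed text, ragged rows, ...
        raise FormatError(f"cannot parse table {path}: {exc}") from exc


def read_expression(path: PathLike, dialect: str = "\t") -> ExpressionMatrix:
    """Read a gene x sample FPKM matrix from TSV.

    First column holds gene ids, the header row sample ids; the body must
    be numeric and non-negative.  Row and column order are preserved.
    """
    df = _read_table(path, dialect)
    df.index.name = "gene_id"
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for gi, row in df.iterrows():
            for si, v in row.items():
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric cell at gene {gi!r}, sample {si!r}: {v!r}"
                    ) from None
        raise
    return ExpressionMatrix(df)


def write_expression(m: ExpressionMatrix, path: PathLike) -> None:
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_samples(path: PathLike) -> SampleTable:
    """Read the per-sample design TSV (columns ``sample_id``, ``group``,
    optional ``cohort``, ``tissue``, ``is_brain``, ``is_vital``,
    ``vital_organ``)."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"cannot parse sample table {path}: {exc}") from exc
    return SampleTable(df)


def write_samples(s: SampleTable, path: PathLike) -> None:
    t = s.table.copy()
    t["is_brain"] = t["is_brain"].astype(int)
    t["is_vital"] = t["is_vital"].astype(int)
    t.to_csv(path, sep="\t", index=False)


def read_evidence(path: PathLike) -> EvidenceTable:
    """Read the gene x source 0/1 evidence TSV."""
    df = _read_table(path)
    df.index.name = "gene_id"
    return EvidenceTable(df)


def write_evidence(ev: EvidenceTable, path: PathLike) -> None:
    df = ev.table.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return ``log2(FPKM + pseudocount)`` with shape and ids unchanged.

    Strictly monotone per cell, so within-gene and within-sample orderings
    are preserved.  ``pseudocount=0`` is permitted only when every value is
    strictly positive.
    """
    if pseudocount < 0:
        raise FormatError(f"pseudocount must be >= 0, got {pseudocount}")
    arr = m.values.to_numpy()
    if pseudocount == 0 and (arr <= 0).any():
        raise FormatError("pseudocount 0 requires strictly positive values")
    out = np.log2(arr + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        scale="log2",
    )
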