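"""Differential-translation post-processing and summary statistics.

Polysome-associated mRNA is sequenced and compared between untreated and
drug-treated cells; the negative-binomial model fit itself (DESeq2-style
Wald test) is upstream of this package, which consumes its output
convention — a table of gene id, log2 fold change, raw and adjusted
p-value.  This module covers the surrounding steps:

* counts-per-million filtering of raw count matrices (a gene is kept
  when it reaches the CPM threshold in every biological sample, or in at
  least ``min_samples`` of them);
* Benjamini–Hochberg step-up FDR adjustment;
* classification of genes into translationally up / down / unchanged
  using the conventional "more than twofold at FDR < alpha" rule
  (|log2FC| > 1, adjusted p < 0.05 by default; the twofold bound is a
  strict inequality, so a gene at exactly twofold is unchanged);
* summary statistics per condition (counts of up/down genes and the
  upregulated fraction as an integer percent) and pairwise overlaps of
  up and down sets between two treatment doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from fluoribo.errors import DataError


@dataclass
class CountMatrix:
    """Genes x samples read counts with per-sample library sizes.

    ``library_size`` defaults to the column sums; it may be overridden
    (e.g. with sizes computed before an upstream filter).
    """

    counts: pd.DataFrame  # genes (rows) x samples (columns), non-negative ints
    library_size: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise DataError("negative counts")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)
        else:
            self.library_size = self.library_size.reindex(self.counts.columns)
            if self.library_size.isna().any():
                raise DataError("library_size missing for some samples")

    def cpm(self) -> pd.DataFrame:
        """Counts per million: count / library_size * 1e6."""
        if (self.library_size <= 0).any():
            raise DataError("zero or negative library size")
        return self.counts.div(self.library_size, axis=1) * 1e6


@dataclass(frozen=True)
class DifferentialTranslationRecord:
    """One gene's differential-translation result (model fit consumed upstream)."""

    gene: str
    log2fc: float
    padj: float | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        for name in ("pvalue", "padj"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise DataError(f"{name} outside [0, 1] for gene {self.gene!r}")


@dataclass(frozen=True)
class TranslationClassification:
    """Partition of genes into up / down / unchanged at given thresholds."""

    up: frozenset[str]
    down: frozenset[str]
    unchanged: frozenset[str]
    log2fc_threshold: float
    alpha: float

    def __post_init__(self) -> None:
        if self.up & self.down or self.up & self.unchanged or self.down & self.unchanged:
            raise DataError("classification sets are not disjoint")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down | self.unchanged


def cpm_filter(
    m: CountMatrix, min_cpm: float = 1.0, min_samples: int | None = None
) -> CountMatrix:
    """Drop genes below ``min_cpm`` counts-per-million.

    By default a gene must reach the threshold in *every* sample
    (``min_samples=None``); pass an integer for an "in at least k
    samples" rule.  Library sizes are carried over unchanged so CPM
    values are not distorted by the filter itself.  Row order of
    retained genes is preserved.
    """
    cpm = m.cpm()
    ok = cpm >= min_cpm
    if min_samples is None:
        keep = ok.all(axis=1)
    else:
        if not 1 <= min_samples <= cpm.shape[1]:
            raise DataError(f"min_samples {min_samples} outside [1, {cpm.shape[1]}]")
        keep = ok.sum(axis=1) >= min_samples
    return CountMatrix(counts=m.counts.loc[keep].copy(), library_size=m.library_size)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _records_to_frame(
    records: Sequence[DifferentialTranslationRecord] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.rename(columns={"gene_id": "gene", "log2FoldChange": "log2fc"})
        required = {"gene", "log2fc"}
        if not required.issubset(df.columns):
            raise DataError(f"records frame missing columns: {sorted(required - set(df.columns))}")
        for col in ("pvalue", "padj"):
            if col not in df.columns:
                df[col] = np.nan
        return df[["gene", "log2fc", "pvalue", "padj"]]
    return pd.DataFrame(
        [
            {"gene": r.gene, "log2fc": r.log2fc, "pvalue": r.pvalue, "padj": r.padj}
            for r in records
        ]
    )


def classify_translation(
    records: Sequence[DifferentialTranslationRecord] | pd.DataFrame,
    log2fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> TranslationClassification:
    """Classify genes as translationally up, down or unchanged.

    up: log2FC > threshold and padj < alpha; down: log2FC < -threshold
    and padj < alpha; everything else unchanged.  When ``padj`` is absent
    but every record carries a raw p-value, Benjamini–Hochberg adjusted
    values are computed across the whole table first.
    """
    if log2fc_threshold < 0:
        raise DataError("log2fc_threshold must be non-negative")
    if not 0 < alpha <= 1:
        raise DataError("alpha must lie in (0, 1]")
    df = _records_to_frame(records)
    if df.empty:
        raise DataError("no records to classify")
    if df["gene"].duplicated().any():
        raise DataError("duplicate gene ids")
    missing_padj = df["padj"].isna()
    if missing_padj.any():
        if df.loc[missing_padj, "pvalue"].isna().any():
            raise DataError("records missing both pvalue and padj")
        if missing_padj.all():
            df["padj"] = benjamini_hochberg(df["pvalue"].to_numpy())
        else:
            raise DataError("padj present for some records but not all")
    sig = df["padj"] < alpha
    up = df.loc[sig & (df["log2fc"] > log2fc_threshold), "gene"]
    down = df.loc[sig & (df["log2fc"] < -log2fc_threshold), "gene"]
    classified = set(up) | set(down)
    unchanged = df.loc[~df["gene"].isin(classified), "gene"]
    return TranslationClassification(
        up=frozenset(up),
        down=frozenset(down),
        unchanged=frozenset(unchanged),
        log2fc_threshold=log2fc_threshold,
        alpha=alpha,
    )


def condition_summary(n_up: int, n_down: int) -> dict:
    """Counts and upregulated fraction for one condition.

    The fraction is reported to the nearest integer percent; with no
    altered genes it is undefined (None), never 0.
    """
    if n_up < 0 or n_down < 0:
        raise DataError("negative counts")
    n_total = n_up + n_down
    pct_up = round(100 * n_up / n_total) if n_total else None
    return {"n_up": n_up, "n_down": n_down, "n_total": n_total, "pct_up": pct_up}


def summarize_classification(
    a: TranslationClassification,
    b: TranslationClassification | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> dict:
    """Summarise one or two classifications.

    Per condition: up/down/total counts and the upregulated fraction as
    an integer percent (None when no gene is altered).  When the gene
    universe is known (unchanged set populated), the fraction of
    analysed genes that is altered is also reported.  With two
    classifications, pairwise overlaps of the up sets and of the down
    sets are added as (only-A, both, only-B) counts.
    """
    summary: dict = {"conditions": {}}
    for label, c in ((labels[0], a), (labels[1], b)):
        if c is None:
            continue
        cond = condition_summary(len(c.up), len(c.down))
        n_universe = len(c.genes)
        if c.unchanged and n_universe:
            cond["pct_altered_of_analyzed"] = round(100 * cond["n_total"] / n_universe)
        summary["conditions"][label] = cond
    if b is not None:
        summary["overlap"] = {
            "up": {
                f"only_{labels[0]}": len(a.up - b.up),
                "both": len(a.up & b.up),
                f"only_{labels[1]}": len(b.up - a.up),
            },
            "down": {
                f"only_{labels[0]}": len(a.down - b.down),
                "both": len(a.down & b.down),
                f"only_{labels[1]}": len(b.down - a.down),
            },
        }
    return summary


# ---------------------------------------------------------------------------
# TSV plumbing (DESeq2-style output convention)

_DE_COLUMNS = {"gene_id": "gene", "log2FoldChange": "log2fc", "pvalue": "pvalue", "padj": "padj"}


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-translation TSV (gene_id, log2FoldChange, pvalue, padj).

    Extra columns are ignored; pvalue/padj may each be absent.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "log2FoldChange"}.issubset(df.columns):
        raise DataError(f"DE table {path} missing gene_id/log2FoldChange columns")
    present = {k: v for k, v in _DE_COLUMNS.items() if k in df.columns}
    return df[list(present)].rename(columns=present)


def classification_to_frame(c: TranslationClassification) -> pd.DataFrame:
    """Long-format classification table (gene, class), sorted by gene id."""
    rows = [(g, "up") for g in sorted(c.up)]
    rows += [(g, "down") for g in sorted(c.down)]
    rows += [(g, "unchanged") for g in sorted(c.unchanged)]
    return pd.DataFrame(rows, columns=["gene", "class"])


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a genes x samples count TSV (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(counts=df)
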