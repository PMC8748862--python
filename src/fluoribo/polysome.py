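"""Translation efficiency from polysome-fractionation qPCR.

A cytoplasmic lysate is split by sucrose-gradient sedimentation into a
total cytoplasmic fraction and a (heavy) polysomal fraction; each gene's
mRNA is quantified in both by qPCR.  Translation efficiency (TE) is the
ratio of polysomal to cytoplasmic quantity — a gene whose mRNA stays
loaded on polysomes under drug treatment keeps a high TE even as global
protein synthesis drops.

Quantities may be supplied directly or as Ct (cycle-threshold) values,
converted with quantity = efficiency^(-ct) at an amplification
efficiency of 2 per cycle by default (ideal doubling).  Replicates are
aggregated by the geometric mean of quantities, equivalent to the
arithmetic mean of Ct, since qPCR measures on a log scale.  TE values
are reported both raw and normalised per gene to the mean TE of a
control condition (typically untreated, "NT"), whose normalised TE is 1
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from fluoribo.errors import DataError

FRACTIONS = ("cytoplasmic", "polysomal")


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR well: a gene in one fraction of one condition replicate.

    Exactly one of ``ct`` and ``quantity`` must be given.
    """

    gene: str
    condition: str
    fraction: str
    replicate: int
    ct: float | None = None
    quantity: float | None = None

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise DataError(f"fraction must be one of {FRACTIONS}, got {self.fraction!r}")
        if (self.ct is None) == (self.quantity is None):
            raise DataError("exactly one of ct/quantity must be present")
        if self.ct is not None and self.ct <= 0:
            raise DataError("ct must be positive")
        if self.quantity is not None and self.quantity <= 0:
            raise DataError("quantity must be positive")
        if self.replicate < 1:
            raise DataError("replicate index must be >= 1")


@dataclass(frozen=True)
class TranslationEfficiency:
    """Polysomal / cytoplasmic quantity ratio for one gene and condition."""

    gene: str
    condition: str
    te: float
    te_normalized: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.te <= 0 or self.te_normalized <= 0:
            raise DataError("translation efficiency must be positive")


def ct_to_quantity(ct: float, efficiency: float = 2.0) -> float:
    """Relative quantity from a cycle-threshold value.

    ``quantity = efficiency ** (-ct)``: each cycle multiplies template by
    ``efficiency``, so a lower Ct means exponentially more starting
    material.  Efficiency must lie in (1, 2] (2 = perfect doubling).
    """
    if not 1.0 < efficiency <= 2.0:
        raise DataError(f"amplification efficiency {efficiency} outside (1, 2]")
    return float(efficiency ** (-ct))


def _records_frame(records: Sequence[QpcrRecord], efficiency: float) -> pd.DataFrame:
    rows = []
    for r in records:
        q = r.quantity if r.quantity is not None else ct_to_quantity(r.ct, efficiency)
        rows.append(
            {
                "gene": r.gene,
                "condition": r.condition,
                "fraction": r.fraction,
                "replicate": r.replicate,
                "quantity": q,
            }
        )
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["gene", "condition", "fraction", "replicate"])
    if dup.any():
        raise DataError("duplicate replicate ids within (gene, condition, fraction)")
    return df


def translation_efficiency(
    records: Sequence[QpcrRecord],
    control_condition: str,
    efficiency: float = 2.0,
) -> list[TranslationEfficiency]:
    """Compute per-(gene, condition) TE, normalised per gene to the control.

    Replicate quantities within each fraction are aggregated by geometric
    mean; TE is the aggregated polysomal over cytoplasmic quantity, and
    ``te_normalized`` divides by the gene's TE in ``control_condition``.
    Raises when a (gene, condition) lacks either fraction or when a gene
    has no control-condition measurement.
    """
    if not records:
        raise DataError("no qPCR records")
    df = _records_frame(records, efficiency)
    # geometric mean per (gene, condition, fraction)
    agg = (
        df.assign(logq=np.log(df["quantity"]))
        .groupby(["gene", "condition", "fraction"], sort=False)
        .agg(logq=("logq", "mean"), n=("logq", "size"))
        .reset_index()
    )
    agg["gmean"] = np.exp(agg["logq"])
    wide = agg.pivot(index=["gene", "condition"], columns="fraction", values="gmean")
    for frac in FRACTIONS:
        if frac not in wide.columns or wide[frac].isna().any():
            missing = (
                wide.index[wide[frac].isna()].tolist()
                if frac in wide.columns
                else wide.index.tolist()
            )
            raise DataError(f"missing {frac} fraction for: {missing}")
    n_rep = (
        agg.groupby(["gene", "condition"])["n"].min().reindex(wide.index).astype(int)
    )
    te = wide["polysomal"] / wide["cytoplasmic"]
    te_df = te.rename("te").reset_index()
    ctrl = te_df[te_df["condition"] == control_condition].groupby("gene")["te"].mean()
    out = []
    for _, row in te_df.iterrows():
        gene = row["gene"]
        if gene not in ctrl.index:
            raise DataError(f"gene {gene!r} has no {control_condition!r} measurement")
        out.append(
            TranslationEfficiency(
                gene=gene,
                condition=row["condition"],
                te=float(row["te"]),
                te_normalized=float(row["te"] / ctrl[gene]),
                n_replicates=int(n_rep[(gene, row["condition"])]),
            )
        )
    return out


def read_qpcr_csv(path, efficiency: float = 2.0) -> list[QpcrRecord]:
    """Read qPCR records (gene, condition, fraction, replicate, ct|quantity)."""
    df = pd.read_csv(path)
    required = {"gene", "condition", "fraction", "replicate"}
    if not required.issubset(df.columns):
        raise DataError(f"qPCR CSV missing columns: {sorted(required - set(df.columns))}")
    has_ct = "ct" in df.columns
    has_q = "quantity" in df.columns
    if not has_ct and not has_q:
        raise DataError("qPCR CSV needs a 'ct' or 'quantity' column")
    records = []
    for _, row in df.iterrows():
        ct = float(row["ct"]) if has_ct and pd.notna(row.get("ct")) else None
        q = float(row["quantity"]) if has_q and pd.notna(row.get("quantity")) else None
        records.append(
            QpcrRecord(
                gene=str(row["gene"]),
                condition=str(row["condition"]),
                fraction=str(row["fraction"]),
                replicate=int(row["replicate"]),
                ct=ct,
                quantity=q,
            )
        )
    return records


def te_to_frame(results: Sequence[TranslationEfficiency]) -> pd.DataFrame:
    """Tabulate TE results (gene, condition, te, te_normalized, n_replicates)."""
    return pd.DataFrame(
        [
            {
                "gene": t.gene,
                "condition": t.condition,
                "te": t.te,
                "te_normalized": t.te_normalized,
                "n_replicates": t.n_replicates,
            }
            for t in results
        ]
    )
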