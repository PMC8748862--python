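"""Seeded synthetic-data generators with known ground truth.

Each generator emulates the statistical structure its paired estimator
assumes, so every stage of the pipeline can be exercised — and its
parameter recovery measured — without any external data:

* nucleoside concentration vectors proportional to the ribosome's base
  composition, plus a 5-FUrd term at a planted molecules-per-ribosome
  truth, under multiplicative lognormal noise (instrument responses are
  positive with roughly proportional error);
* calibration standards on a known line with additive Gaussian response
  noise;
* qPCR Ct values with planted translation-efficiency ratios (additive
  Gaussian Ct noise — qPCR error is additive on the cycle scale);
* differential-translation tables with planted up/down gene counts
  (adjusted p-values are emitted directly, with raw p-values consistent
  with their ranks, because the count-model fit is upstream of this
  package);
* negative-binomial count matrices for exercising the CPM filter;
* linear-plus-Gaussian-noise growth curves.

All draws flow from a ``numpy.random.default_rng(seed)`` created inside
each call — no global random state — so a fixed seed gives byte-identical
outputs.

The module also provides a synthetic rRNA set: random sequences at the
lengths of the four human cytoplasmic rRNA species (18S 1869 nt,
28S 5070 nt, 5.8S 157 nt, 5S 121 nt) with a GC-rich base bias typical of
human rRNA.  These are synthetic stand-ins, not the real sequences; any
user-supplied rRNA FASTA can be used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fluoribo.composition import (
    NucleotideComposition,
    RibosomeComposition,
    RnaSequence,
    nucleotide_composition,
    ribosome_composition,
)
from fluoribo.errors import DataError
from fluoribo.lchrms import CalibrationStandard, NucleosideMeasurement
from fluoribo.polysome import QpcrRecord
from fluoribo.reporters import GrowthCurve
from fluoribo.translatome import CountMatrix

#: Lengths (nt) of the four human cytoplasmic rRNA species, used for the
#: synthetic stand-in set.
HUMAN_RRNA_LENGTHS: dict[str, int] = {"18S": 1869, "28S": 5070, "5.8S": 157, "5S": 121}

#: Base probabilities for synthetic rRNA (GC-rich, as human rRNA is).
_RRNA_BASE_PROBS = {"A": 0.19, "C": 0.27, "G": 0.33, "U": 0.21}


def simulate_rrna_set(seed: int = 0) -> list[RnaSequence]:
    """Generate a synthetic four-species rRNA set at human rRNA lengths.

    The sequences are random (GC-biased) and synthetic; they carry the
    realistic lengths and base-frequency skew needed by the composition
    denominator, nothing more.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list(_RRNA_BASE_PROBS))
    probs = np.array(list(_RRNA_BASE_PROBS.values()))
    out = []
    for name, length in HUMAN_RRNA_LENGTHS.items():
        residues = "".join(rng.choice(bases, size=length, p=probs))
        out.append(RnaSequence(id=f"synthetic_{name}_rRNA", residues=residues))
    return out


def default_ribosome_composition(seed: int = 0) -> RibosomeComposition:
    """Composition of the synthetic four-species ribosome (one copy each)."""
    seqs = simulate_rrna_set(seed)
    return ribosome_composition([(s.id, nucleotide_composition(s)) for s in seqs])


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def simulate_nucleoside_measurements(
    truth: float,
    comp: RibosomeComposition,
    ribosome_conc: float = 1.0,
    cv: float = 0.02,
    n: int = 3,
    seed: int = 0,
):
    """Simulate LC-HRMS nucleoside concentrations at a planted truth.

    Expected concentrations are ``ribosome_conc * N_X`` for X in
    {A, C, G, U} and ``ribosome_conc * truth`` for 5-FUrd; each observed
    value multiplies its expectation by unit-mean lognormal noise with
    coefficient of variation ``cv``.
    """
    if truth < 0:
        raise DataError("truth must be non-negative")
    if cv < 0:
        raise DataError("cv must be non-negative")
    if ribosome_conc <= 0:
        raise DataError("ribosome_conc must be positive")
    if n < 1:
        raise DataError("need at least one replicate")
    rng = np.random.default_rng(seed)
    expected = np.array(
        [comp.N_A, comp.N_C, comp.N_G, comp.N_U, truth], dtype=float
    ) * ribosome_conc
    out = []
    for i in range(n):
        obs = expected * _lognormal_factors(rng, cv, expected.shape)
        out.append(
            NucleosideMeasurement(
                sample_id=f"sim_{i + 1}",
                conc_A=float(obs[0]),
                conc_C=float(obs[1]),
                conc_G=float(obs[2]),
                conc_U=float(obs[3]),
                conc_5FUrd=float(obs[4]),
            )
        )
    return out


def simulate_calibration_standards(
    slope: float,
    intercept: float,
    levels: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    analyte: str = "5FUrd",
    internal_standard_area: float = 1e5,
) -> list[CalibrationStandard]:
    """Standards on the line response = slope*c + intercept, plus Gaussian noise.

    The internal-standard area is held at a nominal constant; peak areas
    are back-formed from the (noisy) response ratios.
    """
    levels = list(levels)
    if len(set(levels)) < 2:
        raise DataError("need at least 2 distinct concentration levels")
    if noise_sd < 0:
        raise DataError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for c in levels:
        response = slope * c + intercept + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        out.append(
            CalibrationStandard(
                analyte=analyte,
                known_concentration=float(c),
                peak_area=float(max(response, 0.0) * internal_standard_area),
                internal_standard_area=internal_standard_area,
            )
        )
    return out


def simulate_de_table(
    n_genes: int,
    n_up: int,
    n_down: int,
    lfc_magnitude: float = 2.0,
    seed: int = 0,
    alpha: float = 0.05,
    null_lfc_sd: float = 0.3,
) -> pd.DataFrame:
    """Differential-translation table with planted up/down genes.

    Planted genes carry log2FC = +/- ``lfc_magnitude`` (which must exceed
    1 so they pass the twofold threshold) and adjusted p-values drawn
    below ``alpha``; null genes carry small log2FC noise and adjusted
    p-values at or above ``alpha``.  Raw p-values are derived from the
    adjusted ones by inverting the step-up within ranks, so p <= padj and
    the ranks agree.  Columns follow the DESeq2 output convention.
    """
    if n_up + n_down > n_genes:
        raise DataError("planted counts exceed n_genes")
    if lfc_magnitude <= 1.0:
        raise DataError("lfc_magnitude must exceed 1 (the twofold threshold)")
    rng = np.random.default_rng(seed)
    n_null = n_genes - n_up - n_down
    log2fc = np.concatenate(
        [
            np.full(n_up, lfc_magnitude),
            np.full(n_down, -lfc_magnitude),
            rng.normal(0.0, null_lfc_sd, n_null),
        ]
    )
    padj = np.concatenate(
        [
            rng.uniform(1e-8, alpha * 0.99, n_up + n_down),
            rng.uniform(alpha, 1.0, n_null),
        ]
    )
    # raw p consistent with padj ranks: invert the step-up at each rank
    order = np.argsort(padj, kind="stable")
    pvalue = np.empty_like(padj)
    ranks = np.arange(1, n_genes + 1)
    pvalue[order] = padj[order] * ranks / n_genes
    genes = np.array([f"gene{i + 1:05d}" for i in range(n_genes)])
    perm = rng.permutation(n_genes)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "log2FoldChange": log2fc[perm],
            "pvalue": pvalue[perm],
            "padj": padj[perm],
        }
    )


def simulate_count_matrix(
    n_genes: int = 500,
    n_samples: int = 4,
    mean_library_size: int = 1_000_000,
    dispersion: float = 0.1,
    seed: int = 0,
) -> CountMatrix:
    """Negative-binomial count matrix for exercising the CPM filter.

    Gene expected expression spans several orders of magnitude
    (lognormal means), so a realistic fraction of genes sits near the
    1-CPM boundary.
    """
    rng = np.random.default_rng(seed)
    gene_means = rng.lognormal(mean=2.0, sigma=2.0, size=n_genes)
    lib_factors = rng.uniform(0.7, 1.3, size=n_samples)
    r = 1.0 / dispersion
    counts = np.empty((n_genes, n_samples), dtype=int)
    for j in range(n_samples):
        mu = gene_means * lib_factors[j] * (mean_library_size / gene_means.sum())
        p = r / (r + mu)
        counts[:, j] = rng.negative_binomial(r, p)
    df = pd.DataFrame(
        counts,
        index=[f"gene{i + 1:05d}" for i in range(n_genes)],
        columns=[f"sample{j + 1}" for j in range(n_samples)],
    )
    return CountMatrix(counts=df)


def simulate_qpcr_dataset(
    te_map: Mapping[str, Mapping[str, float]],
    ct_sd: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    efficiency: float = 2.0,
    baseline_ct: float = 22.0,
) -> list[QpcrRecord]:
    """qPCR records with planted absolute TE per (gene, condition).

    ``te_map[gene][condition]`` is the planted polysomal/cytoplasmic
    ratio.  Cytoplasmic Ct values are drawn around ``baseline_ct``;
    polysomal Ct is offset by ``-log_eff(te)`` so the quantity ratio
    equals the planted TE, plus Gaussian noise of sd ``ct_sd`` on every
    well.  Recovered normalised TE equals te[condition] / te[control].
    """
    if ct_sd < 0:
        raise DataError("ct_sd must be non-negative")
    if replicates < 1:
        raise DataError("need at least one replicate")
    rng = np.random.default_rng(seed)
    log_eff = np.log(efficiency)
    records = []
    for gene, by_cond in te_map.items():
        for condition, te in by_cond.items():
            if te <= 0:
                raise DataError(f"non-positive planted TE for {gene}/{condition}")
            offset = np.log(te) / log_eff
            for rep in range(1, replicates + 1):
                noise = rng.normal(0, ct_sd, 2) if ct_sd else np.zeros(2)
                records.append(
                    QpcrRecord(
                        gene=gene,
                        condition=condition,
                        fraction="cytoplasmic",
                        replicate=rep,
                        ct=float(baseline_ct + noise[0]),
                    )
                )
                records.append(
                    QpcrRecord(
                        gene=gene,
                        condition=condition,
                        fraction="polysomal",
                        replicate=rep,
                        ct=float(baseline_ct - offset + noise[1]),
                    )
                )
    return records


def simulate_growth_curve(
    slope: float,
    intercept: float,
    timepoints: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "sim",
    condition: str = "NT",
) -> GrowthCurve:
    """Growth curve index = intercept + slope*t + Gaussian noise."""
    timepoints = tuple(float(t) for t in timepoints)
    if len(timepoints) < 2:
        raise DataError("need at least 2 timepoints")
    if noise_sd < 0:
        raise DataError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints)
    noise = rng.normal(0, noise_sd, t.shape) if noise_sd else np.zeros(t.shape)
    index = intercept + slope * t + noise
    return GrowthCurve(
        sample_id=sample_id,
        condition=condition,
        timepoints=timepoints,
        index=tuple(float(v) for v in index),
    )
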