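"""Ribosomal RNA base composition.

The 5-FUrd-per-ribosome statistic divides measured nucleoside
concentration ratios by the "relative quantity of each nucleotide per
ribosome" — i.e. by the exact counts of A, C, G and U in one complete
ribosome.  A human cytoplasmic ribosome carries one copy each of the
18S rRNA (small subunit) and the 28S, 5.8S and 5S rRNAs (large subunit),
so the per-ribosome count of base X is the sum of X counts over those
species.  Which species enter the sum is configurable: experiments on
gel-purified rRNA use only 18S+28S, whole-ribosome preparations use all
four.

Modified residues (pseudouridine, 2'-O-methylated bases, and 5-FUrd
itself) are not representable in FASTA and are counted as their parent
base.  IUPAC ambiguity codes are tolerated but tracked separately and
never silently absorbed into a base count: a sequence whose ambiguous
fraction exceeds ``max_ambiguous_frac`` (default 1%) is rejected,
because an unknown denominator would bias every downstream estimate.
"""

from __future__ import annotations

import collections
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from fluoribo.errors import DataError

#: Canonical RNA alphabet after normalisation.
CANONICAL_BASES = ("A", "C", "G", "U")

#: IUPAC ambiguity codes (RNA) plus the gap characters occasionally left
#: in alignment-derived FASTA files.
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")

_ALLOWED = frozenset(CANONICAL_BASES) | AMBIGUITY_CODES


@dataclass(frozen=True)
class RnaSequence:
    """A normalised RNA sequence: uppercase, T replaced by U.

    Parameters
    ----------
    id
        FASTA header (first word plus description as Biopython reports it).
    residues
        Sequence string over ``{A, C, G, U}`` plus IUPAC ambiguity codes.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise DataError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise DataError(
                f"sequence {self.id!r} contains non-IUPAC residues: {sorted(bad)}"
            )

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "RnaSequence":
        """Normalise a raw (possibly DNA-alphabet, mixed-case) sequence."""
        return cls(id=id, residues=raw.upper().replace("T", "U"))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NucleotideComposition:
    """Exact base tally of one RNA sequence."""

    n_A: int
    n_C: int
    n_G: int
    n_U: int
    n_ambiguous: int
    length: int

    def __post_init__(self) -> None:
        counts = (self.n_A, self.n_C, self.n_G, self.n_U, self.n_ambiguous)
        if any(c < 0 for c in counts):
            raise DataError("negative count in composition")
        if sum(counts) != self.length:
            raise DataError(
                f"composition counts sum to {sum(counts)}, not length {self.length}"
            )

    def count(self, base: str) -> int:
        """Count of a canonical base (``A``, ``C``, ``G`` or ``U``)."""
        if base not in CANONICAL_BASES:
            raise DataError(f"unknown base {base!r}")
        return getattr(self, f"n_{base}")

    def __add__(self, other: "NucleotideComposition") -> "NucleotideComposition":
        return NucleotideComposition(
            n_A=self.n_A + other.n_A,
            n_C=self.n_C + other.n_C,
            n_G=self.n_G + other.n_G,
            n_U=self.n_U + other.n_U,
            n_ambiguous=self.n_ambiguous + other.n_ambiguous,
            length=self.length + other.length,
        )


@dataclass(frozen=True)
class RibosomeComposition:
    """Per-ribosome base counts: elementwise sum over rRNA species.

    ``components`` retains the provenance (one ``(sequence id,
    NucleotideComposition)`` pair per rRNA species, one copy each).
    """

    components: tuple[tuple[str, NucleotideComposition], ...]
    N_A: int
    N_C: int
    N_G: int
    N_U: int
    total_length: int

    def __post_init__(self) -> None:
        if not self.components:
            raise DataError("ribosome composition requires at least one component")
        for base in CANONICAL_BASES:
            expected = sum(c.count(base) for _, c in self.components)
            if getattr(self, f"N_{base}") != expected:
                raise DataError(f"N_{base} does not equal the component sum")
        if self.total_length != sum(c.length for _, c in self.components):
            raise DataError("total_length does not equal the component sum")

    def count(self, base: str) -> int:
        if base not in CANONICAL_BASES:
            raise DataError(f"unknown base {base!r}")
        return getattr(self, f"N_{base}")


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a (multi-record) FASTA file into normalised RNA sequences.

    Accepts DNA-alphabet files (T is mapped to U) and wrapped or
    single-line records.  Raises :class:`DataError` on a missing file,
    an empty file, or a record with an empty sequence.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"no records in FASTA file: {path}")
    out = []
    for rec in records:
        if len(rec.seq) == 0:
            raise DataError(f"record {rec.id!r} has an empty sequence")
        out.append(RnaSequence.from_raw(id=rec.description or rec.id, raw=str(rec.seq)))
    return out


def nucleotide_composition(
    seq: RnaSequence, max_ambiguous_frac: float = 0.01
) -> NucleotideComposition:
    """Exact character tally of a normalised sequence.

    Ambiguity codes are counted in ``n_ambiguous`` and reported via a
    warning; if they exceed ``max_ambiguous_frac`` of the length the
    sequence is rejected, since the composition is a denominator and
    must not silently absorb unknowns.
    """
    tally = collections.Counter(seq.residues)
    n_ambiguous = sum(n for ch, n in tally.items() if ch in AMBIGUITY_CODES)
    if n_ambiguous:
        frac = n_ambiguous / len(seq)
        if frac > max_ambiguous_frac:
            raise DataError(
                f"sequence {seq.id!r}: ambiguous fraction {frac:.2%} exceeds "
                f"{max_ambiguous_frac:.2%}"
            )
        warnings.warn(
            f"sequence {seq.id!r}: {n_ambiguous} ambiguous residues "
            f"({frac:.2%}) excluded from base counts",
            stacklevel=2,
        )
    return NucleotideComposition(
        n_A=tally.get("A", 0),
        n_C=tally.get("C", 0),
        n_G=tally.get("G", 0),
        n_U=tally.get("U", 0),
        n_ambiguous=n_ambiguous,
        length=len(seq),
    )


def ribosome_composition(
    components: Sequence[tuple[str, NucleotideComposition]],
) -> RibosomeComposition:
    """Sum per-species compositions into one per-ribosome composition.

    ``components`` lists one ``(id, composition)`` pair per rRNA species
    present in the ribosome definition (one copy each).
    """
    components = tuple(components)
    if not components:
        raise DataError("empty component list")
    sums = {b: sum(c.count(b) for _, c in components) for b in CANONICAL_BASES}
    return RibosomeComposition(
        components=components,
        N_A=sums["A"],
        N_C=sums["C"],
        N_G=sums["G"],
        N_U=sums["U"],
        total_length=sum(c.length for _, c in components),
    )


def composition_from_fasta(
    path: str | Path, ids: Iterable[str] | None = None
) -> RibosomeComposition:
    """Build a ribosome composition directly from a FASTA of rRNA species.

    ``ids`` optionally restricts (and orders) the records used, matched
    against the first whitespace-delimited token of each header; by
    default every record in the file contributes one copy.
    """
    seqs = read_fasta(path)
    if ids is not None:
        by_key = {s.id.split()[0]: s for s in seqs}
        missing = [i for i in ids if i not in by_key]
        if missing:
            raise DataError(f"ids not found in {path}: {missing}")
        seqs = [by_key[i] for i in ids]
    return ribosome_composition([(s.id, nucleotide_composition(s)) for s in seqs])


def compositions_to_frame(
    pairs: Sequence[tuple[str, NucleotideComposition]],
) -> pd.DataFrame:
    """Tabulate compositions with columns id, n_A, n_C, n_G, n_U, n_ambiguous, length."""
    return pd.DataFrame(
        [
            {
                "id": sid,
                "n_A": c.n_A,
                "n_C": c.n_C,
                "n_G": c.n_G,
                "n_U": c.n_U,
                "n_ambiguous": c.n_ambiguous,
                "length": c.length,
            }
            for sid, c in pairs
        ]
    )


def composition_from_frame(df: pd.DataFrame) -> RibosomeComposition:
    """Rebuild a ribosome composition from a composition table (CSV round-trip)."""
    pairs = [
        (
            str(row["id"]),
            NucleotideComposition(
                n_A=int(row["n_A"]),
                n_C=int(row["n_C"]),
                n_G=int(row["n_G"]),
                n_U=int(row["n_U"]),
                n_ambiguous=int(row.get("n_ambiguous", 0)),
                length=int(row["length"]),
            ),
        )
        for _, row in df.iterrows()
    ]
    return ribosome_composition(pairs)
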