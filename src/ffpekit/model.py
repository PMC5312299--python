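"""Core domain types shared across the package.

The internal coordinate convention is 0-based, half-open ``[start, end)``
throughout; conversion to SAM's 1-based coordinates happens only inside
:mod:`ffpekit.alignment_io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")

#: byte-value -> base code lookup: A=0, C=1, G=2, T=3, anything else (N) = 4
BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODE[_b] = _i
BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence over the alphabet ACGTN."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Encode a base string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(slots=True)
class AlignedMolecule:
    """One merged, mapped sequencing read (a single DNA molecule).

    ``query_bases`` is stored in sequencing (molecule) orientation: for a
    reverse-strand molecule it is the reverse complement of what the
    reference-forward SAM record shows.  ``ref_bases`` is the matched
    reference slice over ``[start, end)`` in reference-forward orientation.
    For gapless alignments ``len(query_bases) == end - start``; gapped reads
    keep their full query string and are recognised (and skipped) by the
    damage profiler through the length mismatch.
    """

    contig: str
    start: int
    end: int
    strand: str  # "+" (forward) or "-" (reverse) relative to the reference
    query_bases: str
    ref_bases: str
    mapq: int = 60
    is_duplicate: bool = False
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.ref_bases) != self.end - self.start:
            raise ValueError(
                "ref_bases length does not match the aligned span: "
                f"{len(self.ref_bases)} vs {self.end - self.start}"
            )
        if not set(self.query_bases) <= _VALID_BASES:
            raise ValueError("query_bases contains characters outside ACGTN")
        if not set(self.ref_bases) <= _VALID_BASES:
            raise ValueError("ref_bases contains characters outside ACGTN")

    @property
    def length(self) -> int:
        """Aligned molecule length in bp (reference span)."""
        return self.end - self.start

    @property
    def is_gapless(self) -> bool:
        return len(self.query_bases) == self.end - self.start

    @property
    def duplicate_key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.start, self.end, self.strand)

    def molecule_ref_bases(self) -> str:
        """Reference bases in molecule (sequencing) orientation."""
        if self.strand == "-":
            return revcomp(self.ref_bases)
        return self.ref_bases


class ReferenceStore:
    """In-memory reference with random access to [start, end) slices.

    Slices that leave a contig raise ``IndexError`` rather than padding, so
    flank lookups at contig edges fail loudly and can be counted by callers.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("ReferenceStore requires at least one sequence")
        self._seqs: dict[str, str] = {
            name: str(seq).upper() for name, seq in sequences.items()
        }

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceStore":
        import pyfaidx

        fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fasta[name][:]) for name in fasta.keys()})

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def contigs(self) -> Iterator[str]:
        return iter(self._seqs)

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    def length(self, contig: str) -> int:
        return len(self._seqs[contig])

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def sequence(self, contig: str) -> str:
        return self._seqs[contig]

    def fetch(self, contig: str, start: int, end: int) -> str:
        if contig not in self._seqs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self._seqs[contig]
        if start < 0 or end > len(seq) or end < start:
            raise IndexError(
                f"slice [{start}, {end}) outside contig {contig} "
                f"of length {len(seq)}"
            )
        return seq[start:end]


@dataclass(slots=True)
class LibraryMetrics:
    """One library's accounting row (the Tables 2/3-style bookkeeping).

    ``reads_unique_mapped`` counts unique reads mapped to the genome for
    shotgun libraries, or unique reads on target for exome libraries.
    """

    library_id: str
    library_type: str = "ss"  # ss | dsMPI | dsNEB
    assay: str = "genome"  # genome | exome
    molecules_total: float = 0.0
    reads_total: int = 0
    reads_mapped: int = 0
    reads_unique: int = 0
    reads_unique_mapped: int = 0
    median_length: float = 0.0
    storage_years: float = float("nan")
    mappable_bp: float = 0.0
    estimated_coverage: float = 0.0
    fold_enrichment: float = float("nan")
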