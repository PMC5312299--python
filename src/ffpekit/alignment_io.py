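"""SAM I/O, duplicate marking and read subsampling.

Alignments are consumed from (and written to) SAM/BAM through pysam and
normalised into :class:`~ffpekit.model.AlignedMolecule`.  Coordinates are
converted between SAM's 1-based convention and the internal 0-based
half-open convention at this boundary only.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .model import AlignedMolecule, ReferenceStore, revcomp

logger = logging.getLogger(__name__)

_GAPLESS_OPS = {0, 7, 8}  # M, =, X


def read_alignments(
    path: str,
    min_mapq: int = 0,
    reference: ReferenceStore | None = None,
) -> Iterator[AlignedMolecule]:
    """Stream mapped primary alignments as AlignedMolecule records.

    Unmapped, secondary and supplementary records are skipped, as are
    records below ``min_mapq``.  ``ref_bases`` is taken from ``reference``
    when given, otherwise reconstructed from the MD tag; records allowing
    neither are skipped with a warning.  The yielded count is logged.
    """
    n_yielded = n_skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            try:
                mol = _to_molecule(rec, reference)
            except (ValueError, KeyError, IndexError) as exc:
                n_skipped += 1
                logger.warning("skipping malformed record %s: %s", rec.query_name, exc)
                continue
            if mol is None:
                n_skipped += 1
                continue
            n_yielded += 1
            yield mol
    logger.info("read_alignments: %d molecules yielded, %d skipped", n_yielded, n_skipped)


def _to_molecule(
    rec: pysam.AlignedSegment, reference: ReferenceStore | None
) -> AlignedMolecule | None:
    seq = rec.query_sequence
    if seq is None:
        logger.warning("record %s has no sequence; skipped", rec.query_name)
        return None
    contig = rec.reference_name
    start, end = rec.reference_start, rec.reference_end
    if reference is not None:
        ref_bases = reference.fetch(contig, start, end)
    else:
        try:
            ref_bases = rec.get_reference_sequence().upper()
        except ValueError as exc:
            raise ValueError(f"no reference and no MD tag: {exc}") from exc
    strand = "-" if rec.is_reverse else "+"
    query = revcomp(seq.upper()) if rec.is_reverse else seq.upper()
    lib = rec.get_tag("LB") if rec.has_tag("LB") else ""
    return AlignedMolecule(
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        query_bases=query,
        ref_bases=ref_bases,
        mapq=rec.mapping_quality,
        is_duplicate=rec.is_duplicate,
        library_id=lib,
    )


def write_alignments(
    molecules: Iterable[AlignedMolecule],
    path: str,
    reference: ReferenceStore,
) -> int:
    """Write molecules as a coordinate-unsorted SAM/BAM file.

    Round-trips through :func:`read_alignments`: coordinates, strand and
    sequences are reproduced exactly.  Returns the number of records written.
    """
    contigs = list(reference.contigs())
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": reference.length(c)} for c in contigs],
    }
    mode = "wb" if str(path).endswith(".bam") else "w"
    n = 0
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        tid = {c: i for i, c in enumerate(contigs)}
        for i, mol in enumerate(molecules):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"mol{i}"
            rec.reference_id = tid[mol.contig]
            rec.reference_start = mol.start
            rec.mapping_quality = mol.mapq
            rec.flag = (16 if mol.strand == "-" else 0) | (1024 if mol.is_duplicate else 0)
            seq = revcomp(mol.query_bases) if mol.strand == "-" else mol.query_bases
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            rec.cigartuples = [(0, len(seq))]
            if mol.library_id:
                rec.set_tag("LB", mol.library_id)
            out.write(rec)
            n += 1
    return n


def mark_duplicates(
    molecules: Sequence[AlignedMolecule],
) -> tuple[list[AlignedMolecule], float]:
    """Mark PCR duplicates in place and return (molecules, unique_fraction).

    Molecules sharing ``(contig, start, end, strand)`` form one duplicate
    group; the first-seen member of each group stays non-duplicate (merged
    single-end reads observe both molecule ends, so the coordinate pair
    identifies the molecule).  ``unique_fraction = n_groups / n_molecules``.
    """
    molecules = list(molecules)
    if not molecules:
        raise ValueError("mark_duplicates: empty input")
    seen: set[tuple[str, int, int, str]] = set()
    for mol in molecules:
        key = mol.duplicate_key
        if key in seen:
            mol.is_duplicate = True
        else:
            mol.is_duplicate = False
            seen.add(key)
    return molecules, len(seen) / len(molecules)


def sample_reads(
    molecules: Iterable[AlignedMolecule],
    n: int,
    seed: int,
    unique_only: bool = False,
    min_length: int | None = None,
) -> list[AlignedMolecule]:
    """Reservoir-sample up to ``n`` molecules passing the filters.

    Deterministic for a given seed.  If fewer than ``n`` molecules pass the
    filters, all of them are returned (with a warning).  The returned sample
    preserves stream order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    reservoir: list[tuple[int, AlignedMolecule]] = []
    seen = 0
    for mol in molecules:
        if unique_only and mol.is_duplicate:
            continue
        if min_length is not None and mol.length < min_length:
            continue
        if seen < n:
            reservoir.append((seen, mol))
        else:
            j = int(rng.integers(0, seen + 1))
            if j < n:
                reservoir[j] = (seen, mol)
        seen += 1
    if seen == 0:
        logger.warning("sample_reads: no molecules passed the filters")
    elif seen < n:
        logger.warning("sample_reads: only %d of requested %d available", seen, n)
    reservoir.sort(key=lambda t: t[0])
    return [mol for _, mol in reservoir]
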