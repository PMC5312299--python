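"""SNV filtering, substitution spectra and the damage false-positive model.

Cytosine deamination puts C>T (and, via the complementary strand, G>A)
substitutions into roughly 1% of reads at any position.  A variant filter
requiring bidirectional support, a minimum unique-read coverage and a
minimum allele frequency keeps almost all such damage below the calling
threshold; the residual risk is modelled here with a Poisson count of
damaged reads at a site.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .damage_profiler import SUBSTITUTION_CLASSES
from .model import AlignedMolecule, ReferenceStore


@dataclass(slots=True)
class VariantCall:
    """A site-level SNV call with per-strand allele support.

    ``pos`` is 0-based internally; VCF's 1-based positions are converted at
    the format boundary.
    """

    contig: str
    pos: int
    ref_base: str
    alt_base: str
    coverage: int
    alt_fwd: int
    alt_rev: int

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        if self.alt_fwd + self.alt_rev > self.coverage:
            raise ValueError("alt reads exceed coverage")
        if min(self.alt_fwd, self.alt_rev, self.coverage) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def alt_reads(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def frequency(self) -> float:
        return self.alt_reads / self.coverage if self.coverage else 0.0

    @property
    def substitution_class(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"


@dataclass
class FilterResult:
    passing: list[VariantCall]
    rejections: dict[str, int]

    @property
    def n_input(self) -> int:
        return len(self.passing) + sum(self.rejections.values())


def filter_variants(
    calls: Iterable[VariantCall],
    min_coverage: int = 8,
    min_frequency: float = 0.10,
    require_bidirectional: bool = True,
) -> FilterResult:
    """Apply the damage-aware SNV filter.

    A call passes iff coverage >= ``min_coverage`` AND frequency >=
    ``min_frequency`` AND (if required) at least one alt-supporting unique
    read on each strand.  Each rejected call is tallied under the first
    failing rule, in the order coverage, frequency, unidirectional, so the
    tallies and the passes sum to the input size.  Idempotent and
    order-independent.
    """
    passing: list[VariantCall] = []
    rejections = {"coverage": 0, "frequency": 0, "unidirectional": 0}
    for call in calls:
        if call.coverage < min_coverage:
            rejections["coverage"] += 1
        elif call.frequency < min_frequency:
            rejections["frequency"] += 1
        elif require_bidirectional and (call.alt_fwd < 1 or call.alt_rev < 1):
            rejections["unidirectional"] += 1
        else:
            passing.append(call)
    return FilterResult(passing=passing, rejections=rejections)


def variant_spectrum(calls: Sequence[VariantCall]) -> pd.Series:
    """Frequencies of the 12 substitution classes among calls (sum 1)."""
    calls = list(calls)
    if not calls:
        raise ValueError("variant_spectrum requires at least one call")
    counts = Counter(c.substitution_class for c in calls)
    total = sum(counts.values())
    return pd.Series(
        {cls: counts.get(cls, 0) / total for cls in SUBSTITUTION_CLASSES},
        name="frequency",
    )


@dataclass
class FalsePositiveModel:
    """Poisson model of damage-driven false-positive calls.

    At a site with ``coverage`` unique reads, the number of reads carrying a
    C>T damage substitution is modelled as Poisson(damage_rate x coverage).
    A false positive requires at least ``min_alt_reads`` damaged reads and a
    damaged-read fraction above (``strict_threshold``) or at-or-above the
    reporting threshold ``freq_threshold``.  The strict/inclusive choice is
    exposed because either reading of "e.g. 5% of sequencing reads" is
    defensible and they differ up to an order of magnitude at high coverage.
    """

    damage_rate: float = 0.01
    freq_threshold: float = 0.05
    min_alt_reads: int = 2
    max_coverage: int = 100
    strict_threshold: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.damage_rate <= 1:
            raise ValueError("damage_rate must be in [0, 1]")
        if not 0 < self.freq_threshold < 1:
            raise ValueError("freq_threshold must be in (0, 1)")

    def required_alt_reads(self, coverage: int) -> int:
        x = self.freq_threshold * coverage
        if self.strict_threshold:
            k = math.floor(x) + 1  # smallest integer strictly exceeding x
        else:
            k = math.ceil(x)  # smallest integer reaching x
        return max(self.min_alt_reads, k)


def fp_probability(model: FalsePositiveModel, coverage: int) -> float:
    """P(a site is called as a damage-only false positive) at a coverage."""
    if not 1 <= coverage <= model.max_coverage:
        raise ValueError(
            f"coverage must be in [1, {model.max_coverage}], got {coverage}"
        )
    k = model.required_alt_reads(coverage)
    lam = model.damage_rate * coverage
    return float(stats.poisson.sf(k - 1, lam))


def fp_curve(model: FalsePositiveModel) -> pd.DataFrame:
    """False-positive probability per coverage 1..max, with the maximum.

    Nondecreasing in ``damage_rate`` at fixed coverage; the sawtooth over
    coverage comes from the integer read threshold.
    """
    cov = np.arange(1, model.max_coverage + 1)
    probs = np.array([fp_probability(model, int(c)) for c in cov])
    df = pd.DataFrame({"coverage": cov, "fp_probability": probs})
    df.attrs["max_fp_probability"] = float(probs.max())
    df.attrs["argmax_coverage"] = int(cov[int(np.argmax(probs))])
    df.attrs["strict_threshold"] = model.strict_threshold
    return df


def read_variants_tsv(path: str) -> list[VariantCall]:
    """Read calls from a flat TSV with 1-based positions.

    Required columns: contig, pos, ref, alt, coverage, alt_fwd, alt_rev.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "pos", "ref", "alt", "coverage", "alt_fwd", "alt_rev"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    return [
        VariantCall(
            contig=str(r.contig),
            pos=int(r.pos) - 1,
            ref_base=str(r.ref),
            alt_base=str(r.alt),
            coverage=int(r.coverage),
            alt_fwd=int(r.alt_fwd),
            alt_rev=int(r.alt_rev),
        )
        for r in df.itertuples()
    ]


def read_variants_vcf(path: str) -> list[VariantCall]:
    """Read biallelic SNVs from a VCF.

    Per-strand alt support is taken from the samtools-style INFO/DP4 field
    (ref-fwd, ref-rev, alt-fwd, alt-rev); coverage from DP4's sum, falling
    back to INFO/DP.  Records without strand information are skipped.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            info = rec.info
            if "DP4" not in info:
                continue
            dp4 = list(info["DP4"])
            coverage = int(sum(dp4)) if "DP" not in info else int(info["DP"])
            calls.append(
                VariantCall(
                    contig=rec.contig,
                    pos=rec.pos - 1,
                    ref_base=ref,
                    alt_base=alt,
                    coverage=coverage,
                    alt_fwd=int(dp4[2]),
                    alt_rev=int(dp4[3]),
                )
            )
    return calls


def write_variants_tsv(calls: Sequence[VariantCall], path: str) -> None:
    pd.DataFrame(
        [
            {
                "contig": c.contig,
                "pos": c.pos + 1,
                "ref": c.ref_base,
                "alt": c.alt_base,
                "coverage": c.coverage,
                "alt_fwd": c.alt_fwd,
                "alt_rev": c.alt_rev,
                "frequency": c.frequency,
                "class": c.substitution_class,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def pileup_calls(
    molecules: Iterable[AlignedMolecule],
    reference: ReferenceStore,
    min_alt_reads: int = 2,
) -> list[VariantCall]:
    """Naive pileup caller over unique, gapless molecules.

    Counts per-strand alt support and unique-read depth column by column and
    emits every site with at least ``min_alt_reads`` reads of one alternate
    allele.  This is a deliberately simple caller for simulated data with
    truth alignments, not a replacement for a production caller.
    """
    depth: dict[str, np.ndarray] = {}
    alt_counts: dict[tuple[str, int, str], list[int]] = defaultdict(lambda: [0, 0])
    for mol in molecules:
        if mol.is_duplicate or not mol.is_gapless:
            continue
        if mol.contig not in depth:
            depth[mol.contig] = np.zeros(reference.length(mol.contig), dtype=np.int32)
        depth[mol.contig][mol.start : mol.end] += 1
        q = mol.query_bases if mol.strand == "+" else _revcomp(mol.query_bases)
        sidx = 0 if mol.strand == "+" else 1
        r = mol.ref_bases
        for i in range(len(r)):
            if q[i] != r[i] and q[i] in "ACGT" and r[i] in "ACGT":
                alt_counts[(mol.contig, mol.start + i, q[i])][sidx] += 1
    calls = []
    for (contig, pos, alt), (fwd, rev) in sorted(alt_counts.items()):
        if fwd + rev < min_alt_reads:
            continue
        calls.append(
            VariantCall(
                contig=contig,
                pos=pos,
                ref_base=reference.fetch(contig, pos, pos + 1),
                alt_base=alt,
                coverage=int(depth[contig][pos]),
                alt_fwd=fwd,
                alt_rev=rev,
            )
        )
    return calls


def _revcomp(seq: str) -> str:
    from .model import revcomp

    return revcomp(seq)
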