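"""Known-truth generator of FFPE-like sequencing libraries.

The generator emulates the statistical structure of FFPE-derived reads so
every analysis module is testable without external data:

* a random i.i.d. reference of chosen GC content,
* molecule lengths drawn log-normal (median ``exp(mu)``) truncated >= 10 bp,
* 5' breakpoints biased towards positions preceded by adenine on the
  molecule's own template strand (crosslink-adjacent strand breaks),
* C>T deamination elevated at molecule ends and decaying exponentially to
  an interior plateau,
* single-strand vs double-strand library representation (a ds read shows
  the complementary strand's deamination as G>A towards its 3' end),
* geometric PCR copy counts controlling the unique-read fraction,
* optional planted SNVs at known sites and allele frequencies.

The mapper is bypassed: reads carry their true alignments, so no aligner
dependency exists and recovery tests compare against exact truth.
All randomness flows from a single ``numpy`` Generator seeded from the
config, making every output bit-stable per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import AlignedMolecule, ReferenceStore, revcomp

_BASES = np.array(list("ACGT"))
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


@dataclass
class SimulationConfig:
    """Parameter vector of one simulated library.

    Defaults are the FFPE single-strand preset: median molecule length
    61 bp, flanking-adenine fraction 0.53, terminal C>T 3% decaying to an
    interior 1%, two-fold mean PCR duplication, on a 1 Mb reference of 42%
    GC (the human genome's overall GC content).
    """

    seed: int = 0
    reference_length: int = 1_000_000
    reference_gc: float = 0.42
    contig: str = "sim1"
    n_fragments: int = 100_000
    length_median: float = 61.0
    length_sigma: float = 0.35
    min_length: int = 10
    #: multiplicative weight for breakpoints immediately 3' of an A on the
    #: molecule's template strand; 1.0 = unbiased.
    a_bias: float = 1.0
    ct_end_rate: float = 0.03
    ct_interior_rate: float = 0.01
    decay_constant: float = 5.0
    library_type: str = "ss"  # ss | ds
    duplication_mean: float = 2.0
    n_variants_planted: int = 0
    variant_freq_range: tuple[float, float] = (0.2, 0.9)
    library_id: str = "sim"

    def __post_init__(self) -> None:
        for r in (self.ct_end_rate, self.ct_interior_rate):
            if not 0 <= r <= 1:
                raise ValueError("deamination rates must be in [0, 1]")
        if self.a_bias < 0:
            raise ValueError("a_bias must be >= 0")
        if self.duplication_mean < 1:
            raise ValueError("duplication_mean must be >= 1")
        if self.library_type not in ("ss", "ds"):
            raise ValueError("library_type must be 'ss' or 'ds'")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated library, for recovery testing."""

    config: SimulationConfig
    fragments: pd.DataFrame  # start, end, strand, copies, n_ct, n_ga
    variants: pd.DataFrame  # contig, pos (0-based), ref, alt, frequency

    @property
    def n_unique(self) -> int:
        return len(self.fragments)

    @property
    def n_reads(self) -> int:
        return int(self.fragments["copies"].sum())


def a_bias_for_flanking_fraction(target: float, a_fraction: float) -> float:
    """Invert the closed-form flanking-A expectation to a mechanism weight.

    With template-A fraction ``w`` and weight ``a``, the expected fraction of
    molecules whose 5'-flanking base is A is ``w*a / (w*a + 1 - w)``; this
    returns the ``a`` achieving a ``target`` fraction.
    """
    if not 0 < target < 1 or not 0 < a_fraction < 1:
        raise ValueError("fractions must be in (0, 1)")
    return target * (1 - a_fraction) / (a_fraction * (1 - target))


def expected_flanking_a(a_bias: float, a_fraction: float) -> float:
    return a_fraction * a_bias / (a_fraction * a_bias + 1 - a_fraction)


def preset(name: str, **overrides) -> SimulationConfig:
    """Named presets: ``ffpe_ss``, ``ffpe_ds`` and ``frozen``.

    ``ffpe_ss``/``ffpe_ds`` target the FFPE read-outs (flanking-A 0.53,
    terminal C>T 0.03, interior 0.01, median 61/86 bp); ``frozen`` is the
    undamaged contrast (no A-bias, no deamination, median 150 bp, no
    duplication).
    """
    gc = overrides.get("reference_gc", 0.42)
    w_a = (1 - gc) / 2
    presets = {
        "ffpe_ss": dict(
            library_type="ss",
            length_median=61.0,
            a_bias=a_bias_for_flanking_fraction(0.53, w_a),
            ct_end_rate=0.03,
            ct_interior_rate=0.01,
            duplication_mean=2.0,
        ),
        "ffpe_ds": dict(
            library_type="ds",
            length_median=86.0,
            a_bias=a_bias_for_flanking_fraction(0.53, w_a),
            ct_end_rate=0.03,
            ct_interior_rate=0.01,
            duplication_mean=2.0,
        ),
        "frozen": dict(
            library_type="ss",
            length_median=150.0,
            a_bias=1.0,
            ct_end_rate=0.0,
            ct_interior_rate=0.0,
            duplication_mean=1.0,
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
    params = presets[name] | overrides
    return SimulationConfig(library_id=name, **params)


def simulate_reference(
    length: int, gc: float, seed: int, contig: str = "sim1"
) -> ReferenceStore:
    """I.i.d. reference with P(G) + P(C) = gc, deterministic per seed."""
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return ReferenceStore({contig: "".join(_BASES[codes])})


def simulate_fragments(
    reference: ReferenceStore,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw fragment coordinates with A-biased 5' breakpoints.

    Strand is uniform.  The molecule's 5' breakpoint falls, with weight
    ``a_bias`` vs 1, at positions whose 5'-neighbouring base on the template
    strand is adenine — for forward molecules that is reference A at
    ``start - 1``; for reverse molecules reference T at ``end`` (adenine on
    the complementary strand).  Lengths are log-normal truncated at
    ``min_length``; fragments exceeding the contig are redrawn.
    """
    contig = next(iter(reference.contigs()))
    seq = np.frombuffer(reference.sequence(contig).encode(), dtype=np.uint8)
    L = len(seq)
    n = config.n_fragments
    # weight vectors for the molecule 5' breakpoint, per strand
    w_fwd = np.where(seq[:-1] == ord("A"), config.a_bias, 1.0)  # break after i-1
    p_fwd = w_fwd / w_fwd.sum()
    w_rev = np.where(seq[1:] == ord("T"), config.a_bias, 1.0)  # end index e-1
    p_rev = w_rev / w_rev.sum()

    mu = np.log(config.length_median)
    strands = rng.random(n) < 0.5  # True = forward
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    while len(todo):
        lengths = np.rint(
            rng.lognormal(mu, config.length_sigma, size=len(todo))
        ).astype(np.int64)
        fwd = strands[todo]
        b = np.empty(len(todo), dtype=np.int64)
        if fwd.any():
            b[fwd] = rng.choice(L - 1, size=int(fwd.sum()), p=p_fwd) + 1
        if (~fwd).any():
            b[~fwd] = rng.choice(L - 1, size=int((~fwd).sum()), p=p_rev)
        s = np.where(fwd, b, b + 1 - lengths)
        e = s + lengths
        ok = (lengths >= config.min_length) & (s >= 0) & (e <= L)
        starts[todo[ok]] = s[ok]
        ends[todo[ok]] = e[ok]
        todo = todo[~ok]
    return pd.DataFrame(
        {
            "contig": contig,
            "start": starts,
            "end": ends,
            "strand": np.where(strands, "+", "-"),
        }
    )


def deamination_rate(
    distance: np.ndarray | int, config: SimulationConfig
) -> np.ndarray | float:
    """Per-C C>T probability at a distance (0-based) from a molecule end."""
    return config.ct_interior_rate + (
        config.ct_end_rate - config.ct_interior_rate
    ) * np.exp(-np.asarray(distance) / config.decay_constant)


def apply_deamination(
    fragment: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Deaminate one molecule strand: each C converts to T with probability
    ``rate(d)`` where d is the distance to the *nearer* molecule end.

    Returns the damaged sequence and the converted positions.
    """
    arr = np.frombuffer(fragment.encode(), dtype=np.uint8).copy()
    n = len(arr)
    d = np.minimum(np.arange(n), n - 1 - np.arange(n))
    is_c = arr == ord("C")
    hit = is_c & (rng.random(n) < deamination_rate(d, config))
    arr[hit] = ord("T")
    return arr.tobytes().decode(), np.flatnonzero(hit).tolist()


def plant_variants(
    reference: ReferenceStore,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Choose variant sites, alt alleles and allele frequencies."""
    contig = next(iter(reference.contigs()))
    L = reference.length(contig)
    n = config.n_variants_planted
    if n == 0:
        return pd.DataFrame(columns=["contig", "pos", "ref", "alt", "frequency"])
    pos = np.sort(
        rng.choice(np.arange(L // 10, L - L // 10), size=n, replace=False)
    )
    lo, hi = config.variant_freq_range
    rows = []
    for p in pos:
        ref_base = reference.fetch(contig, int(p), int(p) + 1)
        alt = rng.choice([b for b in "ACGT" if b != ref_base])
        rows.append(
            {
                "contig": contig,
                "pos": int(p),
                "ref": ref_base,
                "alt": str(alt),
                "frequency": float(lo if lo == hi else rng.uniform(lo, hi)),
            }
        )
    return pd.DataFrame(rows)


def build_library(
    reference: ReferenceStore,
    fragments: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    variants: pd.DataFrame | None = None,
) -> tuple[list[AlignedMolecule], SimulationTruth]:
    """Turn fragments into reads with damage, variants and PCR duplicates.

    Single-strand libraries read the molecule strand itself, so its C>T
    damage shows at both read ends.  Double-strand libraries read either
    strand of the repaired duplex: the read 5' region keeps that strand's
    C>T while the 3' region is filled in by copying the partner strand,
    whose terminal C>T surfaces as G>A — modelled as C>T with the 5'-distance
    rate plus G>A with the 3'-distance rate on every read.  PCR copies are
    identical replicates of the damaged molecule (geometric copy count).
    """
    if variants is None:
        variants = plant_variants(reference, config, rng)
    contig = next(iter(reference.contigs()))
    var_by_pos = {
        int(r.pos): (str(r.ref), str(r.alt), float(r.frequency))
        for r in variants.itertuples()
    }
    copies = rng.geometric(1.0 / config.duplication_mean, size=len(fragments))
    reads: list[AlignedMolecule] = []
    frag_rows = []
    for i, (start, end, strand, ncopy) in enumerate(
        zip(fragments["start"], fragments["end"], fragments["strand"], copies)
    ):
        start, end = int(start), int(end)
        ref_span = reference.fetch(contig, start, end)
        dup_span = ref_span
        # plant variants on the duplex (both strands) per molecule
        for p, (ref_b, alt_b, freq) in var_by_pos.items():
            if start <= p < end and rng.random() < freq:
                off = p - start
                dup_span = dup_span[:off] + alt_b + dup_span[off + 1 :]
        mol_seq = dup_span if strand == "+" else revcomp(dup_span)
        if config.library_type == "ss":
            read_seq, ct_pos = apply_deamination(mol_seq, config, rng)
            n_ct, n_ga = len(ct_pos), 0
        else:
            read_seq, n_ct, n_ga = _deaminate_ds(mol_seq, config, rng)
        for _ in range(int(ncopy)):
            reads.append(
                AlignedMolecule(
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    query_bases=read_seq,
                    ref_bases=ref_span,
                    mapq=60,
                    library_id=config.library_id,
                )
            )
        frag_rows.append(
            {
                "start": start,
                "end": end,
                "strand": strand,
                "copies": int(ncopy),
                "n_ct": n_ct,
                "n_ga": n_ga,
            }
        )
    truth = SimulationTruth(
        config=config, fragments=pd.DataFrame(frag_rows), variants=variants
    )
    return reads, truth


def _deaminate_ds(
    mol_seq: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Double-strand read damage: C>T by 5'-distance, G>A by 3'-distance."""
    arr = np.frombuffer(mol_seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    d5 = np.arange(n)
    d3 = n - 1 - d5
    u = rng.random(n)
    ct = (arr == ord("C")) & (u < deamination_rate(d5, config))
    ga = (arr == ord("G")) & (u < deamination_rate(d3, config))
    arr[ct] = ord("T")
    arr[ga] = ord("A")
    return arr.tobytes().decode(), int(ct.sum()), int(ga.sum())


def simulate_library(
    config: SimulationConfig,
) -> tuple[ReferenceStore, list[AlignedMolecule], SimulationTruth]:
    """One-call convenience: reference + fragments + reads + truth."""
    reference = simulate_reference(
        config.reference_length, config.reference_gc, config.seed, config.contig
    )
    rng = np.random.default_rng(config.seed + 1)
    fragments = simulate_fragments(reference, config, rng)
    variants = plant_variants(reference, config, rng)
    reads, truth = build_library(reference, fragments, config, rng, variants)
    return reference, reads, truth


def write_fastq(molecules: Sequence[AlignedMolecule], path: str) -> None:
    """Write reads (molecule orientation) as FASTQ, for external mappers."""
    with open(path, "w") as fh:
        for i, mol in enumerate(molecules):
            fh.write(
                f"@mol{i}\n{mol.query_bases}\n+\n{'I' * len(mol.query_bases)}\n"
            )


def truth_to_tsv(truth: SimulationTruth, path: str) -> None:
    truth.fragments.to_csv(path, sep="\t", index=False)
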