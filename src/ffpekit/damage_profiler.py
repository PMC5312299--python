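"""Positional damage read-outs for FFPE-derived molecules.

Formalin fixation leaves two diagnostic footprints in sequencing data that
this module quantifies from aligned molecules:

* **A-fragmentation** — strand breaks next to adenines enrich adenine as the
  reference base immediately outside the sequenced molecule's 5' end (and,
  through the complementary strand, thymine outside the 3' end).
* **Cytosine deamination** — C>T substitutions elevated at molecule ends
  (single-stranded, frayed termini) over the molecule interior.

Frequencies are conditional on the reference base at the column: the rate of
X>Y at position *p* is (# columns with reference X and query Y) divided by
(# columns with reference X), which is the standard per-class damage-pattern
read-out.  Columns whose reference or query base is N are excluded from the
denominators; reads with alignment gaps are skipped entirely, as the model
assumes column-wise alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_io import sample_reads
from .model import AlignedMolecule, ReferenceStore, encode_bases, revcomp, BASES

#: the 12 substitution classes, reference base > query base
SUBSTITUTION_CLASSES = [f"{x}>{y}" for x in BASES for y in BASES if x != y]


@dataclass
class DamageProfile:
    """Positional substitution frequencies and flanking base composition.

    ``subst_freq_5p`` / ``subst_freq_3p``: rows are positions 1..k counted
    from the respective molecule end (1 = terminal base), columns the 12
    substitution classes.

    ``ref_base_comp_5p``: rows are offsets -flank..-1 (reference bases
    outside the molecule, -1 immediately 5' of the first base) followed by
    positions 1..k inside the molecule.  ``ref_base_comp_3p`` mirrors this:
    rows -k..-1 are inside the molecule (-1 = 3'-terminal base) and +1..+flank
    outside (+1 immediately past the 3' end).
    """

    subst_freq_5p: pd.DataFrame
    subst_freq_3p: pd.DataFrame
    ref_base_comp_5p: pd.DataFrame
    ref_base_comp_3p: pd.DataFrame
    n_reads_used: int
    n_skipped: int
    orientation_mode: str
    k_positions: int
    flank: int
    # raw (position x ref-code x query-code) counts, kept for CI computation
    pair_counts_5p: np.ndarray = field(repr=False, default=None)
    pair_counts_3p: np.ndarray = field(repr=False, default=None)
    flank_counts_5p: np.ndarray = field(repr=False, default=None)
    flank_counts_3p: np.ndarray = field(repr=False, default=None)
    #: (ref-code x query-code) counts over columns at least k positions from
    #: both molecule ends — the asymptotic interior, clear of end decay
    interior_counts: np.ndarray = field(repr=False, default=None)

    def denominator_5p(self, position: int, ref_base: str) -> int:
        """Number of N-free columns with the given reference base at a
        position (1-based from the 5' end) — the frequency denominator."""
        b = BASES.index(ref_base)
        return int(self.pair_counts_5p[position - 1, b, :4].sum())

    def denominator_3p(self, position: int, ref_base: str) -> int:
        b = BASES.index(ref_base)
        return int(self.pair_counts_3p[position - 1, b, :4].sum())

    def to_tsv(self, path: str) -> None:
        rows = []
        for end, df in (("5p", self.subst_freq_5p), ("3p", self.subst_freq_3p)):
            for pos, row in df.iterrows():
                for cls, val in row.items():
                    rows.append(("subst", end, pos, cls, val))
        for end, df in (("5p", self.ref_base_comp_5p), ("3p", self.ref_base_comp_3p)):
            for pos, row in df.iterrows():
                for base, val in row.items():
                    rows.append(("composition", end, pos, base, val))
        pd.DataFrame(rows, columns=["table", "end", "position", "class", "frequency"]).to_csv(
            path, sep="\t", index=False
        )

    def to_json(self, path: str) -> None:
        payload = {
            "n_reads_used": self.n_reads_used,
            "n_skipped": self.n_skipped,
            "orientation_mode": self.orientation_mode,
            "k_positions": self.k_positions,
            "flank": self.flank,
            "subst_freq_5p": self.subst_freq_5p.to_dict(orient="index"),
            "subst_freq_3p": self.subst_freq_3p.to_dict(orient="index"),
            "ref_base_comp_5p": self.ref_base_comp_5p.to_dict(orient="index"),
            "ref_base_comp_3p": self.ref_base_comp_3p.to_dict(orient="index"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


@dataclass
class LengthDistribution:
    """Histogram of molecule lengths with its order-statistic median."""

    histogram: pd.Series  # index: length (bp), values: counts
    median: float
    count: int


def _normalise_rows(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = counts / totals
    out[np.isnan(out)] = 0.0
    return out


def damage_profile(
    molecules: Iterable[AlignedMolecule],
    reference: ReferenceStore,
    k_positions: int = 25,
    flank: int = 10,
    min_length: int = 30,
    orientation_mode: str = "molecule",
) -> DamageProfile:
    """Count positional substitutions and flanking composition.

    In ``orientation_mode="molecule"`` reverse-strand reads are reverse
    complemented (query and reference context both) so positions count from
    the original molecule's 5' end — the natural mode for single-strand
    libraries, where the sequenced strand *is* the molecule.  In
    ``"as_mapped"`` all reads are taken in reference-forward orientation,
    the conventional mode for double-strand libraries (where deamination on
    the complementary strand surfaces as G>A at the read 3' end).

    Molecules shorter than ``min_length``, gapped molecules, and molecules
    whose flank window leaves the contig are skipped and counted.
    """
    if k_positions < 1 or flank < 1:
        raise ValueError("k_positions and flank must be >= 1")
    if orientation_mode not in ("molecule", "as_mapped"):
        raise ValueError(f"unknown orientation_mode {orientation_mode!r}")
    k, f = k_positions, flank
    pair5 = np.zeros((k, 5, 5), dtype=np.int64)
    pair3 = np.zeros((k, 5, 5), dtype=np.int64)
    flank5 = np.zeros((f, 5), dtype=np.int64)
    flank3 = np.zeros((f, 5), dtype=np.int64)
    interior = np.zeros((5, 5), dtype=np.int64)
    n_used = n_skipped = 0

    for mol in molecules:
        if not mol.is_gapless or mol.length < min_length:
            n_skipped += 1
            continue
        try:
            left = reference.fetch(mol.contig, mol.start - f, mol.start)
            right = reference.fetch(mol.contig, mol.end, mol.end + f)
        except (IndexError, KeyError):
            n_skipped += 1
            continue
        if orientation_mode == "molecule" and mol.strand == "-":
            q = mol.query_bases
            r = revcomp(mol.ref_bases)
            f5, f3 = revcomp(right), revcomp(left)
        else:
            q = revcomp(mol.query_bases) if mol.strand == "-" else mol.query_bases
            r = mol.ref_bases
            f5, f3 = left, right
        qc, rc = encode_bases(q), encode_bases(r)
        m = min(len(qc), k)
        idx = np.arange(m)
        np.add.at(pair5, (idx, rc[:m], qc[:m]), 1)
        np.add.at(pair3, (idx, rc[::-1][:m], qc[::-1][:m]), 1)
        if len(qc) > 2 * k:
            np.add.at(interior, (rc[k:-k], qc[k:-k]), 1)
        # flank rows run -flank..-1 (5') and +1..+flank (3'), outside->inside
        np.add.at(flank5, (np.arange(f), encode_bases(f5)), 1)
        np.add.at(flank3, (np.arange(f), encode_bases(f3)), 1)
        n_used += 1

    positions = np.arange(1, k + 1)
    subst5 = _subst_table(pair5, positions)
    subst3 = _subst_table(pair3, positions)
    comp5 = _composition_table(flank5, pair5, np.arange(-f, 0), positions)
    comp3 = _composition_table(
        flank3, pair3, np.arange(1, f + 1), -positions, inside_first=True
    )
    return DamageProfile(
        subst_freq_5p=subst5,
        subst_freq_3p=subst3,
        ref_base_comp_5p=comp5,
        ref_base_comp_3p=comp3,
        n_reads_used=n_used,
        n_skipped=n_skipped,
        orientation_mode=orientation_mode,
        k_positions=k,
        flank=f,
        pair_counts_5p=pair5,
        pair_counts_3p=pair3,
        flank_counts_5p=flank5,
        flank_counts_3p=flank3,
        interior_counts=interior,
    )


def _subst_table(pair: np.ndarray, positions: np.ndarray) -> pd.DataFrame:
    k = pair.shape[0]
    freqs = np.zeros((k, len(SUBSTITUTION_CLASSES)))
    # denominator: N-free columns with the given reference base
    denom = pair[:, :4, :4].sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        for j, cls in enumerate(SUBSTITUTION_CLASSES):
            x, y = BASES.index(cls[0]), BASES.index(cls[2])
            freqs[:, j] = np.where(denom[:, x] > 0, pair[:, x, y] / denom[:, x], 0.0)
    return pd.DataFrame(freqs, index=positions, columns=SUBSTITUTION_CLASSES)


def _composition_table(
    flank_counts: np.ndarray,
    pair: np.ndarray,
    flank_index: np.ndarray,
    inside_index: np.ndarray,
    inside_first: bool = False,
) -> pd.DataFrame:
    inside_counts = pair[:, :4, :].sum(axis=2)  # ref-base counts, N excluded
    flank_freq = _normalise_rows(flank_counts[:, :4].astype(float))
    inside_freq = _normalise_rows(inside_counts.astype(float))
    if inside_first:
        data = np.vstack([inside_freq[::-1], flank_freq])
        index = np.concatenate([inside_index[::-1], flank_index])
    else:
        data = np.vstack([flank_freq, inside_freq])
        index = np.concatenate([flank_index, inside_index])
    return pd.DataFrame(data, index=index, columns=list(BASES))


def a_fragmentation_fraction(
    profile: DamageProfile, library_type: str = "ss"
) -> dict[str, float]:
    """Flanking-adenine read-out of formalin crosslink fragmentation.

    ``frac_A_5p`` is the frequency of adenine as the reference base at
    offset -1 (immediately 5' of the molecule); ``frac_T_3p`` the frequency
    of thymine at offset +1 past the 3' end.  For double-strand libraries
    profiled in as-mapped orientation the thymine-outside-3' read-out is the
    reverse-strand complement of the same crosslink phenomenon; the cells
    read out are identical, only the interpretation differs.
    """
    if library_type not in ("ss", "ds"):
        raise ValueError(f"library_type must be 'ss' or 'ds', got {library_type!r}")
    return {
        "frac_A_5p": float(profile.ref_base_comp_5p.loc[-1, "A"]),
        "frac_T_3p": float(profile.ref_base_comp_3p.loc[1, "T"]),
    }


def ct_end_elevation(profile: DamageProfile) -> dict[str, float]:
    """Terminal vs interior C>T rates.

    Terminal rates are the C>T frequency at position 1 from each end.
    ``rate_interior`` pools the C>T counts over positions 10..k from both
    ends (count-weighted); note that when end damage decays over several bp
    this window still carries a small residue of the end elevation.
    ``rate_interior_deep`` therefore pools only columns at least k positions
    away from *both* molecule ends (on molecules long enough to have any)
    and is the better estimate of the interior plateau.
    """
    if profile.k_positions < 10:
        raise ValueError("ct_end_elevation requires k_positions >= 10")
    c, t = BASES.index("C"), BASES.index("T")
    num = den = 0
    for pair in (profile.pair_counts_5p, profile.pair_counts_3p):
        num += pair[9:, c, t].sum()
        den += pair[9:, c, :4].sum()
    deep_den = profile.interior_counts[c, :4].sum()
    deep = profile.interior_counts[c, t] / deep_den if deep_den else 0.0
    return {
        "rate_5p_terminal": float(profile.subst_freq_5p.loc[1, "C>T"]),
        "rate_3p_terminal": float(profile.subst_freq_3p.loc[1, "C>T"]),
        "rate_interior": float(num / den) if den else 0.0,
        "rate_interior_deep": float(deep),
    }


def length_distribution(
    molecules: Sequence[AlignedMolecule],
    min_length: int = 10,
    n_sample: int = 100_000,
    seed: int = 0,
) -> LengthDistribution:
    """Molecule length histogram and median from a seeded subsample."""
    sampled = sample_reads(molecules, n_sample, seed=seed, min_length=min_length)
    if not sampled:
        raise ValueError("no molecules of the required minimum length")
    lengths = np.array([m.length for m in sampled])
    hist = pd.Series(lengths).value_counts().sort_index()
    return LengthDistribution(
        histogram=hist, median=float(np.median(lengths)), count=len(lengths)
    )


def gc_content(molecules: Iterable[AlignedMolecule]) -> float:
    """(G+C) / (A+C+G+T) over all query bases; N excluded."""
    counts = np.zeros(5, dtype=np.int64)
    for mol in molecules:
        np.add.at(counts, encode_bases(mol.query_bases), 1)
    acgt = counts[:4].sum()
    if acgt == 0:
        raise ValueError("gc_content: no ACGT bases in input")
    return float((counts[1] + counts[2]) / acgt)
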