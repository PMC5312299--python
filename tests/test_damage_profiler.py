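"""Damage read-outs: positional substitutions, flanking composition,
lengths and GC, checked against hand counts and a brute-force oracle."""

import collections

import numpy as np
import pandas as pd
import pytest

import ffpekit as fk
from ffpekit.damage_profiler import SUBSTITUTION_CLASSES

from conftest import binomial_ci_halfwidth, make_molecule


def brute_force_profile(mols, reference, k, flank, min_length, orientation):
    """Independent per-column counting with plain dicts and string slicing."""
    contig = next(iter(reference.contigs()))
    L = reference.length(contig)
    seq = reference.sequence(contig)
    subst5 = collections.Counter()
    denom5 = collections.Counter()
    subst3 = collections.Counter()
    denom3 = collections.Counter()
    comp5 = collections.Counter()
    comp5_tot = collections.Counter()
    used = 0
    for m in mols:
        if len(m.query_bases) != m.length or m.length < min_length:
            continue
        if m.start - flank < 0 or m.end + flank > L:
            continue
        if orientation == "molecule" and m.strand == "-":
            q = m.query_bases
            r = fk.revcomp(m.ref_bases)
            f5 = fk.revcomp(seq[m.end : m.end + flank])
        else:
            q = fk.revcomp(m.query_bases) if m.strand == "-" else m.query_bases
            r = m.ref_bases
            f5 = seq[m.start - flank : m.start]
        used += 1
        for pos in range(min(len(q), k)):
            if r[pos] in "ACGT" and q[pos] in "ACGT":
                denom5[(pos + 1, r[pos])] += 1
                if q[pos] != r[pos]:
                    subst5[(pos + 1, f"{r[pos]}>{q[pos]}")] += 1
            rp, qp = r[-1 - pos], q[-1 - pos]
            if rp in "ACGT" and qp in "ACGT":
                denom3[(pos + 1, rp)] += 1
                if qp != rp:
                    subst3[(pos + 1, f"{rp}>{qp}")] += 1
        for off in range(1, flank + 1):
            base = f5[flank - off]
            if base in "ACGT":
                comp5[(-off, base)] += 1
                comp5_tot[-off] += 1
    return subst5, denom5, subst3, denom3, comp5, comp5_tot, used


@pytest.fixture(scope="module")
def noisy_reads():
    ref = fk.simulate_reference(100_000, 0.45, seed=3)
    config = fk.preset("ffpe_ss", seed=3, n_fragments=800, reference_length=100_000,
                       reference_gc=0.45)
    _, reads, _ = fk.simulate_library(config)
    return ref, reads[:800]


class TestDamageProfile:
    def test_undamaged_reads_have_zero_substitutions(self, small_reference):
        mols = [make_molecule(small_reference, 50 * i, 60, "+" if i % 2 else "-")
                for i in range(2, 40)]
        prof = fk.damage_profile(mols, small_reference)
        assert prof.subst_freq_5p.to_numpy().sum() == 0
        assert prof.subst_freq_3p.to_numpy().sum() == 0
        assert prof.n_reads_used == len(mols)

    def test_flanking_composition_hand_count(self):
        ref = fk.ReferenceStore({"c": "AACGTTTTGGGCCCAAATTTGGGCCCAAATTTGGGCCCAA"})
        # read1 starts at 1 (5' flank A at 0), read2 at 3 (5' flank C at 2)
        m1 = make_molecule(ref, 1, 30)
        m2 = make_molecule(ref, 3, 30)
        prof = fk.damage_profile([m1, m2], ref, flank=1, min_length=10)
        assert prof.ref_base_comp_5p.loc[-1, "A"] == pytest.approx(0.5)
        assert prof.ref_base_comp_5p.loc[-1, "C"] == pytest.approx(0.5)

    def test_a_fragmentation_hand_count(self):
        ref = fk.ReferenceStore({"c": "A" * 15 + "G" + "C" * 30 + "T" * 15})
        # 5' flanking bases: A (start 15: flank ref[14]=A), A, G (start 16)
        mols = [make_molecule(ref, 15, 20), make_molecule(ref, 15, 25),
                make_molecule(ref, 16, 20)]
        prof = fk.damage_profile(mols, ref, flank=2, min_length=10)
        frac = fk.a_fragmentation_fraction(prof)
        assert frac["frac_A_5p"] == pytest.approx(2 / 3)

    def test_all_a_reference_gives_unit_flanking_a(self):
        ref = fk.ReferenceStore({"c": "A" * 200})
        prof = fk.damage_profile([make_molecule(ref, 50, 60)], ref)
        assert fk.a_fragmentation_fraction(prof)["frac_A_5p"] == 1.0

    def test_substitution_class_and_position(self):
        ref = fk.ReferenceStore({"c": "A" * 20 + "CGCGCGCGCG" + "A" * 40})
        ref_bases = ref.fetch("c", 20, 60)
        query = "T" + ref_bases[1:]  # C>T at molecule position 1
        mol = make_molecule(ref, 20, 40, query=query)
        prof = fk.damage_profile([mol], ref)
        assert prof.subst_freq_5p.loc[1, "C>T"] == 1.0
        assert prof.subst_freq_5p.drop(index=1)["C>T"].sum() == 0
        # the same event seen from the 3' end sits at position 40 > k
        assert prof.subst_freq_3p["C>T"].sum() == 0

    def test_reverse_strand_molecule_orientation(self):
        ref = fk.ReferenceStore({"c": "A" * 30 + "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCC" + "T" + "A" * 30})
        # reverse molecule over [30, 60): its 5' terminal base is ref
        # complement of ref[59]=C -> G; a G>A in molecule orientation is a
        # damage C>T on the opposite reference strand.
        mol_ref = ref.fetch("c", 30, 60)
        query = "A" + fk.revcomp(mol_ref)[1:]  # G>A at molecule position 1
        mol = make_molecule(ref, 30, 30, strand="-", query=query)
        prof = fk.damage_profile([mol], ref)
        assert prof.subst_freq_5p.loc[1, "G>A"] == 1.0
        # 5' flank in molecule orientation is complement of ref[60]=T -> A
        assert prof.ref_base_comp_5p.loc[-1, "A"] == 1.0

    def test_matches_brute_force_oracle(self, noisy_reads):
        ref, reads = noisy_reads
        k, flank = 12, 4
        prof = fk.damage_profile(reads, ref, k_positions=k, flank=flank,
                                 min_length=30, orientation_mode="molecule")
        s5, d5, s3, d3, c5, c5t, used = brute_force_profile(
            reads, ref, k, flank, 30, "molecule")
        assert prof.n_reads_used == used
        for pos in range(1, k + 1):
            for cls in SUBSTITUTION_CLASSES:
                denom = d5[(pos, cls[0])]
                expect = s5[(pos, cls)] / denom if denom else 0.0
                assert prof.subst_freq_5p.loc[pos, cls] == pytest.approx(expect), (pos, cls)
                denom3 = d3[(pos, cls[0])]
                expect3 = s3[(pos, cls)] / denom3 if denom3 else 0.0
                assert prof.subst_freq_3p.loc[pos, cls] == pytest.approx(expect3), (pos, cls)
        for off in range(-flank, 0):
            for base in "ACGT":
                expect = c5[(off, base)] / c5t[off]
                assert prof.ref_base_comp_5p.loc[off, base] == pytest.approx(expect)

    def test_composition_rows_sum_to_one(self, noisy_reads):
        ref, reads = noisy_reads
        prof = fk.damage_profile(reads, ref)
        for comp in (prof.ref_base_comp_5p, prof.ref_base_comp_3p):
            np.testing.assert_allclose(comp.sum(axis=1).to_numpy(), 1.0, atol=1e-9)

    def test_identity_plus_substitutions_sum_to_one(self, noisy_reads):
        ref, reads = noisy_reads
        prof = fk.damage_profile(reads, ref)
        pair = prof.pair_counts_5p
        for pos in range(pair.shape[0]):
            for x, base in enumerate("ACGT"):
                denom = pair[pos, x, :4].sum()
                if denom == 0:
                    continue
                identity = pair[pos, x, x] / denom
                subs = sum(prof.subst_freq_5p.loc[pos + 1, f"{base}>{y}"]
                           for y in "ACGT" if y != base)
                assert identity + subs == pytest.approx(1.0, abs=1e-9)

    def test_n_bases_excluded_from_denominators(self):
        ref = fk.ReferenceStore({"c": "A" * 100})
        query = "N" + "A" * 39
        mol = make_molecule(ref, 30, 40, query=query)
        prof = fk.damage_profile([mol], ref)
        assert prof.denominator_5p(1, "A") == 0
        assert prof.denominator_5p(2, "A") == 1

    def test_mirror_invariance_molecule_mode(self, noisy_reads):
        """Reverse-complementing the whole coordinate system leaves the
        molecule-orientation profile unchanged."""
        ref, reads = noisy_reads
        contig = next(iter(ref.contigs()))
        L = ref.length(contig)
        mirror_ref = fk.ReferenceStore({contig: fk.revcomp(ref.sequence(contig))})
        mirrored = [
            fk.AlignedMolecule(
                contig=contig, start=L - m.end, end=L - m.start,
                strand="-" if m.strand == "+" else "+",
                query_bases=m.query_bases,
                ref_bases=fk.revcomp(m.ref_bases), mapq=m.mapq,
            )
            for m in reads
        ]
        p1 = fk.damage_profile(reads, ref, k_positions=10, flank=3)
        p2 = fk.damage_profile(mirrored, mirror_ref, k_positions=10, flank=3)
        pd.testing.assert_frame_equal(p1.subst_freq_5p, p2.subst_freq_5p)
        pd.testing.assert_frame_equal(p1.subst_freq_3p, p2.subst_freq_3p)
        pd.testing.assert_frame_equal(p1.ref_base_comp_5p, p2.ref_base_comp_5p)

    def test_flank_exiting_contig_is_skipped_and_counted(self, small_reference):
        mols = [make_molecule(small_reference, 2, 40),  # flank 10 exits left
                make_molecule(small_reference, 500, 40)]
        prof = fk.damage_profile(mols, small_reference)
        assert prof.n_reads_used == 1
        assert prof.n_skipped == 1


class TestCtEndElevation:
    def test_undamaged_is_zero(self, small_reference):
        mols = [make_molecule(small_reference, 60 * i, 50) for i in range(2, 30)]
        rates = fk.ct_end_elevation(fk.damage_profile(mols, small_reference))
        assert rates == {"rate_5p_terminal": 0.0, "rate_3p_terminal": 0.0,
                         "rate_interior": 0.0, "rate_interior_deep": 0.0}

    def test_recovers_preset_rates(self, ffpe_ss_run):
        prof = ffpe_ss_run["profile"]
        rates = fk.ct_end_elevation(prof)
        n1 = prof.denominator_5p(1, "C")
        assert abs(rates["rate_5p_terminal"] - 0.03) < binomial_ci_halfwidth(0.03, n1)
        n3 = prof.denominator_3p(1, "C")
        assert abs(rates["rate_3p_terminal"] - 0.03) < binomial_ci_halfwidth(0.03, n3)
        # interior plateau: positions 10..25 sit >= 9 bp from the 5' end but
        # can be near the 3' end on short molecules, so allow a small bias
        # above the plateau in addition to counting noise
        assert 0.009 < rates["rate_interior"] < 0.015
        # deep-interior columns (>= 25 bp from both ends) estimate the
        # plateau itself; residual end decay there is below 2e-4
        n_deep = prof.interior_counts[1, :4].sum()
        assert abs(rates["rate_interior_deep"] - 0.01) < (
            binomial_ci_halfwidth(0.01, n_deep) + 2e-4)

    def test_requires_k_at_least_ten(self, small_reference):
        mols = [make_molecule(small_reference, 100, 50)]
        prof = fk.damage_profile(mols, small_reference, k_positions=5)
        with pytest.raises(ValueError):
            fk.ct_end_elevation(prof)

    def test_ds_library_shows_ga_mirror(self, ffpe_ds_run):
        """In as-mapped orientation a ds library shows C>T at 5' and an
        equally elevated G>A at 3' (deamination on the complementary
        strand)."""
        prof = ffpe_ds_run["profile"]
        ct5 = prof.subst_freq_5p.loc[1, "C>T"]
        ga3 = prof.subst_freq_3p.loc[1, "G>A"]
        n5 = prof.denominator_5p(1, "C")
        n3 = prof.denominator_3p(1, "G")
        assert abs(ct5 - 0.03) < binomial_ci_halfwidth(0.03, n5)
        assert abs(ga3 - 0.03) < binomial_ci_halfwidth(0.03, n3)
        # 3' C>T stays at the interior plateau: the ends differ by class
        assert prof.subst_freq_3p.loc[1, "C>T"] < 0.02


class TestLengthAndGc:
    def test_median_singleton(self, small_reference):
        dist = fk.length_distribution([make_molecule(small_reference, 10, 50)])
        assert dist.median == 50

    def test_median_odd(self, small_reference):
        mols = [make_molecule(small_reference, 100 * i, n)
                for i, n in enumerate([40, 60, 80], start=1)]
        assert fk.length_distribution(mols).median == 60

    def test_min_length_filter_and_empty_error(self, small_reference):
        mols = [make_molecule(small_reference, 100, 8)]
        with pytest.raises(ValueError):
            fk.length_distribution(mols, min_length=10)

    def test_histogram_consistent_with_median(self, ffpe_ss_run):
        dist = fk.length_distribution(ffpe_ss_run["unique"], seed=0)
        total = dist.histogram.sum()
        cum = dist.histogram.cumsum()
        below = cum[cum < total / 2].index.max()
        above = dist.histogram.index[cum >= total / 2].min()
        assert below <= dist.median <= max(above, below + 1)

    def test_recovers_target_median(self, ffpe_ss_run):
        dist = fk.length_distribution(ffpe_ss_run["unique"], seed=0)
        assert abs(dist.median - 61) <= 2

    def test_gc_extremes_and_hand_count(self):
        ref = fk.ReferenceStore({"c": "ATATATATATATATATATAT"})
        mols = [make_molecule(ref, 0, 10)]
        assert fk.gc_content(mols) == 0.0
        refgc = fk.ReferenceStore({"c": "GCGCGCGCGCGCGCGCGCGC"})
        assert fk.gc_content([make_molecule(refgc, 0, 10)]) == 1.0
        refmix = fk.ReferenceStore({"c": "ACGTAATT"})
        mols = [make_molecule(refmix, 0, 4), make_molecule(refmix, 4, 4)]
        # reads ACGT + AATT carry 2 G/C bases among 8
        assert fk.gc_content(mols) == pytest.approx(2 / 8)

    def test_gc_recovers_reference_gc(self, ffpe_ss_run):
        assert fk.gc_content(ffpe_ss_run["unique"][:20000]) == pytest.approx(
            0.42, abs=0.01)
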