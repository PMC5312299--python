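import numpy as np
import pytest

import ffpekit as fk


def make_molecule(
    ref,
    start,
    length,
    strand="+",
    query=None,
    contig=None,
    mapq=60,
    is_duplicate=False,
):
    """Build an AlignedMolecule over a ReferenceStore slice, defaulting the
    query to an undamaged copy of the reference in molecule orientation."""
    contig = contig or next(iter(ref.contigs()))
    ref_bases = ref.fetch(contig, start, start + length)
    if query is None:
        query = fk.revcomp(ref_bases) if strand == "-" else ref_bases
    return fk.AlignedMolecule(
        contig=contig,
        start=start,
        end=start + length,
        strand=strand,
        query_bases=query,
        ref_bases=ref_bases,
        mapq=mapq,
        is_duplicate=is_duplicate,
    )


@pytest.fixture(scope="session")
def small_reference():
    return fk.simulate_reference(50_000, 0.5, seed=42, contig="toy")


@pytest.fixture(scope="session")
def ffpe_ss_run():
    """Full-size single-strand FFPE preset with known truth.

    100,000 fragments on a 1 Mb reference: median length 61 bp, flanking-A
    0.53, terminal C>T 0.03, interior 0.01, duplication mean 2.  Shared by
    the recovery and acceptance tests.
    """
    config = fk.preset("ffpe_ss", seed=1, n_fragments=100_000)
    reference, reads, truth = fk.simulate_library(config)
    reads, unique_fraction = fk.mark_duplicates(reads)
    unique = [m for m in reads if not m.is_duplicate]
    sampled = fk.sample_reads(unique, 100_000, seed=1, min_length=30)
    profile = fk.damage_profile(sampled, reference, orientation_mode="molecule")
    return {
        "config": config,
        "reference": reference,
        "reads": reads,
        "unique": unique,
        "unique_fraction": unique_fraction,
        "truth": truth,
        "profile": profile,
    }


@pytest.fixture(scope="session")
def ffpe_ds_run():
    """Double-strand FFPE preset (100,000 fragments), profiled as mapped."""
    config = fk.preset("ffpe_ds", seed=2, n_fragments=100_000)
    reference, reads, truth = fk.simulate_library(config)
    reads, unique_fraction = fk.mark_duplicates(reads)
    unique = [m for m in reads if not m.is_duplicate]
    profile = fk.damage_profile(unique, reference, orientation_mode="as_mapped")
    return {
        "config": config,
        "reference": reference,
        "unique": unique,
        "unique_fraction": unique_fraction,
        "truth": truth,
        "profile": profile,
    }


def binomial_ci_halfwidth(p, n, z=3.0):
    """Normal-approximation binomial half width (3 sigma by default)."""
    return z * np.sqrt(p * (1 - p) / n)
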