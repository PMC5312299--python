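"""Library accounting: yield, complexity, coverage and group statistics.

The central extrapolation is the *mappable bp* estimate

    mappable_bp = molecules_total x (reads_unique_mapped / reads_total)
                  x median_length

i.e. the ddPCR-measured molecule count scaled by the fraction of sequenced
reads that are both unique and mapped, times the median molecule length.
Dividing by the genome (3.3e9 bp) or exome (3.3e7 bp) size turns this into
an anticipated unique-read coverage had the library been sequenced
exhaustively.

Complexity is summarised by binomial-thinning rarefaction over the
duplicate-group-size multiset, and group contrasts use the exact two-sided
Wilcoxon rank-sum test (normal approximation with tie and continuity
corrections when ties are present).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

GENOME_SIZE_BP = 3.3e9
EXOME_SIZE_BP = 3.3e7
#: exome target share of the genome used for fold-enrichment
DEFAULT_TARGET_FRACTION = EXOME_SIZE_BP / GENOME_SIZE_BP


def estimate_mappable_bp(
    molecules_total: float,
    reads_total: float,
    reads_unique_mapped: float,
    median_length: float,
) -> float:
    """Total mappable bp a library could deliver if sequenced to exhaustion.

    The unique fraction and the mapped-of-unique fraction multiply to the
    single ratio ``reads_unique_mapped / reads_total``.
    """
    if reads_total <= 0:
        raise ValueError("reads_total must be > 0")
    if min(molecules_total, reads_unique_mapped, median_length) < 0:
        raise ValueError("inputs must be non-negative")
    return molecules_total * (reads_unique_mapped / reads_total) * median_length


def estimate_coverage(mappable_bp: float, target_size_bp: float) -> float:
    """Fold coverage of a genome/exome of ``target_size_bp``."""
    if target_size_bp <= 0:
        raise ValueError("target_size_bp must be > 0")
    return mappable_bp / target_size_bp


def fold_enrichment(
    reads_on_target: float,
    reads_mapped_genome: float,
    target_fraction: float = DEFAULT_TARGET_FRACTION,
) -> float:
    """On-target read share relative to the target's share of the genome.

    Comparable across experiments even when the targeted regions differ in
    size; ~1.0 means capture did nothing.
    """
    if reads_mapped_genome <= 0:
        raise ValueError("reads_mapped_genome must be > 0")
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    return (reads_on_target / reads_mapped_genome) / target_fraction


@dataclass
class RarefactionCurve:
    """Expected unique reads as a function of sequencing depth."""

    sizes: np.ndarray
    expected_unique: np.ndarray
    total_reads: int
    observed_unique: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reads": self.sizes, "expected_unique": self.expected_unique}
        )


def expected_unique(group_sizes: np.ndarray, subsample: float) -> float:
    """E[# duplicate groups seen] when drawing ``subsample`` of N reads.

    Binomial-thinning approximation: each read survives independently with
    probability s/N, so a group of size c is seen with probability
    1 - (1 - s/N)^c.
    """
    group_sizes = np.asarray(group_sizes)
    n_total = group_sizes.sum()
    frac = subsample / n_total
    return float(np.sum(1.0 - np.power(1.0 - frac, group_sizes)))


def rarefaction_curve(
    group_sizes: Sequence[int], step: int = 100_000
) -> RarefactionCurve:
    """Rarefaction over the duplicate-group-size multiset at multiples of
    ``step``, anchored at the observed totals.

    The curve is nondecreasing and concave, and its value at the full read
    count equals the observed number of unique molecules.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    sizes_arr = np.asarray(list(group_sizes), dtype=np.int64)
    if len(sizes_arr) == 0 or sizes_arr.min() < 1:
        raise ValueError("group sizes must be a nonempty multiset of counts >= 1")
    n_total = int(sizes_arr.sum())
    grid = np.arange(step, n_total + 1, step, dtype=np.int64)
    if len(grid) == 0 or grid[-1] != n_total:
        grid = np.append(grid, n_total)
    values = np.array([expected_unique(sizes_arr, s) for s in grid])
    return RarefactionCurve(
        sizes=grid,
        expected_unique=values,
        total_reads=n_total,
        observed_unique=int(len(sizes_arr)),
    )


def naive_extrapolation(
    group_sizes: Sequence[int], total_molecules: float, at_reads: Sequence[float]
) -> np.ndarray:
    """Naive extrapolation beyond the observed depth.

    Group sizes are scaled by the total-molecule / sequenced-molecule ratio
    and the same thinning formula is applied; labelled "naive" because no
    rational-function model of the unseen-species problem is fitted.
    """
    sizes_arr = np.asarray(list(group_sizes), dtype=float)
    n_total = sizes_arr.sum()
    scale = total_molecules / n_total
    scaled = sizes_arr * scale
    return np.array(
        [
            float(np.sum(1.0 - np.power(1.0 - min(s / total_molecules, 1.0), scaled)))
            for s in at_reads
        ]
    )


@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float  # Mann-Whitney U of the first sample
    method: str  # "exact" | "normal_tie_corrected"
    tie_corrected: bool


def wilcoxon_exact(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution of the rank sum when the pooled sample
    is tie-free; with ties it falls back to the normal approximation with
    mid-ranks, tie correction and continuity correction (the convention of
    R's ``wilcox.test``, which the flagged result mirrors).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if has_ties:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return WilcoxonResult(float(res.pvalue), float(res.statistic),
                              "normal_tie_corrected", True)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    return WilcoxonResult(float(res.pvalue), float(res.statistic), "exact", False)


def yield_comparison(table1: pd.DataFrame) -> dict:
    """Per-sample yield ratios and rank-sum contrasts between methods.

    Expects columns ``molecules_ss``, ``molecules_dsMPI``, ``molecules_dsNEB``
    and ``is_ntc``.  Negative-control rows are excluded from statistics and
    summarised separately.  Rows with a missing value in a pair are dropped
    pairwise (with a warning in the returned dict).

    Because the averaging convention behind a single summary number is not
    unique, three are reported: the mean of the per-sample ss/dsNEB ratios,
    the mean over all per-sample ratios (both comparisons pooled), and the
    ratio of group means.
    """
    df = table1.copy()
    ntc = df[df["is_ntc"]]
    df = df[~df["is_ntc"]]
    ratios = pd.DataFrame(
        {
            "sample": df["sample"],
            "ss_vs_dsNEB": df["molecules_ss"] / df["molecules_dsNEB"],
            "ss_vs_dsMPI": df["molecules_ss"] / df["molecules_dsMPI"],
        }
    )
    pooled = pd.concat([ratios["ss_vs_dsNEB"], ratios["ss_vs_dsMPI"]]).dropna()
    tests = {}
    for name, (a, b) in {
        "ss_vs_dsNEB": ("molecules_ss", "molecules_dsNEB"),
        "ss_vs_dsMPI": ("molecules_ss", "molecules_dsMPI"),
        "dsNEB_vs_dsMPI": ("molecules_dsNEB", "molecules_dsMPI"),
    }.items():
        sub = df[[a, b]].dropna()
        tests[name] = wilcoxon_exact(sub[a], sub[b])
    return {
        "ratios": ratios,
        "min_ratio": float(pooled.min()),
        "max_ratio": float(pooled.max()),
        "mean_ratio_ss_vs_dsNEB": float(ratios["ss_vs_dsNEB"].mean()),
        "mean_ratio_pooled": float(pooled.mean()),
        "ratio_of_means": float(
            df["molecules_ss"].mean()
            / df[["molecules_dsNEB", "molecules_dsMPI"]].mean().mean()
        ),
        "tests": tests,
        "n_samples": int(len(df)),
        "ntc_molecules": ntc.filter(like="molecules").to_dict(orient="list"),
        "n_dropped": int(df[["molecules_ss", "molecules_dsNEB", "molecules_dsMPI"]]
                         .isna().any(axis=1).sum()),
    }


def storage_time_regression(
    metrics: pd.DataFrame, years: Sequence[float]
) -> pd.DataFrame:
    """OLS of each damage metric on FFPE storage time, Holm-corrected.

    ``metrics``: one column per damage read-out (e.g. 5'-end C>T rate,
    3'-end C>T rate, median molecule length), one row per library.  Returns
    slope, adjusted R-squared, the raw slope p-value and the Holm-adjusted
    p-value across the metric family.
    """
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    years_arr = np.asarray(list(years), dtype=float)
    if len(years_arr) < 3:
        raise ValueError("storage_time_regression requires >= 3 points")
    if np.allclose(years_arr, years_arr[0]):
        raise ValueError("storage time is constant; slope is not identifiable")
    X = sm.add_constant(years_arr)
    rows = []
    for col in metrics.columns:
        fit = sm.OLS(metrics[col].to_numpy(dtype=float), X).fit()
        rows.append(
            {
                "metric": col,
                "slope": fit.params[1],
                "adj_r_squared": fit.rsquared_adj,
                "p_value": fit.pvalues[1],
            }
        )
    out = pd.DataFrame(rows).set_index("metric")
    out["p_holm"] = multipletests(out["p_value"].to_numpy(), method="holm")[1]
    out.attrs["correction"] = "holm"
    return out


def metrics_from_counts(
    library_id: str,
    molecules_total: float,
    reads_total: int,
    reads_mapped: int,
    reads_unique: int,
    reads_unique_mapped: int,
    median_length: float,
    assay: str = "genome",
    library_type: str = "ss",
    storage_years: float = float("nan"),
    reads_on_target: int | None = None,
    target_size_bp: float | None = None,
) -> "LibraryMetrics":
    """Assemble one accounting row, deriving mappable bp and coverage."""
    from .model import LibraryMetrics

    if target_size_bp is None:
        target_size_bp = EXOME_SIZE_BP if assay == "exome" else GENOME_SIZE_BP
    mappable = estimate_mappable_bp(
        molecules_total, reads_total, reads_unique_mapped, median_length
    )
    m = LibraryMetrics(
        library_id=library_id,
        library_type=library_type,
        assay=assay,
        molecules_total=molecules_total,
        reads_total=reads_total,
        reads_mapped=reads_mapped,
        reads_unique=reads_unique,
        reads_unique_mapped=reads_unique_mapped,
        median_length=median_length,
        storage_years=storage_years,
        mappable_bp=mappable,
        estimated_coverage=estimate_coverage(mappable, target_size_bp),
    )
    if assay == "exome" and reads_on_target is not None and reads_mapped > 0:
        m.fold_enrichment = fold_enrichment(reads_on_target, reads_mapped)
    return m


def metrics_table(table: pd.DataFrame, assay: str = "genome") -> pd.DataFrame:
    """Recompute the mappable-bp and coverage columns for a metadata table.

    ``table`` carries the count columns of the Tables 2/3-style fixtures;
    NTC rows (``is_ntc``) and rows without a median length are passed
    through with NaN in the derived columns.
    """
    unique_mapped_col = (
        "reads_on_target_unique" if assay == "exome" else "reads_unique_mapped"
    )
    target = EXOME_SIZE_BP if assay == "exome" else GENOME_SIZE_BP
    out = table.copy()
    mappable, coverage, enrichment = [], [], []
    for _, row in out.iterrows():
        if row.get("is_ntc", False) or pd.isna(row["median_length"]):
            mappable.append(np.nan)
            coverage.append(np.nan)
            enrichment.append(np.nan)
            continue
        mb = estimate_mappable_bp(
            row["molecules_total"],
            row["reads_total"],
            row[unique_mapped_col],
            row["median_length"],
        )
        mappable.append(mb)
        coverage.append(estimate_coverage(mb, target))
        if assay == "exome":
            enrichment.append(
                fold_enrichment(row["reads_on_target"], row["reads_mapped_genome"])
            )
        else:
            enrichment.append(np.nan)
    out["mappable_bp"] = mappable
    out["estimated_coverage"] = coverage
    if assay == "exome":
        out["fold_enrichment"] = enrichment
    return out
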