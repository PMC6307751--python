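"""Size distributions and statistical comparisons over colony records.

Colony size distributions are reported as normalized probability
densities (optionally averaged across replicate wells or mice with
per-bin standard deviations). Median colony sizes are compared with the
two-sided Wilcoxon rank-sum test, multi-group distributions with the
Kruskal-Wallis test, and per-well Ki-67 summary fractions with an
unpaired (Welch) t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .imgops import ParameterError


@dataclass
class SizeDistribution:
    """Normalized histogram of colony sizes (cells or px^2)."""

    sizes: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray
    n: int
    density_sd: np.ndarray | None = None  # per-bin SD across replicates

    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))


@dataclass
class ComparisonResult:
    test_name: str  # "wilcoxon_ranksum" | "kruskal_wallis" | "t_unpaired"
    statistic: float
    p_value: float
    group_ns: list[int] = field(default_factory=list)


def make_bin_edges(
    sizes: np.ndarray, n_bins: int = 20, log: bool = True
) -> np.ndarray:
    """Default binning: log-spaced edges spanning the data (colony size
    distributions are right-skewed); linear when ``log=False``."""
    sizes = np.asarray(sizes, dtype=float)
    lo, hi = float(sizes.min()), float(sizes.max())
    if hi <= lo:
        lo, hi = lo - 0.5, hi + 0.5
    if log and lo > 0:
        return np.geomspace(lo, hi, n_bins + 1)
    return np.linspace(lo, hi, n_bins + 1)


def size_pdf(
    sizes,
    bin_edges: np.ndarray | None = None,
    n_bins: int = 20,
    log: bool = True,
) -> SizeDistribution:
    """Probability density of colony sizes over the given bins.

    The density integrates to 1 for any nonempty input (values outside
    the bin range are clipped onto the edge bins so no mass is lost).
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ParameterError("size_pdf requires at least one size")
    if bin_edges is None:
        bin_edges = make_bin_edges(sizes, n_bins=n_bins, log=log)
    bin_edges = np.asarray(bin_edges, dtype=float)
    clipped = np.clip(sizes, bin_edges[0], bin_edges[-1])
    density, _ = np.histogram(clipped, bins=bin_edges, density=True)
    return SizeDistribution(sizes=sizes, bin_edges=bin_edges, density=density, n=sizes.size)


def average_pdfs(replicates: list[SizeDistribution]) -> SizeDistribution:
    """Mean density with per-bin standard deviation across replicate
    wells or mice binned on identical edges."""
    if not replicates:
        raise ParameterError("average_pdfs requires at least one replicate")
    edges = replicates[0].bin_edges
    for rep in replicates[1:]:
        if not np.array_equal(rep.bin_edges, edges):
            raise ParameterError("replicates must share bin edges")
    stack = np.vstack([rep.density for rep in replicates])
    return SizeDistribution(
        sizes=np.concatenate([rep.sizes for rep in replicates]),
        bin_edges=edges,
        density=stack.mean(axis=0),
        density_sd=stack.std(axis=0, ddof=0),
        n=int(sum(rep.n for rep in replicates)),
    )


def compare_medians(a, b) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test for a median size difference.

    Uses the exact null distribution for small groups (min n <= 8,
    no ties) and the tie-corrected normal approximation otherwise.
    The approximation omits the continuity correction so that identical
    samples report exactly z = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return ComparisonResult(
        test_name="wilcoxon_ranksum",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_ns=[int(a.size), int(b.size)],
    )


def compare_distributions(groups: list) -> ComparisonResult:
    """Kruskal-Wallis H test (tie-corrected) across >= 2 groups."""
    if len(groups) < 2:
        raise ParameterError("Kruskal-Wallis requires >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ParameterError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        # all observations tied: mean ranks are equal by construction
        return ComparisonResult(
            "kruskal_wallis", 0.0, 1.0, [int(g.size) for g in arrays]
        )
    stat, p = sps.kruskal(*arrays)
    return ComparisonResult(
        "kruskal_wallis", float(stat), float(p), [int(g.size) for g in arrays]
    )


def compare_means(a, b) -> ComparisonResult:
    """Unpaired t-test (Welch, unequal variances) on per-well summary
    values such as the fraction of high-Ki-67 colonies."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("t-test requires >= 2 values per group")
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        "t_unpaired", float(stat), float(p), [int(a.size), int(b.size)]
    )


@dataclass
class Ki67Summary:
    """Empirical cumulative frequency of per-colony Ki-67 indices and
    the fraction of colonies with index strictly above the cutoff."""

    indices: np.ndarray
    cumulative_x: np.ndarray  # sorted index values
    cumulative_y: np.ndarray  # fraction of colonies with index <= x
    fraction_above_cutoff: float
    cutoff: float

    @property
    def fraction_zero(self) -> float:
        """Fraction of completely non-proliferative colonies (index 0),
        the y-intercept of the cumulative curve."""
        return float(np.mean(self.indices == 0))


def ki67_summary(indices, cutoff: float = 0.8) -> Ki67Summary:
    """Summarize per-colony Ki-67 indices (fraction of constituent cells
    expressing Ki-67)."""
    arr = np.asarray(
        [i for i in np.atleast_1d(indices) if i is not None], dtype=float
    )
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ParameterError("no Ki-67 indices available")
    if not (0.0 <= cutoff <= 1.0):
        raise ParameterError("cutoff must lie in [0, 1]")
    x = np.sort(arr)
    y = np.arange(1, arr.size + 1) / arr.size
    return Ki67Summary(
        indices=arr,
        cumulative_x=x,
        cumulative_y=y,
        fraction_above_cutoff=float(np.mean(arr > cutoff)),
        cutoff=cutoff,
    )


def compare_ki67_fractions(per_well_a, per_well_b) -> ComparisonResult:
    """Unpaired t-test between two groups of per-well fractions of
    colonies above the Ki-67 index cutoff."""
    return compare_means(per_well_a, per_well_b)
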