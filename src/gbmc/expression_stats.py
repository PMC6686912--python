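"""Expression transforms and the comparison statistics battery.

Covers the quantitative core of a between-accession / between-genotype
expression comparison: FPKM and log10(FPKM+1) transforms, the CPM
expression filter, TMM (trimmed mean of M-values) normalization
factors, binomial coverage thinning, and the statistics used to compare
gene groups — bootstrap test on distribution means, Wilcoxon
signed-rank on ortholog pairs, Cohen's d effect size, discrete log2
fold-change classes, a 2x2 chi-square of DEG counts against group, and
printed-proportion arithmetic.

All statistics return a :class:`ComparisonResult` carrying the observed
value, p-value and (where defined) an effect size with its conventional
|d| category (negligible < 0.2 <= small < 0.5 <= medium < 0.8 <= large).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "ComparisonResult",
    "DiffClassCounts",
    "ProportionReport",
    "fpkm_from_counts",
    "log_transform",
    "cpm",
    "cpm_filter",
    "tmm_factors",
    "equalize_coverage",
    "mean_difference",
    "bootstrap_mean_diff",
    "wilcoxon_signed_rank",
    "cohens_d",
    "effect_category",
    "discrete_diff_classes",
    "clamp_differences",
    "chi_square_independence",
    "proportion_and_ratio",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class CountMatrix:
    """Raw RNA-seq counts (genes x samples) with gene lengths in bp.

    ``lib_sizes`` defaults to the column sums; pass explicit sizes to
    model mapped-library totals that include genes outside the matrix.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs a length")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = self.lib_sizes.reindex(self.counts.columns)
            if self.lib_sizes.isna().any():
                raise ValueError("every sample needs a library size")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class ExpressionMatrix:
    """FPKM values (genes x samples) with a one-shot transform tag."""

    values: pd.DataFrame
    transform: str = "raw"

    def __post_init__(self) -> None:
        if self.transform not in ("raw", "log10p1"):
            raise ValueError(f"unknown transform tag {self.transform!r}")
        if self.transform == "raw" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw FPKM values must be non-negative")


@dataclass
class ComparisonResult:
    """A named statistic with p-value, effect size and metadata."""

    statistic: str
    observed: float
    p_value: float
    n: int | None = None  # bootstrap replicates or degrees of freedom
    effect_size_d: float | None = None
    effect_category: str | None = None
    direction: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")


class DiffClassCounts(NamedTuple):
    """Counts of genes up / down / unchanged at a log2 threshold."""

    n_up: int
    n_down: int
    n_unchanged: int
    threshold: float


class ProportionReport(NamedTuple):
    """Fractions of a total, printed-style percents, and pairwise ratios."""

    fractions: list[float]
    percents: list[float]
    pairwise_ratios: dict[tuple[int, int], float]


# ---------------------------------------------------------------------------
# transforms and filters

def fpkm_from_counts(cm: CountMatrix) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM[g, s] = counts[g, s] * 1e9 / (lib_size[s] * length[g]).
    """
    if (cm.lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    fpkm = cm.counts * 1e9
    fpkm = fpkm.div(cm.lib_sizes, axis=1).div(cm.lengths, axis=0)
    return ExpressionMatrix(fpkm, "raw")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log10(FPKM + 1); refuses to transform twice."""
    if m.transform != "raw":
        raise ValueError("matrix already log-transformed")
    return ExpressionMatrix(np.log10(m.values + 1.0), "log10p1")


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million mapped reads."""
    return cm.counts.mul(1e6, axis=0).div(cm.lib_sizes, axis=1)


def cpm_filter(
    cm: CountMatrix, min_cpm: float = 1.0, min_libraries: int = 2
) -> CountMatrix:
    """Keep genes with CPM >= min_cpm in at least min_libraries samples.

    Library sizes are preserved from the unfiltered matrix, matching the
    convention that filtering does not change the sequencing depth.
    """
    if min_libraries > cm.counts.shape[1]:
        raise ValueError("min_libraries exceeds sample count")
    keep = (cpm(cm) >= min_cpm).sum(axis=1) >= min_libraries
    return CountMatrix(
        cm.counts.loc[keep], cm.lengths.loc[keep], cm.lib_sizes.copy()
    )


# ---------------------------------------------------------------------------
# TMM normalization

def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one library against the reference library.

    Log-ratios M and abundances A are computed on library-size-scaled
    proportions; genes with zero counts in either library drop out; the
    30% M-tails and 5% A-tails are doubly trimmed; the factor is
    2**(weighted mean of the surviving M values), weighted by inverse
    asymptotic binomial (delta-method) variances.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    The reference library is the sample whose upper-quartile
    library-size-scaled count is closest to the mean upper-quartile,
    unless ``ref_sample`` names one.  Factors are rescaled so their log
    mean is zero (geometric mean 1).
    """
    if cm.counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = cm.counts.to_numpy(dtype=float)
    lib = cm.lib_sizes.to_numpy(dtype=float)
    if ref_sample is None:
        f75 = np.quantile(x, 0.75, axis=0) / lib
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = int(cm.counts.columns.get_loc(ref_sample))
    ref = x[:, ref_idx]
    factors = np.array(
        [
            _tmm_pair_factor(x[:, j], ref, lib[j], lib[ref_idx])
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.counts.columns, name="tmm_factor")


def equalize_coverage(
    cm: CountMatrix, target_depth: int, seed: int
) -> CountMatrix:
    """Thin each library down to a common target depth.

    Each count is replaced by a Binomial(count, target_depth/lib_size)
    draw, which leaves per-gene expectations unbiased on the FPKM scale.
    """
    if (cm.lib_sizes < target_depth).any():
        small = cm.lib_sizes[cm.lib_sizes < target_depth].index.tolist()
        raise ValueError(f"target depth exceeds library size for {small}")
    rng = np.random.default_rng(seed)
    thinned = cm.counts.copy()
    for s in cm.counts.columns:
        p = target_depth / float(cm.lib_sizes[s])
        thinned[s] = rng.binomial(cm.counts[s].to_numpy().astype(np.int64), p)
    return CountMatrix(thinned, cm.lengths.copy())


# ---------------------------------------------------------------------------
# comparison statistics

def mean_difference(x, y, paired: bool = False) -> float:
    """mean(x - y) when paired, mean(x) - mean(y) otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired vectors must share length and order")
        return float(np.mean(x - y))
    return float(np.mean(x) - np.mean(y))


def bootstrap_mean_diff(
    x, y, n_reps: int = 1000, seed: int = 0
) -> ComparisonResult:
    """Bootstrap test on the difference of two distribution means.

    Both gene sets are independently resampled with replacement at their
    original sizes ``n_reps`` times.  The two-sided p-value is the
    fraction of centered bootstrap differences at least as extreme as
    the observed difference, with a +1/(n_reps+1) continuity adjustment
    so p is never exactly zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("bootstrap inputs must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(np.mean(x) - np.mean(y))
    bx = x[rng.integers(0, x.size, size=(n_reps, x.size))].mean(axis=1)
    by = y[rng.integers(0, y.size, size=(n_reps, y.size))].mean(axis=1)
    centered = (bx - by) - observed
    p = (1 + int(np.sum(np.abs(centered) >= abs(observed)))) / (n_reps + 1)
    return ComparisonResult(
        statistic="bootstrap_mean_diff",
        observed=observed,
        p_value=min(1.0, p),
        n=n_reps,
        direction=int(np.sign(observed)),
    )


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumeration over all sign assignments.

    Ranks are doubled to integers (mid-ranks are half-integers) and the
    null distribution of the positive rank sum is built by dynamic
    programming — a polynomial product over (1 + z**(2r)) — which is
    equivalent to enumerating all 2**n sign vectors.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        # polynomial multiply by (1 + z**r); copy so old coefficients are used
        dist[r:] += dist[:-r].copy()
    dist /= dist.sum()
    w2 = int(np.rint(2 * w_plus))
    cdf = float(dist[: w2 + 1].sum())
    sf = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(diffs, exact_max_n: int = 25) -> ComparisonResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped and ties mid-ranked.  The two-sided
    p-value is exact (sign enumeration) for n <= ``exact_max_n`` and a
    tie-corrected normal approximation above.  All-zero differences
    return a degenerate result with p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return ComparisonResult(
            statistic="wilcoxon_signed_rank",
            observed=0.0,
            p_value=1.0,
            n=0,
            extra={"degenerate": True},
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    mu = n * (n + 1) / 4.0
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        _, tie_counts = np.unique(ranks, return_counts=True)
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts ** 3 - tie_counts
        ) / 48.0
        z = (w_plus - mu) / np.sqrt(sigma2)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "normal_approx"
    return ComparisonResult(
        statistic="wilcoxon_signed_rank",
        observed=w_plus,
        p_value=p,
        n=n,
        direction=int(np.sign(w_plus - mu)),
        extra={"method": method, "degenerate": False},
    )


def effect_category(d: float) -> str:
    """Conventional |d| bins: negligible/small/medium/large at 0.2/0.5/0.8."""
    a = abs(d)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def cohens_d(x, y) -> ComparisonResult:
    """Cohen's d with the pooled sample standard deviation.

    d = (mean(x) - mean(y)) / s_pooled, with
    s_pooled^2 = ((n_x-1)s_x^2 + (n_y-1)s_y^2) / (n_x + n_y - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("Cohen's d needs at least two values per sample")
    s2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (
        nx + ny - 2
    )
    if s2 == 0:
        raise ValueError("zero pooled variance; d undefined")
    d = float((np.mean(x) - np.mean(y)) / np.sqrt(s2))
    return ComparisonResult(
        statistic="cohens_d",
        observed=d,
        p_value=1.0,
        n=nx + ny - 2,
        effect_size_d=d,
        effect_category=effect_category(d),
        direction=int(np.sign(d)),
    )


def discrete_diff_classes(
    fpkm_x, fpkm_y, threshold_log2: float = 1.0
) -> DiffClassCounts:
    """Classify paired genes by their log2 (FPKM+1) fold change.

    Delta = log2((FPKM_x + 1) / (FPKM_y + 1)); up when Delta >=
    threshold, down when Delta <= -threshold (boundary inclusive),
    unchanged otherwise.
    """
    if threshold_log2 <= 0:
        raise ValueError("threshold must be positive")
    x = np.asarray(fpkm_x, dtype=float)
    y = np.asarray(fpkm_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must share length")
    delta = np.log2((x + 1.0) / (y + 1.0))
    n_up = int(np.sum(delta >= threshold_log2))
    n_down = int(np.sum(delta <= -threshold_log2))
    return DiffClassCounts(
        n_up=n_up,
        n_down=n_down,
        n_unchanged=int(delta.size - n_up - n_down),
        threshold=float(threshold_log2),
    )


def clamp_differences(deltas, bound: float = 1.0) -> np.ndarray:
    """Clamp expression differences to [-bound, bound] for display."""
    if bound <= 0:
        raise ValueError("bound must be positive")
    return np.clip(np.asarray(deltas, dtype=float), -bound, bound)


def chi_square_independence(table) -> ComparisonResult:
    """Pearson chi-square of independence for a 2x2 table, df = 1.

    No Yates continuity correction.  Expected counts are reported in
    the result's ``extra``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, dof, expected = stats.chi2_contingency(t, correction=False)
    return ComparisonResult(
        statistic="chi_square_independence",
        observed=float(chi2),
        p_value=float(p),
        n=int(dof),
        extra={"expected": expected},
    )


def _round_half_up(x: float, places: int = 2) -> float:
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def proportion_and_ratio(part_counts: Sequence[int]) -> ProportionReport:
    """Fractions of the total, percents (2 decimals, half-up), and the
    ratio count[i]/count[j] for every ordered pair i < j."""
    counts = [int(c) for c in part_counts]
    total = sum(counts)
    if total <= 0:
        raise ValueError("total count must be positive")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    fractions = [c / total for c in counts]
    percents = [_round_half_up(100.0 * f) for f in fractions]
    ratios = {
        (i, j): counts[i] / counts[j]
        for i in range(len(counts))
        for j in range(i + 1, len(counts))
        if counts[j] > 0
    }
    return ProportionReport(fractions, percents, ratios)
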