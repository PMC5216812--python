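"""Bulk-expression cohort processing.

CPM normalization, the keratinocyte-contamination sample filter, expression-
range stratification into low/mid/high groups, a negative-binomial exact
conditional differential-expression test with a common moment-estimated
dispersion, and nonparametric rank tests for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .survival import benjamini_hochberg

__all__ = [
    "CountMatrix",
    "CPMMatrix",
    "FilterReport",
    "Stratification",
    "StratMode",
    "DEResult",
    "compute_cpm",
    "keratinocyte_contamination_filter",
    "stratify_by_expression_range",
    "nb_exact_de_test",
    "rank_group_tests",
    "DEFAULT_MARKERS",
]

#: Keratinocyte-lineage marker genes used by the contamination filter.
#: "BNC" maps to the modern symbol BNC1; override via the ``markers`` argument.
DEFAULT_MARKERS = ("IVL", "KRT14", "BNC1")


@dataclass
class CountMatrix:
    """Gene x sample matrix of nonnegative counts."""

    gene_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.counts).all() or (self.counts < 0).any():
            raise ValueError("counts must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: Sequence) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])

    def gene_row(self, gene_id) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not present in matrix") from None
        return self.counts[i]


@dataclass
class CPMMatrix:
    gene_ids: list
    sample_ids: list
    cpm: np.ndarray

    def gene_row(self, gene_id) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not present in matrix") from None
        return self.cpm[i]

    def subset_samples(self, sample_ids: Sequence) -> "CPMMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CPMMatrix(list(self.gene_ids), list(sample_ids), self.cpm[:, idx])


def compute_cpm(m: CountMatrix) -> CPMMatrix:
    """Counts-per-million: each column scaled so it sums to 1e6."""
    colsums = m.counts.sum(axis=0)
    zero = np.nonzero(colsums == 0)[0]
    if zero.size:
        bad = [m.sample_ids[i] for i in zero]
        raise ValueError(f"zero library size for sample(s): {bad}")
    return CPMMatrix(list(m.gene_ids), list(m.sample_ids), m.counts / colsums * 1e6)


@dataclass
class FilterReport:
    kept_sample_ids: list
    removed_sample_ids: list
    per_sample_marker_cpm: dict
    rule: dict


def keratinocyte_contamination_filter(
    cpm: CPMMatrix,
    markers: Sequence = DEFAULT_MARKERS,
    t_all: float = 5.0,
    t_two: float = 20.0,
) -> FilterReport:
    """Flag samples contaminated with normal skin by marker-gene CPM.

    A sample is removed iff all three marker CPMs exceed ``t_all``, or at
    least two exceed ``t_two`` (strict inequalities in both rules).
    """
    markers = tuple(markers)
    if len(markers) != 3:
        raise ValueError(f"exactly three marker genes required, got {markers}")
    missing = [g for g in markers if g not in cpm.gene_ids]
    if missing:
        raise KeyError(f"marker gene(s) missing from matrix: {missing}")
    rows = np.stack([cpm.gene_row(g) for g in markers])  # 3 x n_samples
    all_over = (rows > t_all).all(axis=0)
    two_over = (rows > t_two).sum(axis=0) >= 2
    removed = all_over | two_over
    kept_ids = [s for s, r in zip(cpm.sample_ids, removed) if not r]
    removed_ids = [s for s, r in zip(cpm.sample_ids, removed) if r]
    per_sample = {
        s: tuple(float(v) for v in rows[:, j]) for j, s in enumerate(cpm.sample_ids)
    }
    return FilterReport(
        kept_sample_ids=kept_ids,
        removed_sample_ids=removed_ids,
        per_sample_marker_cpm=per_sample,
        rule={"markers": list(markers), "t_all": t_all, "t_two": t_two},
    )


class StratMode(str, Enum):
    RANGE = "range"
    QUANTILE = "quantile"


@dataclass
class Stratification:
    gene_id: object
    low_cut: float
    high_cut: float
    mode: StratMode
    fraction: float
    group_of_sample: dict

    def samples_in(self, group: str) -> list:
        return [s for s, g in self.group_of_sample.items() if g == group]


def stratify_by_expression_range(
    cpm: CPMMatrix,
    gene_id,
    fraction: float = 0.10,
    mode: StratMode | str = StratMode.RANGE,
) -> Stratification:
    """Split samples into low/mid/high by one gene's expression.

    ``range`` mode places the cuts a fixed fraction of the value range in
    from the observed min and max; ``quantile`` mode uses the empirical
    ``fraction`` and ``1 - fraction`` quantiles. Values strictly below the
    low cut are "low", strictly above the high cut "high", boundaries "mid".
    """
    mode = StratMode(mode)
    if not 0 < fraction < 0.5:
        raise ValueError(f"fraction must lie in (0, 0.5), got {fraction}")
    values = cpm.gene_row(gene_id)
    if len(np.unique(values)) < 3:
        raise ValueError(
            f"gene {gene_id!r} has fewer than 3 distinct values; range degenerate"
        )
    if mode is StratMode.RANGE:
        lo, hi = float(values.min()), float(values.max())
        span = hi - lo
        low_cut = lo + fraction * span
        high_cut = hi - fraction * span
    else:
        low_cut = float(np.quantile(values, fraction))
        high_cut = float(np.quantile(values, 1 - fraction))
    groups = {}
    for s, v in zip(cpm.sample_ids, values):
        groups[s] = "low" if v < low_cut else ("high" if v > high_cut else "mid")
    return Stratification(gene_id, low_cut, high_cut, mode, fraction, groups)


@dataclass
class DEResult:
    gene_ids: list
    log2_fold_change: np.ndarray  # high vs low
    p_value: np.ndarray
    fdr_adjusted_p: np.ndarray
    is_overexpressed: np.ndarray
    is_underexpressed: np.ndarray
    dispersion: float
    thresholds: dict = field(default_factory=dict)

    @property
    def n_overexpressed(self) -> int:
        return int(self.is_overexpressed.sum())

    @property
    def n_underexpressed(self) -> int:
        return int(self.is_underexpressed.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "log2_fold_change": self.log2_fold_change,
                "p_value": self.p_value,
                "fdr_adjusted_p": self.fdr_adjusted_p,
                "is_overexpressed": self.is_overexpressed,
                "is_underexpressed": self.is_underexpressed,
            }
        )


def _estimate_common_dispersion(pseudo: np.ndarray, in_a: np.ndarray) -> float:
    """Method-of-moments common NB dispersion from within-group residuals.

    For NB, var = mu + phi * mu^2, so phi = (var - mu) / mu^2 per gene and
    group; the estimate pools gene/group pairs weighted by their df,
    floored at zero (Poisson).
    """
    num = 0.0
    den = 0.0
    for mask in (in_a, ~in_a):
        sub = pseudo[:, mask]
        if sub.shape[1] < 2:
            continue
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mu > 0
        w = sub.shape[1] - 1
        num += w * np.sum(var[ok] - mu[ok])
        den += w * np.sum(mu[ok] ** 2)
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def _exact_conditional_p(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact conditional test on group sums.

    Under a common per-sample NB(mu, phi) model, the group sums are NB with
    sizes n_a/phi and n_b/phi and the conditional law of S_a given
    S_a + S_b = s is free of mu. p = sum of conditional point probabilities
    <= that of the observed split. phi = 0 degenerates to
    Binomial(s, n_a/(n_a+n_b)).
    """
    s = s_a + s_b
    if s == 0:
        return 1.0
    if phi <= 0:
        logpmf = stats.binom(s, n_a / (n_a + n_b)).logpmf(np.arange(s + 1))
    else:
        ra, rb = n_a / phi, n_b / phi
        k = np.arange(s + 1, dtype=float)
        # NB convolution conditional: P(k) ∝ C(ra+k-1,k) C(rb+s-k-1,s-k)
        logpmf = (
            gammaln(ra + k)
            - gammaln(k + 1)
            + gammaln(rb + s - k)
            - gammaln(s - k + 1)
        )
        logpmf -= logsumexp(logpmf)
    obs = logpmf[s_a]
    keep = logpmf <= obs + 1e-9
    return float(min(1.0, np.exp(logsumexp(logpmf[keep]))))


def nb_exact_de_test(
    counts: CountMatrix,
    groups: Mapping,
    fdr: float = 0.005,
    min_fold: float = 2.0,
    prior_count: float = 0.5,
) -> DEResult:
    """Differential expression, high vs low, via an NB exact conditional test.

    Counts are scaled to a common library size (the geometric mean of the
    observed ones) and rounded; a single common dispersion is estimated by
    the method of moments, then each gene's group sums are compared with the
    exact conditional test. P-values are BH-adjusted and genes flagged over/
    underexpressed at |fold| >= ``min_fold`` and FDR < ``fdr``. Log2 fold
    changes use a ``prior_count`` offset on mean normalized counts.
    """
    labels = [groups[s] for s in counts.sample_ids if s in groups]
    used = [s for s in counts.sample_ids if s in groups]
    bad = set(labels) - {"high", "low"}
    if bad:
        raise ValueError(f"group labels must be 'high'/'low', got extra {bad}")
    in_a = np.array([groups[s] == "high" for s in used], dtype=bool)
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError(f"each group needs >= 2 samples (high={n_a}, low={n_b})")

    sub = counts.subset_samples(used)
    libs = sub.counts.sum(axis=0)
    if (libs == 0).any():
        raise ValueError("zero library size in DE input")
    common_lib = float(np.exp(np.mean(np.log(libs))))
    pseudo = np.rint(sub.counts / libs * common_lib)

    phi = _estimate_common_dispersion(pseudo, in_a)

    sums_a = pseudo[:, in_a].sum(axis=1).astype(int)
    sums_b = pseudo[:, ~in_a].sum(axis=1).astype(int)
    pvals = np.array(
        [
            _exact_conditional_p(int(sa), int(sb), n_a, n_b, phi)
            for sa, sb in zip(sums_a, sums_b)
        ]
    )
    mean_a = pseudo[:, in_a].mean(axis=1)
    mean_b = pseudo[:, ~in_a].mean(axis=1)
    log2fc = np.log2((mean_a + prior_count) / (mean_b + prior_count))

    adj = benjamini_hochberg(pvals)
    min_l2 = np.log2(min_fold)
    over = (log2fc > min_l2) & (adj < fdr)
    under = (log2fc < -min_l2) & (adj < fdr)
    return DEResult(
        gene_ids=list(sub.gene_ids),
        log2_fold_change=log2fc,
        p_value=pvals,
        fdr_adjusted_p=adj,
        is_overexpressed=over,
        is_underexpressed=under,
        dispersion=float(phi),
        thresholds={"fdr": fdr, "min_fold": min_fold, "prior_count": prior_count},
    )


def rank_group_tests(values: Sequence[float], labels: Sequence) -> tuple[float, float]:
    """Nonparametric group comparison.

    Two groups: two-sided Mann-Whitney U (exact when both groups have <= 8
    observations and no ties, normal approximation with tie correction
    otherwise). More than two: Kruskal-Wallis chi-square test. Returns
    (statistic, p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("rank tests require at least two groups")
    groups = [values[labels == g] for g in uniq]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if np.all(values == values[0]):
        # all observations identical: no evidence against the null
        return 0.0, 1.0
    if len(uniq) == 2:
        a, b = groups
        ties = len(np.unique(values)) < len(values)
        method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
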