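"""Survival and categorical statistics.

From-scratch implementations of the estimators the cohort pipeline reports:
the Kaplan-Meier product-limit curve, the Mantel-Haenszel log-rank test with
an observed/expected hazard-ratio estimate, Fisher's exact test on 2x2
tables by full enumeration over the hypergeometric support, Benjamini-
Hochberg step-up FDR adjustment, and the concordance summary for matched
primary/metastasis status tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaincc

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "ContingencyTable2x2",
    "km_estimate",
    "logrank_test",
    "fisher_exact_2x2",
    "benjamini_hochberg",
    "concordance_summary",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time in days, event flag (True = death), group label."""

    sample_id: str
    time_days: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_days) or self.time_days < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: time_days must be finite and >= 0, "
                f"got {self.time_days}"
            )


@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``survival_prob[i]`` is S(t) just after ``event_times[i]``; the curve is a
    right-continuous step function starting at S(0) = 1.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median_days: float | None = None

    def survival_at(self, t: float) -> float:
        """S(t) of the step function (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed_a: float
    expected_a: float
    observed_b: float
    expected_b: float
    hazard_ratio_oe: float
    group_a: str = "a"
    group_b: str = "b"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = cohorts and columns = status."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"entry {name} must be a nonnegative integer, got {v}")


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Ties are handled with the usual convention that deaths precede
    censorings occurring at the same time. The median is the smallest
    event time at which the curve drops to <= 0.5, or None if the curve
    never reaches 0.5.
    """
    if len(records) == 0:
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.time_days for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    uniq = np.unique(times[events]) if events.any() else np.array([], dtype=float)
    n = len(times)
    at_risk, n_ev, surv = [], [], []
    s = 1.0
    for t in uniq:
        r = int(np.sum(times >= t))  # deaths precede censorings at equal times
        d = int(np.sum(events & (times == t)))
        s *= 1.0 - d / r
        at_risk.append(r)
        n_ev.append(d)
        surv.append(s)

    surv_arr = np.asarray(surv, dtype=float)
    median = None
    below = np.nonzero(surv_arr <= 0.5)[0]
    if below.size:
        median = float(uniq[below[0]])
    return KMCurve(
        event_times=uniq,
        survival_prob=surv_arr,
        n_at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
        median_days=median,
    )


def _chi2_sf_1df(x: float) -> float:
    # regularized upper incomplete gamma: P(X > x) for chi-square, 1 df
    return float(gammaincc(0.5, x / 2.0))


def logrank_test(records: Sequence[SurvivalRecord]) -> LogRankResult:
    """Two-group Mantel-Haenszel log-rank test (1 df, no continuity correction).

    At each distinct event time a 2x2 table of deaths by group is formed; the
    statistic is (sum O_a - sum E_a)^2 / sum V with the hypergeometric
    variance V per table. The hazard ratio is estimated as the ratio of
    observed/expected event counts, (O_a/E_a)/(O_b/E_b).
    """
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"logrank_test requires exactly two groups, got {groups}")
    ga, gb = groups
    times = np.array([r.time_days for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    in_a = np.array([r.group == ga for r in records], dtype=bool)
    if not events.any():
        raise ValueError("log-rank undefined: no events observed")

    obs_a = obs_b = exp_a = exp_b = var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = events & (times == t)
        d_t = int(dying.sum())
        d_a = int((dying & in_a).sum())
        obs_a += d_a
        obs_b += d_t - d_a
        e_a = d_t * n_a / n_t
        exp_a += e_a
        exp_b += d_t - e_a
        if n_t > 1:
            var += d_t * (n_a / n_t) * (1 - n_a / n_t) * (n_t - d_t) / (n_t - 1)

    chi2 = (obs_a - exp_a) ** 2 / var if var > 0 else 0.0
    p = _chi2_sf_1df(chi2) if var > 0 else 1.0
    if obs_b > 0 and exp_a > 0 and exp_b > 0 and obs_a > 0:
        hr = (obs_a / exp_a) / (obs_b / exp_b)
    else:
        hr = math.inf if obs_b == 0 or exp_a == 0 else 0.0
    return LogRankResult(
        chi_square=float(chi2),
        p_value=float(p),
        observed_a=float(obs_a),
        expected_a=float(exp_a),
        observed_b=float(obs_b),
        expected_b=float(exp_b),
        hazard_ratio_oe=float(hr),
        group_a=ga,
        group_b=gb,
    )


def _log_hypergeom_pmf(k: int, row1: int, col1: int, n: int) -> float:
    # P(X = k) for X ~ Hypergeom(n, row1, col1)
    return (
        _lchoose(row1, k)
        + _lchoose(n - row1, col1 - k)
        - _lchoose(n, col1)
    )


def _lchoose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_2x2(t: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test by enumeration over the support.

    The two-sided p-value is the sum of hypergeometric point probabilities
    not exceeding that of the observed table (the dominant convention; a
    small relative tolerance absorbs floating-point noise). The odds ratio
    is the sample odds ratio ad/bc, NaN when bc = 0 and ad = 0 undefined.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    row1, col1 = a + b, a + c
    lo, hi = max(0, col1 - (c + d)), min(row1, col1)
    logp_obs = _log_hypergeom_pmf(a, row1, col1, n)
    total = 0.0
    for k in range(lo, hi + 1):
        lp = _log_hypergeom_pmf(k, row1, col1, n)
        if lp <= logp_obs + 1e-9:
            total += math.exp(lp)
    p = min(1.0, total)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return odds, p


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """BH step-up adjusted p-values, returned in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


@dataclass
class ConcordanceSummary:
    n_concordant: int
    n_total: int
    discordant_patient_ids: list = field(default_factory=list)


def concordance_summary(matched_table) -> ConcordanceSummary:
    """Count patients whose primary and metastasis statuses agree.

    ``matched_table`` is any iterable of objects/rows exposing
    ``patient_id``, ``primary_status`` and ``metastasis_status`` attributes
    or mapping keys, with statuses in {"+", "-"}.
    """
    rows = list(matched_table)
    if not rows:
        raise ValueError("empty matched table")

    def get(row, key):
        if hasattr(row, key):
            return getattr(row, key)
        return row[key]

    n_conc = 0
    discordant = []
    for row in rows:
        # U+2212 minus appears in transcribed tables; treat it as "-"
        p = str(get(row, "primary_status")).replace("−", "-")
        m = str(get(row, "metastasis_status")).replace("−", "-")
        for s in (p, m):
            if s not in {"+", "-"}:
                raise ValueError(f"malformed status symbol {s!r}")
        if p == m:
            n_conc += 1
        else:
            discordant.append(get(row, "patient_id"))
    return ConcordanceSummary(n_conc, len(rows), discordant)
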