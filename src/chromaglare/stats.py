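"""Ordinal response statistics and data-cleaning filters.

The study's inference layer for 4-point ordinal glare votes in a mixed
2 (transmittance, between) × 4 (color, within) design: the Friedman test on
within-participant blocks, Dunn's pooled-rank post-hoc test with Bonferroni
correction, Cliff's delta effect sizes, Cronbach's alpha for internal
consistency across questionnaire items, the two-sample Kolmogorov-Smirnov
test for metric comparability, RMSE/bias agreement metrics for the
image-derived photometry, and the weather-stability / sun-visibility session
filters.

All rank statistics use mid-ranks with tie-corrected variances — 4-point
ordinal data is tie-dominated, so the corrections matter. The tests are
implemented from their formulas; library implementations serve as
cross-checks in the test suite, not as the computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats as sps

__all__ = [
    "TestResult",
    "EffectSize",
    "AgreementMetrics",
    "WeatherRecord",
    "friedman_test",
    "dunn_posthoc",
    "cliffs_delta",
    "cronbach_alpha",
    "ks_two_sample",
    "agreement",
    "clean_sessions",
    "ghi_deviation",
    "DEFAULT_DELTA_THRESHOLDS",
    "RESPONSE_COLUMNS",
]

#: |δ| cuts for negligible / small / moderate / large effect labels.
DEFAULT_DELTA_THRESHOLDS = (0.147, 0.33, 0.474)

#: Fixed header of a response-table CSV (one row per participant × color).
RESPONSE_COLUMNS = [
    "participant_id", "group", "color", "presentation_order", "session_id",
    "glare_binary", "glare_ordinal", "glare_numeric", "discomfort_degree",
    "valid",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    p_adjusted: float | None = None
    groups: tuple[str, str] | None = None
    n: tuple[int, int] | None = None


@dataclass(frozen=True)
class EffectSize:
    """Cliff's delta with a threshold-based magnitude label."""

    delta: float
    magnitude: str


@dataclass(frozen=True)
class AgreementMetrics:
    rmse: float
    nrmse: float
    nbias: float


@dataclass(frozen=True)
class WeatherRecord:
    """Per-session sky record: GHI samples (W/m², 30 s cadence) and sun visibility."""

    session_id: str
    ghi_series: np.ndarray
    sun_visible: np.ndarray      # boolean flag per sample

    def __post_init__(self):
        object.__setattr__(self, "ghi_series", np.asarray(self.ghi_series, float))
        object.__setattr__(self, "sun_visible", np.asarray(self.sun_visible, bool))
        if np.any(self.ghi_series < 0):
            raise ValueError("GHI must be nonnegative")
        if self.ghi_series.shape != self.sun_visible.shape:
            raise ValueError("ghi_series and sun_visible must align")


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _tie_counts(x: np.ndarray) -> np.ndarray:
    _, counts = np.unique(x, return_counts=True)
    return counts


def friedman_test(block_matrix: np.ndarray) -> TestResult:
    """Friedman χ² test on a participants × conditions ordinal matrix.

    Blocks containing missing values are dropped listwise. Within-block
    mid-ranks; the statistic uses the tie-corrected form

        χ² = [12N/(k(k+1))·Σ(R̄_j − (k+1)/2)²] / [1 − ΣΣ(t³−t)/(Nk(k²−1))]

    with df = k − 1 and an upper-tail χ² p-value.
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 conditions")
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if n < 2:
        raise ValueError("need >= 2 complete blocks")
    ranks = np.apply_along_axis(_midranks, 1, m)
    rbar = ranks.mean(axis=0)
    stat = 12.0 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2.0) ** 2)
    ties = sum(float(np.sum(c ** 3 - c)) for c in
               (_tie_counts(row) for row in m))
    correction = 1.0 - ties / (n * k * (k * k - 1.0))
    if correction <= 0:       # every block fully tied
        return TestResult(0.0, 1.0, "friedman", df=k - 1)
    stat /= correction
    p = float(sps.chi2.sf(stat, k - 1))
    return TestResult(float(stat), p, "friedman", df=float(k - 1))


def dunn_posthoc(samples: dict[str, np.ndarray],
                 m_comparisons: int | None = None) -> list[TestResult]:
    """Dunn's pairwise z-tests on ranks pooled across all groups.

    For groups i, j with mean pooled mid-ranks R̄:

        z = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))·(1/n_i + 1/n_j)]

    Two-sided normal p-values; Bonferroni adjustment multiplies by the
    number of comparisons (default: all pairs) and caps at 1.
    """
    names = list(samples)
    arrays = [np.asarray(samples[g], dtype=float) for g in names]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = _midranks(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g, a in zip(names, arrays):
        mean_ranks[g] = float(ranks[start:start + a.size].mean())
        sizes[g] = a.size
        start += a.size
    tie_term = float(np.sum(_tie_counts(pooled) ** 3 - _tie_counts(pooled))) / (
        12.0 * (N - 1))
    var0 = N * (N + 1) / 12.0 - tie_term
    pairs = list(combinations(names, 2))
    m = m_comparisons if m_comparisons is not None else len(pairs)
    out = []
    for g1, g2 in pairs:
        se = np.sqrt(var0 * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
        out.append(TestResult(float(z), p, "dunn",
                              p_adjusted=min(1.0, m * p),
                              groups=(g1, g2), n=(sizes[g1], sizes[g2])))
    return out


def cliffs_delta(a: np.ndarray, b: np.ndarray,
                 thresholds: tuple[float, float, float] = DEFAULT_DELTA_THRESHOLDS
                 ) -> EffectSize:
    """Cliff's delta: δ = [#(a>b) − #(a<b)] / (n₁·n₂) over all pairs.

    Positive δ means ``a`` tends to exceed ``b``. The magnitude label uses
    configurable |δ| cuts (default 0.147/0.33/0.474 for
    small/moderate/large).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    # O(n log n) via counting b-values below/above each a through sorted search
    bs = np.sort(b)
    less = np.searchsorted(bs, a, side="left")        # # b < a_i
    greater = b.size - np.searchsorted(bs, a, side="right")
    delta = float((less.sum() - greater.sum()) / (a.size * b.size))
    mag = abs(delta)
    t1, t2, t3 = thresholds
    label = ("negligible" if mag < t1 else "small" if mag < t2
             else "moderate" if mag < t3 else "large")
    return EffectSize(delta, label)


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of a participants × items score matrix.

    α = k/(k−1)·(1 − Σσ²_i/σ²_total) with unbiased (n−1) variances.
    """
    m = np.asarray(items, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 participants and >= 2 items")
    k = m.shape[1]
    item_var = m.var(axis=0, ddof=1).sum()
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance: alpha undefined")
    return float(k / (k - 1.0) * (1.0 - item_var / total_var))


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test with the asymptotic p-value.

    D = sup|F₁ − F₂| over the pooled support; p from the Kolmogorov
    distribution at D·sqrt(n₁n₂/(n₁+n₂)).
    """
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    support = np.concatenate([a, b])
    f1 = np.searchsorted(a, support, side="right") / a.size
    f2 = np.searchsorted(b, support, side="right") / b.size
    d = float(np.max(np.abs(f1 - f2)))
    en = np.sqrt(a.size * b.size / (a.size + b.size))
    p = float(np.clip(special.kolmogorov(en * d), 0.0, 1.0))
    return TestResult(d, p, "ks", n=(a.size, b.size))


def agreement(test: np.ndarray, reference: np.ndarray) -> AgreementMetrics:
    """RMSE, normalized RMSE and normalized bias of test vs reference values."""
    t = np.asarray(test, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if t.shape != r.shape or t.size == 0:
        raise ValueError("inputs must be nonempty and of equal length")
    mref = r.mean()
    if mref == 0:
        raise ValueError("reference mean is zero: normalization undefined")
    rmse = float(np.sqrt(np.mean((t - r) ** 2)))
    return AgreementMetrics(rmse, rmse / mref, float((t - r).mean() / mref))


def ghi_deviation(ghi: np.ndarray) -> float:
    """Relative GHI deviation (max − min)/mean over an exposure."""
    g = np.asarray(ghi, dtype=float)
    if g.size == 0 or g.mean() == 0:
        raise ValueError("need a nonempty GHI series with nonzero mean")
    return float((g.max() - g.min()) / g.mean())


def clean_sessions(records: pd.DataFrame,
                   weather: dict[str, WeatherRecord],
                   max_ghi_deviation: float = 0.25) -> pd.DataFrame:
    """Apply the session filters: stable sky and an unobstructed sun.

    A record is valid iff its session's GHI deviation (max−min)/mean is at
    most ``max_ghi_deviation`` *and* the sun was visible for the whole
    exposure. Returns a copy with the ``valid`` flag set.
    """
    out = records.copy()
    flags = []
    for sid in out["session_id"]:
        try:
            w = weather[sid]
        except KeyError:
            raise KeyError(f"no weather record for session {sid!r}") from None
        flags.append(ghi_deviation(w.ghi_series) <= max_ghi_deviation
                     and bool(w.sun_visible.all()))
    out["valid"] = flags
    return out
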