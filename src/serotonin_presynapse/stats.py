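"""Nonparametric statistical battery for model-derived features.

The feature distributions produced by the kinetic model are strongly
non-normal (genotype classes give multimodal mixtures), so all group
comparisons are rank-based:

* Kruskal--Wallis (tie-corrected, chi-square approximation) for the
  three-group comparison (suicide attempters / non-attempters / unaffected);
* Mann--Whitney U for two-group comparisons (exact enumeration for small
  tie-free samples, normal approximation with tie correction otherwise);
* Pearson chi-square of independence (optional Yates continuity correction
  for 2x2 tables) for categorical demographics;
* two-way Aligned Rank Transform (ART) ANOVA for factorial designs with
  diagnosis and suicide-attempt status as fixed between-subjects factors.

The ART procedure: for each effect (two mains and the interaction), the
response is *aligned* — every other effect's cell-mean contribution is
subtracted so only the target effect and residual noise remain — then
mid-ranked, and a full two-factor fixed-effects ANOVA (Type-III sums of
squares, effects coding; unbalanced cells supported) is fitted to the
ranks.  Only the target effect's F and p are kept from each fit.  Post hoc
contrasts for a significant main effect are Tukey-HSD-adjusted pairwise
comparisons on that effect's aligned ranks.

Significance conventions follow common psychiatric-genetics practice:
p < 0.05 significant, 0.05--0.10 a trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TestResult",
    "ARTResult",
    "kruskal_wallis",
    "mann_whitney",
    "chi_square_independence",
    "normality_screen",
    "art_align",
    "alignment_diagnostics",
    "art_anova",
    "art_posthoc",
    "significance_label",
]

ALPHA = 0.05
TREND = 0.10


def significance_label(p: float) -> str:
    """'significant' below 0.05, 'trend' in (0.05, 0.10], else 'ns'."""
    if p < ALPHA:
        return "significant"
    if p <= TREND:
        return "trend"
    return "ns"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    method: str
    n_per_group: tuple[int, ...] = ()
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")
        if not np.isfinite(self.statistic):
            raise ValueError("non-finite statistic")


@dataclass(frozen=True)
class ARTResult:
    """Per-effect results of a two-way aligned-rank-transform ANOVA."""

    effects: Mapping[str, TestResult]
    diagnostics: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.effects) != 3:
            raise ValueError("a two-factor ART ANOVA has exactly three effects")


# ---------------------------------------------------------------------------
# classical rank tests (scipy-backed)
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal--Wallis H with a chi-square(k−1) p-value.

    Degenerate input (every value identical across all groups) returns
    H = 0, p = 1 with the degenerate flag set.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(
            statistic=0.0,
            df=len(arrays) - 1,
            p_value=1.0,
            method="kruskal-wallis",
            n_per_group=tuple(a.size for a in arrays),
            degenerate=True,
        )
    h, p = sps.kruskal(*arrays)
    return TestResult(
        statistic=float(h),
        df=len(arrays) - 1,
        p_value=float(p),
        method="kruskal-wallis",
        n_per_group=tuple(a.size for a in arrays),
    )


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 20
) -> TestResult:
    """Two-sided Mann--Whitney U (U reported for the first sample).

    Exact enumeration when both samples have at most ``exact_max_n``
    observations and no ties; otherwise the normal approximation with
    mid-rank tie correction.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    small = xa.size <= exact_max_n and ya.size <= exact_max_n
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        df=None,
        p_value=float(min(res.pvalue, 1.0)),
        method=f"mann-whitney ({method})",
        n_per_group=(xa.size, ya.size),
    )


def chi_square_independence(
    table: Sequence[Sequence[float]] | np.ndarray, yates: bool = False
) -> TestResult:
    """Pearson chi-square of independence on an r x c count table.

    Yates continuity correction is applied only when requested and the
    table is 2x2.  Tables with a zero row or column margin are rejected.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    correction = bool(yates) and counts.shape == (2, 2)
    chi2, p, dof, _ = sps.chi2_contingency(counts, correction=correction)
    return TestResult(
        statistic=float(chi2),
        df=dof,
        p_value=float(p),
        method="chi-square" + (" (yates)" if correction else ""),
    )


def normality_screen(x: Sequence[float]) -> TestResult:
    """Shapiro--Wilk screen; verdict 'non-normal' when p < 0.05."""
    arr = np.asarray(x, dtype=float)
    if not (3 <= arr.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(arr == arr[0]):
        raise ValueError("degenerate (constant) sample")
    w, p = sps.shapiro(arr)
    verdict = "non-normal" if p < ALPHA else "normal"
    return TestResult(
        statistic=float(w),
        df=None,
        p_value=float(p),
        method=f"shapiro-wilk ({verdict})",
        n_per_group=(arr.size,),
    )


# ---------------------------------------------------------------------------
# aligned rank transform ANOVA
# ---------------------------------------------------------------------------

def _check_layout(y: np.ndarray, a: np.ndarray, b: np.ndarray):
    if not (len(y) == len(a) == len(b)):
        raise ValueError("y, A and B must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite responses")
    a_levels = [str(v) for v in pd.unique(a)]
    b_levels = [str(v) for v in pd.unique(b)]
    for la in a_levels:
        for lb in b_levels:
            if not np.any((a == la) & (b == lb)):
                raise ValueError(f"empty cell ({la}, {lb}) in factorial layout")
    return a_levels, b_levels


def _cell_means(y, a, b, a_levels, b_levels):
    """Unweighted cell/marginal means (least-squares-means convention)."""
    mu = np.empty((len(a_levels), len(b_levels)))
    for i, la in enumerate(a_levels):
        for j, lb in enumerate(b_levels):
            mu[i, j] = y[(a == la) & (b == lb)].mean()
    mu_a = mu.mean(axis=1)
    mu_b = mu.mean(axis=0)
    grand = mu.mean()
    return mu, mu_a, mu_b, grand


def art_align(
    y: Sequence[float],
    a: Sequence[str],
    b: Sequence[str],
) -> dict[str, np.ndarray]:
    """Aligned responses for each effect of a two-factor layout.

    Returns a dict with keys ``"A"``, ``"B"`` and ``"A:B"``.  For each
    effect the estimated contributions of *all other* effects are removed
    from the response using unweighted cell means, leaving residual plus the
    target effect only — the standard ART construction.
    """
    ya = np.asarray(y, dtype=float)
    aa = np.asarray([str(v) for v in a])
    ba = np.asarray([str(v) for v in b])
    a_levels, b_levels = _check_layout(ya, aa, ba)
    mu, mu_a, mu_b, grand = _cell_means(ya, aa, ba, a_levels, b_levels)
    ai = np.array([a_levels.index(v) for v in aa])
    bi = np.array([b_levels.index(v) for v in ba])
    resid = ya - mu[ai, bi]
    return {
        "A": resid + (mu_a[ai] - grand),
        "B": resid + (mu_b[bi] - grand),
        "A:B": resid + (mu[ai, bi] - mu_a[ai] - mu_b[bi] + grand),
    }


def alignment_diagnostics(
    y: Sequence[float], a: Sequence[str], b: Sequence[str]
) -> dict[str, float]:
    """Residual traces of stripped effects in each aligned response.

    For each effect's aligned data, re-estimates the cell-mean decomposition
    and reports the largest absolute *stripped* component — e.g. in the
    A-aligned response, the spread of B marginal means and interaction
    terms.  On noiseless factorial data these must vanish (≲1e−10).
    """
    aa = np.asarray([str(v) for v in a])
    ba = np.asarray([str(v) for v in b])
    aligned = art_align(y, aa, ba)
    a_levels, b_levels = _check_layout(np.asarray(y, float), aa, ba)
    out: dict[str, float] = {}
    for effect, ya in aligned.items():
        mu, mu_a, mu_b, grand = _cell_means(ya, aa, ba, a_levels, b_levels)
        inter = mu - mu_a[:, None] - mu_b[None, :] + grand
        traces = {
            "A": np.max(np.abs(mu_a - grand)),
            "B": np.max(np.abs(mu_b - grand)),
            "A:B": np.max(np.abs(inter)),
        }
        stripped = [k for k in traces if k != effect]
        out[effect] = float(max(traces[k] for k in stripped))
        out[f"{effect}:grand_mean"] = float(abs(np.mean(ya - np.mean(ya))))
    return out


def _effects_design(ai, bi, n_a, n_b):
    """Sum-to-zero (effects) coded design matrix with intercept.

    Column blocks: intercept | A (n_a−1) | B (n_b−1) | A:B ((n_a−1)(n_b−1)).
    Returns the matrix and the column slices per effect.
    """
    n = len(ai)
    a_cols = np.zeros((n, n_a - 1))
    for k in range(n_a - 1):
        a_cols[:, k] = np.where(ai == k, 1.0, np.where(ai == n_a - 1, -1.0, 0.0))
    b_cols = np.zeros((n, n_b - 1))
    for k in range(n_b - 1):
        b_cols[:, k] = np.where(bi == k, 1.0, np.where(bi == n_b - 1, -1.0, 0.0))
    ab_cols = np.empty((n, (n_a - 1) * (n_b - 1)))
    idx = 0
    for ka in range(n_a - 1):
        for kb in range(n_b - 1):
            ab_cols[:, idx] = a_cols[:, ka] * b_cols[:, kb]
            idx += 1
    X = np.column_stack([np.ones(n), a_cols, b_cols, ab_cols])
    slices = {
        "A": slice(1, n_a),
        "B": slice(n_a, n_a + n_b - 1),
        "A:B": slice(n_a + n_b - 1, X.shape[1]),
    }
    return X, slices


def _type3_f(ranks: np.ndarray, X: np.ndarray, cols: slice, df_resid: int):
    """Type-III F for one effect via full-vs-reduced OLS comparison."""
    full = sm.OLS(ranks, X).fit()
    keep = np.ones(X.shape[1], dtype=bool)
    keep[cols] = False
    reduced = sm.OLS(ranks, X[:, keep]).fit()
    q = cols.stop - cols.start
    ss_effect = reduced.ssr - full.ssr
    if full.ssr <= 1e-12 * max(1.0, float(np.var(ranks)) * len(ranks)):
        if ss_effect <= 1e-10:
            return 0.0, 1.0, True  # all-tied ranks: no information
        return float("inf"), 0.0, False
    f = (ss_effect / q) / (full.ssr / df_resid)
    f = max(f, 0.0)
    p = float(sps.f.sf(f, q, df_resid))
    return float(f), p, False


def art_anova(
    y: Sequence[float],
    a: Sequence[str],
    b: Sequence[str],
    a_name: str = "A",
    b_name: str = "B",
) -> ARTResult:
    """Two-way ART ANOVA with fixed between-subjects factors.

    For each effect the aligned response is mid-ranked and the full
    two-factor ANOVA (Type-III, effects coding) is fitted to the ranks;
    only the target effect's F, df and p are reported.
    """
    ya = np.asarray(y, dtype=float)
    aa = np.asarray([str(v) for v in a])
    ba = np.asarray([str(v) for v in b])
    a_levels, b_levels = _check_layout(ya, aa, ba)
    n_a, n_b = len(a_levels), len(b_levels)
    n = len(ya)
    df_resid = n - n_a * n_b
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    ai = np.array([a_levels.index(v) for v in aa])
    bi = np.array([b_levels.index(v) for v in ba])
    X, slices = _effects_design(ai, bi, n_a, n_b)
    aligned = art_align(ya, aa, ba)
    name_map = {"A": a_name, "B": b_name, "A:B": f"{a_name}:{b_name}"}
    df_map = {"A": n_a - 1, "B": n_b - 1, "A:B": (n_a - 1) * (n_b - 1)}
    effects: dict[str, TestResult] = {}
    for effect, y_eff in aligned.items():
        ranks = sps.rankdata(y_eff)
        f, p, degenerate = _type3_f(ranks, X, slices[effect], df_resid)
        effects[name_map[effect]] = TestResult(
            statistic=f,
            df=(df_map[effect], df_resid),
            p_value=p,
            method="art-anova (type III)",
            degenerate=degenerate,
        )
    diag = alignment_diagnostics(ya, aa, ba)
    return ARTResult(effects=effects, diagnostics=diag)


def art_posthoc(
    y: Sequence[float],
    a: Sequence[str],
    b: Sequence[str],
    factor: str = "A",
) -> pd.DataFrame:
    """Tukey-HSD pairwise contrasts on a main effect's aligned ranks.

    Returns one row per level pair with the rank-mean difference, adjusted
    p-value and direction ('lower'/'higher' for the first-named level).
    """
    if factor not in ("A", "B"):
        raise ValueError("factor must be 'A' or 'B'")
    aa = np.asarray([str(v) for v in a])
    ba = np.asarray([str(v) for v in b])
    labels = aa if factor == "A" else ba
    if np.unique(labels).size < 2:
        raise ValueError("post hoc needs a factor with at least two levels")
    aligned = art_align(y, aa, ba)[factor]
    ranks = sps.rankdata(aligned)
    tukey = pairwise_tukeyhsd(ranks, labels, alpha=ALPHA)
    frame = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    frame = frame.rename(
        columns={"p-adj": "p_adj", "meandiff": "rank_mean_diff"}
    )[["group1", "group2", "rank_mean_diff", "p_adj", "reject"]]
    frame["rank_mean_diff"] = frame["rank_mean_diff"].astype(float)
    frame["p_adj"] = frame["p_adj"].astype(float)
    frame["direction"] = np.where(
        frame["rank_mean_diff"] > 0, "group1 lower", "group1 higher"
    )
    return frame
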