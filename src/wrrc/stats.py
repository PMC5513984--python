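"""Nonparametric analysis pipeline for the nine score measures.

Mirrors the original analysis plan: a skew/kurtosis z-score normality
screen (+/-1.96), Friedman omnibus tests across the three conditions (on
totals, then first- and second-syllable scores), pairwise post-hocs under
Bonferroni-adjusted alphas (0.05/3 -> 0.017, 0.01/3 -> 0.003), Mann-Whitney
sex contrasts on all nine measures, and Spearman correlations between
condition scores with shared-variance percentages.

The post-hoc default applies a between-group rank test to the within-subject
condition scores, reproducing the original choice; a within-subject Wilcoxon
signed-rank alternative is available via ``method="wilcoxon"``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import fftconvolve

__all__ = [
    "TestResult",
    "PosthocRow",
    "CorrelationResult",
    "AnalysisReport",
    "normality_screen",
    "friedman",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "pairwise_posthoc",
    "spearman_with_shared_variance",
    "shared_variance_pct",
    "bonferroni_alpha",
    "run_full_analysis",
]

MEASURES = ["RH", "RH1", "RH2", "NR", "NR1", "NR2", "UnSc", "UnSc1", "UnSc2"]
FAMILIES = {
    "total": ["RH", "NR", "UnSc"],
    "syllable1": ["RH1", "NR1", "UnSc1"],
    "syllable2": ["RH2", "NR2", "UnSc2"],
}
EXACT_MAX_N = 8  # exact enumeration below/at this per-sample size


@dataclass
class TestResult:
    name: str
    statistic: float
    df: int | None
    p: float
    alpha: float
    significant: bool
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class PosthocRow:
    pair: tuple[str, str]
    statistic: float
    p: float
    alpha_adjusted: float
    significant: bool
    method: str


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    r_s: float
    p: float
    shared_pct: float
    unexplained_pct: float
    alpha: float
    significant: bool


@dataclass
class AnalysisReport:
    normality: dict = field(default_factory=dict)
    omnibus: list = field(default_factory=list)
    posthoc: dict = field(default_factory=dict)
    sex_contrasts: list = field(default_factory=list)
    correlations: list = field(default_factory=list)
    correlation_followups: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "normality": self.normality,
            "omnibus": [asdict(t) for t in self.omnibus],
            "posthoc": {k: [asdict(r) for r in v] for k, v in self.posthoc.items()},
            "sex_contrasts": [asdict(t) for t in self.sex_contrasts],
            "correlations": [asdict(c) for c in self.correlations],
            "correlation_followups": [asdict(c) for c in self.correlation_followups],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = ["Normality screen (z in +/-1.96):"]
        for m, d in self.normality.items():
            lines.append(
                f"  {m:6s} z_skew={d['z_skew']:+6.2f} z_kurt={d['z_kurt']:+6.2f} "
                f"normal={d['normal']}"
            )
        lines.append("Omnibus (Friedman, df=2):")
        for t in self.omnibus:
            lines.append(f"  {t.name:10s} chi2={t.statistic:7.3f} p={t.p:.3f} sig={t.significant}")
        for fam, rows in self.posthoc.items():
            lines.append(f"Post-hoc [{fam}] (alpha {rows[0].alpha_adjusted}):")
            for r in rows:
                lines.append(
                    f"  {r.pair[0]:6s} vs {r.pair[1]:6s} stat={r.statistic:8.2f} "
                    f"p={r.p:.3f} sig={r.significant}"
                )
        lines.append("Sex contrasts (Mann-Whitney):")
        for t in self.sex_contrasts:
            lines.append(f"  {t.name:6s} U={t.statistic:7.1f} p={t.p:.3f} sig={t.significant}")
        lines.append("Correlations (Spearman):")
        for c in self.correlations + self.correlation_followups:
            lines.append(
                f"  {c.pair[0]:6s} vs {c.pair[1]:6s} r_s={c.r_s:+.3f} p={c.p:.3f} "
                f"shared={c.shared_pct:.1f}% sig={c.significant}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# individual tests


def normality_screen(x) -> tuple[float, float, bool]:
    """Skewness and excess-kurtosis z-values; normal iff both in (-1.96, 1.96).

    Uses the adjusted Fisher-Pearson skewness with its small-sample standard
    error sqrt(6n(n-1)/((n-2)(n+1)(n+3))), and the matching excess-kurtosis
    standard error 2*SE_skew*sqrt((n^2-1)/((n-3)(n+5))).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("normality screen requires n >= 8")
    if np.all(x == x[0]):  # constant sample: moments undefined, treat as unremarkable
        return 0.0, 0.0, True
    g1 = sps.skew(x, bias=False)
    g2 = sps.kurtosis(x, fisher=True, bias=False)
    se_skew = np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    se_kurt = 2.0 * se_skew * np.sqrt((n**2 - 1) / ((n - 3) * (n + 5)))
    z_skew = float(g1 / se_skew)
    z_kurt = float(g2 / se_kurt)
    normal = abs(z_skew) < 1.96 and abs(z_kurt) < 1.96
    return z_skew, z_kurt, normal


def _friedman_exact_p(ranks: np.ndarray, observed_ss: float) -> float:
    """Exact permutation p for k = 3: P(sum of squared column rank-sums >=
    observed) over all within-row orderings, by dynamic programming.

    Each row contributes one of the 6 permutations of its (mid-)rank triple;
    the joint distribution of the first two column sums is convolved row by
    row (ranks doubled to keep half-integers integral).
    """
    n = ranks.shape[0]
    size = 6 * n + 1  # doubled ranks sum to at most 6 per row entry
    dist = np.zeros((size, size))
    dist[0, 0] = 1.0
    for row in ranks:
        r = np.round(2 * row).astype(int)
        step = np.zeros((7, 7))
        for perm in itertools.permutations(range(3)):
            step[r[perm[0]], r[perm[1]]] += 1.0
        dist = fftconvolve(dist, step)[:size, :size]
    total_2 = int(np.round(2 * ranks.sum()))  # doubled grand total
    s1, s2 = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    s3 = total_2 - s1 - s2
    ss = (s1**2 + s2**2 + s3**2) / 4.0  # undo doubling
    mask = (dist > 1e-12) & (ss >= observed_ss - 1e-9)
    return float(dist[mask].sum() / dist[dist > 1e-12].sum())


def friedman(scores, alpha: float = 0.05, name: str = "friedman") -> TestResult:
    """Friedman chi-square (mid-ranks, standard tie correction).

    The p-value is the asymptotic chi-square tail (df = k - 1) for n > 8
    subjects; for n <= 8 with k = 3 conditions it is the exact permutation
    probability over all within-row orderings."""
    m = np.asarray(scores, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 3:
        raise ValueError("need an n x k matrix with n >= 2 subjects, k >= 3 conditions")
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    c = 1.0 - tie_term / (n * k * (k**2 - 1))
    if c <= 0:  # every row fully tied
        stat, p, method = 0.0, 1.0, "degenerate (all rows tied)"
    elif n <= EXACT_MAX_N and k == 3:
        stat = chi / c
        p = _friedman_exact_p(ranks, float(np.sum(col_sums**2)))
        method = "friedman chi-square (tie-corrected, exact permutation)"
    else:
        stat = chi / c
        p = float(sps.chi2.sf(stat, k - 1))
        method = "friedman chi-square (tie-corrected, asymptotic)"
    return TestResult(
        name=name,
        statistic=float(stat),
        df=k - 1,
        p=p,
        alpha=alpha,
        significant=p < alpha,
        method=method,
    )


def _mw_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of the first sample from pooled mid-ranks."""
    n1 = a.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney(a, b, alpha: float = 0.05, name: str = "mann-whitney") -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact (full enumeration of group labelings over pooled mid-ranks, with
    the symmetric rejection region |U - n1 n2 / 2|) when both samples have
    at most 8 observations; otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    u_obs = _mw_u(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # fully tied: no evidence either way
        return TestResult(name, u_obs, None, 1.0, alpha, False, "degenerate (all tied)")
    if max(n1, n2) <= EXACT_MAX_N:
        ranks = sps.rankdata(np.concatenate([a, b]))
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu)
        total = 0
        extreme = 0
        base = n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - base
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                extreme += 1
        p = extreme / total
        method = "exact enumeration (mid-ranks)"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "tie-corrected normal approximation"
    return TestResult(
        name=name,
        statistic=u_obs,
        df=None,
        p=min(p, 1.0),
        alpha=alpha,
        significant=p < alpha,
        method=method,
    )


def wilcoxon_signed_rank(a, b, alpha: float = 0.05, name: str = "wilcoxon") -> TestResult:
    """Within-subject alternative for paired condition scores."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.all(a == b):
        return TestResult(name, 0.0, None, 1.0, alpha, False, "wilcoxon signed-rank")
    res = sps.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox")
    return TestResult(
        name=name,
        statistic=float(res.statistic),
        df=None,
        p=float(res.pvalue),
        alpha=alpha,
        significant=res.pvalue < alpha,
        method="wilcoxon signed-rank",
    )


def bonferroni_alpha(nominal_alpha: float, n_comparisons: int = 3) -> float:
    """Adjusted alpha, rounded to three decimals (0.05 -> 0.017, 0.01 -> 0.003)."""
    return round(nominal_alpha / n_comparisons, 3)


def pairwise_posthoc(
    scores,
    labels: list[str],
    nominal_alpha: float = 0.05,
    method: str = "mannwhitney",
) -> list[PosthocRow]:
    """All three pairwise comparisons, each flagged against the
    Bonferroni-adjusted alpha.

    ``method="mannwhitney"`` (default) reproduces the original between-group
    treatment of within-subject scores; ``method="wilcoxon"`` is the paired
    alternative.
    """
    m = np.asarray(scores, dtype=float)
    if m.shape[1] != len(labels):
        raise ValueError("labels must match the number of columns")
    alpha_adj = bonferroni_alpha(nominal_alpha, 3)
    test = mann_whitney if method == "mannwhitney" else wilcoxon_signed_rank
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        t = test(m[:, i], m[:, j], alpha=alpha_adj)
        rows.append(
            PosthocRow(
                pair=(labels[i], labels[j]),
                statistic=t.statistic,
                p=t.p,
                alpha_adjusted=alpha_adj,
                significant=t.p < alpha_adj,
                method=t.method,
            )
        )
    return rows


def shared_variance_pct(r_s: float) -> float:
    """Shared variance in percent, 100 * r_s^2, reported to one decimal
    (r_s = 0.438 -> 19.2)."""
    return round(100.0 * r_s**2, 1)


def spearman_with_shared_variance(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """Spearman rho (mid-ranks) with shared variance = 100 * rho^2 (1 dp).

    The p-value is exact (full permutation enumeration) for n <= 8, else
    scipy's asymptotic approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need equal-length samples with n >= 5")
    if np.all(x == x[0]) or np.all(y == y[0]):  # constant input: no evidence
        return 0.0, 1.0, 0.0
    rho, p = sps.spearmanr(x, y)
    if x.size <= EXACT_MAX_N:
        # exact permutation p: enumerate all orderings of one variable
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rx = (rx - rx.mean()) / np.sqrt(np.sum((rx - rx.mean()) ** 2))
        ry = (ry - ry.mean()) / np.sqrt(np.sum((ry - ry.mean()) ** 2))
        perms = np.array(list(itertools.permutations(range(x.size))))
        rhos = ry[perms] @ rx
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-9))
    return float(rho), float(p), shared_variance_pct(float(rho))


# ---------------------------------------------------------------------------
# full report


def _correlation(df: pd.DataFrame, a: str, b: str, alpha: float) -> CorrelationResult:
    r, p, shared = spearman_with_shared_variance(df[a], df[b])
    return CorrelationResult(
        pair=(a, b),
        r_s=r,
        p=p,
        shared_pct=shared,
        unexplained_pct=round(100.0 - shared, 1),
        alpha=alpha,
        significant=p < alpha,
    )


def run_full_analysis(
    scores: pd.DataFrame,
    nominal_alpha: float = 0.05,
    posthoc_method: str = "mannwhitney",
) -> AnalysisReport:
    """Execute the whole analysis on an 11-column score table.

    Order: normality screen on all nine measures; Friedman omnibus per
    measure family (totals, first syllables, second syllables); pairwise
    post-hocs (Bonferroni alpha 0.017) for omnibus tests significant at
    the nominal level; Mann-Whitney sex contrasts on all nine measures;
    Spearman correlations between the three total scores (alpha 0.017) with
    syllable-level follow-ups for any nominally significant total pair.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 listeners")
    missing = [m for m in MEASURES if m not in scores.columns]
    if missing:
        raise ValueError(f"score table lacks columns: {missing}")
    report = AnalysisReport()

    for m in MEASURES:
        z_s, z_k, ok = normality_screen(scores[m])
        report.normality[m] = {"z_skew": z_s, "z_kurt": z_k, "normal": ok}

    corr_alpha = bonferroni_alpha(nominal_alpha, 3)
    for fam, cols in FAMILIES.items():
        matrix = scores[cols].to_numpy(dtype=float)
        omni = friedman(matrix, alpha=nominal_alpha, name=fam)
        report.omnibus.append(omni)
        if omni.significant:
            report.posthoc[fam] = pairwise_posthoc(
                matrix, cols, nominal_alpha=nominal_alpha, method=posthoc_method
            )

    males = scores[scores["sex"] == "male"]
    females = scores[scores["sex"] == "female"]
    if len(males) > 0 and len(females) > 0:
        for m in MEASURES:
            t = mann_whitney(males[m], females[m], alpha=nominal_alpha, name=m)
            report.sex_contrasts.append(t)

    total_pairs = [("RH", "NR"), ("RH", "UnSc"), ("NR", "UnSc")]
    for a, b in total_pairs:
        c = _correlation(scores, a, b, corr_alpha)
        report.correlations.append(c)
        if c.p < nominal_alpha:
            for s in ("1", "2"):
                report.correlation_followups.append(
                    _correlation(scores, a + s, b + s, corr_alpha)
                )
    return report
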