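"""Within-subjects inference: repeated-measures ANOVA and friends.

Implements one-way and fully-crossed two-way repeated-measures ANOVA by
explicit sum-of-squares decomposition, Greenhouse-Geisser (GG) epsilon from
the double-centered condition covariance, Mauchly's sphericity test on the
orthonormal-contrast covariance, Bonferroni-corrected paired t contrasts,
and partial eta squared effect sizes. p-values come from the F and t
distributions (scipy's incomplete-beta evaluations); everything else is
computed here.

Each effect is tested against its own subject-by-effect interaction error
term. Both uncorrected and GG-corrected results are always reported; the
``use_gg`` flag marks which one a conventional report would quote, by the
rule "apply GG when Mauchly's test rejects sphericity at 0.05".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.linalg import helmert

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "gg_epsilon",
    "mauchly_test",
    "partial_eta_squared",
    "bonferroni_pairwise",
    "screen_participants",
    "complete_cases_matrix",
]


@dataclass
class AnovaResult:
    """One tested effect of a repeated-measures ANOVA."""

    effect: str
    ss_effect: float
    ss_error: float
    df1: int
    df2: int
    F: float
    epsilon_gg: float
    df1_corr: float
    df2_corr: float
    p_uncorrected: float
    p_gg: float
    partial_eta_sq: float
    mauchly_w: float = float("nan")
    mauchly_p: float = float("nan")
    use_gg: bool = False
    note: str = ""

    @property
    def p_reported(self) -> float:
        return self.p_gg if self.use_gg else self.p_uncorrected

    def format(self) -> str:
        """Journal-style one-liner, e.g. ``F(2,68) = 8.25, p = 0.001, ηp² = 0.20``."""
        if self.use_gg:
            d1, d2 = f"{self.df1_corr:.2f}", f"{self.df2_corr:.2f}"
        else:
            d1, d2 = f"{self.df1:d}", f"{self.df2:d}"
        p = self.p_reported
        p_str = "p < 0.001" if p < 0.001 else f"p = {p:.3f}"
        return (
            f"F({d1},{d2}) = {self.F:.2f}, {p_str}, "
            f"ηp² = {self.partial_eta_sq:.2f}"
        )


@dataclass
class PairwiseResult:
    """One Bonferroni-corrected paired contrast."""

    pair: tuple[str, str]
    mean_diff: float
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    m: int
    note: str = ""


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Effect size ηp² = F·df1 / (F·df1 + df2) = SS_effect/(SS_effect+SS_error)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    return F * df1 / (F * df1 + df2)


def _as_matrix(values) -> np.ndarray:
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("expected a subject x condition matrix")
    if not np.all(np.isfinite(y)):
        raise ValueError("matrix contains missing/non-finite cells; drop incomplete subjects first")
    return y


def gg_epsilon(values) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance.

    For a subject x k matrix, epsilon = (tr S~)² / ((k-1) * sum(S~²)) where
    S~ is the doubly-centered sample covariance of the k conditions. Bounded
    in [1/(k-1), 1]; equals 1 under compound symmetry, and is identically 1
    for k=2 (a single contrast cannot violate sphericity).
    """
    y = _as_matrix(values)
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if k == 2:
        return 1.0
    s = np.cov(y, rowvar=False)
    st = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    denom = (k - 1) * np.sum(st**2)
    if denom <= 0:
        return 1.0
    eps = np.trace(st) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_test(values) -> tuple[float, float, int, float]:
    """Mauchly's sphericity test on the orthonormal-contrast covariance.

    Returns (W, chi2, df, p). W = det(M) / (tr(M)/(k-1))^(k-1) with
    M = C S C' for orthonormal contrasts C (Helmert) and sample covariance S;
    the chi-square uses the standard small-sample factor. For k=2 the test is
    degenerate (df=0): W=1, p=1.
    """
    y = _as_matrix(values)
    n, k = y.shape
    d = k - 1
    if d < 1:
        raise ValueError("need at least 2 conditions")
    df = d * (d + 1) // 2 - 1
    if df <= 0:
        return 1.0, 0.0, 0, 1.0
    if n <= d:
        raise ValueError(
            "contrast covariance is singular (n <= k-1); Mauchly's test is "
            "unavailable -- consider applying the GG correction always"
        )
    c = helmert(k, full=False)  # (k-1, k), orthonormal rows
    m = c @ np.cov(y, rowvar=False) @ c.T
    det = np.linalg.det(m)
    tr = np.trace(m)
    if det <= 0 or tr <= 0:
        raise ValueError(
            "contrast covariance is numerically singular; Mauchly's test is "
            "unavailable -- consider applying the GG correction always"
        )
    w = det / (tr / d) ** d
    corr = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * corr * math.log(w)
    # two-term asymptotic expansion of the null distribution (standard in
    # ezANOVA/SPSS-style implementations)
    w2 = (
        (d + 2.0) * (d - 1.0) * (d - 2.0) * (2.0 * d**3 + 6.0 * d**2 + 3.0 * k + 2.0)
        / (288.0 * ((n - 1) * d * corr) ** 2)
    )
    p1 = float(sstats.chi2.sf(chi2, df))
    p2 = float(sstats.chi2.sf(chi2, df + 4))
    p = p1 + w2 * (p2 - p1)
    return float(w), float(chi2), int(df), float(p)


def _finish(effect: str, ss_eff: float, ss_err: float, df1: int, df2: int,
            eps: float, mw: float, mp: float, alpha_gg: float) -> AnovaResult:
    note = ""
    if ss_err <= 1e-12 * max(ss_eff, 1.0):
        # perfectly additive data: F unbounded, p at its exact limit
        F = float("inf")
        p_unc = p_gg = 0.0
        eta = 1.0
        note = "zero error sum of squares; F reported as infinite limit"
    else:
        F = (ss_eff / df1) / (ss_err / df2)
        p_unc = float(sstats.f.sf(F, df1, df2))
        p_gg = float(sstats.f.sf(F, eps * df1, eps * df2))
        eta = ss_eff / (ss_eff + ss_err)
    use_gg = bool(np.isfinite(mp) and mp <= alpha_gg)
    return AnovaResult(
        effect=effect, ss_effect=float(ss_eff), ss_error=float(ss_err),
        df1=int(df1), df2=int(df2), F=F, epsilon_gg=float(eps),
        df1_corr=float(eps * df1), df2_corr=float(eps * df2),
        p_uncorrected=p_unc, p_gg=p_gg, partial_eta_sq=float(eta),
        mauchly_w=mw, mauchly_p=mp, use_gg=use_gg, note=note,
    )


def rm_anova_oneway(values, effect: str = "condition",
                    alpha_gg: float = 0.05) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subject x k matrix.

    Decomposes SS_total = SS_subjects + SS_condition + SS_error and tests
    MS_condition / MS_error on (k-1, (k-1)(n-1)) degrees of freedom, with the
    GG-corrected version alongside.
    """
    y = _as_matrix(values)
    n, k = y.shape
    if n <= 1:
        raise ValueError("need at least 2 subjects")
    if k < 2:
        raise ValueError("need at least 2 conditions")
    grand = y.mean()
    ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_cond = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_cond
    df1, df2 = k - 1, (k - 1) * (n - 1)
    eps = gg_epsilon(y)
    try:
        mw, _, mdf, mp = mauchly_test(y)
        if mdf == 0:
            mp = float("nan")
    except ValueError:
        mw, mp = float("nan"), float("nan")
    return _finish(effect, ss_cond, ss_err, df1, df2, eps, mw, mp, alpha_gg)


def rm_anova_twoway(values, a_levels: int, b_levels: int,
                    effect_names: tuple[str, str] = ("A", "B"),
                    alpha_gg: float = 0.05) -> dict[str, AnovaResult]:
    """Two-way fully-crossed repeated-measures ANOVA.

    ``values`` is subject x (a*b) with cells ordered B-fastest (all b levels
    of the first a level, then the next), or a 3-D subject x a x b array.
    Each effect (A, B, A x B) is tested against its own subject-interaction
    error term; GG epsilon comes from the matching contrast covariance
    (marginal means for main effects, Kronecker-Helmert contrasts for the
    interaction).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim == 2:
        if y.shape[1] != a_levels * b_levels:
            raise ValueError(
                f"expected {a_levels * b_levels} cells per subject, got {y.shape[1]}"
            )
        y = y.reshape(y.shape[0], a_levels, b_levels)
    elif y.ndim != 3 or y.shape[1:] != (a_levels, b_levels):
        raise ValueError("values must be subject x a x b (or flattened cells)")
    if not np.all(np.isfinite(y)):
        raise ValueError("incomplete crossing: missing cells; drop incomplete subjects first")
    n, a, b = y.shape
    if n <= 1:
        raise ValueError("need at least 2 subjects")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_abs = ss_total - ss_s - ss_a - ss_b - ss_ab - ss_as - ss_bs

    name_a, name_b = effect_names
    out: dict[str, AnovaResult] = {}

    def _mauchly_or_nan(mat):
        try:
            mw, _, mdf, mp = mauchly_test(mat)
            return (mw, float("nan")) if mdf == 0 else (mw, mp)
        except ValueError:
            return float("nan"), float("nan")

    mw, mp = _mauchly_or_nan(m_sa)
    out[name_a] = _finish(name_a, ss_a, ss_as, a - 1, (a - 1) * (n - 1),
                          gg_epsilon(m_sa), mw, mp, alpha_gg)
    mw, mp = _mauchly_or_nan(m_sb)
    out[name_b] = _finish(name_b, ss_b, ss_bs, b - 1, (b - 1) * (n - 1),
                          gg_epsilon(m_sb), mw, mp, alpha_gg)

    # interaction epsilon from Kronecker-Helmert contrasts on the cells
    cells = y.reshape(n, a * b)
    c_int = np.kron(helmert(a, full=False), helmert(b, full=False))
    d_int = (a - 1) * (b - 1)
    m_int = c_int @ np.cov(cells, rowvar=False) @ c_int.T
    denom = d_int * np.sum(m_int**2)
    eps_int = 1.0 if denom <= 0 else float(
        np.clip(np.trace(m_int) ** 2 / denom, 1.0 / d_int, 1.0)
    )
    # Mauchly for the interaction works on the contrast covariance directly
    mw, mp = float("nan"), float("nan")
    if n > d_int:
        det = np.linalg.det(m_int)
        tr = np.trace(m_int)
        if det > 0 and tr > 0:
            w = det / (tr / d_int) ** d_int
            dfm = d_int * (d_int + 1) // 2 - 1
            if dfm > 0:
                corr = 1.0 - (2.0 * d_int**2 + d_int + 2.0) / (6.0 * d_int * (n - 1))
                chi2 = -(n - 1) * corr * math.log(w)
                mw, mp = float(w), float(sstats.chi2.sf(chi2, dfm))
    inter = f"{name_a} x {name_b}"
    out[inter] = _finish(inter, ss_ab, ss_abs, d_int, d_int * (n - 1),
                         eps_int, mw, mp, alpha_gg)
    return out


def bonferroni_pairwise(values, labels: list[str] | None = None) -> list[PairwiseResult]:
    """All-pairs paired t-tests with Bonferroni correction.

    For k conditions there are m = k(k-1)/2 comparisons and each raw p-value
    is multiplied by m (capped at 1). A zero-variance difference yields p=1
    when the mean difference is 0 and is flagged otherwise.
    """
    y = _as_matrix(values)
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if labels is None:
        labels = [f"level{i + 1}" for i in range(k)]
    m = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            d = y[:, i] - y[:, j]
            md = float(d.mean())
            sd = float(d.std(ddof=1))
            note = ""
            if sd == 0.0:
                if md == 0.0:
                    t, p = 0.0, 1.0
                else:
                    t = math.copysign(float("inf"), md)
                    p = 0.0
                    note = "zero-variance difference with nonzero mean"
            else:
                t = md / (sd / math.sqrt(n))
                p = float(2.0 * sstats.t.sf(abs(t), n - 1))
            out.append(
                PairwiseResult(
                    pair=(labels[i], labels[j]), mean_diff=md, t=float(t),
                    df=n - 1, p_raw=p, p_bonferroni=min(1.0, m * p), m=m,
                    note=note,
                )
            )
    return out


def screen_participants(sss_scores) -> np.ndarray:
    """Inclusion mask from Stanford Sleepiness Scale scores (1-7).

    A score greater than 3 indicates low pre-task alertness and excludes the
    participant; a score of exactly 3 is still included.
    """
    scores = np.asarray(sss_scores)
    if scores.size and (np.any(scores < 1) or np.any(scores > 7)
                        or not np.all(scores == np.round(scores))):
        raise ValueError("sleepiness scores must be integers in 1..7")
    return scores <= 3


def complete_cases_matrix(
    table: pd.DataFrame, value: str, subject: str = "subject",
    factors: list[str] | None = None, levels: dict[str, list] | None = None,
) -> tuple[np.ndarray, list, pd.MultiIndex | pd.Index, int]:
    """Pivot a long table to subject x cells, dropping incomplete subjects.

    Returns (values matrix, kept subject ids, cell index, n_dropped). Cell
    order follows ``levels`` when given (dict factor -> ordered level list),
    otherwise first appearance. Subjects missing any cell are listwise
    dropped and counted.
    """
    factors = factors or ["condition"]
    piv = table.pivot_table(index=subject, columns=factors, values=value,
                            aggfunc="mean", sort=False)
    if levels:
        if len(factors) == 1:
            piv = piv.reindex(columns=levels[factors[0]])
        else:
            piv = piv.reindex(
                columns=pd.MultiIndex.from_product(
                    [levels[f] for f in factors], names=factors
                )
            )
    complete = piv.dropna(axis=0)
    n_dropped = piv.shape[0] - complete.shape[0]
    return complete.to_numpy(float), list(complete.index), complete.columns, n_dropped
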