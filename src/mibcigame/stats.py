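"""Statistical comparison stage: normality gating, group comparisons,
correlation, sphericity, and one-way repeated-measures ANOVA.

The within-subject ANOVA decomposes SS_total into subject, condition
and error components; F = MS_condition / MS_error is referred to
F(k−1, (n−1)(k−1)), and sphericity-corrected p-values are obtained by
scaling both degrees of freedom with the Greenhouse–Geisser epsilon,
the Huynh–Feldt epsilon (classical 1976 form, n in the numerator,
capped at 1), and the lower bound 1/(k−1). Univariate tests delegate
to scipy; the sphericity machinery and ANOVA decomposition are
implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, ParameterError

#: sample-size product below which the Mann–Whitney p is exact
EXACT_MWU_LIMIT = 400


def _as_1d(x, name="x") -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size == 0:
        raise DataError(f"{name} is empty")
    if not np.all(np.isfinite(x)):
        raise DataError(f"{name} contains non-finite values")
    return x


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p)."""
    x = _as_1d(x)
    if not 3 <= x.size <= 5000:
        raise ParameterError(
            f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}"
        )
    if np.ptp(x) == 0:
        raise DataError("Shapiro-Wilk undefined for zero-variance data")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x, y, alternative: str = "two-sided"
                   ) -> tuple[float, float]:
    """Mann–Whitney U test; exact p for small samples (no ties),
    normal approximation with tie correction otherwise."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = ("exact" if x.size * y.size <= EXACT_MWU_LIMIT and not has_ties
              else "asymptotic")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))


def t_test_ind(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample t-test."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if x.size + y.size - 2 < 1:
        raise DataError(
            f"t-test has zero error degrees of freedom "
            f"(n_x={x.size}, n_y={y.size})"
        )
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation (rho, p)."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if x.size != y.size:
        raise DataError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ParameterError("Pearson correlation requires n >= 3")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# sphericity and repeated-measures ANOVA


def _check_matrix(data) -> np.ndarray:
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ParameterError("data must be subjects × conditions")
    return data


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k × (k−1) matrix with orthonormal columns orthogonal to 1."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis)
    # drop the column (numerically) parallel to the intercept
    keep = [j for j in range(k)
            if abs(q[:, j] @ np.ones(k)) < 1e-8][: k - 1]
    return q[:, keep]


def mauchly(data) -> tuple[float, float, float]:
    """Mauchly's test of sphericity → (chi2, df, p).

    With k = 2 conditions sphericity holds trivially (df = 0, p = 1).
    """
    data = _check_matrix(data)
    n, k = data.shape
    if k < 2:
        raise ParameterError("Mauchly needs at least 2 conditions")
    if n <= k - 1:
        raise ParameterError(
            f"Mauchly needs more subjects ({n}) than k-1 ({k - 1})"
        )
    if k == 2:
        return 0.0, 0.0, 1.0
    m = _orthonormal_contrasts(k)
    s = np.cov(data @ m, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    if np.any(eig <= 0):
        raise DataError("contrast covariance is singular; Mauchly undefined")
    w = float(np.prod(eig) / (np.mean(eig) ** (k - 1)))
    d = k - 1
    f = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * math.log(w)
    df = k * (k - 1) / 2.0 - 1.0
    # two-term asymptotic expansion of the null distribution (the
    # correction used by ezANOVA), noticeably better at small n
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d ** 3 + 6 * d ** 2 + 3 * k + 2)
          / (288.0 * ((n - 1) * d * f) ** 2))
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return float(chi2), float(df), p


def sphericity_epsilons(data) -> dict[str, float]:
    """Greenhouse–Geisser, Huynh–Feldt (classical, capped at 1) and
    lower-bound epsilons from the double-centered condition covariance."""
    data = _check_matrix(data)
    n, k = data.shape
    s = np.cov(data, rowvar=False, ddof=1)
    c = np.eye(k) - 1.0 / k
    sc = c @ s @ c
    eig = np.linalg.eigvalsh(sc)
    eig = eig[eig > 1e-12 * max(1.0, eig.max())]
    lb = 1.0 / (k - 1)
    gg = float(np.sum(eig) ** 2 / ((k - 1) * np.sum(eig ** 2)))
    gg = min(1.0, max(lb, gg))
    hf_num = n * (k - 1) * gg - 2.0
    hf_den = (k - 1) * (n - 1 - (k - 1) * gg)
    hf = 1.0 if hf_den <= 0 else min(1.0, hf_num / hf_den)
    hf = max(hf, gg)
    return {"gg": gg, "hf": hf, "lb": lb}


@dataclass
class RMAnovaResult:
    """One-way within-subject ANOVA with sphericity corrections."""

    ss_condition: float
    ss_error: float
    ss_subjects: float
    df_condition: float
    df_error: float
    ms_condition: float
    ms_error: float
    F: float
    p: float
    p_gg: float
    p_hf: float
    p_lb: float
    epsilon_gg: float
    epsilon_hf: float
    epsilon_lb: float
    mauchly_chi2: float
    mauchly_df: float
    mauchly_p: float
    n_subjects: int
    n_dropped: int = 0

    def summary(self) -> pd.DataFrame:
        """Table with the conventional SumSq/df/MeanSq/F/p column set,
        including the GG-, HF- and lower-bound-corrected p-values."""
        rows = {
            "condition": [self.ss_condition, self.df_condition,
                          self.ms_condition, self.F, self.p, self.p_gg,
                          self.p_hf, self.p_lb],
            "error": [self.ss_error, self.df_error, self.ms_error,
                      np.nan, np.nan, np.nan, np.nan, np.nan],
        }
        return pd.DataFrame(
            rows, index=["SumSq", "df", "MeanSq", "F", "p-Value",
                         "p-ValueGG", "p-ValueHF", "p-ValueLB"],
        ).T


def rm_anova(data) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a subjects × conditions
    matrix. Subjects with any missing condition are dropped (listwise
    deletion); the number dropped is recorded on the result."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ParameterError("data must be subjects × conditions")
    complete = np.all(np.isfinite(data), axis=1)
    n_dropped = int(np.sum(~complete))
    data = data[complete]
    n, k = data.shape
    if k < 2:
        raise ParameterError(f"need at least 2 conditions, got {k}")
    if n < 2:
        raise ParameterError(f"need at least 2 complete subjects, got {n}")

    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_subjects = k * np.sum((subj_means - grand) ** 2)
    ss_condition = n * np.sum((cond_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_subjects - ss_condition

    df_c = k - 1.0
    df_e = (n - 1.0) * (k - 1.0)
    ms_c = ss_condition / df_c
    ms_e = ss_error / df_e

    if ms_e <= 0:
        # degenerate: no within-subject variability beyond the condition
        f_stat = 0.0 if ss_condition <= 1e-12 * max(1.0, abs(ss_total)) \
            else math.inf
        p = p_gg = p_hf = p_lb = 1.0 if f_stat == 0.0 else 0.0
        eps = {"gg": 1.0 / df_c, "hf": 1.0 / df_c, "lb": 1.0 / df_c}
    else:
        f_stat = ms_c / ms_e
        eps = sphericity_epsilons(data)
        p = float(sps.f.sf(f_stat, df_c, df_e))
        p_gg = float(sps.f.sf(f_stat, df_c * eps["gg"], df_e * eps["gg"]))
        p_hf = float(sps.f.sf(f_stat, df_c * eps["hf"], df_e * eps["hf"]))
        p_lb = float(sps.f.sf(f_stat, df_c * eps["lb"], df_e * eps["lb"]))

    try:
        m_chi2, m_df, m_p = mauchly(data)
    except (ParameterError, DataError):
        # too few subjects or a singular contrast covariance: the ANOVA
        # is still valid, only the sphericity test is unavailable
        m_chi2, m_df, m_p = math.nan, math.nan, math.nan
    return RMAnovaResult(
        ss_condition=float(ss_condition), ss_error=float(ss_error),
        ss_subjects=float(ss_subjects), df_condition=df_c, df_error=df_e,
        ms_condition=float(ms_c), ms_error=float(ms_e), F=float(f_stat),
        p=p, p_gg=p_gg, p_hf=p_hf, p_lb=p_lb,
        epsilon_gg=eps["gg"], epsilon_hf=eps["hf"], epsilon_lb=1.0 / df_c,
        mauchly_chi2=m_chi2, mauchly_df=m_df, mauchly_p=m_p,
        n_subjects=n, n_dropped=n_dropped,
    )


def rm_anova_long(df: pd.DataFrame, dv: str, within: str,
                  subject: str) -> RMAnovaResult:
    """Repeated-measures ANOVA from a long-format table."""
    wide = df.pivot_table(index=subject, columns=within, values=dv,
                          aggfunc="mean")
    return rm_anova(wide.to_numpy())


class RepeatedMeasuresAnova:
    """Model-object wrapper: build from a wide matrix or a long frame,
    ``fit()`` returns the :class:`RMAnovaResult`."""

    def __init__(self, data):
        self.data = _check_matrix(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dv: str, within: str,
                       subject: str) -> "RepeatedMeasuresAnova":
        wide = df.pivot_table(index=subject, columns=within, values=dv,
                              aggfunc="mean")
        return cls(wide.to_numpy())

    def fit(self) -> RMAnovaResult:
        return rm_anova(self.data)
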