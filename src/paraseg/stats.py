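"""Reliability and model-comparison statistics.

Implements, from the classical mean-square decompositions:

* ICC(2,1) — two-way random-effects, absolute-agreement, single-measure
  intraclass correlation with the exact F-based 95% CI (Shrout-Fleiss /
  McGraw-Wong form);
* Bland-Altman bias and 95% limits of agreement;
* fully factorial repeated-measures ANOVA for an arbitrary number of
  within-subject factors, each effect tested against its own
  subject-by-effect interaction mean square;
* post-hoc two-sided paired t-tests (no multiple-testing correction: raw
  alpha comparisons, as is conventional when a single best condition is
  compared against the rest — interpret accordingly);
* normality/sphericity assumption checks: Shapiro-Wilk, sample skewness,
  excess kurtosis, Mauchly's W with its chi-square approximation, the
  Greenhouse-Geisser epsilon (reported, applied only on request), and Q-Q
  plot coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    value: float
    ci_low: float
    ci_high: float
    msr: float  # between-subject (rows) mean square
    msc: float  # between-rater (columns) mean square
    mse: float  # residual mean square
    n: int
    k: int
    degenerate: bool = False


def icc_2_1(x, y, alpha: float = 0.05) -> ICCResult:
    """Absolute-agreement single-measure ICC between two paired raters.

    ``x`` and ``y`` are the two raters' measurements of the same subjects.
    Zero between-subject variance leaves the coefficient undefined; the
    result is then NaN with ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("ICC needs at least 3 paired measurements")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite measurements")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(msr, 0.0) and np.isclose(denom, 0.0):
        return ICCResult(np.nan, np.nan, np.nan, msr, msc, mse, n, k, True)
    icc = (msr - mse) / denom

    # exact F-based CI (McGraw & Wong, ICC(A,1))
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a):
        v = ((a * msc + b * mse) ** 2 /
             ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
        f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msr - f_u * mse) /
              (f_u * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = (n * (f_l * msr - mse) /
              (k * msc + (k * n - k - n) * mse + n * f_l * msr))
    else:
        lo = hi = 1.0
    return ICCResult(float(icc), float(lo), float(hi), msr, msc, mse, n, k)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def bland_altman(x, y) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (bias ± 1.96 SD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need at least 2 paired measurements")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t-test; degenerate zero-variance differences map to
    (0, 1) when the means agree, (±inf, 0) otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (full factorial, within-subject)
# ---------------------------------------------------------------------------

def rm_anova(df: pd.DataFrame, dv: str, within: list[str],
             subject: str = "subject") -> pd.DataFrame:
    """Fully factorial within-subject ANOVA on a complete balanced table.

    Every subject must be measured exactly once in every factor-level cell
    (no imputation). Each effect F is its mean square over the mean square
    of its interaction with subject. Returns one row per effect with
    SS, df, MS, F, p and the error term's SS/df.
    """
    factors = list(within)
    cols = [subject] + factors + [dv]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    d = df[cols].copy()
    levels = {f: sorted(d[f].unique(), key=str) for f in factors}
    n_subj = d[subject].nunique()
    n_cells = int(np.prod([len(levels[f]) for f in factors]))
    counts = d.groupby([subject] + factors, observed=True).size()
    if len(counts) != n_subj * n_cells or (counts != 1).any():
        raise ValueError("design is not complete and balanced "
                         "(each subject needs exactly one value per cell)")

    grand = d[dv].mean()
    units = factors + [subject]
    # orthogonal effect estimates per observation by Möbius inversion over
    # marginal means (valid because the design is balanced)
    effect_obs: dict[frozenset, np.ndarray] = {frozenset(): np.full(len(d), grand)}
    for r in range(1, len(units) + 1):
        for T in combinations(units, r):
            key = frozenset(T)
            m = d.groupby(list(T), observed=True)[dv].transform("mean").to_numpy()
            e = m.copy()
            for sub_key, sub_e in effect_obs.items():
                if sub_key < key:
                    e -= sub_e
            effect_obs[key] = e

    def _df_of(key: frozenset) -> int:
        out = 1
        for u in key:
            out *= (n_subj - 1) if u == subject else (len(levels[u]) - 1)
        return out

    rows = []
    for r in range(1, len(factors) + 1):
        for S in combinations(factors, r):
            key = frozenset(S)
            err_key = key | {subject}
            ss = float(np.sum(effect_obs[key] ** 2))
            ss_err = float(np.sum(effect_obs[err_key] ** 2))
            df_eff = _df_of(key)
            df_err = _df_of(err_key)
            ms = ss / df_eff
            ms_err = ss_err / df_err
            f = ms / ms_err if ms_err > 0 else np.inf
            p = float(sps.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
            rows.append({"effect": ":".join(S), "SS": ss, "df": df_eff,
                         "MS": ms, "F": float(f), "p": p,
                         "SS_error": ss_err, "df_error": df_err})
    return pd.DataFrame(rows)


def posthoc_best_vs_rest(df: pd.DataFrame, dv: str, condition: str,
                         subject: str = "subject") -> pd.DataFrame:
    """Paired t-tests of the highest-mean condition against every other.

    P-values are reported raw (alpha-level comparisons, no correction).
    """
    wide = df.pivot_table(index=subject, columns=condition, values=dv)
    if wide.isna().any().any():
        raise ValueError("conditions are not complete across subjects")
    best = wide.mean().idxmax()
    rows = []
    for cond in wide.columns:
        if cond == best:
            continue
        t, p = paired_t(wide[best].to_numpy(), wide[cond].to_numpy())
        rows.append({"best": best, "other": cond,
                     "mean_best": float(wide[best].mean()),
                     "mean_other": float(wide[cond].mean()),
                     "t": t, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def mauchly(table: np.ndarray) -> dict:
    """Mauchly's test of sphericity on an (n subjects x k conditions) table.

    Uses the k-1 orthonormal contrasts of the condition covariance matrix;
    with k < 3 sphericity is trivially satisfied and the test is skipped.
    Also returns the Greenhouse-Geisser epsilon.
    """
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    if k < 3:
        return {"W": np.nan, "chi2": np.nan, "df": 0, "p": np.nan,
                "gg_epsilon": 1.0, "skipped": True,
                "note": "fewer than 3 conditions: sphericity holds trivially"}
    # orthonormal contrast basis (k x k-1): Helmert, normalized
    C = np.zeros((k, k - 1))
    for j in range(k - 1):
        C[: j + 1, j] = 1.0
        C[j + 1, j] = -(j + 1)
        C[:, j] /= np.linalg.norm(C[:, j])
    S = np.cov(table, rowvar=False, ddof=1)
    Sc = C.T @ S @ C
    eig = np.linalg.eigvalsh(Sc)
    eig = np.clip(eig, 1e-300, None)
    W = float(np.prod(eig) / (eig.mean() ** (k - 1)))
    df = k * (k - 1) // 2 - 1
    d = k - 1
    f_corr = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f_corr * np.log(W)
    # Box series approximation with the second-order term
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2.0 * d**3 + 6.0 * d**2 + 3.0 * k + 2.0)
          / (288.0 * ((n - 1) * d * f_corr) ** 2))
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    gg = float(np.trace(Sc) ** 2 / ((k - 1) * np.trace(Sc @ Sc)))
    return {"W": W, "chi2": float(chi2), "df": df, "p": p,
            "gg_epsilon": gg, "skipped": False, "note": ""}


def assumption_checks(residuals, table: np.ndarray | None = None) -> dict:
    """Normality (Shapiro-Wilk, skewness, excess kurtosis, Q-Q coordinates)
    and, when a subject-by-condition ``table`` is given, Mauchly sphericity.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    if len(r) < 3:
        raise ValueError("need at least 3 residuals")
    sw_stat, sw_p = sps.shapiro(r)
    srt = np.sort(r)
    probs = (np.arange(1, len(r) + 1) - 0.5) / len(r)
    out = {
        "shapiro_w": float(sw_stat), "shapiro_p": float(sw_p),
        "skewness": float(sps.skew(r)),
        "kurtosis": float(sps.kurtosis(r)),  # excess (normal -> 0)
        "qq": {"theoretical": sps.norm.ppf(probs).tolist(),
               "sample": srt.tolist()},
    }
    if table is not None:
        out["mauchly"] = mauchly(np.asarray(table))
    return out
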