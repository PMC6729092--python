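"""Cohort-level statistics: Type II two-way ANOVA, Sidak correction,
Pearson correlation maps, Cohen effect sizes and noncentral-t power.

The group sizes of the study design are heavily unbalanced (31 PD vs 6
controls), so main effects use Type II sums of squares: each main effect
is adjusted for the other main effect (ignoring the interaction), and the
interaction is adjusted for both mains.  The decomposition is computed by
explicit nested-OLS model comparison, which also makes it cheap enough for
Monte-Carlo calibration of the Type-I error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DegenerateInputError, DesignError

__all__ = [
    "AnovaResult",
    "EffectSize",
    "PowerSpec",
    "anova_two_way_type2",
    "sidak_adjust",
    "pearson",
    "correlation_map",
    "cohen_d",
    "power_ttest",
    "required_n_ttest",
    "achieved_power_ttest",
    "required_n_correlation",
]


# ---------------------------------------------------------------------------
# two-way ANOVA, Type II sums of squares
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Type II ANOVA table plus Sidak-adjusted post-hoc cell contrasts.

    ``table`` has one row per effect (group, trial, interaction, residual)
    with columns ``sum_sq, df, F, p``; ``posthoc`` lists pairwise cell
    comparisons with raw and Sidak-adjusted p-values (``m`` = number of
    contrasts performed).
    """

    table: pd.DataFrame
    posthoc: pd.DataFrame
    n_contrasts: int

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _dummies(levels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (k-1 columns for k levels)."""
    uniq = np.unique(levels)
    return np.column_stack([(levels == u).astype(float) for u in uniq[1:]])


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def anova_two_way_type2(
    values: np.ndarray,
    group: np.ndarray,
    trial: np.ndarray,
    posthoc: bool = True,
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with Type II sums of squares.

    SS(A) = RSS(1+B) - RSS(1+A+B); SS(B) symmetrically; SS(AB) =
    RSS(1+A+B) - RSS(1+A+B+AB).  F statistics use the full-model residual
    mean square.  Post-hoc pairwise cell t-tests are Sidak adjusted.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group)
    tr = np.asarray(trial)
    if not (y.shape == g.shape == tr.shape) or y.ndim != 1:
        raise ValueError("values, group and trial must be equal-length 1-D arrays")
    g_levels, t_levels = np.unique(g), np.unique(tr)
    if len(g_levels) < 2 or len(t_levels) < 2:
        raise DesignError("each factor needs at least 2 levels")
    for gl, tl in itertools.product(g_levels, t_levels):
        if not np.any((g == gl) & (tr == tl)):
            raise DesignError(f"empty design cell: group={gl!r}, trial={tl!r}")

    n = y.size
    ones = np.ones((n, 1))
    A = _dummies(g)
    B = _dummies(tr)
    AB = np.column_stack(
        [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
    )
    rss_b = _rss(np.hstack([ones, B]), y)
    rss_a = _rss(np.hstack([ones, A]), y)
    rss_ab = _rss(np.hstack([ones, A, B]), y)
    rss_full = _rss(np.hstack([ones, A, B, AB]), y)

    df_a, df_b = A.shape[1], B.shape[1]
    df_i = AB.shape[1]
    df_res = n - 1 - df_a - df_b - df_i
    if df_res < 1:
        raise DesignError("no residual degrees of freedom")
    mse = rss_full / df_res

    rows = {}
    for name, ss, df in (
        ("group", max(rss_b - rss_ab, 0.0), df_a),
        ("trial", max(rss_a - rss_ab, 0.0), df_b),
        ("group:trial", max(rss_ab - rss_full, 0.0), df_i),
    ):
        F = (ss / df) / mse
        rows[name] = {"sum_sq": ss, "df": df, "F": F, "p": float(sstats.f.sf(F, df, df_res))}
    rows["residual"] = {"sum_sq": rss_full, "df": df_res, "F": np.nan, "p": np.nan}
    table = pd.DataFrame(rows).T[["sum_sq", "df", "F", "p"]]

    ph_rows = []
    if posthoc:
        cells = list(itertools.product(g_levels, t_levels))
        pairs = list(itertools.combinations(cells, 2))
        raw_p = []
        for (g1, t1), (g2, t2) in pairs:
            y1 = y[(g == g1) & (tr == t1)]
            y2 = y[(g == g2) & (tr == t2)]
            if len(y1) > 1 and len(y2) > 1:
                tstat, p = sstats.ttest_ind(y1, y2)
            else:
                tstat, p = np.nan, np.nan
            raw_p.append(p)
            ph_rows.append(
                {
                    "cell_a": f"{g1}:{t1}",
                    "cell_b": f"{g2}:{t2}",
                    "mean_diff": float(y1.mean() - y2.mean()),
                    "t": float(tstat),
                    "p": float(p),
                }
            )
        m = len(pairs)
        adj = sidak_adjust([r["p"] for r in ph_rows])
        for r, pa in zip(ph_rows, adj):
            r["p_sidak"] = pa
    ph = pd.DataFrame(ph_rows)
    return AnovaResult(table=table, posthoc=ph, n_contrasts=len(ph_rows))


def sidak_adjust(pvals, m: int | None = None) -> list[float]:
    """Sidak multiple-comparison adjustment: p_adj = 1 - (1 - p)^m."""
    p = np.asarray(pvals, dtype=float)
    valid = p[~np.isnan(p)]
    if np.any((valid < 0) | (valid > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return [float(np.clip(1 - (1 - pi) ** m, 0, 1)) for pi in p]


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def pearson(x, y) -> tuple[float, float, float]:
    """Pearson product-moment correlation: returns (r, r², two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("pearson needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero-variance input to pearson")
    res = sstats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def correlation_map(
    sparc_tidy: pd.DataFrame,
    scores: pd.DataFrame,
    score_cols: list[str] | None = None,
    alpha: float = 0.05,
    sidak: bool = False,
) -> pd.DataFrame:
    """Correlate every clinical score with every (phase x channel) SPARC value.

    ``sparc_tidy`` needs columns ``subject_id, channel, phase, sparc`` (one
    row per subject after trial averaging); ``scores`` needs ``subject_id``
    plus numeric score columns.  Output mirrors the published layout:
    questionnaire, TUG phase, SPARC variable, r, r², p (raw p-values by
    default; Sidak-adjusted column added when ``sidak=True``).  Degenerate
    (constant) inputs yield NaN entries rather than aborting the map.
    """
    need = {"subject_id", "channel", "phase", "sparc"}
    if not need.issubset(sparc_tidy.columns):
        raise ValueError(f"sparc_tidy must have columns {sorted(need)}")
    if "subject_id" not in scores.columns:
        raise ValueError("scores must have a subject_id column")
    merged = sparc_tidy.merge(scores, on="subject_id", how="inner")
    if merged.empty:
        raise DesignError("no overlapping subjects between SPARC table and scores")
    if score_cols is None:
        score_cols = [
            c
            for c in scores.columns
            if c not in ("subject_id", "group", "severity")
            and pd.api.types.is_numeric_dtype(scores[c])
        ]
    rows = []
    for score in score_cols:
        for (phase, channel), sub in merged.groupby(["phase", "channel"], sort=False):
            sub = sub.dropna(subset=[score, "sparc"])
            try:
                r, r2, p = pearson(sub["sparc"].to_numpy(), sub[score].to_numpy())
            except (DegenerateInputError, ValueError):
                r = r2 = p = np.nan
            rows.append(
                {
                    "questionnaire": score,
                    "phase": phase,
                    "channel": channel,
                    "r": r,
                    "r2": r2,
                    "p": p,
                    "n": int(sub.shape[0]),
                }
            )
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha
    if sidak:
        mask = out["p"].notna()
        out.loc[mask, "p_sidak"] = sidak_adjust(out.loc[mask, "p"].tolist())
    return out


# ---------------------------------------------------------------------------
# effect sizes and power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with the conventional class labels.

    Classes: < 0.2 negligible, 0.2 small, 0.5 moderate, 0.8 large; an
    effect > 0.4 is flagged clinically relevant.
    """

    d: float
    label: str = field(init=False)
    clinically_relevant: bool = field(init=False)

    def __post_init__(self) -> None:
        d = abs(self.d)
        if d >= 0.8:
            label = "large"
        elif d >= 0.5:
            label = "moderate"
        elif d >= 0.2:
            label = "small"
        else:
            label = "negligible"
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "clinically_relevant", d > 0.4)


def cohen_d(group_a, group_b) -> EffectSize:
    """Cohen's d: absolute mean difference over the pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if pooled == 0:
        raise DegenerateInputError("zero pooled SD in cohen_d")
    return EffectSize(d=float(abs(a.mean() - b.mean()) / pooled))


@dataclass(frozen=True)
class PowerSpec:
    """A two-sample-t (or correlation) power computation."""

    effect_size: float
    alpha: float = 0.05
    power: float = 0.90
    tails: int = 1
    design: str = "two-sample-t"

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def power_ttest(d: float, n1: int, n2: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of a two-sample t-test via the noncentral t distribution.

    ncp = d * sqrt(n1*n2/(n1+n2)), df = n1+n2-2.  At d = 0 the returned
    value equals alpha (the rejection probability under the null).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    if tails == 1:
        tc = sstats.t.ppf(1 - alpha, df)
        return float(1 - sstats.nct.cdf(tc, df, ncp))
    tc = sstats.t.ppf(1 - alpha / 2, df)
    return float(1 - sstats.nct.cdf(tc, df, ncp) + sstats.nct.cdf(-tc, df, ncp))


def required_n_ttest(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest equal per-group n reaching the target power (floor n = 2)."""
    for n in range(2, n_max + 1):
        if power_ttest(spec.effect_size, n, n, spec.alpha, spec.tails) >= spec.power:
            return n
    raise ValueError(f"target power not reached by n = {n_max}")


def achieved_power_ttest(spec: PowerSpec, n1: int, n2: int) -> float:
    """Retrospective power for (possibly unequal) group sizes."""
    return power_ttest(spec.effect_size, n1, n2, spec.alpha, spec.tails)


def required_n_correlation(spec: PowerSpec) -> int:
    """Smallest n to detect a Pearson correlation, Fisher-z convention.

    n = ((z_alpha + z_power) / atanh(r))² + 3, rounded up.  For r = 0.65,
    alpha 0.05, power 0.95 this gives 22 (one-tailed; the unrounded value
    is 21.004) or 25 (two-tailed).
    """
    r = spec.effect_size
    if not 0 < r < 1:
        raise ValueError("correlation effect size must lie in (0, 1)")
    alpha = spec.alpha if spec.tails == 1 else spec.alpha / 2
    za = sstats.norm.ppf(1 - alpha)
    zb = sstats.norm.ppf(spec.power)
    n = ((za + zb) / np.arctanh(r)) ** 2 + 3
    return max(4, int(np.ceil(n)))
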