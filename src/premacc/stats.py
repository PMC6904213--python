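"""Repeated-measures ANOVA with sphericity handling, and t-test machinery.

Only the within-subject designs used by the analyses are supported (one or
two within factors, complete and balanced).  Greenhouse–Geisser correction
is applied to the degrees of freedom whenever Mauchly's test rejects
sphericity at p < 0.05.  Linear and quadratic contrasts over ordered
factor levels are available as one-sample t-tests on per-subject contrast
scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AnovaResult", "TTestResult", "rm_anova", "t_test_suite", "ordered_contrast"]


@dataclass
class AnovaResult:
    """One within-subject effect from a repeated-measures ANOVA."""

    effect: str
    F: float
    df1: float
    df2: float
    p_uncorrected: float
    mauchly_W: float | None
    mauchly_p: float | None
    gg_epsilon: float
    df1_corrected: float
    df2_corrected: float
    p: float                     # GG-corrected when sphericity is violated
    sphericity_violated: bool


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    label: str
    corrected_alpha: float
    significant: bool


def _check_complete(df: pd.DataFrame, subject: str, factors: list[str]) -> None:
    counts = df.groupby([subject] + factors, observed=True).size()
    if counts.empty or counts.nunique() != 1:
        raise ValueError("design must be complete and balanced (no missing cells)")
    n_cells = df.groupby(factors, observed=True).ngroups
    per_subj = df.groupby(subject, observed=True).size()
    if (per_subj != n_cells * counts.iloc[0]).any():
        raise ValueError("design must be complete and balanced (no missing cells)")


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str | list[str],
    subject: str = "subject",
    alpha_sphericity: float = 0.05,
) -> list[AnovaResult]:
    """One- or two-factor within-subject ANOVA with GG-corrected df.

    ``data`` is long-format with one row per subject × cell.  Mauchly's
    test is run per effect (where it is defined); whenever it rejects at
    ``alpha_sphericity`` the Greenhouse–Geisser-corrected p-value is
    reported as ``p``, otherwise the uncorrected one.
    """
    import pingouin as pg

    factors = [within] if isinstance(within, str) else list(within)
    _check_complete(data, subject, factors)

    if len(factors) == 1:
        aov = pg.rm_anova(
            data=data, dv=dv, within=factors[0], subject=subject,
            correction=True, detailed=False,
        )
    elif len(factors) == 2:
        aov = pg.rm_anova(data=data, dv=dv, within=factors, subject=subject)
    else:
        raise ValueError("only 1- or 2-factor within designs are supported")

    def field(row, name, default=np.nan):
        v = row.get(name, default)
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    results = []
    for _, row in aov.iterrows():
        if row["Source"] == "Error":
            continue
        effect = str(row["Source"])
        df1, df2 = float(row["ddof1"]), float(row["ddof2"])
        eps = field(row, "eps")
        if not np.isfinite(eps):
            eps = 1.0
        sph_p_val = field(row, "p_spher")
        W = field(row, "W_spher")
        if not np.isfinite(sph_p_val):
            # pingouin omits the sphericity test for 2-level and 2-way effects
            W, sph_p_val = _mauchly(data, dv, effect, factors, subject)
        p_unc = float(row["p_unc"])
        violated = bool(
            sph_p_val is not None
            and np.isfinite(sph_p_val)
            and sph_p_val < alpha_sphericity
        )
        if df1 <= 1:
            eps, violated = 1.0, False
        if violated:
            p_gg = field(row, "p_GG_corr")
            p_corr = (
                float(p_gg)
                if np.isfinite(p_gg)
                else float(sps.f.sf(row["F"], eps * df1, eps * df2))
            )
        else:
            p_corr = p_unc
        results.append(
            AnovaResult(
                effect=effect,
                F=float(row["F"]),
                df1=df1,
                df2=df2,
                p_uncorrected=p_unc,
                mauchly_W=W if np.isfinite(W) else None,
                mauchly_p=sph_p_val,
                gg_epsilon=eps,
                df1_corrected=eps * df1,
                df2_corrected=eps * df2,
                p=p_corr,
                sphericity_violated=violated,
            )
        )
    return results


def _wide(data: pd.DataFrame, dv: str, effect: str, factors: list[str], subject: str) -> pd.DataFrame:
    """Subject × condition table of cell means for one effect."""
    if " * " in effect:
        cols = effect.split(" * ")
        cells = data.groupby([subject] + cols, observed=True)[dv].mean().reset_index()
        cells["_cond"] = cells[cols].astype(str).agg("|".join, axis=1)
        return cells.pivot(index=subject, columns="_cond", values=dv)
    return (
        data.groupby([subject, effect], observed=True)[dv].mean().reset_index()
        .pivot(index=subject, columns=effect, values=dv)
    )


def _mauchly(
    data: pd.DataFrame, dv: str, effect: str, factors: list[str], subject: str
) -> tuple[float, float | None]:
    import pingouin as pg

    wide = _wide(data, dv, effect, factors, subject)
    if wide.shape[1] <= 2:
        return 1.0, None   # sphericity trivially holds with 2 levels
    sph = pg.sphericity(wide)
    return float(sph.W), float(sph.pval)


def t_test_suite(
    comparisons: list[tuple[str, np.ndarray, float | np.ndarray]],
    family_size: int | None = None,
    alpha: float = 0.05,
) -> list[TTestResult]:
    """One-sample / paired t-tests with a Bonferroni-corrected alpha.

    Each comparison is ``(label, values, mu0_or_partner)``: a scalar third
    element gives a one-sample test against it, an array a paired test.
    ``corrected_alpha`` = alpha / family size (family defaults to the
    number of comparisons).  Zero-variance inputs yield NaN statistics
    with ``significant=False``.
    """
    family = family_size if family_size is not None else len(comparisons)
    corrected = alpha / family
    out = []
    for label, values, other in comparisons:
        v = np.asarray(values, dtype=float)
        if np.ndim(other) > 0:
            v = v - np.asarray(other, dtype=float)
            mu0 = 0.0
        else:
            mu0 = float(other)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ValueError(f"{label}: need n >= 2")
        if np.std(v, ddof=1) == 0:
            out.append(TTestResult(np.nan, len(v) - 1, np.nan, label, corrected, False))
            continue
        res = sps.ttest_1samp(v, mu0)
        out.append(
            TTestResult(
                t=float(res.statistic),
                df=len(v) - 1,
                p=float(res.pvalue),
                label=label,
                corrected_alpha=corrected,
                significant=bool(res.pvalue < corrected),
            )
        )
    return out


def ordered_contrast(
    wide: pd.DataFrame, kind: str = "linear"
) -> TTestResult:
    """Linear or quadratic contrast over ordered condition columns.

    ``wide`` is subject × condition (columns in factor order).  The
    contrast score per subject is tested against zero.
    """
    k = wide.shape[1]
    x = np.arange(k, dtype=float) - (k - 1) / 2
    if kind == "linear":
        w = x
    elif kind == "quadratic":
        w = x ** 2 - np.mean(x ** 2)
    else:
        raise ValueError(f"unknown contrast {kind!r}")
    scores = wide.to_numpy(float) @ w
    res = sps.ttest_1samp(scores, 0.0)
    return TTestResult(
        t=float(res.statistic),
        df=len(scores) - 1,
        p=float(res.pvalue),
        label=f"{kind} contrast",
        corrected_alpha=0.05,
        significant=bool(res.pvalue < 0.05),
    )
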