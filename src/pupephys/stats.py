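"""Statistical wrappers for the analysis pipeline.

Probabilities and percentages are arcsine transformed (arcsin of the
square root) before testing to correct for edge effects. Paired and
unpaired t tests report Cohen's D; the 2x2 repeated-measures ANOVA
(state x movement) reports partial eta squared and the four planned
paired contrasts at a Bonferroni-adjusted alpha. A Shapiro–Wilk check is
advisory only — no nonparametric fallback is applied.

Distribution functions come from scipy; the content here is the contrast
structure, transforms, and effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst


@dataclass
class StatResult:
    name: str
    statistic: float | None
    df: float | tuple | None
    p: float | None
    effect_size: float | None = None
    effect_size_name: str = ""
    alpha_used: float = 0.05
    note: str = ""

    @property
    def missing(self) -> bool:
        return self.statistic is None


def arcsine_transform(p):
    """arcsin(sqrt(p)) for proportions in [0, 1]; monotone, maps to [0, pi/2]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.ndim(p) == 0 else out


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Per-test alpha under Bonferroni correction: alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def cohens_d_paired(x: np.ndarray, y: np.ndarray) -> float | None:
    """Mean difference divided by the SD of the differences (ddof=1)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if np.allclose(d, 0) else None
    return float(d.mean() / sd)


def cohens_d_unpaired(x: np.ndarray, y: np.ndarray) -> float | None:
    """Mean difference divided by the pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        return 0.0 if np.isclose(x.mean(), y.mean()) else None
    return float((x.mean() - y.mean()) / pooled)


def paired_comparison(x, y, alpha: float = 0.05, name: str = "paired_t") -> StatResult:
    """Paired t test with Cohen's D.

    Identical samples yield t = 0, D = 0, p = 1. A constant nonzero
    difference has zero variance, so the statistic is undefined and
    reported missing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired comparison needs >= 2 pairs of equal length")
    d = x - y
    n = d.size
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return StatResult(name, 0.0, n - 1, 1.0, 0.0, "cohens_d", alpha)
        return StatResult(name, None, n - 1, None, None, "cohens_d", alpha,
                          note="zero-variance differences")
    t, p = sst.ttest_rel(x, y)
    return StatResult(name, float(t), n - 1, float(p), cohens_d_paired(x, y),
                      "cohens_d", alpha)


def unpaired_comparison(x, y, alpha: float = 0.05, name: str = "unpaired_t") -> StatResult:
    """Two-sample t test (equal variances) with Cohen's D."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("unpaired comparison needs >= 2 samples per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if np.isclose(x.mean(), y.mean()):
            return StatResult(name, 0.0, x.size + y.size - 2, 1.0, 0.0, "cohens_d", alpha)
        return StatResult(name, None, x.size + y.size - 2, None, None, "cohens_d",
                          alpha, note="zero variance in both groups")
    t, p = sst.ttest_ind(x, y)
    return StatResult(name, float(t), x.size + y.size - 2, float(p),
                      cohens_d_unpaired(x, y), "cohens_d", alpha)


def _contrast_f(contrast: np.ndarray, name: str) -> StatResult:
    """F test of a 1-df within-subject contrast (F = t^2 of the one-sample
    t on the per-subject contrast values); partial eta squared =
    F / (F + df_error)."""
    n = contrast.size
    dfe = n - 1
    sd = contrast.std(ddof=1)
    if sd == 0:
        if np.allclose(contrast, 0):
            return StatResult(name, 0.0, (1, dfe), 1.0, 0.0, "partial_eta_sq")
        return StatResult(name, None, (1, dfe), None, None, "partial_eta_sq",
                          note="zero-variance contrast with nonzero mean")
    t = contrast.mean() / (sd / np.sqrt(n))
    f = t * t
    p = float(sst.f.sf(f, 1, dfe))
    return StatResult(name, float(f), (1, dfe), p, float(f / (f + dfe)), "partial_eta_sq")


def rm_anova_2x2(
    table: pd.DataFrame,
    subject: str = "animal_id",
    factor_a: str = "state",
    factor_b: str = "movement",
    value: str = "rate_hz",
    alpha: float = 0.05,
) -> dict[str, StatResult]:
    """2x2 repeated-measures ANOVA with the four planned paired contrasts.

    ``table`` is long-form with one row per subject x cell. Subjects with
    any missing cell are dropped (logged in the returned note). Main
    effects and the interaction are 1-df within-subject contrasts
    (univariate, no sphericity issue at 1 df), with partial eta squared.
    The planned comparisons — within each level of one factor across the
    other — use a Bonferroni-adjusted alpha of ``alpha / 4``.
    """
    lev_a = sorted(table[factor_a].unique())
    lev_b = sorted(table[factor_b].unique())
    if len(lev_a) != 2 or len(lev_b) != 2:
        raise ValueError("rm_anova_2x2 needs exactly two levels per factor")
    wide = table.pivot_table(index=subject, columns=[factor_a, factor_b],
                             values=value, aggfunc="mean")
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if len(complete) < 3:
        raise ValueError("need >= 3 subjects with complete 2x2 cells")
    y = np.stack(
        [[complete[(a, b)].to_numpy() for b in lev_b] for a in lev_a]
    )  # shape (2, 2, n)

    main_a = y[1].mean(axis=0) - y[0].mean(axis=0)
    main_b = y[:, 1].mean(axis=0) - y[:, 0].mean(axis=0)
    inter = (y[1, 1] - y[1, 0]) - (y[0, 1] - y[0, 0])
    out = {
        factor_a: _contrast_f(main_a, factor_a),
        factor_b: _contrast_f(main_b, factor_b),
        "interaction": _contrast_f(inter, "interaction"),
    }
    adj = bonferroni_adjust(alpha, 4)
    planned = {
        f"{lev_a[0]}:{lev_b[1]}_vs_{lev_b[0]}": (y[0, 1], y[0, 0]),
        f"{lev_a[1]}:{lev_b[1]}_vs_{lev_b[0]}": (y[1, 1], y[1, 0]),
        f"{lev_b[0]}:{lev_a[1]}_vs_{lev_a[0]}": (y[1, 0], y[0, 0]),
        f"{lev_b[1]}:{lev_a[1]}_vs_{lev_a[0]}": (y[1, 1], y[0, 1]),
    }
    for nm, (u, v) in planned.items():
        res = paired_comparison(u, v, alpha=adj, name=nm)
        if dropped:
            res.note = (res.note + f"; {dropped} subject(s) dropped (incomplete cells)").strip("; ")
        out[nm] = res
    if dropped:
        for key in (factor_a, factor_b, "interaction"):
            out[key].note = f"{dropped} subject(s) dropped (incomplete cells)"
    return out


def normality_check(sample, alpha: float = 0.05) -> StatResult:
    """Shapiro–Wilk normality test; advisory only (no fallback is taken).

    Out-of-range n (outside 3..5000) or constant samples are reported
    missing.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3 or x.size > 5000:
        return StatResult("shapiro_wilk", None, x.size, None,
                          note=f"n={x.size} outside supported range")
    if np.ptp(x) == 0:
        return StatResult("shapiro_wilk", None, x.size, None, note="constant sample")
    w, p = sst.shapiro(x)
    return StatResult("shapiro_wilk", float(w), x.size, float(p), alpha_used=alpha)
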