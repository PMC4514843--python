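"""Per-gene differential-translation testing.

For each gene, polysome-associated log2 expression P is regressed on the
paired cytosolic log2 expression C with a condition-specific intercept and
a single common slope (ANCOVA / analysis of partial variance):

    P = alpha_condition + beta * C + eps

The condition effect is the shift in adjusted means (intercepts at the
common slope), tested with an RVM-moderated F.  Genes pass to the
significant set only if (i) BH-adjusted p <= maxRvmPAdj, (ii) the
translational-activity difference |dPT| = |dP - dC| >= selDeltaPT, and
(iii) the fitted slope is not credibly outside [minSlope, maxSlope].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import AnalysisSettings, ExpressionMatrix, Fraction, ValidationError
from .rvm import RvmParams, fit_rvm, moderate_variance, moderated_f

log = logging.getLogger("polyapv.translation")

MIN_TESTABLE_GENES = 50

RESULT_COLUMNS = [
    "gene_id", "slope", "slope_se", "delta_p", "delta_c", "delta_pt",
    "adj_mean_diff", "ss_effect", "residual_var", "df_resid", "f_stat",
    "p_value", "padj", "slope_flag", "deltaPT_pass", "significant",
    "direction", "rank_deficient",
]


@dataclass(frozen=True)
class GeneApvFit:
    """Summary of the common-slope ANCOVA fit for one gene."""

    slope: float
    slope_se: float
    adjusted_means: dict  # condition -> intercept evaluated at the grand mean C
    rss: float
    df_resid: int
    ss_effect: float
    delta_p: float
    delta_c: float
    delta_pt: float
    rank_deficient: bool = False


def _apv_arrays(
    P: np.ndarray, C: np.ndarray, conditions: Sequence[str]
) -> dict:
    """Vectorized ANCOVA sufficient statistics.

    P and C are (genes x samples); ``conditions`` labels each sample
    column.  Returns per-gene arrays (closed-form normal-equation solve of
    the common-slope model via pooled within-condition sums of squares).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if P.shape != C.shape:
        raise ValidationError(f"P {P.shape} and C {C.shape} differ in shape")
    conditions = list(conditions)
    if len(conditions) != P.shape[1]:
        raise ValidationError("one condition label per sample is required")
    labels: list[str] = []
    for c in conditions:
        if c not in labels:
            labels.append(c)
    K = len(labels)
    if K < 2:
        raise ValidationError(">=2 conditions are required")
    n_samples = P.shape[1]
    groups = [np.array([i for i, c in enumerate(conditions) if c == lab])
              for lab in labels]
    for lab, idx in zip(labels, groups):
        if idx.size < 2:
            raise ValidationError(
                f"condition {lab!r} has {idx.size} replicate(s); >=2 required"
            )

    # within-condition centered cross-products, pooled over conditions
    Sxx = np.zeros(P.shape[0])
    Sxy = np.zeros(P.shape[0])
    Syy = np.zeros(P.shape[0])
    p_means = np.empty((P.shape[0], K))
    c_means = np.empty((P.shape[0], K))
    for j, idx in enumerate(groups):
        x = C[:, idx]
        y = P[:, idx]
        xm = x.mean(axis=1)
        ym = y.mean(axis=1)
        c_means[:, j] = xm
        p_means[:, j] = ym
        xc = x - xm[:, None]
        yc = y - ym[:, None]
        Sxx += (xc * xc).sum(axis=1)
        Sxy += (xc * yc).sum(axis=1)
        Syy += (yc * yc).sum(axis=1)

    # totals centered about the grand mean (reduced model: no condition term)
    xg = C.mean(axis=1)
    yg = P.mean(axis=1)
    xct = C - xg[:, None]
    yct = P - yg[:, None]
    Txx = (xct * xct).sum(axis=1)
    Txy = (xct * yct).sum(axis=1)
    Tyy = (yct * yct).sum(axis=1)

    rank_deficient = Sxx <= 1e-12 * np.maximum(1.0, Txx)
    safe_Sxx = np.where(rank_deficient, 1.0, Sxx)
    beta = Sxy / safe_Sxx
    rss = Syy - Sxy**2 / safe_Sxx
    rss = np.maximum(rss, 0.0)
    m = n_samples - K - 1

    safe_Txx = np.where(Txx <= 1e-12, 1.0, Txx)
    rss_reduced = Tyy - np.where(Txx <= 1e-12, 0.0, Txy**2 / safe_Txx)
    ss_effect = np.maximum(rss_reduced - rss, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        slope_se = np.sqrt((rss / max(m, 1)) / safe_Sxx)
    beta = np.where(rank_deficient, np.nan, beta)
    slope_se = np.where(rank_deficient, np.nan, slope_se)

    delta_p = p_means[:, -1] - p_means[:, 0]
    delta_c = c_means[:, -1] - c_means[:, 0]
    # intercepts evaluated at the grand mean of C ("adjusted means")
    adj_means = p_means - beta[:, None] * (c_means - xg[:, None])
    return {
        "labels": labels,
        "beta": beta,
        "slope_se": slope_se,
        "rss": rss,
        "df_resid": m,
        "ss_effect": np.where(rank_deficient, np.nan, ss_effect),
        "delta_p": delta_p,
        "delta_c": delta_c,
        "delta_pt": delta_p - delta_c,
        "adj_means": adj_means,
        "rank_deficient": rank_deficient,
        "df1": K - 1,
    }


def fit_gene_apv(
    P: Sequence[float], C: Sequence[float], conditions: Sequence[str]
) -> GeneApvFit:
    """Common-slope ANCOVA fit for a single gene.

    ``P`` and ``C`` are paired per (condition, replicate); the condition
    label sequence defines the grouping (first label = reference).
    """
    out = _apv_arrays(np.asarray(P)[None, :], np.asarray(C)[None, :], conditions)
    rank_deficient = bool(out["rank_deficient"][0])
    return GeneApvFit(
        slope=float(out["beta"][0]),
        slope_se=float(out["slope_se"][0]),
        adjusted_means={lab: float(out["adj_means"][0, j])
                        for j, lab in enumerate(out["labels"])},
        rss=float(out["rss"][0]),
        df_resid=int(out["df_resid"]),
        ss_effect=float(out["ss_effect"][0]),
        delta_p=float(out["delta_p"][0]),
        delta_c=float(out["delta_c"][0]),
        delta_pt=float(out["delta_pt"][0]),
        rank_deficient=rank_deficient,
    )


def _slope_flags(
    beta: np.ndarray,
    slope_se: np.ndarray,
    df_resid: int,
    settings: AnalysisSettings,
) -> np.ndarray:
    """Vectorized slope-reliability filter.

    A gene is flagged (excluded from the significant set) when its fitted
    slope is credibly outside [minSlope, maxSlope]: a one-sided t-test
    against the violated boundary with p < slopeP.  Zero standard error
    with the estimate outside the bounds flags deterministically.
    """
    flags = np.zeros(beta.shape, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        below = beta < settings.minSlope
        above = beta > settings.maxSlope
        outside = below | above
        zero_se = outside & (slope_se == 0)
        flags |= zero_se
        check = outside & (slope_se > 0)
        if np.any(check):
            t_lo = (beta - settings.minSlope) / slope_se
            t_hi = (beta - settings.maxSlope) / slope_se
            p_lo = stats.t.cdf(t_lo, df_resid)   # H0: beta = minSlope, alt <
            p_hi = stats.t.sf(t_hi, df_resid)    # H0: beta = maxSlope, alt >
            flags |= check & below & (p_lo < settings.slopeP)
            flags |= check & above & (p_hi < settings.slopeP)
    return flags


def slope_filter(fit: GeneApvFit, settings: AnalysisSettings) -> bool:
    """Slope flag for a single fitted gene (True = exclude)."""
    if fit.df_resid < 1:
        raise ValidationError("slope_filter requires residual df >= 1")
    return bool(
        _slope_flags(
            np.array([fit.slope]), np.array([fit.slope_se]),
            fit.df_resid, settings,
        )[0]
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class TranslationResult:
    """Per-gene translation-analysis table plus the fit metadata."""

    table: pd.DataFrame
    rvm_params: Optional[RvmParams]
    settings: AnalysisSettings
    contrast: tuple[str, str]

    @property
    def significant_genes(self) -> list[str]:
        sig = self.table[self.table["significant"]]
        return list(sig["gene_id"])

    def significant_by_direction(self, direction: str) -> list[str]:
        sig = self.table[
            self.table["significant"] & (self.table["direction"] == direction)
        ]
        return list(sig["gene_id"])


def run_translation_analysis(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    settings: Optional[AnalysisSettings] = None,
    moderation: bool = True,
) -> TranslationResult:
    """Full differential-translation analysis for one two-condition contrast.

    ``contrast = (reference, treatment)``; effects are treatment minus
    reference.  ``moderation=False`` disables the RVM (classical ANCOVA),
    mainly for validation.
    """
    if settings is None:
        settings = AnalysisSettings()
    c1, c2 = contrast
    available = set(matrix.design.conditions)
    missing = [c for c in (c1, c2) if c not in available]
    if missing:
        raise ValidationError(
            f"contrast condition(s) {missing} absent from design "
            f"(available: {sorted(available)})"
        )

    P, p_design = matrix.submatrix(Fraction.POLYSOMAL, [c1, c2])
    C, c_design = matrix.submatrix(Fraction.CYTOSOLIC, [c1, c2])
    pairing_p = list(zip(p_design["condition"], p_design["replicate"]))
    pairing_c = list(zip(c_design["condition"], c_design["replicate"]))
    if pairing_p != pairing_c:
        raise ValidationError(
            "cytosolic and polysomal samples do not pair by "
            "(condition, replicate)"
        )
    conditions = list(p_design["condition"])

    gene_mask = np.ones(matrix.n_genes, dtype=bool)
    if settings.min_expression is not None:
        mean_expr = np.concatenate([P, C], axis=1).mean(axis=1)
        gene_mask = mean_expr >= settings.min_expression
        log.info("expression filter: %d of %d genes retained",
                 int(gene_mask.sum()), matrix.n_genes)

    stats_out = _apv_arrays(P[gene_mask], C[gene_mask], conditions)
    m = stats_out["df_resid"]
    if m < 1:
        raise ValidationError(
            f"residual df {m} < 1; add replicates or conditions"
        )
    testable = ~stats_out["rank_deficient"]
    n_deficient = int((~testable).sum())
    if n_deficient:
        log.warning("%d gene(s) rank-deficient; excluded from testing",
                    n_deficient)
    if int(testable.sum()) < MIN_TESTABLE_GENES:
        raise ValidationError(
            f"only {int(testable.sum())} testable genes; "
            f">= {MIN_TESTABLE_GENES} required to fit the RVM"
        )

    residual_var = stats_out["rss"] / m
    if moderation:
        params = fit_rvm(residual_var[testable], m)
    else:
        params = RvmParams.from_prior(nu0=0.0, s0_sq=1.0)

    s_tilde = np.asarray(moderate_variance(residual_var, m, params), dtype=float)
    f_stat = np.full(residual_var.shape, np.nan)
    p_val = np.full(residual_var.shape, np.nan)
    f_t, p_t = moderated_f(
        stats_out["ss_effect"][testable], stats_out["df1"],
        s_tilde[testable], m, params,
    )
    f_stat[testable] = f_t
    p_val[testable] = p_t

    padj = np.full(residual_var.shape, np.nan)
    padj[testable] = bh_adjust(p_val[testable])

    slope_flag = np.zeros(residual_var.shape, dtype=bool)
    slope_flag[testable] = _slope_flags(
        stats_out["beta"][testable], stats_out["slope_se"][testable],
        m, settings,
    )
    delta_pt = stats_out["delta_pt"]
    deltaPT_pass = np.abs(delta_pt) >= settings.selDeltaPT
    significant = (
        testable
        & (padj <= settings.maxRvmPAdj)
        & deltaPT_pass
        & ~slope_flag
    )
    direction = np.where(delta_pt < 0, "repressed", "enhanced")

    gene_ids = matrix.gene_ids[gene_mask].astype(str)
    labels = stats_out["labels"]
    adj_means = stats_out["adj_means"]
    adj_mean_diff = adj_means[:, -1] - adj_means[:, 0]
    table = pd.DataFrame({
        "gene_id": gene_ids,
        "slope": stats_out["beta"],
        "slope_se": stats_out["slope_se"],
        "delta_p": stats_out["delta_p"],
        "delta_c": stats_out["delta_c"],
        "delta_pt": delta_pt,
        "adj_mean_diff": adj_mean_diff,
        "ss_effect": stats_out["ss_effect"],
        "residual_var": residual_var,
        "df_resid": m,
        "f_stat": f_stat,
        "p_value": p_val,
        "padj": padj,
        "slope_flag": slope_flag,
        "deltaPT_pass": deltaPT_pass,
        "significant": significant,
        "direction": direction,
        "rank_deficient": ~testable,
    })
    # stable sort: padj ascending, gene id as the reproducible tie-break
    table = table.sort_values(
        ["padj", "gene_id"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    log.info(
        "translation %s vs %s: %d genes tested, %d significant "
        "(%d repressed / %d enhanced)",
        c2, c1, int(testable.sum()), int(significant.sum()),
        int((significant & (delta_pt < 0)).sum()),
        int((significant & (delta_pt >= 0)).sum()),
    )
    return TranslationResult(
        table=table,
        rvm_params=params if moderation else None,
        settings=settings,
        contrast=(c1, c2),
    )
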