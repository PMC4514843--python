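"""RVM-moderated differential expression of cytosolic mRNA and ISG calling.

A gene is an ISG when its cytosolic abundance rises at least ``isg_fold``
(default 1.5) on the linear scale between the control and IFN conditions;
by default a BH-adjusted significance gate (padj <= maxRvmPAdj) is applied
on top, switchable off via ``isg_require_significance`` to obtain a
fold-only list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_model import AnalysisSettings, ExpressionMatrix, Fraction, ValidationError
from .rvm import RvmParams, fit_rvm, moderate_variance, moderated_f
from .translation_apv import MIN_TESTABLE_GENES, bh_adjust

log = logging.getLogger("polyapv.de")

DE_COLUMNS = ["gene_id", "delta_c", "fold_change", "f_stat", "p_value",
              "padj", "is_isg"]


@dataclass
class DeResult:
    table: pd.DataFrame
    rvm_params: RvmParams
    settings: AnalysisSettings
    contrast: tuple[str, str]

    @property
    def isg_genes(self) -> list[str]:
        return list(self.table.loc[self.table["is_isg"], "gene_id"])


def run_cytosolic_de(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    settings: Optional[AnalysisSettings] = None,
) -> DeResult:
    """Per-gene two-sample comparison on the cytosolic fraction.

    ``contrast = (reference, treatment)``, e.g. ("control", "IFN");
    delta_c is treatment minus reference in log2 units.  Residual
    variances are pooled within conditions and RVM-moderated.
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
    X1, _ = matrix.submatrix(Fraction.CYTOSOLIC, [c1])
    X2, _ = matrix.submatrix(Fraction.CYTOSOLIC, [c2])
    n1, n2 = X1.shape[1], X2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"need >=2 replicates per condition, got {n1} and {n2}"
        )
    if matrix.n_genes < MIN_TESTABLE_GENES:
        raise ValidationError(
            f"only {matrix.n_genes} genes; >= {MIN_TESTABLE_GENES} required"
        )

    delta_c = X2.mean(axis=1) - X1.mean(axis=1)
    ss_within = (
        ((X1 - X1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((X2 - X2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    )
    m = n1 + n2 - 2
    s_sq = ss_within / m
    params = fit_rvm(s_sq, m)
    s_tilde = np.asarray(moderate_variance(s_sq, m, params), dtype=float)
    # the condition sum of squares of the two-group comparison
    ss_effect = delta_c**2 / (1.0 / n1 + 1.0 / n2)
    f_stat, p_val = moderated_f(ss_effect, 1, s_tilde, m, params)
    padj = bh_adjust(p_val)
    fold = np.exp2(delta_c)
    is_isg = fold >= settings.isg_fold
    if settings.isg_require_significance:
        is_isg &= padj <= settings.maxRvmPAdj

    table = pd.DataFrame({
        "gene_id": matrix.gene_ids.astype(str),
        "delta_c": delta_c,
        "fold_change": fold,
        "f_stat": f_stat,
        "p_value": p_val,
        "padj": padj,
        "is_isg": is_isg,
    })
    table = table.sort_values(
        ["padj", "gene_id"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    log.info("cytosolic DE %s vs %s: %d ISG(s) at fold >= %.3g",
             c2, c1, int(is_isg.sum()), settings.isg_fold)
    return DeResult(table=table, rvm_params=params, settings=settings,
                    contrast=(c1, c2))


def rank_by_fold(de: "DeResult | pd.DataFrame", k: int) -> list[str]:
    """Top-k gene ids by descending linear fold change, ties broken by
    gene id; k larger than the table returns the full ranking."""
    table = de.table if isinstance(de, DeResult) else de
    ordered = table.sort_values(
        ["fold_change", "gene_id"], ascending=[False, True], kind="stable"
    )
    return list(ordered["gene_id"].head(max(k, 0)) if k >= 0 else ordered["gene_id"])
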