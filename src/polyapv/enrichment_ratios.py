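"""Gene-set overlap enrichment and polysomal-to-cytoplasmic ratio statistics.

The enrichment question is of the form "is the set of translationally
repressed genes enriched for ISGs?": fold enrichment is the observed
overlap relative to the expectation under independence, and the p-value is
the exact hypergeometric upper tail (one-sided, enrichment) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ValidationError

log = logging.getLogger("polyapv.enrichment")


@dataclass(frozen=True)
class EnrichmentResult:
    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    fold_enrichment: float
    p_value: float

    def __post_init__(self):
        if not (0 <= self.n_overlap <= min(self.n_set_a, self.n_set_b)
                <= self.n_universe):
            raise ValidationError(
                "inconsistent enrichment counts: "
                f"overlap={self.n_overlap} |A|={self.n_set_a} "
                f"|B|={self.n_set_b} universe={self.n_universe}"
            )


def overlap_enrichment(
    set_a: Sequence[str],
    set_b: Sequence[str],
    universe: Sequence[str],
    alternative: str = "greater",
) -> EnrichmentResult:
    """Exact hypergeometric overlap test of two gene sets in a universe.

    fold = (overlap/|A|) / (|B|/universe).  ``alternative`` is
    ``"greater"`` (enrichment upper tail, default) or ``"two-sided"``
    (Fisher exact).  Both sets must be subsets of the universe.
    """
    uni = set(map(str, universe))
    if not uni:
        raise ValidationError("universe must be non-empty")
    a = set(map(str, set_a))
    b = set(map(str, set_b))
    stray_a = sorted(a - uni)
    stray_b = sorted(b - uni)
    if stray_a or stray_b:
        raise ValidationError(
            "gene sets are not subsets of the universe; "
            f"offenders in setA: {stray_a[:10]}, in setB: {stray_b[:10]}"
        )
    M, nA, nB = len(uni), len(a), len(b)
    k = len(a & b)
    expected = nA * nB / M
    fold = (k / expected) if expected > 0 else (np.inf if k else 0.0)
    if alternative == "greater":
        p = float(stats.hypergeom.sf(k - 1, M, nB, nA)) if nA and nB else 1.0
    elif alternative == "two-sided":
        table = [[k, nA - k], [nB - k, M - nA - nB + k]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    p = min(p, 1.0)
    return EnrichmentResult(
        n_universe=M, n_set_a=nA, n_set_b=nB, n_overlap=k,
        fold_enrichment=float(fold), p_value=p,
    )


def correlation_check(
    delta_translation: "pd.Series | dict",
    delta_cytosolic: "pd.Series | dict",
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of per-gene translation changes vs cytosolic
    induction, on the intersection of gene ids.

    Returns (r, scatter table).  Zero variance in either vector yields a
    NaN sentinel (logged) rather than an exception.
    """
    x = pd.Series(delta_translation, dtype=float)
    y = pd.Series(delta_cytosolic, dtype=float)
    common = x.index.intersection(y.index)
    if len(common) < 3:
        raise ValidationError(
            f"need >=3 matched genes, got {len(common)}"
        )
    table = pd.DataFrame({
        "gene_id": common.astype(str),
        "delta_translation": x.loc[common].to_numpy(),
        "delta_cytosolic": y.loc[common].to_numpy(),
    })
    xv = table["delta_translation"].to_numpy()
    yv = table["delta_cytosolic"].to_numpy()
    if np.std(xv) == 0 or np.std(yv) == 0:
        log.warning("correlation_check: zero variance; returning NaN")
        return float("nan"), table
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r, table


@dataclass(frozen=True)
class RatioResult:
    """Group-wise polysomal/cytosolic ratio summaries and the two-sample
    t-test between the two groups."""

    summary: pd.DataFrame  # group, n, mean_ratio, ci_low, ci_high
    t_stat: float
    p_value: float
    groups: tuple[str, str]


def polysomal_cytoplasmic_ratio(
    poly_abundance: Sequence[float],
    cyto_abundance: Sequence[float],
    group_labels: Sequence[str],
    welch: bool = False,
    conf_level: float = 0.95,
) -> RatioResult:
    """Per-replicate poly/cyto ratios compared between two groups.

    Abundances are linear-scale (e.g. qPCR ng); each replicate contributes
    one ratio.  The two groups are compared with a two-sided two-sample
    t-test (pooled variance by default, Welch optional); per-group 95% CIs
    use the t quantile on the replicate ratios.
    """
    poly = np.asarray(poly_abundance, dtype=float)
    cyto = np.asarray(cyto_abundance, dtype=float)
    labels = np.asarray(group_labels)
    if not (poly.shape == cyto.shape == labels.shape):
        raise ValidationError("poly, cyto and group_labels must align")
    if np.any(cyto == 0):
        bad = np.nonzero(cyto == 0)[0]
        raise ValidationError(
            f"zero cytosolic abundance at replicate index(es) {list(bad)}"
        )
    ratios = poly / cyto
    group_names: list[str] = []
    for g in labels:
        if g not in group_names:
            group_names.append(g)
    if len(group_names) != 2:
        raise ValidationError(
            f"exactly two groups are required, got {group_names}"
        )
    rows = []
    per_group = []
    for g in group_names:
        r = ratios[labels == g]
        if r.size < 2:
            raise ValidationError(
                f"group {g!r} has {r.size} replicate(s); >=2 required"
            )
        per_group.append(r)
        mean = r.mean()
        se = r.std(ddof=1) / np.sqrt(r.size)
        tq = stats.t.ppf(0.5 + conf_level / 2.0, r.size - 1)
        rows.append({
            "group": g, "n": int(r.size), "mean_ratio": float(mean),
            "ci_low": float(mean - tq * se), "ci_high": float(mean + tq * se),
        })
    r1, r2 = per_group
    t_stat, p = stats.ttest_ind(r1, r2, equal_var=not welch)
    return RatioResult(
        summary=pd.DataFrame(rows),
        t_stat=float(t_stat),
        p_value=float(p),
        groups=(group_names[0], group_names[1]),
    )
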