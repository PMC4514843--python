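"""Seeded synthetic experiments with the structure the analysis assumes.

Per gene g a residual variance sigma_g^2 is drawn from an inverse-gamma
distribution (equivalently the precision 1/sigma_g^2 is gamma with rate
``var_scale``), a baseline is drawn, and for every (condition, replicate):

    C = baseline + delta_cytosolic * [IFN condition]            + N(0, sigma_g)
    P = intercept + slope * C + delta_translation * [inhibitor] + N(0, sigma_g)

Condition effects are additive on the log2 scale.  The polysome-specific
shift is applied in inhibitor-containing conditions (BUFFERED genes are
the exception: their shift tracks the IFN conditions so that a cytosolic
change leaves polysomes flat).  Everything is deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    AnalysisSettings,
    DesignError,
    ExpressionMatrix,
    Fraction,
    SampleDesign,
    ValidationError,
)
from .motif import MotifLabel, TssRecord, classify_tss

log = logging.getLogger("polyapv.synthetic")

PURINES = "AG"
PYRIMIDINES_STR = "CT"


class GeneClass(str, Enum):
    NULL = "NULL"
    TOP_REPRESSED = "TOP_REPRESSED"
    ISG = "ISG"
    ISG_TOP_SWITCH = "ISG_TOP_SWITCH"
    BUFFERED = "BUFFERED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GeneClassSpec:
    """A block of genes sharing planted effects.

    ``delta_translation`` is the polysome-specific log2 shift (applied in
    inhibitor conditions, or in IFN conditions for BUFFERED genes);
    ``delta_cytosolic`` is the IFN induction in log2 units.
    """

    label: GeneClass
    n_genes: int
    delta_translation: float = 0.0
    delta_cytosolic: float = 0.0
    slope: float = 1.0

    def __post_init__(self):
        if self.n_genes < 0:
            raise ValidationError("n_genes must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Variance / baseline hyperparameters.

    Per-gene variances follow InvGamma(shape=var_shape, scale=var_scale),
    i.e. precisions follow Gamma(shape=var_shape, rate=var_scale).  In the
    scale parameterization used by the RVM fitter this corresponds to
    precision ~ Gamma(a=var_shape, scale=1/var_scale).
    """

    var_shape: float = 3.0
    var_scale: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0

    def __post_init__(self):
        if self.var_shape <= 1.0:
            raise ValidationError(
                "var_shape must exceed 1 so gene variances have finite mean"
            )
        if self.var_scale <= 0:
            raise ValidationError("var_scale must be positive")

    @property
    def rvm_a(self) -> float:
        """Precision-gamma shape in the RVM fitter's convention."""
        return self.var_shape

    @property
    def rvm_b(self) -> float:
        """Precision-gamma scale in the RVM fitter's convention."""
        return 1.0 / self.var_scale

    @property
    def mean_variance(self) -> float:
        return self.var_scale / (self.var_shape - 1.0)


@dataclass
class SyntheticTruth:
    """Planted per-gene labels, effects and motif assignments."""

    frame: pd.DataFrame  # gene_id, label, delta_translation, delta_cytosolic,
    #                      slope, sigma_sq, motif_class, motif_class_ifn

    def genes_with_label(self, label: "GeneClass | str") -> list[str]:
        lab = GeneClass(label).value
        return list(self.frame.loc[self.frame["label"] == lab, "gene_id"])

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read(path) -> "SyntheticTruth":
        return SyntheticTruth(pd.read_csv(path, sep="\t"))


def _condition_roles(
    conditions: Sequence[str],
    ifn_conditions: Optional[Iterable[str]] = None,
    inhibitor_conditions: Optional[Iterable[str]] = None,
) -> tuple[set[str], set[str]]:
    """Which conditions carry IFN induction / inhibitor repression.

    Inferred from the label text ("ifn" / "torin" or "rapa" substrings,
    case-insensitive) unless given explicitly.
    """
    if ifn_conditions is None:
        ifn = {c for c in conditions if "ifn" in c.lower()}
    else:
        ifn = set(ifn_conditions)
    if inhibitor_conditions is None:
        inhib = {c for c in conditions
                 if "torin" in c.lower() or "rapa" in c.lower()}
    else:
        inhib = set(inhibitor_conditions)
    return ifn, inhib


_MOTIF_FOR_LABEL = {
    GeneClass.NULL: MotifLabel.NON_TOP,
    GeneClass.ISG: MotifLabel.NON_TOP,
    GeneClass.BUFFERED: MotifLabel.NON_TOP,
}


def _assign_motifs(labels: Sequence[GeneClass]) -> tuple[list[str], list[str]]:
    """Motif class per gene (default condition, IFN condition).

    TOP_REPRESSED genes alternate TOP / TOP_LIKE; switch genes are
    NON_TOP by default and TOP_LIKE under IFN.
    """
    default: list[str] = []
    under_ifn: list[str] = []
    n_top_seen = 0
    for lab in labels:
        if lab == GeneClass.TOP_REPRESSED:
            cls = MotifLabel.TOP if n_top_seen % 2 == 0 else MotifLabel.TOP_LIKE
            n_top_seen += 1
            default.append(cls.value)
            under_ifn.append(cls.value)
        elif lab == GeneClass.ISG_TOP_SWITCH:
            default.append(MotifLabel.NON_TOP.value)
            under_ifn.append(MotifLabel.TOP_LIKE.value)
        else:
            cls = _MOTIF_FOR_LABEL[lab]
            default.append(cls.value)
            under_ifn.append(cls.value)
    return default, under_ifn


def generate_experiment(
    classes: Sequence[GeneClassSpec],
    noise: NoiseSpec,
    conditions: Sequence[str],
    n_replicates: int,
    seed: int,
    intercept: float = 0.0,
    ifn_conditions: Optional[Iterable[str]] = None,
    inhibitor_conditions: Optional[Iterable[str]] = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a paired cytosolic/polysomal expression experiment."""
    conditions = list(conditions)
    if len(conditions) < 2:
        raise DesignError(">=2 conditions are required")
    if n_replicates < 2:
        raise DesignError(">=2 replicates are required")
    labels_seen = [c.label for c in classes]
    if len(set(labels_seen)) != len(labels_seen):
        raise ValidationError("class labels must be unique within a config")
    n_genes = sum(c.n_genes for c in classes)
    if n_genes == 0:
        raise ValidationError("at least one gene is required")

    ifn_set, inhib_set = _condition_roles(
        conditions, ifn_conditions, inhibitor_conditions
    )
    log.info("simulating %d genes x %d conditions x %d replicates "
             "(IFN: %s; inhibitor: %s)", n_genes, len(conditions),
             n_replicates, sorted(ifn_set), sorted(inhib_set))

    width = max(4, len(str(n_genes)))
    gene_ids = []
    gene_labels: list[GeneClass] = []
    d_trans = np.empty(n_genes)
    d_cyto = np.empty(n_genes)
    slopes = np.empty(n_genes)
    i = 0
    for spec in classes:
        for _ in range(spec.n_genes):
            gene_ids.append(f"G{i + 1:0{width}d}")
            gene_labels.append(spec.label)
            d_trans[i] = spec.delta_translation
            d_cyto[i] = spec.delta_cytosolic
            slopes[i] = spec.slope
            i += 1

    rng = np.random.default_rng(seed)
    # variance ~ InvGamma(shape, scale) == scale / Gamma(shape, 1)
    sigma_sq = noise.var_scale / rng.gamma(noise.var_shape, 1.0, size=n_genes)
    sigma = np.sqrt(sigma_sq)
    baseline = rng.normal(noise.baseline_mean, noise.baseline_sd, size=n_genes)

    n_per_frac = len(conditions) * n_replicates
    eps_c = rng.standard_normal((n_genes, n_per_frac)) * sigma[:, None]
    eps_p = rng.standard_normal((n_genes, n_per_frac)) * sigma[:, None]

    is_buffered = np.array(
        [lab == GeneClass.BUFFERED for lab in gene_labels]
    )

    C = np.empty((n_genes, n_per_frac))
    P = np.empty((n_genes, n_per_frac))
    col = 0
    design_rows = []
    col_meta = []
    for cond in conditions:
        in_ifn = cond in ifn_set
        in_inhib = cond in inhib_set
        # BUFFERED genes take their polysome shift with the IFN conditions
        trans_on = np.where(is_buffered, float(in_ifn), float(in_inhib))
        for rep in range(1, n_replicates + 1):
            C[:, col] = baseline + d_cyto * float(in_ifn) + eps_c[:, col]
            P[:, col] = (
                intercept + slopes * C[:, col] + d_trans * trans_on
                + eps_p[:, col]
            )
            col_meta.append((cond, rep))
            col += 1

    for frac, block in ((Fraction.CYTOSOLIC, "cyto"), (Fraction.POLYSOMAL, "poly")):
        for cond, rep in col_meta:
            design_rows.append({
                "sample_id": f"{block}_{cond}_r{rep}",
                "fraction": frac.value,
                "condition": cond,
                "replicate": rep,
            })
    design = SampleDesign.from_frame(pd.DataFrame(design_rows))
    values = np.concatenate([C, P], axis=1)
    matrix = ExpressionMatrix(
        gene_ids=np.array(gene_ids, dtype=object), values=values, design=design
    )

    motif_default, motif_ifn = _assign_motifs(gene_labels)
    truth = SyntheticTruth(pd.DataFrame({
        "gene_id": gene_ids,
        "label": [lab.value for lab in gene_labels],
        "delta_translation": d_trans,
        "delta_cytosolic": d_cyto,
        "slope": slopes,
        "sigma_sq": sigma_sq,
        "motif_class": motif_default,
        "motif_class_ifn": motif_ifn,
    }))
    return matrix, truth


# ---------------------------------------------------------------------------
# TSS sequence generation
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[j] for j in rng.integers(0, len(alphabet), size=n))


def _make_top(rng: np.random.Generator, settings: AnalysisSettings) -> str:
    run_len = int(rng.integers(settings.top_min_run,
                               min(settings.top_max_run, 12) + 1))
    return (
        "C"
        + _random_bases(rng, PYRIMIDINES_STR, run_len)
        + _random_bases(rng, PURINES, 1)
        + _random_bases(rng, "ACGT", 8)
    )


def _make_top_like(rng: np.random.Generator, settings: AnalysisSettings) -> str:
    # purine first base rules TOP out; the stretch then starts at position 2
    run_len = int(rng.integers(settings.toplike_min_run,
                               settings.toplike_min_run + 6))
    return (
        _random_bases(rng, PURINES, 1)
        + _random_bases(rng, PYRIMIDINES_STR, run_len)
        + _random_bases(rng, PURINES, 1)
        + _random_bases(rng, "ACGT", 8)
    )


def _make_non_top(rng: np.random.Generator, settings: AnalysisSettings) -> str:
    guard = settings.toplike_max_start + 1
    if rng.random() < 0.5:
        # purine-only cap region; any downstream run starts after the window
        prefix = _random_bases(rng, PURINES, guard)
    else:
        # short pyrimidine run (below toplike_min_run) then purines
        k = int(rng.integers(2, min(settings.toplike_max_start,
                                    settings.toplike_min_run - 1) + 1))
        prefix = (
            _random_bases(rng, PYRIMIDINES_STR, k)
            + _random_bases(rng, PURINES, guard - k)
        )
    return prefix + _random_bases(rng, "ACGT", 8)


_BUILDERS = {
    MotifLabel.TOP: _make_top,
    MotifLabel.TOP_LIKE: _make_top_like,
    MotifLabel.NON_TOP: _make_non_top,
}


def generate_tss_sequences(
    truth: SyntheticTruth,
    settings: Optional[AnalysisSettings] = None,
    seed: int = 0,
) -> list[TssRecord]:
    """Emit cap-anchored sequences whose classification matches the truth.

    ISG_TOP_SWITCH genes yield two records per gene: a ``control``
    condition variant (NON_TOP) and an ``IFN`` variant (TOP_LIKE).  Each
    emitted sequence is verified against the classifier before release.
    """
    if settings is None:
        settings = AnalysisSettings()
    rng = np.random.default_rng(seed)
    records: list[TssRecord] = []
    for row in truth.frame.itertuples(index=False):
        default_cls = MotifLabel(row.motif_class)
        ifn_cls = MotifLabel(row.motif_class_ifn)
        if default_cls != ifn_cls:
            pairs = [("control", default_cls), ("IFN", ifn_cls)]
        else:
            pairs = [(None, default_cls)]
        for condition, target in pairs:
            seq = _BUILDERS[target](rng, settings)
            got = classify_tss(seq, settings).label
            if got != target:  # pragma: no cover - construction guarantee
                raise RuntimeError(
                    f"generated sequence {seq!r} classifies {got}, "
                    f"wanted {target}"
                )
            records.append(TssRecord(gene_id=row.gene_id, sequence=seq,
                                     condition=condition))
    return records


# ---------------------------------------------------------------------------
# polysome RNA yields
# ---------------------------------------------------------------------------


def simulate_yields(
    conditions: Sequence[str],
    n_replicates: int,
    seed: int,
    cyto_mean: float = 1000.0,
    poly_mean: float = 500.0,
    poly_scale: Optional[dict] = None,
    cv: float = 0.05,
) -> pd.DataFrame:
    """Tidy RNA-yield table (ng) per (condition, replicate, fraction).

    ``poly_scale`` maps condition -> multiplicative factor on the
    polysomal mean (e.g. 0.58 for a strong inhibitor arm).
    """
    if n_replicates < 2:
        raise DesignError(">=2 replicates are required")
    poly_scale = poly_scale or {}
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        factor = float(poly_scale.get(cond, 1.0))
        for rep in range(1, n_replicates + 1):
            cyto = rng.normal(cyto_mean, cv * cyto_mean)
            poly = rng.normal(poly_mean * factor, cv * poly_mean * factor)
            rows.append({"condition": cond, "replicate": rep,
                         "fraction": Fraction.CYTOSOLIC.value,
                         "ng": float(cyto)})
            rows.append({"condition": cond, "replicate": rep,
                         "fraction": Fraction.POLYSOMAL.value,
                         "ng": float(poly)})
    return pd.DataFrame(rows)


def polysome_yield_summary(
    yields: pd.DataFrame, control: str = "control"
) -> pd.DataFrame:
    """Per-(condition, fraction) mean +/- sd, percent change vs control and
    a two-sided Welch t-test against the control condition."""
    required = {"condition", "replicate", "fraction", "ng"}
    missing = required - set(yields.columns)
    if missing:
        raise ValidationError(f"yields table is missing columns: {sorted(missing)}")
    if control not in set(yields["condition"]):
        raise ValidationError(f"control condition {control!r} absent from yields")
    for (cond, frac), grp in yields.groupby(["condition", "fraction"]):
        if len(grp) < 2:
            raise DesignError(
                f"condition {cond!r} fraction {frac!r} has a single replicate"
            )
    rows = []
    for frac, frac_grp in yields.groupby("fraction"):
        ctrl = frac_grp.loc[frac_grp["condition"] == control, "ng"].to_numpy()
        for cond, grp in frac_grp.groupby("condition"):
            vals = grp["ng"].to_numpy()
            if cond == control:
                p = 1.0
            else:
                p = float(stats.ttest_ind(vals, ctrl, equal_var=False)[1])
            rows.append({
                "condition": cond,
                "fraction": frac,
                "n": int(vals.size),
                "mean_ng": float(vals.mean()),
                "sd_ng": float(vals.std(ddof=1)),
                "pct_change_vs_control": float(
                    100.0 * (vals.mean() - ctrl.mean()) / ctrl.mean()
                ),
                "welch_p_vs_control": p,
            })
    out = pd.DataFrame(rows).sort_values(
        ["fraction", "condition"], kind="stable"
    ).reset_index(drop=True)
    return out
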