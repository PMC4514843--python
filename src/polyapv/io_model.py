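"""Shared data types, file readers/writers, settings and logging.

File dialect: tab-separated UTF-8 text with "." as the decimal mark.
Expression matrices carry gene ids in the first column and one column per
sample; the companion design table binds each sample to a fraction,
condition and replicate.  All expression values are log2-scale; upstream
normalization is out of scope and inputs are assumed normalized.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .motif import TssRecord, normalize_sequence, SequenceError

log = logging.getLogger("polyapv")

DESIGN_COLUMNS = ["sample_id", "fraction", "condition", "replicate"]


def configure_logging(level: int = logging.INFO) -> None:
    """Route package logging to stderr with a terse stage-oriented format."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    root = logging.getLogger("polyapv")
    root.handlers[:] = [handler]
    root.setLevel(level)


# ---------------------------------------------------------------------------
# validation errors (one named class per malformed-input case)
# ---------------------------------------------------------------------------


class ValidationError(ValueError):
    """Base class for input-validation failures."""


class UnknownFractionError(ValidationError):
    """Design row with a fraction label outside {cytosolic, polysomal}."""


class SampleMismatchError(ValidationError):
    """Sample present in the matrix but not the design, or vice versa."""


class DuplicateGeneIdError(ValidationError):
    """Matrix with a repeated gene identifier."""


class NonNumericValueError(ValidationError):
    """Matrix cell that cannot be parsed as a finite number."""


class DesignError(ValidationError):
    """Structurally invalid design (unpaired fractions, <2 replicates...)."""


class Fraction(str, Enum):
    CYTOSOLIC = "cytosolic"
    POLYSOMAL = "polysomal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """One row per sample: (sample_id, fraction, condition, replicate).

    Invariant: within each condition, every replicate index owns exactly
    one cytosolic and one polysomal sample, and every condition has at
    least two replicates.
    """

    frame: pd.DataFrame

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> "SampleDesign":
        missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
        if missing:
            raise DesignError(f"design is missing columns: {missing}")
        frame = frame[DESIGN_COLUMNS].copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["fraction"] = frame["fraction"].astype(str)
        frame["condition"] = frame["condition"].astype(str)

        bad_fraction = sorted(
            set(frame["fraction"]) - {f.value for f in Fraction}
        )
        if bad_fraction:
            raise UnknownFractionError(
                f"unknown fraction label(s): {bad_fraction}"
            )
        try:
            frame["replicate"] = frame["replicate"].astype(int)
        except (TypeError, ValueError) as exc:
            raise DesignError(f"non-integer replicate column: {exc}") from exc
        if (frame["replicate"] < 1).any():
            raise DesignError("replicate indices must be positive integers")
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"]
            raise DesignError(f"duplicate sample ids: {sorted(set(dups))}")

        for (cond, rep), grp in frame.groupby(["condition", "replicate"]):
            fracs = sorted(grp["fraction"])
            if fracs != [Fraction.CYTOSOLIC.value, Fraction.POLYSOMAL.value]:
                raise DesignError(
                    f"condition {cond!r} replicate {rep} must have exactly one "
                    f"cytosolic and one polysomal sample, found {fracs}"
                )
        for cond, grp in frame.groupby("condition"):
            n_rep = grp["replicate"].nunique()
            if n_rep < 2:
                raise DesignError(
                    f"condition {cond!r} has {n_rep} replicate(s); >=2 required"
                )
        return SampleDesign(frame.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.frame["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def n_replicates(self, condition: str) -> int:
        sub = self.frame[self.frame["condition"] == condition]
        return int(sub["replicate"].nunique())

    def select(
        self,
        fraction: "Fraction | str",
        conditions: Optional[Sequence[str]] = None,
    ) -> pd.DataFrame:
        """Design rows for one fraction (optionally restricted to conditions),
        sorted by (condition order given, replicate) so that cytosolic and
        polysomal selections pair positionally."""
        frac = Fraction(fraction).value
        sub = self.frame[self.frame["fraction"] == frac]
        if conditions is not None:
            sub = sub[sub["condition"].isin(conditions)]
            order = {c: i for i, c in enumerate(conditions)}
            sub = sub.assign(_ord=sub["condition"].map(order))
            sub = sub.sort_values(["_ord", "replicate"]).drop(columns="_ord")
        else:
            sub = sub.sort_values(["condition", "replicate"])
        return sub.reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """genes x samples log2 abundances bound to a :class:`SampleDesign`.

    Columns are stored in design order; values are finite floats.
    """

    gene_ids: np.ndarray
    values: np.ndarray
    design: SampleDesign

    def __post_init__(self):
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D genes x samples array")
        if len(gene_ids) != values.shape[0]:
            raise ValidationError(
                f"{len(gene_ids)} gene ids but {values.shape[0]} matrix rows"
            )
        if values.shape[1] != len(self.design.frame):
            raise SampleMismatchError(
                f"matrix has {values.shape[1]} sample columns but the design "
                f"has {len(self.design.frame)} rows"
            )
        uniq, counts = np.unique(gene_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            raise DuplicateGeneIdError(
                f"duplicate gene ids: {list(uniq[counts > 1])[:10]}"
            )
        if not np.isfinite(values).all():
            n_bad = int((~np.isfinite(values)).sum())
            raise NonNumericValueError(
                f"{n_bad} non-finite expression value(s) in matrix"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def submatrix(
        self,
        fraction: "Fraction | str",
        conditions: Optional[Sequence[str]] = None,
    ) -> tuple[np.ndarray, pd.DataFrame]:
        """Values (genes x selected samples) and the matching design rows,
        ordered by (condition, replicate)."""
        sub = self.design.select(fraction, conditions)
        col_index = {s: i for i, s in enumerate(self.design.sample_ids)}
        cols = [col_index[s] for s in sub["sample_id"]]
        return self.values[:, cols], sub


# ---------------------------------------------------------------------------
# analysis settings
# ---------------------------------------------------------------------------


@dataclass
class AnalysisSettings:
    """All tunable thresholds of the pipeline, with study defaults."""

    minSlope: float = -1.0
    maxSlope: float = 2.0
    slopeP: float = 0.01
    maxRvmPAdj: float = 0.15
    selDeltaPT: float = math.log2(1.5)
    isg_fold: float = 1.5
    isg_require_significance: bool = True
    toplike_min_run: int = 5
    toplike_max_start: int = 4
    top_min_run: int = 5
    top_max_run: int = 15
    top_allow_long: bool = False
    min_expression: Optional[float] = None  # optional pre-test filter, off
    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.minSlope < self.maxSlope:
            raise ValidationError("minSlope must be < maxSlope")
        for name in ("slopeP", "maxRvmPAdj"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        for name in ("toplike_min_run", "toplike_max_start", "top_min_run",
                     "top_max_run"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.top_min_run > self.top_max_run:
            raise ValidationError("top_min_run must be <= top_max_run")
        if self.isg_fold <= 0:
            raise ValidationError("isg_fold must be positive")

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in self.__dataclass_fields__  # type: ignore[attr-defined]
        }

    def header_comment(self) -> str:
        """One-line settings echo used at the top of result files."""
        keys = ["minSlope", "maxSlope", "slopeP", "maxRvmPAdj", "selDeltaPT",
                "isg_fold"]
        parts = " ".join(f"{k}={getattr(self, k):g}" for k in keys)
        return f"# settings: {parts}"

    @staticmethod
    def from_dict(d: dict) -> "AnalysisSettings":
        known = set(AnalysisSettings.__dataclass_fields__)  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown settings keys: {sorted(unknown)}")
        return AnalysisSettings(**d)

    @staticmethod
    def from_yaml(path: "str | Path") -> "AnalysisSettings":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "settings" in data:
            data = data["settings"]
        return AnalysisSettings.from_dict(data)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_design(path: "str | Path") -> SampleDesign:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return SampleDesign.from_frame(frame)


def write_design(design: SampleDesign, path: "str | Path") -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def read_expression(
    matrix_path: "str | Path", design_path: "str | Path"
) -> ExpressionMatrix:
    """Read an expression TSV plus its design TSV into a validated matrix.

    The matrix header row holds sample ids and the first column gene ids;
    columns are reordered to follow the design row order.
    """
    design = read_design(design_path)
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#",
                      dtype=str)
    matrix_samples = list(raw.columns.astype(str))
    design_samples = design.sample_ids
    only_matrix = [s for s in matrix_samples if s not in set(design_samples)]
    only_design = [s for s in design_samples if s not in set(matrix_samples)]
    if only_matrix or only_design:
        raise SampleMismatchError(
            "sample mismatch between matrix and design; "
            f"only in matrix: {only_matrix}; only in design: {only_design}"
        )
    raw = raw[design_samples]
    try:
        values = raw.to_numpy(dtype=float)
    except ValueError as exc:
        raise NonNumericValueError(
            f"non-numeric expression cell in {matrix_path}: {exc}"
        ) from exc
    gene_ids = raw.index.astype(str).to_numpy(dtype=object)
    matrix = ExpressionMatrix(gene_ids=gene_ids, values=values, design=design)
    log.info("read expression matrix %d genes x %d samples from %s",
             matrix.n_genes, matrix.n_samples, matrix_path)
    return matrix


def write_expression(
    matrix: ExpressionMatrix,
    matrix_path: "str | Path",
    design_path: "str | Path | None" = None,
) -> None:
    frame = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.gene_ids, name="gene_id"),
        columns=matrix.design.sample_ids,
    )
    # default pandas float repr round-trips exactly under python 3
    frame.to_csv(matrix_path, sep="\t")
    if design_path is not None:
        write_design(matrix.design, design_path)


def read_fasta_tss(path: "str | Path") -> list[TssRecord]:
    """Read cap-anchored sequences; headers are ``gene_id`` or
    ``gene_id|condition``.  Sequences are upper-cased with U mapped to T."""
    records: list[TssRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        condition: Optional[str] = None
        if "|" in header:
            gene_id, condition = header.split("|", 1)
        else:
            gene_id = header
        seq = normalize_sequence(str(rec.seq), name=header)
        records.append(TssRecord(gene_id=gene_id, sequence=seq,
                                 condition=condition))
    return records


def write_fasta_tss(records: Iterable[TssRecord], path: "str | Path") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            header = rec.gene_id
            if rec.condition is not None:
                header = f"{rec.gene_id}|{rec.condition}"
            fh.write(f">{header}\n{rec.sequence}\n")


def read_gene_set(path: "str | Path") -> list[str]:
    """Plain-text gene set, one id per line; blank lines and '#' comments
    are skipped; order preserved, duplicates dropped."""
    out: dict[str, None] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.setdefault(token, None)
    return list(out)


def write_gene_set(genes: Iterable[str], path: "str | Path") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_result_table(
    frame: pd.DataFrame,
    path: "str | Path",
    settings: Optional[AnalysisSettings] = None,
    extra_comments: Sequence[str] = (),
) -> None:
    """Write a results TSV with a commented settings header block."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if settings is not None:
            fh.write(settings.header_comment() + "\n")
        for line in extra_comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_result_table(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
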