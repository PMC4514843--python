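"""Classification of 5'-terminal (TSS-anchored) sequences into TOP / TOP-like / non-TOP.

A TOP sequence starts with a cytidine immediately followed by an
uninterrupted pyrimidine run whose length falls within a configurable
window (default 5-15).  A TOP-like sequence instead only needs a
pyrimidine stretch (default length >= 5) that begins close to the cap
(default within the first 4 bases).  Everything else is non-TOP.

Positions are 1-based with position 1 being the first transcribed base.
``N`` is treated as a non-pyrimidine and therefore breaks runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

PYRIMIDINES = frozenset("CT")
VALID_BASES = frozenset("ACGTN")


class SequenceError(ValueError):
    """Raised for empty sequences or characters outside {A,C,G,T,U,N}."""


class MotifLabel(str, Enum):
    TOP = "TOP"
    TOP_LIKE = "TOP_LIKE"
    NON_TOP = "NON_TOP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def normalize_sequence(seq: str, *, name: str = "<sequence>") -> str:
    """Upper-case, map U->T and validate the alphabet.

    Raises :class:`SequenceError` on an empty sequence or characters
    outside {A, C, G, T, U, N}.
    """
    if seq is None or len(seq) == 0:
        raise SequenceError(f"empty sequence for record {name!r}")
    norm = seq.upper().replace("U", "T")
    bad = set(norm) - VALID_BASES
    if bad:
        raise SequenceError(
            f"record {name!r} contains invalid characters: {sorted(bad)!r}"
        )
    return norm


@dataclass(frozen=True)
class TssRecord:
    """A 5'-end sequence anchored at the cap (position 1 = first base)."""

    gene_id: str
    sequence: str
    condition: Optional[str] = None

    def normalized(self) -> "TssRecord":
        return TssRecord(
            gene_id=self.gene_id,
            sequence=normalize_sequence(self.sequence, name=self.gene_id),
            condition=self.condition,
        )


@dataclass(frozen=True)
class MotifClass:
    """Classification outcome plus the diagnostics used to reach it."""

    label: MotifLabel
    first_base: str
    pyrimidine_run_after_c: int
    best_stretch_start: int  # 1-based; 0 when the sequence has no pyrimidines
    best_stretch_len: int


def _maximal_pyrimidine_runs(seq: str) -> list[tuple[int, int]]:
    """All maximal runs of {C,T} as (1-based start, length)."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, base in enumerate(seq):
        if base in PYRIMIDINES:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start + 1, i - start))
            start = None
    if start is not None:
        runs.append((start + 1, len(seq) - start))
    return runs


def classify_tss(record: "TssRecord | str", settings=None) -> MotifClass:
    """Classify one cap-anchored sequence.

    ``record`` may be a :class:`TssRecord` or a bare sequence string.
    ``settings`` is an :class:`polyapv.io_model.AnalysisSettings`; defaults
    are used when omitted.
    """
    from .io_model import AnalysisSettings  # local import avoids a cycle

    if settings is None:
        settings = AnalysisSettings()
    if isinstance(record, str):
        record = TssRecord(gene_id="<anonymous>", sequence=record)
    seq = normalize_sequence(record.sequence, name=record.gene_id)

    decision_window = max(
        settings.toplike_max_start + settings.toplike_min_run,
        1 + settings.top_max_run,
    )
    if "N" in seq[:decision_window]:
        log.warning(
            "sequence for %s has N within the first %d bases; "
            "treated as non-pyrimidine",
            record.gene_id,
            decision_window,
        )

    first_base = seq[0]
    # run of consecutive pyrimidines starting at position 2
    run_after_c = 0
    for base in seq[1:]:
        if base in PYRIMIDINES:
            run_after_c += 1
        else:
            break

    runs = _maximal_pyrimidine_runs(seq)
    near_cap = [r for r in runs if r[0] <= settings.toplike_max_start]
    if near_cap:
        best_start, best_len = max(near_cap, key=lambda r: (r[1], -r[0]))
    elif runs:
        best_start, best_len = max(runs, key=lambda r: (r[1], -r[0]))
    else:
        best_start, best_len = 0, 0

    is_top = first_base == "C" and settings.top_min_run <= run_after_c and (
        run_after_c <= settings.top_max_run or settings.top_allow_long
    )
    if is_top:
        label = MotifLabel.TOP
    elif near_cap and best_len >= settings.toplike_min_run:
        label = MotifLabel.TOP_LIKE
    else:
        label = MotifLabel.NON_TOP

    return MotifClass(
        label=label,
        first_base=first_base,
        pyrimidine_run_after_c=run_after_c,
        best_stretch_start=best_start,
        best_stretch_len=best_len,
    )


def classify_fasta(
    records: Iterable[TssRecord], settings=None
) -> pd.DataFrame:
    """Element-wise :func:`classify_tss` over a batch of records.

    Returns a table with one row per record; per-record errors are
    captured in an ``error`` column instead of aborting the batch.
    Class counts are attached as ``frame.attrs["class_counts"]``.
    """
    rows = []
    for rec in records:
        row = {
            "gene_id": rec.gene_id,
            "condition": rec.condition if rec.condition is not None else "",
        }
        try:
            cls = classify_tss(rec, settings)
            row.update(
                motif_class=cls.label.value,
                first_base=cls.first_base,
                run_after_c=cls.pyrimidine_run_after_c,
                stretch_start=cls.best_stretch_start,
                stretch_len=cls.best_stretch_len,
                error="",
            )
        except SequenceError as exc:
            row.update(
                motif_class="",
                first_base="",
                run_after_c=-1,
                stretch_start=-1,
                stretch_len=-1,
                error=str(exc),
            )
        rows.append(row)
    columns = [
        "gene_id",
        "condition",
        "motif_class",
        "first_base",
        "run_after_c",
        "stretch_start",
        "stretch_len",
        "error",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    counts = {label.value: 0 for label in MotifLabel}
    if len(frame):
        observed = frame.loc[frame["motif_class"] != "", "motif_class"]
        counts.update(observed.value_counts().to_dict())
    frame.attrs["class_counts"] = counts
    return frame


def class_counts(frame: pd.DataFrame) -> dict[str, int]:
    """Summary counts per motif class for a :func:`classify_fasta` table."""
    counts = {label.value: 0 for label in MotifLabel}
    if len(frame):
        observed = frame.loc[frame["motif_class"] != "", "motif_class"]
        counts.update(observed.value_counts().to_dict())
    return counts
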