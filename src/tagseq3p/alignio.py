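"""Reading aligned tag reads and post-alignment quality filtering.

3'-tag libraries produce one short single-end read per transcript, anchored
near the polyadenylation site. After splice-aware alignment, low-quality
mappings are removed with three per-read criteria, all relative to the read
length taken from the CIGAR string:

* the aligned (matching) portion must exceed ``min_match_frac`` of the read,
* the mismatch count (NM tag) must be strictly below ``max_mismatches``,
* the aligner score (AS tag) must exceed ``min_score_frac`` of the read.

Multi-mapping reads (NH > 1) are dropped by default because tag counting is
only well defined for uniquely placed reads.

All internal coordinates are 0-based half-open; SAM's 1-based inclusive
positions are converted on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Tuple

import pysam

logger = logging.getLogger(__name__)

# CIGAR ops, per the SAM spec numeric encoding used by pysam.
_CIGAR_OPS = "MIDNSHP=X"
_QUERY_CONSUMING = frozenset("MIS=X")
_REFERENCE_CONSUMING = frozenset("MDN=X")
_MATCH_OPS = frozenset("M=X")

Cigar = Tuple[Tuple[str, int], ...]


class AlignmentFormatError(ValueError):
    """Raised for unparseable alignment input."""


class ReferenceMismatchError(ValueError):
    """Raised when records reference names absent from the header/annotation."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned tag read.

    ``start`` is 0-based; ``end`` is derived from the reference-consuming
    CIGAR operations. ``sequence`` is stored in file orientation, i.e. the
    reverse complement of the original read for minus-strand alignments.
    """

    query_id: str
    reference: str
    start: int
    cigar: Cigar
    strand: str
    sequence: Optional[str] = None
    n_mismatches: Optional[int] = None
    align_score: Optional[float] = None
    n_hits: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for op, length in self.cigar:
            if op not in _CIGAR_OPS:
                raise ValueError(f"unknown CIGAR op {op!r}")
            if length <= 0:
                raise ValueError("CIGAR op lengths must be positive")
        interior = [op for op, _ in self.cigar][1:-1] if len(self.cigar) > 2 else []
        if "S" in interior:
            raise ValueError("soft clips may only appear at the CIGAR ends")

    @property
    def end(self) -> int:
        """Reference end (exclusive)."""
        return self.start + sum(
            n for op, n in self.cigar if op in _REFERENCE_CONSUMING
        )

    @property
    def read_length(self) -> int:
        """Full read length in nt (query-consuming CIGAR ops)."""
        return sum(n for op, n in self.cigar if op in _QUERY_CONSUMING)

    def soft_clips(self) -> Tuple[int, int]:
        """(leading, trailing) soft-clip lengths."""
        lead = self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0
        trail = (
            self.cigar[-1][1]
            if len(self.cigar) > 1 and self.cigar[-1][0] == "S"
            else 0
        )
        return lead, trail


@dataclass(frozen=True)
class FilterPolicy:
    """Post-alignment quality thresholds.

    Comparisons are strict: matched fraction and score fraction must exceed
    their bounds, and the mismatch count must be strictly below
    ``max_mismatches`` ("less than 4" with the default).
    """

    min_match_frac: float = 0.5
    max_mismatches: int = 4
    min_score_frac: float = 0.66
    unique_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_match_frac <= 1:
            raise ValueError("min_match_frac must be in (0, 1]")
        if not 0 < self.min_score_frac <= 1:
            raise ValueError("min_score_frac must be in (0, 1]")
        if self.max_mismatches < 1:
            raise ValueError("max_mismatches must be >= 1")


@dataclass
class FilterBreakdown:
    """Per-criterion outcome of one filter evaluation.

    Each field is True (passed), False (failed) or None (criterion skipped
    because the required tag was absent).
    """

    match_frac: Optional[bool] = None
    mismatches: Optional[bool] = None
    score: Optional[bool] = None
    unique: Optional[bool] = None
    skipped: Tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return all(v is not False for v in
                   (self.match_frac, self.mismatches, self.score, self.unique))


def matched_length(record: AlignmentRecord) -> int:
    """Number of query bases aligned to the reference (M/=/X ops)."""
    return sum(n for op, n in record.cigar if op in _MATCH_OPS)


def passes_filters(
    record: AlignmentRecord, policy: FilterPolicy = FilterPolicy()
) -> Tuple[bool, FilterBreakdown]:
    """Evaluate the three quality criteria plus the uniqueness requirement.

    A criterion whose tag is absent from the record is skipped (counted in
    ``breakdown.skipped`` and logged once per criterion kind), never silently
    treated as a pass or fail of the others.
    """
    bd = FilterBreakdown()
    skipped = []
    rl = record.read_length
    bd.match_frac = matched_length(record) > policy.min_match_frac * rl

    if record.n_mismatches is None:
        skipped.append("mismatches")
        logger.warning(
            "record %s lacks an NM tag; mismatch criterion skipped",
            record.query_id,
        )
    else:
        bd.mismatches = record.n_mismatches < policy.max_mismatches

    if record.align_score is None:
        skipped.append("score")
        logger.warning(
            "record %s lacks an AS tag; score criterion skipped",
            record.query_id,
        )
    else:
        bd.score = record.align_score > policy.min_score_frac * rl

    if policy.unique_only:
        if record.n_hits is None:
            skipped.append("unique")
            logger.warning(
                "record %s lacks an NH tag; uniqueness criterion skipped",
                record.query_id,
            )
        else:
            bd.unique = record.n_hits == 1

    bd.skipped = tuple(skipped)
    return bd.passed, bd


def filter_records(
    records: Iterable[AlignmentRecord], policy: FilterPolicy = FilterPolicy()
) -> Iterator[AlignmentRecord]:
    """Yield only records passing :func:`passes_filters`."""
    for rec in records:
        ok, _ = passes_filters(rec, policy)
        if ok:
            yield rec


def _from_pysam(seg: pysam.AlignedSegment, reference: str) -> AlignmentRecord:
    cigar = tuple(
        (_CIGAR_OPS[op], length) for op, length in (seg.cigartuples or ())
    )
    return AlignmentRecord(
        query_id=seg.query_name or "",
        reference=reference,
        start=seg.reference_start,
        cigar=cigar,
        strand="-" if seg.is_reverse else "+",
        sequence=seg.query_sequence,
        n_mismatches=seg.get_tag("NM") if seg.has_tag("NM") else None,
        align_score=seg.get_tag("AS") if seg.has_tag("AS") else None,
        n_hits=seg.get_tag("NH") if seg.has_tag("NH") else None,
    )


def reference_names(path: str | Path) -> Tuple[str, ...]:
    """Reference sequence names declared in the SAM/BAM header."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return tuple(fh.references)


def read_alignments(
    path: str | Path,
    region: Optional[Tuple[str, int, int]] = None,
) -> Iterator[AlignmentRecord]:
    """Stream mapped records from a SAM/BAM file.

    Unmapped records are skipped. ``region`` (reference, start, end) requires
    a coordinate-sorted, indexed BAM. Records naming a reference absent from
    the header raise :class:`ReferenceMismatchError` (pysam normally enforces
    this at parse time already).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        fh = pysam.AlignmentFile(str(path), check_sq=False)
    except (ValueError, OSError) as exc:
        raise AlignmentFormatError(f"cannot parse {path}: {exc}") from exc
    try:
        known = set(fh.references)
        it = fh.fetch(*region) if region is not None else fh
        for seg in it:
            if seg.is_unmapped:
                continue
            ref = seg.reference_name
            if ref not in known:
                raise ReferenceMismatchError(
                    f"record {seg.query_name} references unknown sequence {ref!r}"
                )
            yield _from_pysam(seg, ref)
    finally:
        fh.close()


def read_sample_sheet(path: str | Path):
    """Load a headered delimited sample sheet.

    Required columns: sample_id, path, genotype, time_point, replicate.
    Delimiter is sniffed between tab and comma.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"sample_id", "path", "genotype", "time_point", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"sample sheet {path} missing columns: {sorted(missing)}"
        )
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s) in sheet: {dups}")
    return df
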