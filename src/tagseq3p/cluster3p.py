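"""Overlap-cluster quantification of 3'-tag reads with polyA validation.

The quantifier groups filtered read hits into maximal overlap clusters per
(reference, strand) and sample. Because a templated polyA tail appears in
the alignment as an A-rich soft clip (T-rich leading clip on the minus
strand, where the file stores the reverse complement), tail-carrying reads
mark a cluster as a genuine transcript 3' end. Clusters are matched across
biological replicates by interval overlap into meta-clusters; a
meta-cluster is kept when the polyA evidence satisfies the replicate rule,
and its reads are counted toward the strand-matched gene it overlaps most.

The replicate rule has two interpretations, both available:

* ``per_replicate`` (default): at least one replicate's cluster individually
  contains >= ``min_polya_reads`` tailed reads;
* ``pooled``: the tailed reads summed over replicates reach the bound.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignio import (
    AlignmentRecord,
    FilterPolicy,
    read_alignments,
    passes_filters,
)
from .annot import GeneIndex, load_annotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PolyAPolicy:
    """Thresholds for calling a soft clip a polyA tail.

    ``min_tail`` is the minimum clip length in nt; ``min_purity`` the
    minimum fraction of A (or T on the minus strand) in the clip. Defaults
    reject short adventitious clips while tolerating one sequencing error
    in tails of 10 nt or more.
    """

    min_tail: int = 5
    min_purity: float = 0.9

    def __post_init__(self) -> None:
        if self.min_tail < 1:
            raise ValueError("min_tail must be >= 1")
        if not 0 < self.min_purity <= 1:
            raise ValueError("min_purity must be in (0, 1]")


@dataclass
class TagCluster:
    """A maximal run of overlapping read hits from one sample."""

    sample_id: str
    reference: str
    strand: str
    start: int
    end: int
    n_reads: int
    n_polya_reads: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("a cluster holds at least one read")
        if not 0 <= self.n_polya_reads <= self.n_reads:
            raise ValueError("0 <= n_polya_reads <= n_reads required")

    def overlaps(self, other: "TagCluster") -> bool:
        return (
            self.reference == other.reference
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class MetaCluster:
    """Replicate-matched clusters on one (reference, strand)."""

    reference: str
    strand: str
    start: int
    end: int
    members: List[TagCluster] = field(default_factory=list)
    validated: bool = False

    def polya_counts(self) -> List[int]:
        return [m.n_polya_reads for m in self.members]

    def reads_by_sample(self) -> Dict[str, int]:
        out: Dict[str, int] = defaultdict(int)
        for m in self.members:
            out[m.sample_id] += m.n_reads
        return dict(out)

    @property
    def total_reads(self) -> int:
        return sum(m.n_reads for m in self.members)


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with sample metadata.

    ``counts`` is a genes x samples DataFrame; ``samples`` is indexed by
    sample_id with columns genotype, time_point, replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns must match sample metadata index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, samples: pd.DataFrame) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(counts=counts, samples=samples.loc[counts.columns])


def detect_polya(
    record: AlignmentRecord, policy: PolyAPolicy = PolyAPolicy()
) -> Tuple[bool, int]:
    """Look for a soft-clipped polyA tail at the transcript 3' end.

    For a plus-strand alignment the tail is the trailing soft clip and is
    A-rich; for a minus-strand alignment it is the leading soft clip and is
    T-rich, because the stored sequence is the reverse complement of the
    read. Returns (has_tail, clip_length); clip_length is 0 when no clip
    exists at the 3' end.
    """
    lead, trail = record.soft_clips()
    if record.strand == "+":
        clip_len = trail
        base = "A"
        clip_seq = (
            record.sequence[-trail:] if trail and record.sequence else ""
        )
    else:
        clip_len = lead
        base = "T"
        clip_seq = record.sequence[:lead] if lead and record.sequence else ""
    if clip_len == 0 or not clip_seq:
        return False, clip_len
    purity = clip_seq.upper().count(base) / len(clip_seq)
    has_tail = clip_len >= policy.min_tail and purity >= policy.min_purity
    return has_tail, clip_len


def build_clusters(
    records: Iterable[AlignmentRecord],
    sample_id: str,
    polya_policy: PolyAPolicy = PolyAPolicy(),
) -> List[TagCluster]:
    """Connected components of the interval-overlap relation.

    Computed per (reference, strand) by a sweep over start-sorted intervals;
    the cluster interval is the union span of its members. Output is ordered
    by (reference, strand, start) and independent of input record order.
    """
    by_key: Dict[Tuple[str, str], List[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        by_key[(rec.reference, rec.strand)].append(rec)

    clusters: List[TagCluster] = []
    for (ref, strand) in sorted(by_key):
        recs = sorted(by_key[(ref, strand)], key=lambda r: (r.start, r.end))
        cur_start = cur_end = None
        cur_n = cur_polya = 0
        for rec in recs:
            tailed = detect_polya(rec, polya_policy)[0]
            if cur_end is not None and rec.start < cur_end:
                cur_end = max(cur_end, rec.end)
                cur_n += 1
                cur_polya += tailed
            else:
                if cur_end is not None:
                    clusters.append(
                        TagCluster(sample_id, ref, strand, cur_start, cur_end,
                                   cur_n, cur_polya)
                    )
                cur_start, cur_end = rec.start, rec.end
                cur_n, cur_polya = 1, int(tailed)
        if cur_end is not None:
            clusters.append(
                TagCluster(sample_id, ref, strand, cur_start, cur_end,
                           cur_n, cur_polya)
            )
    return clusters


def group_replicates(
    clusters_by_sample: Mapping[str, Sequence[TagCluster]],
    replicate_sets: Mapping[str, Iterable[str]],
) -> Dict[str, List[MetaCluster]]:
    """Merge per-sample clusters across biological replicates.

    Within each replicate group, clusters on the same (reference, strand)
    are joined by transitive interval overlap; the meta interval is the
    union span. Returns ``{group_name: [MetaCluster, ...]}``.
    """
    sample_to_group: Dict[str, str] = {}
    for group, sids in replicate_sets.items():
        for sid in sids:
            if sid in sample_to_group:
                raise ValueError(f"sample {sid!r} in more than one group")
            sample_to_group[sid] = group
    unknown = set(clusters_by_sample) - set(sample_to_group)
    if unknown:
        raise ValueError(
            f"samples with clusters but no replicate group: {sorted(unknown)}"
        )

    out: Dict[str, List[MetaCluster]] = {g: [] for g in replicate_sets}
    pooled: Dict[Tuple[str, str, str], List[TagCluster]] = defaultdict(list)
    for sid, clusters in clusters_by_sample.items():
        group = sample_to_group[sid]
        for c in clusters:
            pooled[(group, c.reference, c.strand)].append(c)

    for (group, ref, strand) in sorted(pooled):
        members = sorted(
            pooled[(group, ref, strand)], key=lambda c: (c.start, c.end)
        )
        cur: Optional[MetaCluster] = None
        for c in members:
            if cur is not None and c.start < cur.end:
                cur.end = max(cur.end, c.end)
                cur.members.append(c)
            else:
                if cur is not None:
                    out[group].append(cur)
                cur = MetaCluster(ref, strand, c.start, c.end, [c])
        if cur is not None:
            out[group].append(cur)
    return out


def validate_metacluster(
    meta: MetaCluster,
    min_polya_reads: int = 2,
    mode: str = "per_replicate",
) -> bool:
    """Decide whether a meta-cluster carries sufficient polyA evidence.

    ``per_replicate``: some member cluster individually holds
    >= ``min_polya_reads`` tailed reads. ``pooled``: tailed reads summed
    over members reach the bound. Sets and returns ``meta.validated``.
    """
    if not meta.members:
        raise ValueError("meta-cluster has no members")
    counts = meta.polya_counts()
    if mode == "per_replicate":
        ok = max(counts) >= min_polya_reads
    elif mode == "pooled":
        ok = sum(counts) >= min_polya_reads
    else:
        raise ValueError(f"unknown validation mode {mode!r}")
    meta.validated = ok
    return ok


def assign_and_count(
    metas: Iterable[MetaCluster],
    index: GeneIndex,
    samples: pd.DataFrame,
) -> Tuple[CountMatrix, List[dict]]:
    """Assign validated meta-clusters to genes and tally per-sample counts.

    Each validated meta-cluster goes wholly to the strand-matched gene with
    the largest overlap (ties by gene_id); intergenic clusters are reported
    with coordinates and read totals and excluded from the matrix. Genes
    without a validated cluster keep count 0.
    """
    metas = list(metas)
    known_refs = set(index.references)
    offenders = sorted(
        {m.reference for m in metas} - known_refs
    )
    if offenders:
        raise ValueError(
            f"meta-cluster references absent from annotation: {offenders}"
        )

    gene_ids = list(index.genes)
    sample_ids = list(samples.index)
    counts = pd.DataFrame(
        np.zeros((len(gene_ids), len(sample_ids)), dtype=np.int64),
        index=gene_ids,
        columns=sample_ids,
    )
    intergenic: List[dict] = []
    for i, meta in enumerate(metas):
        if not meta.validated:
            continue
        hits = index.overlapping_genes(
            meta.reference, meta.strand, meta.start, meta.end
        )
        if not hits:
            intergenic.append(
                {
                    "reference": meta.reference,
                    "start": meta.start,
                    "end": meta.end,
                    "name": f"meta_{i}",
                    "score": meta.total_reads,
                    "strand": meta.strand,
                }
            )
            continue
        gene = hits[0][0]
        for sid, n in meta.reads_by_sample().items():
            counts.at[gene.gene_id, sid] += n
    return CountMatrix(counts=counts, samples=samples), intergenic


def write_intergenic_bed(report: List[dict], path: str | Path) -> None:
    """Write the unassigned-cluster report as BED6."""
    with open(path, "w") as fh:
        for row in report:
            fh.write(
                f"{row['reference']}\t{row['start']}\t{row['end']}\t"
                f"{row['name']}\t{row['score']}\t{row['strand']}\n"
            )


@dataclass
class QuantifyResult:
    matrix: CountMatrix
    intergenic: List[dict]
    stage_counts: Dict[str, int]


def quantify(
    sample_sheet: pd.DataFrame,
    annotation: GeneIndex | str | Path,
    filter_policy: FilterPolicy = FilterPolicy(),
    polya_policy: PolyAPolicy = PolyAPolicy(),
    min_polya_reads: int = 2,
    validation_mode: str = "per_replicate",
) -> QuantifyResult:
    """End-to-end driver: alignments to gene x sample count matrix.

    Replicate groups are genotype x time_point; validation is applied within
    each group. The stage-count log records reads and clusters surviving
    each step so the read-conservation invariant can be audited.
    """
    index = (
        annotation
        if isinstance(annotation, GeneIndex)
        else load_annotation(annotation)
    )
    samples = sample_sheet.set_index("sample_id")

    stage = {"reads_mapped": 0, "reads_filtered": 0, "clusters": 0,
             "metaclusters": 0, "metaclusters_validated": 0,
             "reads_assigned": 0, "reads_intergenic": 0,
             "reads_rejected": 0}
    clusters_by_sample: Dict[str, List[TagCluster]] = {}
    for sid, row in samples.iterrows():
        kept: List[AlignmentRecord] = []
        n_mapped = 0
        for rec in read_alignments(row["path"]):
            n_mapped += 1
            if passes_filters(rec, filter_policy)[0]:
                kept.append(rec)
        stage["reads_mapped"] += n_mapped
        stage["reads_filtered"] += len(kept)
        clusters = build_clusters(kept, sid, polya_policy)
        if not clusters:
            logger.warning("sample %s produced no clusters", sid)
        clusters_by_sample[sid] = clusters
        stage["clusters"] += len(clusters)

    replicate_sets: Dict[str, List[str]] = defaultdict(list)
    for sid, row in samples.iterrows():
        replicate_sets[f"{row['genotype']}:{row['time_point']}"].append(sid)

    grouped = group_replicates(clusters_by_sample, replicate_sets)
    all_metas: List[MetaCluster] = []
    for group in sorted(grouped):
        for meta in grouped[group]:
            validate_metacluster(meta, min_polya_reads, validation_mode)
            if not meta.validated:
                stage["reads_rejected"] += meta.total_reads
            all_metas.append(meta)
    stage["metaclusters"] = len(all_metas)
    stage["metaclusters_validated"] = sum(m.validated for m in all_metas)

    matrix, intergenic = assign_and_count(all_metas, index, samples)
    stage["reads_assigned"] = int(matrix.counts.to_numpy().sum())
    stage["reads_intergenic"] = sum(r["score"] for r in intergenic)
    return QuantifyResult(matrix=matrix, intergenic=intergenic,
                          stage_counts=stage)
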