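"""GFF3 gene models and strand-aware interval lookup.

Gene extent is the GFF3 ``gene`` feature span; tag clusters are assigned to
the strand-matched gene they overlap most. Lookup is backed by one interval
tree per (reference, strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """A gene span in 0-based half-open coordinates."""

    gene_id: str
    reference: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class GeneIndex:
    """Interval lookup over gene models, keyed by (reference, strand)."""

    def __init__(self, genes: List[GeneModel], stranded: bool = True):
        self.stranded = stranded
        self.genes: Dict[str, GeneModel] = {}
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene ID {g.gene_id!r}")
            self.genes[g.gene_id] = g
            key = (g.reference, g.strand if stranded else ".")
            self._trees.setdefault(key, IntervalTree()).addi(g.start, g.end, g)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def references(self) -> Tuple[str, ...]:
        return tuple(sorted({g.reference for g in self.genes.values()}))

    def overlapping_genes(
        self, reference: str, strand: str, start: int, end: int
    ) -> List[Tuple[GeneModel, int]]:
        """Strand-matched genes overlapping [start, end), with overlap length.

        Sorted by overlap length descending, ties by gene_id. Unknown
        references yield an empty list with a logged warning.
        """
        if end <= start:
            raise ValueError("query interval must be non-empty")
        key = (reference, strand if self.stranded else ".")
        tree = self._trees.get(key)
        if tree is None:
            if not any(ref == reference for ref, _ in self._trees):
                logger.warning("query reference %r not in annotation", reference)
            return []
        hits = []
        for iv in tree.overlap(start, end):
            g: GeneModel = iv.data
            ov = min(end, g.end) - max(start, g.start)
            hits.append((g, ov))
        hits.sort(key=lambda t: (-t[1], t[0].gene_id))
        return hits


def load_annotation(
    path: str | Path,
    feature_type: str = "gene",
    stranded: bool = True,
) -> GeneIndex:
    """Parse a GFF3 file into a :class:`GeneIndex`.

    One :class:`GeneModel` per feature of ``feature_type``; GFF3 1-based
    inclusive coordinates become 0-based half-open. Fails if no feature of
    that type exists (the error names the types that do) or on duplicate IDs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    genes: List[GeneModel] = []
    for feat in db.features_of_type(feature_type):
        ids = feat.attributes.get("ID")
        gene_id = ids[0] if ids else feat.id
        genes.append(
            GeneModel(
                gene_id=gene_id,
                reference=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand,
            )
        )
    if not genes:
        found = sorted({f.featuretype for f in db.all_features()})
        raise AnnotationError(
            f"no {feature_type!r} features in {path}; found types: {found}"
        )
    return GeneIndex(genes, stranded=stranded)
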