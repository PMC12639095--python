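"""Shared fixtures: synthetic alignments, annotation and count experiments."""

from pathlib import Path

import pytest

from tagseq3p.alignio import AlignmentRecord
from tagseq3p.simdata import SimConfig, simulate_annotation, simulate_tag_reads


def make_record(
    start=100,
    cigar=(("M", 75),),
    strand="+",
    reference="chr1",
    sequence=None,
    query_id="r1",
    n_mismatches=0,
    align_score=75,
    n_hits=1,
):
    return AlignmentRecord(
        query_id=query_id,
        reference=reference,
        start=start,
        cigar=tuple(cigar),
        strand=strand,
        sequence=sequence,
        n_mismatches=n_mismatches,
        align_score=align_score,
        n_hits=n_hits,
    )


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"


def write_sam(path: Path, records: str) -> Path:
    path.write_text(SAM_HEADER + records)
    return path


@pytest.fixture(scope="session")
def sim_fixture(tmp_path_factory):
    """20-gene, 3-replicate noise-free read fixture with full polyA tails."""
    root = tmp_path_factory.mktemp("simfix")
    cfg = SimConfig(n_genes=20, seed=7, polya_fraction=1.0)
    ann = simulate_annotation(cfg)
    gff = root / "annotation.gff3"
    ann.write_gff3(gff)
    sheet, truth = simulate_tag_reads(cfg, ann, root / "reads")
    return {"config": cfg, "annotation": ann, "gff": gff,
            "sheet": sheet, "truth": truth, "root": root}
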