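"""Ground-truthed synthetic fixtures for every pipeline stage.

Emulates the structure of a 3'-tag experiment: ~75 bp single-end reads
piled up just inside annotated gene 3' ends, a configurable fraction
carrying a strand-appropriate soft-clipped polyA tail, three biological
replicates per condition, and negative-binomial counts with planted fold
changes across the seasonal transitions R1 -> D1 -> R2.

Reads are emitted directly as SAM alignments (the pipeline's scope starts
downstream of the aligner). Tail bases are written into the stored sequence
respecting the reverse-complement convention: an A-tail on a plus-strand
read is a trailing A-run; on a minus-strand read it is a leading T-run.
All generators are deterministic given the seed: identical seeds give
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annot import GeneModel

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Generator knobs; defaults mirror the study design.

    ``reads_per_gene_log_mean``/``_log_sigma`` parameterize a log-normal
    over per-gene expected read counts. ``polya_fraction`` is the fraction
    of reads given a soft-clipped tail; tail lengths are uniform over
    [tail_min, tail_max]. ``error_rate`` substitutes bases in the aligned
    portion (mismatches are still reported as NM=0 since the emitted file
    has no reference sequence to disagree with; the knob exists to vary
    sequence content).
    """

    n_genes: int = 20
    genome_length: int = 200_000
    n_replicates: int = 3
    read_length: int = 75
    gene_length: int = 2_000
    min_spacing: int = 500
    reads_per_gene_log_mean: float = 3.0
    reads_per_gene_log_sigma: float = 0.6
    polya_fraction: float = 1.0
    tail_min: int = 8
    tail_max: int = 20
    three_prime_window: int = 40
    error_rate: float = 0.0
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.polya_fraction <= 1:
            raise ValueError("polya_fraction must be in [0, 1]")
        if self.tail_min < 1 or self.tail_max < self.tail_min:
            raise ValueError("need 1 <= tail_min <= tail_max")
        for name in ("n_genes", "genome_length", "n_replicates",
                     "read_length", "gene_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimAnnotation:
    genes: List[GeneModel]
    references: Dict[str, int]
    three_prime_ends: Dict[str, int]

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for ref, length in sorted(self.references.items()):
                fh.write(f"##sequence-region {ref} 1 {length}\n")
            for g in self.genes:
                fh.write(
                    f"{g.reference}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )

    def write_reference_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reference\tlength\n")
            for ref, length in sorted(self.references.items()):
                fh.write(f"{ref}\t{length}\n")


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated dataset."""

    true_counts: pd.DataFrame                       # genes x samples
    planted_log2fc: Optional[pd.DataFrame] = None   # genes x transitions
    reregulated_genes: Tuple[str, ...] = ()
    decoy_read_ids: Tuple[str, ...] = ()
    depth_factors: Optional[pd.Series] = None


def simulate_annotation(config: SimConfig) -> SimAnnotation:
    """Place non-overlapping genes on one reference, strands ~Bernoulli(0.5).

    Fails when ``genome_length`` cannot hold ``n_genes`` genes of
    ``gene_length`` with ``min_spacing`` between them.
    """
    rng = np.random.default_rng(config.seed)
    ref = "chrSim1"
    slot = config.gene_length + config.min_spacing
    needed = config.n_genes * slot + config.min_spacing
    if needed > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} cannot pack "
            f"{config.n_genes} genes of {config.gene_length} nt with "
            f"{config.min_spacing} nt spacing (needs {needed})"
        )
    # Distribute leftover space as random extra gaps, keeping order fixed.
    leftover = config.genome_length - needed
    extra = rng.multinomial(leftover, np.full(config.n_genes,
                                              1 / config.n_genes))
    genes: List[GeneModel] = []
    ends3: Dict[str, int] = {}
    pos = config.min_spacing
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        pos += int(extra[i])
        start = pos
        end = start + config.gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{str(i + 1).zfill(width)}"
        genes.append(GeneModel(gid, ref, start, end, strand))
        ends3[gid] = end if strand == "+" else start
        pos = end + config.min_spacing
    return SimAnnotation(
        genes=genes,
        references={ref: config.genome_length},
        three_prime_ends=ends3,
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _sam_record(
    qname: str,
    flag: int,
    ref: str,
    pos0: int,
    cigar: str,
    seq: str,
    nm: int,
    align_score: int,
    nh: int,
) -> str:
    return (
        f"{qname}\t{flag}\t{ref}\t{pos0 + 1}\t255\t{cigar}\t*\t0\t0\t"
        f"{seq}\t*\tNM:i:{nm}\tAS:i:{align_score}\tNH:i:{nh}\n"
    )


def simulate_tag_reads(
    config: SimConfig,
    annotation: SimAnnotation,
    out_dir: str | Path,
    truth_counts: Optional[pd.DataFrame] = None,
    sample_ids: Optional[Sequence[str]] = None,
    genotype: str = "G1",
    time_point: str = "T1",
    with_decoys: bool = False,
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Write one SAM file per replicate and return the sample sheet + truth.

    Reads for a gene end within ``three_prime_window`` nt of its 3'
    terminus, entirely inside the gene body. ``polya_fraction`` of reads
    carry a qualifying soft-clipped tail; the aligned portion shrinks so
    the full read stays ``read_length`` nt. All intended reads carry
    NM/AS/NH tags that pass the default filter policy; decoys are extra
    reads built to fail exactly one criterion each, labeled in the truth.
    """
    rng = np.random.default_rng(config.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if sample_ids is None:
        sample_ids = [
            f"{genotype}_{time_point}_rep{r + 1}"
            for r in range(config.n_replicates)
        ]
    gene_ids = [g.gene_id for g in annotation.genes]
    if truth_counts is None:
        lam = rng.lognormal(
            config.reads_per_gene_log_mean,
            config.reads_per_gene_log_sigma,
            size=len(gene_ids),
        )
        counts = rng.poisson(lam[:, None],
                             size=(len(gene_ids), len(sample_ids)))
        counts = np.maximum(counts, 3)  # every gene observable per sample
        truth_counts = pd.DataFrame(counts, index=gene_ids,
                                    columns=list(sample_ids))
    truth_counts = truth_counts.astype(int)

    header = "@HD\tVN:1.6\tSO:unsorted\n" + "".join(
        f"@SQ\tSN:{ref}\tLN:{length}\n"
        for ref, length in sorted(annotation.references.items())
    )
    decoy_ids: List[str] = []
    rows = []
    for sid in sample_ids:
        lines: List[str] = [header]
        serial = 0
        for gene in annotation.genes:
            n = int(truth_counts.at[gene.gene_id, sid])
            for _ in range(n):
                serial += 1
                qname = f"{sid}:{gene.gene_id}:{serial}"
                tailed = rng.random() < config.polya_fraction
                tail = (
                    int(rng.integers(config.tail_min, config.tail_max + 1))
                    if tailed
                    else 0
                )
                m = config.read_length - tail
                offset = int(rng.integers(0, config.three_prime_window + 1))
                if gene.strand == "+":
                    end3 = gene.end - offset
                    start = end3 - m
                    cigar = f"{m}M{tail}S" if tail else f"{m}M"
                    seq = _random_seq(rng, m) + "A" * tail
                    flag = 0
                else:
                    start3 = gene.start + offset
                    start = start3
                    cigar = f"{tail}S{m}M" if tail else f"{m}M"
                    seq = "T" * tail + _random_seq(rng, m)
                    flag = 16
                lines.append(
                    _sam_record(qname, flag, gene.reference, start, cigar,
                                seq, 0, config.read_length, 1)
                )
        if with_decoys:
            ref = annotation.genes[0].reference
            pos = annotation.genes[0].start + 10
            rl = config.read_length
            short = rl // 2 - 3  # matched fraction below half
            decoys = [
                (f"{sid}:decoy:match_frac",
                 f"{short}M{rl - short}S",
                 _random_seq(rng, rl), 0, rl, 1),
                (f"{sid}:decoy:mismatches", f"{rl}M",
                 _random_seq(rng, rl), 5, rl, 1),
                (f"{sid}:decoy:score", f"{rl}M",
                 _random_seq(rng, rl), 0, int(0.5 * rl), 1),
                (f"{sid}:decoy:multimap", f"{rl}M",
                 _random_seq(rng, rl), 0, rl, 2),
            ]
            for qname, cigar, seq, nm, score, nh in decoys:
                decoy_ids.append(qname)
                lines.append(
                    _sam_record(qname, 0, ref, pos, cigar, seq, nm, score, nh)
                )
        path = out_dir / f"{sid}.sam"
        path.write_text("".join(lines))
        rep = sid.rsplit("rep", 1)[-1]
        rows.append(
            {
                "sample_id": sid,
                "path": str(path),
                "genotype": genotype,
                "time_point": time_point,
                "replicate": rep,
            }
        )
    sheet = pd.DataFrame(rows)
    truth = GroundTruth(true_counts=truth_counts,
                        decoy_read_ids=tuple(decoy_ids))
    return sheet, truth


def simulate_count_experiment(
    config: SimConfig,
    genotypes: Sequence[str] = ("G1",),
    time_points: Sequence[str] = ("R1", "D1", "R2"),
    n_genes: Optional[int] = None,
    base_mean: float = 200.0,
    n_de: int = 100,
    de_log2fc: float = 2.0,
    n_reregulated: int = 26,
    depth_log_sigma: float = 0.25,
    base_log_sigma: float = 0.5,
) -> Tuple["pd.DataFrame", GroundTruth]:
    """NB counts with planted transition effects and re-regulated genes.

    Per-gene baselines are log-normal around ``base_mean``. ``n_de`` genes
    receive a +/-``de_log2fc`` shift in the first transition; the first
    ``n_reregulated`` of them lose the effect in the second transition
    (their expression returns to baseline), making them re-regulated by
    construction. Counts are NB with dispersion ``nb_dispersion`` and
    log-normal per-sample depth factors. Returns (CountMatrix, GroundTruth).
    """
    from .cluster3p import CountMatrix

    rng = np.random.default_rng(config.seed + 2)
    n_genes = n_genes if n_genes is not None else config.n_genes
    if n_de > n_genes or n_reregulated > n_de:
        raise ValueError("need n_reregulated <= n_de <= n_genes")
    width = len(str(n_genes))
    gene_ids = [f"gene{str(i + 1).zfill(width)}" for i in range(n_genes)]
    transitions = [
        f"{time_points[i]}-{time_points[i + 1]}"
        for i in range(len(time_points) - 1)
    ]

    baseline = rng.lognormal(np.log(base_mean), base_log_sigma, size=n_genes)
    lfc = pd.DataFrame(0.0, index=gene_ids, columns=transitions)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc.iloc[de_idx, 0] = signs * de_log2fc
    rereg = tuple(sorted(gene_ids[i] for i in de_idx[:n_reregulated]))
    if len(transitions) > 1:
        # Re-regulated genes revert; other DE genes keep their new level.
        for i, g in zip(de_idx[:n_reregulated],
                        (gene_ids[i] for i in de_idx[:n_reregulated])):
            lfc.at[g, transitions[1]] = -lfc.at[g, transitions[0]]

    sample_rows = []
    for g in genotypes:
        for tp in time_points:
            for r in range(config.n_replicates):
                sample_rows.append(
                    {
                        "sample_id": f"{g}_{tp}_rep{r + 1}",
                        "genotype": g,
                        "time_point": tp,
                        "replicate": str(r + 1),
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    depth = pd.Series(
        rng.lognormal(0.0, depth_log_sigma, size=len(samples)),
        index=samples.index,
        name="depth_factor",
    )

    # Cumulative planted effect per time point.
    cum = {time_points[0]: np.zeros(n_genes)}
    for i, tr in enumerate(transitions):
        cum[time_points[i + 1]] = cum[time_points[i]] + lfc[tr].to_numpy()

    alpha = config.nb_dispersion
    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, (sid, row) in enumerate(samples.iterrows()):
        mu = baseline * 2.0 ** cum[row["time_point"]] * depth[sid]
        if alpha > 0:
            size = 1.0 / alpha
            counts[:, j] = rng.negative_binomial(size, size / (size + mu))
        else:
            counts[:, j] = rng.poisson(mu)
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples.index),
        samples=samples,
    )
    truth = GroundTruth(
        true_counts=matrix.counts.copy(),
        planted_log2fc=lfc,
        reregulated_genes=rereg,
        depth_factors=depth,
    )
    return matrix, truth
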