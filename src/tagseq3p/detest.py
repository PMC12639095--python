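"""Differential expression between time points and re-regulation calls.

The engine is a fully specified negative-binomial Wald test (named
``nb-wald-mom`` in output headers): depth-normalized counts, a pseudocount
fold change log2((mean_b + c)/(mean_a + c)), a per-gene method-of-moments
dispersion alpha = max(0, (var - mean)/mean^2) from within-group pooled
moments, and a delta-method standard error under the NB variance
mean + alpha * mean^2. With very few replicates the raw moment estimate is
often truncated at zero, which understates the variance and makes a naive
Wald test anti-conservative; the per-gene dispersion is therefore floored
at the across-gene median (a simple moderation in the spirit of the
empirical-Bayes shrinkage used by mainstream DE engines) before the
two-sided normal p-value is computed. There is no fold-change shrinkage.

Significance follows the strict thresholds: a gene is up when
log2FC > lfc_threshold and FDR < fdr_threshold, down when
log2FC < -lfc_threshold and FDR < fdr_threshold, else ns.

A shared DEG (significant in every genotype) is re-regulated across two
consecutive transitions when it is significant in exactly one of them
(``sig_in_one``) or flips direction between them (``reversed``) —
interpreted as transcriptional resetting once the stress is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster3p import CountMatrix
from .normqc import SizeFactors

ENGINE_NAME = "nb-wald-mom"

LN2 = np.log(2.0)


@dataclass(frozen=True)
class Contrast:
    """Two disjoint replicate groups, log2FC oriented b over a.

    For the seasonal label "R1-D1", group_a holds the R1 replicates and
    group_b the D1 replicates, so log2FC is D1 over R1.
    """

    label: str
    group_a: Tuple[str, ...]
    group_b: Tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("contrast groups must be disjoint")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each group needs >= 2 samples")


def nb_wald_test(
    matrix: CountMatrix,
    factors: SizeFactors,
    contrast: Contrast,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB Wald statistics for one contrast.

    Returns a DataFrame indexed by gene_id with columns base_mean, log2fc,
    se, p_value.
    """
    missing = [
        s
        for s in contrast.group_a + contrast.group_b
        if s not in matrix.counts.columns
    ]
    if missing:
        raise ValueError(f"contrast samples absent from matrix: {missing}")

    norm = matrix.counts.div(factors.factors, axis=1)
    a = norm[list(contrast.group_a)].to_numpy(dtype=float)
    b = norm[list(contrast.group_b)].to_numpy(dtype=float)
    if not a.any() or not b.any():
        raise ValueError(
            f"contrast {contrast.label}: one group has all-zero counts"
        )
    n_a, n_b = a.shape[1], b.shape[1]

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    # Method-of-moments dispersion from within-group pooled moments.
    var_pooled = (
        (n_a - 1) * a.var(axis=1, ddof=1) + (n_b - 1) * b.var(axis=1, ddof=1)
    ) / (n_a + n_b - 2)
    grand_mean = np.concatenate([a, b], axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(
            grand_mean > 0,
            np.maximum(0.0, (var_pooled - grand_mean) / grand_mean**2),
            0.0,
        )
    # Moderation: floor each gene's dispersion at the across-gene median so
    # zero-truncated estimates cannot understate the variance.
    alpha = np.maximum(alpha, np.median(alpha))

    var_mean_a = (mean_a + alpha * mean_a**2) / n_a
    var_mean_b = (mean_b + alpha * mean_b**2) / n_b
    se = (
        np.sqrt(
            var_mean_a / (mean_a + pseudocount) ** 2
            + var_mean_b / (mean_b + pseudocount) ** 2
        )
        / LN2
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        z = np.where((se == 0) & (log2fc != 0),
                     np.inf * np.sign(log2fc), z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)

    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "p_value": p,
        },
        index=matrix.counts.index,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_sig(
    results: pd.DataFrame,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Attach fdr and sig_class columns (strict thresholds).

    up: log2fc > lfc_threshold and fdr < fdr_threshold;
    down: log2fc < -lfc_threshold and fdr < fdr_threshold; else ns.
    """
    out = results.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    sig = out["fdr"] < fdr_threshold
    out["sig_class"] = np.select(
        [sig & (out["log2fc"] > lfc_threshold),
         sig & (out["log2fc"] < -lfc_threshold)],
        ["up", "down"],
        default="ns",
    )
    return out


def run_contrast(
    matrix: CountMatrix,
    factors: SizeFactors,
    contrast: Contrast,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Test, adjust and classify one contrast in a single call."""
    res = nb_wald_test(matrix, factors, contrast, pseudocount)
    return classify_sig(res, lfc_threshold, fdr_threshold)


def shared_deg_sets(
    per_genotype: Mapping[str, Set[str]],
) -> pd.DataFrame:
    """Disjoint-region decomposition of per-genotype DEG sets (UpSet table).

    Rows cover every non-empty genotype combination, with a membership
    bit-vector, the gene count and the sorted member list. Region counts
    sum to the union size; the all-genotype region is the shared DEG set.
    """
    if len(per_genotype) < 2:
        raise ValueError("need sets for >= 2 genotypes")
    genotypes = sorted(per_genotype)
    union = set().union(*per_genotype.values())
    membership: Dict[Tuple[bool, ...], List[str]] = {}
    for gene in union:
        key = tuple(gene in per_genotype[g] for g in genotypes)
        membership.setdefault(key, []).append(gene)

    rows = []
    for key in sorted(membership, key=lambda k: (-sum(k), k), reverse=False):
        genes = sorted(membership[key])
        rows.append(
            {
                "membership": "".join("1" if b else "0" for b in key),
                "genotypes": ",".join(
                    g for g, b in zip(genotypes, key) if b
                ),
                "n_genes": len(genes),
                "genes": ";".join(genes),
            }
        )
    return pd.DataFrame(rows)


def shared_degs(
    per_genotype: Mapping[str, Set[str]],
) -> Set[str]:
    """Genes significant in every genotype (direction-agnostic)."""
    return set.intersection(*(set(s) for s in per_genotype.values()))


@dataclass(frozen=True)
class ReregulationCall:
    gene_id: str
    status_t1: str
    status_t2: str
    reregulated: bool
    criterion: str  # sig_in_one | reversed | none


def classify_reregulation(
    t1: pd.DataFrame,
    t2: pd.DataFrame,
    shared: Iterable[str],
) -> List[ReregulationCall]:
    """Classify shared DEGs across two consecutive transitions.

    ``sig_in_one``: significant (up or down) in exactly one transition;
    ``reversed``: significant in both with opposite direction; ``none``
    otherwise. Both result frames must carry a sig_class column and cover
    every shared gene.
    """
    shared = sorted(shared)
    for name, df in (("transition 1", t1), ("transition 2", t2)):
        missing = [g for g in shared if g not in df.index]
        if missing:
            raise ValueError(f"{name} results missing genes: {missing}")

    calls: List[ReregulationCall] = []
    for gene in shared:
        s1 = t1.at[gene, "sig_class"]
        s2 = t2.at[gene, "sig_class"]
        sig1, sig2 = s1 != "ns", s2 != "ns"
        if sig1 != sig2:
            criterion = "sig_in_one"
        elif sig1 and sig2 and s1 != s2:
            criterion = "reversed"
        else:
            criterion = "none"
        calls.append(
            ReregulationCall(
                gene_id=gene,
                status_t1=s1,
                status_t2=s2,
                reregulated=criterion != "none",
                criterion=criterion,
            )
        )
    return calls


def reregulation_table(calls: List[ReregulationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "status_t1": c.status_t1,
                "status_t2": c.status_t2,
                "reregulated": c.reregulated,
                "criterion": c.criterion,
            }
            for c in calls
        ]
    )
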