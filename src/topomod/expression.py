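"""Expression-based validation of module structure.

If modules are biologically real, genes catalysing reversible reactions of
the same module should co-vary more than genes of equally close reactions
in different modules.  Distance two in the shared-metabolite reaction graph
(one intermediate reaction) is the closest two reversible reactions of
different modules can be, so the comparison is made at exactly that
distance: Pearson correlations of all mappable gene pairs across the two
reactions' GPRs, split intra/extra module, compared by two-sample
Kolmogorov-Smirnov and Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ModulePartition
from .model import GPR

__all__ = [
    "CorrelationRecord",
    "load_expression",
    "filter_genes",
    "distance2_pairs",
    "correlate",
    "compare_distributions",
]

# An expression matrix is a genes x samples DataFrame of normalised values
# (e.g. log2(TPM+1)); the index holds gene ids, columns hold sample ids.
ExpressionMatrix = pd.DataFrame


@dataclass(frozen=True)
class CorrelationRecord:
    reaction_a: str
    reaction_b: str
    gene_a: str
    gene_b: str
    r: float
    klass: str  # intra | extra


def load_expression(path) -> ExpressionMatrix:
    """Genes x samples TSV with a header row; first column is the gene id.
    GCT files (two-line preamble) are accepted."""
    with open(path) as fh:
        first = fh.readline()
    skip = 2 if first.startswith("#1.2") or first.strip() == "#1.2" else 0
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    df = df.select_dtypes(include=[np.number])
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("non-finite expression values")
    return df


def filter_genes(
    expr: ExpressionMatrix,
    gpr: dict[str, GPR],
    sd_min: float = 0.6,
    promiscuity_max: int = 50,
) -> ExpressionMatrix:
    """Drop constitutive genes (standard deviation <= ``sd_min``) and
    promiscuous genes appearing in the GPR of more than ``promiscuity_max``
    reactions (they produce artificially high correlations)."""
    counts: dict[str, int] = {}
    for g in gpr.values():
        for gene in g.genes:
            counts[gene] = counts.get(gene, 0) + 1
    sd = expr.std(axis=1, ddof=1)
    keep = (sd > sd_min) & pd.Series(
        {g: counts.get(g, 0) <= promiscuity_max for g in expr.index}
    )
    out = expr.loc[keep[keep].index]
    if out.empty:
        raise ValueError("no genes survive filtering")
    return out


def distance2_pairs(
    graph: nx.Graph, part: ModulePartition
) -> list[tuple[str, str, str]]:
    """Unordered pairs of reversible reactions at shortest-path distance
    exactly two, tagged intra/extra by the partition."""
    member_of = part.module_of()
    reversible = set(member_of)
    out = []
    for u in sorted(reversible):
        if u not in graph:
            continue
        n1 = set(graph.neighbors(u))
        n2 = set()
        for w in n1:
            n2.update(graph.neighbors(w))
        n2 -= n1
        n2.discard(u)
        for v in sorted(n2 & reversible):
            if u < v:
                klass = "intra" if member_of[u] == member_of[v] else "extra"
                out.append((u, v, klass))
    return out


def correlate(
    pairs: list[tuple[str, str, str]],
    expr: ExpressionMatrix,
    gpr: dict[str, GPR],
    min_samples: int = 3,
) -> list[CorrelationRecord]:
    """Pearson r for every mappable gene pair of every reaction pair.

    Records are per gene pair (not aggregated per reaction); reaction pairs
    with no mappable genes are skipped silently, and the whole call raises
    only on structural errors.
    """
    if expr.shape[1] < min_samples:
        raise ValueError(f"need >= {min_samples} shared samples")
    genes_needed = sorted(
        {
            gene
            for a, b, _ in pairs
            for r in (a, b)
            for gene in gpr.get(r, GPR()).genes
            if gene in expr.index
        }
    )
    if not genes_needed:
        return []
    sub = expr.loc[genes_needed]
    corr = np.corrcoef(sub.to_numpy())
    gidx = {g: i for i, g in enumerate(genes_needed)}
    records = []
    for a, b, klass in pairs:
        ga = [g for g in sorted(gpr.get(a, GPR()).genes) if g in gidx]
        gb = [g for g in sorted(gpr.get(b, GPR()).genes) if g in gidx]
        for x in ga:
            for y in gb:
                if x == y:
                    continue
                records.append(
                    CorrelationRecord(a, b, x, y, float(corr[gidx[x], gidx[y]]), klass)
                )
    return records


def compare_distributions(records: list[CorrelationRecord]) -> dict:
    """KS and rank-sum comparison of intra- vs extra-module |r|.

    Returns the p-values, per-class summary fractions (|r|>0.8, |r|<0.1),
    medians and a 20-bin histogram of |r| per class.
    """
    intra = np.abs([rec.r for rec in records if rec.klass == "intra"])
    extra = np.abs([rec.r for rec in records if rec.klass == "extra"])
    if len(intra) == 0 or len(extra) == 0:
        raise ValueError("both intra and extra classes must be non-empty")
    if min(len(intra), len(extra)) < 10:
        warnings.warn("fewer than 10 records in a class; tests are unreliable")
    ks = stats.ks_2samp(intra, extra)
    rank = stats.ranksums(intra, extra)
    bins = np.linspace(0.0, 1.0, 21)
    report = {
        "n_intra": int(len(intra)),
        "n_extra": int(len(extra)),
        "ks_pvalue": float(ks.pvalue),
        "ks_statistic": float(ks.statistic),
        "ranksum_pvalue": float(rank.pvalue),
        "median_intra": float(np.median(intra)),
        "median_extra": float(np.median(extra)),
        "frac_gt_0.8_intra": float(np.mean(intra > 0.8)),
        "frac_gt_0.8_extra": float(np.mean(extra > 0.8)),
        "frac_lt_0.1_intra": float(np.mean(intra < 0.1)),
        "frac_lt_0.1_extra": float(np.mean(extra < 0.1)),
        "hist_bins": bins.tolist(),
        "hist_intra": np.histogram(intra, bins=bins)[0].tolist(),
        "hist_extra": np.histogram(extra, bins=bins)[0].tolist(),
    }
    return report
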