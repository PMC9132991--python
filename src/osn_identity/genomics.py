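"""OR gene genomic layout: anchors, Jenks natural-breaks cluster detection.

OR genes sit in genomic clusters.  Cluster membership is derived from the
data itself: sorted distances between adjacent genes are split by a k=3
Jenks natural-breaks optimization, the lowest class is taken as the
intra-cluster distance group, and the clustering threshold is that group's
mean plus three standard deviations.  Neighbouring genes closer than the
threshold share a cluster.

Anchor positions follow the start-codon rule: the strand-aware genomic
coordinate of the start codon, except for multi-exon coding sequences where
the first position of the last coding exon is used instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class GenomicsError(ValueError):
    pass


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    strand: str
    anchor_position: int  # bp, 1-based
    multi_exon_cds: bool = False

    def __post_init__(self) -> None:
        if self.anchor_position < 1:
            raise GenomicsError(f"{self.gene_id}: anchor position must be >= 1")
        if self.strand not in "+-":
            raise GenomicsError(f"{self.gene_id}: strand must be + or -")


def read_gtf_cds(path: str | Path) -> dict[str, list[tuple[str, str, int, int]]]:
    """Parse CDS records from a GTF into gene_id -> [(chrom, strand, start, end)].

    GTF coordinates are 1-based closed intervals; they are kept as such.
    """
    records: dict[str, list[tuple[str, str, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].rstrip(";").split(";")
                if kv.strip()
            )
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GenomicsError("CDS record without gene_id attribute")
            records.setdefault(gene_id, []).append((f[0], f[6], int(f[3]), int(f[4])))
    return records


def anchor_positions(
    cds_records: dict[str, list[tuple[str, str, int, int]]]
) -> list[GeneAnnotation]:
    """Anchor per gene: start codon, or first position of the last coding exon
    for a multi-exon CDS.  "First" and "last" are in translation order, so on
    the minus strand the last coding exon is the leftmost one and its first
    position is its rightmost base.
    """
    out = []
    for gene_id, recs in cds_records.items():
        if not recs:
            raise GenomicsError(f"{gene_id}: no CDS record")
        chroms = {r[0] for r in recs}
        strands = {r[1] for r in recs}
        if len(chroms) > 1 or len(strands) > 1:
            raise GenomicsError(f"{gene_id}: CDS records span chromosomes or strands")
        chrom, strand = recs[0][0], recs[0][1]
        exons = sorted((r[2], r[3]) for r in recs)
        multi = len(exons) > 1
        if strand == "+":
            anchor = exons[-1][0] if multi else exons[0][0]
        else:
            # translation order runs right-to-left
            anchor = exons[0][1] if multi else exons[-1][1]
        out.append(GeneAnnotation(gene_id, chrom, strand, anchor, multi))
    return out


def adjacent_distances(anchors: list[GeneAnnotation]) -> np.ndarray:
    """Distances between position-adjacent genes per chromosome, concatenated."""
    dists: list[int] = []
    by_chrom: dict[str, list[int]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chromosome, []).append(a.anchor_position)
    for positions in by_chrom.values():
        positions.sort()
        dists.extend(int(b - a) for a, b in itertools.pairwise(positions))
    return np.array(sorted(dists), dtype=float)


def jenks_breaks(values, k: int = 3) -> list[float]:
    """Optimal 1D partition into k classes minimizing within-class SSD.

    Dynamic programming over sorted values with prefix sums; O(n^2 k).
    Returns the k+1 class boundaries [min, b1, ..., b_{k-1}, max] where each
    internal boundary is the largest member of its class.  Ties in optimal
    cost are broken toward the smaller lowest class.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < k:
        raise GenomicsError(f"need at least {k} values for {k} classes, got {n}")
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:
        # within-class sum of squared deviations for x[i:j]
        m = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / m

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + ssd(i, j)
                # strict < keeps the earliest split, i.e. smaller lowest class
                if v < best:
                    best, arg = v, i
            cost[c, j] = best
            cut[c, j] = arg
    # recover class boundaries
    bounds = [float(x[-1])]
    j = n
    for c in range(k, 0, -1):
        i = cut[c, j]
        if c > 1:
            bounds.append(float(x[i - 1]))
        j = i
    bounds.append(float(x[0]))
    return bounds[::-1]


@dataclass
class ClusterModel:
    """Fitted OR gene cluster structure.

    ``breaks`` are the k=3 Jenks boundaries on the sorted adjacent-gene
    distances; the intra-cluster group is the class(es) below the selected
    internal break (see :func:`cluster_threshold`), and the clustering
    threshold is intra mean + 3 * intra SD.
    """

    breaks: list[float]
    intra_mean: float
    intra_sd: float
    threshold: float
    cluster_assignment: dict[str, int] = field(default_factory=dict)


def cluster_threshold(
    adjacent: np.ndarray,
    k: int = 3,
    n_sd: float = 3.0,
    intra_break: str = "auto",
) -> ClusterModel:
    """Jenks k=3 on adjacent distances; threshold = intra mean + n_sd * SD.

    ``intra_break`` selects which internal break separates the intra group:
    "lower" keeps only the lowest Jenks class, "upper" keeps the two lowest
    classes, and "auto" (default) picks the internal break with the largest
    relative separation between the classes it divides.  With k = 3 the
    optimizer spends its two internal breaks either subdividing the
    intra-cluster tail (then the upper break divides intra from inter) or
    subdividing the inter-cluster gaps (then the lower break does), so the
    discriminating break is the one sitting in the dominant value gap.
    """
    adjacent = np.asarray(adjacent, dtype=float)
    if adjacent.size < k:
        raise GenomicsError("need at least k adjacent distances")
    breaks = jenks_breaks(adjacent, k=k)
    if intra_break == "lower":
        cutoff = breaks[1]
    elif intra_break == "upper":
        cutoff = breaks[-2]
    elif intra_break == "auto":
        srt = np.sort(adjacent)
        best_ratio, cutoff = -np.inf, breaks[1]
        for b in breaks[1:-1]:
            below = srt[srt <= b]
            above = srt[srt > b]
            if below.size == 0 or above.size == 0:
                continue
            ratio = above.min() / max(below.max(), 1e-12)
            if ratio > best_ratio:
                best_ratio, cutoff = ratio, b
    else:
        raise GenomicsError("intra_break must be 'lower', 'upper' or 'auto'")
    intra = adjacent[adjacent <= cutoff]
    if intra.size < 2:
        raise GenomicsError("intra-cluster distance group has fewer than 2 values")
    mean = float(intra.mean())
    sd = float(intra.std(ddof=1))
    return ClusterModel(breaks=breaks, intra_mean=mean, intra_sd=sd, threshold=mean + n_sd * sd)


def aggregate_clusters(anchors: list[GeneAnnotation], threshold: float) -> dict[str, int]:
    """Maximal runs of adjacent genes with gaps < threshold share a cluster id."""
    if threshold <= 0:
        raise GenomicsError("threshold must be positive")
    assignment: dict[str, int] = {}
    cluster_id = 0
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chromosome, []).append(a)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda a: a.anchor_position)
        assignment[genes[0].gene_id] = cluster_id
        for prev, cur in itertools.pairwise(genes):
            if cur.anchor_position - prev.anchor_position >= threshold:
                cluster_id += 1
            assignment[cur.gene_id] = cluster_id
        cluster_id += 1
    return assignment


def fit_cluster_model(
    anchors: list[GeneAnnotation], k: int = 3, n_sd: float = 3.0, intra_break: str = "auto"
) -> ClusterModel:
    """Full pipeline: adjacent distances -> Jenks threshold -> clusters."""
    model = cluster_threshold(adjacent_distances(anchors), k=k, n_sd=n_sd, intra_break=intra_break)
    model.cluster_assignment = aggregate_clusters(anchors, model.threshold)
    return model


def pairwise_genomic_distances(
    anchors: list[GeneAnnotation], assignment: dict[str, int]
) -> pd.DataFrame:
    """Unordered same-cluster pair distances; cross-cluster pairs are flagged
    distant and carry no distance (NaN)."""
    rows = []
    anns = sorted(anchors, key=lambda a: a.gene_id)
    for a, b in itertools.combinations(anns, 2):
        same = assignment[a.gene_id] == assignment[b.gene_id]
        rows.append(
            {
                "gene_a": a.gene_id,
                "gene_b": b.gene_id,
                "same_cluster": same,
                "same_chromosome": a.chromosome == b.chromosome,
                "distance": float(abs(a.anchor_position - b.anchor_position)) if same else np.nan,
            }
        )
    return pd.DataFrame(rows)
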