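"""Association between transcriptomic, genomic and sequence distances.

Joins the three distance worlds into one table with a row per unordered
pair of OSN populations, then runs the comparisons that ask what predicts
transcriptomic identity: binned distance distributions with Spearman rank
correlations over the first bins, close/distant thresholds (95th percentile
of neighbouring same-cluster genomic distances; 5th percentile of
same-class amino-acid differences), a four-way category comparison by
rank-sum tests with Bonferroni correction, per-bin close-pair proportions,
and the enhancer-set comparison (are populations whose OR genes share a
cis-regulatory element transcriptomically closer than the rest of their
cluster?).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

logger = logging.getLogger(__name__)


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class CloseThresholds:
    genomic_close: float  # bp; 95th percentile of neighbouring same-cluster distances
    aa_close: float  # 5th percentile of same-class aa differences


CATEGORIES = ("near_similar", "far_similar", "near_dissimilar", "far_dissimilar")


def build_pair_table(
    centroid_matrix: pd.DataFrame,
    genomic_pairs: pd.DataFrame,
    aa_matrix: pd.DataFrame,
    cluster_assignment: dict[str, int],
    class_labels: dict[str, str],
    chromosome: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per unordered population pair present in all three sources.

    ``genomic_pairs`` is the same-cluster pair table from the genomics
    module (gene_a, gene_b, same_cluster, distance).  Populations missing
    from any source are dropped with a logged count.
    """
    pops_t = set(centroid_matrix.index)
    pops_a = set(aa_matrix.index)
    pops_g = set(cluster_assignment)
    shared = sorted(pops_t & pops_a & pops_g)
    if not shared:
        raise AssociationError("no population shared by all distance sources")
    dropped = len(pops_t | pops_a | pops_g) - len(shared)
    if dropped:
        logger.info("dropped %d populations missing from at least one source", dropped)

    gmap = {}
    for row in genomic_pairs.itertuples(index=False):
        gmap[frozenset((row.gene_a, row.gene_b))] = (
            row.distance,
            bool(row.same_cluster),
            bool(getattr(row, "same_chromosome", row.same_cluster)),
        )
    rows = []
    for a, b in itertools.combinations(shared, 2):
        dist, same_cluster, same_chrom = gmap.get(frozenset((a, b)), (np.nan, False, False))
        rows.append(
            {
                "pop_a": a,
                "pop_b": b,
                "transcriptomic_distance": float(centroid_matrix.loc[a, b]),
                "genomic_distance": dist if same_cluster else np.nan,
                "aa_difference": float(aa_matrix.loc[a, b]),
                "same_cluster": same_cluster,
                "same_class": class_labels.get(a) == class_labels.get(b),
                "same_chromosome": (
                    chromosome[a] == chromosome[b] if chromosome is not None else same_chrom
                ),
            }
        )
    return pd.DataFrame(rows)


def binned_distribution(
    table: pd.DataFrame,
    metric: str,
    n_bins: int,
    mode: str = "equal_width",
    same_class_and_cluster: bool | None = None,
) -> list[pd.DataFrame]:
    """Bin pairs by a distance metric; each bin carries its pairs.

    ``metric`` is "genomic" or "aa".  By default the genomic analysis is
    restricted to same-class, same-cluster pairs (where the genomic
    distance is defined) and the aa analysis to same-class pairs.
    """
    if n_bins < 2:
        raise AssociationError("n_bins must be >= 2")
    col = {"genomic": "genomic_distance", "aa": "aa_difference"}.get(metric)
    if col is None:
        raise AssociationError("metric must be 'genomic' or 'aa'")
    sub = table
    restrict = same_class_and_cluster
    if restrict is None:
        restrict = True
    if restrict:
        sub = sub[sub["same_class"]]
        if metric == "genomic":
            sub = sub[sub["same_cluster"]]
    sub = sub.dropna(subset=[col])
    if sub.empty:
        raise AssociationError(f"no pairs with defined {col}")
    v = sub[col].to_numpy(dtype=float)
    if mode == "equal_width":
        edges = np.linspace(v.min(), v.max(), n_bins + 1)
    elif mode == "equal_frequency":
        edges = np.quantile(v, np.linspace(0, 1, n_bins + 1))
    else:
        raise AssociationError("mode must be 'equal_width' or 'equal_frequency'")
    edges[-1] = np.nextafter(edges[-1], np.inf)
    idx = np.clip(np.digitize(v, edges) - 1, 0, n_bins - 1)
    return [sub.iloc[np.flatnonzero(idx == b)] for b in range(n_bins)]


def first_bins_spearman(
    table: pd.DataFrame,
    metric: str,
    n_bins: int = 10,
    n_first_bins: int = 3,
    mode: str = "equal_width",
) -> tuple[float, float, int]:
    """Spearman rho between the metric and transcriptomic distance over the
    raw pairs falling in the first ``n_first_bins`` bins."""
    bins = binned_distribution(table, metric, n_bins, mode=mode)
    sub = pd.concat(bins[:n_first_bins])
    if len(sub) < 3:
        raise AssociationError("fewer than 3 pairs in the first bins")
    col = "genomic_distance" if metric == "genomic" else "aa_difference"
    x = sub[col].to_numpy(dtype=float)
    y = sub["transcriptomic_distance"].to_numpy(dtype=float)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise AssociationError("constant input to Spearman correlation")
    rho, p = spearmanr(x, y)
    return float(rho), float(p), len(sub)


def close_thresholds(
    neighbor_genomic_distances,
    same_class_aa_differences,
    genomic_percentile: float = 95.0,
    aa_percentile: float = 5.0,
) -> CloseThresholds:
    """Percentile thresholds (linear interpolation between order statistics)."""
    g = np.asarray(neighbor_genomic_distances, dtype=float)
    a = np.asarray(same_class_aa_differences, dtype=float)
    if g.size == 0 or a.size == 0:
        raise AssociationError("empty threshold input")
    return CloseThresholds(
        genomic_close=float(np.percentile(g, genomic_percentile)),
        aa_close=float(np.percentile(a, aa_percentile)),
    )


def classify_pairs(table: pd.DataFrame, thresholds: CloseThresholds) -> pd.DataFrame:
    """Label pairs near/far x similar/dissimilar.

    near = same cluster and genomic distance <= genomic_close; far =
    different cluster.  Same-cluster pairs beyond genomic_close are neither
    and are excluded from the four-way comparison (category NaN, logged).
    similar = aa difference <= aa_close.
    """
    out = table.copy()
    similar = out["aa_difference"] <= thresholds.aa_close
    near = out["same_cluster"] & (out["genomic_distance"] <= thresholds.genomic_close)
    far = ~out["same_cluster"]
    cat = np.full(len(out), None, dtype=object)
    cat[near & similar] = "near_similar"
    cat[near & ~similar] = "near_dissimilar"
    cat[far & similar] = "far_similar"
    cat[far & ~similar] = "far_dissimilar"
    excluded = int((~near & ~far).sum())
    if excluded:
        logger.info("%d same-cluster pairs beyond the close threshold excluded", excluded)
    out["category"] = cat
    return out


def category_tests(classified: pd.DataFrame) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests (continuity-corrected) on
    transcriptomic distances between categories; Bonferroni over the tested
    category pairs."""
    groups = {
        c: g["transcriptomic_distance"].to_numpy(dtype=float)
        for c, g in classified.dropna(subset=["category"]).groupby("category")
        if len(g) >= 2
    }
    skipped = [c for c in CATEGORIES if c not in groups]
    if skipped:
        logger.info("categories with <2 members excluded: %s", skipped)
    if len(groups) < 2:
        raise AssociationError("need at least 2 non-empty categories")
    pairs = list(itertools.combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        stat, p = mannwhitneyu(groups[a], groups[b], alternative="two-sided", use_continuity=True)
        rows.append(
            {
                "category_a": a,
                "category_b": b,
                "n_a": groups[a].size,
                "n_b": groups[b].size,
                "median_a": float(np.median(groups[a])),
                "median_b": float(np.median(groups[b])),
                "statistic": float(stat),
                "pvalue": float(p),
            }
        )
    res = pd.DataFrame(rows)
    res["pvalue_bonferroni"] = np.minimum(res["pvalue"] * len(pairs), 1.0)
    return res


def proportion_close_by_bin(
    table: pd.DataFrame, thresholds: CloseThresholds, n_bins: int
) -> pd.DataFrame:
    """Equal-width bins over transcriptomic distance; per-bin fraction of
    genomically close and of sequence-similar pairs (empty bins -> NaN)."""
    if n_bins < 2:
        raise AssociationError("n_bins must be >= 2")
    t = table["transcriptomic_distance"].to_numpy(dtype=float)
    edges = np.linspace(t.min(), t.max(), n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    idx = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    close_g = (table["same_cluster"] & (table["genomic_distance"] <= thresholds.genomic_close)).to_numpy()
    close_a = (table["aa_difference"] <= thresholds.aa_close).to_numpy()
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        rows.append(
            {
                "bin": b,
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "n_pairs": n,
                "prop_genomic_close": float(close_g[mask].mean()) if n else np.nan,
                "prop_aa_close": float(close_a[mask].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def enhancer_comparison(
    centroid_matrix: pd.DataFrame, cluster_members: list[str], enhancer_members: list[str]
) -> dict:
    """Within-enhancer vs other within-cluster centroid distances.

    Compares the transcriptomic distances among populations whose OR genes
    are targets of one enhancer to the remaining pairs in the same gene
    cluster, by a two-sided continuity-corrected rank-sum test.
    """
    members = [m for m in cluster_members if m in centroid_matrix.index]
    enh = [m for m in enhancer_members if m in members]
    if len(enh) < 2:
        raise AssociationError("need at least 2 enhancer members with centroids")
    enh_set = set(enh)
    within, others = [], []
    for a, b in itertools.combinations(members, 2):
        d = float(centroid_matrix.loc[a, b])
        if a in enh_set and b in enh_set:
            within.append(d)
        else:
            others.append(d)
    if not others:
        raise AssociationError("enhancer set covers the whole cluster; no comparison possible")
    stat, p = mannwhitneyu(within, others, alternative="two-sided", use_continuity=True)
    return {
        "n_within": len(within),
        "n_other": len(others),
        "median_within": float(np.median(within)),
        "median_other": float(np.median(others)),
        "statistic": float(stat),
        "pvalue": float(p),
    }
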