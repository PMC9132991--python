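"""Transcriptomic distance statistics between OSN populations.

Cells live in a selected principal-component space; pairwise Euclidean
distances split into *intra* (same population, i.e. same receptor) and
*inter* (different population) sets.  The evidence that same-receptor
neurons are transcriptomically closer is summarized by Cohen's d between
the two distance distributions, referenced against a permutation null in
which population labels are reshuffled over all cells (1000 permutations by
default), and by a two-sample Kolmogorov–Smirnov test.

`PopulationDistance` is the model object (embedding + labels); `fit()`
returns a `PopulationDistanceResults` carrying the observed statistics,
the permutation distributions and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import ks_2samp


class DistanceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# elementary statistics


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean(a) - mean(b)) / pooled SD.

    Pooled SD uses Bessel-corrected sample variances weighted by degrees of
    freedom.  Degenerate (zero pooled SD) input raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DistanceError("need at least 2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise DistanceError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / pooled)


def ks_compare(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov statistic and p value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DistanceError("empty sample")
    if method == "auto":
        method = "exact" if min(a.size, b.size) < 30 else "asymp"
    res = ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# distances and partitions


@dataclass
class PairwiseDistanceSet:
    distances: np.ndarray  # condensed upper triangle
    labels: np.ndarray  # population per cell
    n_pcs_used: int

    def __post_init__(self) -> None:
        n = self.labels.size
        if self.distances.size != n * (n - 1) // 2:
            raise DistanceError("condensed distance count does not match label count")


@dataclass
class IntraInterPartition:
    intra: np.ndarray
    inter: np.ndarray

    @property
    def n_intra(self) -> int:
        return self.intra.size

    @property
    def n_inter(self) -> int:
        return self.inter.size


def pairwise_distances(coordinates: np.ndarray, labels, n_pcs: int | None = None) -> PairwiseDistanceSet:
    """Condensed Euclidean distances over the first ``n_pcs`` coordinates."""
    coordinates = np.asarray(coordinates, dtype=float)
    labels = np.asarray(labels)
    if labels.size != coordinates.shape[0]:
        raise DistanceError("one label per cell required")
    if n_pcs is None:
        n_pcs = coordinates.shape[1]
    if n_pcs > coordinates.shape[1]:
        raise DistanceError(f"requested {n_pcs} PCs, embedding has {coordinates.shape[1]}")
    d = pdist(coordinates[:, :n_pcs], metric="euclidean")
    return PairwiseDistanceSet(distances=d, labels=labels, n_pcs_used=n_pcs)


def _same_label_mask(labels: np.ndarray) -> np.ndarray:
    """Condensed-order boolean mask of same-label pairs."""
    n = labels.size
    iu, ju = np.triu_indices(n, k=1)
    return labels[iu] == labels[ju]


def partition_intra_inter(dists: PairwiseDistanceSet) -> IntraInterPartition:
    mask = _same_label_mask(dists.labels)
    intra = dists.distances[mask]
    inter = dists.distances[~mask]
    if intra.size == 0:
        raise DistanceError("empty intra set: no population has 2 cells")
    if inter.size == 0:
        raise DistanceError("empty inter set: all cells share one population")
    return IntraInterPartition(intra=intra, inter=inter)


# ---------------------------------------------------------------------------
# centroids


@dataclass
class CentroidSet:
    population_ids: list
    coordinates: np.ndarray  # populations x PCs
    cells_per_population: np.ndarray


def centroids(coordinates: np.ndarray, labels, min_cells: int = 10) -> CentroidSet:
    """Per-population arithmetic mean in PC space, restricted to populations
    with at least ``min_cells`` cells."""
    coordinates = np.asarray(coordinates, dtype=float)
    labels = np.asarray(labels)
    pops, counts = np.unique(labels, return_counts=True)
    keep = counts >= min_cells
    if not keep.any():
        raise DistanceError(f"no population has >= {min_cells} cells")
    pops, counts = pops[keep], counts[keep]
    cents = np.vstack([coordinates[labels == p].mean(axis=0) for p in pops])
    return CentroidSet(population_ids=list(pops), coordinates=cents, cells_per_population=counts)


def centroid_distance_matrix(cents: CentroidSet) -> pd.DataFrame:
    if len(cents.population_ids) < 2:
        raise DistanceError("need at least 2 populations")
    diff = cents.coordinates[:, None, :] - cents.coordinates[None, :, :]
    mat = np.sqrt((diff**2).sum(axis=-1))
    return pd.DataFrame(mat, index=cents.population_ids, columns=cents.population_ids)


# ---------------------------------------------------------------------------
# permutation null


@dataclass
class PermutationResult:
    n_perm: int
    seed: int
    d_intra_vs_perm: np.ndarray  # one Cohen's d per permutation
    d_inter_vs_perm: np.ndarray
    pooled_perm_intra: np.ndarray | None  # None in histogram mode
    pooled_hist: tuple[np.ndarray, np.ndarray] | None = None
    pooled_size: int = 0


def permutation_null(
    dists: PairwiseDistanceSet,
    n_perm: int = 1000,
    seed: int = 0,
    pool_mode: str = "full",
    n_hist_bins: int = 200,
) -> PermutationResult:
    """Permutation null for the intra/inter comparison.

    Per permutation, population labels are reshuffled uniformly over all
    cells, the distances between same-(shuffled-)label cells form the
    permuted intra set, and a Cohen's d is computed between the observed
    intra (and inter) sets and that permuted set.  ``pool_mode='histogram'``
    accumulates the pooled permuted distances as a fixed-bin histogram
    instead of materializing n_intra * n_perm values.
    """
    obs = partition_intra_inter(dists)
    rng = np.random.default_rng(seed)
    labels = dists.labels.copy()
    n = labels.size
    iu, ju = np.triu_indices(n, k=1)
    d_intra = np.empty(n_perm)
    d_inter = np.empty(n_perm)
    pooled: list[np.ndarray] = []
    hist_edges = None
    hist_counts = None
    if pool_mode == "histogram":
        hi = float(dists.distances.max())
        hist_edges = np.linspace(0.0, hi * (1 + 1e-9), n_hist_bins + 1)
        hist_counts = np.zeros(n_hist_bins, dtype=np.int64)
    elif pool_mode != "full":
        raise DistanceError("pool_mode must be 'full' or 'histogram'")
    pooled_size = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        mask = perm[iu] == perm[ju]
        perm_intra = dists.distances[mask]
        d_intra[_] = cohens_d(obs.intra, perm_intra)
        d_inter[_] = cohens_d(obs.inter, perm_intra)
        pooled_size += perm_intra.size
        if pool_mode == "full":
            pooled.append(perm_intra)
        else:
            hist_counts += np.histogram(perm_intra, bins=hist_edges)[0]
    return PermutationResult(
        n_perm=n_perm,
        seed=seed,
        d_intra_vs_perm=d_intra,
        d_inter_vs_perm=d_inter,
        pooled_perm_intra=np.concatenate(pooled) if pool_mode == "full" else None,
        pooled_hist=(hist_counts, hist_edges) if pool_mode == "histogram" else None,
        pooled_size=pooled_size,
    )


# ---------------------------------------------------------------------------
# size-bin subsampling robustness


def size_bin_robustness(
    coordinates: np.ndarray,
    labels,
    n_size_bins: int = 5,
    subsample_frac: float = 1 / 3,
    n_iter: int = 10_000,
    seed: int = 0,
    n_pcs: int | None = None,
) -> pd.DataFrame:
    """Compare inter-population distances of small vs large populations.

    Populations are binned equal-frequency by size; within the smallest- and
    largest-size bins, per iteration ceil(frac * n) cells are drawn from each
    population, inter-population distances among the subsampled cells are
    collected, and Cohen's d is computed for small-vs-large, small-vs-intra
    and large-vs-intra (intra = all intra-population distances, unsubsampled).
    Returns one row per iteration.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    labels = np.asarray(labels)
    if n_pcs is not None:
        coordinates = coordinates[:, :n_pcs]
    pops, counts = np.unique(labels, return_counts=True)
    order = np.argsort(counts, kind="stable")
    pops, counts = pops[order], counts[order]
    edges = np.array_split(np.arange(pops.size), n_size_bins)
    small_pops, large_pops = pops[edges[0]], pops[edges[-1]]
    if small_pops.size < 2 or large_pops.size < 2:
        raise DistanceError("extreme size bins need at least 2 populations each")

    dset = pairwise_distances(coordinates, labels)
    intra = partition_intra_inter(dset).intra
    full = np.zeros((labels.size, labels.size))
    iu, ju = np.triu_indices(labels.size, k=1)
    full[iu, ju] = dset.distances
    full += full.T
    idx_by_pop = {p: np.flatnonzero(labels == p) for p in pops}

    rng = np.random.default_rng(seed)

    def draw_inter(bin_pops) -> np.ndarray:
        chosen = [
            rng.choice(idx_by_pop[p], size=int(np.ceil(subsample_frac * idx_by_pop[p].size)), replace=False)
            for p in bin_pops
        ]
        vals = []
        for i in range(len(chosen)):
            for j in range(i + 1, len(chosen)):
                vals.append(full[np.ix_(chosen[i], chosen[j])].ravel())
        return np.concatenate(vals)

    rows = []
    for it in range(n_iter):
        inter_small = draw_inter(small_pops)
        inter_large = draw_inter(large_pops)
        rows.append(
            {
                "iteration": it,
                "d_small_vs_large": cohens_d(inter_small, inter_large),
                "d_small_vs_intra": cohens_d(inter_small, intra),
                "d_large_vs_intra": cohens_d(inter_large, intra),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results objects


@dataclass
class PopulationDistanceResults:
    """Fitted intra/inter distance comparison with its permutation null."""

    n_cells: int
    n_populations: int
    n_pcs_used: int
    d_intra_inter: float
    ks_statistic: float
    ks_pvalue: float
    n_intra: int
    n_inter: int
    permutation: PermutationResult | None = None
    partition: IntraInterPartition | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        rows = [
            ("cells", self.n_cells),
            ("populations", self.n_populations),
            ("PCs used", self.n_pcs_used),
            ("intra pairs", self.n_intra),
            ("inter pairs", self.n_inter),
            ("Cohen's d (intra vs inter)", round(self.d_intra_inter, 4)),
            ("KS statistic (intra vs inter)", round(self.ks_statistic, 4)),
            ("KS p value", float(f"{self.ks_pvalue:.3g}")),
        ]
        if self.permutation is not None:
            rows += [
                ("permutations", self.permutation.n_perm),
                ("mean Cohen's d (intra vs perm)", round(float(self.permutation.d_intra_vs_perm.mean()), 4)),
                ("mean Cohen's d (inter vs perm)", round(float(self.permutation.d_inter_vs_perm.mean()), 4)),
                ("pooled perm-intra pairs", self.permutation.pooled_size),
            ]
        out = pd.DataFrame({"statistic": [r[0] for r in rows]})
        out["value"] = pd.Series([r[1] for r in rows], dtype=object)
        return out

    def plot_null(self, ax=None):
        """Diagnostic: permutation d distributions vs the observed d."""
        import matplotlib.pyplot as plt

        if self.permutation is None:
            raise DistanceError("fit with permutations to plot the null")
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.permutation.d_intra_vs_perm, bins=40, alpha=0.6, label="intra vs perm")
        ax.hist(self.permutation.d_inter_vs_perm, bins=40, alpha=0.6, label="inter vs perm")
        ax.axvline(self.d_intra_inter, color="k", ls="--", label="observed intra vs inter")
        ax.set_xlabel("Cohen's d")
        ax.legend()
        return ax


class PopulationDistance:
    """Model: cells in PC space with population labels.

    Parameters
    ----------
    coordinates : cells x components PC coordinates
    labels : population (receptor) id per cell
    n_pcs : number of leading PCs to use (default: all provided)
    """

    def __init__(self, coordinates: np.ndarray, labels, n_pcs: int | None = None):
        self.dists = pairwise_distances(coordinates, labels, n_pcs=n_pcs)
        self.coordinates = np.asarray(coordinates, dtype=float)
        self.labels = np.asarray(labels)

    def fit(
        self, n_perm: int = 1000, seed: int = 0, pool_mode: str = "full"
    ) -> PopulationDistanceResults:
        part = partition_intra_inter(self.dists)
        d = cohens_d(part.intra, part.inter)
        ks_stat, ks_p = ks_compare(part.intra, part.inter)
        perm = (
            permutation_null(self.dists, n_perm=n_perm, seed=seed, pool_mode=pool_mode)
            if n_perm > 0
            else None
        )
        return PopulationDistanceResults(
            n_cells=self.labels.size,
            n_populations=int(np.unique(self.labels).size),
            n_pcs_used=self.dists.n_pcs_used,
            d_intra_inter=d,
            ks_statistic=ks_stat,
            ks_pvalue=ks_p,
            n_intra=part.n_intra,
            n_inter=part.n_inter,
            permutation=perm,
            partition=part,
        )
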