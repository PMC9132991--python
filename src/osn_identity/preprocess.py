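"""Single-cell preprocessing: normalization, receptor assignment, multiplet
filtering, PCA embedding and elbow-based component selection.

The pipeline mirrors a standard droplet workflow for olfactory sensory
neurons: library-size normalization (scale 1e4, natural log, pseudocount 1),
assignment of each cell to the OSN population of its highest-expressed
receptor gene, removal of low-level and multi-receptor cells by a
median-minus-3-MAD cutoff on the top receptor level, PCA on scaled genes,
and kneedle elbow detection (S = 1, convex, decreasing) on the explained
standard deviation of the top components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Cells x genes UMI counts with a flagged subset of receptor genes."""

    counts: sp.spmatrix | np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    receptor_gene_flags: np.ndarray

    def __post_init__(self) -> None:
        self.receptor_gene_flags = np.asarray(self.receptor_gene_flags, dtype=bool)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise PreprocessError("id lists do not match matrix shape")
        if len(set(self.gene_ids)) != n_genes:
            raise PreprocessError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise PreprocessError("duplicate cell ids")
        if self.receptor_gene_flags.size != n_genes:
            raise PreprocessError("receptor flag length mismatch")
        if not self.receptor_gene_flags.any():
            raise PreprocessError("at least one receptor gene must be flagged")

    def dense(self) -> np.ndarray:
        return self.counts.toarray() if sp.issparse(self.counts) else np.asarray(self.counts)


@dataclass
class NormalizedMatrix:
    values: np.ndarray  # cells x genes
    gene_ids: list[str]
    cell_ids: list[str]
    receptor_gene_flags: np.ndarray
    normalization: dict = field(
        default_factory=lambda: {"scale_factor": 1e4, "pseudocount": 1, "log_base": "e"}
    )


@dataclass
class PopulationAssignment:
    """Per-cell receptor-based population call."""

    cell_ids: list[str]
    status: np.ndarray  # {assigned, no_receptor, below_cutoff, multireceptor}
    receptor_id: np.ndarray  # object array, None when not assigned
    top_receptor_level: np.ndarray
    second_receptor_level: np.ndarray
    ties: list[str] = field(default_factory=list)
    cutoff: float | None = None

    def population_sizes(self) -> pd.Series:
        mask = self.status == "assigned"
        return pd.Series(self.receptor_id[mask]).value_counts()

    def assigned_labels(self) -> pd.Series:
        mask = self.status == "assigned"
        return pd.Series(self.receptor_id[mask], index=np.asarray(self.cell_ids)[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "status": self.status,
                "receptor_id": [r if r is not None else "" for r in self.receptor_id],
                "top_receptor_level": self.top_receptor_level,
                "second_receptor_level": self.second_receptor_level,
            }
        )


@dataclass
class Embedding:
    coordinates: np.ndarray  # cells x components
    explained_sd: np.ndarray
    cell_ids: list[str]
    n_selected: int
    receptor_genes_excluded: bool

    def __post_init__(self) -> None:
        if np.any(np.diff(self.explained_sd) > 1e-9):
            raise PreprocessError("explained_sd must be non-increasing")
        if not 1 <= self.n_selected <= self.coordinates.shape[1]:
            raise PreprocessError("n_selected out of range")

    def selected(self, n_pcs: int | None = None) -> np.ndarray:
        n = self.n_selected if n_pcs is None else n_pcs
        if n > self.coordinates.shape[1]:
            raise PreprocessError(f"requested {n} PCs, only {self.coordinates.shape[1]} available")
        return self.coordinates[:, :n]


def log_normalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """value[c, g] = ln(1 + scale_factor * count[c, g] / total[c])."""
    if scale_factor <= 0:
        raise PreprocessError("scale_factor must be positive")
    dense = counts.dense().astype(float)
    totals = dense.sum(axis=1)
    bad = np.flatnonzero(totals == 0)
    if bad.size:
        names = [counts.cell_ids[i] for i in bad[:10]]
        raise PreprocessError(f"cells with zero total counts: {names}")
    values = np.log1p(scale_factor * dense / totals[:, None])
    return NormalizedMatrix(
        values=values,
        gene_ids=list(counts.gene_ids),
        cell_ids=list(counts.cell_ids),
        receptor_gene_flags=counts.receptor_gene_flags.copy(),
        normalization={"scale_factor": scale_factor, "pseudocount": 1, "log_base": "e"},
    )


def assign_populations(normalized: NormalizedMatrix) -> PopulationAssignment:
    """Rank receptor genes per cell by normalized level; the top receptor
    defines the population.  Exact ties are broken lexicographically by
    receptor id and recorded."""
    flags = normalized.receptor_gene_flags
    if not flags.any():
        raise PreprocessError("no receptor genes flagged")
    rec_values = normalized.values[:, flags]
    rec_ids = np.asarray([g for g, f in zip(normalized.gene_ids, flags) if f])
    # lexicographic id order makes argmax deterministic for exact ties
    order = np.argsort(rec_ids)
    rec_values = rec_values[:, order]
    rec_ids = rec_ids[order]

    n_cells = rec_values.shape[0]
    status = np.full(n_cells, "assigned", dtype=object)
    receptor = np.full(n_cells, None, dtype=object)
    top = np.zeros(n_cells)
    second = np.zeros(n_cells)
    ties: list[str] = []
    top_idx = np.argmax(rec_values, axis=1)
    for c in range(n_cells):
        vals = rec_values[c]
        if not np.any(vals > 0):
            status[c] = "no_receptor"
            continue
        i = top_idx[c]
        top[c] = vals[i]
        receptor[c] = rec_ids[i]
        rest = np.delete(vals, i)
        second[c] = rest.max() if rest.size else 0.0
        if rest.size and second[c] == top[c]:
            ties.append(normalized.cell_ids[c])
    if ties:
        logger.info("%d cells with exact top-receptor ties (lexicographic tie-break)", len(ties))
    return PopulationAssignment(
        cell_ids=list(normalized.cell_ids),
        status=np.asarray(status, dtype=object),
        receptor_id=receptor,
        top_receptor_level=top,
        second_receptor_level=second,
        ties=ties,
    )


def mad_multiplet_filter(
    assignment: PopulationAssignment, n_mads: float = 3.0, scaled_mad: bool = True
) -> PopulationAssignment:
    """Median - n_mads * MAD cutoff on top receptor levels.

    Cells whose top receptor falls below the cutoff become ``below_cutoff``;
    cells with a second receptor at or above the cutoff become
    ``multireceptor``.  ``scaled_mad`` applies the 1.4826 normal-consistency
    constant (the default of common statistical environments).
    """
    with_rec = assignment.status != "no_receptor"
    levels = assignment.top_receptor_level[with_rec]
    if levels.size < 2:
        raise PreprocessError("need at least 2 cells with receptor expression for MAD")
    med = float(np.median(levels))
    mad = float(np.median(np.abs(levels - med)))
    if scaled_mad:
        mad *= 1.4826
    cutoff = med - n_mads * mad

    status = assignment.status.copy()
    for c in range(len(assignment.cell_ids)):
        if status[c] == "no_receptor":
            continue
        if assignment.top_receptor_level[c] < cutoff:
            status[c] = "below_cutoff"
        elif assignment.second_receptor_level[c] >= cutoff and assignment.second_receptor_level[c] > 0:
            status[c] = "multireceptor"
        else:
            status[c] = "assigned"
    out = PopulationAssignment(
        cell_ids=list(assignment.cell_ids),
        status=status,
        receptor_id=assignment.receptor_id.copy(),
        top_receptor_level=assignment.top_receptor_level.copy(),
        second_receptor_level=assignment.second_receptor_level.copy(),
        ties=list(assignment.ties),
        cutoff=cutoff,
    )
    return out


def filter_populations_min_cells(
    assignment: PopulationAssignment, min_cells: int
) -> PopulationAssignment:
    """Drop assigned cells whose population has fewer than ``min_cells`` cells.

    Excluded cells keep their receptor id but get status ``below_cutoff``-like
    exclusion marker ``small_population``.
    """
    if min_cells < 1:
        raise PreprocessError("min_cells must be >= 1")
    sizes = assignment.population_sizes()
    keep = set(sizes[sizes >= min_cells].index)
    status = assignment.status.copy()
    for c in range(len(assignment.cell_ids)):
        if status[c] == "assigned" and assignment.receptor_id[c] not in keep:
            status[c] = "small_population"
    return PopulationAssignment(
        cell_ids=list(assignment.cell_ids),
        status=status,
        receptor_id=assignment.receptor_id.copy(),
        top_receptor_level=assignment.top_receptor_level.copy(),
        second_receptor_level=assignment.second_receptor_level.copy(),
        ties=list(assignment.ties),
        cutoff=assignment.cutoff,
    )


def pca_embed(
    normalized: NormalizedMatrix,
    n_components: int = 50,
    exclude_receptor_genes: bool = True,
    random_state: int = 0,
) -> Embedding:
    """PCA on centred, unit-scaled genes with a deterministic sign convention.

    Zero-variance genes are dropped (count logged).  Each component is
    flipped so that its largest-magnitude gene loading is positive.
    """
    values = normalized.values
    if exclude_receptor_genes:
        values = values[:, ~normalized.receptor_gene_flags]
    n_cells = values.shape[0]
    sd = values.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d zero-variance genes before scaling", dropped)
    values = values[:, keep]
    if values.shape[1] < n_components:
        raise PreprocessError(
            f"{values.shape[1]} non-constant genes < {n_components} requested components"
        )
    if n_components > n_cells - 1:
        raise PreprocessError("n_components must be <= cells - 1")
    scaled = (values - values.mean(axis=0)) / sd[keep]
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=random_state)
    coords = pca.fit_transform(scaled)
    # sign convention: largest-magnitude loading positive
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[k] *= -1
            coords[:, k] *= -1
    explained_sd = pca.singular_values_ / np.sqrt(n_cells - 1)
    n_sel = select_top_pcs(explained_sd)
    return Embedding(
        coordinates=coords,
        explained_sd=explained_sd,
        cell_ids=list(normalized.cell_ids),
        n_selected=n_sel,
        receptor_genes_excluded=exclude_receptor_genes,
    )


def select_top_pcs(explained_sd: np.ndarray, sensitivity: float = 1.0) -> int:
    """Kneedle elbow on a convex decreasing curve; returns the component
    count at the detected elbow (1-based).

    Offline, unsmoothed variant: normalize x and y to [0, 1], flip the
    decreasing convex curve into a concave increasing one, and scan the
    difference-to-diagonal curve; the first local maximum whose difference
    the curve subsequently drops below (by the sensitivity-scaled mean x
    spacing) is the knee.  If no knee is detected the fallback returns
    min(15, n) with a warning.
    """
    y = np.asarray(explained_sd, dtype=float)
    n = y.size
    if n < 3:
        raise PreprocessError("need at least 3 components for elbow detection")
    x = np.arange(n, dtype=float)
    x_n = x / (n - 1)
    span = y.max() - y.min()
    if span == 0:
        warnings.warn("flat explained-sd curve; falling back to min(15, n) components")
        return min(15, n)
    y_n = (y - y.min()) / span
    y_t = 1.0 - y_n  # convex decreasing -> concave increasing
    diff = y_t - x_n
    # interior local maxima of the difference curve
    lmx = [
        i
        for i in range(1, n - 1)
        if diff[i] >= diff[i - 1] and diff[i] >= diff[i + 1]
    ]
    threshold_drop = sensitivity * np.mean(np.diff(x_n))
    for i in lmx:
        t = diff[i] - threshold_drop
        j = i + 1
        while j < n:
            if j in lmx and j != i:
                break
            if diff[j] < t:
                return i + 1  # knee at 1-based component count
            j += 1
    warnings.warn("no knee detected in explained-sd curve; falling back to min(15, n)")
    return min(15, n)
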