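"""Synthetic OR families, single-cell UMI datasets, and bulk exposure data.

Three generators with known ground truth for every downstream stage:

* ``simulate_or_family`` grows a receptor family by random gene duplication.
  Each duplicate lands adjacent to its parent in the same genomic cluster
  with probability ``cis_duplication_prob`` (otherwise it founds a new
  cluster), so genomic proximity is confounded with sequence similarity —
  the structure the association analyses must untangle.  Protein sequences
  evolve by Poisson substitutions along the branches.

* ``simulate_osn_counts`` draws negative-binomial UMI counts for cells of
  each receptor-defined population.  Population expression programs are a
  mixture of a Brownian diffusion along the family tree (weight
  ``sequence_coupling``) and independent offsets, so transcriptomic
  similarity between populations can be coupled, with tunable strength, to
  receptor sequence similarity.  Doublets are sums of two random cells.

* ``simulate_exposure_counts`` draws bulk exon/transcript counts where
  transcriptionally modulated genes change intron and exon rates together
  while post-transcriptionally modulated genes change exon rates only.

Negative-binomial parameterization throughout: variance = mu + mu^2 * dispersion.
All randomness flows from the spec seed through numpy SeedSequence spawning,
so each stage draws from its own substream and outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .preprocess import CountMatrix

_AAS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class SimulationError(ValueError):
    pass


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + mu^2 * dispersion."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        raise SimulationError("nb_dispersion must be > 0")
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) / shape)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# OR family


@dataclass(frozen=True)
class ORFamilySpec:
    n_receptors: int = 1141
    alignment_length: int = 310
    substitution_rate: float = 1.0  # expected substitutions per site per unit branch length
    cis_duplication_prob: float = 0.85
    n_chromosomes: int = 19
    intra_cluster_spacing: float = 25_000.0  # mean bp between adjacent cluster genes
    inter_cluster_gap: float = 5_000_000.0  # minimum bp between clusters
    branch_length_mean: float = 0.12
    class_split_depth: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_receptors < 2:
            raise SimulationError("n_receptors must be >= 2")
        if self.alignment_length < 10:
            raise SimulationError("alignment_length must be >= 10")
        if not 0 <= self.cis_duplication_prob <= 1:
            raise SimulationError("cis_duplication_prob must be in [0, 1]")
        if self.inter_cluster_gap <= self.intra_cluster_spacing:
            raise SimulationError("inter_cluster_gap must exceed intra_cluster_spacing")
        if self.substitution_rate < 0 or self.branch_length_mean <= 0:
            raise SimulationError("rates must be non-negative, branch length mean positive")
        if self.n_chromosomes < 1 or self.class_split_depth < 1:
            raise SimulationError("n_chromosomes and class_split_depth must be >= 1")


@dataclass
class Tree:
    """Rooted binary tree stored as parent/branch-length arrays.

    Node 0 is the root (branch length 0); tips carry receptor indices in
    ``tip_receptor`` (-1 for internal nodes).
    """

    parent: np.ndarray
    length: np.ndarray
    tip_receptor: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for i in range(1, self.n_nodes):
            ch[self.parent[i]].append(i)
        return ch

    def tips_under(self) -> dict[int, np.ndarray]:
        """Receptor indices under each node."""
        ch = self.children()
        out: dict[int, np.ndarray] = {}

        def rec(node: int) -> np.ndarray:
            if self.tip_receptor[node] >= 0:
                out[node] = np.array([self.tip_receptor[node]])
            else:
                out[node] = np.concatenate([rec(c) for c in ch[node]])
            return out[node]

        rec(0)
        return out

    def shared_path_matrix(self) -> np.ndarray:
        """C[i, j] = summed branch length of the shared root path of tips i, j
        (the Brownian-motion covariance up to the diffusion rate)."""
        n_tips = int((self.tip_receptor >= 0).sum())
        C = np.zeros((n_tips, n_tips))
        under = self.tips_under()
        for node in range(1, self.n_nodes):
            tips = under[node]
            C[np.ix_(tips, tips)] += self.length[node]
        return C

    def patristic_matrix(self) -> np.ndarray:
        C = self.shared_path_matrix()
        depth = np.diag(C)
        return depth[:, None] + depth[None, :] - 2 * C

    def to_newick(self, tip_names: list[str]) -> str:
        ch = self.children()

        def rec(node: int) -> str:
            if self.tip_receptor[node] >= 0:
                return f"{tip_names[self.tip_receptor[node]]}:{self.length[node]:.6f}"
            inner = ",".join(rec(c) for c in ch[node])
            return f"({inner}):{self.length[node]:.6f}"

        inner = ",".join(rec(c) for c in ch[0])
        return f"({inner});"


@dataclass
class ORFamily:
    receptor_ids: list[str]
    aligned_sequences: list[str]
    chromosome: list[str]
    position: np.ndarray  # 1-based bp
    true_cluster: np.ndarray
    class_label: list[str]
    tree: Tree

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.aligned_sequences}
        if len(lens) > 1:
            raise SimulationError("aligned sequences differ in length")
        by_chrom: dict[str, list[int]] = {}
        for c, p in zip(self.chromosome, self.position):
            by_chrom.setdefault(c, []).append(int(p))
        for c, ps in by_chrom.items():
            srt = sorted(ps)
            if any(a >= b for a, b in zip(srt, srt[1:])):
                raise SimulationError(f"positions not strictly increasing on {c}")

    @property
    def n_receptors(self) -> int:
        return len(self.receptor_ids)

    def annotations(self):
        """GeneAnnotation list for the genomics module (single-exon CDS)."""
        from .genomics import GeneAnnotation

        return [
            GeneAnnotation(r, c, "+", int(p))
            for r, c, p in zip(self.receptor_ids, self.chromosome, self.position)
        ]


def simulate_or_family(spec: ORFamilySpec) -> ORFamily:
    spec.validate()
    seq = np.random.SeedSequence(spec.seed)
    rng_tree, rng_layout, rng_seq = (np.random.default_rng(s) for s in seq.spawn(3))

    n = spec.n_receptors
    # grow the tree by random duplication of a uniformly chosen tip
    parent = [-1, 0, 0]
    length = [0.0] + list(rng_tree.exponential(spec.branch_length_mean, 2))
    tip_nodes = [1, 2]
    while len(tip_nodes) < n:
        k = int(rng_tree.integers(len(tip_nodes)))
        node = tip_nodes[k]
        c1, c2 = len(parent), len(parent) + 1
        parent += [node, node]
        length += list(rng_tree.exponential(spec.branch_length_mean, 2))
        tip_nodes[k] = c1  # c1 continues the parent lineage
        tip_nodes.append(c2)

    # genomic placement: per-chromosome ordered cluster lists of tip nodes
    chrom_of_cluster: dict[int, int] = {}
    cluster_order: dict[int, list[int]] = {}  # cluster -> ordered tip nodes
    clusters_on_chrom: dict[int, list[int]] = {c: [] for c in range(spec.n_chromosomes)}
    node_cluster: dict[int, int] = {}

    def new_cluster(node: int) -> None:
        cid = len(chrom_of_cluster)
        chrom = int(rng_layout.integers(spec.n_chromosomes))
        chrom_of_cluster[cid] = chrom
        clusters_on_chrom[chrom].append(cid)
        cluster_order[cid] = [node]
        node_cluster[node] = cid

    # replay the duplication history for the layout; the tree build above
    # recorded it implicitly: children of each internal node
    ch = {i: [] for i in range(len(parent))}
    for i in range(1, len(parent)):
        ch[parent[i]].append(i)

    def place(node: int) -> None:
        kids = ch[node]
        if not kids:
            return
        c1, c2 = kids
        # c1 inherits the parent's slot
        cid = node_cluster.pop(node)
        idx = cluster_order[cid].index(node)
        cluster_order[cid][idx] = c1
        node_cluster[c1] = cid
        if rng_layout.random() < spec.cis_duplication_prob:
            side = int(rng_layout.integers(2))
            cluster_order[cid].insert(idx + side, c2)
            node_cluster[c2] = cid
        else:
            new_cluster(c2)
        place(c1)
        place(c2)

    # founders: the root's two children each found a lineage/cluster
    root_kids = ch[0]
    new_cluster(root_kids[0])
    new_cluster(root_kids[1])
    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * len(parent) + 100))
    try:
        place(root_kids[0])
        place(root_kids[1])
    finally:
        sys.setrecursionlimit(old_limit)

    # receptor indexing by tip node order of appearance
    tip_nodes_sorted = sorted(tip_nodes)
    tip_index = {node: i for i, node in enumerate(tip_nodes_sorted)}
    tip_receptor = np.full(len(parent), -1)
    for node, i in tip_index.items():
        tip_receptor[node] = i
    tree = Tree(np.asarray(parent), np.asarray(length), tip_receptor)

    # coordinates: clusters laid left to right per chromosome
    position = np.zeros(n, dtype=np.int64)
    chromosome = [""] * n
    cluster_id = np.zeros(n, dtype=int)
    for chrom, cids in clusters_on_chrom.items():
        cursor = 1 + int(rng_layout.exponential(spec.intra_cluster_spacing))
        for cid in cids:
            for j, node in enumerate(cluster_order[cid]):
                if j > 0:
                    # bounded jitter: intra gaps stay well below mean + 3 SD,
                    # so cluster membership is recoverable from the layout
                    cursor += max(1, int(rng_layout.uniform(0.2, 1.8) * spec.intra_cluster_spacing))
                r = tip_index[node]
                position[r] = cursor
                chromosome[r] = f"chr{chrom + 1}"
                cluster_id[r] = cid
            cursor += int(spec.inter_cluster_gap + rng_layout.exponential(spec.inter_cluster_gap / 10))

    # sequences: Poisson substitutions along branches
    root_seq = rng_seq.integers(20, size=spec.alignment_length)
    seqs: dict[int, np.ndarray] = {0: root_seq}
    for node in range(1, len(parent)):
        s = seqs[parent[node]].copy()
        n_sub = rng_seq.poisson(spec.substitution_rate * length[node] * spec.alignment_length)
        if n_sub:
            sites = rng_seq.integers(spec.alignment_length, size=n_sub)
            for site in sites:
                s[site] = (s[site] + 1 + rng_seq.integers(19)) % 20
        seqs[node] = s

    # class labels from the clades at class_split_depth
    depth_nodes: list[int] = []

    def collect(node: int, depth: int) -> None:
        if depth == spec.class_split_depth or not ch[node]:
            depth_nodes.append(node)
            return
        for c in ch[node]:
            collect(c, depth + 1)

    collect(0, 0)
    under = tree.tips_under()
    class_label = ["II"] * n
    for r in under[depth_nodes[0]]:
        class_label[r] = "I"

    receptor_ids = [f"OR{i + 1:04d}" for i in range(n)]
    aligned = ["".join(_AAS[seqs[node]]) for node in tip_nodes_sorted]
    return ORFamily(
        receptor_ids=receptor_ids,
        aligned_sequences=aligned,
        chromosome=chromosome,
        position=position,
        true_cluster=cluster_id,
        class_label=class_label,
        tree=tree,
    )


# ---------------------------------------------------------------------------
# single-cell counts


@dataclass(frozen=True)
class OSNSimSpec:
    cells_per_population_mean: float = 8.4
    cells_per_population_dispersion: float = 1.2
    n_genes: int = 2000
    program_scale: float = 0.5  # SD of population log-expression offsets
    sequence_coupling: float = 0.5  # fraction of program variance diffused on the tree
    library_size_mean: float = 5000.0
    library_size_shape: float = 8.0
    nb_dispersion: float = 0.1
    receptor_expression_rate: float = 0.02  # expected UMI fraction of the chosen receptor
    receptor_rate_log_sd: float = 0.8  # per-cell lognormal spread of that fraction
    doublet_rate: float = 0.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.sequence_coupling <= 1:
            raise SimulationError("sequence_coupling must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        if not 0 <= self.doublet_rate < 1:
            raise SimulationError("doublet_rate must be in [0, 1)")
        if not 0 < self.receptor_expression_rate < 1:
            raise SimulationError("receptor_expression_rate must be in (0, 1)")
        if self.n_genes < 2 or self.cells_per_population_mean <= 0:
            raise SimulationError("invalid population/gene sizing")


@dataclass
class SyntheticSCDataset:
    counts: sp.csr_matrix  # cells x genes (receptor genes included, flagged)
    gene_ids: list[str]
    cell_ids: list[str]
    receptor_gene_flags: np.ndarray
    true_population: np.ndarray
    true_doublet: np.ndarray
    doublet_sources: list[tuple[int, int]]
    true_program: pd.DataFrame  # population x gene log-offsets

    def to_count_matrix(self) -> CountMatrix:
        return CountMatrix(
            counts=self.counts,
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            receptor_gene_flags=self.receptor_gene_flags,
        )


def population_programs(
    family: ORFamily, spec: OSNSimSpec, rng: np.random.Generator
) -> np.ndarray:
    """Population x gene log-offset matrix: sqrt(c) tree-Brownian + sqrt(1-c)
    independent, each component scaled to marginal SD ``program_scale``."""
    n_pop = family.n_receptors
    if spec.program_scale == 0:
        return np.zeros((n_pop, spec.n_genes))
    C = family.tree.shared_path_matrix()
    scale = np.mean(np.diag(C))
    C_norm = C / scale if scale > 0 else np.eye(n_pop)
    L = np.linalg.cholesky(C_norm + 1e-10 * np.eye(n_pop))
    z_tree = rng.standard_normal((n_pop, spec.n_genes))
    z_ind = rng.standard_normal((n_pop, spec.n_genes))
    c = spec.sequence_coupling
    prog = spec.program_scale * (np.sqrt(c) * (L @ z_tree) + np.sqrt(1 - c) * z_ind)
    return prog


def simulate_osn_counts(family: ORFamily, spec: OSNSimSpec) -> SyntheticSCDataset:
    spec.validate()
    if family.n_receptors == 0:
        raise SimulationError("empty family")
    seq = np.random.SeedSequence(spec.seed)
    rng_prog, rng_cells, rng_counts, rng_doub = (np.random.default_rng(s) for s in seq.spawn(4))

    n_pop = family.n_receptors
    n_genes = spec.n_genes
    prog = population_programs(family, spec, rng_prog)
    baseline = rng_prog.normal(0.0, spec.baseline_log_sd, n_genes)

    cells_per_pop = _nb_draw(
        rng_cells,
        np.full(n_pop, spec.cells_per_population_mean),
        spec.cells_per_population_dispersion,
    )

    gene_ids = [f"Gene{g + 1:05d}" for g in range(n_genes)] + list(family.receptor_ids)
    flags = np.zeros(n_genes + n_pop, dtype=bool)
    flags[n_genes:] = True

    blocks = []
    true_pop: list[str] = []
    for p in range(n_pop):
        n_cells = int(cells_per_pop[p])
        if n_cells == 0:
            continue
        lib = rng_counts.gamma(
            spec.library_size_shape, spec.library_size_mean / spec.library_size_shape, n_cells
        )
        # receptor UMI fraction varies between cells (lognormal, unit mean)
        sd = spec.receptor_rate_log_sd
        rec_frac = spec.receptor_expression_rate * rng_counts.lognormal(-sd * sd / 2, sd, n_cells)
        rec_frac = np.clip(rec_frac, 0.0, 0.9)
        w = np.exp(baseline + prog[p])
        w = w / w.sum()
        mu = lib[:, None] * (1.0 - rec_frac)[:, None] * w[None, :]
        block = np.zeros((n_cells, n_genes + n_pop), dtype=np.int64)
        block[:, :n_genes] = _nb_draw(rng_counts, mu, spec.nb_dispersion)
        block[:, n_genes + p] = _nb_draw(rng_counts, lib * rec_frac, spec.nb_dispersion)
        blocks.append(block)
        true_pop.extend([family.receptor_ids[p]] * n_cells)
    if not blocks:
        raise SimulationError("no cells drawn; increase cells_per_population_mean")
    counts = np.vstack(blocks)
    n_single = counts.shape[0]
    true_population = np.asarray(true_pop, dtype=object)
    true_doublet = np.zeros(n_single, dtype=bool)
    doublet_sources: list[tuple[int, int]] = []

    if spec.doublet_rate > 0 and n_single >= 2:
        n_doub = int(round(spec.doublet_rate / (1 - spec.doublet_rate) * n_single))
        extra = np.zeros((n_doub, counts.shape[1]), dtype=np.int64)
        extra_pop = []
        for d in range(n_doub):
            i, j = rng_doub.choice(n_single, size=2, replace=False)
            extra[d] = counts[i] + counts[j]
            # label the doublet by its larger-library source
            src = i if counts[i].sum() >= counts[j].sum() else j
            extra_pop.append(true_population[src])
            doublet_sources.append((int(i), int(j)))
        counts = np.vstack([counts, extra])
        true_population = np.concatenate([true_population, np.asarray(extra_pop, dtype=object)])
        true_doublet = np.concatenate([true_doublet, np.ones(n_doub, dtype=bool)])

    cell_ids = [f"cell{i + 1:05d}" for i in range(counts.shape[0])]
    return SyntheticSCDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        receptor_gene_flags=flags,
        true_population=true_population,
        true_doublet=true_doublet,
        doublet_sources=doublet_sources,
        true_program=pd.DataFrame(
            prog, index=family.receptor_ids, columns=gene_ids[:n_genes]
        ),
    )


# ---------------------------------------------------------------------------
# bulk exposure counts


@dataclass(frozen=True)
class ExposureSimSpec:
    n_genes: int = 5000
    n_control: int = 3
    n_exposed: int = 3
    frac_txn_up: float = 0.05
    frac_txn_down: float = 0.05
    frac_post: float = 0.05
    fc_magnitude: float = 2.0  # log2 fold-change magnitude
    intron_fraction: float = 0.3
    intron_fraction_concentration: float = 30.0
    nb_dispersion: float = 0.05
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    depth_log_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.frac_txn_up + self.frac_txn_down + self.frac_post > 1:
            raise SimulationError("modulated fractions must sum to <= 1")
        if not 0 < self.intron_fraction < 1:
            raise SimulationError("intron_fraction must be in (0, 1)")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        if min(self.n_genes, self.n_control, self.n_exposed) < 1:
            raise SimulationError("need at least one gene and one sample per condition")


@dataclass
class SyntheticExposureDataset:
    exon_counts: pd.DataFrame  # gene x sample
    transcript_counts: pd.DataFrame
    condition: pd.Series  # per sample: control / exposed
    truth: pd.DataFrame  # per gene: modulation class + true log2 FC (exon level)

    @property
    def intron_counts(self) -> pd.DataFrame:
        return self.transcript_counts - self.exon_counts


def simulate_exposure_counts(spec: ExposureSimSpec) -> SyntheticExposureDataset:
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_genes
    n_up = int(round(spec.frac_txn_up * n))
    n_down = int(round(spec.frac_txn_down * n))
    n_post = int(round(spec.frac_post * n))
    classes = np.array(
        ["txn_up"] * n_up + ["txn_down"] * n_down + ["post"] * n_post
        + ["none"] * (n - n_up - n_down - n_post),
        dtype=object,
    )
    rng.shuffle(classes)

    base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, n)
    conc = spec.intron_fraction_concentration
    ifrac = rng.beta(spec.intron_fraction * conc, (1 - spec.intron_fraction) * conc, n)
    exon_rate = base * (1 - ifrac)
    intron_rate = base * ifrac

    fc_sign = np.zeros(n)
    fc_sign[classes == "txn_up"] = 1.0
    fc_sign[classes == "txn_down"] = -1.0
    post = classes == "post"
    fc_sign[post] = rng.choice([-1.0, 1.0], size=int(post.sum()))
    log2fc = fc_sign * spec.fc_magnitude
    mult = 2.0**log2fc

    samples = [f"ctrl{i + 1}" for i in range(spec.n_control)] + [
        f"exp{i + 1}" for i in range(spec.n_exposed)
    ]
    condition = pd.Series(
        ["control"] * spec.n_control + ["exposed"] * spec.n_exposed, index=samples
    )
    depth = rng.lognormal(0.0, spec.depth_log_sd, len(samples))

    exon = np.zeros((n, len(samples)), dtype=np.int64)
    intron = np.zeros((n, len(samples)), dtype=np.int64)
    txn = (classes == "txn_up") | (classes == "txn_down")
    for j, s in enumerate(samples):
        exposed = condition[s] == "exposed"
        e_rate = exon_rate.copy()
        i_rate = intron_rate.copy()
        if exposed:
            e_rate = e_rate * np.where(txn | post, mult, 1.0)
            i_rate = i_rate * np.where(txn, mult, 1.0)
        exon[:, j] = _nb_draw(rng, depth[j] * e_rate, spec.nb_dispersion)
        intron[:, j] = _nb_draw(rng, depth[j] * i_rate, spec.nb_dispersion)

    genes = [f"Gene{g + 1:05d}" for g in range(n)]
    exon_df = pd.DataFrame(exon, index=genes, columns=samples)
    transcript_df = pd.DataFrame(exon + intron, index=genes, columns=samples)
    truth = pd.DataFrame({"class": classes, "true_log2fc": log2fc}, index=genes)
    return SyntheticExposureDataset(
        exon_counts=exon_df, transcript_counts=transcript_df, condition=condition, truth=truth
    )
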