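"""Readers and writers for the pipeline's on-disk formats.

Single-cell counts travel as the 10x triplet dialect (matrix.mtx +
genes.tsv with id and symbol columns + barcodes.tsv); OR families as gapped
FASTA + GTF (one CDS per receptor, 1-based closed intervals) + newick;
tables as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .preprocess import CountMatrix
from .simulate import ORFamily, SyntheticSCDataset


def write_10x(dataset_or_matrix, out_dir: str | Path) -> None:
    """Write a 10x-style triplet (genes x cells matrix.mtx, genes.tsv, barcodes.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(dataset_or_matrix, SyntheticSCDataset):
        counts = dataset_or_matrix.counts
        gene_ids = dataset_or_matrix.gene_ids
        cell_ids = dataset_or_matrix.cell_ids
        flags = dataset_or_matrix.receptor_gene_flags
    else:
        cm: CountMatrix = dataset_or_matrix
        counts, gene_ids, cell_ids, flags = cm.counts, cm.gene_ids, cm.cell_ids, cm.receptor_gene_flags
    mat = sp.csr_matrix(counts).T.tocoo()  # 10x stores genes x cells
    mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    pd.DataFrame({"gene_id": gene_ids, "symbol": gene_ids, "receptor": np.asarray(flags, int)}).to_csv(
        out / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)


def read_10x(in_dir: str | Path) -> CountMatrix:
    """Read a 10x triplet directory into a CountMatrix (cells x genes)."""
    d = Path(in_dir)
    mat = sp.csr_matrix(mmread(str(d / "matrix.mtx"))).T
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)
    flags = (
        genes.iloc[:, 2].astype(int).to_numpy(dtype=bool)
        if genes.shape[1] > 2
        else np.zeros(len(genes), dtype=bool)
    )
    return CountMatrix(
        counts=mat,
        gene_ids=genes.iloc[:, 0].astype(str).tolist(),
        cell_ids=barcodes.iloc[:, 0].astype(str).tolist(),
        receptor_gene_flags=flags,
    )


def write_or_family(family: ORFamily, out_dir: str | Path, cds_length_nt: int = 930) -> None:
    """Write alignment FASTA, one-CDS-per-receptor GTF, newick tree and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "alignment.fasta", "w") as fh:
        for rid, seq in zip(family.receptor_ids, family.aligned_sequences):
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(out / "annotation.gtf", "w") as fh:
        for rid, chrom, pos in zip(family.receptor_ids, family.chromosome, family.position):
            start, end = int(pos), int(pos) + cds_length_nt - 1
            fh.write(
                f"{chrom}\tsim\tCDS\t{start}\t{end}\t.\t+\t0\t"
                f'gene_id "{rid}"; transcript_id "{rid}.t1";\n'
            )
    with open(out / "tree.nwk", "w") as fh:
        fh.write(family.tree.to_newick(family.receptor_ids) + "\n")
    pd.DataFrame(
        {
            "receptor_id": family.receptor_ids,
            "chromosome": family.chromosome,
            "position": family.position,
            "true_cluster": family.true_cluster,
            "class_label": family.class_label,
        }
    ).to_csv(out / "family_truth.tsv", sep="\t", index=False)


def write_sc_truth(dataset: SyntheticSCDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "cell_id": dataset.cell_ids,
            "true_population": dataset.true_population,
            "true_doublet": dataset.true_doublet.astype(int),
        }
    ).to_csv(out / "cell_truth.tsv", sep="\t", index=False)
    dataset.true_program.to_csv(out / "true_program.tsv", sep="\t")


def write_exposure(dataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.exon_counts.to_csv(out / "exon_counts.tsv", sep="\t")
    dataset.transcript_counts.to_csv(out / "transcript_counts.tsv", sep="\t")
    pd.DataFrame({"sample": dataset.condition.index, "condition": dataset.condition.values}).to_csv(
        out / "samples.tsv", sep="\t", index=False
    )
    dataset.truth.to_csv(out / "gene_truth.tsv", sep="\t")


def read_exposure(in_dir: str | Path):
    d = Path(in_dir)
    exon = pd.read_csv(d / "exon_counts.tsv", sep="\t", index_col=0)
    transcript = pd.read_csv(d / "transcript_counts.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    condition = pd.Series(samples["condition"].values, index=samples["sample"].astype(str))
    return exon, transcript, condition
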