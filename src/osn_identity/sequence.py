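"""Odorant-receptor protein sequence dissimilarity.

Implements the Miyata amino-acid replacement score between aligned receptor
pairs: every substituted column contributes the replacement score of the two
residues, every insertion column (residue aligned to a gap) contributes the
mean replacement score of the present residue against the 19 alternatives,
and the per-pair dissimilarity is the sum over columns.  The replacement
matrix derives from the classic two-property (polarity, side-chain volume)
formulation: d(a, b) = sqrt((dp / s_dp)^2 + (dv / s_dv)^2) with s_* the
standard deviations of the pairwise property differences.  It ships as a
frozen TSV fixture; a user-supplied 20x20 matrix file is also accepted.

Also implements the alignment trimming rule used before scoring: keep the
columns from the modal first-methionine column through the last column with
a gap fraction below 90%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = "-."
#: residues without a defined replacement score; treated as gaps with a warning
AMBIGUOUS = "XBZJUO*"

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_GAP_CODE = 20


class AlignmentError(ValueError):
    """Raised for malformed or untrimmable alignments."""


def load_miyata_matrix(path: str | Path | None = None) -> pd.DataFrame:
    """Return the 20x20 Miyata replacement matrix as a labelled DataFrame.

    Parameters
    ----------
    path
        Optional TSV file with one header row and one labelled row per
        residue.  When omitted the packaged fixture is used.
    """
    if path is None:
        with resources.files("osn_identity").joinpath("data/miyata1979.tsv").open() as fh:
            mat = pd.read_csv(fh, sep="\t", index_col=0)
    else:
        mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    if sorted(mat.index) != sorted(AMINO_ACIDS) or sorted(mat.columns) != sorted(AMINO_ACIDS):
        raise ValueError("replacement matrix must be labelled with the 20 standard residues")
    mat = mat.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)].astype(float)
    arr = mat.to_numpy()
    if not np.allclose(arr, arr.T):
        raise ValueError("replacement matrix must be symmetric")
    if np.any(np.diag(arr) != 0):
        raise ValueError("replacement matrix must have a zero diagonal")
    if np.any(arr < 0):
        raise ValueError("replacement matrix must be non-negative")
    return mat


def _extended_score_table(matrix: pd.DataFrame) -> np.ndarray:
    """21x21 lookup with the gap code: residue-vs-gap scores the residue's
    mean replacement score against the 19 other residues; gap-vs-gap is 0."""
    core = matrix.to_numpy(dtype=float)
    table = np.zeros((21, 21))
    table[:20, :20] = core
    insertion = core.sum(axis=1) / 19.0  # diagonal is zero, so sum/19 = mean vs others
    table[:20, _GAP_CODE] = insertion
    table[_GAP_CODE, :20] = insertion
    return table


def encode_alignment(rows: list[str]) -> np.ndarray:
    """Integer-encode gapped protein rows (gap/ambiguous -> gap code)."""
    if not rows:
        raise AlignmentError("empty alignment")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise AlignmentError("alignment rows differ in length")
    out = np.empty((len(rows), length), dtype=np.int8)
    n_ambiguous = 0
    for i, row in enumerate(rows):
        for j, ch in enumerate(row.upper()):
            if ch in _AA_INDEX:
                out[i, j] = _AA_INDEX[ch]
            elif ch in GAP_CHARS:
                out[i, j] = _GAP_CODE
            elif ch in AMBIGUOUS:
                out[i, j] = _GAP_CODE
                n_ambiguous += 1
            else:
                raise AlignmentError(f"invalid residue {ch!r} in row {i}, column {j}")
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} ambiguous residues (X/B/Z/...) treated as gaps", stacklevel=2
        )
    return out


@dataclass
class ORAlignment:
    """A gapped protein multiple alignment over a receptor family."""

    receptor_ids: list[str]
    rows: list[str]
    class_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.receptor_ids) != len(self.rows):
            raise AlignmentError("one row per receptor id required")
        if len(set(self.receptor_ids)) != len(self.receptor_ids):
            raise AlignmentError("duplicate receptor ids")
        self._encoded = encode_alignment(self.rows)

    @property
    def n_columns(self) -> int:
        return self._encoded.shape[1]

    @property
    def encoded(self) -> np.ndarray:
        return self._encoded

    @classmethod
    def from_fasta(cls, path: str | Path, class_labels: dict[str, str] | None = None) -> "ORAlignment":
        ids, rows = [], []
        seq: list[str] = []
        name = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if name is not None:
                        ids.append(name)
                        rows.append("".join(seq))
                    name = line[1:].split()[0]
                    seq = []
                elif line:
                    seq.append(line)
        if name is not None:
            ids.append(name)
            rows.append("".join(seq))
        return cls(ids, rows, class_labels or {})


def trim_alignment(alignment: ORAlignment, gap_fraction: float = 0.90) -> ORAlignment:
    """Trim to the window between the modal first-methionine column and the
    last column whose gap fraction is below ``gap_fraction``."""
    enc = alignment.encoded
    n_seq, n_col = enc.shape
    m_code = _AA_INDEX["M"]
    first_m = np.full(n_seq, -1)
    for i in range(n_seq):
        hits = np.flatnonzero(enc[i] == m_code)
        if hits.size:
            first_m[i] = hits[0]
    with_m = first_m[first_m >= 0]
    if with_m.size == 0:
        raise AlignmentError("no sequence contains a methionine; cannot locate start column")
    cols, counts = np.unique(with_m, return_counts=True)
    start = int(cols[np.argmax(counts)])  # modal first-M column; ties -> leftmost

    # column that maximizes overall M frequency, logged when it differs
    m_freq = (enc == m_code).sum(axis=0)
    alt = int(np.argmax(m_freq))
    if alt != start:
        logger.info("modal first-M column %d differs from max-M-frequency column %d", start, alt)

    gap_frac = (enc == _GAP_CODE).mean(axis=0)
    keep = np.flatnonzero(gap_frac < gap_fraction)
    keep = keep[keep >= start]
    if keep.size == 0:
        raise AlignmentError("no column at or after the start column passes the gap filter")
    end = int(keep[-1])
    rows = [r[start : end + 1] for r in alignment.rows]
    return ORAlignment(list(alignment.receptor_ids), rows, dict(alignment.class_labels))


def miyata_pair_difference(
    row_a: str, row_b: str, matrix: pd.DataFrame | None = None
) -> float:
    """Summed Miyata replacement score between two equal-length gapped rows."""
    if len(row_a) != len(row_b):
        raise AlignmentError("rows must have equal length")
    if matrix is None:
        matrix = load_miyata_matrix()
    enc = encode_alignment([row_a, row_b])
    table = _extended_score_table(matrix)
    return float(table[enc[0], enc[1]].sum())


def pairwise_aa_matrix(
    alignment: ORAlignment, matrix: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Symmetric receptor-by-receptor matrix of summed Miyata scores."""
    if matrix is None:
        matrix = load_miyata_matrix()
    table = _extended_score_table(matrix)
    enc = alignment.encoded
    n = enc.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        # vectorized over all later rows at once
        scores = table[enc[i][None, :], enc[i + 1 :]].sum(axis=1)
        out[i, i + 1 :] = scores
        out[i + 1 :, i] = scores
    return pd.DataFrame(out, index=alignment.receptor_ids, columns=alignment.receptor_ids)
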