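"""Bulk FACS-seq analysis of odorant-induced transcriptional modulation.

Stages: low-expression filtering by the local minimum of the count-density
curve, median-of-ratios size factors, a simplified negative-binomial Wald
differential-expression test against a log2 fold-change threshold of 0.5
with Benjamini–Hochberg adjustment, cross-population overlap of modulated
genes, and the exon–intron split analysis (EISA) that attributes expression
changes to transcription (intron and exon reads move together) versus
mRNA stability (exon reads move alone).

The DE stage is a deliberately simplified NB Wald test — moment-estimated
per-gene dispersion with a floor, no shrinkage — standing in for the
pipeline topology of heavier DE machinery, not replicating it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import gaussian_kde, norm, ttest_ind
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class ExposureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# filtering and normalization


def density_count_threshold(gene_counts, n_grid: int = 512) -> float:
    """Low-expression threshold from the count-density curve.

    Gaussian KDE (Silverman bandwidth) of log1p(counts) on a 512-point
    grid; the threshold is the first interior local minimum between the two
    largest density modes, mapped back to the count scale.  With no usable
    interior minimum the fallback is the 1st percentile of nonzero counts.
    """
    x = np.asarray(gene_counts, dtype=float)
    if x.size < 50:
        raise ExposureError("need at least 50 genes for a density threshold")
    lx = np.log1p(x)

    def fallback() -> float:
        nz = x[x > 0]
        if nz.size == 0:
            raise ExposureError("all counts are zero")
        warnings.warn("no interior density minimum; falling back to 1st percentile of nonzero counts")
        return float(np.percentile(nz, 1.0))

    try:
        kde = gaussian_kde(lx, bw_method="silverman")
    except np.linalg.LinAlgError:
        return fallback()
    grid = np.linspace(lx.min(), lx.max(), n_grid)
    dens = kde(grid)
    d = np.diff(dens)
    maxima = [i for i in range(1, n_grid - 1) if d[i - 1] > 0 >= d[i]]
    if len(maxima) < 2:
        return fallback()
    top2 = sorted(sorted(maxima, key=lambda i: dens[i], reverse=True)[:2])
    lo, hi = top2
    interior = np.arange(lo + 1, hi)
    if interior.size == 0:
        return fallback()
    valley = interior[np.argmin(dens[interior])]
    return float(np.expm1(grid[valley]))


def filter_low_expression(
    counts: pd.DataFrame, condition: pd.Series, threshold: float | None = None
) -> tuple[pd.DataFrame, float]:
    """Drop genes below the density threshold across either condition.

    A gene is kept if, in at least one condition, all its samples exceed
    the threshold.
    """
    if threshold is None:
        threshold = density_count_threshold(counts.mean(axis=1).to_numpy())
    keep = pd.Series(False, index=counts.index)
    for cond in condition.unique():
        cols = condition.index[condition == cond]
        keep |= (counts[cols] > threshold).all(axis=1)
    return counts.loc[keep], float(threshold)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios factors: per sample, the median over all-nonzero
    genes of count / geometric mean across samples."""
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ExposureError("no gene with nonzero counts in all samples")
    sub = mat[nonzero]
    geo = np.exp(np.log(sub).mean(axis=1))
    ratios = sub / geo[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


# ---------------------------------------------------------------------------
# NB Wald differential expression


@dataclass
class DEResults:
    """Per-gene Wald test results for exposed vs control."""

    table: pd.DataFrame  # log2_fold_change, wald_p, bh_adjusted_p, direction
    lfc_threshold: float
    alpha: float
    n_excluded: int

    @property
    def up(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "down"]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("genes tested", len(self.table)),
                ("genes excluded (all zero)", self.n_excluded),
                ("log2FC threshold", self.lfc_threshold),
                ("alpha (BH)", self.alpha),
                ("upregulated", len(self.up)),
                ("downregulated", len(self.down)),
            ],
            columns=["statistic", "value"],
        )


class NBWaldDE:
    """Negative-binomial Wald differential-expression model.

    Per gene, an NB GLM (log link) with a condition covariate and
    log-size-factor offsets; dispersion by method of moments on
    size-normalized counts with a floor of 0.01; a two-tailed Wald test of
    the condition coefficient against the null |log2FC| <= lfc_threshold;
    BH adjustment over the tested genes.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        condition: pd.Series,
        size_factors_: pd.Series | None = None,
        dispersion_floor: float = 0.01,
    ):
        self.counts = counts
        self.condition = condition.loc[counts.columns]
        for cond in ("control", "exposed"):
            if (self.condition == cond).sum() < 2:
                raise ExposureError(f"need at least 2 {cond} samples")
        self.size_factors = size_factors_ if size_factors_ is not None else size_factors(counts)
        self.dispersion_floor = dispersion_floor

    def _dispersion(self, y_norm: np.ndarray, groups: np.ndarray) -> float:
        # method of moments on within-group residual variance
        mu = np.array([y_norm[groups == g].mean() for g in (0, 1)])[groups]
        m = mu.mean()
        if m <= 0:
            return self.dispersion_floor
        var = ((y_norm - mu) ** 2).sum() / max(y_norm.size - 2, 1)
        disp = (var - m) / m**2
        return float(max(disp, self.dispersion_floor))

    def fit(self, lfc_threshold: float = 0.5, alpha: float = 0.05) -> DEResults:
        sf = self.size_factors.loc[self.counts.columns].to_numpy(dtype=float)
        offset = np.log(sf)
        x = (self.condition == "exposed").to_numpy(dtype=float)
        design = sm.add_constant(x)
        theta = lfc_threshold * np.log(2.0)

        rows = []
        excluded = 0
        for gene, y in self.counts.iterrows():
            y = y.to_numpy(dtype=float)
            if y.sum() == 0:
                excluded += 1
                continue
            disp = self._dispersion(y / sf, x.astype(int))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.GLM(
                        y,
                        design,
                        family=sm.families.NegativeBinomial(alpha=disp),
                        offset=offset,
                    )
                    res = model.fit()
                beta, se = res.params[1], res.bse[1]
            except Exception:  # degenerate fits fall back to moment estimates
                mu0 = max((y / sf)[x == 0].mean(), 1e-8)
                mu1 = max((y / sf)[x == 1].mean(), 1e-8)
                beta = np.log(mu1 / mu0)
                se = np.sqrt(disp * 2 + 1.0)
            if se == 0 or not np.isfinite(se):
                excluded += 1
                continue
            z = (abs(beta) - theta) / se
            p = 2 * norm.sf(z) if z > 0 else 1.0
            rows.append({"gene": gene, "log2_fold_change": beta / np.log(2.0), "wald_p": min(p, 1.0)})
        if excluded:
            logger.info("%d genes excluded from DE (all-zero or degenerate)", excluded)
        if not rows:
            raise ExposureError("no testable genes")
        table = pd.DataFrame(rows).set_index("gene")
        table["bh_adjusted_p"] = multipletests(table["wald_p"], method="fdr_bh")[1]
        direction = np.where(
            (table["bh_adjusted_p"] < alpha) & (table["log2_fold_change"] >= lfc_threshold),
            "up",
            np.where(
                (table["bh_adjusted_p"] < alpha) & (table["log2_fold_change"] <= -lfc_threshold),
                "down",
                "ns",
            ),
        )
        table["direction"] = direction
        return DEResults(table=table, lfc_threshold=lfc_threshold, alpha=alpha, n_excluded=excluded)


def nb_wald_de(
    counts: pd.DataFrame,
    condition: pd.Series,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
    size_factors_: pd.Series | None = None,
) -> DEResults:
    """Functional wrapper around :class:`NBWaldDE`."""
    return NBWaldDE(counts, condition, size_factors_=size_factors_).fit(
        lfc_threshold=lfc_threshold, alpha=alpha
    )


# ---------------------------------------------------------------------------
# overlap between populations


@dataclass(frozen=True)
class OverlapSummary:
    shared_up: int
    shared_down: int
    proportion_up: float
    proportion_down: float
    n_up_a: int
    n_up_b: int
    n_down_a: int
    n_down_b: int


def overlap_analysis(de_a: DEResults, de_b: DEResults) -> OverlapSummary:
    """Shared up/down genes between two populations' DE results.

    Proportions use the smaller per-direction set as denominator, matching
    the convention shared-count / min(set sizes).
    """
    if not set(de_a.table.index) & set(de_b.table.index):
        raise ExposureError("disjoint gene universes")

    def prop(shared: int, na: int, nb: int) -> float:
        denom = min(na, nb)
        return shared / denom if denom else 0.0

    up_a, up_b = set(de_a.up), set(de_b.up)
    dn_a, dn_b = set(de_a.down), set(de_b.down)
    su, sd = len(up_a & up_b), len(dn_a & dn_b)
    return OverlapSummary(
        shared_up=su,
        shared_down=sd,
        proportion_up=prop(su, len(up_a), len(up_b)),
        proportion_down=prop(sd, len(dn_a), len(dn_b)),
        n_up_a=len(up_a),
        n_up_b=len(up_b),
        n_down_a=len(dn_a),
        n_down_b=len(dn_b),
    )


# ---------------------------------------------------------------------------
# exon-intron split analysis


def intronic_counts(
    exon_counts: pd.DataFrame, transcript_counts: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Intron = transcript - exon, clipped at zero; returns clip count.

    Negative raw differences arise from overlapping-gene artifacts and are
    clipped to zero rather than erroring.
    """
    if exon_counts.shape != transcript_counts.shape or not exon_counts.index.equals(
        transcript_counts.index
    ):
        raise ExposureError("exon and transcript matrices must share genes and samples")
    diff = transcript_counts - exon_counts
    clipped = int((diff < 0).to_numpy().sum())
    if clipped:
        logger.warning("%d exon counts exceeded transcript counts; clipped to 0", clipped)
    return diff.clip(lower=0), clipped


def eisa_fold_changes(
    feature_counts: pd.DataFrame, sf: pd.Series, condition: pd.Series
) -> pd.DataFrame:
    """Per gene: normalized count of each exposed sample / mean normalized
    control count (NaN where the control mean is zero)."""
    ctrl = condition.index[condition == "control"]
    expo = condition.index[condition == "exposed"]
    if len(ctrl) < 1:
        raise ExposureError("need at least one control sample")
    normed = feature_counts / sf.loc[feature_counts.columns]
    ctrl_mean = normed[ctrl].mean(axis=1)
    fc = normed[expo].div(ctrl_mean, axis=0)
    fc[ctrl_mean == 0] = np.nan
    n_missing = int(fc.isna().any(axis=1).sum())
    if n_missing:
        logger.info("%d genes with undefined fold change (zero control mean)", n_missing)
    return fc


def eisa_tests(
    feature_counts: pd.DataFrame,
    sf: pd.Series,
    condition: pd.Series,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Two-sided two-sample t test per gene on normalized counts, BH across
    genes.  Zero-variance genes (both groups constant) are excluded.

    By default the test runs on log1p-normalized counts: expression changes
    are multiplicative (the fold-change readout is displayed on a log2
    scale), so the log transform stabilizes the NB variance and the t test
    compares log fold changes.  ``log_scale=False`` tests the linear scale.
    """
    ctrl = condition.index[condition == "control"]
    expo = condition.index[condition == "exposed"]
    if len(ctrl) < 2 or len(expo) < 2:
        raise ExposureError("need at least 2 samples per condition")
    normed = feature_counts / sf.loc[feature_counts.columns]
    if log_scale:
        normed = np.log1p(normed)
    a = normed[expo].to_numpy(dtype=float)
    b = normed[ctrl].to_numpy(dtype=float)
    var_ok = (a.std(axis=1) > 0) | (b.std(axis=1) > 0)
    n_excl = int((~var_ok).sum())
    if n_excl:
        logger.info("%d zero-variance genes excluded from t tests", n_excl)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = ttest_ind(a[var_ok], b[var_ok], axis=1)
    out = pd.DataFrame(
        {
            "mean_exposed": a[var_ok].mean(axis=1),
            "mean_control": b[var_ok].mean(axis=1),
            "t_statistic": stat,
            "pvalue": p,
        },
        index=feature_counts.index[var_ok],
    )
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


@dataclass
class EisaResults:
    """Per-gene exonic and intronic fold changes, tests and classification."""

    exon_fc: pd.DataFrame
    intron_fc: pd.DataFrame
    exon_tests: pd.DataFrame
    intron_tests: pd.DataFrame
    classification: pd.Series | None = None
    q_cut: float = 0.1
    min_intron_counts: int = 14

    def summary(self) -> pd.DataFrame:
        rows = [
            ("genes (exon tests)", len(self.exon_tests)),
            ("genes (intron tests)", len(self.intron_tests)),
            ("exon significant (q < cut)", int((self.exon_tests["qvalue"] < self.q_cut).sum())),
            ("intron significant (q < cut)", int((self.intron_tests["qvalue"] < self.q_cut).sum())),
        ]
        if self.classification is not None:
            for cls, n in self.classification.value_counts().items():
                rows.append((f"class: {cls}", int(n)))
        return pd.DataFrame(rows, columns=["statistic", "value"])


class ExonIntronSplit:
    """EISA model: exon and transcript count matrices with condition labels.

    fit() normalizes by transcript-level median-of-ratios factors, computes
    exonic and intronic fold changes and t tests, and classifies each gene
    as transcriptional (exon and intron move together), post-transcriptional
    (exon moves, intron flat, with an intronic power guard), or none.
    """

    def __init__(
        self,
        exon_counts: pd.DataFrame,
        transcript_counts: pd.DataFrame,
        condition: pd.Series,
        size_factors_: pd.Series | None = None,
    ):
        self.exon_counts = exon_counts
        self.transcript_counts = transcript_counts
        self.condition = condition.loc[exon_counts.columns]
        self.intron_counts, self.n_clipped = intronic_counts(exon_counts, transcript_counts)
        self.size_factors = (
            size_factors_ if size_factors_ is not None else size_factors(transcript_counts)
        )

    def fit(
        self, q_cut: float = 0.1, min_intron_counts: int = 14, log_scale: bool = True
    ) -> EisaResults:
        sf, cond = self.size_factors, self.condition
        exon_fc = eisa_fold_changes(self.exon_counts, sf, cond)
        intron_fc = eisa_fold_changes(self.intron_counts, sf, cond)
        exon_t = eisa_tests(self.exon_counts, sf, cond, log_scale=log_scale)
        intron_t = eisa_tests(self.intron_counts, sf, cond, log_scale=log_scale)
        cls = classify_modulation(
            exon_t,
            intron_t,
            total_intron_counts=self.intron_counts.sum(axis=1),
            q_cut=q_cut,
            min_intron_counts=min_intron_counts,
        )
        return EisaResults(
            exon_fc=exon_fc,
            intron_fc=intron_fc,
            exon_tests=exon_t,
            intron_tests=intron_t,
            classification=cls,
            q_cut=q_cut,
            min_intron_counts=min_intron_counts,
        )


def classify_modulation(
    exon_tests: pd.DataFrame,
    intron_tests: pd.DataFrame,
    total_intron_counts: pd.Series,
    q_cut: float = 0.1,
    min_intron_counts: int = 14,
) -> pd.Series:
    """Per-gene modulation class.

    transcriptional: exonic and intronic features significant with the same
    direction of change; post_transcriptional: exonic significant, intronic
    not, with intron counts above the power guard (> min_intron_counts in
    total); otherwise none.
    """
    genes = exon_tests.index
    out = pd.Series("none", index=genes, dtype=object)
    exon_sig = exon_tests["qvalue"] < q_cut
    exon_dir = np.sign(exon_tests["mean_exposed"] - exon_tests["mean_control"])
    intron_sig = intron_tests["qvalue"].reindex(genes) < q_cut
    intron_dir = np.sign(
        (intron_tests["mean_exposed"] - intron_tests["mean_control"]).reindex(genes)
    )
    powered = total_intron_counts.reindex(genes).fillna(0) > min_intron_counts
    txn = exon_sig & intron_sig.fillna(False) & (exon_dir == intron_dir)
    post = exon_sig & ~intron_sig.fillna(False) & powered
    out[txn] = "transcriptional"
    out[post & ~txn] = "post_transcriptional"
    return out
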