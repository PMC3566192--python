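"""Subject QC, identity-by-state similarity, and classical MDS ancestry.

The pipeline mirrors the standard population-structure workflow: filter
subjects on call rate and heterozygosity, compute the genome-wide average
proportion of alleles shared identical by state between every pair of
subjects, then extract orthogonal ancestral dimensions by classical
(Torgerson) multidimensional scaling of the IBS distance matrix.  The first
dimension captures the maximal variance in genetic similarity, each further
dimension the maximum residual variance orthogonal to the preceding ones —
equivalent, up to scaling, to principal components of the centered
similarity matrix.  Per-SNP loadings (correlations of dosage with each
dimension) support downstream proxy-panel construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .io_formats import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "QcReport",
    "SimilarityMatrix",
    "AncestryModel",
    "qc_subjects",
    "compute_ibs",
    "mds_from_similarity",
    "snp_loadings",
]


@dataclass
class QcReport:
    """Which subjects were removed and why."""

    removed_call_rate: list[str]
    removed_heterozygosity: list[str]
    call_rate: pd.Series
    het_rate: pd.Series

    @property
    def removed(self) -> list[str]:
        return sorted(set(self.removed_call_rate) | set(self.removed_heterozygosity))


@dataclass
class SimilarityMatrix:
    """Pairwise mean IBS proportions with per-pair non-missing SNP counts."""

    subject_ids: list[str]
    s: np.ndarray
    n_used: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if self.s.shape != (n, n) or self.n_used.shape != (n, n):
            raise ValueError("similarity matrix shape does not match subjects")
        if not np.allclose(self.s, self.s.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.s), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if self.s.min() < -1e-12 or self.s.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")


@dataclass
class AncestryModel:
    """MDS ancestral dimensions: subject scores, eigenvalues, SNP loadings."""

    subject_ids: list[str]
    scores: np.ndarray  # n x d
    eigenvalues: np.ndarray  # d, non-increasing
    variance_fraction: np.ndarray  # share of total positive eigenvalue mass
    loadings: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def d(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.subject_ids, name="subject"),
            columns=[f"MDS{k + 1}" for k in range(self.d)],
        )


# ---------------------------------------------------------------------------


def qc_subjects(
    panel: GenotypePanel,
    min_call_rate: float = 0.99,
    het_sd: float = 3.0,
) -> tuple[GenotypePanel, QcReport]:
    """Drop subjects with low call rate or outlying heterozygosity.

    Heterozygosity rate is the fraction of non-missing calls that are
    heterozygous; subjects outside mean ± ``het_sd`` standard deviations are
    removed, the ±3 SD threshold being the GWAS QC convention.
    """
    if panel.n_subjects == 0:
        raise ValueError("empty panel")
    observed = panel.calls != MISSING
    n_obs = observed.sum(axis=1)
    call_rate = n_obs / panel.n_snps
    with np.errstate(invalid="ignore"):
        het_rate = (panel.calls == 1).sum(axis=1) / np.maximum(n_obs, 1)

    mean, sd = het_rate.mean(), het_rate.std(ddof=0)
    low_call = call_rate < min_call_rate
    if sd == 0:
        het_out = np.zeros(panel.n_subjects, dtype=bool)
    else:
        het_out = np.abs(het_rate - mean) > het_sd * sd
    keep = ~(low_call | het_out)
    if not keep.any():
        raise ValueError("subject QC removed every subject")

    ids = np.array(panel.subject_ids)
    report = QcReport(
        removed_call_rate=list(ids[low_call]),
        removed_heterozygosity=list(ids[het_out]),
        call_rate=pd.Series(call_rate, index=ids),
        het_rate=pd.Series(het_rate, index=ids),
    )
    if report.removed:
        logger.info(
            "subject QC removed %d of %d subjects (call rate: %s; heterozygosity: %s)",
            len(report.removed),
            panel.n_subjects,
            report.removed_call_rate,
            report.removed_heterozygosity,
        )
    return panel.take_subjects(np.flatnonzero(keep)), report


def compute_ibs(panel: GenotypePanel) -> SimilarityMatrix:
    """Mean proportion of alleles shared identical by state per subject pair.

    Per SNP the shared proportion is (2 - |g_i - g_j|) / 2; the pairwise mean
    runs over SNPs non-missing in both subjects.  Computed via indicator
    matrix products, so it scales to thousands of subjects without a Python
    pair loop.
    """
    if panel.n_subjects < 2:
        raise ValueError("IBS needs at least two subjects")
    calls = panel.calls
    ind = [
        (calls == g).astype(np.float32) for g in (0, 1, 2)
    ]  # dosage-class indicators, zero at missing
    valid = (calls != MISSING).astype(np.float32)

    n_used = valid @ valid.T
    off = np.array(n_used, copy=True)
    np.fill_diagonal(off, 1.0)
    zero_pairs = np.argwhere(off == 0)
    if zero_pairs.size:
        i, j = zero_pairs[0]
        raise ValueError(
            "no overlapping non-missing SNPs for pair "
            f"({panel.subject_ids[i]}, {panel.subject_ids[j]})"
        )

    # sum over SNPs of |g_i - g_j| decomposed over dosage classes
    diff1 = ind[0] @ ind[1].T + ind[1] @ ind[2].T
    diff1 = diff1 + diff1.T
    diff2 = ind[0] @ ind[2].T
    diff2 = diff2 + diff2.T
    total_diff = diff1 + 2.0 * diff2

    s = 1.0 - total_diff / (2.0 * n_used)
    s = np.asarray(s, dtype=np.float64)
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(
        list(panel.subject_ids), s, np.asarray(n_used, dtype=np.int64)
    )


def mds_from_similarity(similarity: SimilarityMatrix, d: int = 5) -> AncestryModel:
    """Classical (Torgerson) MDS of the IBS distance matrix.

    The squared-distance matrix takes entries d2_ij = 1 - s_ij; it is
    double-centered, B = -1/2 J D^2 J, and the top ``d`` eigenpairs give
    scores C_k = v_k * sqrt(lambda_k).  Because D^2 is affine in S, B equals
    J S J / 2 and the scores coincide (up to scaling) with principal
    components of the centered similarity matrix.  Each dimension's sign is
    fixed so the subject with the largest absolute score is positive, making
    downstream loadings and proxy weights reproducible.
    """
    n = len(similarity.subject_ids)
    if not 1 <= d <= n - 1:
        raise ValueError(f"d must be in [1, {n - 1}], got {d}")
    d2 = 1.0 - similarity.s
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigvals[0]), 1.0)
    n_positive = int((eigvals > tol).sum())
    if d > n_positive:
        raise ValueError(
            f"requested {d} dimensions but only {n_positive} positive "
            "eigenvalues are available"
        )
    top_vals = eigvals[:d]
    scores = eigvecs[:, :d] * np.sqrt(top_vals)
    for k in range(d):
        i_max = int(np.argmax(np.abs(scores[:, k])))
        if scores[i_max, k] < 0:
            scores[:, k] = -scores[:, k]
    positive_mass = eigvals[eigvals > tol].sum()
    return AncestryModel(
        subject_ids=list(similarity.subject_ids),
        scores=scores,
        eigenvalues=top_vals,
        variance_fraction=top_vals / positive_mass,
    )


def snp_loadings(panel: GenotypePanel, model: AncestryModel) -> pd.DataFrame:
    """Pearson correlation of each SNP dosage with each ancestral dimension.

    Missing calls are dropped pairwise.  Monomorphic SNPs (no dosage variance
    among the non-missing calls) get loading 0 with a log warning.  The
    result is also attached to ``model.loadings``.
    """
    if list(panel.subject_ids) != list(model.subject_ids):
        raise ValueError("panel subjects do not match ancestry model subjects")
    calls = panel.calls.astype(np.float64)
    valid = panel.calls != MISSING
    calls[~valid] = 0.0
    v = valid.astype(np.float64)

    n_valid = v.sum(axis=0)  # per SNP
    g_sum = calls.sum(axis=0)
    g2_sum = (calls**2).sum(axis=0)

    loadings = np.zeros((panel.n_snps, model.d))
    for k in range(model.d):
        c = model.scores[:, k]
        c_sum = c @ v
        c2_sum = (c**2) @ v
        gc_sum = c @ calls
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = gc_sum - g_sum * c_sum / n_valid
            var_g = g2_sum - g_sum**2 / n_valid
            var_c = c2_sum - c_sum**2 / n_valid
            denom = np.sqrt(var_g * var_c)
            r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
        loadings[:, k] = np.clip(r, -1.0, 1.0)

    degenerate = np.flatnonzero(
        (g2_sum - g_sum**2 / np.maximum(n_valid, 1)) <= 1e-12
    )
    if degenerate.size:
        logger.warning(
            "%d monomorphic/degenerate SNPs received loading 0 (first: %s)",
            degenerate.size,
            panel.snp_ids[degenerate[0]],
        )
    frame = pd.DataFrame(
        loadings,
        index=pd.Index(panel.snp_ids, name="snp"),
        columns=[f"MDS{k + 1}" for k in range(model.d)],
    )
    model.loadings = frame
    return frame
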