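"""Compress genome-wide MDS ancestry into small weighted SNP panels.

Pipeline: (1) LD-prune the marker set to approximate linkage equilibrium
(pairwise r^2 below a threshold, sliding window); (2) per ancestral
dimension, rank the pruned SNPs by absolute loading and keep the top K
(default 700); (3) regress the dimension's scores on those K dosages in a
single multiple regression and keep the coefficients as scoring weights.
New genotypes are scored as ``intercept + sum_m w_m g_m`` with missing calls
imputed from training dosage means — so a proxy dimension can be computed
from a few hundred markers instead of hundreds of thousands.  Training R^2
is reported per dimension; because selection and weighting use the same
subjects, held-out performance is expected to be somewhat lower
(overfitting is reported, not corrected).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ancestry import AncestryModel
from .io_formats import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

__all__ = ["ProxyPanel", "ld_prune", "build_proxy", "apply_proxy"]


@dataclass
class ProxyPanel:
    """Per-dimension SNP ids, regression weights and training metadata."""

    dimensions: list[str]
    snp_ids: dict[str, list[str]]
    weights: dict[str, np.ndarray]
    intercepts: dict[str, float]
    training_means: dict[str, np.ndarray]  # mean dosage per panel SNP
    r2_achieved: dict[str, float]

    def __post_init__(self) -> None:
        for dim in self.dimensions:
            if len(self.snp_ids[dim]) != len(self.weights[dim]):
                raise ValueError(f"{dim}: weight count != SNP count")
            if not 0.0 <= self.r2_achieved[dim] <= 1.0 + 1e-12:
                raise ValueError(f"{dim}: r2_achieved outside [0, 1]")

    # -- serialization: TSV of weights + JSON header --------------------
    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        rows = []
        for dim in self.dimensions:
            for snp, w, mean in zip(
                self.snp_ids[dim], self.weights[dim], self.training_means[dim]
            ):
                rows.append(
                    {"dimension": dim, "snp": snp, "weight": w, "training_mean": mean}
                )
        pd.DataFrame(rows).to_csv(
            prefix.with_suffix(".weights.tsv"), sep="\t", index=False
        )
        header = {
            "dimensions": self.dimensions,
            "intercepts": self.intercepts,
            "r2_achieved": self.r2_achieved,
        }
        prefix.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def read(cls, prefix: str | Path) -> "ProxyPanel":
        prefix = Path(prefix)
        weights = pd.read_csv(prefix.with_suffix(".weights.tsv"), sep="\t")
        header = json.loads(prefix.with_suffix(".json").read_text())
        snp_ids, w, means = {}, {}, {}
        for dim, grp in weights.groupby("dimension", sort=False):
            snp_ids[dim] = list(grp["snp"])
            w[dim] = grp["weight"].to_numpy(dtype=float)
            means[dim] = grp["training_mean"].to_numpy(dtype=float)
        return cls(
            dimensions=list(header["dimensions"]),
            snp_ids=snp_ids,
            weights=w,
            intercepts={k: float(v) for k, v in header["intercepts"].items()},
            training_means=means,
            r2_achieved={k: float(v) for k, v in header["r2_achieved"].items()},
        )


# ---------------------------------------------------------------------------


def _imputed_dosage(panel: GenotypePanel) -> np.ndarray:
    """Float dosage matrix with missing calls replaced by per-SNP means."""
    g = panel.calls.astype(np.float64)
    miss = panel.calls == MISSING
    if miss.any():
        g[miss] = np.nan
        means = np.nanmean(g, axis=0)
        means = np.where(np.isfinite(means), means, 0.0)
        idx = np.where(miss)
        g[idx] = means[idx[1]]
    return g


def ld_prune(
    panel: GenotypePanel,
    r2_max: float = 0.1,
    window: int = 50,
    step: int = 5,
) -> list[str]:
    """Greedy sliding-window LD pruning; returns the retained SNP ids.

    Within each window of ``window`` SNPs, while any retained pair has
    squared dosage correlation above ``r2_max``, the later-positioned SNP of
    the worst (highest r^2) pair is removed; the window then advances by
    ``step`` SNPs.  Deterministic, and idempotent on its own output.
    Correlations use mean-imputed dosages.
    """
    if not panel.is_sorted():
        raise ValueError("panel must be sorted by (chrom, pos) before pruning")
    g = _imputed_dosage(panel)
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    m = panel.n_snps
    removed = np.zeros(m, dtype=bool)
    start = 0
    while True:
        stop = min(start + window, m)
        idx = [
            j
            for j in range(start, stop)
            if not removed[j] and sd[j] > 0
        ]
        while len(idx) > 1:
            sub = g[:, idx] / sd[idx]
            corr = (sub.T @ sub) / sub.shape[0]
            r2 = corr**2
            np.fill_diagonal(r2, 0.0)
            worst = np.unravel_index(np.argmax(r2), r2.shape)
            if r2[worst] <= r2_max:
                break
            # remove the later-positioned member of the worst pair
            drop_local = max(worst)
            removed[idx[drop_local]] = True
            idx.pop(drop_local)
        if stop >= m:
            break
        start += step
    retained = [panel.snp_ids[j] for j in range(m) if not removed[j]]
    logger.info("LD pruning retained %d of %d SNPs", len(retained), m)
    return retained


def build_proxy(
    panel: GenotypePanel,
    model: AncestryModel,
    pruned: list[str],
    k_panel: int = 700,
) -> ProxyPanel:
    """Select top-|loading| pruned SNPs per dimension and fit scoring weights.

    One multiple regression per dimension: scores ~ intercept + K dosages
    (missing mean-imputed).  If the selected design is rank-deficient the
    lowest-|loading| collinear SNPs are dropped until it is full rank.
    """
    if k_panel <= 0:
        raise ValueError("k_panel must be positive")
    if not pruned:
        raise ValueError("pruned SNP set is empty")
    if k_panel >= panel.n_subjects:
        raise ValueError(
            f"k_panel={k_panel} must be smaller than the {panel.n_subjects} "
            "training subjects"
        )
    loadings = model.loadings
    if loadings is None:
        raise ValueError("ancestry model has no SNP loadings; run snp_loadings first")
    if list(panel.subject_ids) != list(model.subject_ids):
        raise ValueError("panel subjects do not match ancestry model subjects")

    pruned_set = [s for s in panel.snp_ids if s in set(pruned)]
    col_of = {s: j for j, s in enumerate(panel.snp_ids)}
    g = _imputed_dosage(panel)
    all_means = panel.calls.astype(float)
    all_means[panel.calls == MISSING] = np.nan
    snp_means = np.nanmean(np.where(np.isnan(all_means), np.nan, all_means), axis=0)
    snp_means = np.where(np.isfinite(snp_means), snp_means, 0.0)

    dims = list(loadings.columns)
    snp_ids: dict[str, list[str]] = {}
    weights: dict[str, np.ndarray] = {}
    intercepts: dict[str, float] = {}
    means: dict[str, np.ndarray] = {}
    r2s: dict[str, float] = {}
    for k, dim in enumerate(dims):
        load = loadings.loc[pruned_set, dim]
        ranked = sorted(pruned_set, key=lambda s: (-abs(load[s]), s))
        chosen = ranked[: min(k_panel, len(ranked))]
        cols = [col_of[s] for s in chosen]
        y = model.scores[:, k]
        while True:
            design = np.column_stack([np.ones(panel.n_subjects), g[:, cols]])
            if np.linalg.matrix_rank(design) == design.shape[1]:
                break
            dropped = chosen.pop()  # lowest |loading| first
            cols.pop()
            logger.warning(
                "%s: dropped collinear SNP %s from proxy design", dim, dropped
            )
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ coef
        sst = float(np.sum((y - y.mean()) ** 2))
        sse = float(np.sum((y - fitted) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        snp_ids[dim] = chosen
        weights[dim] = coef[1:]
        intercepts[dim] = float(coef[0])
        means[dim] = snp_means[cols]
        r2s[dim] = float(min(max(r2, 0.0), 1.0))
    return ProxyPanel(
        dimensions=dims,
        snp_ids=snp_ids,
        weights=weights,
        intercepts=intercepts,
        training_means=means,
        r2_achieved=r2s,
    )


def apply_proxy(panel: GenotypePanel, proxy: ProxyPanel) -> pd.DataFrame:
    """Score new genotypes with a proxy panel.

    Requires >= 80% of each dimension's panel SNPs to be present; absent
    SNPs and missing calls are imputed with the stored training means, so an
    entirely missing subject scores at ``intercept + w . training_means``.
    """
    col_of = {s: j for j, s in enumerate(panel.snp_ids)}
    scores = {}
    for dim in proxy.dimensions:
        ids = proxy.snp_ids[dim]
        present = [s for s in ids if s in col_of]
        overlap = len(present) / len(ids)
        if overlap < 0.8:
            raise ValueError(
                f"{dim}: only {overlap:.1%} of panel SNPs present in the "
                "genotypes (need >= 80%)"
            )
        w = proxy.weights[dim]
        tmeans = proxy.training_means[dim]
        g = np.tile(tmeans, (panel.n_subjects, 1))
        for j, s in enumerate(ids):
            if s in col_of:
                col = panel.calls[:, col_of[s]].astype(float)
                col[panel.calls[:, col_of[s]] == MISSING] = tmeans[j]
                g[:, j] = col
        scores[dim] = proxy.intercepts[dim] + g @ w
    return pd.DataFrame(scores, index=pd.Index(panel.subject_ids, name="subject"))
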