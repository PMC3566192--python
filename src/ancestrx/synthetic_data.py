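"""Synthetic admixed genotypes and longitudinal multi-drug trial outcomes.

Genotypes follow a Balding–Nichols divergence model: each SNP draws an
ancestral frequency p ~ Uniform(0.1, 0.9) and population-specific frequencies
p_j ~ Beta(p(1-F)/F, (1-p)(1-F)/F), so that E[p_j] = p and
Var(p_j) = F p (1-p).  Subjects mix the K ancestral populations with
Dirichlet(alpha) proportions Q_i, and dosages are Binomial(2, Q_i · p).

Trial outcomes follow a linear-growth mixed model: for subject i at visit
time t on a given drug-outcome combination,

    y_i(t) = alpha + t * (beta_drug + gamma' Q_i + b_i) + a_i + c' x_i + eps,

with random slope b_i ~ N(0, sigma_b^2), random intercept a_i ~ N(0,
sigma_a^2), residual eps ~ N(0, sigma_e^2), and optional time-constant
covariates x_i with effects c.  Visits after baseline are dropped
independently (missing completely at random).  Self-reported ethnicity is the
arg-max of Q_i, optionally misclassified at a configurable rate, emitted as
0/1 indicator columns — emulating how categorical self-report coarsens a
continuous ancestral mosaic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ETHNICITY_COLUMNS, GenotypePanel, PhenotypeTable

__all__ = [
    "AdmixtureDesign",
    "TrialDesign",
    "balding_nichols_frequencies",
    "simulate_admixed_genotypes",
    "simulate_trial",
]


def balding_nichols_frequencies(
    p: np.ndarray, fst: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """Population-specific allele frequencies around ancestral frequencies.

    For each ancestral frequency p the population frequency is drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F p (1-p) —
    F acting as the fixation index between the populations.  Returns an
    ``n_pops x len(p)`` matrix.
    """
    p = np.asarray(p, dtype=float)
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b, size=(n_pops, p.size))


@dataclass
class AdmixtureDesign:
    """Parameters of the Balding–Nichols admixture generator.

    Defaults mirror a modestly diverged three-way admixture (F=0.1 is on the
    order of continental-scale divergence) with symmetric mixing.
    """

    n_subjects: int = 300
    n_snps: int = 5000
    n_pops: int = 3
    fst: float = 0.1
    dirichlet_alpha: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_snps <= 0:
            raise ValueError("n_subjects and n_snps must be positive")
        if self.n_pops < 1:
            raise ValueError("need at least one ancestral population")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        if self.dirichlet_alpha is None:
            self.dirichlet_alpha = (1.0,) * self.n_pops
        alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if alpha.shape != (self.n_pops,) or (alpha <= 0).any():
            raise ValueError("dirichlet_alpha must be n_pops positive values")
        self.dirichlet_alpha = tuple(alpha)


def simulate_admixed_genotypes(
    design: AdmixtureDesign,
) -> tuple[GenotypePanel, np.ndarray]:
    """Draw an admixed genotype panel and the true admixture matrix Q.

    Returns the panel (dosages count the 'B' allele; orientation is irrelevant
    to IBS/MDS) and the subjects x K matrix of true ancestry proportions.
    SNPs are mutually independent given the population frequencies — no
    linkage disequilibrium along the chromosome is simulated — and are laid
    out on a single pseudo-chromosome at 10 kb spacing.
    """
    rng = np.random.default_rng(design.seed)
    n, m, k, f = design.n_subjects, design.n_snps, design.n_pops, design.fst

    p = rng.uniform(0.1, 0.9, size=m)
    pop_freq = balding_nichols_frequencies(p, f, k, rng)  # K x SNPs
    q = rng.dirichlet(design.dirichlet_alpha, size=n)  # subjects x K
    subject_freq = q @ pop_freq  # subjects x SNPs, in [0, 1]
    calls = rng.binomial(2, subject_freq).astype(np.int8)

    width = len(str(m))
    panel = GenotypePanel(
        subject_ids=[f"S{i + 1:0{len(str(n))}d}" for i in range(n)],
        snp_ids=[f"snp{j + 1:0{width}d}" for j in range(m)],
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1, dtype=np.int64) * 10_000,
        alleles=[("A", "B")] * m,
        calls=calls,
    )
    return panel, q


@dataclass
class TrialDesign:
    """Parameters of the longitudinal multi-drug outcome generator.

    ``beta_drug`` maps (drug, outcome) — or just drug, applied to every
    outcome — to the fixed response slope per unit time.  ``gamma`` is the
    ancestry effect: each subject's slope shifts by gamma' Q_i.  Visit times
    default to five scheduled assessments (baseline plus four follow-ups),
    matching the 3.5-4.5 observations per subject typical of the trials this
    emulates once dropout removes ~15% of follow-up visits.
    """

    drugs: Sequence[str] = ("drugA",)
    outcomes: Sequence[str] = ("symptom_score",)
    visits: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0)
    beta_drug: Mapping[str, float] | Mapping[tuple[str, str], float] | float = -0.5
    gamma: Sequence[float] = (0.0, 0.0, 0.0)
    sigma_b: float = 0.3
    sigma_a: float = 0.5
    sigma_e: float = 1.0
    dropout_rate: float = 0.15
    alpha: float = 10.0
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    ethnicity_misclass: float = 0.0
    ethnicity_other_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.sigma_e < 0 or self.sigma_a < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 <= self.ethnicity_misclass <= 1.0:
            raise ValueError("ethnicity_misclass must be in [0, 1]")
        if not 0.0 <= self.ethnicity_other_rate < 1.0:
            raise ValueError("ethnicity_other_rate must be in [0, 1)")
        if len(self.visits) < 2:
            raise ValueError("need at least two scheduled visits")
        if list(self.visits) != sorted(self.visits) or self.visits[0] != 0.0:
            raise ValueError("visits must be sorted and start at baseline 0")

    def slope(self, drug: str, outcome: str) -> float:
        if isinstance(self.beta_drug, (int, float)):
            return float(self.beta_drug)
        if (drug, outcome) in self.beta_drug:
            return float(self.beta_drug[(drug, outcome)])
        if drug in self.beta_drug:
            return float(self.beta_drug[drug])
        raise KeyError(f"no beta_drug entry for ({drug}, {outcome})")


def ethnicity_from_admixture(
    q: np.ndarray,
    misclass: float,
    rng: np.random.Generator,
    other_rate: float = 0.0,
) -> np.ndarray:
    """Arg-max coarsening of admixture into a single category per subject.

    With probability ``misclass`` a subject reports a uniformly random other
    category; with probability ``other_rate`` a subject reports none of the
    named categories (label -1), playing the role of the unnamed reference
    group that trial questionnaires record as "other".  Returns integer
    labels in {-1, 0..K-1}.
    """
    q = np.asarray(q, dtype=float)
    labels = np.argmax(q, axis=1)
    k = q.shape[1]
    if misclass > 0 and k > 1:
        flip = rng.random(len(labels)) < misclass
        offset = rng.integers(1, k, size=len(labels))
        labels = np.where(flip, (labels + offset) % k, labels)
    if other_rate > 0:
        labels = np.where(rng.random(len(labels)) < other_rate, -1, labels)
    return labels


def simulate_trial(
    q: np.ndarray,
    design: TrialDesign,
    subject_ids: Sequence[str] | None = None,
) -> PhenotypeTable:
    """Simulate longitudinal outcomes for every drug x outcome combination.

    Every subject contributes observations to every combination (random
    effects are redrawn independently per combination, so distinct families
    are exchangeable under gamma = 0).  Baseline visits are always retained;
    follow-ups are dropped MCAR at ``dropout_rate``.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2:
        raise ValueError("Q must be a subjects x K matrix")
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows of Q must sum to 1")
    n, k = q.shape
    if subject_ids is None:
        subject_ids = [f"S{i + 1:0{len(str(n))}d}" for i in range(n)]
    if len(subject_ids) != n:
        raise ValueError(
            f"{len(subject_ids)} subject ids for {n} admixture rows"
        )
    gamma = np.asarray(design.gamma, dtype=float)
    if gamma.shape != (k,):
        raise ValueError(f"gamma length {gamma.shape} does not match K={k}")

    rng = np.random.default_rng(design.seed)
    labels = ethnicity_from_admixture(
        q, design.ethnicity_misclass, rng, design.ethnicity_other_rate
    )
    eth = np.zeros((n, len(ETHNICITY_COLUMNS)), dtype=float)
    for j in range(min(k, len(ETHNICITY_COLUMNS))):
        eth[:, j] = labels == j

    covariates = {
        name: rng.standard_normal(n) for name in design.covariate_effects
    }
    ancestry_shift = q @ gamma
    visits = np.asarray(design.visits, dtype=float)

    rows: list[dict] = []
    for drug in design.drugs:
        for outcome in design.outcomes:
            beta = design.slope(drug, outcome)
            b = rng.normal(0.0, design.sigma_b, size=n)
            a_i = rng.normal(0.0, design.sigma_a, size=n)
            keep = rng.random((n, len(visits))) >= design.dropout_rate
            keep[:, 0] = True  # baseline always observed
            noise = rng.normal(0.0, design.sigma_e, size=(n, len(visits)))
            slope_i = beta + ancestry_shift + b
            cov_term = np.zeros(n)
            for name, effect in design.covariate_effects.items():
                cov_term = cov_term + effect * covariates[name]
            y = (
                design.alpha
                + a_i[:, None]
                + cov_term[:, None]
                + visits[None, :] * slope_i[:, None]
                + noise
            )
            for i in range(n):
                for t_idx in np.flatnonzero(keep[i]):
                    row = {
                        "subject": subject_ids[i],
                        "drug": drug,
                        "outcome": outcome,
                        "time": visits[t_idx],
                        "value": y[i, t_idx],
                    }
                    for name, vals in covariates.items():
                        row[name] = vals[i]
                    for j, col in enumerate(ETHNICITY_COLUMNS):
                        row[col] = eth[i, j]
                    rows.append(row)
    return PhenotypeTable(pd.DataFrame(rows))
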