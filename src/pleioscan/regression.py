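"""Reverse regression of genotype dosage on multiple phenotypes.

For each SNP the genotype dosage G_i (expected effect-allele count) is
modelled as a Gaussian linear function of the J observed phenotypes,

    G_i = alpha + sum_j beta_j * y_ij + eps_i,    eps_i ~ N(0, sigma^2).

A joint J-degree-of-freedom test of association compares the maximised
log-likelihood of the unconstrained model with the null model (beta = 0).
Because every phenotype enters as a predictor, each beta_j is adjusted for
all other phenotypes, which implicitly accounts for their correlation, and
quantitative and categorical traits can share one model.

Signal dissection fits the model for every subset of phenotypes and ranks
subsets by the Bayesian information criterion (BIC); the minimum-BIC subset
is reported as the combination of phenotypes best supported by the data.
All subsets are fitted on one shared complete-case sample (individuals
missing the dosage or ANY phenotype are dropped) so their BICs are
comparable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .genio import (
    ConsistencyError,
    DosageVector,
    PhenotypeTable,
    PleioscanError,
    SnpRecord,
    dosage,
    effect_allele_frequency,
    info_score,
)
from .genio import MonomorphicError

__all__ = [
    "SingularFitError",
    "ReverseFit",
    "AssocResult",
    "design_blocks",
    "fit_reverse",
    "joint_test",
    "bic",
    "all_subsets",
    "select_best",
    "sidak",
    "analyse_snp",
    "MAX_SUBSET_PHENOTYPES",
    "GENOME_WIDE_P",
]

# 2^J guard for exhaustive subset enumeration.
MAX_SUBSET_PHENOTYPES = 20

# Conventional genome-wide significance threshold.
GENOME_WIDE_P = 5e-8


class SingularFitError(PleioscanError):
    """Design matrix is rank deficient (collinear phenotypes / constant dosage)."""


@dataclass
class ReverseFit:
    """Maximum-likelihood fit of the reverse regression for one phenotype subset.

    ``sigma2`` is the ML residual variance (RSS / n); ``loglik`` the
    maximised Gaussian log-likelihood; ``vcov`` the sigma2 * (X'X)^-1
    sub-block for the phenotype coefficients; ``k_params`` the number of
    free mean parameters plus one for sigma2 (categorical phenotypes may
    contribute several indicator columns each).
    """

    subset: tuple[int, ...]
    alpha: float
    beta: np.ndarray
    vcov: np.ndarray
    sigma2: float
    loglik: float
    n_used: int
    k_params: int
    rss: float


@dataclass
class AssocResult:
    """Per-SNP association summary: joint test plus optional subset BICs."""

    snp_id: str
    rsid: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    info: float
    n_used: int
    full_fit: Optional[ReverseFit]
    null_loglik: float
    chi2: float
    df: int
    p_value: float
    subset_bics: Optional[dict[tuple[int, ...], float]] = None
    failed: bool = False
    reason: str = ""

    @property
    def delta_bics(self) -> Optional[dict[tuple[int, ...], float]]:
        """BIC(subset) - BIC(null); the null anchors at 0 by construction."""
        if self.subset_bics is None:
            return None
        null = self.subset_bics[()]
        return {s: b - null for s, b in self.subset_bics.items()}


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def design_blocks(phenos: PhenotypeTable) -> list[np.ndarray]:
    """Per-phenotype predictor blocks.

    Continuous and binary phenotypes contribute one numeric column.
    Discrete phenotypes with more than two observed levels are expanded to
    level indicators (first level dropped), so one phenotype can contribute
    several columns; the extra columns count as extra parameters in the BIC.
    """
    blocks: list[np.ndarray] = []
    for j, kind in enumerate(phenos.column_kinds):
        col = phenos.values[:, j]
        if kind == "discrete":
            levels = np.unique(col[~np.isnan(col)])
            if levels.size > 2:
                block = np.column_stack(
                    [(col == lev).astype(float) for lev in levels[1:]]
                )
                # keep NaN propagation: rows missing the phenotype stay NaN
                block[np.isnan(col)] = np.nan
                blocks.append(block)
                continue
        blocks.append(col.reshape(-1, 1))
    return blocks


def _complete_cases(d: DosageVector, phenos: PhenotypeTable) -> np.ndarray:
    """Mask of individuals observed for the dosage and every phenotype."""
    ok = ~np.isnan(d.values)
    ok &= ~np.isnan(phenos.values).any(axis=1)
    return ok


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_reverse(
    d: DosageVector,
    phenos: PhenotypeTable,
    subset: Sequence[int],
    _mask: Optional[np.ndarray] = None,
    _blocks: Optional[list[np.ndarray]] = None,
) -> ReverseFit:
    """Fit the reverse regression for one phenotype subset.

    Complete cases are always taken over the FULL phenotype set so that fits
    for different subsets of the same SNP share one sample.  ``_mask`` and
    ``_blocks`` let :func:`all_subsets` reuse the complete-case restriction
    and design blocks across the 2^J fits.
    """
    if d.n != phenos.n_individuals:
        raise ConsistencyError(
            f"dosage has {d.n} individuals, phenotype table {phenos.n_individuals}"
        )
    subset = tuple(sorted(set(int(j) for j in subset)))
    if any(j < 0 or j >= phenos.n_phenotypes for j in subset):
        raise IndexError(f"phenotype index out of range in subset {subset}")

    mask = _complete_cases(d, phenos) if _mask is None else _mask
    blocks = design_blocks(phenos) if _blocks is None else _blocks
    g = d.values[mask]
    n = int(g.shape[0])

    cols = [b[mask] for j, b in enumerate(blocks) if j in subset]
    p_cols = sum(c.shape[1] for c in cols)
    if n < p_cols + 2:
        raise SingularFitError(
            f"only {n} complete cases for {p_cols} predictors (need >= {p_cols + 2})"
        )
    X = np.column_stack([np.ones(n)] + cols) if cols else np.ones((n, 1))
    k = X.shape[1]

    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k or np.ptp(g) == 0.0:
        raise SingularFitError(
            "rank-deficient design (collinear phenotypes or constant dosage)"
        )
    coef = np.linalg.solve(xtx, X.T @ g)
    resid = g - X @ coef
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= 0.0:
        raise SingularFitError("zero residual variance")
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    vcov_full = sigma2 * np.linalg.inv(xtx)
    return ReverseFit(
        subset=subset,
        alpha=float(coef[0]),
        beta=coef[1:].copy(),
        vcov=vcov_full[1:, 1:].copy(),
        sigma2=sigma2,
        loglik=loglik,
        n_used=n,
        k_params=k + 1,  # mean parameters + sigma^2
        rss=rss,
    )


def joint_test(full: ReverseFit, null_loglik: float, J: int,
               null_n_used: Optional[int] = None) -> tuple[float, float]:
    """J-df likelihood-ratio test of the full model against beta = 0.

    Returns ``(chi2, p)``; chi2 is floored at 0 against roundoff.  Both fits
    must use the same complete-case sample.
    """
    if null_n_used is not None and null_n_used != full.n_used:
        raise ConsistencyError(
            f"null fitted on {null_n_used} individuals, full on {full.n_used}"
        )
    chi2 = max(2.0 * (full.loglik - null_loglik), 0.0)
    p = float(stats.chi2.sf(chi2, J))
    return chi2, max(p, np.nextafter(0.0, 1.0))


def bic(fit: ReverseFit) -> float:
    """BIC = -2 loglik + k log(n) with k = coefficients + intercept + sigma^2."""
    return -2.0 * fit.loglik + fit.k_params * math.log(fit.n_used)


def all_subsets(
    d: DosageVector, phenos: PhenotypeTable
) -> dict[tuple[int, ...], float]:
    """BIC for every one of the 2^J phenotype subsets (including the null).

    All subsets are fitted on the shared complete-case sample.  Guarded at
    J <= 20 to keep the enumeration tractable.
    """
    J = phenos.n_phenotypes
    if J > MAX_SUBSET_PHENOTYPES:
        raise PleioscanError(
            f"exhaustive subset search requires J <= {MAX_SUBSET_PHENOTYPES}, got {J}"
        )
    mask = _complete_cases(d, phenos)
    blocks = design_blocks(phenos)
    out: dict[tuple[int, ...], float] = {}
    for r in range(J + 1):
        for subset in itertools.combinations(range(J), r):
            fit = fit_reverse(d, phenos, subset, _mask=mask, _blocks=blocks)
            out[subset] = bic(fit)
    return out


def subset_sort_key(subset: tuple[int, ...]):
    """Canonical subset order: by size, then lexicographically."""
    return (len(subset), subset)


def select_best(subset_bics: Mapping[tuple[int, ...], float]) -> tuple[int, ...]:
    """Minimum-BIC subset; ties broken by smaller subset then lexicographic."""
    if not subset_bics:
        raise PleioscanError("empty subset->BIC map")
    return min(subset_bics, key=lambda s: (subset_bics[s],) + subset_sort_key(s))


def sidak(p: float, m: int) -> float:
    """Sidak multiple-testing adjustment: 1 - (1 - p)^m."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return -math.expm1(m * math.log1p(-p)) if p < 1.0 else 1.0


# ---------------------------------------------------------------------------
# Per-SNP driver
# ---------------------------------------------------------------------------

def analyse_snp(
    record: SnpRecord,
    phenos: PhenotypeTable,
    effect_allele: str = "B",
    with_subsets: bool = False,
) -> AssocResult:
    """Full association analysis of one SNP: dosage, info, joint test, BICs.

    Degenerate SNPs (monomorphic, rank-deficient) are returned as failed
    result rows with a reason rather than raised, so a genome scan never
    aborts on one bad SNP.
    """
    d = dosage(record, effect_allele)
    ident = dict(
        snp_id=record.snp_id,
        rsid=record.rsid,
        chromosome=record.chromosome,
        position=record.position,
        effect_allele=d.effect_allele,
        other_allele=d.other_allele,
    )

    def _failed(reason: str, eaf: float = math.nan, info: float = math.nan) -> AssocResult:
        return AssocResult(
            **ident, eaf=eaf, info=info, n_used=0, full_fit=None,
            null_loglik=math.nan, chi2=math.nan, df=phenos.n_phenotypes,
            p_value=math.nan, failed=True, reason=reason,
        )

    try:
        eaf = effect_allele_frequency(d)
    except MonomorphicError as exc:
        return _failed(str(exc))
    try:
        info = info_score(record, effect_allele)
    except MonomorphicError as exc:
        return _failed(str(exc), eaf=eaf)

    J = phenos.n_phenotypes
    try:
        mask = _complete_cases(d, phenos)
        blocks = design_blocks(phenos)
        null_fit = fit_reverse(d, phenos, (), _mask=mask, _blocks=blocks)
        full_fit = fit_reverse(d, phenos, tuple(range(J)), _mask=mask, _blocks=blocks)
    except (SingularFitError, ConsistencyError) as exc:
        return _failed(str(exc), eaf=eaf, info=info)
    chi2, p = joint_test(full_fit, null_fit.loglik, J, null_fit.n_used)

    subset_bics = None
    if with_subsets:
        subset_bics = all_subsets(d, phenos)

    return AssocResult(
        **ident,
        eaf=eaf,
        info=info,
        n_used=full_fit.n_used,
        full_fit=full_fit,
        null_loglik=null_fit.loglik,
        chi2=chi2,
        df=J,
        p_value=p,
        subset_bics=subset_bics,
    )
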