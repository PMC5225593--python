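"""Fixed-effects meta-analysis of reverse-regression effect vectors.

Each study contributes, per SNP, a length-J coefficient vector (one entry
per phenotype) with its J x J variance-covariance matrix.  Studies are
pooled by the synthesis-of-regression-slopes method — multivariate
fixed-effects generalised least squares with inverse-covariance weights:

    V_pool  = (sum_k V_k^-1)^-1
    b_pool  = V_pool . sum_k V_k^-1 b_k

The pooled effect is tested with a J-df Wald statistic b' V^-1 b.

Residual population structure is handled by genomic control on J degrees
of freedom: lambda is the ratio of the median observed Wald statistic to
the median of the chi-square(J) distribution.  Variance-covariance matrices
are inflated by lambda when lambda > 1, first within each study and again
after meta-analysis ("double" genomic control).

Per-subset BIC differences from the null model add across studies (the
underlying log-likelihoods are from independent samples), so signal
dissection carries over to the meta-analysis level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .genio import ConsistencyError, PleioscanError
from .regression import select_best, subset_sort_key

logger = logging.getLogger("pleioscan")

__all__ = [
    "SnpEntry",
    "StudySummary",
    "MetaResult",
    "align_alleles",
    "pool_slopes",
    "wald_test",
    "gc_lambda",
    "apply_gc",
    "pool_bics",
    "meta_analyse",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, b) for b in reversed(allele.upper()))


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G SNPs read the same on both strands."""
    return _complement(a1) == a2.upper()


@dataclass
class SnpEntry:
    """One study's summary statistics for one SNP."""

    snp_id: str
    rsid: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    info: float
    n_used: int
    beta: np.ndarray  # length J
    vcov: np.ndarray  # J x J
    chi2: float
    p_value: float
    delta_bics: Optional[dict[tuple[int, ...], float]] = None
    ambiguous: bool = False

    def key(self) -> tuple[str, int]:
        return (self.chromosome, self.position)

    def flipped(self) -> "SnpEntry":
        """Re-express on the opposite effect allele: beta negated, eaf
        complemented; the variance-covariance matrix is unchanged."""
        return SnpEntry(
            snp_id=self.snp_id,
            rsid=self.rsid,
            chromosome=self.chromosome,
            position=self.position,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            info=self.info,
            n_used=self.n_used,
            beta=-self.beta,
            vcov=self.vcov,
            chi2=self.chi2,
            p_value=self.p_value,
            delta_bics=self.delta_bics,
            ambiguous=self.ambiguous,
        )


@dataclass
class StudySummary:
    """A study's per-SNP association summaries with shared phenotype order."""

    study_id: str
    phenotype_names: list[str]
    entries: list[SnpEntry]

    @property
    def J(self) -> int:
        return len(self.phenotype_names)

    def by_key(self) -> dict[tuple[str, int], SnpEntry]:
        out: dict[tuple[str, int], SnpEntry] = {}
        for e in self.entries:
            if e.key() in out:
                prev = out[e.key()]
                if prev.snp_id != e.snp_id or prev.rsid != e.rsid:
                    raise ConsistencyError(
                        f"{self.study_id}: duplicate position {e.key()} with "
                        f"conflicting ids {prev.snp_id}/{e.snp_id}"
                    )
            out[e.key()] = e
        return out


@dataclass
class MetaResult:
    """Pooled association result for one SNP."""

    snp_id: str
    rsid: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float  # sample-size weighted across contributing studies
    pooled_beta: np.ndarray
    pooled_vcov: np.ndarray
    chi2: float
    df: int
    p_value: float
    k_studies: int
    n_total: int
    pooled_delta_bics: Optional[dict[tuple[int, ...], float]] = None
    best_subset: Optional[tuple[int, ...]] = None
    ambiguous: bool = False
    failed: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------
# Allele alignment
# ---------------------------------------------------------------------------

def align_alleles(entries: Sequence[SnpEntry]) -> list[SnpEntry]:
    """Express all studies' entries for one SNP on a common effect allele.

    The first entry defines the reference orientation.  An entry with the
    allele pair swapped has its coefficient vector negated and its allele
    frequency complemented; pairs that match only after strand complement
    are re-oriented the same way; incompatible pairs are dropped with a
    logged reason.  Strand-ambiguous (A/T, C/G) SNPs are flagged, never
    auto-flipped on frequency.
    """
    if not entries:
        return []
    ref = entries[0]
    ref_pair = (ref.effect_allele.upper(), ref.other_allele.upper())
    ambiguous = is_strand_ambiguous(*ref_pair)
    out = []
    for e in entries:
        pair = (e.effect_allele.upper(), e.other_allele.upper())
        comp = (_complement(pair[0]), _complement(pair[1]))
        if pair == ref_pair:
            aligned = e
        elif pair == (ref_pair[1], ref_pair[0]):
            aligned = e.flipped()
        elif not ambiguous and comp == ref_pair:
            aligned = e  # same orientation, opposite strand labels
        elif not ambiguous and comp == (ref_pair[1], ref_pair[0]):
            aligned = e.flipped()
        else:
            logger.warning(
                "dropping %s at %s:%s: alleles %s/%s incompatible with %s/%s",
                e.rsid, e.chromosome, e.position,
                pair[0], pair[1], ref_pair[0], ref_pair[1],
            )
            continue
        if ambiguous:
            aligned.ambiguous = True
        out.append(aligned)
    return out


# ---------------------------------------------------------------------------
# Pooling and testing
# ---------------------------------------------------------------------------

def pool_slopes(
    betas: Sequence[np.ndarray], vcovs: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-covariance-weighted fixed-effects pooling of coefficient vectors.

    Singular per-study matrices exclude that study for the SNP (logged);
    with no usable studies a :class:`PleioscanError` is raised.
    """
    if len(betas) != len(vcovs):
        raise ConsistencyError("betas and vcovs differ in length")
    precision = None
    weighted = None
    used = 0
    for b, v in zip(betas, vcovs):
        b = np.asarray(b, dtype=float)
        v = np.asarray(v, dtype=float)
        try:
            vinv = np.linalg.inv(v)
        except np.linalg.LinAlgError:
            logger.warning("excluding one study from pooling: singular vcov")
            continue
        precision = vinv if precision is None else precision + vinv
        wb = vinv @ b
        weighted = wb if weighted is None else weighted + wb
        used += 1
    if used == 0:
        raise PleioscanError("no studies with invertible vcov to pool")
    pooled_vcov = np.linalg.inv(precision)
    pooled_beta = pooled_vcov @ weighted
    return pooled_beta, pooled_vcov


def wald_test(
    pooled_beta: np.ndarray, pooled_vcov: np.ndarray, J: int
) -> tuple[float, float]:
    """J-df Wald test: chi2 = b' V^-1 b, upper-tail chi-square p."""
    try:
        chi2 = float(pooled_beta @ np.linalg.solve(pooled_vcov, pooled_beta))
    except np.linalg.LinAlgError as exc:
        raise PleioscanError(f"singular pooled vcov: {exc}") from None
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, J))
    return chi2, max(p, np.nextafter(0.0, 1.0))


def gc_lambda(chi2_stats: Sequence[float], J: int) -> float:
    """Genomic-control inflation factor on J degrees of freedom.

    lambda = median(observed chi2) / median(chi-square(J)).  Intended for
    genome-scale collections of statistics; a warning is logged below 100.
    """
    arr = np.asarray([s for s in chi2_stats if np.isfinite(s)], dtype=float)
    if arr.size == 0:
        raise PleioscanError("no finite statistics: lambda undefined")
    if arr.size < 100:
        logger.warning("gc_lambda from only %d statistics; estimate is noisy", arr.size)
    return float(np.median(arr) / stats.chi2.ppf(0.5, J))


def apply_gc(vcov: np.ndarray, lam: float) -> np.ndarray:
    """Inflate a variance-covariance matrix by lambda, unless lambda < 1."""
    if not math.isfinite(lam):
        raise ValueError(f"lambda must be finite, got {lam}")
    return vcov * lam if lam >= 1.0 else vcov.copy()


def pool_bics(
    per_study: Sequence[Mapping[tuple[int, ...], float]]
) -> dict[tuple[int, ...], float]:
    """Sum per-study BIC differences from the null model, subset by subset.

    Log-likelihoods from independent samples add, and each study's sample
    size penalty is already inside its own BIC, so the pooled ranking is the
    sum of the per-study differences.  Subset keys must agree exactly.
    """
    if not per_study:
        raise PleioscanError("no per-study BIC maps to pool")
    keys = set(per_study[0])
    for m in per_study[1:]:
        if set(m) != keys:
            raise ConsistencyError("subset keys differ across studies")
    return {s: float(sum(m[s] for m in per_study)) for s in sorted(keys, key=subset_sort_key)}


# ---------------------------------------------------------------------------
# Whole-scan driver
# ---------------------------------------------------------------------------

@dataclass
class MetaScan:
    """Result of a meta-analysis over a set of studies."""

    phenotype_names: list[str]
    results: list[MetaResult]
    study_lambdas: dict[str, float]
    meta_lambda: float


def meta_analyse(
    studies: Sequence[StudySummary],
    gc_study: bool = False,
    gc_meta: bool = False,
    info_min: Optional[float] = None,
    maf_min: Optional[float] = None,
    drop_ambiguous: bool = False,
    study_lambdas: Optional[Mapping[str, float]] = None,
) -> MetaScan:
    """Pool every SNP present in at least one study.

    Study-level genomic control (``gc_study``) computes lambda_k from each
    study's Wald statistics (or takes precomputed overrides) and inflates
    every V_k before pooling; meta-level control (``gc_meta``) repeats the
    correction on the pooled Wald statistics.  SNPs present in only a
    subset of studies are pooled over the available ones, with the study
    count and total sample size reported.
    """
    if not studies:
        raise PleioscanError("no studies supplied")
    phen = studies[0].phenotype_names
    for s in studies[1:]:
        if s.phenotype_names != phen:
            raise ConsistencyError(
                f"phenotype order mismatch: {s.study_id} has {s.phenotype_names}, "
                f"expected {phen}"
            )
    J = len(phen)

    # Per-study filtering and lambda computation.
    lam_k: dict[str, float] = {}
    inflated_any = False  # did study-level GC actually scale any V_k?
    maps: list[dict[tuple[str, int], SnpEntry]] = []
    for s in studies:
        entries = [
            e for e in s.entries
            if not (info_min is not None and (not math.isfinite(e.info) or e.info < info_min))
            and not (maf_min is not None and not (maf_min <= e.eaf <= 1.0 - maf_min))
            and np.all(np.isfinite(e.beta))
        ]
        if gc_study:
            if study_lambdas is not None and s.study_id in study_lambdas:
                lam = float(study_lambdas[s.study_id])
            else:
                walds = []
                for e in entries:
                    try:
                        walds.append(wald_test(e.beta, e.vcov, J)[0])
                    except PleioscanError:
                        continue
                lam = gc_lambda(walds, J)
            lam_k[s.study_id] = lam
            if lam > 1.0:
                inflated_any = True
                entries = [
                    SnpEntry(
                        **{**e.__dict__, "vcov": apply_gc(e.vcov, lam)}
                    )
                    for e in entries
                ]
        maps.append(StudySummary(s.study_id, phen, entries).by_key())

    all_keys = sorted(set().union(*maps), key=lambda k: (k[0], k[1]))
    results: list[MetaResult] = []
    for key in all_keys:
        present = [m[key] for m in maps if key in m]
        aligned = align_alleles(present)
        if not aligned:
            continue
        if drop_ambiguous and aligned[0].ambiguous:
            continue
        ref = aligned[0]
        n_total = sum(e.n_used for e in aligned)
        try:
            if len(aligned) == 1:
                # single contributing study: pass beta and V through exactly
                # (pooling would round-trip two matrix inversions)
                pooled_beta, pooled_vcov = ref.beta.copy(), ref.vcov.copy()
                if np.linalg.matrix_rank(pooled_vcov) < J:
                    raise PleioscanError("singular vcov for single-study SNP")
            else:
                pooled_beta, pooled_vcov = pool_slopes(
                    [e.beta for e in aligned], [e.vcov for e in aligned]
                )
            if len(aligned) == 1 and not inflated_any and math.isfinite(ref.chi2):
                # single contributing study, untouched covariance: pass the
                # study's own test through unchanged
                chi2, p = ref.chi2, ref.p_value
            else:
                chi2, p = wald_test(pooled_beta, pooled_vcov, J)
        except PleioscanError as exc:
            results.append(
                MetaResult(
                    snp_id=ref.snp_id, rsid=ref.rsid, chromosome=ref.chromosome,
                    position=ref.position, effect_allele=ref.effect_allele,
                    other_allele=ref.other_allele, eaf=math.nan,
                    pooled_beta=np.full(J, math.nan),
                    pooled_vcov=np.full((J, J), math.nan),
                    chi2=math.nan, df=J, p_value=math.nan,
                    k_studies=len(aligned), n_total=n_total,
                    ambiguous=ref.ambiguous, failed=True, reason=str(exc),
                )
            )
            continue
        eaf = (
            sum(e.eaf * e.n_used for e in aligned) / n_total
            if n_total > 0 else math.nan
        )
        pooled_db = None
        best = None
        if all(e.delta_bics is not None for e in aligned):
            pooled_db = pool_bics([e.delta_bics for e in aligned])
            best = select_best(pooled_db)
        results.append(
            MetaResult(
                snp_id=ref.snp_id, rsid=ref.rsid, chromosome=ref.chromosome,
                position=ref.position, effect_allele=ref.effect_allele,
                other_allele=ref.other_allele, eaf=eaf,
                pooled_beta=pooled_beta, pooled_vcov=pooled_vcov,
                chi2=chi2, df=J, p_value=p,
                k_studies=len(aligned), n_total=n_total,
                pooled_delta_bics=pooled_db, best_subset=best,
                ambiguous=ref.ambiguous,
            )
        )

    # Meta-level genomic control: recompute every pooled test with the
    # inflated covariance when lambda_MA > 1.
    lam_ma = math.nan
    ok = [r for r in results if not r.failed]
    if ok:
        lam_ma = gc_lambda([r.chi2 for r in ok], J)
        if gc_meta and lam_ma > 1.0:
            for r in ok:
                r.pooled_vcov = apply_gc(r.pooled_vcov, lam_ma)
                r.chi2, r.p_value = wald_test(r.pooled_beta, r.pooled_vcov, J)
    return MetaScan(
        phenotype_names=phen,
        results=results,
        study_lambdas=lam_k,
        meta_lambda=lam_ma,
    )
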