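"""Forward simulation of GWAS studies with known truth.

The generator works forward — genotype causes phenotype — which is the
direction the biology runs and the direction that makes parameter-recovery
claims meaningful for the reverse-regression analysis:

* genotypes are drawn under Hardy-Weinberg equilibrium at a target minor
  allele frequency;
* phenotypes follow ``y_i = g_i * b + e_i`` with ``e_i`` multivariate
  normal with unit variances and a specified correlation matrix, so ``b``
  is a per-allele shift in phenotype standard-deviation units;
* imputation uncertainty blurs the one-hot genotype indicator towards a
  Dirichlet(1,1,1) draw: ``p = (1 - w) * onehot + w * dirichlet`` with
  ``w`` the ``imputation_noise`` weight (0 gives hard calls with info
  score exactly 1).

All randomness flows through one seeded generator, so output files are
byte-identical across runs with the same configuration.  The simulator
does not model linkage disequilibrium between SNPs or population
stratification; SNPs are independent draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genio import (
    PhenotypeTable,
    PleioscanError,
    SnpRecord,
    write_gen,
    write_sample,
)

__all__ = ["SimConfig", "SimTruth", "simulate_arrays", "simulate_study",
           "simulate_multi_study"]


class ConfigError(PleioscanError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-level simulation settings.

    ``forward_effects`` is the length-J vector of per-allele phenotype
    shifts (SD units) applied at every causal SNP; ``causal_fraction``
    controls how many SNPs carry it.  ``pheno_corr`` defaults to the
    identity (uncorrelated residuals).
    """

    n: int = 1000
    J: int = 4
    maf: float = 0.3
    pheno_corr: Optional[np.ndarray] = None
    forward_effects: Optional[np.ndarray] = None
    imputation_noise: float = 0.0
    n_snps: int = 100
    causal_fraction: float = 0.0
    seed: int = 0
    chromosome: str = "1"

    def resolved_corr(self) -> np.ndarray:
        R = np.eye(self.J) if self.pheno_corr is None else np.asarray(self.pheno_corr, float)
        if R.shape != (self.J, self.J):
            raise ConfigError(f"pheno_corr must be {self.J}x{self.J}")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ConfigError("pheno_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 1e-10:
            raise ConfigError("pheno_corr must be positive definite")
        return R

    def resolved_effects(self) -> np.ndarray:
        b = np.zeros(self.J) if self.forward_effects is None else np.asarray(self.forward_effects, float)
        if b.shape != (self.J,):
            raise ConfigError(f"forward_effects must have length {self.J}")
        return b

    def validate(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ConfigError(f"maf must be in (0, 0.5], got {self.maf}")
        if not 0.0 <= self.imputation_noise <= 1.0:
            raise ConfigError("imputation_noise must be in [0, 1]")
        self.resolved_corr()
        self.resolved_effects()


@dataclass
class SimTruth:
    """Ground truth matching the emitted study."""

    seed: int
    causal: np.ndarray  # bool per SNP
    effects: np.ndarray  # (n_snps, J): per-SNP forward effect vectors
    realized_maf: np.ndarray  # per SNP, from the true hard genotypes

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            J = self.effects.shape[1]
            cols = ["snp_index", "causal", "realized_maf"] + [f"b{j+1}" for j in range(J)]
            fh.write("\t".join(cols) + "\n")
            for i in range(self.causal.shape[0]):
                row = [str(i), str(int(self.causal[i])), format(self.realized_maf[i], ".6g")]
                row += [format(v, ".6g") for v in self.effects[i]]
                fh.write("\t".join(row) + "\n")


@dataclass
class SimStudy:
    """In-memory simulated study: records, phenotypes, and truth."""

    records: list[SnpRecord]
    phenotypes: PhenotypeTable
    truth: SimTruth


def _blur_probs(g: np.ndarray, w: float, rng: np.random.Generator) -> np.ndarray:
    """One-hot genotype indicators blended with a Dirichlet(1,1,1) draw."""
    n = g.shape[0]
    onehot = np.zeros((n, 3))
    onehot[np.arange(n), g] = 1.0
    if w == 0.0:
        return onehot
    blur = rng.dirichlet(np.ones(3), size=n)
    return (1.0 - w) * onehot + w * blur


def simulate_arrays(cfg: SimConfig) -> SimStudy:
    """Simulate one study entirely in memory."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    R = cfg.resolved_corr()
    b = cfg.resolved_effects()
    L = np.linalg.cholesky(R)

    n, J = cfg.n, cfg.J
    causal = rng.random(cfg.n_snps) < cfg.causal_fraction
    effects = np.where(causal[:, None], b[None, :], 0.0)
    records: list[SnpRecord] = []
    realized = np.empty(cfg.n_snps)

    # Phenotypes are driven by the FIRST causal SNP (if any); additional
    # causal SNPs would require a multi-locus phenotype model, which is out
    # of scope for independent-SNP fixtures, so at most one SNP is causal
    # per study draw.
    causal_idx = int(np.argmax(causal)) if causal.any() else -1
    if causal.any():
        causal[:] = False
        causal[causal_idx] = True
        effects = np.where(causal[:, None], b[None, :], 0.0)

    g_causal = None
    for s in range(cfg.n_snps):
        g = rng.binomial(2, cfg.maf, size=n)
        realized[s] = g.mean() / 2.0
        if s == causal_idx:
            g_causal = g
        probs = _blur_probs(g, cfg.imputation_noise, rng)
        records.append(
            SnpRecord(
                snp_id=f"snp{s + 1}",
                rsid=f"rs{s + 1}",
                chromosome=cfg.chromosome,
                position=1000 * (s + 1),
                allele_a="A",
                allele_b="G",
                probs=probs,
                dialect="snpid-first",
            )
        )

    e = rng.standard_normal((n, J)) @ L.T
    y = e if g_causal is None else g_causal[:, None] * b[None, :] + e
    phenos = PhenotypeTable(
        individual_ids=[f"ind{i + 1}" for i in range(n)],
        phenotype_names=[f"pheno{j + 1}" for j in range(J)],
        values=y,
        column_kinds=["continuous"] * J,
    )
    truth = SimTruth(seed=cfg.seed, causal=causal, effects=effects, realized_maf=realized)
    return SimStudy(records=records, phenotypes=phenos, truth=truth)


def simulate_study(cfg: SimConfig, out_dir, prefix: str = "study") -> tuple[Path, Path, SimTruth]:
    """Simulate a study and write its GEN, SAMPLE and truth files.

    Returns ``(gen_path, sample_path, truth)``.  Files are byte-identical
    across runs for a fixed configuration.
    """
    study = simulate_arrays(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen_path = out_dir / f"{prefix}.gen"
    sample_path = out_dir / f"{prefix}.sample"
    truth_path = out_dir / f"{prefix}.truth.tsv"
    write_gen(study.records, gen_path)
    cols = {
        name: study.phenotypes.values[:, j]
        for j, name in enumerate(study.phenotypes.phenotype_names)
    }
    write_sample(
        sample_path,
        study.phenotypes.individual_ids,
        cols,
        {name: "P" for name in cols},
    )
    study.truth.to_tsv(truth_path)
    return gen_path, sample_path, study.truth


def simulate_multi_study(
    cfgs: Sequence[SimConfig],
    shared_truth: bool = True,
    swap_alleles_in: Sequence[int] = (),
) -> list[SimStudy]:
    """Simulate several studies with independent samples.

    With ``shared_truth`` every study uses the first configuration's causal
    structure (same SNP map, same forward effects) while drawing its own
    individuals.  ``swap_alleles_in`` lists study indices whose allele
    labels (and genotype probability triples) are swapped, to exercise
    allele alignment downstream.
    """
    if not cfgs:
        raise ConfigError("need at least one study configuration")
    if shared_truth:
        J0, m0 = cfgs[0].J, cfgs[0].n_snps
        for c in cfgs[1:]:
            if c.J != J0 or c.n_snps != m0:
                raise ConfigError("shared_truth requires identical J and SNP map")
        cfgs = [
            replace(
                c,
                causal_fraction=cfgs[0].causal_fraction,
                forward_effects=cfgs[0].resolved_effects().copy(),
                maf=cfgs[0].maf,
            )
            for c in cfgs
        ]
        # Shared causal flags: force the same causal SNP index by making the
        # flag draw deterministic across studies.
        base = simulate_arrays(cfgs[0])
        causal = base.truth.causal
        studies = [base]
        for c in cfgs[1:]:
            s = simulate_arrays(replace(c, causal_fraction=0.0))
            if causal.any():
                # re-inject the shared causal SNP into this study's sample
                idx = int(np.argmax(causal))
                rng = np.random.default_rng((c.seed, 7))
                g = rng.binomial(2, c.maf, size=c.n)
                s.records[idx].probs = _blur_probs(g, c.imputation_noise, rng)
                s.truth.realized_maf[idx] = g.mean() / 2.0
                b = cfgs[0].resolved_effects()
                s.phenotypes.values += g[:, None] * b[None, :]
                s.truth.causal = causal.copy()
                s.truth.effects = base.truth.effects.copy()
            studies.append(s)
    else:
        studies = [simulate_arrays(c) for c in cfgs]

    for i in swap_alleles_in:
        for rec in studies[i].records:
            rec.allele_a, rec.allele_b = rec.allele_b, rec.allele_a
            rec.probs = rec.probs[:, ::-1].copy()
    return studies
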