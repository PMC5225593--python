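"""Oxford GEN/SAMPLE input/output and per-SNP genotype summaries.

The GEN format (as emitted by the IMPUTE family of imputation tools) stores
one SNP per row: five leading metadata columns followed by three genotype
probabilities ``(pAA, pAB, pBB)`` per individual.  Two dialects of the five
leading columns circulate: ``snp_id rsid position alleleA alleleB`` and
``chromosome rsid position alleleA alleleB``; both are accepted and the
detected dialect is recorded on each record.  The SAMPLE format carries one
individual per row with a two-line header (column names, then type codes
``0/D/C/B/P``).

Dosage is the expected count of the chosen effect allele, in [0, 2].
Imputation quality is summarised by the IMPUTE-style info score, a ratio of
the observed dosage variance to the variance expected under Hardy-Weinberg
equilibrium at the estimated allele frequency.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, TextIO

import numpy as np

__all__ = [
    "PleioscanError",
    "FormatError",
    "ConsistencyError",
    "PhenotypeLookupError",
    "MonomorphicError",
    "SnpRecord",
    "PhenotypeTable",
    "DosageVector",
    "read_gen",
    "write_gen",
    "read_sample",
    "write_sample",
    "dosage",
    "effect_allele_frequency",
    "info_score",
]

# Probability triples should sum to ~1; a sum below MISSING_SUM marks the
# genotype missing (the Oxford convention writes "0 0 0" for no-calls).
PROB_SUM_TOL = 0.02
MISSING_SUM = 0.1

# Tokens accepted as a chromosome in the first GEN column.
_CHROM_TOKENS = {str(i) for i in range(1, 26)} | {
    "X", "Y", "XY", "MT", "M",
    "0X", "0Y",
}


class PleioscanError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PleioscanError):
    """A file does not conform to the expected on-disk format."""


class ConsistencyError(PleioscanError):
    """Inputs that must agree (sample sizes, phenotype sets) do not."""


class PhenotypeLookupError(PleioscanError):
    """A requested phenotype is absent from the SAMPLE file."""


class MonomorphicError(PleioscanError):
    """Allele frequency is 0 or 1, so a frequency-scaled quantity is undefined."""


@dataclass
class SnpRecord:
    """One SNP's identity, alleles, and per-individual genotype probabilities.

    ``probs`` is an (n, 3) float array of ``(pAA, pAB, pBB)`` triples.  A
    triple whose sum is below :data:`MISSING_SUM` is a missing genotype.
    """

    snp_id: str
    rsid: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str
    probs: np.ndarray
    dialect: str = "snpid-first"  # or "chrom-first"

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the genotype is missing."""
        return self.probs.sum(axis=1) < MISSING_SUM

    def validate(self) -> None:
        if self.position < 1:
            raise FormatError(f"{self.rsid}: position must be >= 1, got {self.position}")
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise FormatError(f"{self.rsid}: probability array must be (n, 3)")
        sums = self.probs.sum(axis=1)
        bad = (~self.missing_mask()) & (np.abs(sums - 1.0) > PROB_SUM_TOL)
        if bad.any():
            i = int(np.argmax(bad))
            raise FormatError(
                f"{self.rsid}: genotype probabilities for individual {i} sum to "
                f"{sums[i]:.4f}, outside 1 +/- {PROB_SUM_TOL}"
            )


@dataclass
class PhenotypeTable:
    """Individuals x phenotypes matrix with NaN as the missing marker."""

    individual_ids: list[str]
    phenotype_names: list[str]
    values: np.ndarray  # (n, J) float, NaN = missing
    column_kinds: list[str]  # per column: "continuous" | "binary" | "discrete"

    def __post_init__(self) -> None:
        if len(set(self.phenotype_names)) != len(self.phenotype_names):
            raise ConsistencyError("phenotype names must be unique")
        if self.values.shape != (len(self.individual_ids), len(self.phenotype_names)):
            raise ConsistencyError(
                f"phenotype matrix shape {self.values.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.phenotype_names)} phenotypes"
            )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]

    def select(self, names: Sequence[str]) -> "PhenotypeTable":
        idx = [self.phenotype_names.index(n) for n in names]
        return PhenotypeTable(
            individual_ids=self.individual_ids,
            phenotype_names=[self.phenotype_names[i] for i in idx],
            values=self.values[:, idx].copy(),
            column_kinds=[self.column_kinds[i] for i in idx],
        )


@dataclass
class DosageVector:
    """Expected effect-allele counts per individual; NaN = missing genotype."""

    values: np.ndarray
    effect_allele: str
    other_allele: str

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# GEN reading/writing
# ---------------------------------------------------------------------------

def _open_text(path) -> TextIO:
    """Open ``path`` for text reading, transparently handling gzip.

    Detection is by the gzip magic bytes, not the file extension.
    """
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    return io.TextIOWrapper(raw, encoding="ascii")


def _detect_dialect(first_field: str) -> str:
    tok = first_field.upper()
    if tok.startswith("CHR"):
        tok = tok[3:]
    return "chrom-first" if tok in _CHROM_TOKENS else "snpid-first"


def read_gen(path, n_expected: Optional[int] = None) -> Iterator[SnpRecord]:
    """Stream :class:`SnpRecord` objects from a (possibly gzipped) GEN file.

    Each row must carry 5 leading columns then exactly 3*n probabilities;
    malformed rows raise :class:`FormatError` naming the line, and a sample
    size differing from ``n_expected`` (or from earlier rows) raises
    :class:`ConsistencyError`.
    """
    n_seen: Optional[int] = n_expected
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 8 or (len(fields) - 5) % 3 != 0:
                raise FormatError(
                    f"{path}: line {lineno}: expected 5 metadata columns plus "
                    f"3n probabilities, got {len(fields)} columns"
                )
            n = (len(fields) - 5) // 3
            if n_seen is None:
                n_seen = n
            elif n != n_seen:
                raise ConsistencyError(
                    f"{path}: line {lineno}: {n} individuals, expected {n_seen}"
                )
            try:
                position = int(fields[2])
                probs = np.array(fields[5:], dtype=float).reshape(n, 3)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            dialect = _detect_dialect(fields[0])
            if dialect == "chrom-first":
                chromosome, snp_id = fields[0], fields[1]
            else:
                chromosome, snp_id = "NA", fields[0]
            rec = SnpRecord(
                snp_id=snp_id,
                rsid=fields[1],
                chromosome=chromosome,
                position=position,
                allele_a=fields[3],
                allele_b=fields[4],
                probs=probs,
                dialect=dialect,
            )
            rec.validate()
            yield rec


def _fmt(x: float) -> str:
    """Canonical probability formatting: 6 significant digits, idempotent
    under a read/write round trip."""
    return format(x, ".6g")


def write_gen(records: Iterable[SnpRecord], path) -> None:
    """Write records to ``path`` in GEN format (gzip if the name ends .gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rec in records:
            lead = rec.chromosome if rec.dialect == "chrom-first" else rec.snp_id
            meta = [lead, rec.rsid, str(rec.position), rec.allele_a, rec.allele_b]
            probs = [_fmt(p) for p in rec.probs.ravel()]
            fh.write(" ".join(meta + probs) + "\n")


# ---------------------------------------------------------------------------
# SAMPLE reading/writing
# ---------------------------------------------------------------------------

_KIND_FROM_CODE = {"C": "continuous", "P": "continuous", "B": "binary", "D": "discrete"}
_VALID_CODES = {"0", "C", "P", "B", "D"}


def read_sample(path, phenotype_names: Sequence[str]) -> PhenotypeTable:
    """Read the requested phenotype columns from a SAMPLE file.

    The file has two header lines: column names, then per-column type codes
    (``0`` identifier/other, ``D`` discrete, ``C`` continuous covariate,
    ``B`` binary phenotype, ``P`` continuous phenotype).  ``NA`` is parsed
    as missing.  Individual order is preserved.
    """
    if not phenotype_names:
        raise PhenotypeLookupError("at least one phenotype name is required")
    with _open_text(path) as fh:
        header = fh.readline().split()
        codes = fh.readline().split()
        if len(header) != len(codes):
            raise FormatError(
                f"{path}: header has {len(header)} names but {len(codes)} type codes"
            )
        bad = [c for c in codes if c not in _VALID_CODES]
        if bad:
            raise FormatError(f"{path}: unknown column type code(s) {bad}")
        missing = [n for n in phenotype_names if n not in header]
        if missing:
            raise PhenotypeLookupError(
                f"phenotype(s) {missing} not in {path}; available columns: {header}"
            )
        col_idx = [header.index(n) for n in phenotype_names]
        kinds = [_KIND_FROM_CODE.get(codes[i], "continuous") for i in col_idx]

        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=3):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}: line {lineno}: {len(fields)} fields, expected {len(header)}"
                )
            ids.append(fields[0])
            row = []
            for i in col_idx:
                v = fields[i]
                row.append(math.nan if v.upper() == "NA" else float(v))
            rows.append(row)
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(col_idx)))
    return PhenotypeTable(
        individual_ids=ids,
        phenotype_names=list(phenotype_names),
        values=values,
        column_kinds=kinds,
    )


def write_sample(
    path,
    individual_ids: Sequence[str],
    columns: dict[str, np.ndarray],
    codes: dict[str, str],
) -> None:
    """Write a SAMPLE file with the standard two-line header.

    ``columns`` maps name -> value vector; ``codes`` maps name -> type code.
    The mandatory ``ID_1 ID_2 missing`` prefix columns are synthesised.
    """
    names = list(columns)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write(" ".join(["ID_1", "ID_2", "missing"] + names) + "\n")
        fh.write(" ".join(["0", "0", "0"] + [codes[n] for n in names]) + "\n")
        for i, iid in enumerate(individual_ids):
            vals = []
            for n in names:
                v = float(columns[n][i])
                vals.append("NA" if math.isnan(v) else _fmt(v))
            fh.write(" ".join([iid, iid, "0"] + vals) + "\n")


# ---------------------------------------------------------------------------
# Dosage, allele frequency, info score
# ---------------------------------------------------------------------------

def dosage(record: SnpRecord, effect_allele: str = "B") -> DosageVector:
    """Expected effect-allele count per individual.

    With effect allele B the dosage is ``pAB + 2*pBB``; with A it is
    ``pAB + 2*pAA``.  Missing triples give NaN.
    """
    if effect_allele not in ("A", "B"):
        raise ValueError("effect_allele must be 'A' or 'B'")
    p = record.probs
    if effect_allele == "B":
        values = p[:, 1] + 2.0 * p[:, 2]
        eff, oth = record.allele_b, record.allele_a
    else:
        values = p[:, 1] + 2.0 * p[:, 0]
        eff, oth = record.allele_a, record.allele_b
    values = values.astype(float).copy()
    values[record.missing_mask()] = np.nan
    return DosageVector(values=values, effect_allele=eff, other_allele=oth)


def effect_allele_frequency(d: DosageVector) -> float:
    """Mean non-missing dosage divided by 2."""
    ok = ~np.isnan(d.values)
    if not ok.any():
        raise MonomorphicError("all genotypes missing: allele frequency undefined")
    return float(d.values[ok].mean() / 2.0)


def info_score(record: SnpRecord, effect_allele: str = "B") -> float:
    """IMPUTE-style imputation quality measure.

    ``info = 1 - mean_i(f_i - e_i^2) / (2 theta (1 - theta))`` where
    ``e_i`` is the expected effect-allele dosage, ``f_i = pAB + 4*p_hom``
    (homozygote for the effect allele) is the expected squared dosage, and
    ``theta`` is the effect-allele frequency.  Equals 1 exactly for hard
    calls; clipped below at 0.  Monomorphic SNPs have no defined info score.
    """
    d = dosage(record, effect_allele)
    ok = ~np.isnan(d.values)
    if ok.sum() < 2:
        raise MonomorphicError("need >= 2 non-missing genotypes for info score")
    theta = effect_allele_frequency(d)
    if theta <= 0.0 or theta >= 1.0:
        raise MonomorphicError(f"allele frequency {theta}: info score undefined")
    p = record.probs[ok]
    e = d.values[ok]
    hom = p[:, 2] if effect_allele == "B" else p[:, 0]
    f = p[:, 1] + 4.0 * hom
    info = 1.0 - float(np.mean(f - e * e)) / (2.0 * theta * (1.0 - theta))
    return max(info, 0.0)
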