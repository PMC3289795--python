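"""Core data types and I/O for unphased biallelic case-control genotype data.

The observational unit is a subjects x SNPs matrix of unphased genotypes.
Each SNP carries an ordered allele pair (A, B) with A preceding B in
lexicographic order (A < C < G < T) regardless of allele frequency; the
three genotype states AA / AB / BB are encoded as integer codes 0 / 1 / 2,
with -1 for missing.  A binary phenotype (1 = trait present) is stored
alongside, aligned by subject.

Native on-disk format is a tab-separated dialect (see
:func:`read_genotype_tsv`); VCF is supported as an optional ingestion path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: genotype codes
AA: int = 0
AB: int = 1
BB: int = 2
MISSING: int = -1

GENOTYPE_LABELS = ("AA", "AB", "BB")
VALID_ALLELES = frozenset("ACGT")
MISSING_TOKEN = ".."


class FormatError(ValueError):
    """Malformed file structure (headers, column counts)."""


class DataError(ValueError):
    """Well-formed file containing invalid values."""


class EmptyInputError(DataError):
    """No usable records survived parsing/filtering."""


def _check_allele_pair(a: str, b: str, context: str) -> None:
    if a not in VALID_ALLELES or b not in VALID_ALLELES:
        raise DataError(f"{context}: alleles must be single characters in ACGT, got {a!r}/{b!r}")
    if not a < b:
        raise DataError(f"{context}: alleles must be distinct and lexicographically ordered, got {a!r}/{b!r}")


@dataclass(frozen=True)
class GenotypeMatrix:
    """Subjects x SNPs categorical genotype matrix.

    Parameters
    ----------
    subject_ids : sequence of str
        Unique subject identifiers, one per row.
    snp_ids : sequence of str
        Unique SNP identifiers, one per column.
    alleles : sequence of (str, str)
        Per-SNP ordered allele pair; first allele must precede the second
        lexicographically and both must be in ACGT.
    codes : ndarray of int8, shape (n_subjects, n_snps)
        Genotype codes: 0 = AA, 1 = AB, 2 = BB, -1 = missing.
    """

    subject_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    alleles: tuple[tuple[str, str], ...]
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        object.__setattr__(self, "alleles", tuple((a, b) for a, b in self.alleles))
        codes = np.asarray(self.codes, dtype=np.int8)
        object.__setattr__(self, "codes", codes)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise DataError("subject_ids are not unique")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise DataError("snp_ids are not unique")
        if len(self.alleles) != len(self.snp_ids):
            raise DataError("alleles/snp_ids length mismatch")
        for snp, (a, b) in zip(self.snp_ids, self.alleles):
            _check_allele_pair(a, b, f"SNP {snp}")
        if codes.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise DataError(
                f"codes shape {codes.shape} does not match "
                f"({len(self.subject_ids)}, {len(self.snp_ids)})"
            )
        bad = ~np.isin(codes, (AA, AB, BB, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(f"invalid genotype code {codes[i, j]} at subject row {i}, SNP column {j}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def genotype_string(self, i: int, j: int) -> str:
        """Two-character genotype string for subject row i, SNP column j."""
        code = int(self.codes[i, j])
        if code == MISSING:
            return MISSING_TOKEN
        a, b = self.alleles[j]
        return (a + a, a + b, b + b)[code]

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            subject_ids=self.subject_ids,
            snp_ids=tuple(self.snp_ids[j] for j in idx),
            alleles=tuple(self.alleles[j] for j in idx),
            codes=self.codes[:, idx],
        )


@dataclass(frozen=True)
class PhenotypeVector:
    """Binary trait labels aligned with a :class:`GenotypeMatrix`.

    ``labels`` is 1 where the trait is present (T) and 0 otherwise.
    """

    subject_ids: tuple[str, ...]
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        labels = np.asarray(self.labels, dtype=np.int8)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1 or len(labels) != len(self.subject_ids):
            raise DataError("labels must be 1-D and aligned with subject_ids")
        if not np.isin(labels, (0, 1)).all():
            raise DataError("phenotype labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class GenotypeCountTable:
    """Per-SNP 2x3 phenotype-by-genotype count table.

    ``counts[0]`` is the (AA, AB, BB) count triple among subjects with the
    trait, ``counts[1]`` the triple among subjects without it.  Missing
    genotypes are tracked separately and excluded from the 2x3 body.
    """

    snp_id: str
    counts: np.ndarray = field(repr=False)
    n_missing_t: int = 0
    n_missing_not_t: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (2, 3):
            raise DataError(f"count table for {self.snp_id} must be 2x3, got {counts.shape}")
        if (counts < 0).any() or self.n_missing_t < 0 or self.n_missing_not_t < 0:
            raise DataError(f"negative counts in table for {self.snp_id}")

    @property
    def n_t(self) -> int:
        """Number of trait subjects, including missing genotypes."""
        return int(self.counts[0].sum()) + self.n_missing_t

    @property
    def n_not_t(self) -> int:
        return int(self.counts[1].sum()) + self.n_missing_not_t


# ---------------------------------------------------------------------------
# genotype TSV dialect
# ---------------------------------------------------------------------------

def _parse_snp_column(token: str, position: int) -> tuple[str, tuple[str, str]]:
    # header token: "<snp_id>:<A>/<B>"
    if ":" not in token:
        raise FormatError(f"header column {position}: expected '<snp_id>:<A>/<B>', got {token!r}")
    snp_id, _, pair = token.rpartition(":")
    if not snp_id or "/" not in pair:
        raise FormatError(f"header column {position}: expected '<snp_id>:<A>/<B>', got {token!r}")
    a, _, b = pair.partition("/")
    try:
        _check_allele_pair(a, b, f"header column {position} ({snp_id})")
    except DataError as exc:
        raise FormatError(str(exc)) from None
    return snp_id, (a, b)


def _genotype_code(cell: str, alleles: tuple[str, str], row: int, col: str) -> int:
    if cell == MISSING_TOKEN:
        return MISSING
    a, b = alleles
    if len(cell) != 2 or any(ch not in (a, b) for ch in cell):
        raise DataError(
            f"row {row}, SNP {col}: genotype {cell!r} is not composed of declared alleles {a}/{b}"
        )
    return cell.count(b)  # 0 -> AA, 1 -> AB, 2 -> BB; "GA" and "AG" both count one B


def read_genotype_tsv(path: str | Path) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Read the native genotype TSV dialect.

    Layout: a header line ``subject_id<TAB>phenotype<TAB><snp>:<A>/<B> ...``
    followed by one row per subject with phenotype 0/1 and two-character
    genotype strings (``..`` for missing).  Heterozygote strings are
    canonicalized, so ``GA`` and ``AG`` map to the same AB state.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if len(fields) < 2 or fields[0] != "subject_id" or fields[1] != "phenotype":
            raise FormatError(
                "header must start with 'subject_id<TAB>phenotype', got "
                f"{fields[:2]!r}"
            )
        snp_ids: list[str] = []
        alleles: list[tuple[str, str]] = []
        for pos, token in enumerate(fields[2:], start=3):
            snp_id, pair = _parse_snp_column(token, pos)
            snp_ids.append(snp_id)
            alleles.append(pair)

        subject_ids: list[str] = []
        labels: list[int] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(fields):
                raise FormatError(
                    f"row {lineno}: expected {len(fields)} columns, got {len(cells)}"
                )
            subject_ids.append(cells[0])
            if cells[1] not in ("0", "1"):
                raise DataError(f"row {lineno}: phenotype must be 0 or 1, got {cells[1]!r}")
            labels.append(int(cells[1]))
            rows.append(
                [
                    _genotype_code(cell, alleles[j], lineno, snp_ids[j])
                    for j, cell in enumerate(cells[2:])
                ]
            )

    codes = np.array(rows, dtype=np.int8).reshape(len(subject_ids), len(snp_ids))
    matrix = GenotypeMatrix(tuple(subject_ids), tuple(snp_ids), tuple(alleles), codes)
    phenotype = PhenotypeVector(tuple(subject_ids), np.array(labels, dtype=np.int8))
    return matrix, phenotype


def write_genotype_tsv(matrix: GenotypeMatrix, phenotype: PhenotypeVector, path: str | Path) -> None:
    """Write the native genotype TSV dialect (inverse of :func:`read_genotype_tsv`)."""
    if matrix.subject_ids != phenotype.subject_ids:
        raise DataError("matrix and phenotype subjects are not aligned")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        cols = [f"{s}:{a}/{b}" for s, (a, b) in zip(matrix.snp_ids, matrix.alleles)]
        fh.write("\t".join(["subject_id", "phenotype", *cols]) + "\n")
        for i, sid in enumerate(matrix.subject_ids):
            genos = [matrix.genotype_string(i, j) for j in range(matrix.n_snps)]
            fh.write("\t".join([sid, str(int(phenotype.labels[i])), *genos]) + "\n")


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def _read_phenotype_table(path: str | Path) -> dict[str, int]:
    table: dict[str, int] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"phenotype file line {lineno}: expected 2 columns")
            sid, value = parts
            if lineno == 1 and value not in ("0", "1"):
                continue  # header line
            if value not in ("0", "1"):
                raise DataError(f"phenotype file line {lineno}: value must be 0/1, got {value!r}")
            table[sid] = int(value)
    return table


def read_vcf(path: str | Path, phenotype_path: str | Path) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Read biallelic SNPs from a VCF plus a two-column sample/phenotype TSV.

    REF/ALT are re-ordered lexicographically into the (A, B) convention
    before any downstream computation, so genotype codes always count copies
    of the lexicographically later allele.  Multi-allelic and non-SNP records
    are skipped (a count is logged).  Output subjects follow VCF sample
    order; every VCF sample must appear in the phenotype file.
    """
    from cyvcf2 import VCF  # deferred: only needed on this path

    phen = _read_phenotype_table(phenotype_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in phen]
    if absent:
        raise DataError(f"VCF samples missing from phenotype file: {absent[:5]}")

    snp_ids: list[str] = []
    alleles: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for idx, variant in enumerate(vcf):
        ref = (variant.REF or "").upper()
        alts = [a.upper() for a in (variant.ALT or [])]
        if len(ref) != 1 or len(alts) != 1 or len(alts[0]) != 1 \
                or ref not in VALID_ALLELES or alts[0] not in VALID_ALLELES:
            n_skipped += 1
            continue
        alt = alts[0]
        snp_id = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        alt_copies = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            a0, a1 = gt[0], gt[1]
            alt_copies[i] = MISSING if (a0 < 0 or a1 < 0) else (a0 > 0) + (a1 > 0)
        if ref < alt:
            pair, codes = (ref, alt), alt_copies
        else:  # ALT is the lexicographically first allele: flip B-copy counts
            pair = (alt, ref)
            codes = np.where(alt_copies == MISSING, MISSING, 2 - alt_copies).astype(np.int8)
        snp_ids.append(snp_id)
        alleles.append(pair)
        columns.append(codes)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    if not snp_ids:
        raise EmptyInputError("no biallelic SNP records in VCF")

    codes = np.column_stack(columns).astype(np.int8)
    matrix = GenotypeMatrix(tuple(samples), tuple(snp_ids), tuple(alleles), codes)
    labels = np.array([phen[s] for s in samples], dtype=np.int8)
    phenotype = PhenotypeVector(tuple(samples), labels)
    return matrix, phenotype


# ---------------------------------------------------------------------------
# genotype counting
# ---------------------------------------------------------------------------

def count_arrays(
    matrix: GenotypeMatrix, phenotype: PhenotypeVector
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP counts.

    Returns ``(n_t, n_not_t, missing_t, missing_not_t)`` where the first two
    are (n_snps, 3) genotype-count arrays for trait / no-trait subjects.
    """
    if matrix.subject_ids != phenotype.subject_ids:
        raise DataError("matrix and phenotype subjects are not aligned")
    y = phenotype.labels.astype(bool)
    out = []
    for mask in (y, ~y):
        sub = matrix.codes[mask]
        out.append(np.stack([(sub == g).sum(axis=0) for g in (AA, AB, BB)], axis=1))
        out.append((sub == MISSING).sum(axis=0))
    n_t, miss_t, n_not, miss_not = out
    return n_t.astype(np.int64), n_not.astype(np.int64), miss_t, miss_not


def count_genotypes(matrix: GenotypeMatrix, phenotype: PhenotypeVector) -> list[GenotypeCountTable]:
    """One :class:`GenotypeCountTable` per SNP, partitioning non-missing subjects."""
    n_t, n_not, miss_t, miss_not = count_arrays(matrix, phenotype)
    return [
        GenotypeCountTable(
            snp_id=snp,
            counts=np.stack([n_t[j], n_not[j]]),
            n_missing_t=int(miss_t[j]),
            n_missing_not_t=int(miss_not[j]),
        )
        for j, snp in enumerate(matrix.snp_ids)
    ]


def tables_to_arrays(tables: Iterable[GenotypeCountTable]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Stack count tables into ``(snp_ids, n_t, n_not_t)`` arrays."""
    tables = list(tables)
    snp_ids = [t.snp_id for t in tables]
    n_t = np.stack([t.counts[0] for t in tables]) if tables else np.zeros((0, 3), np.int64)
    n_not = np.stack([t.counts[1] for t in tables]) if tables else np.zeros((0, 3), np.int64)
    return snp_ids, n_t, n_not
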