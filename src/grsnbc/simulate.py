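"""Case-control genotype simulation.

Controls follow Hardy-Weinberg genotype frequencies ``(p^2, 2p(1-p), (1-p)^2)``
in (AA, AB, BB) order with ``p`` the minor-allele (A) frequency.  Case
frequencies tilt the control triple by the odds ratio according to the mode
of inheritance and are renormalized to sum to one:

* additive:   ``(p^2, 2*OR*p(1-p), OR^2*(1-p)^2)``
* recessive:  ``(p^2, 2p(1-p),     OR*(1-p)^2)``
* dominant:   ``(p^2, 2*OR*p(1-p), OR*(1-p)^2)``

As printed, the odds ratio multiplies the (1-p)^2 homozygote, i.e. the
*major*-allele genotypes carry the risk tilt; ``risk_on_minor=True``
transposes the tilt onto the minor-allele genotypes (the AUC geometry is
unchanged, only the per-allele interpretation flips).

Causal SNPs form the full OR x MAF x mode grid; null SNPs get MAFs drawn
uniformly from a configurable range, redrawn per replicate and shared
between the discovery and replication splits of that replicate.  A
count-mode generator produces per-SNP multinomial count tables with the
same distribution, for genome-scale designs where a subject-level matrix
would not fit in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import GenotypeCountTable, GenotypeMatrix, PhenotypeVector

ADDITIVE = "additive"
RECESSIVE = "recessive"
DOMINANT = "dominant"
MODES = (ADDITIVE, RECESSIVE, DOMINANT)

DISCOVERY = "discovery"
REPLICATION = "replication"
_SPLIT_CODE = {DISCOVERY: 0, REPLICATION: 1}

#: substream tags under (replicate, ...) spawn keys
_KEY_NULL_MAF = 1000
_KEY_COUNTS = 0
_KEY_MATRIX = 1

#: refuse subject-level simulation above this many genotype cells
DEFAULT_CELL_CAP = 200_000_000

#: allele pair assigned to simulated SNPs (A is the minor allele)
SIM_ALLELES = ("A", "C")


@dataclass(frozen=True)
class SimulationDesign:
    """Grid design for a case-control simulation study."""

    n_cases: int = 3000
    n_controls: int = 3000
    or_grid: tuple[float, ...] = (1.2, 1.3, 1.4, 1.5, 1.6)
    maf_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    modes: tuple[str, ...] = MODES
    n_null: int = 500_000
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    n_replicates: int = 5
    seed: int = 0
    risk_on_minor: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "or_grid", tuple(float(x) for x in self.or_grid))
        object.__setattr__(self, "maf_grid", tuple(float(x) for x in self.maf_grid))
        object.__setattr__(self, "modes", tuple(self.modes))
        object.__setattr__(self, "null_maf_range", tuple(self.null_maf_range))
        if self.n_cases <= 0 or self.n_controls <= 0 or self.n_replicates <= 0:
            raise ValueError("sample sizes and replicate count must be positive")
        if self.n_null < 0:
            raise ValueError("n_null must be non-negative")
        if any(o <= 0 for o in self.or_grid):
            raise ValueError("all odds ratios must be positive")
        if any(not 0 < p <= 0.5 for p in self.maf_grid):
            raise ValueError("all MAFs must lie in (0, 0.5]")
        for m in self.modes:
            if m not in MODES:
                raise ValueError(f"unknown inheritance mode {m!r}")
        lo, hi = self.null_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("null_maf_range must satisfy 0 < low <= high <= 0.5")

    @property
    def n_causal(self) -> int:
        return len(self.or_grid) * len(self.maf_grid) * len(self.modes)

    @property
    def n_snps(self) -> int:
        return self.n_causal + self.n_null

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationDesign":
        import yaml

        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        payload = {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "or_grid": list(self.or_grid),
            "maf_grid": list(self.maf_grid),
            "modes": list(self.modes),
            "n_null": self.n_null,
            "null_maf_range": list(self.null_maf_range),
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "risk_on_minor": self.risk_on_minor,
        }
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass(frozen=True)
class TruthTable:
    """Ground truth for every simulated SNP (grid rows first, then nulls)."""

    snp_ids: tuple[str, ...]
    is_causal: np.ndarray = field(repr=False)
    modes: tuple[str | None, ...] = field(repr=False)
    odds_ratios: np.ndarray = field(repr=False)
    mafs: np.ndarray = field(repr=False)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("snp_id\tis_causal\tmode\todds_ratio\tmaf\n")
            for j, snp in enumerate(self.snp_ids):
                fh.write(
                    f"{snp}\t{int(self.is_causal[j])}\t{self.modes[j] or 'NA'}\t"
                    f"{self.odds_ratios[j]:.10g}\t{self.mafs[j]:.10g}\n"
                )


def control_genotype_freqs(p: float) -> np.ndarray:
    """Hardy-Weinberg (AA, AB, BB) triple ``(p^2, 2p(1-p), (1-p)^2)``."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    q = 1.0 - p
    return np.array([p * p, 2.0 * p * q, q * q])


def mode_tilt(mode: str, odds_ratio: float, risk_on_minor: bool = False) -> np.ndarray:
    """Per-genotype odds tilt applied to the control triple in cases."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if mode == ADDITIVE:
        tilt = np.array([1.0, odds_ratio, odds_ratio**2])
    elif mode == RECESSIVE:
        tilt = np.array([1.0, 1.0, odds_ratio])
    elif mode == DOMINANT:
        tilt = np.array([1.0, odds_ratio, odds_ratio])
    else:
        raise ValueError(f"unknown inheritance mode {mode!r}")
    return tilt[::-1].copy() if risk_on_minor else tilt


def case_genotype_freqs(
    p: float, odds_ratio: float, mode: str, risk_on_minor: bool = False
) -> np.ndarray:
    """Normalized case genotype triple for the given mode and odds ratio."""
    unnormalized = control_genotype_freqs(p) * mode_tilt(mode, odds_ratio, risk_on_minor)
    return unnormalized / unnormalized.sum()


# ---------------------------------------------------------------------------
# deterministic substreams
# ---------------------------------------------------------------------------

def _rng(design: SimulationDesign, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=spawn_key))


def null_mafs(design: SimulationDesign, replicate: int) -> np.ndarray:
    """Replicate-level null-SNP MAF draw, shared by both splits."""
    rng = _rng(design, replicate, _KEY_NULL_MAF)
    lo, hi = design.null_maf_range
    return rng.uniform(lo, hi, size=design.n_null)


def truth_table(design: SimulationDesign, replicate: int) -> TruthTable:
    snp_ids: list[str] = []
    modes: list[str | None] = []
    ors: list[float] = []
    mafs: list[float] = []
    for mode in design.modes:
        for o in design.or_grid:
            for p in design.maf_grid:
                snp_ids.append(f"causal_{mode[:3]}_or{o:g}_maf{p:g}")
                modes.append(mode)
                ors.append(o)
                mafs.append(p)
    width = max(6, len(str(max(design.n_null, 1))))
    nm = null_mafs(design, replicate)
    for j in range(design.n_null):
        snp_ids.append(f"null_{j:0{width}d}")
        modes.append(None)
        ors.append(1.0)
        mafs.append(float(nm[j]))
    k = len(snp_ids)
    is_causal = np.zeros(k, dtype=bool)
    is_causal[: design.n_causal] = True
    return TruthTable(
        snp_ids=tuple(snp_ids),
        is_causal=is_causal,
        modes=tuple(modes),
        odds_ratios=np.array(ors),
        mafs=np.array(mafs),
    )


def _freq_triples(design: SimulationDesign, truth: TruthTable) -> tuple[np.ndarray, np.ndarray]:
    """(case, control) genotype frequency arrays, shape (n_snps, 3)."""
    k = len(truth.snp_ids)
    control = np.empty((k, 3))
    case = np.empty((k, 3))
    for j in range(k):
        control[j] = control_genotype_freqs(float(truth.mafs[j]))
        if truth.is_causal[j]:
            case[j] = case_genotype_freqs(
                float(truth.mafs[j]),
                float(truth.odds_ratios[j]),
                truth.modes[j],
                design.risk_on_minor,
            )
        else:
            case[j] = control[j]
    return case, control


def draw_genotype_codes(
    rng: np.random.Generator, freqs: np.ndarray, n_subjects: int
) -> np.ndarray:
    """Draw an (n_subjects, n_snps) int8 code matrix from per-SNP triples."""
    cum0 = freqs[:, 0]
    cum1 = freqs[:, 0] + freqs[:, 1]
    u = rng.random((n_subjects, freqs.shape[0]))
    return ((u > cum0).astype(np.int8) + (u > cum1).astype(np.int8))


def simulate_dataset(
    design: SimulationDesign,
    split: str = DISCOVERY,
    replicate: int = 0,
    cell_cap: int = DEFAULT_CELL_CAP,
) -> tuple[GenotypeMatrix, PhenotypeVector, TruthTable]:
    """Subject-level simulation of one split of one replicate.

    Deterministic given (seed, replicate, split).  Cases come first in the
    output.  Designs whose genotype matrix would exceed ``cell_cap`` cells
    are refused; use :func:`simulate_counts` for genome-scale ranking.
    """
    split_code = _SPLIT_CODE[split]
    truth = truth_table(design, replicate)
    n_subj = design.n_cases + design.n_controls
    if n_subj * len(truth.snp_ids) > cell_cap:
        raise ValueError(
            f"{n_subj} x {len(truth.snp_ids)} genotype cells exceed the cap "
            f"({cell_cap}); use simulate_counts for ranking at this scale"
        )
    case_f, control_f = _freq_triples(design, truth)
    rng = _rng(design, replicate, split_code, _KEY_MATRIX)
    codes = np.empty((n_subj, len(truth.snp_ids)), dtype=np.int8)
    codes[: design.n_cases] = draw_genotype_codes(rng, case_f, design.n_cases)
    codes[design.n_cases:] = draw_genotype_codes(rng, control_f, design.n_controls)
    subject_ids = tuple(
        [f"{split}_r{replicate}_case{i}" for i in range(design.n_cases)]
        + [f"{split}_r{replicate}_ctrl{i}" for i in range(design.n_controls)]
    )
    alleles = tuple(SIM_ALLELES for _ in truth.snp_ids)
    matrix = GenotypeMatrix(subject_ids, truth.snp_ids, alleles, codes)
    labels = np.concatenate(
        [np.ones(design.n_cases, dtype=np.int8), np.zeros(design.n_controls, dtype=np.int8)]
    )
    return matrix, PhenotypeVector(subject_ids, labels), truth


def simulate_count_arrays(
    design: SimulationDesign, split: str = DISCOVERY, replicate: int = 0
) -> tuple[TruthTable, np.ndarray, np.ndarray]:
    """Count-mode simulation: per-SNP multinomial genotype counts per group.

    Returns ``(truth, n_t, n_not_t)`` with count arrays of shape
    (n_snps, 3).  Distributionally identical to tabulating
    :func:`simulate_dataset` output, without materializing the matrix.
    """
    split_code = _SPLIT_CODE[split]
    truth = truth_table(design, replicate)
    case_f, control_f = _freq_triples(design, truth)
    rng = _rng(design, replicate, split_code, _KEY_COUNTS)
    n_t = rng.multinomial(design.n_cases, case_f)
    n_not = rng.multinomial(design.n_controls, control_f)
    return truth, n_t.astype(np.int64), n_not.astype(np.int64)


def simulate_counts(
    design: SimulationDesign, split: str = DISCOVERY, replicate: int = 0
) -> tuple[list[GenotypeCountTable], TruthTable]:
    """Count-mode simulation returning one :class:`GenotypeCountTable` per SNP."""
    truth, n_t, n_not = simulate_count_arrays(design, split, replicate)
    tables = [
        GenotypeCountTable(snp_id=snp, counts=np.stack([n_t[j], n_not[j]]))
        for j, snp in enumerate(truth.snp_ids)
    ]
    return tables, truth


def replication_codes_for_snps(
    design: SimulationDesign, replicate: int, truth: TruthTable, snp_indices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level replication genotypes restricted to selected SNPs.

    Used by genome-scale experiments: ranking runs on count-mode discovery
    data, then only the selected SNP columns are materialized for scoring.
    Returns ``(codes, labels)`` with cases first.
    """
    idx = np.asarray(list(snp_indices), dtype=int)
    case_f, control_f = _freq_triples(design, truth)
    rng = _rng(design, replicate, _SPLIT_CODE[REPLICATION], _KEY_MATRIX)
    codes = np.empty((design.n_cases + design.n_controls, len(idx)), dtype=np.int8)
    codes[: design.n_cases] = draw_genotype_codes(rng, case_f[idx], design.n_cases)
    codes[design.n_cases:] = draw_genotype_codes(rng, control_f[idx], design.n_controls)
    labels = np.concatenate(
        [np.ones(design.n_cases, dtype=np.int8), np.zeros(design.n_controls, dtype=np.int8)]
    )
    return codes, labels


def scaled_design(design: SimulationDesign, **overrides) -> SimulationDesign:
    """Convenience copy-with-overrides for scaled-down runs."""
    return replace(design, **overrides)
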