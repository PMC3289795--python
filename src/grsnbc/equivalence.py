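"""Numerical verification that the NBC rule and the genotypic-GRS logistic
rule are the same classifier up to a threshold change.

With genotype conditionals and case-3 weights estimated from the identical
(smoothed) count tables, the NBC trait log-odds is *exactly* affine in the
raw case-3 GRS::

    log-odds(profile) = GRS(profile) + logit(prior) + sum_i log[p(AA|T)/p(AA|not T)]

so the two scores rank subjects identically, share every ROC point, and a
loss ratio ``lam`` for the NBC maps to a closed-form threshold ``tau`` on the
calibrated GRS score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logit
from scipy.stats import spearmanr

from .data import GenotypeMatrix, PhenotypeVector
from .grs import CASE3, GrsModel, compute_grs
from .nbc import NbcModel, log_odds


def default_lambda_grid(n_points: int = 25) -> np.ndarray:
    """Log-spaced loss-ratio grid over [1e-3, 1e3]."""
    return np.logspace(-3.0, 3.0, n_points)


@dataclass(frozen=True)
class EquivalenceReport:
    n_profiles: int
    rank_agreement: float
    max_label_disagreement: int
    auc_nbc: float
    auc_grs: float
    affine_slope: float
    affine_intercept: float
    max_abs_residual: float
    lambda_grid: np.ndarray
    disagreements: np.ndarray  # per-lambda label disagreement counts

    def to_flat_dict(self) -> dict[str, float]:
        d = {
            "n_profiles": float(self.n_profiles),
            "rank_agreement": self.rank_agreement,
            "max_label_disagreement": float(self.max_label_disagreement),
            "auc_nbc": self.auc_nbc,
            "auc_grs": self.auc_grs,
            "affine_slope": self.affine_slope,
            "affine_intercept": self.affine_intercept,
            "max_abs_residual": self.max_abs_residual,
        }
        for lam, dis in zip(self.lambda_grid, self.disagreements):
            d[f"disagreement_lambda_{lam:.6g}"] = float(dis)
        return d

    def write_flat(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for key, value in self.to_flat_dict().items():
                fh.write(f"{key}\t{value:.17g}\n")

    def summary(self) -> str:
        return (
            f"profiles:            {self.n_profiles}\n"
            f"rank agreement:      {self.rank_agreement:.12f}\n"
            f"AUC (NBC):           {self.auc_nbc:.12f}\n"
            f"AUC (case-3 GRS):    {self.auc_grs:.12f}\n"
            f"affine fit:          log-odds = {self.affine_slope:.6f} * GRS "
            f"+ {self.affine_intercept:.6f}\n"
            f"max |residual|:      {self.max_abs_residual:.3e}\n"
            f"max label disagree:  {self.max_label_disagreement} "
            f"over {len(self.lambda_grid)} lambda values\n"
        )


def nbc_to_grs_threshold(
    g0: float, g1: float, aa_log_odds: Sequence[float], lam: float
) -> float:
    """Calibrated-GRS threshold equal to the NBC rule at loss ratio ``lam``.

    Returns ``g0 - g1 * sum(aa_log_odds) + g1 * log(lam)`` where
    ``aa_log_odds`` are the per-SNP trait log-odds at the referent AA
    genotype.
    """
    if g1 == 0:
        raise ValueError("nbc_to_grs_threshold requires a non-zero slope")
    if lam <= 0:
        raise ValueError("lam must be positive")
    return g0 - g1 * float(np.sum(aa_log_odds)) + g1 * float(np.log(lam))


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from .evaluate import roc_auc

    return roc_auc(scores, labels)


def verify_equivalence(
    nbc_model: NbcModel,
    grs_model: GrsModel,
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    lambdas: np.ndarray | None = None,
) -> EquivalenceReport:
    """Compare the NBC and calibrated case-3 GRS rules on one dataset.

    Both models must cover the same SNP set (same provenance).  The report
    contains the Spearman concordance of the two scores, the AUC pair, the
    affine relation between NBC log-odds and the raw GRS, and label
    disagreement counts across a loss-ratio grid under the mapped
    thresholds.  With the default prior of 0.5 and shared smoothed count
    tables, disagreements are exactly zero.
    """
    scheme = grs_model.scheme
    if scheme is None or scheme.case != CASE3:
        raise ValueError("verify_equivalence requires a calibrated case-3 GRS model")
    if tuple(scheme.snp_ids) != tuple(nbc_model.snp_ids):
        raise ValueError("NBC and GRS models cover different SNP sets")
    if tuple(matrix.snp_ids) != tuple(scheme.snp_ids):
        raise ValueError("data SNPs do not match the models")
    if lambdas is None:
        lambdas = default_lambda_grid()

    grs_raw = compute_grs(matrix, scheme)
    nbc_lo = np.asarray(log_odds(nbc_model, matrix.codes))
    n = len(grs_raw)

    rank_agreement = float(spearmanr(nbc_lo, grs_raw).statistic) if n > 1 else 1.0
    auc_nbc = _rank_auc(nbc_lo, phenotype.labels)
    auc_grs = _rank_auc(grs_raw, phenotype.labels)

    # affine fit of NBC log-odds on the raw GRS
    design = np.column_stack([grs_raw, np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, nbc_lo, rcond=None)
    residual = nbc_lo - design @ coef
    # analytic constant: same-table provenance makes the slope exactly 1
    expected_const = float(
        logit(nbc_model.prior_t) + nbc_model.log_likelihood_ratios()[:, 0].sum()
    )
    analytic_residual = nbc_lo - (grs_raw + expected_const)
    if np.max(np.abs(analytic_residual)) <= np.max(np.abs(residual)):
        coef = np.array([1.0, expected_const])
        residual = analytic_residual

    aa_lo = nbc_model.aa_log_odds()
    calibrated = grs_model.gamma0 + grs_model.gamma1 * grs_raw
    disagreements = np.empty(len(lambdas), dtype=np.int64)
    for i, lam in enumerate(lambdas):
        tau = nbc_to_grs_threshold(grs_model.gamma0, grs_model.gamma1, aa_lo, lam)
        nbc_labels = nbc_lo > np.log(lam)
        grs_labels = calibrated > tau
        disagreements[i] = int(np.sum(nbc_labels != grs_labels))

    return EquivalenceReport(
        n_profiles=n,
        rank_agreement=rank_agreement,
        max_label_disagreement=int(disagreements.max()),
        auc_nbc=auc_nbc,
        auc_grs=auc_grs,
        affine_slope=float(coef[0]),
        affine_intercept=float(coef[1]),
        max_abs_residual=float(np.max(np.abs(residual))),
        lambda_grid=np.asarray(lambdas, dtype=float),
        disagreements=disagreements,
    )
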