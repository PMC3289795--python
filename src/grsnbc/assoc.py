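"""Per-SNP association estimation and ranking.

Two single-SNP logistic models are supported: the *genotypic* model with
free AB-vs-AA and BB-vs-AA log-odds ratios (closed form from the 2x3 count
table), and the *additive* model with a single per-B-allele slope (fitted
by Newton iteration on the grouped counts).  A ranking operation orders
SNPs by strength of genotypic association for nested-model construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._logistic import FittingError, fit_logistic
from .data import GenotypeCountTable, tables_to_arrays

logger = logging.getLogger(__name__)

ADDITIVE = "additive"
GENOTYPIC = "genotypic"

BIC_BAYES_FACTOR = "bic_bayes_factor"
GENOTYPIC_CHI2 = "genotypic_chi2"

#: default pseudo-count added to every cell of a table that has a zero cell
DEFAULT_SMOOTHING = 0.5


class DegenerateSnpError(ValueError):
    """Count table cannot support the requested fit."""


class SeparationWarning(UserWarning):
    """Perfect separation: maximum-likelihood estimate is infinite."""


@dataclass(frozen=True)
class SnpEffect:
    """Estimated single-SNP logistic effect.

    For the additive model ``v`` is the per-B-allele slope and ``z`` is
    ``None``; for the genotypic model ``v`` and ``z`` are the AB-vs-AA and
    BB-vs-AA log-odds ratios.
    """

    snp_id: str
    model: str
    intercept: float
    v: float
    z: float | None = None
    se_intercept: float = float("nan")
    se_v: float = float("nan")
    se_z: float | None = None
    separated: bool = False


@dataclass(frozen=True)
class RankStatistic:
    snp_id: str
    evidence: float
    rank: int


def smooth_counts(counts: np.ndarray, smoothing: float = DEFAULT_SMOOTHING) -> np.ndarray:
    """Haldane-Anscombe-style smoothing of a 2x3 count table.

    The pseudo-count is added to *every* cell, but only when some cell is
    zero; clean tables pass through unchanged.  The same rule feeds both the
    genotypic GRS weights and the NBC conditionals, which keeps their
    classification rules exactly equivalent after smoothing.
    """
    counts = np.asarray(counts, dtype=float)
    if smoothing > 0 and (counts == 0).any():
        return counts + smoothing
    return counts


def fit_genotypic(table: GenotypeCountTable, smoothing: float = DEFAULT_SMOOTHING) -> SnpEffect:
    """Closed-form genotypic log-odds ratios from the 2x3 table.

    ``v = log[(n_T,AB / n_notT,AB) / (n_T,AA / n_notT,AA)]`` and analogously
    ``z`` for BB; the intercept is the trait log-odds in the AA stratum.
    These cross-product ratios are the exact MLE of the two-indicator
    logistic regression on the same table.
    """
    raw = np.asarray(table.counts, dtype=float)
    if raw[0].sum() == 0 or raw[1].sum() == 0:
        raise DegenerateSnpError(f"{table.snp_id}: a phenotype group has no observations")
    c = smooth_counts(raw, smoothing)
    if (c == 0).any():
        raise DegenerateSnpError(
            f"{table.snp_id}: zero cells remain with smoothing={smoothing}; "
            "use a positive pseudo-count"
        )
    with np.errstate(divide="ignore"):
        odds = np.log(c[0]) - np.log(c[1])  # per-genotype trait log-odds
    intercept = odds[0]
    v = odds[1] - odds[0]
    z = odds[2] - odds[0]
    inv = 1.0 / c
    se_int = float(np.sqrt(inv[0, 0] + inv[1, 0]))
    se_v = float(np.sqrt(inv[:, [0, 1]].sum()))
    se_z = float(np.sqrt(inv[:, [0, 2]].sum()))
    return SnpEffect(
        snp_id=table.snp_id,
        model=GENOTYPIC,
        intercept=float(intercept),
        v=float(v),
        z=float(z),
        se_intercept=se_int,
        se_v=se_v,
        se_z=se_z,
    )


def _additive_separated(n_t: np.ndarray, n_not: np.ndarray) -> bool:
    # with a monotone 1-D covariate, perfect separation means the observed
    # dosage ranges of the two groups do not overlap
    levels = np.arange(3)
    lt = levels[n_t > 0]
    ln = levels[n_not > 0]
    return lt.max() < ln.min() or lt.min() > ln.max()


def fit_additive(table: GenotypeCountTable, tol: float = 1e-10, max_iter: int = 100) -> SnpEffect:
    """MLE of the one-covariate logistic model with dosage 0/1/2 for AA/AB/BB.

    Fitted on grouped counts (three covariate levels), which has the same
    likelihood as the subject-level fit.  Perfect separation yields a
    warning and an infinite-slope sentinel instead of an exception.
    """
    n_t = np.asarray(table.counts[0], dtype=float)
    n_not = np.asarray(table.counts[1], dtype=float)
    total = n_t + n_not
    observed = total > 0
    if observed.sum() < 2:
        raise DegenerateSnpError(
            f"{table.snp_id}: additive fit needs at least two observed genotype categories"
        )
    if n_t.sum() == 0 or n_not.sum() == 0:
        raise DegenerateSnpError(f"{table.snp_id}: a phenotype group has no observations")
    if _additive_separated(n_t, n_not):
        warnings.warn(
            f"{table.snp_id}: perfect separation in additive fit", SeparationWarning, stacklevel=2
        )
        sign = 1.0 if n_t @ np.arange(3) / n_t.sum() > n_not @ np.arange(3) / n_not.sum() else -1.0
        return SnpEffect(
            snp_id=table.snp_id, model=ADDITIVE, intercept=float("nan"),
            v=sign * float("inf"), separated=True,
        )
    x = np.arange(3, dtype=float)[observed]
    X = np.column_stack([np.ones_like(x), x])
    y = n_t[observed] / total[observed]
    try:
        beta, se, _ = fit_logistic(X, y, weights=total[observed], tol=tol, max_iter=max_iter)
    except FittingError as exc:
        raise FittingError(f"{table.snp_id}: {exc}") from exc
    return SnpEffect(
        snp_id=table.snp_id,
        model=ADDITIVE,
        intercept=float(beta[0]),
        v=float(beta[1]),
        se_intercept=float(se[0]),
        se_v=float(se[1]),
    )


def risk_allele(effect: SnpEffect) -> str:
    """Risk allele from an additive fit: ``A`` when the slope is negative, else ``B``."""
    if effect.model != ADDITIVE:
        raise ValueError("risk_allele requires an additive-model effect")
    return "A" if effect.v < 0 else "B"


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _xlogy(n: np.ndarray, p: np.ndarray) -> np.ndarray:
    from scipy.special import xlogy

    return xlogy(n, p)


def genotypic_evidence(
    n_t: np.ndarray, n_not: np.ndarray, method: str = BIC_BAYES_FACTOR
) -> np.ndarray:
    """Vectorized genotypic-association evidence for stacked count arrays.

    ``BIC_BAYES_FACTOR`` returns the log Bayes factor of the genotypic
    logistic model against the intercept-only model, approximated from the
    BIC difference with equal prior odds; this is a strictly increasing
    function of the approximate posterior probability of association and
    does not saturate in double precision the way the probability does.
    ``GENOTYPIC_CHI2`` returns the 2-df Pearson chi-square statistic.
    Degenerate tables (an empty phenotype row) get ``-inf``.
    """
    n_t = np.asarray(n_t, dtype=float)
    n_not = np.asarray(n_not, dtype=float)
    col = n_t + n_not
    row_t = n_t.sum(axis=1)
    row_not = n_not.sum(axis=1)
    n = row_t + row_not
    degenerate = (row_t == 0) | (row_not == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == BIC_BAYES_FACTOR:
            p_sat = np.where(col > 0, n_t / np.where(col > 0, col, 1.0), 0.0)
            ll_sat = (_xlogy(n_t, p_sat) + _xlogy(n_not, 1.0 - p_sat)).sum(axis=1)
            p0 = row_t / n
            ll_null = _xlogy(row_t, p0) + _xlogy(row_not, 1.0 - p0)
            # log BF = (BIC_null - BIC_geno) / 2 with 1 vs 3 parameters
            evidence = (ll_sat - ll_null) - np.log(n)
        elif method == GENOTYPIC_CHI2:
            e_t = np.where(n[:, None] > 0, np.outer(row_t, np.ones(3)) * col / n[:, None], 0.0)
            e_not = col - e_t
            terms = np.where(e_t > 0, (n_t - e_t) ** 2 / np.where(e_t > 0, e_t, 1.0), 0.0)
            terms += np.where(e_not > 0, (n_not - e_not) ** 2 / np.where(e_not > 0, e_not, 1.0), 0.0)
            evidence = terms.sum(axis=1)
        else:
            raise ValueError(f"unknown ranking method {method!r}")
    evidence = np.where(degenerate, -np.inf, evidence)
    if degenerate.any():
        logger.info("genotypic_evidence: %d degenerate tables set to -inf", int(degenerate.sum()))
    return evidence


def rank_order(snp_ids: Sequence[str], evidence: np.ndarray) -> np.ndarray:
    """Indices sorting by descending evidence, ties broken by snp_id."""
    ids = np.asarray(snp_ids, dtype=object)
    return np.lexsort((ids, -np.asarray(evidence, dtype=float)))


def rank_snps(
    tables: Iterable[GenotypeCountTable], method: str = BIC_BAYES_FACTOR
) -> list[RankStatistic]:
    """Order SNPs by genotypic-association evidence (descending).

    Ties are broken by snp_id lexicographic order, so the output is
    invariant to input order.
    """
    snp_ids, n_t, n_not = tables_to_arrays(tables)
    if not snp_ids:
        raise ValueError("rank_snps requires at least one table")
    evidence = genotypic_evidence(n_t, n_not, method=method)
    order = rank_order(snp_ids, evidence)
    stats = [None] * len(snp_ids)
    for rank, idx in enumerate(order, start=1):
        stats[rank - 1] = RankStatistic(snp_id=snp_ids[idx], evidence=float(evidence[idx]), rank=rank)
    return stats


def write_effects_tsv(
    effects: Iterable[SnpEffect],
    path: str | Path,
    ranks: Iterable[RankStatistic] | None = None,
) -> None:
    """Export per-SNP effects (and optional ranking) as TSV."""
    rank_by_id = {r.snp_id: r for r in ranks} if ranks is not None else {}
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("snp_id\tmodel\tintercept\tv\tz\tse_v\tse_z\tevidence\trank\n")
        for e in effects:
            r = rank_by_id.get(e.snp_id)
            fh.write(
                "\t".join(
                    [
                        e.snp_id,
                        e.model,
                        f"{e.intercept:.10g}",
                        f"{e.v:.10g}",
                        "NA" if e.z is None else f"{e.z:.10g}",
                        f"{e.se_v:.10g}",
                        "NA" if e.se_z is None else f"{e.se_z:.10g}",
                        "NA" if r is None else f"{r.evidence:.10g}",
                        "NA" if r is None else str(r.rank),
                    ]
                )
                + "\n"
            )
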