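"""Naive Bayes classification of a binary trait from genotype profiles.

The score is the posterior probability of the trait given a subject's
genotypes, computed under conditional independence of SNPs given the trait.
All products are accumulated in log space; per-SNP genotype conditionals
come from the (optionally smoothed) case/control count tables, so the model
shares its sufficient statistic with the genotypic GRS weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.special import expit, logit

from .assoc import DEFAULT_SMOOTHING, smooth_counts
from .data import MISSING, GenotypeCountTable

DEFAULT_PRIOR = 0.5


@dataclass(frozen=True)
class NbcModel:
    """Prior plus per-SNP genotype conditionals p(S|T) and p(S|not T)."""

    snp_ids: tuple[str, ...]
    prior_t: float
    cond_t: np.ndarray = field(repr=False)       # (n_snps, 3)
    cond_not_t: np.ndarray = field(repr=False)   # (n_snps, 3)
    smoothing: float = DEFAULT_SMOOTHING

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        ct = np.asarray(self.cond_t, dtype=float)
        cn = np.asarray(self.cond_not_t, dtype=float)
        object.__setattr__(self, "cond_t", ct)
        object.__setattr__(self, "cond_not_t", cn)
        if not 0.0 < self.prior_t < 1.0:
            raise ValueError("prior_t must be in (0, 1)")
        k = len(self.snp_ids)
        if ct.shape != (k, 3) or cn.shape != (k, 3):
            raise ValueError("conditional arrays must have shape (n_snps, 3)")
        for name, arr in (("cond_t", ct), ("cond_not_t", cn)):
            if (arr <= 0).any():
                raise ValueError(f"{name} must be strictly positive (apply smoothing)")
            if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-12:
                raise ValueError(f"{name} rows must sum to 1 within 1e-12")

    def log_likelihood_ratios(self) -> np.ndarray:
        """(n_snps, 3) matrix of log[p(g|T) / p(g|not T)] per genotype."""
        return np.log(self.cond_t) - np.log(self.cond_not_t)

    def aa_log_odds(self) -> np.ndarray:
        """Per-SNP trait log-odds at the referent AA genotype,
        logit(prior) + log-likelihood-ratio(AA)."""
        return logit(self.prior_t) + self.log_likelihood_ratios()[:, 0]


def fit_nbc(
    tables: Iterable[GenotypeCountTable],
    prior_t: float = DEFAULT_PRIOR,
    smoothing: float = DEFAULT_SMOOTHING,
) -> NbcModel:
    """Estimate genotype conditionals as (smoothed) within-group relative
    frequencies.  Uses the same smoothing rule as the genotypic GRS weights."""
    tables = list(tables)
    if not tables:
        raise ValueError("fit_nbc requires at least one table")
    snp_ids = []
    cond_t = np.empty((len(tables), 3))
    cond_not = np.empty((len(tables), 3))
    for j, t in enumerate(tables):
        raw = np.asarray(t.counts, dtype=float)
        if raw[0].sum() == 0 or raw[1].sum() == 0:
            raise ValueError(f"{t.snp_id}: a phenotype group has no observations")
        c = smooth_counts(raw, smoothing)
        if (c == 0).any():
            raise ValueError(
                f"{t.snp_id}: zero cells remain with smoothing={smoothing}"
            )
        snp_ids.append(t.snp_id)
        cond_t[j] = c[0] / c[0].sum()
        cond_not[j] = c[1] / c[1].sum()
    return NbcModel(
        snp_ids=tuple(snp_ids), prior_t=prior_t,
        cond_t=cond_t, cond_not_t=cond_not, smoothing=smoothing,
    )


def _profile_codes(model: NbcModel, profile: np.ndarray) -> np.ndarray:
    codes = np.asarray(profile, dtype=np.int8)
    if codes.shape[-1] != len(model.snp_ids):
        raise ValueError(
            f"profile covers {codes.shape[-1]} SNPs, model has {len(model.snp_ids)}"
        )
    return codes


def log_odds(model: NbcModel, profile: np.ndarray) -> float | np.ndarray:
    """Trait log-odds logit p(T|profile): prior log-odds plus the sum of
    per-SNP genotype log-likelihood ratios.

    ``profile`` is a 1-D array of genotype codes (0/1/2, -1 missing) or a
    2-D subjects x SNPs matrix of them; missing SNPs contribute nothing.
    """
    codes = np.atleast_2d(_profile_codes(model, profile))
    llr = model.log_likelihood_ratios()  # (k, 3)
    per_snp = np.where(
        codes == MISSING, 0.0, np.take_along_axis(llr.T, np.maximum(codes, 0), axis=0)
    )
    total = per_snp.sum(axis=-1) + logit(model.prior_t)
    return float(total[0]) if np.ndim(profile) == 1 else total


def posterior(model: NbcModel, profile: np.ndarray) -> float | np.ndarray:
    """Posterior probability of the trait given the profile.

    Equals ``p(T) prod p(Si|T) / [p(T) prod p(Si|T) + (1-p(T)) prod p(Si|not T)]``,
    evaluated in log space as the inverse-logit of :func:`log_odds`.
    """
    return expit(log_odds(model, profile))


def classify(score: float | np.ndarray, lam: float) -> bool | np.ndarray:
    """Loss-ratio classification: trait iff posterior ``score > lam / (1 + lam)``.

    Equivalent to trait log-odds > log(lam).  ``lam = 1`` is the
    most-probable-outcome rule (threshold 0.5); the boundary is exclusive.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    result = np.asarray(score) > lam / (1.0 + lam)
    return bool(result) if np.ndim(score) == 0 else result


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_nbc_tsv(model: NbcModel, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"#prior_t\t{model.prior_t:.12g}\n#smoothing\t{model.smoothing:.12g}\n")
        fh.write("snp_id\tpAA_T\tpAB_T\tpBB_T\tpAA_notT\tpAB_notT\tpBB_notT\n")
        for j, snp in enumerate(model.snp_ids):
            row = [f"{x:.17g}" for x in (*model.cond_t[j], *model.cond_not_t[j])]
            fh.write("\t".join([snp, *row]) + "\n")


def read_nbc_tsv(path: str | Path) -> NbcModel:
    prior = DEFAULT_PRIOR
    smoothing = DEFAULT_SMOOTHING
    snp_ids: list[str] = []
    cond_t: list[list[float]] = []
    cond_not: list[list[float]] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                if key == "prior_t":
                    prior = float(value)
                elif key == "smoothing":
                    smoothing = float(value)
                continue
            if line.startswith("snp_id\t"):
                continue
            parts = line.split("\t")
            snp_ids.append(parts[0])
            values = [float(x) for x in parts[1:7]]
            cond_t.append(values[:3])
            cond_not.append(values[3:])
    ct = np.array(cond_t)
    cn = np.array(cond_not)
    # renormalize away decimal round-off from serialization
    ct /= ct.sum(axis=1, keepdims=True)
    cn /= cn.sum(axis=1, keepdims=True)
    return NbcModel(snp_ids=tuple(snp_ids), prior_t=prior,
                    cond_t=ct, cond_not_t=cn, smoothing=smoothing)
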