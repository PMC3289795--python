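"""Genetic risk scores: weighting schemes, score computation, calibration,
and the threshold-shift algebra that makes intercept and slope irrelevant
to classification.

Three weighting schemes are supported:

* ``case1`` — risk-allele counting: genotype weights (0, 1, 2) oriented by
  the risk allele of a per-SNP additive fit.
* ``case2`` — additive log-odds-ratio weights ``(0, v, 2v)``.
* ``case3`` — genotypic log-odds-ratio weights ``(0, v, z)``.

A score is calibrated into a log-odds classification score by a univariate
logistic regression ``gamma0 + gamma1 * GRS``; the two ``shift_threshold_*``
operations map thresholds between differently calibrated scores so the
resulting rules label every profile identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._logistic import fit_logistic
from .assoc import ADDITIVE, GENOTYPIC, SeparationWarning, SnpEffect, risk_allele
from .data import MISSING, GenotypeMatrix, PhenotypeVector

CASE1 = "case1"
CASE2 = "case2"
CASE3 = "case3"
CASES = (CASE1, CASE2, CASE3)


@dataclass(frozen=True)
class WeightScheme:
    """Per-SNP genotype weights (w, v, z) for the AA/AB/BB states.

    ``weights`` has shape (n_snps, 3); ``risk_alleles`` is populated for
    ``case1`` only.
    """

    case: str
    snp_ids: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    risk_alleles: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.case not in CASES:
            raise ValueError(f"unknown GRS case {self.case!r}")
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (len(self.snp_ids), 3):
            raise ValueError("weights must have shape (n_snps, 3)")
        if self.risk_alleles is not None:
            object.__setattr__(self, "risk_alleles", tuple(self.risk_alleles))


@dataclass(frozen=True)
class GrsModel:
    """Calibrated logistic score ``gamma0 + gamma1 * GRS``."""

    gamma0: float
    gamma1: float
    scheme: WeightScheme | None = None
    se_gamma0: float = float("nan")
    se_gamma1: float = float("nan")
    separated: bool = False


@dataclass(frozen=True)
class ClassificationRule:
    """A 'score > threshold => trait' rule.

    ``kind`` records whether ``threshold`` is a log-odds cut (``tau``) or a
    loss ratio (``lambda``); the two interconvert exactly via
    ``tau = log(lambda)`` on the log-odds scale of the same score.
    """

    score_id: str
    threshold: float
    kind: str = "tau"  # "tau" | "lambda"

    def __post_init__(self) -> None:
        if self.kind not in ("tau", "lambda"):
            raise ValueError("kind must be 'tau' or 'lambda'")
        if self.kind == "lambda" and self.threshold <= 0:
            raise ValueError("lambda must be positive")


def build_weights(case: str, effects: Sequence[SnpEffect]) -> WeightScheme:
    """Assemble a weighting scheme from fitted per-SNP effects.

    ``case1``/``case2`` require additive effects; ``case3`` genotypic ones.
    """
    if case not in CASES:
        raise ValueError(f"unknown GRS case {case!r}")
    needed = GENOTYPIC if case == CASE3 else ADDITIVE
    for e in effects:
        if e.model != needed:
            raise ValueError(f"{case} weights need {needed} effects; {e.snp_id} is {e.model}")
    snp_ids = tuple(e.snp_id for e in effects)
    if case == CASE1:
        risk = tuple(risk_allele(e) for e in effects)
        weights = np.array([(0.0, 1.0, 2.0) if r == "B" else (2.0, 1.0, 0.0) for r in risk])
        return WeightScheme(case=case, snp_ids=snp_ids, weights=weights, risk_alleles=risk)
    if case == CASE2:
        weights = np.array([(0.0, e.v, 2.0 * e.v) for e in effects])
    else:
        weights = np.array([(0.0, e.v, e.z) for e in effects])
    return WeightScheme(case=case, snp_ids=snp_ids, weights=weights)


def compute_grs(matrix: GenotypeMatrix, scheme: WeightScheme) -> np.ndarray:
    """Per-subject weighted sum of genotype weights; missing genotypes add 0."""
    position = {s: j for j, s in enumerate(scheme.snp_ids)}
    try:
        cols = np.array([position[s] for s in matrix.snp_ids])
    except KeyError as exc:
        raise ValueError(f"SNP {exc.args[0]!r} in matrix is absent from the weight scheme") from None
    w = scheme.weights[cols]  # aligned to matrix columns
    codes = matrix.codes
    contrib = np.where(
        codes == MISSING, 0.0, np.take_along_axis(w.T, np.maximum(codes, 0), axis=0)
    )
    return contrib.sum(axis=1)


def calibrate(
    grs_scores: np.ndarray, phenotype: PhenotypeVector, scheme: WeightScheme | None = None
) -> GrsModel:
    """Maximum-likelihood (gamma0, gamma1) of the trait on the GRS.

    Perfect separation produces a warning and an infinite-slope sentinel;
    degenerate (constant) scores or a single phenotype class are errors.
    """
    scores = np.asarray(grs_scores, dtype=float)
    y = phenotype.labels.astype(float)
    if len(scores) != len(y):
        raise ValueError("scores and phenotype are not aligned")
    if np.unique(scores).size < 2:
        raise ValueError("calibration requires at least two distinct score values")
    if y.min() == y.max():
        raise ValueError("calibration requires both phenotype classes")
    cases, controls = scores[y == 1], scores[y == 0]
    if cases.min() > controls.max() or cases.max() < controls.min():
        warnings.warn("perfect separation in GRS calibration", SeparationWarning, stacklevel=2)
        sign = 1.0 if cases.mean() > controls.mean() else -1.0
        return GrsModel(gamma0=float("nan"), gamma1=sign * float("inf"),
                        scheme=scheme, separated=True)
    X = np.column_stack([np.ones_like(scores), scores])
    beta, se, _ = fit_logistic(X, y)
    if beta[1] <= 0:
        warnings.warn("calibrated GRS slope is not positive", UserWarning, stacklevel=2)
    return GrsModel(
        gamma0=float(beta[0]), gamma1=float(beta[1]), scheme=scheme,
        se_gamma0=float(se[0]), se_gamma1=float(se[1]),
    )


def shift_threshold_intercept(tau: float, alpha0: float, beta0: float) -> float:
    """Threshold for a score whose intercept is ``beta0`` instead of ``alpha0``.

    Classifying with the second score above the returned threshold labels
    every profile exactly as the first score does above ``tau``.
    """
    return tau + beta0 - alpha0


def shift_threshold_slope(tau: float, g0: float, g1: float, b0: float, b1: float) -> float:
    """Threshold for a recalibrated score ``b0 + b1*GRS`` matching
    ``g0 + g1*GRS > tau``.

    Requires ``g1 != 0``; if the slopes disagree in sign the rule
    orientation flips and a warning is emitted (the returned value is still
    the algebraic map).
    """
    if g1 == 0:
        raise ValueError("shift_threshold_slope requires a non-zero reference slope")
    if b1 * g1 < 0:
        warnings.warn(
            "slopes disagree in sign: the mapped rule's orientation is flipped",
            UserWarning,
            stacklevel=2,
        )
    return b0 + b1 * (tau - g0) / g1


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_weights_tsv(scheme: WeightScheme, path: str | Path, model: GrsModel | None = None) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"#case\t{scheme.case}\n")
        if model is not None:
            fh.write(f"#gamma0\t{model.gamma0:.12g}\n#gamma1\t{model.gamma1:.12g}\n")
        fh.write("snp_id\tcase\tw\tv\tz\trisk_allele\n")
        for j, snp in enumerate(scheme.snp_ids):
            w, v, z = scheme.weights[j]
            risk = scheme.risk_alleles[j] if scheme.risk_alleles else "NA"
            fh.write(f"{snp}\t{scheme.case}\t{w:.12g}\t{v:.12g}\t{z:.12g}\t{risk}\n")


def read_weights_tsv(path: str | Path) -> tuple[WeightScheme, GrsModel | None]:
    case = None
    gamma0 = gamma1 = None
    snp_ids: list[str] = []
    weights: list[tuple[float, float, float]] = []
    risk: list[str] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                if key == "case":
                    case = value
                elif key == "gamma0":
                    gamma0 = float(value)
                elif key == "gamma1":
                    gamma1 = float(value)
                continue
            if line.startswith("snp_id\t"):
                continue
            snp, _case, w, v, z, r = line.split("\t")
            snp_ids.append(snp)
            weights.append((float(w), float(v), float(z)))
            risk.append(r)
    if case is None:
        raise ValueError(f"{path}: missing '#case' header")
    risk_alleles = tuple(risk) if case == CASE1 else None
    scheme = WeightScheme(case=case, snp_ids=tuple(snp_ids),
                          weights=np.array(weights), risk_alleles=risk_alleles)
    model = None
    if gamma0 is not None and gamma1 is not None:
        model = GrsModel(gamma0=gamma0, gamma1=gamma1, scheme=scheme)
    return scheme, model
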