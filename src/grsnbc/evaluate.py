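"""ROC/AUC evaluation and nested-model experiments.

The central experiment: simulate paired discovery/replication case-control
sets, rank SNPs on the discovery data by genotypic-association evidence,
build nested classifiers (NBC and the three GRS variants) on the top-k
SNPs for increasing k, score the replication subjects, and average the
replication AUC over replicates.  All methods see the identical ranking,
and each method's score needs no calibration for AUC (AUC is invariant to
strictly increasing transforms), so fitting runs entirely on the
discovery count tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from . import simulate as sim
from .assoc import (
    BIC_BAYES_FACTOR,
    DEFAULT_SMOOTHING,
    RankStatistic,
    genotypic_evidence,
    rank_order,
)
from ._logistic import fit_logistic
from .data import GenotypeMatrix, MISSING, PhenotypeVector, count_arrays

logger = logging.getLogger(__name__)

NBC = "nbc"
GRS_CASE1 = "case1"
GRS_CASE2 = "case2"
GRS_CASE3 = "case3"
ALL_METHODS = (NBC, GRS_CASE1, GRS_CASE2, GRS_CASE3)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    Equals the trapezoidal area under the empirical ROC curve and the
    probability that a random case outscores a random control (ties
    counting one half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = rankdata(scores)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _auc_columns(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """AUC of every column of an (n_subjects, m) score matrix."""
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores, axis=0)
    r1 = ranks[labels == 1].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


@dataclass(frozen=True)
class NestedCurve:
    """Mean replication AUC versus number of top-ranked SNPs for one method."""

    method: str
    k_values: np.ndarray = field(repr=False)
    auc_mean: np.ndarray = field(repr=False)
    auc_replicates: np.ndarray = field(repr=False)  # (n_replicates, len(k_values))

    def __post_init__(self) -> None:
        kv = np.asarray(self.k_values, dtype=int)
        object.__setattr__(self, "k_values", kv)
        object.__setattr__(self, "auc_mean", np.asarray(self.auc_mean, dtype=float))
        object.__setattr__(self, "auc_replicates", np.asarray(self.auc_replicates, dtype=float))
        if not (np.diff(kv) > 0).all():
            raise ValueError("k_values must be strictly increasing")


def peak_k(curve: NestedCurve) -> int:
    """k maximizing the mean AUC; ties resolve to the smallest k."""
    return int(curve.k_values[int(np.argmax(curve.auc_mean))])


def default_k_values(n_causal: int, extra: int = 30, step_beyond: int = 5) -> np.ndarray:
    """Unit steps through the causal range, then coarser steps beyond it."""
    ks = list(range(1, n_causal + 1))
    ks += list(range(n_causal + step_beyond, n_causal + extra + 1, step_beyond))
    return np.array(ks, dtype=int)


# ---------------------------------------------------------------------------
# per-method weight construction from stacked count arrays
# ---------------------------------------------------------------------------

def _smoothed_pair(
    n_t: np.ndarray, n_not: np.ndarray, smoothing: float
) -> tuple[np.ndarray, np.ndarray]:
    n_t = np.asarray(n_t, dtype=float)
    n_not = np.asarray(n_not, dtype=float)
    if smoothing > 0:
        has_zero = ((n_t == 0) | (n_not == 0)).any(axis=1, keepdims=True)
        bump = smoothing * has_zero
        return n_t + bump, n_not + bump
    return n_t, n_not


def _additive_slopes(s_t: np.ndarray, s_not: np.ndarray) -> np.ndarray:
    """Per-SNP additive logistic slopes from smoothed count arrays."""
    x = np.arange(3, dtype=float)
    slopes = np.empty(len(s_t))
    for j in range(len(s_t)):
        total = s_t[j] + s_not[j]
        observed = total > 0
        X = np.column_stack([np.ones(observed.sum()), x[observed]])
        beta, _, _ = fit_logistic(X, s_t[j][observed] / total[observed], weights=total[observed])
        slopes[j] = beta[1]
    return slopes


def method_weight_rows(
    n_t: np.ndarray,
    n_not: np.ndarray,
    methods: Sequence[str],
    smoothing: float = DEFAULT_SMOOTHING,
) -> dict[str, np.ndarray]:
    """(n_snps, 3) genotype-weight rows per method from count arrays.

    The NBC rows are per-genotype log-likelihood ratios (affine-equivalent
    to the case-3 rows per SNP); case 1/2 need a per-SNP additive fit.
    """
    s_t, s_not = _smoothed_pair(n_t, n_not, smoothing)
    out: dict[str, np.ndarray] = {}
    if NBC in methods or GRS_CASE3 in methods:
        log_odds = np.log(s_t) - np.log(s_not)
        if GRS_CASE3 in methods:
            w3 = log_odds - log_odds[:, [0]]
            out[GRS_CASE3] = w3
        if NBC in methods:
            out[NBC] = (
                np.log(s_t / s_t.sum(axis=1, keepdims=True))
                - np.log(s_not / s_not.sum(axis=1, keepdims=True))
            )
    if GRS_CASE1 in methods or GRS_CASE2 in methods:
        slopes = _additive_slopes(s_t, s_not)
        if GRS_CASE2 in methods:
            out[GRS_CASE2] = np.column_stack(
                [np.zeros_like(slopes), slopes, 2.0 * slopes]
            )
        if GRS_CASE1 in methods:
            risk_b = slopes >= 0
            out[GRS_CASE1] = np.where(
                risk_b[:, None], np.array([0.0, 1.0, 2.0]), np.array([2.0, 1.0, 0.0])
            )
    return out


def _nested_aucs(
    weight_rows: Mapping[str, np.ndarray],
    rep_codes: np.ndarray,
    rep_labels: np.ndarray,
    k_values: np.ndarray,
) -> dict[str, np.ndarray]:
    """Replication AUC at every k for every method.

    ``rep_codes`` columns must already be in rank order; prefix sums over
    columns give every nested model's scores in one pass.
    """
    safe = np.maximum(rep_codes, 0)
    missing = rep_codes == MISSING
    aucs: dict[str, np.ndarray] = {}
    for method, w in weight_rows.items():
        contrib = np.take_along_axis(w.T, safe, axis=0)
        if missing.any():
            contrib = np.where(missing, 0.0, contrib)
        cumulative = np.cumsum(contrib, axis=1)
        scores = cumulative[:, k_values - 1]
        aucs[method] = _auc_columns(scores, rep_labels)
    return aucs


def nested_curve(
    discovery: tuple[GenotypeMatrix, PhenotypeVector],
    replication: tuple[GenotypeMatrix, PhenotypeVector],
    ranks: Sequence[RankStatistic],
    methods: Sequence[str] = ALL_METHODS,
    k_values: Sequence[int] | None = None,
    smoothing: float = DEFAULT_SMOOTHING,
) -> list[NestedCurve]:
    """Nested-model AUC curves for one discovery/replication pair.

    Fits every method on the discovery counts of the top-k ranked SNPs and
    scores the replication subjects; all methods share the ranking.
    """
    g_disc, y_disc = discovery
    g_rep, y_rep = replication
    ordered_ids = [r.snp_id for r in sorted(ranks, key=lambda r: r.rank)]
    if k_values is None:
        k_values = np.arange(1, len(ordered_ids) + 1)
    k_values = np.asarray(sorted(set(int(k) for k in k_values)), dtype=int)
    if k_values[-1] > len(ordered_ids):
        raise ValueError(f"k={k_values[-1]} exceeds the {len(ordered_ids)} ranked SNPs")
    top_ids = ordered_ids[: int(k_values[-1])]

    disc_col = {s: j for j, s in enumerate(g_disc.snp_ids)}
    rep_col = {s: j for j, s in enumerate(g_rep.snp_ids)}
    n_t, n_not, _, _ = count_arrays(g_disc, y_disc)
    top_disc = np.array([disc_col[s] for s in top_ids])
    top_rep = np.array([rep_col[s] for s in top_ids])

    weight_rows = method_weight_rows(n_t[top_disc], n_not[top_disc], methods, smoothing)
    aucs = _nested_aucs(weight_rows, g_rep.codes[:, top_rep], y_rep.labels, k_values)
    return [
        NestedCurve(
            method=m,
            k_values=k_values,
            auc_mean=aucs[m],
            auc_replicates=aucs[m][None, :],
        )
        for m in methods
    ]


def run_experiment(
    design: sim.SimulationDesign,
    k_values: Sequence[int] | None = None,
    methods: Sequence[str] = ALL_METHODS,
    ranking_method: str = BIC_BAYES_FACTOR,
    smoothing: float = DEFAULT_SMOOTHING,
    count_mode: bool | None = None,
    cell_cap: int = sim.DEFAULT_CELL_CAP,
) -> dict[str, NestedCurve]:
    """Full nested-model experiment: simulate, rank, fit, evaluate, average.

    For each replicate a discovery and a replication set are simulated, SNPs
    are ranked by genotypic-association evidence on the discovery data, and
    every method's nested AUC curve is measured on the replication set.  The
    returned curves carry the mean AUC over replicates plus the per-replicate
    matrix.  Deterministic given ``design.seed``.

    ``count_mode`` (default: automatic) ranks from multinomial count tables
    and materializes replication genotypes only for the selected SNPs, which
    is how genome-scale null panels (e.g. 500,000 SNPs) stay tractable.
    """
    if k_values is None:
        grid = default_k_values(design.n_causal)
        k_values = grid[grid <= design.n_snps]
    k_values = np.asarray(sorted(set(int(k) for k in k_values)), dtype=int)
    if k_values[0] < 1 or k_values[-1] > design.n_snps:
        raise ValueError("k_values must lie within 1..n_snps")
    n_subj = design.n_cases + design.n_controls
    if count_mode is None:
        count_mode = n_subj * design.n_snps > cell_cap
    k_max = int(k_values[-1])

    per_rep: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    for rep in range(design.n_replicates):
        if count_mode:
            truth, n_t, n_not = sim.simulate_count_arrays(design, sim.DISCOVERY, rep)
            evidence = genotypic_evidence(n_t, n_not, method=ranking_method)
            order = rank_order(truth.snp_ids, evidence)
            top = order[:k_max]
            rep_codes, rep_labels = sim.replication_codes_for_snps(design, rep, truth, top)
            weight_rows = method_weight_rows(n_t[top], n_not[top], methods, smoothing)
            aucs = _nested_aucs(weight_rows, rep_codes, rep_labels, k_values)
        else:
            g_disc, y_disc, truth = sim.simulate_dataset(design, sim.DISCOVERY, rep, cell_cap)
            g_rep, y_rep, _ = sim.simulate_dataset(design, sim.REPLICATION, rep, cell_cap)
            n_t, n_not, _, _ = count_arrays(g_disc, y_disc)
            evidence = genotypic_evidence(n_t, n_not, method=ranking_method)
            order = rank_order(truth.snp_ids, evidence)
            top = order[:k_max]
            weight_rows = method_weight_rows(n_t[top], n_not[top], methods, smoothing)
            aucs = _nested_aucs(weight_rows, g_rep.codes[:, top], y_rep.labels, k_values)
        for m in methods:
            per_rep[m].append(aucs[m])
        logger.info("run_experiment: replicate %d/%d done", rep + 1, design.n_replicates)

    curves: dict[str, NestedCurve] = {}
    for m in methods:
        matrix = np.stack(per_rep[m])
        curves[m] = NestedCurve(
            method=m, k_values=k_values, auc_mean=matrix.mean(axis=0), auc_replicates=matrix
        )
    return curves


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_curves_tsv(curves: Iterable[NestedCurve], path: str | Path) -> None:
    """Long-format TSV of per-replicate and mean AUC values."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("method\tk\treplicate\tauc\n")
        for curve in curves:
            for r in range(curve.auc_replicates.shape[0]):
                for j, k in enumerate(curve.k_values):
                    fh.write(f"{curve.method}\t{k}\t{r}\t{curve.auc_replicates[r, j]:.10f}\n")
            for j, k in enumerate(curve.k_values):
                fh.write(f"{curve.method}\t{k}\tmean\t{curve.auc_mean[j]:.10f}\n")


def plot_curves(curves: Iterable[NestedCurve], path: str | Path) -> None:
    """Mean-AUC-versus-k line plot (one line per method)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    palette = {NBC: "black", GRS_CASE1: "tab:blue", GRS_CASE2: "tab:green", GRS_CASE3: "tab:red"}
    for curve in curves:
        ax.plot(
            curve.k_values, curve.auc_mean,
            label=curve.method, color=palette.get(curve.method),
            linestyle="--" if curve.method == GRS_CASE3 else "-",
        )
    ax.set_xlabel("number of top-ranked SNPs")
    ax.set_ylabel("mean replication AUC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
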