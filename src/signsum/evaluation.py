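"""Ranking-reproducibility metrics and a DLDA/AUC predictive check.

Reproducibility of a ranking statistic is measured by repeatedly
splitting the samples into two stratified halves, ranking genes in each
half independently, and counting how many of the top-``k`` genes the two
halves share.  The overlap is normalised by the expected overlap of two
random selections, ``N_{p,k} = k^2 / p``, giving the ORRS (Overlap Ratio
to Random Selection): ORRS = 1 means no better than chance.

As a sanity check that reproducibly top-ranked genes remain predictive,
a diagonal linear discriminant (DLDA) built from the top genes of one
half is evaluated on the other half by AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import core
from .core import SubsampleScheme, DegenerateGeneWarning
from .data import ExpressionMatrix
from .simulation import StatisticSpec

__all__ = [
    "SplitPlan",
    "ReproducibilityResult",
    "split_data",
    "topk_overlap",
    "orrs",
    "run_reproducibility",
    "DLDAModel",
    "dlda_fit",
    "dlda_predict",
    "auc",
    "dlda_auc",
]


@dataclass(frozen=True)
class SplitPlan:
    """Split-half experiment settings (stratified by group throughout)."""

    n_trials: int = 100
    k_top: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.k_top < 1:
            raise ValueError("k_top must be >= 1")


@dataclass
class ReproducibilityResult:
    """Split-half overlap summary for one statistic."""

    statistic: str
    overlaps: np.ndarray
    p: int
    k: int

    @property
    def n_pk(self) -> float:
        """Expected top-k overlap of two random selections, k^2/p."""
        return self.k * self.k / self.p

    @property
    def mean(self) -> float:
        return float(np.mean(self.overlaps))

    @property
    def sd(self) -> float:
        # a single trial has no spread estimate: undefined by convention
        return float(np.std(self.overlaps, ddof=1)) if len(self.overlaps) > 1 \
            else float("nan")

    @property
    def orrs_mean(self) -> float:
        return self.mean / self.n_pk

    @property
    def orrs_sd(self) -> float:
        return self.sd / self.n_pk


def split_data(matrix: ExpressionMatrix, trial_seed: int
               ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Random stratified split into two disjoint, exhaustive halves.

    The group ratio is preserved; an odd group count puts the extra
    sample in the first half.  Each group must have at least 4 samples
    so both halves support a Welch variance.
    """
    for label in (0, 1):
        if int((matrix.group == label).sum()) < 4:
            raise ValueError(
                f"group {label} has fewer than 4 samples; cannot split"
            )
    rng = np.random.default_rng(trial_seed)
    first, second = [], []
    for label in (0, 1):
        idx = np.flatnonzero(matrix.group == label)
        idx = rng.permutation(idx)
        take = (len(idx) + 1) // 2  # extra sample goes to half 1
        first.append(idx[:take])
        second.append(idx[take:])
    half1 = matrix.select_samples(np.sort(np.concatenate(first)))
    half2 = matrix.select_samples(np.sort(np.concatenate(second)))
    return half1, half2


def topk_overlap(ranking1: pd.DataFrame, ranking2: pd.DataFrame,
                 k: int) -> int:
    """Number of genes shared by the two top-k selections."""
    top1 = set(ranking1["gene_id"].head(k))
    top2 = set(ranking2["gene_id"].head(k))
    return len(top1 & top2)


def orrs(overlaps, p: int, k: int) -> float:
    """Mean overlap divided by the random-selection expectation k^2/p."""
    if not 1 <= k <= p:
        raise ValueError("need 1 <= k <= p")
    return float(np.mean(overlaps)) / (k * k / p)


def _rank_half(half: ExpressionMatrix, spec: StatisticSpec,
               seed: int, n_draws: int) -> pd.DataFrame:
    scheme = None
    if spec.statistic != core.WELCH_T:
        probe = SubsampleScheme(spec.a, spec.b, "monte_carlo", 1)
        if (probe.n_pairs(half.n1, half.n0) <= probe.exact_ceiling
                or spec.statistic == core.SUBSAMPLE_T):
            scheme = SubsampleScheme(spec.a, spec.b, "exact")
        else:
            scheme = SubsampleScheme(spec.a, spec.b, "monte_carlo",
                                     n_draws=n_draws, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateGeneWarning)
        table = core.score(half, spec.statistic, scheme)
        # each half is re-oriented by its own full-half t signs
        return core.rank_genes(table, orientation="oriented_by_full_t",
                               matrix=half)


def run_reproducibility(
    matrix: ExpressionMatrix,
    statistics: tuple[StatisticSpec, ...],
    plan: SplitPlan,
    n_draws: int = 200,
) -> dict[str, ReproducibilityResult]:
    """Split-half top-k overlap and ORRS for each statistic.

    Per trial the samples are split into stratified halves, each half is
    ranked independently (re-oriented by its own Welch-t signs), and the
    top-``k_top`` overlap is recorded.  Identical seeds give identical
    results.
    """
    if plan.k_top > matrix.p:
        raise ValueError("k_top exceeds the number of genes")
    overlaps: dict[str, list[int]] = {s.label: [] for s in statistics}
    seeds = np.random.SeedSequence(plan.master_seed).generate_state(
        2 * plan.n_trials, dtype=np.uint32
    )
    for trial in range(plan.n_trials):
        half1, half2 = split_data(matrix, int(seeds[2 * trial]))
        for spec in statistics:
            base = int(seeds[2 * trial + 1])
            r1 = _rank_half(half1, spec, seed=base, n_draws=n_draws)
            r2 = _rank_half(half2, spec, seed=base + 1, n_draws=n_draws)
            overlaps[spec.label].append(topk_overlap(r1, r2, plan.k_top))
    return {
        label: ReproducibilityResult(label, np.asarray(counts), matrix.p,
                                     plan.k_top)
        for label, counts in overlaps.items()
    }


def reproducibility_frame(results: dict[str, ReproducibilityResult]
                          ) -> pd.DataFrame:
    """Tidy summary table of `run_reproducibility` output."""
    return pd.DataFrame(
        [{"statistic": r.statistic, "mean_overlap": r.mean,
          "sd_overlap": r.sd, "orrs_mean": r.orrs_mean, "orrs_sd": r.orrs_sd}
         for r in results.values()]
    )


# ---------------------------------------------------------------------
# DLDA / AUC
# ---------------------------------------------------------------------

@dataclass
class DLDAModel:
    """Diagonal LDA: per-gene group means with pooled diagonal variances."""

    gene_index: np.ndarray
    mean0: np.ndarray
    mean1: np.ndarray
    pooled_var: np.ndarray


def dlda_fit(train: ExpressionMatrix, gene_subset) -> DLDAModel:
    """Fit a diagonal linear discriminant on the given genes.

    Variances are pooled within-group per gene; genes with zero pooled
    variance are excluded with a warning.
    """
    ids = list(gene_subset)
    if not ids:
        raise ValueError("gene_subset must be non-empty")
    lookup = {g: i for i, g in enumerate(train.gene_ids)}
    missing = [g for g in ids if g not in lookup]
    if missing:
        raise ValueError(f"genes not in the training matrix: {missing[:5]}")
    idx = np.array([lookup[g] for g in ids])
    d, m = train.disease[idx], train.normal[idx]
    n1, n0 = train.n1, train.n0
    pooled = ((n1 - 1) * d.var(axis=1, ddof=1)
              + (n0 - 1) * m.var(axis=1, ddof=1)) / (n1 + n0 - 2)
    keep = pooled > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance gene(s) from DLDA",
            UserWarning, stacklevel=2,
        )
        if not keep.any():
            raise ValueError("all genes have zero pooled variance")
    return DLDAModel(idx[keep], m[keep].mean(axis=1), d[keep].mean(axis=1),
                     pooled[keep])


def dlda_predict(model: DLDAModel, samples: ExpressionMatrix) -> np.ndarray:
    """Discriminant score per sample; larger means more disease-like.

    Score = sum_j [ (x_j - mean0_j)^2 - (x_j - mean1_j)^2 ] / var_j.
    """
    x = samples.values[model.gene_index]  # (g, n)
    v = model.pooled_var[:, None]
    score = ((x - model.mean0[:, None]) ** 2 - (x - model.mean1[:, None]) ** 2) / v
    return score.sum(axis=0)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties counted 0.5)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC needs both groups present")
    return float(roc_auc_score(labels, scores))


def dlda_auc(train: ExpressionMatrix, test: ExpressionMatrix,
             gene_subset) -> float:
    """Train DLDA on ``train`` restricted to ``gene_subset``; AUC on ``test``."""
    model = dlda_fit(train, gene_subset)
    return auc(dlda_predict(model, test), test.group)
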