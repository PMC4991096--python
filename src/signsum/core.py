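"""Per-gene two-sample ranking statistics.

Three statistics are provided, each scored independently per gene:

* the Welch t-statistic ``T_j = sqrt(n) (xbar_1 - xbar_0) / s_j`` with the
  non-pooled denominator ``s_j = sqrt(s1^2/pi1_hat + s0^2/pi0_hat)``,
  ``pi_y_hat = n_y / n``;
* the subsample t-statistic ``U^T_j``, the average over all (or sampled)
  pairs of an ``a``-subset of the disease group and a ``b``-subset of the
  normal group of ``sqrt(a+b) (subset-mean difference) / s_j``;
* the sign-sum statistic ``U^S_j``, the average over the same subset pairs
  of the Heaviside step ``H(subset-mean difference)`` with ``H(0) = 1``.

``U^S`` lies in [0, 1]; a value near 1 means the sign of the subsample
mean difference is stably positive, which is exactly what fails for genes
whose disease group is a mixture of responding and non-responding
subtypes.  At ``a = b = 1`` the sign-sum statistic reduces to the
Mann-Whitney pair proportion (Wilcoxon rank-sum, rescaled).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data import ExpressionMatrix

__all__ = [
    "SubsampleScheme",
    "TopKConvergence",
    "ScoreTable",
    "DegenerateGeneWarning",
    "welch_t",
    "sign_sum",
    "subsample_t",
    "rank_genes",
]

WELCH_T = "welch_t"
SUBSAMPLE_T = "subsample_t"
SIGN_SUM = "sign_sum"


class DegenerateGeneWarning(UserWarning):
    """A gene had zero Welch denominator; its t-score is undefined."""


@dataclass(frozen=True)
class TopKConvergence:
    """Stop Monte-Carlo draws once the top-``k`` gene set stabilizes.

    Draws are added in batches; sampling stops when the number of genes
    entering/leaving the top-``k`` between successive batches is at most
    ``tol``, or when the draw cap is reached.
    """

    k: int = 100
    tol: int = 0


@dataclass(frozen=True)
class SubsampleScheme:
    """Subset sizes and evaluation mode for the subsampling statistics.

    Parameters
    ----------
    a, b : int
        Subset sizes drawn from the disease (``a``) and normal (``b``)
        groups.
    mode : {"exact", "monte_carlo"}
        ``exact`` enumerates all C(n1, a) * C(n0, b) subset pairs and is
        permitted only when that product is at most ``exact_ceiling``.
    n_draws : int
        Monte-Carlo budget.  For general (a, b) this is the number of
        independently drawn subset pairs per gene.  When ``a == 1`` the
        disease singletons are enumerated exhaustively and ``n_draws``
        counts random normal ``b``-subsets, each compared against every
        singleton (cheaper and lower-variance than naive pair draws).
    seed : int
        Master seed; per-gene streams are derived from (seed, gene index)
        so each gene's score is independent of ``p`` and of evaluation
        order.
    convergence_check : TopKConvergence, optional
        If set, draws are added in batches (doubling the cumulative
        count) until the top-k ranking stabilizes or ``max_draws`` is
        reached.
    max_draws : int, optional
        Cap on cumulative draws when ``convergence_check`` is active;
        defaults to ``4 * n_draws``.
    """

    a: int
    b: int
    mode: str = "exact"
    n_draws: int = 10_000
    seed: int = 0
    convergence_check: TopKConvergence | None = None
    max_draws: int | None = None
    exact_ceiling: int = 10_000_000

    def __post_init__(self) -> None:
        if self.a < 1 or self.b < 1:
            raise ValueError("subset sizes a and b must be positive")
        if self.mode not in ("exact", "monte_carlo"):
            raise ValueError(f"unknown evaluation mode {self.mode!r}")
        if self.mode == "monte_carlo" and self.n_draws < 1:
            raise ValueError("n_draws must be >= 1 in monte_carlo mode")

    def n_pairs(self, n1: int, n0: int) -> int:
        """Number of subset pairs enumerated in exact mode."""
        return math.comb(n1, self.a) * math.comb(n0, self.b)

    def validate(self, matrix: ExpressionMatrix) -> None:
        if self.a > matrix.n1:
            raise ValueError(
                f"a={self.a} exceeds the disease group size n1={matrix.n1}"
            )
        if self.b > matrix.n0:
            raise ValueError(
                f"b={self.b} exceeds the normal group size n0={matrix.n0}"
            )
        if self.mode == "exact":
            pairs = self.n_pairs(matrix.n1, matrix.n0)
            if pairs > self.exact_ceiling:
                raise ValueError(
                    f"exact mode needs {pairs} subset pairs per gene "
                    f"(> ceiling {self.exact_ceiling}); use mode='monte_carlo'"
                )

    @property
    def draw_cap(self) -> int:
        return self.max_draws if self.max_draws is not None else 4 * self.n_draws


@dataclass
class ScoreTable:
    """Per-gene scores for one statistic; the object that gets ranked."""

    gene_ids: np.ndarray
    statistic_name: str
    scores: np.ndarray
    params: SubsampleScheme | None = None
    mc_stderr: np.ndarray | None = None
    degenerate: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != np.shape(self.gene_ids):
            raise ValueError("scores and gene_ids must have equal length")
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.scores), dtype=bool)

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"gene_id": self.gene_ids, "statistic": self.statistic_name,
             "score": self.scores}
        )
        if self.mc_stderr is not None:
            frame["mc_stderr"] = self.mc_stderr
        return frame


# ---------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------

def _welch_denominator(matrix: ExpressionMatrix) -> np.ndarray:
    """Full-sample Welch scale s_j = sqrt(s1^2/pi1_hat + s0^2/pi0_hat)."""
    n = matrix.n
    v1 = matrix.disease.var(axis=1, ddof=1)
    v0 = matrix.normal.var(axis=1, ddof=1)
    return np.sqrt(v1 * n / matrix.n1 + v0 * n / matrix.n0)


def welch_t(matrix: ExpressionMatrix) -> ScoreTable:
    """Signed Welch t-statistic per gene.

    Genes whose denominator is exactly zero (zero variance in both
    groups) are flagged degenerate and scored NaN rather than +/-inf; a
    warning lists how many genes were affected.
    """
    if matrix.n1 < 2 or matrix.n0 < 2:
        raise ValueError("Welch t needs at least 2 samples per group")
    diff = matrix.disease.mean(axis=1) - matrix.normal.mean(axis=1)
    s = _welch_denominator(matrix)
    degenerate = s == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) have zero Welch denominator; "
            "their t-scores are undefined (NaN) and rank last",
            DegenerateGeneWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.sqrt(matrix.n) * diff / s
    scores[degenerate] = np.nan
    return ScoreTable(matrix.gene_ids, WELCH_T, scores, degenerate=degenerate)


# ---------------------------------------------------------------------
# subset machinery
# ---------------------------------------------------------------------

def _gene_rngs(seed: int, p: int) -> list[np.random.Generator]:
    # streams keyed by (seed, gene index): independent of p and of order
    return [
        np.random.default_rng(np.random.SeedSequence((seed, j))) for j in range(p)
    ]


def _subset_means_exact(values: np.ndarray, size: int) -> np.ndarray:
    """Means of all C(n, size) subsets per row; shape (p, C(n, size))."""
    n = values.shape[1]
    if size == 1:
        return values.copy()
    idx = np.fromiter(
        (i for combo in combinations(range(n), size) for i in combo), dtype=np.intp
    ).reshape(-1, size)
    return values[:, idx].mean(axis=2)


def _draw_subset_means(
    values: np.ndarray, size: int, n_subsets: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``n_subsets`` random size-``size`` subsets of one row.

    Subsets are uniform without replacement within each subset,
    independent across subsets.
    """
    n = values.shape[0]
    if size == 1:
        return values[rng.integers(0, n, size=n_subsets)]
    keys = rng.random((n_subsets, n))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    return values[idx].mean(axis=1)


def _pair_fraction(disease_means: np.ndarray, normal_means: np.ndarray) -> float:
    """Fraction of (l, m) pairs with disease mean >= normal mean (H(0)=1)."""
    order = np.sort(normal_means)
    hits = np.searchsorted(order, disease_means, side="right").sum()
    return hits / (disease_means.size * normal_means.size)


def _top_k_set(scores: np.ndarray, gene_ids: np.ndarray, k: int) -> frozenset:
    order = np.lexsort((gene_ids.astype(str), -scores))
    return frozenset(order[:k])


# ---------------------------------------------------------------------
# sign-sum statistic
# ---------------------------------------------------------------------

def _sign_sum_exact(matrix: ExpressionMatrix, scheme: SubsampleScheme) -> np.ndarray:
    d_means = _subset_means_exact(matrix.disease, scheme.a)
    n_means = _subset_means_exact(matrix.normal, scheme.b)
    return np.array(
        [_pair_fraction(d_means[j], n_means[j]) for j in range(matrix.p)]
    )


def _sign_sum_mc_singleton(
    matrix: ExpressionMatrix, scheme: SubsampleScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo U^S for a == 1: all disease singletons against random
    normal b-subsets shared across singletons.

    Returns (scores, mc_stderr).  The per-subset statistic
    q_k = (1/n1) #{i : X_i >= mbar_k} is averaged over subsets, so the
    standard error is sd(q) / sqrt(#subsets).
    """
    p = matrix.p
    rngs = _gene_rngs(scheme.seed, p)
    disease = matrix.disease
    normal = matrix.normal
    check = scheme.convergence_check

    sum_q = np.zeros(p)
    sum_q2 = np.zeros(p)
    total = 0
    batch = scheme.n_draws
    prev_top: frozenset | None = None
    while True:
        for j in range(p):
            means = _draw_subset_means(normal[j], scheme.b, batch, rngs[j])
            d_sorted = np.sort(disease[j])
            # q per subset: fraction of singletons >= subset mean
            q = 1.0 - np.searchsorted(d_sorted, means, side="left") / disease.shape[1]
            sum_q[j] += q.sum()
            sum_q2[j] += (q * q).sum()
        total += batch
        scores = sum_q / total
        if check is None:
            break
        top = _top_k_set(scores, matrix.gene_ids, check.k)
        stable = prev_top is not None and len(top ^ prev_top) <= 2 * check.tol
        prev_top = top
        if stable or total >= scheme.draw_cap:
            break
        batch = total  # double the cumulative draw count
    var_q = np.maximum(sum_q2 / total - scores**2, 0.0)
    stderr = np.sqrt(var_q / total)
    return scores, stderr


def _sign_sum_mc_pairs(
    matrix: ExpressionMatrix, scheme: SubsampleScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Generic Monte-Carlo U^S: independent (a-subset, b-subset) pair draws."""
    p = matrix.p
    rngs = _gene_rngs(scheme.seed, p)
    check = scheme.convergence_check
    sum_h = np.zeros(p)
    total = 0
    batch = scheme.n_draws if check is None else max(1, scheme.n_draws // 10)
    cap = scheme.n_draws if check is None else max(scheme.n_draws, scheme.draw_cap)
    prev_top: frozenset | None = None
    while True:
        for j in range(p):
            d = _draw_subset_means(matrix.disease[j], scheme.a, batch, rngs[j])
            m = _draw_subset_means(matrix.normal[j], scheme.b, batch, rngs[j])
            sum_h[j] += np.count_nonzero(d >= m)
        total += batch
        scores = sum_h / total
        if check is None:
            if total >= cap:
                break
            continue
        top = _top_k_set(scores, matrix.gene_ids, check.k)
        stable = prev_top is not None and len(top ^ prev_top) <= 2 * check.tol
        prev_top = top
        if stable or total >= cap:
            break
    # Bernoulli draws: sd = sqrt(u(1-u)) over `total` independent pairs
    stderr = np.sqrt(np.maximum(scores * (1.0 - scores), 0.0) / total)
    return scores, stderr


def sign_sum(matrix: ExpressionMatrix, scheme: SubsampleScheme) -> ScoreTable:
    """Sign-sum statistic U^S per gene.

    Exact mode averages the Heaviside indicator over all
    C(n1, a) * C(n0, b) subset pairs; Monte-Carlo mode returns an
    unbiased estimate with a per-gene standard error.  Ties count as
    positive (H(0) = 1).
    """
    scheme.validate(matrix)
    if scheme.mode == "exact":
        scores = _sign_sum_exact(matrix, scheme)
        stderr = None
    elif scheme.a == 1:
        scores, stderr = _sign_sum_mc_singleton(matrix, scheme)
    else:
        scores, stderr = _sign_sum_mc_pairs(matrix, scheme)
    return ScoreTable(matrix.gene_ids, SIGN_SUM, scores, params=scheme,
                      mc_stderr=stderr)


# ---------------------------------------------------------------------
# subsample t-statistic
# ---------------------------------------------------------------------

def subsample_t(matrix: ExpressionMatrix, scheme: SubsampleScheme) -> ScoreTable:
    """Subsample t-statistic U^T per gene.

    The denominator s_j is the full-sample Welch scale, computed once per
    gene.  In exact mode the average over all subset pairs of the
    subset-mean difference collapses to the full-group mean difference
    (the mean of all a-subset means of a group is the group mean), so the
    exact value is sqrt((a+b)/n) * T_j; this is the literal enumeration
    average, computed without materializing the subsets.
    """
    scheme.validate(matrix)
    if matrix.n1 < 2 or matrix.n0 < 2:
        raise ValueError("subsample t needs at least 2 samples per group")
    s = _welch_denominator(matrix)
    degenerate = s == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) have zero Welch denominator",
            DegenerateGeneWarning,
            stacklevel=2,
        )
    stderr = None
    if scheme.mode == "exact":
        diff = matrix.disease.mean(axis=1) - matrix.normal.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.sqrt(scheme.a + scheme.b) * diff / s
    else:
        p = matrix.p
        rngs = _gene_rngs(scheme.seed, p)
        mean_diff = np.zeros(p)
        sq_diff = np.zeros(p)
        for j in range(p):
            d = _draw_subset_means(matrix.disease[j], scheme.a,
                                   scheme.n_draws, rngs[j])
            m = _draw_subset_means(matrix.normal[j], scheme.b,
                                   scheme.n_draws, rngs[j])
            delta = d - m
            mean_diff[j] = delta.mean()
            sq_diff[j] = delta.var(ddof=1) if scheme.n_draws > 1 else 0.0
        root = np.sqrt(scheme.a + scheme.b)
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = root * mean_diff / s
            stderr = root * np.sqrt(sq_diff / scheme.n_draws) / s
        stderr[degenerate] = np.nan
    scores[degenerate] = np.nan
    return ScoreTable(matrix.gene_ids, SUBSAMPLE_T, scores, params=scheme,
                      mc_stderr=stderr)


def score(matrix: ExpressionMatrix, statistic: str,
          scheme: SubsampleScheme | None = None) -> ScoreTable:
    """Dispatch to one of the three statistics by name."""
    if statistic == WELCH_T:
        return welch_t(matrix)
    if scheme is None:
        raise ValueError(f"{statistic} requires a SubsampleScheme")
    if statistic == SIGN_SUM:
        return sign_sum(matrix, scheme)
    if statistic == SUBSAMPLE_T:
        return subsample_t(matrix, scheme)
    raise ValueError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------

def rank_genes(
    scores: ScoreTable,
    orientation: str = "signed",
    matrix: ExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Rank genes by descending score.

    ``orientation="signed"`` sorts the raw scores.  With
    ``orientation="oriented_by_full_t"`` each gene whose full-data Welch
    t is negative has its expression row negated (flipping the sign of
    its mean difference) and is re-scored before sorting, so a strongly
    down-regulated gene ranks as high as its up-regulated mirror image;
    this requires ``matrix``.

    Ties are broken by descending full-data Welch |t| (when ``matrix`` is
    given), then lexicographic gene_id, so repeated runs and split-half
    experiments are reproducible.  Degenerate (NaN) scores rank last.

    Returns a DataFrame with columns gene_id, score, rank (1 = best).
    """
    values = scores.scores.copy()
    if orientation == "oriented_by_full_t":
        if matrix is None:
            raise ValueError("oriented_by_full_t requires the expression matrix")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateGeneWarning)
            t_full = welch_t(matrix).scores
        flip = np.nan_to_num(t_full, nan=0.0) < 0
        if flip.any():
            flipped = ExpressionMatrix(
                values=np.where(flip[:, None], -matrix.values, matrix.values),
                gene_ids=matrix.gene_ids,
                group=matrix.group,
                sample_ids=matrix.sample_ids,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateGeneWarning)
                values = score(flipped, scores.statistic_name, scores.params).scores
    elif orientation != "signed":
        raise ValueError(f"unknown orientation {orientation!r}")

    if matrix is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateGeneWarning)
            tie_t = np.abs(np.nan_to_num(welch_t(matrix).scores, nan=-np.inf))
    else:
        tie_t = np.zeros(len(values))
    sort_scores = np.nan_to_num(values, nan=-np.inf)
    order = np.lexsort((scores.gene_ids.astype(str), -tie_t, -sort_scores))
    frame = pd.DataFrame(
        {"gene_id": scores.gene_ids[order], "score": values[order],
         "rank": np.arange(1, len(order) + 1)}
    )
    return frame
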