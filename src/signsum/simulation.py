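"""Calibrated homo/hetero/null simulation study.

The study generates expression matrices in which three gene classes are
mixed: *homo* genes (disease group shifted as a whole, N(mu1, sigma1^2)),
*hetero* genes (disease group a two-component mixture
tau1 N(0, 1) + tau2 N(m2, 1), so a proportion tau1 of disease samples is
indistinguishable from normal), and *null* genes (identical in both
groups).  Normal-group expression is N(0, 1) throughout.

The hetero shift m2 is calibrated so the homo and hetero genes have
exactly equal asymptotic Welch t — the t-statistic is blind to the
difference by construction — and performance is measured as the number
of homo genes among the top-ranked ``k_top`` genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import core
from .core import SubsampleScheme, TopKConvergence
from .data import ExpressionMatrix

__all__ = [
    "SITUATIONS",
    "StatisticSpec",
    "SimulationConfig",
    "LabeledDataset",
    "solve_hetero_mean",
    "generate_dataset",
    "run_simulation_study",
]

#: (sigma1_sq, tau1) for the three canonical simulation situations:
#: I  — symmetric half-contaminated mixture, unit homo variance;
#: II — lightly shifted 75 %-responding mixture vs a unit-variance homo
#:      gene (homo and hetero nearly indistinguishable even by sign
#:      counts at b = 1; larger b helps);
#: III — strongly shifted 25 %-responding mixture vs a variance-4 homo
#:      gene (sign counts separate the classes already at b = 1).
SITUATIONS = {"I": (1.0, 0.5), "II": (1.0, 0.25), "III": (4.0, 0.75)}


@dataclass(frozen=True)
class StatisticSpec:
    """One column of the study: a statistic plus its subset sizes."""

    statistic: str
    a: int | None = None
    b: int | None = None

    @property
    def label(self) -> str:
        if self.statistic == core.WELCH_T:
            return "t"
        prefix = "t" if self.statistic == core.SUBSAMPLE_T else "s"
        return f"{prefix}_{{{self.a},{self.b}}}"


#: The canonical comparison: t, t_{1,1}, s_{1,1}, s_{1,5}, s_{1,10}.
DEFAULT_STATISTICS = (
    StatisticSpec(core.WELCH_T),
    StatisticSpec(core.SUBSAMPLE_T, 1, 1),
    StatisticSpec(core.SIGN_SUM, 1, 1),
    StatisticSpec(core.SIGN_SUM, 1, 5),
    StatisticSpec(core.SIGN_SUM, 1, 10),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one cell of the simulation study.

    Defaults are the canonical study conditions: 1000 genes (100 homo,
    100 hetero, 800 null), equal group sizes, 100 replicates, top-100
    ranking depth.  ``situation`` is "I", "II" or "III", or pass
    ``sigma1_sq`` / ``tau1`` explicitly.
    """

    n0: int = 100
    n1: int = 100
    situation: str | None = "I"
    sigma1_sq: float | None = None
    tau1: float | None = None
    p_homo: int = 100
    p_hetero: int = 100
    p_null: int = 800
    mu1: float = 1.0
    n_reps: int = 100
    k_top: int = 100
    statistics: tuple[StatisticSpec, ...] = DEFAULT_STATISTICS
    master_seed: int = 0
    #: normal b-subsets per disease singleton for Monte-Carlo sign-sum
    n_draws: int = 200
    #: double draws until the top-k_top set stabilizes (cap 4x n_draws)
    check_convergence: bool = True

    def __post_init__(self) -> None:
        if min(self.p_homo, self.p_hetero, self.p_null) < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n0 < 2 or self.n1 < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.situation is not None and self.situation not in SITUATIONS:
            raise ValueError(f"unknown situation {self.situation!r}")

    @property
    def params(self) -> tuple[float, float]:
        """(sigma1_sq, tau1) resolved from the situation or overrides."""
        if self.sigma1_sq is not None and self.tau1 is not None:
            return float(self.sigma1_sq), float(self.tau1)
        if self.situation is None:
            raise ValueError("give a situation or sigma1_sq and tau1")
        return SITUATIONS[self.situation]

    @property
    def p(self) -> int:
        return self.p_homo + self.p_hetero + self.p_null

    @property
    def pi1(self) -> float:
        return self.n1 / (self.n0 + self.n1)


@dataclass
class LabeledDataset:
    """A simulated expression matrix plus the true class of every gene."""

    matrix: ExpressionMatrix
    gene_class: np.ndarray  # {"homo", "hetero", "null"} per gene
    m2: float

    def __post_init__(self) -> None:
        if len(self.gene_class) != self.matrix.p:
            raise ValueError("gene_class length must match the matrix")

    @property
    def homo_ids(self) -> set:
        return set(self.matrix.gene_ids[self.gene_class == "homo"])


def solve_hetero_mean(
    sigma1_sq: float,
    tau1: float,
    pi1: float = 0.5,
    pi0: float = 0.5,
    mu1: float = 1.0,
    mu0: float = 0.0,
    sigma0_sq: float = 1.0,
) -> float:
    """Shift m2 of the hetero mixture tau1 N(mu0, s0^2) + tau2 N(m2, s0^2)
    matching the homo gene's asymptotic Welch t.

    The calibration equates

        (mu1 - mu0) / sqrt(sigma1^2/pi1 + sigma0^2/pi0)
      = (mu1* - mu0) / sqrt(sigma1*^2/pi1 + sigma0^2/pi0)

    where mu1* = tau1 mu0 + tau2 m2 and
    sigma1*^2 = sigma0^2 + tau1 tau2 (m2 - mu0)^2 are the mixture
    moments.  Solving for delta = m2 - mu0 gives

        delta^2 (tau2^2 - c^2 tau1 tau2 / pi1) = c^2 sigma0^2 (1/pi1 + 1/pi0)

    with c the common asymptotic t-center; the positive root is
    returned.  Raises if no positive root exists (the hetero mixture
    cannot reach the homo gene's t, e.g. tau2 too small for the given
    effect size).
    """
    if not 0.0 < tau1 < 1.0:
        raise ValueError("tau1 must lie in (0, 1)")
    if sigma1_sq <= 0 or sigma0_sq <= 0:
        raise ValueError("variances must be positive")
    tau2 = 1.0 - tau1
    c = (mu1 - mu0) / np.sqrt(sigma1_sq / pi1 + sigma0_sq / pi0)
    denom = tau2 * tau2 - c * c * tau1 * tau2 / pi1
    if denom <= 0 or c <= 0:
        raise ValueError(
            "no positive hetero shift exists for "
            f"sigma1_sq={sigma1_sq}, tau1={tau1}, pi1={pi1}, mu1={mu1}"
        )
    delta = c * np.sqrt(sigma0_sq * (1.0 / pi1 + 1.0 / pi0) / denom)
    return float(mu0 + delta)


def generate_dataset(config: SimulationConfig, rep_index: int = 0
                     ) -> LabeledDataset:
    """Simulate one replicate of the calibrated study.

    Normal-group entries are N(0, 1) for every gene.  Disease-group
    entries are N(mu1, sigma1^2) for homo genes, the calibrated mixture
    for hetero genes and N(0, 1) for null genes.  Seeding is by
    (master_seed, rep_index), so any replicate is reproducible in
    isolation.
    """
    sigma1_sq, tau1 = config.params
    m2 = solve_hetero_mean(sigma1_sq, tau1, pi1=config.pi1,
                           pi0=1.0 - config.pi1, mu1=config.mu1)
    rng = np.random.default_rng(
        np.random.SeedSequence((config.master_seed, rep_index))
    )
    p, n0, n1 = config.p, config.n0, config.n1

    normal = rng.standard_normal((p, n0))
    disease = rng.standard_normal((p, n1))
    h = config.p_homo
    e = h + config.p_hetero
    disease[:h] = config.mu1 + np.sqrt(sigma1_sq) * disease[:h]
    # hetero rows: component-2 (shifted) indicator per entry
    shifted = rng.random((e - h, n1)) >= tau1
    disease[h:e] += m2 * shifted
    # null rows stay standard normal

    gene_class = np.array(
        ["homo"] * h + ["hetero"] * (e - h) + ["null"] * (p - e), dtype=object
    )
    width = len(str(p))
    gene_ids = np.array(
        [f"{cls}{idx:0{width}d}" for idx, cls in enumerate(gene_class)],
        dtype=object,
    )
    matrix = ExpressionMatrix(
        values=np.hstack([disease, normal]),
        gene_ids=gene_ids,
        group=np.array([1] * n1 + [0] * n0),
    )
    return LabeledDataset(matrix, gene_class, m2)


def _scheme_for(spec: StatisticSpec, config: SimulationConfig,
                matrix: ExpressionMatrix, seed: int) -> SubsampleScheme | None:
    if spec.statistic == core.WELCH_T:
        return None
    probe = SubsampleScheme(spec.a, spec.b, "monte_carlo", 1)
    exact_ok = (probe.n_pairs(matrix.n1, matrix.n0) <= probe.exact_ceiling
                or spec.statistic == core.SUBSAMPLE_T)
    if exact_ok:
        return SubsampleScheme(spec.a, spec.b, "exact")
    check = TopKConvergence(k=config.k_top) if config.check_convergence else None
    return SubsampleScheme(spec.a, spec.b, "monte_carlo",
                           n_draws=config.n_draws, seed=seed,
                           convergence_check=check)


def score_replicate(config: SimulationConfig, rep_index: int
                    ) -> dict[str, int]:
    """Homo-gene count in the top k_top for each statistic, one replicate."""
    data = generate_dataset(config, rep_index)
    homo_ids = data.homo_ids
    counts: dict[str, int] = {}
    for spec in config.statistics:
        scheme = _scheme_for(spec, config, data.matrix,
                             seed=config.master_seed * 100_003 + rep_index)
        table = core.score(data.matrix, spec.statistic, scheme)
        # simulated effects are non-negative by construction: rank signed
        ranking = core.rank_genes(table, orientation="signed",
                                  matrix=data.matrix)
        top = set(ranking["gene_id"].head(config.k_top))
        counts[spec.label] = len(top & homo_ids)
    return counts


def run_simulation_study(config: SimulationConfig,
                         progress: bool = False) -> pd.DataFrame:
    """Mean (sd) homo-gene count in the top k_top per statistic.

    Returns a DataFrame indexed by the statistic label with columns
    ``mean``, ``sd`` and ``n_reps``; per-replicate counts are attached
    as ``frame.attrs["counts"]``.
    """
    rows = []
    for rep in range(config.n_reps):
        rows.append(score_replicate(config, rep))
        if progress:  # pragma: no cover
            print(f"replicate {rep + 1}/{config.n_reps}", flush=True)
    counts = pd.DataFrame(rows)
    out = pd.DataFrame({
        "mean": counts.mean(),
        "sd": counts.std(ddof=1) if len(counts) > 1 else np.nan,
        "n_reps": config.n_reps,
    })
    out.index.name = "statistic"
    out.attrs["counts"] = counts
    return out


def run_all_situations(base: SimulationConfig,
                       situations=("I", "II", "III")) -> pd.DataFrame:
    """Stack `run_simulation_study` over several situations."""
    frames = []
    for sit in situations:
        cfg = replace(base, situation=sit, sigma1_sq=None, tau1=None)
        frame = run_simulation_study(cfg).reset_index()
        frame.insert(0, "situation", sit)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
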