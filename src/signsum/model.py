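"""Model / results front-end for gene ranking.

`GeneRanking` wraps an expression matrix the way a statsmodels model
wraps its data: construct once, then `fit()` with a choice of statistic
and subsampling scheme to obtain a `GeneRankingResults` carrying the
per-gene scores, their Monte-Carlo standard errors, the ranking, and a
`summary()` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import core
from .core import ScoreTable, SubsampleScheme, TopKConvergence
from .data import ExpressionMatrix

__all__ = ["GeneRanking", "GeneRankingResults"]


class GeneRanking:
    """Two-sample gene-ranking model for a genes x samples matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Expression levels with binary group labels (0 = normal,
        1 = disease).
    """

    def __init__(self, matrix: ExpressionMatrix):
        self.matrix = matrix

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, labels) -> "GeneRanking":
        """Build from a genes x samples DataFrame and a sample->label map."""
        return cls(ExpressionMatrix.from_dataframe(frame, labels))

    def fit(
        self,
        statistic: str = "sign_sum",
        a: int = 1,
        b: int = 10,
        mode: str | None = None,
        n_draws: int = 10_000,
        seed: int = 0,
        orientation: str = "signed",
        convergence_check: TopKConvergence | None = None,
    ) -> "GeneRankingResults":
        """Score every gene and rank.

        ``statistic`` is one of ``welch_t``, ``subsample_t`` or
        ``sign_sum``.  ``mode`` defaults to exact enumeration when the
        subset-pair count permits, Monte Carlo otherwise.
        ``orientation="oriented_by_full_t"`` reflects genes with a
        negative full-data Welch t before scoring, so strongly
        down-regulated genes rank alongside up-regulated ones.
        """
        scheme = None
        if statistic != core.WELCH_T:
            if mode is None:
                pairs_ok = (
                    SubsampleScheme(a, b, "monte_carlo", 1).n_pairs(
                        self.matrix.n1, self.matrix.n0
                    )
                    <= SubsampleScheme(a, b, "monte_carlo", 1).exact_ceiling
                )
                mode = "exact" if pairs_ok else "monte_carlo"
            scheme = SubsampleScheme(
                a=a, b=b, mode=mode, n_draws=n_draws, seed=seed,
                convergence_check=convergence_check,
            )
        table = core.score(self.matrix, statistic, scheme)
        ranking = core.rank_genes(table, orientation=orientation,
                                  matrix=self.matrix)
        return GeneRankingResults(self, table, ranking, orientation)


class GeneRankingResults:
    """Fitted per-gene scores plus the resulting ranking."""

    def __init__(
        self,
        model: GeneRanking,
        score_table: ScoreTable,
        ranking: pd.DataFrame,
        orientation: str,
    ):
        self.model = model
        self.score_table = score_table
        self.ranking = ranking
        self.orientation = orientation

    @property
    def scores(self) -> np.ndarray:
        return self.score_table.scores

    @property
    def mc_stderr(self) -> np.ndarray | None:
        return self.score_table.mc_stderr

    def top_genes(self, k: int = 100) -> list[str]:
        """Gene ids of the ``k`` best-ranked genes."""
        return self.ranking["gene_id"].head(k).tolist()

    def to_frame(self) -> pd.DataFrame:
        """Ranking table: gene_id, statistic, score, mc_stderr, rank."""
        frame = self.ranking.copy()
        frame.insert(1, "statistic", self.score_table.statistic_name)
        if self.score_table.mc_stderr is not None:
            stderr = pd.Series(
                self.score_table.mc_stderr,
                index=pd.Index(self.score_table.gene_ids),
            )
            frame["mc_stderr"] = stderr.reindex(frame["gene_id"]).to_numpy()
        return frame

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self, k: int = 10) -> str:
        """Human-readable fit summary with the top-``k`` genes."""
        table = self.score_table
        scheme = table.params
        matrix = self.model.matrix
        lines = [
            "Gene ranking results",
            "=" * 52,
            f"statistic:      {table.statistic_name}",
            f"genes:          {matrix.p}",
            f"samples:        {matrix.n} (disease {matrix.n1}, "
            f"normal {matrix.n0})",
            f"orientation:    {self.orientation}",
        ]
        if scheme is not None:
            lines.append(f"subset sizes:   a={scheme.a}, b={scheme.b} "
                         f"({scheme.mode})")
            if scheme.mode == "monte_carlo":
                lines.append(f"draws:          {scheme.n_draws} "
                             f"(seed {scheme.seed})")
        n_deg = int(table.degenerate.sum())
        if n_deg:
            lines.append(f"degenerate:     {n_deg} gene(s) with undefined t")
        lines.append("-" * 52)
        head = self.to_frame().head(k)
        lines.append(head.to_string(index=False))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<GeneRankingResults: {self.score_table.statistic_name}, "
                f"{len(self.score_table)} genes>")
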