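"""Expression-matrix container and delimited-text I/O.

The universal input is a genes x samples matrix of real-valued expression
levels together with a binary group label per sample (0 = normal,
1 = disease).  Matrices are stored genes-in-rows (microarray convention);
this is made explicit because transcript-matrix tools disagree on
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "ExpressionInputError", "read_expression"]


class ExpressionInputError(ValueError):
    """Raised for malformed expression or label inputs."""


@dataclass
class ExpressionMatrix:
    """Real-valued expression levels for ``p`` genes over ``n`` samples.

    Parameters
    ----------
    values : ndarray, shape (p, n)
        Expression levels; no missing entries allowed.
    gene_ids : sequence of str, length p
        Unique gene identifiers.
    group : ndarray of {0, 1}, length n
        0 = normal group, 1 = disease group.  Both groups must be
        non-empty.
    sample_ids : sequence of str, optional
        Column names; generated if omitted.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    group: np.ndarray
    sample_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.group = np.asarray(self.group, dtype=int)
        if self.values.ndim != 2:
            raise ExpressionInputError("values must be a 2-d genes x samples array")
        p, n = self.values.shape
        if self.gene_ids.shape != (p,):
            raise ExpressionInputError(
                f"gene_ids length {self.gene_ids.shape} does not match {p} rows"
            )
        if self.group.shape != (n,):
            raise ExpressionInputError(
                f"group length {self.group.shape} does not match {n} columns"
            )
        if not np.isin(self.group, (0, 1)).all():
            raise ExpressionInputError("group labels must be 0 (normal) or 1 (disease)")
        if self.n0 < 1 or self.n1 < 1:
            raise ExpressionInputError("both groups must contain at least one sample")
        if len(set(self.gene_ids)) != p:
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ExpressionInputError(f"duplicate gene ids: {dupes[:5]}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionInputError(
                f"non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, column {bad[1]}"
            )
        if self.sample_ids is None:
            self.sample_ids = np.array(
                [f"sample{i}" for i in range(n)], dtype=object
            )
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if self.sample_ids.shape != (n,):
                raise ExpressionInputError("sample_ids length does not match columns")

    # -- derived sizes -------------------------------------------------
    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def n0(self) -> int:
        return int((self.group == 0).sum())

    @property
    def n1(self) -> int:
        return int((self.group == 1).sum())

    @property
    def disease(self) -> np.ndarray:
        """View of the disease-group columns, shape (p, n1)."""
        return self.values[:, self.group == 1]

    @property
    def normal(self) -> np.ndarray:
        """View of the normal-group columns, shape (p, n0)."""
        return self.values[:, self.group == 0]

    # -- construction / conversion ------------------------------------
    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, labels: "pd.Series | dict[str, int]"
    ) -> "ExpressionMatrix":
        """Build from a genes x samples DataFrame plus a sample -> label map.

        Label matching is by sample name and order-independent; every
        column of ``frame`` must have a label.
        """
        labels = pd.Series(labels)
        missing = [c for c in frame.columns if c not in labels.index]
        if missing:
            raise ExpressionInputError(f"samples without a group label: {missing[:5]}")
        group = labels.reindex(frame.columns).to_numpy()
        try:
            values = frame.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ExpressionInputError(f"non-numeric expression cell: {exc}") from exc
        return cls(
            values=values,
            gene_ids=frame.index.to_numpy(dtype=object),
            group=group,
            sample_ids=frame.columns.to_numpy(dtype=object),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    def select_samples(self, index: np.ndarray) -> "ExpressionMatrix":
        """Sub-matrix restricted to the given sample positions."""
        index = np.asarray(index)
        return ExpressionMatrix(
            values=self.values[:, index],
            gene_ids=self.gene_ids,
            group=self.group[index],
            sample_ids=self.sample_ids[index],
        )


def _sniff_delimiter(path: str) -> str:
    with open(path) as handle:
        header = handle.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def read_expression(path: str, labels_path: str) -> ExpressionMatrix:
    """Read a delimited expression table plus its group-label file.

    The expression file is TSV by default (comma accepted): first column
    gene_id, remaining columns one per sample, one header row of sample
    names.  The label file has two columns, sample_id and group
    (0 = normal / 1 = disease), order-independent.
    """
    frame = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0)
    if frame.index.hasnans or frame.isna().any().any():
        cell = np.argwhere(frame.isna().to_numpy())
        where = (
            f"gene {frame.index[cell[0][0]]!r}, column {frame.columns[cell[0][1]]!r}"
            if len(cell)
            else "gene-id column"
        )
        raise ExpressionInputError(f"missing value at {where}")
    labels = pd.read_csv(
        labels_path, sep=_sniff_delimiter(labels_path), index_col=0
    ).iloc[:, 0]
    return ExpressionMatrix.from_dataframe(frame, labels)
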