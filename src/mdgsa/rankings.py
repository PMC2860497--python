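"""Gene-level ranking statistics: ingestion, alignment, aggregation.

A ranking statistic is any per-gene number summarising a biological
property — a moderated t for differential expression, a Cox hazard ratio,
a SNP odds ratio, a splicing index, a copy-number score.  The analysis is
agnostic to how the statistic was computed; it only requires one finite
value per gene (or two, for the bivariate model).  By default statistics
enter the model on their raw scale; standardisation is opt-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateCovariateError, EmptyInputError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRanking",
    "read_ranking",
    "align",
    "aggregate_subunits",
    "standardize",
]


@dataclass
class GeneRanking:
    """One or two finite numeric statistics per gene on an ordered universe."""

    universe: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_dims), float64
    dimension_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.universe = tuple(self.universe)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[0] == 1 and len(self.universe) != 1:
            self.values = self.values.T
        self.dimension_names = tuple(self.dimension_names)
        if len(set(self.universe)) != len(self.universe):
            raise ValueError("duplicate gene identifiers in universe")
        if self.values.shape != (len(self.universe), len(self.dimension_names)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.universe)} genes x {len(self.dimension_names)} dimensions"
            )
        if self.values.shape[1] not in (1, 2):
            raise ValueError("rankings must have 1 or 2 dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite ranking values")
        # a single-gene ranking is legal for plumbing; variance only matters
        # once there is more than one gene to model
        if len(self.universe) > 1 and np.any(self.values.std(axis=0) == 0):
            raise DegenerateCovariateError("a ranking column has zero variance")

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    def column(self, i: int) -> np.ndarray:
        return self.values[:, i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.universe), columns=list(self.dimension_names)
        )


def _from_frame(df: pd.DataFrame) -> GeneRanking:
    return GeneRanking(
        universe=tuple(df.index.astype(str)),
        values=df.to_numpy(dtype=np.float64),
        dimension_names=tuple(str(c) for c in df.columns),
    )


def read_ranking(
    path,
    gene_col: int | str = 0,
    value_cols: list[int] | list[str] | None = None,
    header: bool = False,
) -> GeneRanking:
    """Read a TSV of per-gene statistics.

    Parameters
    ----------
    path:
        Tab-separated file with a gene-identifier column and one or two
        numeric columns.
    gene_col, value_cols:
        Column positions (or names, when ``header`` is true).  By default the
        first column holds gene identifiers and all remaining columns are
        values.
    header:
        Whether the first line is a header row.

    Rows with non-finite values are dropped with a logged count; duplicate
    gene identifiers are aggregated by arithmetic mean with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=0 if header else None, dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a gene column plus >=1 numeric column")
    if isinstance(gene_col, int):
        gene_series = df.iloc[:, gene_col].astype(str)
        rest = df.drop(columns=df.columns[gene_col])
    else:
        gene_series = df[gene_col].astype(str)
        rest = df.drop(columns=[gene_col])
    if value_cols is not None:
        if all(isinstance(c, int) for c in value_cols):
            rest = rest.iloc[:, list(value_cols)]
        else:
            rest = rest[list(value_cols)]
    rest = rest.apply(pd.to_numeric, errors="coerce")
    if rest.shape[1] not in (1, 2):
        raise ParseError(f"{path}: expected 1 or 2 value columns, got {rest.shape[1]}")
    values = rest.to_numpy(dtype=np.float64)
    ok = np.all(np.isfinite(values), axis=1)
    if (~ok).any():
        logger.info("%s: dropped %d row(s) with non-finite values", path, int((~ok).sum()))
    frame = pd.DataFrame(values[ok], index=gene_series[ok].to_numpy())
    if frame.empty:
        raise EmptyInputError(f"{path}: no usable rows after cleaning")
    if frame.index.has_duplicates:
        n_dup = int(frame.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene id(s) aggregated by mean", path, n_dup)
        frame = frame.groupby(level=0, sort=False).mean()
    if not header:
        frame.columns = [f"V{i + 1}" for i in range(frame.shape[1])]
    else:
        frame.columns = [str(c) for c in rest.columns]
    return _from_frame(frame)


def align(rx: GeneRanking, ry: GeneRanking) -> GeneRanking:
    """Join two one-dimensional rankings on their common genes.

    The result is a two-dimensional ranking on the intersection of the two
    universes, ordered lexicographically by gene id for reproducibility;
    column X comes from ``rx`` and column Y from ``ry``.
    """
    if rx.n_dims != 1 or ry.n_dims != 1:
        raise ValueError("align expects two 1-dimensional rankings")
    common = sorted(set(rx.universe) & set(ry.universe))
    if not common:
        raise EmptyInputError("rankings share no genes")
    logger.info("align: %d common gene(s)", len(common))
    fx = rx.to_frame().loc[common]
    fy = ry.to_frame().loc[common]
    name_x, name_y = rx.dimension_names[0], ry.dimension_names[0]
    if name_x == name_y:
        name_x, name_y = f"{name_x}_x", f"{name_y}_y"
    values = np.column_stack([fx.to_numpy()[:, 0], fy.to_numpy()[:, 0]])
    return GeneRanking(
        universe=tuple(common), values=values, dimension_names=(name_x, name_y)
    )


def aggregate_subunits(table, dimension_name: str = "V1") -> GeneRanking:
    """Collapse subunit-level values (e.g. per-exon splicing indices) per gene.

    ``table`` is an iterable of ``(gene_id, value)`` pairs or a two-column
    DataFrame.  The gene-level statistic is the median across its subunits
    (for an even count, the midpoint of the two central values), so one
    aberrant exon does not dominate the gene's score.  Output genes are
    sorted lexicographically; the result does not depend on input order.
    """
    if isinstance(table, pd.DataFrame):
        df = table.iloc[:, :2].copy()
        df.columns = ["gene", "value"]
    else:
        df = pd.DataFrame(list(table), columns=["gene", "value"])
    if df.empty:
        raise EmptyInputError("no subunit rows supplied")
    df["gene"] = df["gene"].astype(str)
    df["value"] = pd.to_numeric(df["value"])
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError("non-finite subunit values")
    med = df.groupby("gene")["value"].median().sort_index()
    return GeneRanking(
        universe=tuple(med.index),
        values=med.to_numpy()[:, None],
        dimension_names=(dimension_name,),
    )


def standardize(r: GeneRanking) -> GeneRanking:
    """Centre each column to mean 0 and scale to sample standard deviation 1."""
    sd = r.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateCovariateError("cannot standardize a constant column")
    values = (r.values - r.values.mean(axis=0)) / sd
    return GeneRanking(
        universe=r.universe, values=values, dimension_names=r.dimension_names
    )
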