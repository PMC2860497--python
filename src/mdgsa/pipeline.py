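"""End-to-end gene-set analysis runs and result tables.

``run_md_gsa`` fits the bivariate logistic model with interaction to every
functional module that survives the size filter, adjusts p-values per
coefficient family across the fitted modules (Benjamini-Hochberg), and
classifies each module into the enrichment-pattern taxonomy.  ``run_uv_gsa``
is the one-dimensional counterpart with a single adjustment family.  Output
ordering is deterministic (lexicographic by set id) and result tables
round-trip through plain TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .exceptions import InsufficientDataError
from .geneset_io import GeneSetCollection, filter_by_size, membership_vector
from .logit import ModelFit, bh_adjust, fit_bivariate, fit_univariate
from .patterns import PatternLabel, classify, effective_signs
from .rankings import GeneRanking, standardize

logger = logging.getLogger(__name__)

__all__ = [
    "GsaConfig",
    "SetResult",
    "EllipseSummary",
    "run_md_gsa",
    "run_uv_gsa",
    "ellipse_summary",
    "write_results",
    "read_results",
]

RESULT_COLUMNS = [
    "set_id", "name", "size",
    "lor_X", "lor_Y", "lor_I",
    "se_X", "se_Y", "se_I",
    "p_X", "p_Y", "p_I",
    "padj_X", "padj_Y", "padj_I",
    "pattern", "converged",
]


@dataclass(frozen=True)
class GsaConfig:
    """Thresholds and flags of a gene-set analysis run.

    ``threshold`` is the significance level applied to BH-adjusted p-values
    when deriving effective coefficient signs.  ``ridge`` (off by default)
    adds an L2 stabiliser on slope coefficients for separated fits.
    """

    min_size: int = 10
    max_size: int = 500
    threshold: float = 0.05
    standardize: bool = False
    ridge: float = 0.0


@dataclass
class SetResult:
    """Per-module analysis outcome: fit, adjusted p-values, pattern."""

    set_id: str
    name: str
    size: int
    fit: ModelFit
    padj_alpha: float
    padj_beta: float | None
    padj_gamma: float | None
    pattern: PatternLabel


@dataclass
class EllipseSummary:
    """Mean and covariance of a 2-D point cloud with a confidence level.

    The ellipse boundary is the locus of points at squared Mahalanobis
    distance chi2.ppf(level, df=2) from the mean.
    """

    mean: np.ndarray
    covariance: np.ndarray
    confidence_level: float
    degenerate: bool = field(default=False)

    @property
    def mahalanobis_radius(self) -> float:
        return float(np.sqrt(chi2.ppf(self.confidence_level, df=2)))

    def boundary(self, n_points: int = 200) -> np.ndarray:
        """(n_points, 2) polygon approximating the ellipse boundary."""
        theta = np.linspace(0.0, 2.0 * np.pi, n_points)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        vals, vecs = np.linalg.eigh(self.covariance)
        vals = np.clip(vals, 0.0, None)
        transform = vecs @ np.diag(np.sqrt(vals))
        return self.mean + self.mahalanobis_radius * circle @ transform.T


def _prepare(ranking: GeneRanking, coll: GeneSetCollection, config: GsaConfig):
    if config.standardize:
        ranking = standardize(ranking)
    coll = filter_by_size(
        coll, ranking.universe, min_size=config.min_size, max_size=config.max_size
    )
    if len(coll) == 0:
        logger.warning("no gene sets survive the size filter; empty result")
    return ranking, coll, sorted(coll.sets)


def run_md_gsa(
    ranking: GeneRanking, coll: GeneSetCollection, config: GsaConfig = GsaConfig()
) -> list[SetResult]:
    """Bivariate gene-set analysis with interaction over a whole collection.

    For every module surviving the size filter the model
    ``logit P(member) = c + alpha*X + beta*Y + gamma*X*Y`` is fitted against
    the full gene universe; raw Wald p-values are then BH-adjusted within
    each coefficient family across the fitted modules, and the effective
    sign triple is classified into a pattern label.
    """
    if ranking.n_dims != 2:
        raise ValueError("run_md_gsa requires a 2-dimensional ranking")
    if len(coll) == 0:
        raise ValueError("empty gene-set collection")
    ranking, coll, order = _prepare(ranking, coll, config)
    logger.info(
        "MD-GSA: universe %d genes, %d set(s) to test, threshold %g",
        len(ranking.universe),
        len(order),
        config.threshold,
    )
    fits: list[tuple[str, int, ModelFit]] = []
    for set_id in order:
        mv = membership_vector(coll, set_id, ranking.universe)
        fit = fit_bivariate(ranking.values, mv, ridge=config.ridge)
        fits.append((set_id, mv.n_members, fit))
    if not fits:
        return []
    padj_a = bh_adjust([f.p_alpha for _, _, f in fits])
    padj_b = bh_adjust([f.p_beta for _, _, f in fits])
    padj_g = bh_adjust([f.p_gamma for _, _, f in fits])
    results = []
    for i, (set_id, size, fit) in enumerate(fits):
        signs = effective_signs(
            (fit.alpha, fit.beta, fit.gamma),
            (padj_a[i], padj_b[i], padj_g[i]),
            threshold=config.threshold,
        )
        results.append(
            SetResult(
                set_id=set_id,
                name=coll.description(set_id),
                size=size,
                fit=fit,
                padj_alpha=float(padj_a[i]),
                padj_beta=float(padj_b[i]),
                padj_gamma=float(padj_g[i]),
                pattern=classify(signs, fit),
            )
        )
    return results


def run_uv_gsa(
    ranking: GeneRanking, coll: GeneSetCollection, config: GsaConfig = GsaConfig()
) -> list[SetResult]:
    """Univariate gene-set analysis: one main effect, one BH family."""
    if ranking.n_dims != 1:
        raise ValueError("run_uv_gsa requires a 1-dimensional ranking")
    if len(coll) == 0:
        raise ValueError("empty gene-set collection")
    ranking, coll, order = _prepare(ranking, coll, config)
    fits = []
    for set_id in order:
        mv = membership_vector(coll, set_id, ranking.universe)
        fit = fit_univariate(ranking.column(0), mv, ridge=config.ridge)
        fits.append((set_id, mv.n_members, fit))
    if not fits:
        return []
    padj_a = bh_adjust([f.p_alpha for _, _, f in fits])
    results = []
    for i, (set_id, size, fit) in enumerate(fits):
        signs = effective_signs(
            (fit.alpha, None, None),
            (padj_a[i], None, None),
            threshold=config.threshold,
        )
        results.append(
            SetResult(
                set_id=set_id,
                name=coll.description(set_id),
                size=size,
                fit=fit,
                padj_alpha=float(padj_a[i]),
                padj_beta=None,
                padj_gamma=None,
                pattern=classify(signs, fit),
            )
        )
    return results


def ellipse_summary(points, level: float = 0.95) -> EllipseSummary:
    """Confidence-ellipse summary of a 2-D point cloud.

    Used for the module-versus-background diagnostic plots: one ellipse for
    all genes, one for the module's genes, each delimiting the region at
    squared Mahalanobis distance up to the chi-square(2) quantile at
    ``level``.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise InsufficientDataError("ellipse summary needs at least 3 points")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    degenerate = bool(np.linalg.matrix_rank(cov) < 2)
    if degenerate:
        logger.warning("degenerate ellipse: covariance is rank-deficient")
    return EllipseSummary(
        mean=mean, covariance=cov, confidence_level=level, degenerate=degenerate
    )


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{x:.6g}"


def results_frame(results: list[SetResult]) -> pd.DataFrame:
    """Flatten results into the standard 17-column table."""
    rows = []
    for r in results:
        f = r.fit
        rows.append(
            {
                "set_id": r.set_id,
                "name": r.name,
                "size": r.size,
                "lor_X": f.alpha,
                "lor_Y": f.beta,
                "lor_I": f.gamma,
                "se_X": f.se_alpha,
                "se_Y": f.se_beta,
                "se_I": f.se_gamma,
                "p_X": f.p_alpha,
                "p_Y": f.p_beta,
                "p_I": f.p_gamma,
                "padj_X": r.padj_alpha,
                "padj_Y": r.padj_beta,
                "padj_I": r.padj_gamma,
                "pattern": str(r.pattern),
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: list[SetResult], path) -> None:
    """Write the result table as TSV with 6-significant-digit numbers."""
    df = results_frame(results)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for _, row in df.iterrows():
            cells = [
                str(row["set_id"]),
                str(row["name"]),
                str(int(row["size"])),
                *(
                    _fmt(row[c])
                    for c in RESULT_COLUMNS[3:15]
                ),
                str(row["pattern"]),
                str(bool(row["converged"])),
            ]
            fh.write("\t".join(cells) + "\n")


def read_results(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
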