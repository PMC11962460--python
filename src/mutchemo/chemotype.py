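"""Metabolite-panel chemotyping: PCA classification, markers, group tests.

A targeted peak-area table (replicates x metabolites) is autoscaled and
projected onto two principal components; mutant lines are then binned by
nearest reference-chemotype centroid in score space, with lines far from
every reference flagged as novel.  Marker metabolites distinguishing two
groups are ranked by Welch t statistic; figure-style pairwise comparisons
use the classical equal-variance Student t test; Mendelian segregation
ratios are tested with a Pearson chi-square goodness of fit.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: non-feature columns of a peak table
METADATA_COLUMNS = ("line_id", "replicate", "class_label")

_FEATURE_RE = re.compile(r"^m\d+$")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Metabolite columns of a peak table (``m01``-style ids)."""
    return [c for c in table.columns if _FEATURE_RE.match(str(c))]


def validate_peak_table(table: pd.DataFrame) -> list[str]:
    """Check basic peak-table structure; returns the feature columns."""
    feats = feature_columns(table)
    if not feats:
        raise ValueError("peak table has no metabolite columns (m01, m02, ...)")
    if (table[feats].to_numpy(dtype=float) < 0).any():
        raise ValueError("peak areas must be non-negative")
    return feats


@dataclass(frozen=True)
class PcaModel:
    """Autoscaling parameters plus the leading principal components."""

    features: tuple[str, ...]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # shape (k, n_features)
    explained_variance_ratio: np.ndarray

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        x = (table[list(self.features)].to_numpy(dtype=float) - self.means) / self.scales
        scores = x @ self.loadings.T
        cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
        return pd.DataFrame(scores, index=table.index, columns=cols)


@dataclass(frozen=True)
class ChemotypeAssignment:
    line_id: str
    assigned_locus: str  # a reference locus id or "novel"
    distance: float
    scores: tuple[float, ...]


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    ratio: tuple[float, ...]
    chi_square: float
    df: int
    p_value: float


def fit_pca(
    table: pd.DataFrame, n_components: int = 2, log_transform: bool = False
) -> tuple[PcaModel, pd.DataFrame]:
    """Autoscale (unit-variance) the panel and fit a k-component PCA.

    Zero-variance metabolites are dropped with a warning; ``log_transform``
    applies log10(area + 1) before scaling.  Returns the fitted model and
    the per-row score table (columns PC1..PCk).
    """
    feats = validate_peak_table(table)
    x = table[feats].to_numpy(dtype=float)
    if log_transform:
        x = np.log10(x + 1.0)
    if x.shape[0] < n_components + 1:
        raise ValueError(f"need >= {n_components + 1} rows to fit {n_components} components")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all metabolites are constant; PCA undefined")
    if (~keep).any():
        dropped = [f for f, k in zip(feats, keep) if not k]
        logger.warning("dropping zero-variance metabolites: %s", dropped)
    feats = [f for f, k in zip(feats, keep) if k]
    if len(feats) < n_components:
        raise ValueError("fewer varying metabolites than requested components")
    x = x[:, keep]
    means = x.mean(axis=0)
    scales = sd[keep]
    z = (x - means) / scales
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    model = PcaModel(
        features=tuple(feats),
        means=means,
        scales=scales,
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
    score_df = pd.DataFrame(
        scores, index=table.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    for col in METADATA_COLUMNS:
        if col in table.columns:
            score_df[col] = table[col].to_numpy()
    return model, score_df


def _score_matrix(scores: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(scores, pd.DataFrame):
        cols = [c for c in scores.columns if str(c).startswith("PC")]
        return scores[cols].to_numpy(dtype=float)
    return np.asarray(scores, dtype=float)


def assign_chemotype(
    query_scores: pd.DataFrame,
    references: Mapping[str, np.ndarray | pd.DataFrame],
    threshold_factor: float = 3.0,
) -> list[ChemotypeAssignment]:
    """Assign each query line to its nearest reference-chemotype centroid.

    ``query_scores`` is a score table with a ``line_id`` column (one row per
    replicate); a line is placed at the mean of its replicate scores.
    ``references`` maps locus id to an (n_replicates, k) array of reference
    score points.  A line is "novel" when its centroid distance exceeds
    ``threshold_factor`` times the median within-reference replicate
    distance.  With no references every line is novel.
    """
    if "line_id" not in query_scores.columns:
        raise ValueError("query score table must carry a line_id column")

    centroids: dict[str, np.ndarray] = {}
    within: list[float] = []
    for locus in sorted(references):
        pts = _score_matrix(references[locus])
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise ValueError(f"reference {locus!r} needs >= 2 replicate score points")
        centroid = pts.mean(axis=0)
        centroids[locus] = centroid
        within.extend(np.linalg.norm(pts - centroid, axis=1))
    threshold = threshold_factor * float(np.median(within)) if within else 0.0

    assignments: list[ChemotypeAssignment] = []
    for line_id, group in query_scores.groupby("line_id", sort=True):
        point = _score_matrix(group).mean(axis=0)
        if not centroids:
            assignments.append(
                ChemotypeAssignment(str(line_id), "novel", float("inf"), tuple(point))
            )
            continue
        best_locus, best_dist = min(
            ((locus, float(np.linalg.norm(point - c))) for locus, c in centroids.items()),
            key=lambda pair: (pair[1], pair[0]),
        )
        locus = best_locus if best_dist <= threshold else "novel"
        assignments.append(ChemotypeAssignment(str(line_id), locus, best_dist, tuple(point)))
    return assignments


def _group_rows(table: pd.DataFrame, group: str) -> pd.DataFrame:
    if "class_label" in table.columns and (table["class_label"] == group).any():
        return table[table["class_label"] == group]
    if "line_id" in table.columns and (table["line_id"] == group).any():
        return table[table["line_id"] == group]
    raise ValueError(f"group {group!r} matches no class_label or line_id")


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / len(a) + vb / len(b))
    if denom == 0:
        return 0.0 if ma == mb else np.inf if mb > ma else -np.inf
    return float((mb - ma) / denom)


def rank_markers(
    table: pd.DataFrame, group_a: str, group_b: str, top_n: int = 240
) -> pd.DataFrame:
    """Rank metabolites separating two groups by |Welch t|, ties by |log2 FC|.

    Returns the ``top_n`` features with columns (metabolite, t_stat,
    fold_change, log2_fold_change, rank); fold change is mean_b / mean_a.
    """
    feats = validate_peak_table(table)
    rows_a = _group_rows(table, group_a)
    rows_b = _group_rows(table, group_b)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    records = []
    for feat in feats:
        a = rows_a[feat].to_numpy(dtype=float)
        b = rows_b[feat].to_numpy(dtype=float)
        t = _welch_t(a, b)
        fc = b.mean() / a.mean() if a.mean() != 0 else np.inf if b.mean() > 0 else 1.0
        log2fc = np.log2(fc) if 0 < fc < np.inf else np.sign(fc - 1) * np.inf if fc != 1 else 0.0
        records.append((feat, t, fc, log2fc))
    ranking = pd.DataFrame(
        records, columns=["metabolite", "t_stat", "fold_change", "log2_fold_change"]
    )
    ranking["_abs_t"] = ranking["t_stat"].abs()
    ranking["_abs_lfc"] = ranking["log2_fold_change"].abs()
    ranking = ranking.sort_values(
        ["_abs_t", "_abs_lfc", "metabolite"], ascending=[False, False, True]
    ).drop(columns=["_abs_t", "_abs_lfc"])
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    if top_n > len(ranking):
        logger.warning("top_n=%d exceeds %d features; returning all", top_n, len(ranking))
    return ranking.head(top_n).reset_index(drop=True)


def compare_groups(
    table: pd.DataFrame, metabolite: str, group_a: str, group_b: str
) -> tuple[float, float, float]:
    """Two-sided equal-variance Student t test on raw peak areas.

    Returns (fold change mean_b/mean_a, t statistic, p value).  Two groups
    with zero variance and equal means give p = 1.
    """
    if metabolite not in table.columns:
        raise ValueError(f"unknown metabolite {metabolite!r}")
    a = _group_rows(table, group_a)[metabolite].to_numpy(dtype=float)
    b = _group_rows(table, group_b)[metabolite].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    fc = b.mean() / a.mean() if a.mean() != 0 else np.inf
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return fc, 0.0, 1.0
        return fc, np.inf if b.mean() > a.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(b, a, equal_var=True)
    return fc, float(t), float(p)


def segregation_test(
    counts: Sequence[int], ratio: Sequence[float] = (1, 2, 1)
) -> SegregationResult:
    """Pearson chi-square goodness of fit of genotype counts to a Mendelian ratio.

    For the default 1:2:1 ratio of an F2 (hom WT : het : hom mutant) the test
    has 2 degrees of freedom.
    """
    counts = tuple(int(c) for c in counts)
    ratio = tuple(float(r) for r in ratio)
    if len(counts) != len(ratio):
        raise ValueError(f"{len(counts)} counts but {len(ratio)} ratio terms")
    if any(c < 0 for c in counts) or sum(counts) <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    total = sum(counts)
    expected = tuple(total * r / sum(ratio) for r in ratio)
    chi2, p = stats.chisquare(counts, f_exp=expected)
    return SegregationResult(
        observed=counts,
        expected=expected,
        ratio=ratio,
        chi_square=float(chi2),
        df=len(counts) - 1,
        p_value=float(p),
    )
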