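"""Ligand chemical-space profiling by descriptor PCA.

Six simple molecular descriptors per compound — molecular weight (Da),
ALogP, polar surface area (Å²), rotatable-bond count, H-bond donor and
acceptor counts — are pooled across the selected Pfam families, trimmed
of distribution outliers (1st/99th percentile, two-tailed, any-descriptor
rule), centred and scaled to unit variance, and decomposed by PCA.  The
first principal component projects each family's ligand set onto one
axis; pairwise Welch t-tests with Bonferroni correction quantify whether
family ligand sets occupy distinct descriptor space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import DESCRIPTOR_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "PcaResult",
    "ChemicalSpacePCA",
    "trim_outliers",
    "scale_unit_variance",
    "pca",
    "project_and_test",
]


@dataclass(frozen=True)
class PcaResult:
    """PCA of the scaled descriptor matrix.

    ``loadings`` has one column per component (PC1..PCk); columns are
    orthonormal and signed so each column's largest-magnitude entry is
    positive.  ``scores`` are the row projections; ``explained_variance``
    are the component variances (non-increasing).
    """

    loadings: pd.DataFrame
    explained_variance: np.ndarray
    scores: pd.DataFrame

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.explained_variance.sum()
        return self.explained_variance / total if total > 0 else self.explained_variance


def trim_outliers(
    table: pd.DataFrame,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
) -> pd.DataFrame:
    """Drop rows with any descriptor outside its [low_pct, high_pct] band.

    Percentiles are computed per column over the full input; a row is
    removed iff ANY of its descriptor values falls strictly below the low
    or strictly above the high percentile.  Single pass by contract:
    trimming the trimmed table would move the percentiles again.
    """
    if table.empty:
        raise ValueError("cannot trim an empty descriptor table")
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    lo = table.quantile(low_pct / 100.0)
    hi = table.quantile(high_pct / 100.0)
    keep = ((table >= lo) & (table <= hi)).all(axis=1)
    return table.loc[keep]


def scale_unit_variance(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Centre each descriptor and scale to unit sample variance (ddof=1).

    Returns (scaled, mean, sd).  A zero-variance column is an error: it
    carries no information and would divide by zero.
    """
    mean = table.mean()
    sd = table.std(ddof=1)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance descriptor column(s): {', '.join(map(str, dead))}")
    return (table - mean) / sd, mean, sd


def pca(scaled: pd.DataFrame | np.ndarray) -> PcaResult:
    """Eigendecomposition of the sample covariance of the scaled matrix.

    Components are ordered by decreasing variance; each loading column is
    signed so that its largest-magnitude element is positive, making
    loadings comparable across runs.  Rank-deficient input still returns,
    with (near-)zero trailing variances.
    """
    if isinstance(scaled, pd.DataFrame):
        X = scaled.to_numpy(dtype=float)
        var_names = list(scaled.columns)
        index = scaled.index
    else:
        X = np.asarray(scaled, dtype=float)
        var_names = [f"x{i+1}" for i in range(X.shape[1])]
        index = pd.RangeIndex(X.shape[0])
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    Xc = X - X.mean(axis=0)
    # SVD of the centred matrix: numerically safer than forming X'X
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    explained = svals**2 / (n - 1)
    loadings = vt.T
    # sign convention: largest-|.| element of each column positive
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = Xc @ loadings
    comp_names = [f"PC{j+1}" for j in range(loadings.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=var_names, columns=comp_names),
        explained_variance=explained,
        scores=pd.DataFrame(scores, index=index, columns=comp_names),
    )


def project_and_test(
    result: PcaResult,
    labels: Mapping | pd.Series,
    min_members: int = 3,
    component: str = "PC1",
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-family PC1 score sets and pairwise Bonferroni-corrected t-tests.

    Welch's unequal-variance two-sample t-test is applied to every pair of
    families with at least ``min_members`` scored compounds; raw p-values
    are multiplied by the number of pairs and capped at 1.  Returns
    (family -> scores array, test table with columns family_a, family_b,
    t_statistic, p_raw, p_bonferroni).
    """
    labels = pd.Series(labels)
    scores = result.scores[component]
    common = scores.index.intersection(labels.index)
    groups: dict[str, np.ndarray] = {}
    for fam, idx in labels.loc[common].groupby(labels.loc[common]).groups.items():
        vals = scores.loc[idx].to_numpy()
        if vals.size < min_members:
            logger.warning("family %s has %d scored compounds (< %d); excluded",
                           fam, vals.size, min_members)
            continue
        groups[str(fam)] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 families with enough compounds")
    pairs = list(combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append((a, b, float(t), float(p), min(float(p) * len(pairs), 1.0)))
    table = pd.DataFrame(
        rows, columns=["family_a", "family_b", "t_statistic", "p_raw", "p_bonferroni"]
    )
    return groups, table


class ChemicalSpacePCA(BaseEstimator, TransformerMixin):
    """Transformer: percentile trimming -> unit-variance scaling -> PCA.

    Parameters
    ----------
    low_pct, high_pct : float, defaults 1 and 99
        Two-tailed percentile band; rows with any descriptor outside the
        band are dropped before scaling (fit only — transform scores any
        row with the fitted scaling).
    columns : sequence of str, optional
        Descriptor columns to use; defaults to the six standard ones when
        present, else all numeric columns.

    Attributes
    ----------
    mean_, scale_ : per-descriptor centring and scaling (post-trim).
    loadings_ : DataFrame, descriptors x components.
    explained_variance_, explained_variance_ratio_ : component variances.
    result_ : PcaResult on the trimmed training rows.
    trimmed_index_ : index of rows retained by the outlier trim.
    """

    def __init__(self, low_pct: float = 1.0, high_pct: float = 99.0,
                 columns: Sequence[str] | None = None):
        self.low_pct = low_pct
        self.high_pct = high_pct
        self.columns = columns

    def _select(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.columns is not None:
            return X[list(self.columns)]
        if all(c in X.columns for c in DESCRIPTOR_COLUMNS):
            return X[list(DESCRIPTOR_COLUMNS)]
        return X.select_dtypes("number")

    def fit(self, X: pd.DataFrame, y=None) -> "ChemicalSpacePCA":
        table = self._select(X).astype(float)
        trimmed = trim_outliers(table, self.low_pct, self.high_pct)
        scaled, mean, sd = scale_unit_variance(trimmed)
        self.mean_ = mean
        self.scale_ = sd
        self.trimmed_index_ = trimmed.index
        self.result_ = pca(scaled)
        self.loadings_ = self.result_.loadings
        self.explained_variance_ = self.result_.explained_variance
        self.explained_variance_ratio_ = self.result_.explained_variance_ratio
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "loadings_"):
            raise RuntimeError("ChemicalSpacePCA is not fitted")
        table = self._select(X).astype(float)
        scaled = (table - self.mean_) / self.scale_
        scores = scaled.to_numpy() @ self.loadings_.to_numpy()
        return pd.DataFrame(scores, index=table.index, columns=self.loadings_.columns)
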