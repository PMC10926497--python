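"""Marker ranking statistics: normalization, Kruskal-Wallis, PLS-DA VIP, PCA.

Preprocessing follows the metabolomics-style convention: each sample row
is divided by its row sum, natural-log transformed with a small pseudo
value guarding zeros, and each marker column is autoscaled (mean-centred,
unit variance; constant columns are left at zero). Missing cells are
imputed beforehand as half the smallest observed positive value of that
marker.

Kruskal-Wallis gives a tie-corrected H per marker with a chi-squared
p-value on groups-1 degrees of freedom (descriptive; no multiple-testing
correction by default, a Benjamini-Hochberg option exists). PLS-DA fits a
PLS2 regression (NIPALS) against the one-hot group matrix and reports VIP
scores, whose squares average to 1 over markers. PCA is a singular-value
decomposition of the autoscaled matrix with percent variance explained
per component and optional collapsing of sample scores to group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.cross_decomposition import PLSRegression

from .io_formats import MarkerTable

__all__ = [
    "NormalizedMatrix",
    "KruskalResult",
    "PlsdaResult",
    "PcaResult",
    "normalize",
    "kruskal_wallis",
    "plsda_vip",
    "pca",
    "top_markers",
]


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame
    groups: pd.Series
    sum_normalized: bool = True
    log_transformed: bool = True
    autoscaled: bool = True
    imputed_cells: list[tuple[str, str]] = None   # (sample, marker) log

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class KruskalResult:
    """Per-marker tie-corrected H, df = groups - 1, chi-squared p-value."""

    table: pd.DataFrame   # index marker; columns H, df, p (and p_adj if requested)

    def __getitem__(self, marker: str) -> tuple[float, int, float]:
        row = self.table.loc[marker]
        return float(row["H"]), int(row["df"]), float(row["p"])


@dataclass
class PlsdaResult:
    scores: pd.DataFrame       # samples x components
    weights: pd.DataFrame      # markers x components
    vip: pd.Series             # per marker


@dataclass
class PcaResult:
    variance_pct: np.ndarray   # per component, sums to 100 over all
    scores: pd.DataFrame       # samples x components
    group_scores: pd.DataFrame | None


def _impute(values: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    out = values.copy()
    log: list[tuple[str, str]] = []
    for marker in out.columns:
        col = out[marker]
        if col.isna().any():
            positive = col[col > 0]
            fill = positive.min() / 2.0 if len(positive) else 0.0
            for sample in col.index[col.isna()]:
                out.loc[sample, marker] = fill
                log.append((sample, marker))
    return out, log


def autoscale(values: pd.DataFrame) -> pd.DataFrame:
    centred = values - values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0   # constant columns stay at zero after centring
    return centred / sd


def normalize(table: MarkerTable) -> NormalizedMatrix:
    """Sum-normalize rows, ln-transform, autoscale columns.

    Missing cells are imputed first (half the marker's smallest positive
    value); an all-zero sample row is an error since it cannot be
    sum-normalized.
    """
    if len(table.samples) < 2:
        raise ValueError("need at least 2 samples")
    values, imputed = _impute(table.values)
    row_sums = values.sum(axis=1)
    zero_rows = row_sums[row_sums == 0]
    if len(zero_rows):
        raise ValueError(f"sample {zero_rows.index[0]!r} has an all-zero marker row")
    rel = values.div(row_sums, axis=0)
    pseudo = 1e-9 * float(np.nanmax(rel.to_numpy()))
    logged = np.log(rel + pseudo)
    scaled = autoscale(logged)
    return NormalizedMatrix(scaled, table.groups.copy(), imputed_cells=imputed)


def kruskal_wallis(matrix: NormalizedMatrix | MarkerTable,
                   groups: pd.Series | None = None,
                   benjamini_hochberg: bool = False) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H and chi-squared p per marker.

    A marker whose observations are all identical is reported as H = 0,
    p = 1 (the tie-correction denominator vanishes there).
    """
    values = matrix.values
    groups = matrix.groups if groups is None else groups
    names = sorted(groups.unique())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    records = []
    df = len(names) - 1
    for marker in values.columns:
        samples = [values.loc[groups == g, marker].to_numpy() for g in names]
        if np.ptp(np.concatenate(samples)) == 0:
            records.append((marker, 0.0, df, 1.0))
            continue
        H, p = sp_stats.kruskal(*samples)
        records.append((marker, float(H), df, float(p)))
    table = pd.DataFrame(records, columns=["marker", "H", "df", "p"]).set_index("marker")
    if benjamini_hochberg:
        table["p_adj"] = sp_stats.false_discovery_control(table["p"], method="bh")
    return KruskalResult(table)


def plsda_vip(matrix: NormalizedMatrix, groups: pd.Series | None = None,
              n_components: int | None = None) -> PlsdaResult:
    """PLS-DA (PLS2 on the one-hot group matrix) with VIP scores.

    VIP_j = sqrt(p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a) with
    SSY_a the Y sum of squares captured by component a, so the squared
    VIPs sum to the number of markers.
    """
    X = matrix.values.to_numpy(dtype=float)
    groups = matrix.groups if groups is None else groups
    names = sorted(groups.unique())
    if len(names) < 2:
        raise ValueError("PLS-DA needs at least 2 groups")
    Y = np.array([[1.0 if g == name else 0.0 for name in names] for g in groups])
    n, p = X.shape
    a_max = min(5, n - 1, p)
    a = a_max if n_components is None else n_components
    if not 1 <= a <= min(n - 1, p):
        raise ValueError("n_components out of range")
    pls = PLSRegression(n_components=a, scale=False)
    pls.fit(X, Y)
    W = pls.x_weights_            # p x a
    T = pls.x_scores_             # n x a
    Q = pls.y_loadings_           # classes x a
    ssy = np.array([
        (T[:, k] @ T[:, k]) * (Q[:, k] @ Q[:, k]) for k in range(a)])
    if ssy.sum() == 0:
        raise ValueError("PLS-DA captured no group variance")
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (Wn**2 @ ssy) / ssy.sum())
    comp_names = [f"comp{k+1}" for k in range(a)]
    return PlsdaResult(
        scores=pd.DataFrame(T, index=matrix.values.index, columns=comp_names),
        weights=pd.DataFrame(W, index=matrix.values.columns, columns=comp_names),
        vip=pd.Series(vip, index=matrix.values.columns, name="VIP"),
    )


def pca(matrix: NormalizedMatrix, collapse_groups: bool = False) -> PcaResult:
    """SVD-based principal component analysis of the autoscaled matrix."""
    values = matrix.values
    if len(values) < 2:
        raise ValueError("need at least 2 samples")
    X = autoscale(values).to_numpy(dtype=float)
    nonconstant = int((X.std(axis=0) > 0).sum())
    if nonconstant < 2:
        raise ValueError("need at least 2 non-constant markers")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    variance_pct = 100.0 * var / var.sum()
    scores = U * s
    comp_names = [f"PC{k+1}" for k in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, index=values.index, columns=comp_names)
    group_scores = None
    if collapse_groups:
        group_scores = scores_df.groupby(matrix.groups).mean()
    return PcaResult(variance_pct, scores_df, group_scores)


def top_markers(kw: KruskalResult, vip: PlsdaResult, k: int = 5) -> list[str]:
    """Markers ranked by (-log10 p from Kruskal-Wallis, then VIP), top k."""
    markers = list(kw.table.index)
    if set(markers) != set(vip.vip.index):
        raise ValueError("Kruskal-Wallis and VIP marker sets differ")
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(kw.table["p"].to_numpy())
    order = sorted(
        markers,
        key=lambda m: (-neglogp[markers.index(m)], -float(vip.vip[m]), m))
    return order[:max(k, 0)]
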