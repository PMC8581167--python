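"""Statistical layer: patterning comparisons and phenotypic outlier calling.

Three decision rules operate on different views of the data:

* spatial patterning — two-sample Kolmogorov-Smirnov on the radial
  distances of marker-positive nuclei; lines whose distribution differs
  from the designated control line at p < 0.01 are radial outliers;
* mean expression — colony percent-positive values of one line against all
  other lines pooled, two-tailed Student's t, outlier at p < 0.001;
* panel-wide differences — Kruskal-Wallis omnibus across lines with Dunn's
  rank-based post hoc pairwise comparisons (Bonferroni-adjusted).

Spearman rank correlations relate the markers' percent-positive values
across colonies, and a standardised PCA of per-line percent-positive
features places clonal lines from one donor near each other.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = ["StatsResult", "ks_radial_compare", "kruskal_dunn", "dunn_posthoc",
           "outlier_mean_expression", "outlier_radial", "marker_correlations",
           "pca_lines"]

ALPHA_OMNIBUS = 0.05
ALPHA_MEAN_OUTLIER = 0.001
ALPHA_RADIAL_OUTLIER = 0.01


@dataclass(frozen=True)
class StatsResult:
    test: str
    statistic: float
    pvalue: float
    description: str = ""
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p value must be in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def ks_radial_compare(distances_a: np.ndarray, distances_b: np.ndarray,
                      marker: str = "", min_positive: int = 10,
                      alpha: float = ALPHA_RADIAL_OUTLIER,
                      labels: tuple[str, str] = ("A", "B")) -> StatsResult:
    """Two-sample KS test on radial distances of marker-positive nuclei."""
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    for arr, name in ((a, labels[0]), (b, labels[1])):
        if arr.size < min_positive:
            raise ValueError(
                f"group {name} has {arr.size} positive nuclei; need >= {min_positive}")
    res = sps.ks_2samp(a, b)
    return StatsResult(test="ks", statistic=float(res.statistic), pvalue=float(res.pvalue),
                       description=f"{marker} radial distance {labels[0]} vs {labels[1]}",
                       alpha=alpha)


def _rank_with_ties(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after a Kruskal-Wallis omnibus.

    z for a pair (i, j) is the difference in mean ranks over the pooled
    sample divided by its standard error with tie correction
    ``sum(t^3 - t) / (12 (N - 1))``. Two-sided p values are adjusted for the
    number of pairs (Bonferroni by default, Holm optional).
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = _rank_with_ties(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g, v in zip(names, values):
        mean_ranks[g] = ranks[start:start + v.size].mean()
        sizes[g] = v.size
        start += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    pairs = list(itertools.combinations(names, 2))
    for g1, g2 in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    m = len(pairs)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p_raw"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(out["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_adj"] = adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def kruskal_dunn(values_by_line: dict[str, np.ndarray], marker: str = "",
                 alpha: float = ALPHA_OMNIBUS,
                 adjust: str = "bonferroni") -> tuple[StatsResult, pd.DataFrame]:
    """Kruskal-Wallis across lines plus Dunn's pairwise post hoc table."""
    if len(values_by_line) < 3:
        raise ValueError("need >= 3 lines for the omnibus comparison")
    for line, v in values_by_line.items():
        if np.asarray(v).size < 3:
            raise ValueError(f"line {line} has fewer than 3 colonies")
    h, p = sps.kruskal(*[np.asarray(v, dtype=float) for v in values_by_line.values()])
    omnibus = StatsResult(test="kruskal", statistic=float(h), pvalue=float(p),
                          description=f"{marker} percent-positive across lines", alpha=alpha)
    pairwise = dunn_posthoc({k: np.asarray(v, dtype=float)
                             for k, v in values_by_line.items()}, adjust=adjust)
    return omnibus, pairwise


def outlier_mean_expression(target_values: np.ndarray, pooled_values: np.ndarray,
                            line: str = "", marker: str = "",
                            alpha: float = ALPHA_MEAN_OUTLIER,
                            equal_var: bool = True, min_pool: int = 10) -> StatsResult:
    """Pooled-t outlier rule: one line's colonies vs all other lines' colonies.

    Student's (pooled-variance) two-tailed t by default; Welch via
    ``equal_var=False``. The target line must not be part of the pool.
    """
    t_vals = np.asarray(target_values, dtype=float)
    p_vals = np.asarray(pooled_values, dtype=float)
    if t_vals.size < 3:
        raise ValueError("target line needs >= 3 colonies")
    if p_vals.size < min_pool:
        raise ValueError(f"pooled comparison group needs >= {min_pool} colonies")
    if np.var(t_vals) == 0 and np.var(p_vals) == 0:
        raise ValueError("zero variance in both groups; t statistic undefined")
    res = sps.ttest_ind(t_vals, p_vals, equal_var=equal_var)
    return StatsResult(test="pooled_t", statistic=float(res.statistic),
                       pvalue=float(res.pvalue),
                       description=f"{marker} mean expression: {line} vs pooled lines",
                       alpha=alpha)


def outlier_radial(target_distances: np.ndarray, control_distances: np.ndarray,
                   line: str = "", control_line: str = "", marker: str = "",
                   alpha: float = ALPHA_RADIAL_OUTLIER) -> StatsResult:
    """Radial-patterning outlier rule: KS of a line against the control line."""
    res = ks_radial_compare(target_distances, control_distances, marker=marker,
                            alpha=alpha, labels=(line or "target", control_line or "control"))
    return StatsResult(test="ks_vs_control", statistic=res.statistic, pvalue=res.pvalue,
                       description=res.description, alpha=alpha)


def marker_correlations(percent_positive: pd.DataFrame, min_obs: int = 5) -> pd.DataFrame:
    """Pairwise Spearman r between markers' percent-positive columns.

    Rows are observations (colonies by default, lines if pre-aggregated);
    a constant column yields NaN against every other marker.
    """
    df = percent_positive.select_dtypes("number")
    if len(df) < min_obs:
        raise ValueError(f"need >= {min_obs} observations, got {len(df)}")
    markers = list(df.columns)
    out = pd.DataFrame(np.eye(len(markers)), index=markers, columns=markers)
    for m1, m2 in itertools.combinations(markers, 2):
        x, y = df[m1].to_numpy(), df[m2].to_numpy()
        if np.all(x == x[0]) or np.all(y == y[0]):
            r = np.nan
        else:
            r = sps.spearmanr(x, y).statistic
        out.loc[m1, m2] = out.loc[m2, m1] = r
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray = field(default_factory=lambda: np.array([]))


def pca_lines(features: pd.DataFrame) -> PCAResult:
    """PCA of per-line percent-positive features (columns standardised).

    Index is the line id; columns are marker features. Variance explained
    sums to 1 across the returned components.
    """
    x = features.select_dtypes("number")
    if len(x) < 2:
        raise ValueError("PCA needs >= 2 observations")
    scaled = StandardScaler().fit_transform(x.to_numpy())
    pca = PCA()
    scores = pca.fit_transform(scaled)
    comp = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=x.index, columns=comp),
        loadings=pd.DataFrame(pca.components_.T, index=x.columns, columns=comp),
        variance_explained=pca.explained_variance_ratio_,
    )
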