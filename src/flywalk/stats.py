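"""Group-level statistics on the 17-parameter behavioral description.

Rank-sum panels with Bonferroni correction, the pairwise Pearson correlation
screen, PCA variance profiles, and canonical variate analysis (CVA) with a
label-shuffle permutation test. CVA finds the axes maximizing between-group
relative to within-group variance via the eigendecomposition of W^-1 B,
where W is the pooled within-group covariance and B the (group-size
weighted) covariance of group means about the grand mean; for g groups there
are g − 1 canonical dimensions. Significance of the group separation on the
first canonical variate is assessed by shuffling group labels and asking how
often the shuffled median distance exceeds the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps


# ---------------------------------------------------------------------------
# rank-sum panel


@dataclass
class TestPanel:
    """Per-parameter two-sided rank-sum tests with a Bonferroni flag."""

    table: pd.DataFrame  # parameter, statistic, p_value, n_a, n_b, significant
    alpha: float
    n_tests: int

    @property
    def cutoff(self) -> float:
        return self.alpha / self.n_tests


def _ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value, exact for small
    tie-free samples; degenerate all-tied data gives p = 1."""
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 0.0, 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def ranksum_panel(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    alpha: float = 0.05,
    min_n: int = 3,
) -> TestPanel:
    """Column-wise rank-sum tests between two feature tables
    (pairwise-complete: NaNs dropped per column); the Bonferroni flag uses
    alpha / (number of columns tested)."""
    cols = [c for c in group_a.columns if c in group_b.columns]
    m = len(cols)
    rows = []
    for col in cols:
        a = group_a[col].dropna().to_numpy(float)
        b = group_b[col].dropna().to_numpy(float)
        if len(a) < min_n or len(b) < min_n:
            rows.append((col, np.nan, np.nan, len(a), len(b), False))
            continue
        stat, p = _ranksum(a, b)
        rows.append((col, stat, p, len(a), len(b), p < alpha / m))
    table = pd.DataFrame(
        rows, columns=["parameter", "statistic", "p_value", "n_a", "n_b", "significant"]
    )
    return TestPanel(table=table, alpha=alpha, n_tests=m)


# ---------------------------------------------------------------------------
# correlation screen


def pairwise_correlations(
    m: pd.DataFrame, alpha: float = 0.05, bonferroni: bool = False, min_n: int = 5
) -> pd.DataFrame:
    """Pearson r for every unordered column pair (m(m−1)/2 pairs),
    pairwise-complete; ``significant`` uses unadjusted alpha by default
    (switchable to Bonferroni across pairs)."""
    cols = list(m.columns)
    n_pairs = len(cols) * (len(cols) - 1) // 2
    cutoff = alpha / n_pairs if bonferroni else alpha
    rows = []
    for ca, cb in combinations(cols, 2):
        sub = m[[ca, cb]].dropna()
        if len(sub) < min_n or sub[ca].nunique() < 2 or sub[cb].nunique() < 2:
            rows.append((ca, cb, np.nan, np.nan, len(sub), False))
            continue
        r, p = sps.pearsonr(sub[ca], sub[cb])
        rows.append((ca, cb, float(r), float(p), len(sub), p < cutoff))
    return pd.DataFrame(
        rows, columns=["param_a", "param_b", "r", "p_value", "n", "significant"]
    )


# ---------------------------------------------------------------------------
# PCA variance profile


def pca_variance(
    m: pd.DataFrame | np.ndarray, standardize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Variance fractions and loadings of the (standardized) covariance of
    complete-case rows.

    Returns (fractions, loadings) with fractions non-increasing and summing
    to 1; loadings[:, k] is the k-th principal axis.
    """
    x = pd.DataFrame(m).dropna().to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 complete rows")
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    cov = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    return evals / evals.sum(), evecs[:, order]


# ---------------------------------------------------------------------------
# canonical variate analysis


@dataclass
class CVAResults:
    """Fitted canonical variates.

    ``axes[:, k]`` is the k-th canonical axis (normalized to unit
    within-group variance, aᵀWa = 1); ``projections`` are per-row scores on
    the canonical axes; ``median_distance`` is the median over group pairs of
    |median(group i on CV1) − median(group j on CV1)| (for two groups simply
    the distance between the two group medians on CV1).
    """

    model: "CanonicalVariates"
    eigenvalues: np.ndarray
    axes: np.ndarray
    projections: np.ndarray
    groups: np.ndarray
    median_distance: float
    ridge_used: float
    permutation_p: float | None = None
    permutation_p_plus_one: float | None = None
    n_permutations: int | None = None
    permutation_seed: int | None = None
    null_distances: np.ndarray | None = None

    def permutation_test(
        self, n_permutations: int = 50_000, seed: int = 0
    ) -> "CVAResults":
        """Label-shuffle null for the CV1 median group distance.

        For each shuffle, group labels are permuted (the label multiset is
        preserved), the CVA refitted, and the CV1 median distance recorded.
        The primary p is the fraction of shuffled distances strictly greater
        than the observed one (ties count as non-exceeding); the
        (k+1)/(n+1) convention is reported alongside.
        """
        if n_permutations < 100:
            raise ValueError("use at least 100 permutations")
        rng = np.random.default_rng(seed)
        model = self.model
        null = np.empty(n_permutations)
        labels = model.group_codes.copy()
        for i in range(n_permutations):
            rng.shuffle(labels)
            null[i] = _cv1_median_distance(
                model.exog, labels, model.n_groups, self.ridge_used
            )
        k = int(np.sum(null > self.median_distance))
        self.null_distances = null
        self.permutation_p = k / n_permutations
        self.permutation_p_plus_one = (k + 1) / (n_permutations + 1)
        self.n_permutations = n_permutations
        self.permutation_seed = seed
        return self

    def summary(self) -> str:
        lines = [
            "Canonical Variate Analysis",
            "==========================",
            f"observations (complete rows): {self.projections.shape[0]}",
            f"groups: {self.model.n_groups} "
            f"({', '.join(map(str, self.model.group_names))})",
            f"canonical dimensions: {self.axes.shape[1]}",
            f"ridge: {self.ridge_used:g}",
            "eigenvalues: "
            + ", ".join(f"{v:.4g}" for v in self.eigenvalues),
            f"CV1 median group distance: {self.median_distance:.4g}",
        ]
        if self.permutation_p is not None:
            lines.append(
                f"permutation test: p = {self.permutation_p:.4g} "
                f"(strictly greater, {self.n_permutations} shuffles; "
                f"(k+1)/(n+1) = {self.permutation_p_plus_one:.4g}, "
                f"seed {self.permutation_seed})"
            )
        return "\n".join(lines)


class CanonicalVariates:
    """Canonical variate analysis of a feature matrix with group labels.

    Rows with any NaN are dropped (complete-case). ``fit`` solves the
    symmetric generalized eigenproblem B a = λ (W + ridge·I) a, equivalent to
    the eigendecomposition of W^-1 B but numerically symmetric; if W is
    singular at ridge 0, a minimal ridge is applied automatically and
    recorded on the results.
    """

    def __init__(
        self,
        data: pd.DataFrame | np.ndarray,
        groups: np.ndarray | list,
        ridge: float = 0.0,
    ):
        df = pd.DataFrame(data)
        groups = np.asarray(groups)
        if len(groups) != len(df):
            raise ValueError("groups must have one label per row")
        keep = ~df.isna().any(axis=1).to_numpy()
        self.exog = df.to_numpy(float)[keep]
        self.group_labels = groups[keep]
        self.group_names, self.group_codes = np.unique(
            self.group_labels, return_inverse=True
        )
        self.n_groups = len(self.group_names)
        self.ridge = ridge
        if self.n_groups < 2:
            raise ValueError("CVA needs at least 2 groups")
        counts = np.bincount(self.group_codes)
        if counts.min() < 2:
            raise ValueError("every group needs at least 2 complete rows")
        if self.exog.shape[0] <= self.n_groups:
            raise ValueError("not enough rows to estimate within-group covariance")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, group_col: str = "group", ridge: float = 0.0
    ) -> "CanonicalVariates":
        feat = df.drop(columns=[group_col])
        feat = feat.select_dtypes(include=[np.number])
        return cls(feat, df[group_col].to_numpy(), ridge=ridge)

    def fit(self) -> CVAResults:
        w, b = _scatter_matrices(self.exog, self.group_codes, self.n_groups)
        ridge = self.ridge
        evals = evecs = None
        for attempt in range(6):
            try:
                evals, evecs = linalg.eigh(b, w + ridge * np.eye(w.shape[0]))
                break
            except linalg.LinAlgError:
                base = np.trace(w) / w.shape[0]
                ridge = max(ridge, 1e-10 * max(base, 1.0)) * (10.0 if attempt else 1.0)
        if evals is None:
            raise linalg.LinAlgError("within-group covariance not invertible")
        order = np.argsort(evals)[::-1]
        n_dim = self.n_groups - 1
        evals = evals[order][:n_dim]
        axes = evecs[:, order][:, :n_dim]  # eigh normalizes aᵀ(W+ridge I)a = 1
        proj = self.exog @ axes
        dist = _median_group_distance(proj[:, 0], self.group_codes, self.n_groups)
        return CVAResults(
            model=self,
            eigenvalues=evals,
            axes=axes,
            projections=proj,
            groups=self.group_labels,
            median_distance=dist,
            ridge_used=ridge,
        )


def _scatter_matrices(
    x: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-group covariance W and group-size-weighted
    between-group covariance B of group means about the grand mean."""
    n, p = x.shape
    grand = x.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for g in range(n_groups):
        xg = x[codes == g]
        c = xg - xg.mean(axis=0)
        w += c.T @ c
        d = (xg.mean(axis=0) - grand)[:, None]
        b += len(xg) * (d @ d.T)
    w /= n - n_groups
    b /= n - 1
    return w, b


def _median_group_distance(cv1: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    medians = [np.median(cv1[codes == g]) for g in range(n_groups)]
    dists = [abs(ma - mb) for ma, mb in combinations(medians, 2)]
    return float(np.median(dists))


def _cv1_median_distance(
    x: np.ndarray, codes: np.ndarray, n_groups: int, ridge: float
) -> float:
    w, b = _scatter_matrices(x, codes, n_groups)
    try:
        evals, evecs = linalg.eigh(b, w + ridge * np.eye(w.shape[0]))
    except linalg.LinAlgError:
        base = np.trace(w) / w.shape[0]
        evals, evecs = linalg.eigh(
            b, w + max(1e-9 * max(base, 1.0), ridge) * np.eye(w.shape[0])
        )
    cv1 = x @ evecs[:, -1]  # eigh returns ascending order
    return _median_group_distance(cv1, codes, n_groups)


def cva(
    m: pd.DataFrame | np.ndarray,
    labels: np.ndarray | list,
    ridge: float = 0.0,
) -> CVAResults:
    """Functional front-end: fit canonical variates on a labeled feature
    matrix."""
    return CanonicalVariates(m, labels, ridge=ridge).fit()


def permutation_test(
    m: pd.DataFrame | np.ndarray,
    labels: np.ndarray | list,
    n_permutations: int = 50_000,
    seed: int = 0,
    ridge: float = 0.0,
) -> CVAResults:
    """Fit CVA and attach the label-shuffle permutation p-value for the CV1
    median group distance."""
    res = cva(m, labels, ridge=ridge)
    return res.permutation_test(n_permutations=n_permutations, seed=seed)
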