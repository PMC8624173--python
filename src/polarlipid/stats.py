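"""Statistical chain for the six-group extraction comparison.

Pipeline order is fixed: glog -> EigenMS -> autoscale -> PCA / tests; each
transformed matrix carries a provenance tag recording the stages applied, and
downstream stages enforce the order.

* glog: generalized logarithm g(x) = log2((x + sqrt(x^2 + lambda^2))/2),
  defined at zero; lambda defaults to the minimum positive matrix value.
* EigenMS: SVD-based removal of systematic bias eigentrends from the
  residual matrix (data minus per-species group means); the number of
  significant trends is chosen by a permutation test on singular values, and
  the estimated bias is re-centered within groups before subtraction so that
  group means are preserved exactly.
* autoscale: per-species mean 0 / SD 1 (ddof=1); zero-variance species are
  dropped with a warning.
* PCA on samples; variance explained per component = sigma_i^2 / sum sigma^2.
* Kruskal-Wallis across the six groups per species, Dunn pairwise post-hoc
  with tie-corrected variance, and Benjamini-Hochberg step-up q-values
  (Benjamini-Yekutieli available as an option).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA as _SKPCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TransformedMatrix", "PCAResult", "TestResult", "glog_transform",
    "eigenms_normalize", "autoscale", "pca", "kruskal_wallis", "dunn_posthoc",
    "bh_adjust", "class_abundances", "discriminant_species", "run_statistics",
    "DEFAULT_SEED",
]

log = logging.getLogger(__name__)

DEFAULT_SEED = 20211021


@dataclass
class TransformedMatrix:
    """Species x samples values plus the ordered provenance of applied stages."""
    data: pd.DataFrame
    stages: tuple[str, ...] = ()

    def require(self, *stages: str) -> None:
        if self.stages != tuple(stages):
            raise ValueError(
                f"pipeline order violated: expected stages {stages}, "
                f"got {self.stages}")


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # species x components
    variance_explained: np.ndarray  # percent, non-increasing


@dataclass
class TestResult:
    per_species: pd.DataFrame     # H, p, q indexed by species
    pairwise: pd.DataFrame        # species, group_a, group_b, z, p, p_adj


def glog_transform(matrix: pd.DataFrame | TransformedMatrix,
                   lam: float | None = None) -> TransformedMatrix:
    """Variance-stabilizing generalized log, defined at x = 0."""
    if isinstance(matrix, TransformedMatrix):
        matrix.require()
        df = matrix.data
    else:
        df = matrix
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("glog input must be non-negative")
    if lam is None:
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("matrix has no positive values to set lambda")
        lam = float(positive.min())
    if lam <= 0:
        raise ValueError("lambda must be positive")
    g = np.log2((x + np.sqrt(x * x + lam * lam)) / 2.0)
    return TransformedMatrix(pd.DataFrame(g, index=df.index, columns=df.columns),
                             stages=("glog",))


def _group_means(x: np.ndarray, groups: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    for g in np.unique(groups):
        idx = groups == g
        out[:, idx] = x[:, idx].mean(axis=1, keepdims=True)
    return out


def eigenms_normalize(matrix: TransformedMatrix,
                      group_labels: Sequence[str],
                      n_permutations: int = 500,
                      alpha: float = 0.05,
                      seed: int = DEFAULT_SEED,
                      max_trends: int | None = None) -> TransformedMatrix:
    """Remove systematic bias eigentrends while preserving group structure.

    Steps: (1) residuals after removing per-species group means; (2) SVD of
    the residual matrix; (3) the number of significant eigentrends is the
    count of leading singular values exceeding their permutation-null
    distribution at level ``alpha`` (rows of the residual matrix permuted
    independently); (4) the bias reconstructed from those trends is
    re-centered within groups and subtracted.
    """
    matrix.require("glog")
    df = matrix.data
    groups = np.asarray(group_labels)
    if len(groups) != df.shape[1]:
        raise ValueError("one group label per sample required")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    x = df.to_numpy(dtype=float)
    resid = x - _group_means(x, groups)
    rank = min(resid.shape)
    if max_trends is None:
        max_trends = rank
    if max_trends > rank:
        raise ValueError(f"requested {max_trends} trends exceeds rank {rank}")

    sv_obs = np.linalg.svd(resid, compute_uv=False)
    if sv_obs[0] <= 1e-12:
        log.info("EigenMS: residual matrix is zero; no trends removed")
        return TransformedMatrix(df.copy(), stages=("glog", "eigenms"))

    rng = np.random.default_rng(seed)
    n_signif = 0
    perm_sv = np.empty((n_permutations, rank))
    group_idx = [np.flatnonzero(groups == g) for g in np.unique(groups)]
    for b in range(n_permutations):
        # permute each species' residuals within groups: keeps the
        # zero-group-mean constraint (and each row's variance) intact while
        # breaking any sample-space alignment across species
        perm = resid.copy()
        for idx in group_idx:
            for row in perm:
                row[idx] = row[rng.permutation(idx)]
        perm_sv[b] = np.linalg.svd(perm, compute_uv=False)[:rank]
    for i in range(max_trends):
        p = (1.0 + np.sum(perm_sv[:, i] >= sv_obs[i])) / (n_permutations + 1.0)
        if p < alpha:
            n_signif += 1
        else:
            break
    log.info("EigenMS: %d significant eigentrend(s)", n_signif)
    if n_signif == 0:
        return TransformedMatrix(df.copy(), stages=("glog", "eigenms"))

    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    v = vt[:n_signif].T                       # samples x trends
    bias = resid @ v @ v.T                    # project residuals onto trends
    bias -= _group_means(bias, groups)        # exact group-mean preservation
    out = x - bias
    return TransformedMatrix(pd.DataFrame(out, index=df.index,
                                          columns=df.columns),
                             stages=("glog", "eigenms"))


def autoscale(matrix: TransformedMatrix) -> TransformedMatrix:
    """Per-species centering and unit-variance scaling (ddof=1)."""
    matrix.require("glog", "eigenms")
    df = matrix.data
    if df.shape[1] < 2:
        raise ValueError("autoscaling needs at least 2 samples")
    sd = df.std(axis=1, ddof=1)
    zero = sd <= 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} zero-variance species "
                      "before autoscaling", stacklevel=2)
    kept = df.loc[~zero]
    scaled = kept.sub(kept.mean(axis=1), axis=0).div(sd[~zero], axis=0)
    return TransformedMatrix(scaled, stages=("glog", "eigenms", "autoscale"))


def pca(matrix: TransformedMatrix | pd.DataFrame,
        n_components: int | None = None) -> PCAResult:
    """PCA of samples; variance explained in percent, non-increasing."""
    if isinstance(matrix, TransformedMatrix):
        matrix.require("glog", "eigenms", "autoscale")
        df = matrix.data
    else:
        df = matrix
    if df.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    x = df.to_numpy(dtype=float).T            # samples x species
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: all samples identical")
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    ncomp = scores.shape[1]
    comp_names = [f"PC{i+1}" for i in range(ncomp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=df.columns, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=df.index,
                              columns=comp_names),
        variance_explained=model.explained_variance_ratio_ * 100.0,
    )


def kruskal_wallis(values_by_group: Sequence[np.ndarray]) -> tuple[float, float]:
    """Rank-based H with tie correction; p from chi-square with k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(values_by_group: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise post-hoc z tests on mean ranks, tie-corrected.

    Returns all k(k-1)/2 pairs with two-sided p per pair (unadjusted here;
    multiplicity is handled downstream with the same BH correction used for
    the Kruskal-Wallis p-values).
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[n], dtype=float) for n in names]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group in Dunn post-hoc")
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    # tie correction to the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts)
    rows = []
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        var = (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))) \
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        diff = mean_ranks[i] - mean_ranks[j]
        z = 0.0 if var <= 0 else diff / np.sqrt(var)
        p = 1.0 if var <= 0 else float(2.0 * sps.norm.sf(abs(z)))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p": p})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])


def bh_adjust(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Step-up FDR-adjusted q-values (Benjamini-Hochberg; "by" for the
    Benjamini-Yekutieli variant), mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    mt_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    return multipletests(p, method=mt_method)[1]


def class_abundances(data: pd.DataFrame,
                     species_class: Mapping[str, str]) -> pd.DataFrame:
    """Class x sample matrix: sum of member-species abundances per sample."""
    unmapped = [s for s in data.index if s not in species_class]
    if unmapped:
        raise ValueError(f"species without class mapping: {unmapped[:5]}")
    cls = pd.Series({s: species_class[s] for s in data.index})
    out = data.groupby(cls).sum()
    out.index.name = "class_code"
    return out


def discriminant_species(tests: TestResult, pca_result: PCAResult,
                         q_threshold: float = 0.05,
                         top_n: int = 16) -> pd.DataFrame:
    """Significant species ranked by |PC1 loading|, truncated to top_n."""
    per = tests.per_species
    signif = per[per["q"] <= q_threshold]
    if signif.empty:
        return pd.DataFrame(columns=["species", "q", "pc1_loading"])
    load = pca_result.loadings["PC1"]
    rows = [{"species": name, "q": float(row["q"]),
             "pc1_loading": float(load.get(name, 0.0))}
            for name, row in signif.iterrows()]
    df = pd.DataFrame(rows)
    df["abs_loading"] = df["pc1_loading"].abs()
    df = df.sort_values(["abs_loading", "species"],
                        ascending=[False, True]).head(top_n)
    return df.drop(columns="abs_loading").reset_index(drop=True)


def run_statistics(data: pd.DataFrame, groups: pd.Series,
                   glog_lambda: float | None = None,
                   eigenms_permutations: int = 500,
                   eigenms_alpha: float = 0.05,
                   q_method: str = "bh",
                   seed: int = DEFAULT_SEED) -> dict:
    """The full chain on one abundance matrix; returns every intermediate.

    Output keys: transformed (TransformedMatrix), pca (PCAResult),
    tests (TestResult).
    """
    labels = groups.loc[data.columns]
    t = glog_transform(data, lam=glog_lambda)
    t = eigenms_normalize(t, labels.to_numpy(),
                          n_permutations=eigenms_permutations,
                          alpha=eigenms_alpha, seed=seed)
    t = autoscale(t)
    p = pca(t)

    group_names = sorted(labels.unique())
    h_rows, pair_rows = [], []
    for name, row in t.data.iterrows():
        by_group = {g: row[labels[labels == g].index].to_numpy()
                    for g in group_names}
        h, pval = kruskal_wallis(list(by_group.values()))
        h_rows.append({"species": name, "H": h, "p": pval})
        dunn = dunn_posthoc(by_group)
        dunn.insert(0, "species", name)
        pair_rows.append(dunn)
    per = pd.DataFrame(h_rows).set_index("species")
    per["q"] = bh_adjust(per["p"].to_numpy(), method=q_method)
    pairwise = pd.concat(pair_rows, ignore_index=True)
    pairwise["p_adj"] = bh_adjust(pairwise["p"].to_numpy(), method=q_method)
    return {"transformed": t, "pca": p,
            "tests": TestResult(per_species=per, pairwise=pairwise)}
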