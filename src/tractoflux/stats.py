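"""Multivariate statistics along fiber-bundle profiles.

Input is a bundle-profile array (subjects x nodes x metrics). The analysis
chain is: prune metrics whose pairwise correlation exceeds a threshold,
reduce the surviving metrics per bundle with PCA (keeping the smallest
number of components reaching a cumulative explained-variance target),
remove covariate influence (age, sex, center) by linear regression, then
test node by node — a two-sample Hotelling T^2 between groups, or a joint
F-test of the component coefficients in a linear model of a clinical score
(AES) — and control the family-wise error rate with a permutation
null distribution of the maximum suprathreshold cluster size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

__all__ = [
    "BundleProfile",
    "PcModel",
    "AlongTractResult",
    "prune_correlated",
    "fit_pca",
    "residualize",
    "hotelling_t2",
    "group_test_along_tract",
    "association_along_tract",
    "permutation_fwe",
    "contingency_chi2",
    "clusters_from_pvalues",
    "group_analysis",
    "aes_analysis",
]

DEFAULT_METRICS = ("FW", "FA", "MD", "AD", "RD")
DEFAULT_COVARIATES = ("age", "sex", "center")


@dataclass(frozen=True)
class BundleProfile:
    """subjects x nodes x metrics array with its labels."""

    data: np.ndarray
    subject_ids: tuple[str, ...]
    metric_names: tuple[str, ...]
    bundle: str = "bundle"

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("profile data must be subjects x nodes x metrics")
        if data.shape[0] != len(self.subject_ids) or data.shape[2] != len(self.metric_names):
            raise ValueError("dimensions inconsistent with subject/metric lists")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "metric_names", tuple(self.metric_names))

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class PcModel:
    retained_metrics: tuple[str, ...]
    loadings: np.ndarray            # metrics x L
    explained_variance_ratio: np.ndarray
    L: int
    mean: np.ndarray
    scale: np.ndarray


@dataclass(frozen=True)
class AlongTractResult:
    statistic: np.ndarray           # per-node T^2 (group) or F (association)
    pvalues: np.ndarray
    effect_size: np.ndarray         # nodes x L Cohen's d (group) or nodes r (association)
    cluster_forming_mask: np.ndarray
    fwe_cluster_size: int
    significant_mask: np.ndarray
    n_permutations: int
    null_max_cluster: np.ndarray
    cluster_pvalue: float           # permutation p of the observed max cluster


# ---------------------------------------------------------------------------
# metric pruning and PCA


def prune_correlated(profile: BundleProfile, threshold: float = 0.8):
    """Greedily drop metrics until all pairwise |r| <= threshold.

    Correlations are computed over the pooled subject x node observations.
    When a pair exceeds the threshold, the member with the larger mean |r|
    against all other metrics is removed (ties: the later metric in the
    listed order goes). Returns (retained metric names, full correlation
    matrix as a DataFrame).
    """
    if len(profile.metric_names) < 2:
        raise ValueError("need at least two metrics to prune")
    pooled = profile.data.reshape(-1, profile.data.shape[2])
    pooled = pooled[~np.isnan(pooled).any(axis=1)]
    corr = np.corrcoef(pooled, rowvar=False)
    corr_df = pd.DataFrame(corr, index=profile.metric_names, columns=profile.metric_names)

    names = list(profile.metric_names)
    active = list(range(len(names)))
    while len(active) > 1:
        sub = np.abs(corr[np.ix_(active, active)])
        np.fill_diagonal(sub, 0.0)
        if sub.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        mean_r = sub.sum(axis=1) / (len(active) - 1)
        # remove the more redundant member; ties broken by listed order
        if mean_r[i] > mean_r[j] or (mean_r[i] == mean_r[j] and active[i] > active[j]):
            drop = i
        else:
            drop = j
        del active[drop]
    if not active:
        raise ValueError("pruning removed every metric")
    return tuple(names[k] for k in active), corr_df


def fit_pca(profile: BundleProfile, var_target: float = 0.80,
            metrics: Sequence[str] | None = None):
    """PCA on pooled, z-scored subject x node observations of one bundle.

    Keeps the smallest L whose cumulative explained variance reaches
    ``var_target``. Components are sign-fixed so the largest-|loading|
    entry of each is positive. Returns (PcModel, scores array
    subjects x nodes x L with NaN where the profile was undefined).
    """
    names = tuple(metrics) if metrics is not None else profile.metric_names
    idx = [profile.metric_names.index(m) for m in names]
    data = profile.data[:, :, idx]
    S, N, M = data.shape
    pooled = data.reshape(S * N, M)
    ok = ~np.isnan(pooled).any(axis=1)
    obs = pooled[ok]
    if obs.shape[0] <= M:
        raise ValueError("not enough defined observations for PCA")
    mean = obs.mean(axis=0)
    scale = obs.std(axis=0, ddof=1)
    keep = scale > 0
    if not keep.all():
        names = tuple(n for n, k in zip(names, keep) if k)
        mean, scale = mean[keep], scale[keep]
        obs = obs[:, keep]
        pooled = pooled[:, keep]
        M = keep.sum()
    z = (obs - mean) / scale
    pca = PCA(n_components=M, svd_solver="full").fit(z)
    evr = pca.explained_variance_ratio_
    L = int(np.searchsorted(np.cumsum(evr), var_target) + 1)
    L = min(L, M)
    loadings = pca.components_[:L].T  # metrics x L
    # sign convention: dominant loading positive
    for c in range(L):
        if loadings[np.argmax(np.abs(loadings[:, c])), c] < 0:
            loadings[:, c] = -loadings[:, c]
    scores = np.full((S * N, L), np.nan)
    scores[ok] = ((pooled[ok] - mean) / scale) @ loadings
    model = PcModel(retained_metrics=names, loadings=loadings,
                    explained_variance_ratio=evr[:L], L=L, mean=mean, scale=scale)
    return model, scores.reshape(S, N, L)


# ---------------------------------------------------------------------------
# covariate removal


def design_matrix(meta: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES) -> np.ndarray:
    """Intercept + numeric/dummy-coded covariate columns."""
    cols = [np.ones(len(meta))]
    for c in covariates:
        col = meta[c]
        if col.dtype.kind in "if":
            cols.append(col.to_numpy(dtype=float))
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient covariate design for columns {list(covariates)}")
    return X


def residualize(scores: np.ndarray, meta: pd.DataFrame,
                covariates: Sequence[str] = DEFAULT_COVARIATES) -> np.ndarray:
    """OLS residuals of every node x component series on the covariates."""
    X = design_matrix(meta, covariates)
    S, N, L = scores.shape
    Y = scores.reshape(S, N * L)
    beta, *_ = np.linalg.lstsq(X, np.nan_to_num(Y), rcond=None)
    resid = Y - X @ beta
    resid[np.isnan(Y)] = np.nan
    return resid.reshape(S, N, L)


# ---------------------------------------------------------------------------
# Hotelling T^2


def hotelling_t2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sample Hotelling T^2 with pooled covariance.

    T^2 = n1 n2/(n1+n2) (xbar-ybar)' S^-1 (xbar-ybar); the F reference is
    F = T^2 (n1+n2-L-1) / (L (n1+n2-2)) with df (L, n1+n2-L-1). Reduces to
    the squared pooled two-sample t statistic when L = 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1, L = x.shape
    n2 = y.shape[0]
    if n1 + n2 <= L + 1:
        raise ValueError("too few subjects for the dimensionality")
    d = x.mean(axis=0) - y.mean(axis=0)
    cx = x - x.mean(axis=0)
    cy = y - y.mean(axis=0)
    S = (cx.T @ cx + cy.T @ cy) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular pooled covariance; reduce the number of "
                         "components (PCA)") from err
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    f = t2 * (n1 + n2 - L - 1) / (L * (n1 + n2 - 2))
    p = float(sps.f.sf(f, L, n1 + n2 - L - 1))
    return t2, f, p


def _hotelling_nodes(x: np.ndarray, y: np.ndarray):
    """Vectorized per-node Hotelling T^2. x: (n1, N, L), y: (n2, N, L)."""
    n1, N, L = x.shape
    n2 = y.shape[0]
    d = x.mean(axis=0) - y.mean(axis=0)               # (N, L)
    cx = x - x.mean(axis=0)
    cy = y - y.mean(axis=0)
    S = (np.einsum("inj,ink->njk", cx, cx) + np.einsum("inj,ink->njk", cy, cy)) / (n1 + n2 - 2)
    sol = np.linalg.solve(S, d[..., None])[..., 0]    # (N, L)
    t2 = n1 * n2 / (n1 + n2) * np.einsum("nj,nj->n", d, sol)
    f = t2 * (n1 + n2 - L - 1) / (L * (n1 + n2 - 2))
    p = sps.f.sf(f, L, n1 + n2 - L - 1)
    return t2, f, p


def cohens_d(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column Cohen's d with pooled SD; x (n1, ..., L), y (n2, ..., L)."""
    n1, n2 = x.shape[0], y.shape[0]
    vx = x.var(axis=0, ddof=1)
    vy = y.var(axis=0, ddof=1)
    sp = np.sqrt(((n1 - 1) * vx + (n2 - 1) * vy) / (n1 + n2 - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (x.mean(axis=0) - y.mean(axis=0)) / sp


def group_test_along_tract(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05):
    """Per-node Hotelling T^2 between the two label groups.

    Returns (t2, p, d) with d the per-node, per-component Cohen's d.
    Nodes where any subject's score is undefined get NaN statistics.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    x = scores[labels == groups[0]]
    y = scores[labels == groups[1]]
    if x.shape[0] < 3 or y.shape[0] < 3:
        raise ValueError("each group needs at least 3 subjects")
    N = scores.shape[1]
    valid = ~np.isnan(scores).any(axis=(0, 2))
    t2 = np.full(N, np.nan)
    p = np.full(N, np.nan)
    d = np.full((N, scores.shape[2]), np.nan)
    if valid.any():
        t2v, _, pv = _hotelling_nodes(x[:, valid], y[:, valid])
        t2[valid], p[valid] = t2v, pv
        d[valid] = cohens_d(x[:, valid], y[:, valid])
    return t2, p, d


# ---------------------------------------------------------------------------
# score association (AES)


def _precompute_bases(scores: np.ndarray, X_cov: np.ndarray):
    """Per-node orthonormal bases of the reduced (covariate) and full
    (covariate + components) designs, for fast repeated regressions."""
    S, N, L = scores.shape
    q_r, _ = np.linalg.qr(X_cov)
    Qf = np.empty((N, S, X_cov.shape[1] + L))
    for n in range(N):
        Xf = np.column_stack([X_cov, scores[:, n, :]])
        Qf[n], _ = np.linalg.qr(Xf)
    return q_r, Qf


def association_along_tract(scores: np.ndarray, aes: np.ndarray, meta: pd.DataFrame,
                            covariates: Sequence[str] = DEFAULT_COVARIATES):
    """Joint F-test of the component coefficients in AES ~ PCs + covariates.

    Per node, the L component columns are tested jointly against the
    covariate-only model. The effect size r is the signed square root of
    the partial R^2 (sign of the dominant component coefficient; the
    signed partial correlation itself when L = 1).
    """
    aes = np.asarray(aes, dtype=float)
    S, N, L = scores.shape
    if np.isnan(aes).any():
        raise ValueError("AES score required for every included subject")
    X_cov = design_matrix(meta, covariates)
    fstat = np.full(N, np.nan)
    p = np.full(N, np.nan)
    r = np.full(N, np.nan)
    df2 = S - X_cov.shape[1] - L
    for n in range(N):
        pcs = scores[:, n, :]
        if np.isnan(pcs).any():
            continue
        Xf = np.column_stack([X_cov, pcs])
        beta_f, *_ = np.linalg.lstsq(Xf, aes, rcond=None)
        rss_f = float(np.sum((aes - Xf @ beta_f) ** 2))
        beta_r, *_ = np.linalg.lstsq(X_cov, aes, rcond=None)
        rss_r = float(np.sum((aes - X_cov @ beta_r) ** 2))
        fstat[n] = ((rss_r - rss_f) / L) / (rss_f / df2) if rss_f > 0 else np.inf
        p[n] = sps.f.sf(fstat[n], L, df2)
        partial_r2 = (rss_r - rss_f) / rss_r if rss_r > 0 else 1.0
        pc_coefs = beta_f[X_cov.shape[1]:]
        sign = math.copysign(1.0, pc_coefs[int(np.argmax(np.abs(pc_coefs)))])
        r[n] = sign * math.sqrt(max(partial_r2, 0.0))
    return fstat, p, r


def _association_pvalues_fast(Qf: np.ndarray, q_r: np.ndarray, aes: np.ndarray,
                              L: int, valid: np.ndarray):
    """Per-node joint-F p-values reusing precomputed design bases."""
    N, S, pf = Qf.shape
    pr = q_r.shape[1]
    yy = float(aes @ aes)
    rss_r = yy - float(np.sum((q_r.T @ aes) ** 2))
    proj = np.einsum("nsp,s->np", Qf, aes)
    rss_f = yy - np.einsum("np,np->n", proj, proj)
    df2 = S - pf
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_r - rss_f) / L) / (rss_f / df2)
    p = sps.f.sf(f, L, df2)
    p = np.where(valid, p, np.nan)
    return p


# ---------------------------------------------------------------------------
# permutation FWE on cluster size


def clusters_from_pvalues(p: np.ndarray, alpha: float):
    """Maximal runs of contiguous nodes with p < alpha.

    NaN nodes (undefined profiles) break runs. Returns a list of
    (start, length) and the suprathreshold mask.
    """
    mask = np.zeros(len(p), dtype=bool)
    with np.errstate(invalid="ignore"):
        mask[~np.isnan(p)] = p[~np.isnan(p)] < alpha
    clusters = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            clusters.append((start, i - start))
            start = None
    if start is not None:
        clusters.append((start, len(mask) - start))
    return clusters, mask


def _max_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def permutation_fwe(pvalue_fn: Callable[[np.ndarray], np.ndarray],
                    labels: np.ndarray, n_perm: int = 10000, alpha: float = 0.05,
                    seed: int = 0, exhaustive: bool = False):
    """Cluster-size FWE correction by label permutation.

    ``pvalue_fn`` maps a label (or score) vector to per-node p-values. The
    observed per-node p-values are thresholded at alpha; under each of
    ``n_perm`` relabelings the maximum suprathreshold run length is
    recorded; the FWE cluster-size threshold is the empirical (1 - alpha)
    quantile (type "higher", rounded up) of that null distribution, and
    observed clusters at least that long are significant.
    """
    import warnings

    if not exhaustive and n_perm < 100:
        warnings.warn("fewer than 100 permutations gives an unstable FWE threshold")
    labels = np.asarray(labels)
    obs_p = pvalue_fn(labels)
    clusters, forming = clusters_from_pvalues(obs_p, alpha)
    obs_max = max((ln for _, ln in clusters), default=0)

    rng = np.random.default_rng(seed)
    if exhaustive:
        perms = _enumerate_two_group(labels)
        n_perm = len(perms)
    else:
        perms = (rng.permutation(labels) for _ in range(n_perm))
    null_max = np.empty(n_perm, dtype=int)
    for i, perm in enumerate(perms):
        pp = pvalue_fn(perm)
        _, m = clusters_from_pvalues(pp, alpha)
        null_max[i] = _max_run(m)
    thr = int(math.ceil(np.quantile(null_max, 1.0 - alpha, method="higher")))
    thr = max(thr, 1)
    significant = np.zeros(len(obs_p), dtype=bool)
    for start, length in clusters:
        if length >= thr:
            significant[start : start + length] = True
    cluster_p = float((1 + np.sum(null_max >= obs_max)) / (1 + n_perm)) if obs_max else 1.0
    return thr, significant, forming, null_max, cluster_p


def _enumerate_two_group(labels: np.ndarray) -> list[np.ndarray]:
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exhaustive enumeration requires two groups")
    n = len(labels)
    k = int(np.sum(labels == groups[0]))
    perms = []
    for pos in combinations(range(n), k):
        lab = np.full(n, groups[1], dtype=labels.dtype)
        lab[list(pos)] = groups[0]
        perms.append(lab)
    return perms


# ---------------------------------------------------------------------------
# demographics


def contingency_chi2(table) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("need a 2x2 table of non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# full per-bundle analyses


def group_analysis(profile: BundleProfile, meta: pd.DataFrame, *,
                   prune_threshold: float = 0.8, var_target: float = 0.80,
                   alpha: float = 0.05, n_perm: int = 10000, seed: int = 0,
                   covariates: Sequence[str] = DEFAULT_COVARIATES,
                   group_col: str = "group") -> tuple[AlongTractResult, PcModel]:
    """Full group-difference chain: prune -> PCA -> residualize ->
    per-node Hotelling T^2 -> permutation cluster-size FWE."""
    retained, _ = prune_correlated(profile, prune_threshold)
    model, scores = fit_pca(profile, var_target, metrics=retained)
    resid = residualize(scores, meta, covariates)
    labels = meta[group_col].to_numpy()

    t2, p_obs, d = group_test_along_tract(resid, labels, alpha)

    def pfn(lab):
        g = np.unique(lab)
        return _group_pvalues(resid, lab, g)

    thr, sig, forming, null_max, cluster_p = permutation_fwe(
        pfn, labels, n_perm=n_perm, alpha=alpha, seed=seed)
    result = AlongTractResult(statistic=t2, pvalues=p_obs, effect_size=d,
                              cluster_forming_mask=forming, fwe_cluster_size=thr,
                              significant_mask=sig, n_permutations=n_perm,
                              null_max_cluster=null_max, cluster_pvalue=cluster_p)
    return result, model


def _group_pvalues(scores: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> np.ndarray:
    x = scores[labels == groups[0]]
    y = scores[labels == groups[1]]
    N = scores.shape[1]
    valid = ~np.isnan(scores).any(axis=(0, 2))
    p = np.full(N, np.nan)
    if valid.any():
        _, _, pv = _hotelling_nodes(x[:, valid], y[:, valid])
        p[valid] = pv
    return p


def aes_analysis(profile: BundleProfile, meta: pd.DataFrame, *,
                 prune_threshold: float = 0.8, var_target: float = 0.80,
                 alpha: float = 0.05, n_perm: int = 10000, seed: int = 0,
                 covariates: Sequence[str] = DEFAULT_COVARIATES,
                 group_col: str = "group", patient_group: str = "LLD",
                 aes_col: str = "AES") -> tuple[AlongTractResult, PcModel]:
    """Association chain within the patient group: prune -> PCA (pooled)
    -> per-node joint F-test of AES ~ PCs + covariates -> permutation
    cluster-size FWE (AES values permuted)."""
    retained, _ = prune_correlated(profile, prune_threshold)
    model, scores = fit_pca(profile, var_target, metrics=retained)

    in_group = (meta[group_col] == patient_group).to_numpy()
    scores_g = scores[in_group]
    meta_g = meta.loc[in_group].reset_index(drop=True)
    aes = meta_g[aes_col].to_numpy(dtype=float)

    fstat, p_obs, r = association_along_tract(scores_g, aes, meta_g, covariates)

    X_cov = design_matrix(meta_g, covariates)
    valid = ~np.isnan(scores_g).any(axis=(0, 2))
    safe = np.where(np.isnan(scores_g), 0.0, scores_g)
    q_r, Qf = _precompute_bases(safe, X_cov)
    L = scores_g.shape[2]

    def pfn(aes_perm):
        return _association_pvalues_fast(Qf, q_r, np.asarray(aes_perm, float), L, valid)

    thr, sig, forming, null_max, cluster_p = permutation_fwe(
        pfn, aes, n_perm=n_perm, alpha=alpha, seed=seed)
    result = AlongTractResult(statistic=fstat, pvalues=p_obs, effect_size=r,
                              cluster_forming_mask=forming, fwe_cluster_size=thr,
                              significant_mask=sig, n_permutations=n_perm,
                              null_max_cluster=null_max, cluster_pvalue=cluster_p)
    return result, model
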