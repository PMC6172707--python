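"""Weighted protein correlation network analysis (WPCNA).

A signed weighted network is built from biweight midcorrelations
(bicor, the outlier-robust similarity), with the soft-threshold power
chosen as the lowest power reaching scale-free topology fit R^2 ~ 0.80.
Adjacency follows the signed convention a_ij = ((1 + r_ij)/2)^beta; the
topological overlap matrix (TOM) uses the *mean* connectivity denominator.
Modules are detected by average-linkage clustering of 1 - TOM with a
depth-controlled static cut, dissolution of undersized clusters, a
PAM-like kME reassignment stage, and merging of modules whose
eigenproteins correlate above 1 - mergeCutHeight.  Eigenproteins are first
principal components of standardized module member profiles; kME is a
feature's correlation with a module eigenprotein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .config import NetworkParams

logger = logging.getLogger("tmtnet")

GREY = "grey"


@dataclass
class ModuleAssignment:
    """Module labels, eigenproteins, kME, and module-trait correlations."""

    labels: pd.Series                       # feature -> module label (grey = none)
    eigenproteins: pd.DataFrame             # module x sample, unit variance
    kme: pd.DataFrame                       # feature x module
    module_trait: pd.DataFrame | None = None
    beta: float | None = None

    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()


# ---------------------------------------------------------------------------
# Biweight midcorrelation
# ---------------------------------------------------------------------------

def _bicor_weights(x: np.ndarray) -> np.ndarray | None:
    """Biweight transform of one vector; None signals a MAD of zero."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1, (1 - u * u) ** 2, 0.0)
    a = (x - med) * w
    norm = np.sqrt(np.sum(a * a))
    return a / norm if norm > 0 else None


def _standardize(x: np.ndarray) -> np.ndarray:
    a = x - x.mean()
    norm = np.sqrt(np.sum(a * a))
    return a / norm if norm > 0 else np.zeros_like(a)


def bicor(x, y, min_pairs: int = 4) -> float:
    """Biweight midcorrelation with the standard 9-MAD outlier weighting.

    Computed on pairwise-complete observations; falls back to Pearson for
    a vector whose MAD is zero (logged); NaN with fewer than ``min_pairs``
    complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < min_pairs:
        return float("nan")
    x, y = x[ok], y[ok]
    ax = _bicor_weights(x)
    if ax is None:
        logger.debug("bicor: MAD=0, Pearson fallback for x")
        ax = _standardize(x)
    ay = _bicor_weights(y)
    if ay is None:
        logger.debug("bicor: MAD=0, Pearson fallback for y")
        ay = _standardize(y)
    return float(np.clip(np.dot(ax, ay), -1.0, 1.0))


def bicor_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """All-pairs bicor of matrix rows (features x samples).

    Each row is biweight-transformed over its observed entries; pairs are
    normalized over shared-observed entries, so missing values never enter.
    """
    X = values.to_numpy(dtype=float)
    M = (~np.isnan(X)).astype(float)
    A = np.zeros_like(X)
    for i in range(X.shape[0]):
        xi = X[i][M[i] > 0]
        t = _bicor_weights(xi)
        if t is None:
            t = _standardize(xi)
        A[i, M[i] > 0] = t
    num = A @ A.T
    A2 = A * A
    den1 = A2 @ M.T  # sum over shared entries of a_i^2 (j observed)
    den = np.sqrt(den1 * den1.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip(num / den, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=values.index, columns=values.index)


def correlation_matrix(values: pd.DataFrame, params: NetworkParams) -> pd.DataFrame:
    if params.corr == "bicor":
        return bicor_matrix(values)
    return values.T.corr()


# ---------------------------------------------------------------------------
# Soft-threshold selection
# ---------------------------------------------------------------------------

def scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index.

    Connectivities are binned (equal width), log10 p(k) is regressed on
    log10 mean(k) over occupied bins, and the squared correlation is
    signed by the negated slope sign (a scale-free network has a negative
    slope).
    """
    k = connectivity[connectivity > 0]
    if k.size < 4 or np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    dk, pk = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            dk.append(k[sel].mean())
            pk.append(sel.mean())
    if len(dk) < 3:
        return float("nan")
    slope, _, r, _, _ = stats.linregress(np.log10(dk), np.log10(pk))
    return float(-np.sign(slope) * r * r)


def adjacency_from_corr(corr: pd.DataFrame, beta: float, signed: bool = True) -> np.ndarray:
    r = corr.to_numpy(dtype=float)
    a = ((1 + r) / 2) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit_table(values: pd.DataFrame, params: NetworkParams,
                         powers: list[float] | None = None) -> dict[float, float]:
    """Signed R^2 of the scale-free fit per candidate power."""
    if values.apply(lambda r: r.nunique(dropna=True), axis=1).le(1).any():
        raise ValueError("matrix contains constant features")
    if powers is None:
        powers = list(np.arange(1.0, 20.0 + 1e-9, params.beta_step))
    corr = correlation_matrix(values, params)
    table = {}
    for beta in powers:
        a = adjacency_from_corr(corr, beta, params.signed)
        table[float(beta)] = scale_free_r2(a.sum(axis=1), params.n_bins)
    return table


def select_beta_from_fit(r2_by_power: dict[float, float], target_r2: float = 0.80,
                         plateau_gain: float = 0.01) -> float:
    """Lowest power with R^2 >= target; otherwise the plateau power (first
    power whose gain over the previous step falls below ``plateau_gain``)."""
    if len(r2_by_power) < 2:
        raise ValueError("need at least two candidate powers")
    powers = sorted(r2_by_power)
    for b in powers:
        if r2_by_power[b] >= target_r2:
            return b
    for prev, b in zip(powers, powers[1:]):
        if r2_by_power[b] - r2_by_power[prev] < plateau_gain:
            logger.info("select_beta: target R2 not reached; plateau at beta=%s", b)
            return b
    logger.info("select_beta: no plateau found; returning highest power")
    return powers[-1]


def pick_beta(values: pd.DataFrame, params: NetworkParams | None = None,
              powers: list[float] | None = None) -> float:
    params = params or NetworkParams()
    table = scale_free_fit_table(values, params, powers)
    return select_beta_from_fit(table, params.target_r2)


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

def adjacency_tom(values: pd.DataFrame, params: NetworkParams | None = None,
                  corr: pd.DataFrame | None = None) -> pd.DataFrame:
    """Signed adjacency raised to beta, then topological overlap.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (denom(k_i, k_j) + 1 - a_ij) with
    the mean (or min) connectivity denominator; TOM is symmetric in [0,1]
    with unit diagonal.
    """
    params = params or NetworkParams()
    if corr is None:
        corr = correlation_matrix(values, params)
    a = adjacency_from_corr(corr, params.beta, params.signed)
    k = a.sum(axis=1)
    shared = a @ a
    if params.tom_denominator == "mean":
        denom = (k[:, None] + k[None, :]) / 2.0 + 1.0 - a
    else:
        denom = np.minimum(k[:, None], k[None, :]) + 1.0 - a
    tom = (shared + a) / denom
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=corr.index, columns=corr.columns)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

# static cut height as a fraction of the tallest merge; deeper split cuts lower
_CUT_FRACTION = {0: 0.99, 1: 0.98, 2: 0.97, 3: 0.96, 4: 0.95}


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != GREY].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], str(m)))
    mapping = {old: f"M{i + 1}" for i, old in enumerate(order)}
    mapping[GREY] = GREY
    return labels.map(mapping)


def _dissolve_small(labels: pd.Series, min_size: int) -> pd.Series:
    sizes = labels.value_counts()
    small = [m for m in sizes.index if m != GREY and sizes[m] < min_size]
    return labels.mask(labels.isin(small), GREY)


def detect_modules(tom: pd.DataFrame, params: NetworkParams | None = None,
                   values: pd.DataFrame | None = None) -> pd.Series:
    """Cluster 1 - TOM into modules; returns feature -> label (grey = none).

    Average-linkage clustering is cut at a deep-split-controlled height;
    clusters below ``min_module_size`` dissolve to grey.  When the
    expression matrix is supplied, a PAM-like stage reassigns features to
    the module of their highest kME, and modules whose eigenproteins
    correlate above 1 - mergeCutHeight are merged.  Labels are ordered by
    size (M1 largest); ties and input order are broken by feature id.
    """
    params = params or NetworkParams()
    features = list(tom.index)
    if len(features) < params.min_module_size:
        logger.warning("detect_modules: %d features < minModuleSize %d; all grey",
                       len(features), params.min_module_size)
        return pd.Series(GREY, index=tom.index)

    order = np.argsort(np.asarray(features, dtype=object))
    tom_sorted = tom.iloc[order, order]
    dist = 1.0 - tom_sorted.to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    cut = _CUT_FRACTION[params.deep_split] * Z[:, 2].max()
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series([f"c{c}" for c in raw], index=tom_sorted.index)
    labels = _dissolve_small(labels, params.min_module_size)

    if values is not None and (labels != GREY).any():
        values = values.loc[labels.index]
        if params.pam_stage:
            eig, kme = eigenproteins_kme(values, labels)
            for f in labels.index:
                cur = labels[f]
                if cur == GREY:
                    continue
                best = kme.loc[f].idxmax()
                if best != cur and kme.loc[f, best] > kme.loc[f, cur]:
                    labels[f] = best
            labels = _dissolve_small(labels, params.min_module_size)
        labels = _merge_close_modules(values, labels, params)

    labels = _relabel_by_size(labels)
    return labels.reindex(tom.index)


def _merge_close_modules(values: pd.DataFrame, labels: pd.Series,
                         params: NetworkParams) -> pd.Series:
    """Merge modules whose eigenproteins are closer than mergeCutHeight."""
    while True:
        mods = sorted(set(labels) - {GREY})
        if len(mods) < 2:
            return labels
        eig, _ = eigenproteins_kme(values, labels)
        ep = eig.loc[mods]
        d = 1.0 - np.corrcoef(ep.to_numpy())
        np.fill_diagonal(d, 0.0)
        Z = average(squareform(np.clip(d, 0, None), checks=False))
        groups = fcluster(Z, t=params.merge_cut_height, criterion="distance")
        if len(set(groups)) == len(mods):
            return labels
        mapping = {}
        for g in set(groups):
            members = [mods[i] for i in range(len(mods)) if groups[i] == g]
            for m in members:
                mapping[m] = members[0]
        mapping[GREY] = GREY
        labels = labels.map(mapping)


# ---------------------------------------------------------------------------
# Eigenproteins and kME
# ---------------------------------------------------------------------------

def eigenproteins_kme(values: pd.DataFrame, labels: pd.Series
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First-PC eigenproteins per module plus the full kME matrix.

    Member profiles are standardized; missing values are mean-imputed for
    the decomposition only.  Each eigenprotein has unit variance and is
    sign-oriented so the mean member correlation is non-negative.  kME is
    bicor(feature, eigenprotein) for every feature x module.
    """
    if values.shape[1] < 2:
        raise ValueError("eigenproteins need at least 2 samples")
    mods = sorted(set(labels) - {GREY})
    eps = {}
    for m in mods:
        sub = values.loc[labels.index[labels == m]].to_numpy(dtype=float)
        mu = np.nanmean(sub, axis=1, keepdims=True)
        sd = np.nanstd(sub, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        z = np.where(np.isnan(z), 0.0, z)  # mean imputation post-standardization
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        ep = vt[0]
        if np.mean([np.corrcoef(row, ep)[0, 1] for row in z]) < 0:
            ep = -ep
        ep = ep / np.std(ep, ddof=1)
        eps[m] = ep
    eigen = pd.DataFrame(eps, index=values.columns).T
    kme = pd.DataFrame(
        {m: [bicor(values.loc[f], eigen.loc[m]) for f in values.index] for m in mods},
        index=values.index)
    return eigen, kme


# ---------------------------------------------------------------------------
# Module-trait correlations
# ---------------------------------------------------------------------------

def _bicor_pvalue(r: float, n: int) -> float:
    if np.isnan(r) or n < 3:
        return float("nan")
    r = min(max(r, -0.9999999), 0.9999999)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), n - 2))


def module_trait_correlation(eigenproteins: pd.DataFrame, traits: pd.DataFrame,
                             spearman_traits: tuple[str, ...] = ("MMSE",)
                             ) -> pd.DataFrame:
    """Correlate eigenproteins with traits.

    bicor with a Student-t p-value for ordinal/molecular traits; Spearman
    for the traits named in ``spearman_traits`` (MMSE by default).  Missing
    trait values are pairwise-dropped; constant traits yield NaN (logged).
    """
    traits = traits.loc[eigenproteins.columns]
    rows = []
    for m in eigenproteins.index:
        ep = eigenproteins.loc[m].to_numpy(dtype=float)
        for t in traits.columns:
            tv = traits[t].to_numpy(dtype=float)
            ok = ~(np.isnan(ep) | np.isnan(tv))
            if ok.sum() < 4 or np.ptp(tv[ok]) == 0:
                logger.info("module_trait_correlation: %s vs %s skipped "
                            "(constant or too few values)", m, t)
                rows.append((m, t, np.nan, np.nan, "skipped"))
                continue
            if t in spearman_traits:
                rho, p = stats.spearmanr(ep[ok], tv[ok])
                rows.append((m, t, float(rho), float(p), "spearman"))
            else:
                rho = bicor(ep[ok], tv[ok])
                rows.append((m, t, rho, _bicor_pvalue(rho, int(ok.sum())), "bicor"))
    return pd.DataFrame(rows, columns=["module", "trait", "rho", "p", "method"])


# ---------------------------------------------------------------------------
# Full network build
# ---------------------------------------------------------------------------

def build_network(values: pd.DataFrame, params: NetworkParams | None = None,
                  traits: pd.DataFrame | None = None,
                  select_power: bool = False) -> ModuleAssignment:
    """Correlation -> adjacency/TOM -> modules -> eigenproteins/kME
    (-> module-trait correlations when traits are given)."""
    params = params or NetworkParams()
    if select_power:
        beta = pick_beta(values, params)
        params = NetworkParams(**{**params.__dict__, "beta": beta})
    corr = correlation_matrix(values, params)
    tom = adjacency_tom(values, params, corr=corr)
    labels = detect_modules(tom, params, values=values)
    eigen, kme = eigenproteins_kme(values, labels)
    mt = None
    if traits is not None and not eigen.empty:
        mt = module_trait_correlation(eigen, traits)
    return ModuleAssignment(labels=labels, eigenproteins=eigen, kme=kme,
                            module_trait=mt, beta=params.beta)
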