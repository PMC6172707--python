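"""Cell-type deconvolution and bootstrap covariate regression.

Per-sample weights for four brain cell types (microglia, astrocytes,
neurons, oligodendroglia) are estimated digital-sorting style: marker
features with complete quantification are matched to a pure-cell-type
reference profile and each sample's mixture is solved by non-negative
least squares on linear scale, then row-normalized to sum to one.

Nuisance covariates (age, sex, PMI, and optionally the cell-type weights)
are removed feature-by-feature with ordinary nonparametric bootstrap
regression: the linear model value ~ covariates + group is refit on
case-resamples, coefficients are aggregated, and only the covariate
components (evaluated at centered covariates, so each feature's grand mean
is preserved) are subtracted.  The disease-group term is modeled but never
subtracted, and missing values are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .config import RegressionSpec
from .normalize import AbundanceMatrix

logger = logging.getLogger("tmtnet")


@dataclass
class CellTypeReference:
    """Marker features with their mean abundances in pure cell types."""

    marker_ids: list[str]
    profile: pd.DataFrame  # marker x cell type, linear scale, >= 0
    collapse_map: dict[str, str] | None = None  # feature -> gene symbol

    def __post_init__(self) -> None:
        if (self.profile < 0).any().any():
            raise ValueError("reference profile must be non-negative")


@dataclass
class CellTypeWeights:
    """Per-sample non-negative weights over the four cell types; rows sum to 1."""

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.weights < -1e-12).any().any():
            raise ValueError("weights must be non-negative")


def collapse_to_symbols(matrix: AbundanceMatrix | pd.DataFrame,
                        symbol_map: dict[str, str]) -> pd.DataFrame:
    """Average rows sharing a gene symbol (available-case mean per sample).

    Features without a symbol mapping are dropped with a logged count.
    """
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    mapped = values.index.map(symbol_map.get)
    n_unmapped = int(pd.isna(mapped).sum())
    if n_unmapped:
        logger.info("collapse_to_symbols: %d unmapped features dropped", n_unmapped)
    keep = ~pd.isna(mapped)
    return values.loc[keep].groupby(mapped[keep]).mean()


def estimate_cell_weights(symbol_matrix: pd.DataFrame,
                          reference: CellTypeReference) -> CellTypeWeights:
    """DSA-style weight estimation by per-sample NNLS on linear scale.

    Only markers with no missing values across samples enter the fit
    (missing marker quantifications would bias the mixture system).
    """
    if (reference.profile.sum(axis=0) <= 0).any():
        raise ValueError("reference has an all-zero cell-type column")
    markers = [m for m in reference.marker_ids if m in symbol_matrix.index]
    complete = [m for m in markers if not symbol_matrix.loc[m].isna().any()]
    ref = reference.profile.loc[complete]
    for ct in ref.columns:
        if (ref[ct] <= 0).all():
            raise ValueError(f"no complete-case marker informs cell type {ct!r}")
    if not complete:
        raise ValueError("no complete-case markers available")
    mixture = np.exp2(symbol_matrix.loc[complete])  # linear scale
    A = ref.to_numpy()
    out = np.empty((symbol_matrix.shape[1], A.shape[1]))
    for si, s in enumerate(symbol_matrix.columns):
        b = mixture[s].to_numpy()
        if np.isnan(b).any():
            raise ValueError(f"sample {s!r} has missing marker values")
        w, _ = nnls(A, b)
        total = w.sum()
        if total <= 0:
            raise ValueError(f"infeasible weight solution for sample {s!r}")
        out[si] = w / total
    return CellTypeWeights(pd.DataFrame(out, index=symbol_matrix.columns,
                                        columns=ref.columns))


# ---------------------------------------------------------------------------
# Bootstrap covariate regression
# ---------------------------------------------------------------------------

def _design_matrix(covariates: pd.DataFrame, remove: tuple[str, ...],
                   retain: str) -> tuple[np.ndarray, int]:
    """[1 | removed covariates | retained-group dummies]; returns the matrix
    and the number of removed-covariate columns (immediately after the
    intercept)."""
    cols = [np.ones(len(covariates))]
    for c in remove:
        cols.append(covariates[c].to_numpy(dtype=float))
    n_removed = len(remove)
    if retain:
        dummies = pd.get_dummies(covariates[retain], drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
    return np.column_stack(cols), n_removed


def bootstrap_regress(matrix: AbundanceMatrix | pd.DataFrame,
                      covariates: pd.DataFrame,
                      spec: RegressionSpec | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Remove covariate components estimated by bootstrap regression.

    Per feature, the model value ~ removed covariates + group is fit on
    available cases and on ``n_boot`` case-resamples; the aggregated
    removed-covariate coefficients, evaluated at covariates centered over
    the feature's observed samples, are subtracted.  Features with fewer
    than (model terms + 2) observations are left unregressed and flagged.
    Rank-deficient resamples are redrawn (logged).

    Returns (regressed values, per-feature coefficients, unregressed ids).
    """
    spec = spec or RegressionSpec()
    values = (matrix.values if isinstance(matrix, AbundanceMatrix) else matrix).copy()
    if covariates.isna().any().any():
        raise ValueError("covariates must be complete for all samples")
    covariates = covariates.loc[values.columns]
    rng = np.random.default_rng(spec.seed)

    X_full, n_removed = _design_matrix(covariates, spec.remove, spec.retain)
    p = X_full.shape[1]
    coef_rows = {}
    unregressed: list[str] = []
    n_redraws = 0

    for f in values.index:
        y_all = values.loc[f].to_numpy(dtype=float)
        obs = ~np.isnan(y_all)
        n_obs = int(obs.sum())
        if n_obs < p + 2:
            unregressed.append(f)
            continue
        X = X_full[obs].copy()
        # center removed covariates over this feature's observed samples
        centers = X[:, 1:1 + n_removed].mean(axis=0)
        X[:, 1:1 + n_removed] -= centers
        y = y_all[obs]

        idx = rng.integers(0, n_obs, size=(spec.n_boot, n_obs))
        betas = np.empty((spec.n_boot, p))
        pending = np.arange(spec.n_boot)
        for _ in range(100):
            Xb = X[idx[pending]]
            XtX = np.einsum("bij,bik->bjk", Xb, Xb)
            Xty = np.einsum("bij,bi->bj", Xb, y[idx[pending]])
            ok = np.linalg.cond(XtX) < 1e10
            if ok.any():
                betas[pending[ok]] = np.linalg.solve(XtX[ok], Xty[ok][..., None])[..., 0]
            pending = pending[~ok]
            if pending.size == 0:
                break
            n_redraws += pending.size
            idx[pending] = rng.integers(0, n_obs, size=(pending.size, n_obs))
        else:
            # irreducibly deficient resamples: fall back to the full-data fit
            beta_full, *_ = np.linalg.lstsq(X, y, rcond=None)
            betas[pending] = beta_full

        agg = np.mean if spec.aggregation == "mean" else np.median
        beta = agg(betas, axis=0)
        coef_rows[f] = beta
        removal = X[:, 1:1 + n_removed] @ beta[1:1 + n_removed]
        y_new = y_all.copy()
        y_new[obs] = y - removal
        values.loc[f] = y_new

    if n_redraws:
        logger.info("bootstrap_regress: %d rank-deficient resamples redrawn", n_redraws)
    if unregressed:
        logger.warning("bootstrap_regress: %d features below the observation "
                       "floor left unregressed", len(unregressed))
    coef_cols = (["intercept"] + list(spec.remove)
                 + [f"group_{c}" for c in
                    pd.get_dummies(covariates[spec.retain], drop_first=True).columns])
    coefs = pd.DataFrame.from_dict(coef_rows, orient="index", columns=coef_cols)
    return values, coefs, unregressed


def two_pass_regress(matrix: AbundanceMatrix | pd.DataFrame,
                     weights: CellTypeWeights, covariates: pd.DataFrame,
                     spec: RegressionSpec | None = None
                     ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Remove cell-type composition variance, then age/sex/PMI.

    Pass 1 regresses on the cell-type weights (three of the four enter the
    design; with rows summing to one the fourth is redundant after
    centering, and the subtracted component is identical).  Pass 2 applies
    the standard covariate scheme.  The output feeds differential
    abundance; the network uses the covariate-only regressed matrix.
    """
    spec = spec or RegressionSpec()
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    w = weights.weights.loc[values.columns]
    aug = covariates.loc[values.columns].join(w.iloc[:, :-1])
    pass1_spec = RegressionSpec(remove=tuple(w.columns[:-1]), retain=spec.retain,
                                n_boot=spec.n_boot, seed=spec.seed,
                                aggregation=spec.aggregation)
    adjusted, _, un1 = bootstrap_regress(values, aug, pass1_spec)
    pass2_spec = RegressionSpec(remove=spec.remove, retain=spec.retain,
                                n_boot=spec.n_boot, seed=spec.seed + 1,
                                aggregation=spec.aggregation)
    adjusted, _, un2 = bootstrap_regress(adjusted, aug, pass2_spec)
    return adjusted, {"pass1": un1, "pass2": un2}
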