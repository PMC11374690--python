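"""Covariate normalization and negative-binomial breakend-rate regression.

Per-bin cohort breakend counts of one simple-SV class are modelled as
NB2 (variance mu + alpha * mu^2) with a log link on z-scored genomic
covariates; the fitted means give the expected breakend surface b_j used
by the simulator and the hotspot d_exp denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genome import BinGrid


@dataclass
class CovariateMatrix:
    """Z-scored covariates over callable bins, with de-normalization stats."""

    values: pd.DataFrame  # indexed by callable-bin position in the grid
    means: pd.Series
    sds: pd.Series
    bin_index: np.ndarray  # grid indices of the callable bins (row order)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class NbModel:
    feature_names: list[str]
    coefficients: np.ndarray  # intercept first, then features, log link
    dispersion: float  # NB2 alpha; 0 = Poisson limit
    std_errors: np.ndarray
    log_likelihood: float
    converged: bool
    n_obs: int
    dropped: list[str] = field(default_factory=list)

    def predict(self, covariates: CovariateMatrix) -> np.ndarray:
        X = _design(covariates, self.feature_names)
        return np.exp(X @ self.coefficients)


def normalize_covariates(grid: BinGrid, ddof: int = 1) -> CovariateMatrix:
    """Z-score covariates over callable bins (sd with n-1 denominator).

    Zero-variance columns are dropped with a warning; if every column is
    degenerate an error is raised.
    """
    callable_idx = np.where(grid.callable_flags)[0]
    if len(callable_idx) < 2:
        raise ValueError("need at least two callable bins")
    raw = grid.covariate_frame().iloc[callable_idx].astype(float)
    if raw.shape[1] == 0:
        raise ValueError("grid carries no covariates")
    means = raw.mean()
    sds = raw.std(ddof=ddof)
    keep = sds > 0
    dropped = list(raw.columns[~keep])
    if dropped:
        warnings.warn(f"dropping zero-variance covariate(s): {dropped}")
    if not keep.any():
        raise ValueError("all covariate columns have zero variance")
    z = (raw.loc[:, keep] - means[keep]) / sds[keep]
    z.index = pd.RangeIndex(len(z))
    return CovariateMatrix(z, means[keep], sds[keep], callable_idx)


def _design(cov: CovariateMatrix, feature_names: list[str]) -> np.ndarray:
    missing = [f for f in feature_names if f not in cov.values.columns]
    if missing:
        raise ValueError(f"covariate keys mismatch: missing {missing}")
    X = cov.values[feature_names].to_numpy()
    return np.column_stack([np.ones(len(X)), X])


def _drop_collinear(cov: CovariateMatrix) -> tuple[list[str], list[str]]:
    """Greedy left-to-right removal of linearly dependent columns."""
    names = cov.feature_names
    kept: list[str] = []
    dropped: list[str] = []
    base = np.ones((len(cov.values), 1))
    for name in names:
        cand = np.column_stack([base, cov.values[name].to_numpy()])
        if np.linalg.matrix_rank(cand) > base.shape[1]:
            kept.append(name)
            base = cand
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(f"dropping collinear covariate(s): {dropped}")
    return kept, dropped


def fit_nb(
    counts: np.ndarray,
    covariates: CovariateMatrix,
    maxiter: int = 200,
) -> NbModel:
    """Maximum-likelihood NB2 regression with log link.

    Falls back to a Poisson GLM when the dispersion estimate collapses to
    zero (or the NB optimizer fails near that boundary). Raises on
    non-convergence.
    """
    counts = np.asarray(counts)
    if len(counts) != len(covariates.values):
        raise ValueError("counts length must equal number of callable bins")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative integers")
    kept, dropped = _drop_collinear(covariates)
    X = _design(covariates, kept)

    nb_res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            nb_res = sm.NegativeBinomial(counts, X).fit(
                disp=0, maxiter=maxiter, method="bfgs"
            )
            alpha = float(nb_res.params[-1])
            if not np.all(np.isfinite(nb_res.params)) or alpha < 1e-8:
                nb_res = None
        except Exception:
            nb_res = None

    if nb_res is not None and nb_res.mle_retvals.get("converged", False):
        return NbModel(
            feature_names=kept,
            coefficients=np.asarray(nb_res.params[:-1], dtype=float),
            dispersion=float(nb_res.params[-1]),
            std_errors=np.asarray(nb_res.bse[:-1], dtype=float),
            log_likelihood=float(nb_res.llf),
            converged=True,
            n_obs=len(counts),
            dropped=dropped,
        )

    # Poisson limit
    pois = sm.GLM(counts, X, family=sm.families.Poisson()).fit(maxiter=maxiter)
    if not pois.converged:
        raise RuntimeError(
            f"NB/Poisson regression failed to converge after {maxiter} iterations"
        )
    return NbModel(
        feature_names=kept,
        coefficients=np.asarray(pois.params, dtype=float),
        dispersion=0.0,
        std_errors=np.asarray(pois.bse, dtype=float),
        log_likelihood=float(pois.llf),
        converged=True,
        n_obs=len(counts),
        dropped=dropped,
    )


def nb2_loglike(counts: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood; at alpha = 0 this is the Poisson log-likelihood."""
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return float(np.sum(counts * np.log(mu) - mu - gammaln(counts + 1)))
    size = 1.0 / alpha
    return float(
        np.sum(
            gammaln(counts + size)
            - gammaln(size)
            - gammaln(counts + 1)
            + size * np.log(size / (size + mu))
            + counts * np.log(mu / (size + mu))
        )
    )


def expected_breakends(
    model: NbModel,
    covariates: CovariateMatrix,
    grid: BinGrid,
    observed_total: float | None = None,
    tolerance: float = 0.02,
) -> BinGrid:
    """Fill b_j on the grid: fitted mean on callable bins, 0 elsewhere."""
    if not model.converged:
        raise ValueError("model did not converge")
    mu = model.predict(covariates)
    b = np.zeros(len(grid))
    b[covariates.bin_index] = mu
    if observed_total is not None and observed_total > 0:
        rel = abs(b.sum() - observed_total) / observed_total
        if rel > tolerance:
            warnings.warn(
                f"sum of fitted b_j deviates from observed total by {rel:.1%}"
            )
    grid.set_b(b)
    return grid


def model_to_text(model: NbModel) -> str:
    lines = [
        f"dispersion\t{model.dispersion!r}",
        f"log_likelihood\t{model.log_likelihood!r}",
        f"converged\t{model.converged}",
        f"n_obs\t{model.n_obs}",
        f"intercept\t{model.coefficients[0]!r}",
    ]
    for name, coef, se in zip(
        model.feature_names, model.coefficients[1:], model.std_errors[1:]
    ):
        lines.append(f"coef:{name}\t{coef!r}\t{se!r}")
    if model.dropped:
        lines.append("dropped\t" + ",".join(model.dropped))
    return "\n".join(lines) + "\n"
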