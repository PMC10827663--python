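"""Empirical-Bayes location/scale batch harmonization and covariate residualization.

Multi-site features carry additive and multiplicative scanner effects.
Harmonization standardizes each feature with covariate structure retained,
estimates per-batch location and scale parameters, shrinks them with
parametric empirical Bayes (normal prior on locations, inverse-gamma on
scales, hyperparameters moment-matched across features, solved by the
classic fixed-point iteration), removes the shrunken effects, and restores
the covariate structure. Diagnostic group must never be the batch variable
nor a removed covariate; a guard enforces this so the group signal is
preserved by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .errors import DesignError, IntegrityError, ParameterError

_CONV = 1e-4


@dataclass
class HarmonizationModel:
    """Fitted batch-adjustment parameters (empirical-Bayes shrunken)."""

    batches: list[str]
    beta_hat: np.ndarray  # (n_design, n_features) grand + covariate coefficients
    grand_mean: np.ndarray  # (n_features,)
    var_pooled: np.ndarray  # (n_features,)
    gamma_hat: np.ndarray  # raw per-batch locations (n_batch, n_features)
    delta2_hat: np.ndarray  # raw per-batch squared scales
    gamma_star: np.ndarray  # EB-shrunken locations
    delta2_star: np.ndarray  # EB-shrunken squared scales
    n_covariates: int
    iterations: list[int] | None = None

    def adjust(
        self, X: np.ndarray, batch: np.ndarray, covariates: np.ndarray | None = None
    ) -> np.ndarray:
        """Remove the fitted batch effects from data with known batch labels.

        Applying the model to its own training data reproduces the
        fit-time output exactly.
        """
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        design_cov = _covariate_matrix(covariates, len(batch))
        stand_mean = self.grand_mean[None, :] + design_cov @ self.beta_hat[-self.n_covariates:] \
            if self.n_covariates else np.broadcast_to(self.grand_mean, X.shape).copy()
        z = (X - stand_mean) / np.sqrt(self.var_pooled)[None, :]
        out = np.empty_like(z)
        for bi, b in enumerate(self.batches):
            rows = np.flatnonzero(batch == b)
            if rows.size == 0:
                continue
            out[rows] = (z[rows] - self.gamma_star[bi]) / np.sqrt(self.delta2_star[bi])
        seen = np.isin(batch, self.batches)
        if not seen.all():
            raise ParameterError(
                f"unseen batch label(s): {sorted(set(batch[~seen]))}"
            )
        return out * np.sqrt(self.var_pooled)[None, :] + stand_mean


def _covariate_matrix(covariates, n_rows: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n_rows, 0))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n_rows:
        raise DesignError(f"covariates have {c.shape[0]} rows, expected {n_rows}")
    return c


def _guard_group(batch: np.ndarray, covariates, group) -> None:
    """Diagnosis must not be removable: not the batch, not a covariate to remove."""
    if group is None:
        return
    group = np.asarray(group)
    codes = pd.factorize(group)[0]
    bcodes = pd.factorize(np.asarray(batch))[0]
    if len(np.unique(codes)) > 1 and _same_partition(bcodes, codes):
        raise IntegrityError("batch variable coincides with diagnostic group")


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    return len(np.unique(a)) == len(np.unique(b)) and len(
        np.unique(a * (b.max() + 1) + b)
    ) == len(np.unique(a))


def combat_fit_transform(
    features: np.ndarray,
    batch: np.ndarray,
    covariates: np.ndarray | None = None,
    group: np.ndarray | None = None,
    eb: bool = True,
) -> tuple[np.ndarray, HarmonizationModel]:
    """Fit and apply empirical-Bayes location/scale harmonization.

    Parameters
    ----------
    features
        subjects x features matrix.
    batch
        per-subject site/scanner labels (>= 2 levels, each with >= 2
        subjects; a single level returns the input unchanged with a
        warning).
    covariates
        design columns whose structure is preserved (e.g. age); an
        intercept is implicit.
    group
        optional diagnostic labels, used only to verify the batch variable
        does not coincide with diagnosis.
    eb
        empirical-Bayes shrinkage of per-batch parameters (default). With
        ``eb=False`` raw per-batch location/scale estimates are removed,
        which equalizes batch means exactly (no shrinkage bias) at the
        cost of noisier per-feature estimates.

    Returns
    -------
    adjusted features (same shape) and the fitted :class:`HarmonizationModel`.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ParameterError("features must be 2-D (subjects x features)")
    batch = np.asarray(batch)
    if batch.shape[0] != X.shape[0]:
        raise DesignError("batch length does not match subject count")
    _guard_group(batch, covariates, group)
    levels = [str(b) for b in pd.unique(batch)]
    if len(levels) < 2:
        warnings.warn("single batch: harmonization is an identity transform")
        model = HarmonizationModel(
            batches=levels,
            beta_hat=np.zeros((1, X.shape[1])),
            grand_mean=X.mean(axis=0),
            var_pooled=np.ones(X.shape[1]),
            gamma_hat=np.zeros((1, X.shape[1])),
            delta2_hat=np.ones((1, X.shape[1])),
            gamma_star=np.zeros((1, X.shape[1])),
            delta2_star=np.ones((1, X.shape[1])),
            n_covariates=0,
        )
        return X.copy(), model
    counts = {lv: int((batch == lv).sum()) for lv in levels}
    singles = [lv for lv, c in counts.items() if c < 2]
    if singles:
        raise DesignError(f"singleton batch(es): {singles}")

    n, p = X.shape
    onehot = np.column_stack([(batch == lv).astype(float) for lv in levels])
    cov = _covariate_matrix(covariates, n)
    design = np.column_stack([onehot, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DesignError("rank-deficient design (batch + covariates)")

    # standardize: grand mean weighted by batch proportions, covariates retained
    beta_hat, *_ = np.linalg.lstsq(design, X, rcond=None)
    props = np.array([counts[lv] / n for lv in levels])
    grand_mean = props @ beta_hat[: len(levels)]
    resid = X - design @ beta_hat
    var_pooled = (resid ** 2).mean(axis=0)
    if np.any(var_pooled <= 0):
        raise DesignError("zero pooled variance for some feature(s)")
    stand_mean = grand_mean[None, :] + (cov @ beta_hat[len(levels):] if cov.size else 0.0)
    z = (X - stand_mean) / np.sqrt(var_pooled)[None, :]

    # per-batch raw location/scale and EB hyperpriors (moment matching)
    gamma_hat = np.stack([z[batch == lv].mean(axis=0) for lv in levels])
    delta2_hat = np.stack([z[batch == lv].var(axis=0, ddof=1) for lv in levels])
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)

    def aprior(d2: np.ndarray) -> float:
        m, s2 = d2.mean(), d2.var(ddof=1)
        return (2 * s2 + m ** 2) / s2

    def bprior(d2: np.ndarray) -> float:
        m, s2 = d2.mean(), d2.var(ddof=1)
        return (m * s2 + m ** 3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    iterations = []
    if not eb:
        gamma_star[:] = gamma_hat
        delta2_star[:] = delta2_hat
    for bi, lv in enumerate(levels if eb else []):
        zb = z[batch == lv]
        nb = zb.shape[0]
        a, b = aprior(delta2_hat[bi]), bprior(delta2_hat[bi])
        g_old = gamma_hat[bi].copy()
        d_old = delta2_hat[bi].copy()
        count = 0
        change = 1.0
        while change > _CONV:
            g_new = (nb * tau2[bi] * gamma_hat[bi] + d_old * gamma_bar[bi]) / (
                nb * tau2[bi] + d_old
            )
            sum2 = ((zb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b) / (nb / 2.0 + a - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                np.max(np.abs(d_new - d_old) / np.abs(d_old)),
            )
            g_old, d_old = g_new, d_new
            count += 1
        gamma_star[bi], delta2_star[bi] = g_old, d_old
        iterations.append(count)

    adjusted = np.empty_like(z)
    for bi, lv in enumerate(levels):
        rows = batch == lv
        adjusted[rows] = (z[rows] - gamma_star[bi]) / np.sqrt(delta2_star[bi])
    adjusted = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean

    model = HarmonizationModel(
        batches=levels,
        beta_hat=beta_hat,
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        n_covariates=cov.shape[1],
        iterations=iterations,
    )
    return adjusted, model


def residualize(
    features: np.ndarray,
    covariates_to_remove: np.ndarray,
    covariate_names: list[str] | None = None,
) -> np.ndarray:
    """OLS residuals per feature for the removed covariates, mean restored.

    Used e.g. to remove age before trait prediction. Refuses to remove a
    covariate named 'group' (diagnosis must stay in the data).
    """
    if covariate_names and any(n.lower() == "group" for n in covariate_names):
        raise IntegrityError("diagnostic group cannot be a removed covariate")
    X = np.asarray(features, dtype=float)
    C = _covariate_matrix(covariates_to_remove, X.shape[0])
    design = np.column_stack([np.ones(X.shape[0]), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DesignError("rank-deficient removal design")
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    return resid + X.mean(axis=0, keepdims=True)
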