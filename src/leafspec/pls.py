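"""Ensemble PLSR models linking leaf reflectance spectra to photosynthetic traits.

The workflow mirrors common chemometric practice for spectra-trait models:

1. choose the number of latent components by repeatedly (default 1000 times)
   splitting the training set 70/30, computing the prediction residual sum of
   squares (PRESS) on the held-in 30% at every candidate component count, and
   applying the one-standard-error rule to the mean PRESS profile;
2. fit an ensemble of sub-models, each on a fresh random 70% subset of the
   training data, keeping every sub-model's coefficient vector and the
   residual sd on its own 30% holdout;
3. predict new spectra with every sub-model, back-transform, and report the
   ensemble mean together with a percentile confidence interval (ensemble
   spread) and prediction interval (spread + residual noise).

Right-skewed traits (Vcmax25, Jmax25) are square-root transformed before
regression and back-transformed for reporting.  Model interpretation uses the
coefficient percentile bands and VIP (variable importance in projection)
scores; wavelengths with ensemble VIP > 1 are flagged as influential.

Single PLS1 fits use the NIPALS algorithm (via scikit-learn) with centred,
unscaled predictors, so reflectance keeps its spectral shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "transform_response",
    "inverse_transform_response",
    "PLSModel",
    "fit_pls",
    "press_profile",
    "select_ncomp",
    "SpectraTraitModel",
    "PLSREnsembleResults",
    "fit_ensemble",
    "predict_ensemble",
    "vip_scores",
    "coefficient_summary",
    "coefficient_difference",
]

_TRANSFORMS = ("none", "sqrt")


def transform_response(values, tag: str):
    """Forward response transformation (``sqrt`` or ``none``)."""
    values = np.asarray(values, dtype=float)
    if tag == "none":
        return values.copy()
    if tag == "sqrt":
        if np.any(values < 0):
            raise ValueError("sqrt transform requires non-negative values")
        return np.sqrt(values)
    raise ValueError(f"unknown transformation {tag!r}; expected one of {_TRANSFORMS}")


def inverse_transform_response(values, tag: str):
    """Inverse of :func:`transform_response` (squares for ``sqrt``).

    Negative values under ``sqrt`` are clipped to zero before squaring: a
    negative predicted square root means a trait indistinguishable from zero.
    """
    values = np.asarray(values, dtype=float)
    if tag == "none":
        return values.copy()
    if tag == "sqrt":
        return np.maximum(values, 0.0) ** 2
    raise ValueError(f"unknown transformation {tag!r}; expected one of {_TRANSFORMS}")


@dataclass
class PLSModel:
    """One PLS1 fit: weights, scores, loadings, regression vector.

    ``coefficients``/``intercept`` reproduce fitted values as ``X @ b + b0``
    on the *transformed* response scale.  ``ss_y`` is the response variance
    captured by each component (used by VIP).
    """

    coefficients: np.ndarray      # (p,)
    intercept: float
    x_weights: np.ndarray         # (p, K), unit-norm columns
    x_loadings: np.ndarray        # (p, K)
    x_scores: np.ndarray          # (n, K)
    y_loadings: np.ndarray        # (K,)
    ss_y: np.ndarray              # (K,)
    n_components: int

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept


def _fit_nipals(X, y, ncomp: int):
    """Centred NIPALS PLS1 via scikit-learn; returns the sklearn object and means."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have inconsistent lengths")
    if np.ptp(y) == 0:
        raise ValueError("constant response: PLS undefined")
    if ncomp < 1 or ncomp > min(n - 1, p):
        raise ValueError(f"ncomp={ncomp} infeasible for X of shape {X.shape}")
    pls = PLSRegression(n_components=ncomp, scale=False)
    with warnings.catch_warnings():
        # sklearn warns when residuals become constant (noiseless low-rank y)
        warnings.simplefilter("ignore")
        pls.fit(X, y.reshape(-1, 1))
    return pls, X.mean(axis=0), float(y.mean())


def _coefficient_path(pls, x_mean, y_mean, ks):
    """Coefficient vectors/intercepts for each component count in ``ks``.

    NIPALS components are nested, so the k-component regression vector is
    ``W_k (P_k' W_k)^{-1} q_k`` using the leading k columns of one fit.
    """
    W = pls.x_weights_
    P = pls.x_loadings_
    q = pls.y_loadings_[0] if pls.y_loadings_.ndim == 2 and pls.y_loadings_.shape[0] == 1 else pls.y_loadings_.ravel()
    K_avail = W.shape[1]
    out = {}
    for k in ks:
        kk = min(k, K_avail)
        M = P[:, :kk].T @ W[:, :kk]
        # lstsq: beyond the effective rank (noiseless low-rank y) M is singular
        sol = np.linalg.lstsq(M, q[:kk], rcond=None)[0]
        b = W[:, :kk] @ sol
        out[k] = (b, y_mean - x_mean @ b)
    return out


def fit_pls(X, y, ncomp: int) -> PLSModel:
    """Fit a single PLS1 model with ``ncomp`` latent components.

    Predictors and response are centred; predictors are not scaled to unit
    variance (reflectance columns share units).
    """
    pls, x_mean, y_mean = _fit_nipals(X, y, ncomp)
    q = pls.y_loadings_.ravel()
    t = pls.x_scores_
    ss_y = q[: t.shape[1]] ** 2 * np.sum(t**2, axis=0)
    b = pls.coef_.ravel()
    return PLSModel(
        coefficients=b,
        intercept=float(y_mean - x_mean @ b),
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        x_scores=t,
        y_loadings=q,
        ss_y=ss_y,
        n_components=ncomp,
    )


def _iteration_rngs(seed: int, stream: int, n_iter: int):
    """Independent, reproducible per-iteration generators (counter-based)."""
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return [np.random.default_rng(child) for child in ss.spawn(n_iter)]


def _split_indices(rng, n: int, train_frac: float):
    n_train = int(round(train_frac * n))
    if train_frac < 1.0 and (n_train == 0 or n_train == n):
        n_train = min(max(n_train, 1), n - 1)
    perm = rng.permutation(n)
    return perm[:n_train], perm[n_train:]


def press_profile(
    X,
    y,
    max_ncomp: int,
    n_iter: int = 1000,
    train_frac: float = 0.7,
    seed: int = 0,
) -> np.ndarray:
    """PRESS at every component count over repeated random 70/30 splits.

    Returns an ``(n_iter, max_ncomp)`` array: entry ``(i, k-1)`` is the sum
    of squared prediction errors of a k-component model, trained on a random
    ``train_frac`` subset in iteration i, on the remaining internal-validation
    observations.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    n_train = int(round(train_frac * n))
    if n_train >= n or n_train < 2:
        raise ValueError("degenerate split: internal-validation part would be empty")
    if max_ncomp > min(n_train - 1, X.shape[1]):
        raise ValueError(
            f"max_ncomp={max_ncomp} infeasible for {n_train}-row training subsets"
        )
    press = np.empty((n_iter, max_ncomp))
    ks = list(range(1, max_ncomp + 1))
    for i, rng in enumerate(_iteration_rngs(seed, 0, n_iter)):
        tr, va = _split_indices(rng, n, train_frac)
        pls, xm, ym = _fit_nipals(X[tr], y[tr], max_ncomp)
        path = _coefficient_path(pls, xm, ym, ks)
        for k in ks:
            b, b0 = path[k]
            press[i, k - 1] = np.sum((y[va] - (X[va] @ b + b0)) ** 2)
    return press


def select_ncomp(press: np.ndarray, se_rule: str = "sem") -> int:
    """One-standard-error choice of the component count from a PRESS matrix.

    Let ``m(k)`` be the mean PRESS over iterations and ``k*`` its argmin.
    The selected count is the smallest k with ``m(k) <= m(k*) + s`` where
    ``s`` is the standard error of PRESS at ``k*`` across iterations
    (``se_rule="sem"``, default) or the plain standard deviation
    (``se_rule="sd"``).
    """
    press = np.asarray(press, dtype=float)
    if press.ndim != 2 or press.shape[1] < 2:
        raise ValueError("need a (n_iter, >=2) PRESS matrix")
    if np.any(np.all(np.isnan(press), axis=0)):
        raise ValueError("PRESS column with no finite values")
    m = np.nanmean(press, axis=0)
    k_star = int(np.nanargmin(m))
    col = press[:, k_star]
    col = col[np.isfinite(col)]
    s = float(np.std(col, ddof=1)) if col.size > 1 else 0.0
    if se_rule == "sem":
        s /= np.sqrt(col.size)
    elif se_rule != "sd":
        raise ValueError("se_rule must be 'sem' or 'sd'")
    return int(np.argmax(m <= m[k_star] + s)) + 1


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection of a single PLS fit.

    ``VIP_j = sqrt( p * sum_k SS_k (w_jk/||w_k||)^2 / sum_k SS_k )`` where
    ``SS_k`` is the response variance captured by component k.  The squared
    scores average to 1 across predictors.
    """
    W = model.x_weights
    ss = model.ss_y
    if np.sum(ss) <= 0:
        raise ValueError("zero explained response variance; VIP undefined")
    p = W.shape[0]
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (Wn**2 @ ss) / np.sum(ss))


class SpectraTraitModel:
    """Ensemble PLSR model of one trait from a spectra matrix.

    Parameters
    ----------
    X : (n, p) array
        Reflectance rows on a common wavelength grid.
    y : (n,) array
        Trait values on the original scale.
    trait : str
        Trait name (bookkeeping only).
    transformation : {"auto", "none", "sqrt"}
        Response transformation; ``"auto"`` square-root transforms the
        right-skewed capacity traits Vcmax25/Jmax25 and leaves others as is.
    wavelengths : array, optional
        Grid labels for interpretation output (defaults to column index).
    """

    def __init__(self, X, y, trait: str = "trait", transformation: str = "auto", wavelengths=None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y have inconsistent lengths")
        self.trait = trait
        if transformation == "auto":
            transformation = "sqrt" if trait in ("Vcmax25", "Jmax25") else "none"
        if transformation not in _TRANSFORMS:
            raise ValueError(f"transformation must be one of {_TRANSFORMS}")
        self.transformation = transformation
        self.wavelengths = (
            np.arange(self.X.shape[1], dtype=float)
            if wavelengths is None
            else np.asarray(wavelengths, dtype=float)
        )
        if self.wavelengths.size != self.X.shape[1]:
            raise ValueError("wavelengths must match X columns")

    def select_ncomp(
        self,
        max_ncomp: int = 25,
        n_iter: int = 1000,
        train_frac: float = 0.7,
        seed: int = 0,
        se_rule: str = "sem",
    ) -> int:
        """PRESS + one-SE component count on this model's training data."""
        yt = transform_response(self.y, self.transformation)
        max_ncomp = min(max_ncomp, int(round(train_frac * self.y.size)) - 2, self.X.shape[1])
        press = press_profile(self.X, yt, max_ncomp, n_iter=n_iter, train_frac=train_frac, seed=seed)
        return select_ncomp(press, se_rule=se_rule)

    def fit(
        self,
        ncomp: int | None = None,
        n_iter: int = 1000,
        train_frac: float = 0.7,
        seed: int = 0,
        max_ncomp: int = 25,
        se_rule: str = "sem",
    ) -> "PLSREnsembleResults":
        """Fit the resampling ensemble.

        When ``ncomp`` is None it is first selected by the PRESS / one-SE
        procedure on the same training data.  Each of the ``n_iter``
        sub-models is fit on a fresh random ``train_frac`` subset (of the
        transformed response); its residual sd comes from its own holdout.
        Sub-model seeds derive from ``seed`` by a counter-based scheme, so
        the whole fit is reproducible bit for bit.
        """
        yt = transform_response(self.y, self.transformation)
        if ncomp is None:
            ncomp = self.select_ncomp(
                max_ncomp=max_ncomp, n_iter=n_iter, train_frac=train_frac,
                seed=seed, se_rule=se_rule,
            )
        n, p = self.X.shape
        coefs = np.empty((n_iter, p))
        intercepts = np.empty(n_iter)
        resid_sd = np.empty(n_iter)
        vip_sum = np.zeros(p)
        for i, rng in enumerate(_iteration_rngs(seed, 1, n_iter)):
            if train_frac >= 1.0:
                tr = np.arange(n)
                va = tr
            else:
                tr, va = _split_indices(rng, n, train_frac)
            try:
                m = fit_pls(self.X[tr], yt[tr], ncomp)
            except Exception as exc:
                raise RuntimeError(f"sub-model fit failed at iteration {i}") from exc
            coefs[i] = m.coefficients
            intercepts[i] = m.intercept
            resid = yt[va] - m.predict(self.X[va])
            resid_sd[i] = float(np.sqrt(np.mean(resid**2)))
            vip_sum += vip_scores(m)
        return PLSREnsembleResults(
            trait=self.trait,
            transformation=self.transformation,
            ncomp=int(ncomp),
            coefs=coefs,
            intercepts=intercepts,
            resid_sd=resid_sd,
            wavelengths=self.wavelengths,
            vip_mean=vip_sum / n_iter,
            seed=int(seed),
            train_frac=float(train_frac),
        )


@dataclass
class PLSREnsembleResults:
    """A fitted ensemble: per-sub-model regression vectors plus summaries.

    Coefficients and residual sds live on the *transformed* response scale;
    predictions are back-transformed before aggregation, so reported means
    and intervals are on the original trait scale.
    """

    trait: str
    transformation: str
    ncomp: int
    coefs: np.ndarray        # (n_iter, p)
    intercepts: np.ndarray   # (n_iter,)
    resid_sd: np.ndarray     # (n_iter,)
    wavelengths: np.ndarray  # (p,)
    vip_mean: np.ndarray     # (p,)
    seed: int
    train_frac: float

    @property
    def n_iter(self) -> int:
        return self.coefs.shape[0]

    def predict(self, X_new, leaf_ids=None, level: float = 0.95, seed: int = 0) -> pd.DataFrame:
        """Ensemble prediction with confidence and prediction intervals.

        Every sub-model predicts on the transformed scale and is
        back-transformed; ``mean`` averages those back-transformed
        predictions.  ``ci95`` brackets the ensemble spread (percentiles of
        the back-transformed sub-model predictions) and ``pi95`` additionally
        draws, per sub-model, Gaussian noise with that sub-model's residual
        sd before back-transforming.  Intervals are widened if needed so that
        pi95 contains ci95 and ci95 contains the mean.
        """
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.coefs.shape[1]:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, ensemble grid has "
                f"{self.coefs.shape[1]}"
            )
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
        preds_t = X_new @ self.coefs.T + self.intercepts  # (n_new, n_iter)
        back = inverse_transform_response(preds_t, self.transformation)
        mean = back.mean(axis=1)
        q = 100.0 * np.array([(1 - level) / 2, 1 - (1 - level) / 2])
        ci_lo, ci_hi = np.percentile(back, q, axis=1)
        noisy = preds_t + rng.normal(size=preds_t.shape) * self.resid_sd
        noisy_back = inverse_transform_response(noisy, self.transformation)
        pi_lo, pi_hi = np.percentile(noisy_back, q, axis=1)
        ci_lo, ci_hi = np.minimum(ci_lo, mean), np.maximum(ci_hi, mean)
        pi_lo = np.minimum(pi_lo, ci_lo)
        pi_hi = np.maximum(pi_hi, ci_hi)
        out = pd.DataFrame(
            {
                "mean": mean,
                "ci95_low": ci_lo,
                "ci95_high": ci_hi,
                "pi95_low": pi_lo,
                "pi95_high": pi_hi,
            }
        )
        if leaf_ids is not None:
            out.insert(0, "leaf_id", np.asarray(leaf_ids))
        return out

    def vip(self) -> np.ndarray:
        """Ensemble VIP: mean of the sub-model VIP scores per wavelength."""
        return self.vip_mean

    def coefficient_summary(self, level: float = 0.95) -> pd.DataFrame:
        """Per-wavelength coefficient mean, percentile band and VIP>1 mask."""
        q = 100.0 * np.array([(1 - level) / 2, 1 - (1 - level) / 2])
        lo, hi = np.percentile(self.coefs, q, axis=0)
        return pd.DataFrame(
            {
                "wavelength": self.wavelengths,
                "coef_mean": self.coefs.mean(axis=0),
                "coef_low": lo,
                "coef_high": hi,
                "vip": self.vip_mean,
                "vip_gt1": self.vip_mean > 1.0,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Ensemble PLSR: trait {self.trait}",
            f"  transformation: {self.transformation}   components: {self.ncomp}",
            f"  sub-models: {self.n_iter} (train_frac={self.train_frac}, seed={self.seed})",
            f"  median sub-model holdout sd (transformed scale): "
            f"{np.median(self.resid_sd):.4f}",
            f"  wavelengths with VIP > 1: {int(np.sum(self.vip_mean > 1))} of "
            f"{self.vip_mean.size}",
        ]
        return "\n".join(lines)

    def to_files(self, header_path, coef_path) -> None:
        """Persist as a JSON header + CSV coefficient matrix."""
        import json

        with open(header_path, "w") as fh:
            json.dump(
                {
                    "trait": self.trait,
                    "transformation": self.transformation,
                    "ncomp": self.ncomp,
                    "seed": self.seed,
                    "train_frac": self.train_frac,
                    "wavelengths": self.wavelengths.tolist(),
                },
                fh,
            )
        mat = np.column_stack([self.intercepts, self.resid_sd, self.coefs])
        cols = ["intercept", "resid_sd"] + [f"{w:g}" for w in self.wavelengths]
        pd.DataFrame(mat, columns=cols).to_csv(coef_path, index=False)


def fit_ensemble(
    X,
    y,
    ncomp: int,
    transformation: str = "none",
    n_iter: int = 1000,
    train_frac: float = 0.7,
    seed: int = 0,
    trait: str = "trait",
    wavelengths=None,
) -> PLSREnsembleResults:
    """Functional wrapper: ``SpectraTraitModel(...).fit(ncomp=...)``."""
    return SpectraTraitModel(
        X, y, trait=trait, transformation=transformation, wavelengths=wavelengths
    ).fit(ncomp=ncomp, n_iter=n_iter, train_frac=train_frac, seed=seed)


def predict_ensemble(ensemble: PLSREnsembleResults, X_new, leaf_ids=None, seed: int = 0):
    """Functional wrapper around :meth:`PLSREnsembleResults.predict`."""
    return ensemble.predict(X_new, leaf_ids=leaf_ids, seed=seed)


def coefficient_summary(ensemble: PLSREnsembleResults, level: float = 0.95) -> pd.DataFrame:
    """Functional wrapper around :meth:`PLSREnsembleResults.coefficient_summary`."""
    return ensemble.coefficient_summary(level=level)


def coefficient_difference(
    ensemble_a: PLSREnsembleResults,
    ensemble_b: PLSREnsembleResults,
    level: float = 0.95,
):
    """Paired difference of two ensembles' coefficient vectors.

    The difference is taken per paired sub-model index, so both ensembles
    must share the wavelength grid and iteration count.  Returns a DataFrame
    (wavelength, mean difference, percentile band, significance mask where
    the band excludes zero) and the Pearson correlation of the two mean
    coefficient vectors.
    """
    if ensemble_a.coefs.shape != ensemble_b.coefs.shape:
        raise ValueError("ensembles differ in sub-model count or grid size")
    if not np.array_equal(ensemble_a.wavelengths, ensemble_b.wavelengths):
        raise ValueError("ensembles are on different wavelength grids")
    diff = ensemble_a.coefs - ensemble_b.coefs
    q = 100.0 * np.array([(1 - level) / 2, 1 - (1 - level) / 2])
    lo, hi = np.percentile(diff, q, axis=0)
    df = pd.DataFrame(
        {
            "wavelength": ensemble_a.wavelengths,
            "diff_mean": diff.mean(axis=0),
            "diff_low": lo,
            "diff_high": hi,
            "significant": (lo > 0) | (hi < 0),
        }
    )
    r = float(
        np.corrcoef(ensemble_a.coefs.mean(axis=0), ensemble_b.coefs.mean(axis=0))[0, 1]
    )
    return df, r
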