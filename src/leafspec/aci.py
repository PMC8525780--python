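"""Maximum-likelihood fitting of A-Ci curves with the FvCB model.

The estimator follows the practice used for field gas-exchange campaigns:
for each leaf, net assimilation observed along a CO2 setpoint sequence is fit
by Gaussian maximum likelihood to the FvCB forward model, with every
observation's prediction rescaled to its own leaf temperature so the fitted
``Vcmax25``, ``Jmax25``, ``Tp25`` and ``Rd25`` are expressed at 25 degC.
Transitions between the Ac/Aj/Ap limbs are not assigned by hand -- they fall
out of the likelihood optimisation.  Whether the triose-phosphate limb (and
hence ``Tp25``) is supported by a curve is decided by comparing the AIC of
the fits with and without it.

The respiration parameter co-estimated here is retained in the fit object for
prediction but is not a substitute for dark-adapted respiration measurements;
those are processed separately by :func:`rdark_from_timeseries`.

The module is organised statsmodels-style: :class:`ACiModel` holds the data,
``fit()`` returns an :class:`ACiResults` carrying estimates, standard errors,
Wald intervals, AIC and per-observation limitation states.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools import numdiff

from .fvcb import (
    FvCBParams,
    KineticConstants,
    LimitationState,
    TemperatureResponses,
    default_kinetics,
    default_temperature_responses,
    fvcb_forward,
    temp_scaler,
)

__all__ = [
    "GasExchangeCurve",
    "ACiModel",
    "ACiResults",
    "ConvergenceError",
    "negloglik",
    "fit_aci",
    "select_tp_model",
    "curve_intervals",
    "DarkRespirationRecord",
    "rdark_from_timeseries",
    "read_gas_exchange",
    "read_dark_respiration",
    "fits_to_dataframe",
    "write_fits",
]

_BOUNDS = {
    "Vcmax25": (1.0, 500.0),
    "Jmax25": (2.0, 800.0),
    "Tp25": (0.5, 100.0),
    "Rd25": (1e-4, 15.0),
}


class ConvergenceError(RuntimeError):
    """Raised when no optimiser restart converges for a curve."""


@dataclass
class GasExchangeCurve:
    """One leaf's A-Ci observations plus identifying metadata.

    A is net assimilation (umol m-2 s-1), Ci the intercellular CO2 mole
    fraction (umol mol-1), Tleaf the leaf temperature (degC) and Q the
    irradiance (umol m-2 s-1; NaN treated as saturating).
    """

    leaf_id: str
    A: np.ndarray
    Ci: np.ndarray
    Tleaf: np.ndarray
    Q: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.Ci = np.asarray(self.Ci, dtype=float)
        self.Tleaf = np.broadcast_to(
            np.asarray(self.Tleaf, dtype=float), self.A.shape
        ).copy()
        if self.Q is not None:
            self.Q = np.broadcast_to(np.asarray(self.Q, dtype=float), self.A.shape).copy()
        if self.A.shape != self.Ci.shape:
            raise ValueError("A and Ci must have the same length")
        if np.any(self.Ci < 0):
            raise ValueError("Ci must be >= 0")

    def __len__(self) -> int:
        return self.A.size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, leaf_id: str, metadata=None):
        sub = df[df["leaf_id"] == leaf_id]
        q = sub["Qin"].to_numpy() if "Qin" in sub.columns else None
        return cls(
            leaf_id=leaf_id,
            A=sub["A"].to_numpy(),
            Ci=sub["Ci"].to_numpy(),
            Tleaf=sub["Tleaf"].to_numpy(),
            Q=q,
            metadata=dict(metadata or {}),
        )


def negloglik(
    params: FvCBParams,
    sigma: float,
    curve: GasExchangeCurve,
    kc: KineticConstants | None = None,
    trp: TemperatureResponses | None = None,
) -> float:
    """Gaussian negative log-likelihood of the observed A under the FvCB model.

    ``-sum log N(A_i | A_hat_i(params, Tleaf_i), sigma^2)`` with predictions
    from :func:`leafspec.fvcb.fvcb_forward`.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    pred, _ = fvcb_forward(params, curve.Ci, curve.Tleaf, curve.Q, kc, trp)
    resid = curve.A - pred
    n = resid.size
    return float(0.5 * n * np.log(2.0 * np.pi * sigma**2) + np.sum(resid**2) / (2.0 * sigma**2))


class ACiModel:
    """FvCB model for one A-Ci curve, ready to fit by maximum likelihood.

    Parameters
    ----------
    curve : GasExchangeCurve
    kc, trp : optional
        Kinetic constants and temperature responses; default to the packaged
        parameterisation.
    theta, alpha : float
        Curvature and apparent quantum yield of the electron-transport light
        response.  A-Ci curves are measured at saturating irradiance, so the
        fit is insensitive to these; they are carried for completeness.
    """

    def __init__(
        self,
        curve: GasExchangeCurve,
        kc: KineticConstants | None = None,
        trp: TemperatureResponses | None = None,
        theta: float = 0.7,
        alpha: float = 0.425,
    ):
        if len(curve) < 6:
            raise ValueError(
                f"curve {curve.leaf_id!r} has {len(curve)} observations; "
                "at least 6 are required for a stable fit"
            )
        self.curve = curve
        self.kc = kc if kc is not None else default_kinetics()
        self.trp = trp if trp is not None else default_temperature_responses()
        self.theta = theta
        self.alpha = alpha

    # -- internal helpers ---------------------------------------------------

    def _param_names(self, include_tp: bool) -> list[str]:
        return ["Vcmax25", "Jmax25", "Tp25", "Rd25"] if include_tp else [
            "Vcmax25",
            "Jmax25",
            "Rd25",
        ]

    def _to_params(self, x: np.ndarray, include_tp: bool) -> FvCBParams:
        if include_tp:
            return FvCBParams(
                Vcmax25=x[0], Jmax25=x[1], Tp25=x[2], Rd25=x[3],
                theta=self.theta, alpha=self.alpha,
            )
        return FvCBParams(
            Vcmax25=x[0], Jmax25=x[1], Rd25=x[2], theta=self.theta, alpha=self.alpha
        )

    def _residuals(self, x: np.ndarray, include_tp: bool) -> np.ndarray:
        pred, _ = fvcb_forward(
            self._to_params(x, include_tp),
            self.curve.Ci,
            self.curve.Tleaf,
            self.curve.Q,
            self.kc,
            self.trp,
        )
        return self.curve.A - pred

    def _heuristic_init(self, include_tp: bool) -> np.ndarray:
        """Initial values from the curve's own geometry.

        Vcmax from inverting the Rubisco limb at low Ci, Jmax from inverting
        the electron-transport limb at the CO2-saturated end, Tp from the
        plateau height / 3, Rd = 1.
        """
        c = self.curve
        Tbar = float(np.mean(c.Tleaf))
        from .fvcb import kinetics_at_T

        Kc, Ko, Gs = kinetics_at_T(Tbar, self.kc, self.trp)
        fV = temp_scaler("Vcmax", Tbar, self.trp)
        fJ = temp_scaler("Jmax", Tbar, self.trp)
        fT = temp_scaler("Tp", Tbar, self.trp)
        rd0 = 1.0

        low = (c.Ci < 300) & (c.Ci > Gs + 20)
        if np.any(low):
            vc = (c.A[low] + rd0) * (c.Ci[low] + Kc * (1 + self.kc.O / Ko)) / (
                c.Ci[low] - Gs
            )
            vc = vc[np.isfinite(vc) & (vc > 0)]
            vcmax0 = float(np.median(vc)) / fV if vc.size else 50.0
        else:
            vcmax0 = 50.0

        i_hi = int(np.argmax(c.Ci))
        amax = float(np.max(c.A))
        j_need = (amax + rd0) * (4 * c.Ci[i_hi] + 8 * Gs) / max(c.Ci[i_hi] - Gs, 1.0)
        # invert the non-rectangular hyperbola where irradiance is known
        if c.Q is not None and np.isfinite(c.Q[i_hi]):
            aq = self.alpha * c.Q[i_hi]
            if aq > 1.05 * j_need:
                j_need = j_need * (aq - self.theta * j_need) / (aq - j_need)
        jmax0 = float(j_need) / fJ
        tp0 = (amax + rd0) / 3.0 / fT

        names = self._param_names(include_tp)
        vals = {"Vcmax25": vcmax0, "Jmax25": jmax0, "Tp25": tp0, "Rd25": rd0}
        x0 = np.array([vals[n] for n in names])
        lb, ub = self._bounds(include_tp)
        return np.clip(x0, lb * 1.01, ub * 0.99)

    def _bounds(self, include_tp: bool) -> tuple[np.ndarray, np.ndarray]:
        names = self._param_names(include_tp)
        lb = np.array([_BOUNDS[n][0] for n in names])
        ub = np.array([_BOUNDS[n][1] for n in names])
        return lb, ub

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        include_tp: bool = False,
        init: FvCBParams | None = None,
        seed: int = 0,
        n_starts: int = 5,
    ) -> "ACiResults":
        """Fit by multi-start bounded least squares (Gaussian MLE).

        The Gaussian likelihood is maximised by minimising the residual sum
        of squares over the rate parameters; ``sigma`` is then the MLE
        ``sqrt(SSR/n)``.  ``n_starts`` restarts jitter the heuristic initial
        values multiplicatively (seeded, deterministic).  Standard errors are
        Wald, from the inverse Hessian of the full negative log-likelihood
        (rate parameters and sigma) at the optimum.
        """
        rng = np.random.default_rng(seed)
        names = self._param_names(include_tp)
        lb, ub = self._bounds(include_tp)
        if init is not None:
            vals = {
                "Vcmax25": init.Vcmax25,
                "Jmax25": init.Jmax25,
                "Tp25": init.Tp25 if init.Tp25 is not None else 20.0,
                "Rd25": init.Rd25,
            }
            x0 = np.clip(np.array([vals[n] for n in names]), lb * 1.01, ub * 0.99)
        else:
            x0 = self._heuristic_init(include_tp)

        best = None
        for k in range(n_starts):
            start = x0 if k == 0 else np.clip(
                x0 * rng.uniform(0.7, 1.3, size=x0.size), lb * 1.01, ub * 0.99
            )
            try:
                sol = optimize.least_squares(
                    self._residuals,
                    start,
                    args=(include_tp,),
                    bounds=(lb, ub),
                    method="trf",
                    x_scale=np.maximum(start, 1.0),
                )
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            ssr = float(2.0 * sol.cost)
            if best is None or ssr < best[1] - 1e-12:
                best = (sol.x.copy(), ssr)
        if best is None:
            raise ConvergenceError(
                f"no optimiser restart converged for curve {self.curve.leaf_id!r}"
            )

        xhat, ssr = best
        n = len(self.curve)
        sigma_mle = float(np.sqrt(max(ssr / n, 1e-16)))
        # degrees-of-freedom corrected residual sd: honest noise scale for
        # standard errors and prediction bands at A-Ci sample sizes (~15 obs)
        dof = max(n - len(names), 1)
        sigma = float(np.sqrt(max(ssr / dof, 1e-16)))
        llf = -0.5 * n * (np.log(2.0 * np.pi * sigma_mle**2) + 1.0)
        k_params = len(names) + 1  # + sigma
        aic = 2.0 * k_params - 2.0 * llf

        params = self._to_params(xhat, include_tp)
        pred, states = fvcb_forward(
            params, self.curve.Ci, self.curve.Tleaf, self.curve.Q, self.kc, self.trp
        )

        # Hessian of the full negative log-likelihood at (theta_hat, sigma_hat).
        sig_for_hess = max(sigma, 1e-3)

        def _nll_vec(z):
            try:
                p = self._to_params(np.maximum(z[:-1], 1e-8), include_tp)
                return negloglik(p, max(z[-1], 1e-8), self.curve, self.kc, self.trp)
            except (ValueError, FloatingPointError):
                return np.inf

        z_hat = np.append(xhat, sig_for_hess)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = numdiff.approx_hess(z_hat, _nll_vec)
        reliable = True
        try:
            eigvals = np.linalg.eigvalsh(H)
            if np.any(eigvals <= 0) or not np.all(np.isfinite(H)):
                raise np.linalg.LinAlgError
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            reliable = False
            cov = np.linalg.pinv(np.where(np.isfinite(H), H, 0.0))
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        if np.any(se[:-1] <= 0) or np.any(~np.isfinite(se)):
            reliable = False
        at_bound = np.any(
            (xhat - lb < 1e-6 * np.maximum(np.abs(lb), 1.0))
            | (ub - xhat < 1e-6 * ub)
        )
        if at_bound or sigma < 1e-6:
            reliable = False

        return ACiResults(
            model=self,
            param_names=list(names),
            estimates=xhat,
            sigma=sigma,
            cov=cov,
            se=se,
            llf=float(llf),
            aic=float(aic),
            n_params=k_params,
            states=states,
            fittedvalues=pred,
            tp_included=include_tp,
            reliable=bool(reliable),
            df_resid=int(dof),
        )

    def fit_select(self, seed: int = 0, n_starts: int = 5) -> "ACiResults":
        """Fit with and without the Ap limb and keep the lower-AIC model."""
        with_tp = self.fit(include_tp=True, seed=seed, n_starts=n_starts)
        without_tp = self.fit(include_tp=False, seed=seed, n_starts=n_starts)
        return select_tp_model(with_tp, without_tp)


@dataclass
class ACiResults:
    """Fitted FvCB parameters for one curve, with uncertainties and diagnostics.

    ``estimates``/``se``/``cov`` are ordered as ``param_names`` (+ sigma as
    the trailing row/column of ``cov`` and ``se``).  ``states`` holds the
    limitation state of every observation at the optimum.  ``reliable`` is
    False when the Hessian was singular, a parameter sat on a bound, or the
    residual noise collapsed -- Wald intervals are then not trustworthy.
    """

    model: ACiModel
    param_names: list[str]
    estimates: np.ndarray
    sigma: float
    cov: np.ndarray
    se: np.ndarray
    llf: float
    aic: float
    n_params: int
    states: np.ndarray
    fittedvalues: np.ndarray
    tp_included: bool
    reliable: bool
    df_resid: int

    @property
    def leaf_id(self) -> str:
        return self.model.curve.leaf_id

    @property
    def nobs(self) -> int:
        return len(self.model.curve)

    @property
    def params(self) -> FvCBParams:
        return self.model._to_params(self.estimates, self.tp_included)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.se[:-1], index=self.param_names, name="se")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald confidence intervals for the rate parameters.

        Critical values come from the t distribution with the residual
        degrees of freedom: A-Ci curves have ~15 observations, where the
        normal quantile noticeably under-covers.
        """
        from scipy.stats import t as t_dist

        tcrit = t_dist.ppf(1.0 - alpha / 2.0, self.df_resid)
        lo = self.estimates - tcrit * self.se[:-1]
        hi = self.estimates + tcrit * self.se[:-1]
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.param_names)

    def predict(self, Ci, Tleaf=None, Q=None):
        """Net assimilation at the point estimates (defaults: mean Tleaf, saturating Q)."""
        if Tleaf is None:
            Tleaf = float(np.mean(self.model.curve.Tleaf))
        A, _ = fvcb_forward(self.params, Ci, Tleaf, Q, self.model.kc, self.model.trp)
        return A

    def intervals(self, ci_grid, level: float = 0.95, n_draws: int = 2000, seed: int = 0):
        """Confidence and prediction bands for A over a Ci grid (see curve_intervals)."""
        return curve_intervals(self, ci_grid, level=level, n_draws=n_draws, seed=seed)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"FvCB A-Ci fit: leaf {self.leaf_id}  (n = {self.nobs})",
            f"  Ap limb included: {self.tp_included}   reliable: {self.reliable}",
            f"  logLik = {self.llf:.3f}   AIC = {self.aic:.3f}   sigma = {self.sigma:.4f}",
            f"  {'param':<10}{'estimate':>10}{'se':>10}{'ci95 low':>10}{'ci95 high':>11}",
        ]
        for i, name in enumerate(self.param_names):
            lines.append(
                f"  {name:<10}{self.estimates[i]:>10.3f}{self.se[i]:>10.3f}"
                f"{ci['lower'].iloc[i]:>10.3f}{ci['upper'].iloc[i]:>11.3f}"
            )
        counts = pd.Series([s.value for s in self.states]).value_counts().to_dict()
        lines.append(f"  limitation states: {counts}")
        return "\n".join(lines)

    def plot(self, ax=None, n_draws: int = 500, seed: int = 0):
        """A-Ci curve with fit, 95% mean band (confidence) and prediction band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        grid = np.linspace(max(np.min(c.Ci), 1.0), np.max(c.Ci), 80)
        mean_band, pred_band = self.intervals(grid, n_draws=n_draws, seed=seed)
        ax.fill_between(grid, pred_band[0], pred_band[1], color="0.85", label="95% prediction")
        ax.fill_between(grid, mean_band[0], mean_band[1], color="seagreen", alpha=0.5, label="95% mean")
        ax.plot(grid, self.predict(grid), "k-", lw=1.2, label="fit")
        ax.plot(c.Ci, c.A, "ko", ms=4, label="observed")
        ax.set_xlabel(r"$C_i$ ($\mu$mol mol$^{-1}$)")
        ax.set_ylabel(r"$A$ ($\mu$mol m$^{-2}$ s$^{-1}$)")
        ax.legend(frameon=False)
        return ax


def fit_aci(
    curve: GasExchangeCurve,
    include_tp: bool = False,
    init: FvCBParams | None = None,
    seed: int = 0,
    kc: KineticConstants | None = None,
    trp: TemperatureResponses | None = None,
    n_starts: int = 5,
) -> ACiResults:
    """Functional wrapper: ``ACiModel(curve).fit(...)``."""
    return ACiModel(curve, kc=kc, trp=trp).fit(
        include_tp=include_tp, init=init, seed=seed, n_starts=n_starts
    )


def select_tp_model(fit_with: ACiResults, fit_without: ACiResults) -> ACiResults:
    """Keep the lower-AIC fit of the two; AIC ties go to the model without Ap.

    Both fits must come from the same curve.  The tie tolerance (|dAIC| <
    1e-6) favours parsimony: an Ap limb that never binds leaves the
    likelihood unchanged and is dropped.
    """
    if fit_with.model.curve is not fit_without.model.curve and (
        fit_with.leaf_id != fit_without.leaf_id
        or len(fit_with.model.curve) != len(fit_without.model.curve)
        or not np.array_equal(fit_with.model.curve.Ci, fit_without.model.curve.Ci)
    ):
        raise ValueError("fits come from different curves")
    if not fit_with.tp_included or fit_without.tp_included:
        raise ValueError("expected (with-Ap, without-Ap) fits in that order")
    if abs(fit_with.aic - fit_without.aic) < 1e-6:
        return fit_without
    return fit_with if fit_with.aic < fit_without.aic else fit_without


def curve_intervals(
    fit: ACiResults,
    ci_grid,
    level: float = 0.95,
    n_draws: int = 2000,
    seed: int = 0,
    Tleaf: float | None = None,
    Q: float | None = None,
):
    """Parametric-bootstrap mean and prediction bands over a Ci grid.

    Parameter vectors are drawn from the multivariate normal implied by the
    inverse Hessian, propagated through the forward model for the mean band;
    the prediction band additionally adds Gaussian observation noise with the
    fitted sigma.  Bands are percentile-based and widened, if necessary, to
    contain the point-estimate prediction.

    Returns ``((mean_low, mean_high), (pred_low, pred_high))`` arrays over
    the grid.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    ci_grid = np.atleast_1d(np.asarray(ci_grid, dtype=float))
    rng = np.random.default_rng(seed)
    cov = fit.cov[:-1, :-1]  # rate-parameter block
    try:
        np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    except np.linalg.LinAlgError:
        warnings.warn(
            "parameter covariance not positive definite; using diagonal", RuntimeWarning
        )
        cov = np.diag(np.clip(np.diag(cov), 0.0, np.inf))
    draws = rng.multivariate_normal(fit.estimates, cov, size=n_draws, method="svd")
    lb, ub = fit.model._bounds(fit.tp_included)
    draws = np.clip(draws, lb * 1.0 + 1e-9, ub)

    if Tleaf is None:
        Tleaf = float(np.mean(fit.model.curve.Tleaf))
    preds = np.empty((n_draws, ci_grid.size))
    for i, x in enumerate(draws):
        p = fit.model._to_params(x, fit.tp_included)
        preds[i], _ = fvcb_forward(p, ci_grid, Tleaf, Q, fit.model.kc, fit.model.trp)

    q = 100.0 * np.array([(1 - level) / 2, 1 - (1 - level) / 2])
    mean_lo, mean_hi = np.percentile(preds, q, axis=0)
    noisy = preds + rng.normal(0.0, fit.sigma, size=preds.shape)
    pred_lo, pred_hi = np.percentile(noisy, q, axis=0)

    point = fit.predict(ci_grid, Tleaf=Tleaf, Q=Q)
    mean_lo, mean_hi = np.minimum(mean_lo, point), np.maximum(mean_hi, point)
    pred_lo = np.minimum(pred_lo, mean_lo)
    pred_hi = np.maximum(pred_hi, mean_hi)
    return (mean_lo, mean_hi), (pred_lo, pred_hi)


# ---------------------------------------------------------------------------
# dark respiration


@dataclass
class DarkRespirationRecord:
    """Dark-adapted respiration for one leaf, normalised to 25 degC.

    Efflux is stored positive (respiration releases CO2).  ``Rdark`` is the
    arithmetic mean of the 1 Hz samples, ``se`` the standard error of that
    mean, and ``Rdark25 = Rdark / f(Tleaf)`` with the Rdark Arrhenius factor.
    """

    leaf_id: str
    samples: np.ndarray
    Tleaf: float
    Rdark: float
    Rdark25: float
    se: float
    se25: float


def rdark_from_timeseries(
    samples,
    Tleaf: float,
    leaf_id: str = "leaf",
    trp: TemperatureResponses | None = None,
    min_samples: int = 30,
) -> DarkRespirationRecord:
    """Average a 1 Hz CO2-efflux time series into a temperature-normalised Rdark."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < min_samples:
        raise ValueError(
            f"need at least {min_samples} efflux samples, got {samples.size}"
        )
    mean = float(np.mean(samples))
    if mean < 0:
        warnings.warn(
            f"negative mean CO2 efflux for leaf {leaf_id!r}; keeping the value",
            RuntimeWarning,
        )
    se = float(np.std(samples, ddof=1) / np.sqrt(samples.size)) if samples.size > 1 else 0.0
    f = float(temp_scaler("Rdark", Tleaf, trp))
    return DarkRespirationRecord(
        leaf_id=leaf_id,
        samples=samples,
        Tleaf=float(Tleaf),
        Rdark=mean,
        Rdark25=mean / f,
        se=se,
        se25=se / f,
    )


# ---------------------------------------------------------------------------
# I/O


def read_gas_exchange(path, metadata_path=None) -> list[GasExchangeCurve]:
    """Read per-observation gas-exchange CSV (leaf_id, A, Ci, Tleaf[, Qin]).

    An optional metadata CSV keyed by leaf_id (species, site, campaign, ...)
    is joined onto each curve's metadata dict.
    """
    df = pd.read_csv(path)
    required = {"leaf_id", "A", "Ci", "Tleaf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gas-exchange CSV missing columns: {sorted(missing)}")
    meta = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path)
        meta = {row["leaf_id"]: row.drop("leaf_id").to_dict() for _, row in mdf.iterrows()}
    return [
        GasExchangeCurve.from_dataframe(df, leaf_id, metadata=meta.get(leaf_id))
        for leaf_id in df["leaf_id"].unique()
    ]


def read_dark_respiration(path, trp: TemperatureResponses | None = None):
    """Read a dark-respiration CSV (leaf_id, time_s, efflux, Tleaf) into records."""
    df = pd.read_csv(path)
    records = []
    for leaf_id, sub in df.groupby("leaf_id", sort=False):
        records.append(
            rdark_from_timeseries(
                sub["efflux"].to_numpy(),
                float(sub["Tleaf"].iloc[0]),
                leaf_id=str(leaf_id),
                trp=trp,
            )
        )
    return records


def fits_to_dataframe(fits: Sequence[ACiResults]) -> pd.DataFrame:
    """One row per fitted leaf: estimates, se, Wald ci95, AIC, sigma, flags."""
    rows = []
    for f in fits:
        ci = f.conf_int()
        row = {
            "leaf_id": f.leaf_id,
            "n_obs": f.nobs,
            "tp_included": f.tp_included,
            "reliable": f.reliable,
            "sigma": f.sigma,
            "logLik": f.llf,
            "AIC": f.aic,
        }
        for name in ("Vcmax25", "Jmax25", "Tp25", "Rd25"):
            if name in f.param_names:
                i = f.param_names.index(name)
                row[name] = f.estimates[i]
                row[f"{name}_se"] = f.se[i]
                row[f"{name}_ci95_low"] = ci["lower"].iloc[i]
                row[f"{name}_ci95_high"] = ci["upper"].iloc[i]
            else:
                row[name] = np.nan
                row[f"{name}_se"] = np.nan
                row[f"{name}_ci95_low"] = np.nan
                row[f"{name}_ci95_high"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_fits(fits: Sequence[ACiResults], csv_path, states_json_path=None) -> None:
    """Write the fits table and, optionally, per-observation limitation states."""
    fits_to_dataframe(fits).to_csv(csv_path, index=False)
    if states_json_path is not None:
        payload = {f.leaf_id: [s.value for s in f.states] for f in fits}
        with open(states_json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
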