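"""Conditional quasi-Poisson regression with stratum effects eliminated.

The response is the daily visit count; conditioning on each stratum's total
turns the Poisson likelihood into a within-stratum multinomial whose cell
probabilities are ``softmax`` of the linear predictor, so the thousands of
stratum intercepts are never estimated.  The model is fitted by Newton
iterations on that conditional log-likelihood with analytic gradient and
Hessian; overdispersion is handled quasi-likelihood style by scaling the
model-based covariance with the Pearson dispersion.

This is algebraically identical to Poisson regression on stratum indicator
dummies (and, for event-level data, to conditional logistic regression on
the same referent sets), but orders of magnitude cheaper.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import ScalingSpec
from .splines import NaturalSplineBasis

__all__ = [
    "ConditionalPoissonModel",
    "ConditionalPoissonResults",
    "RiskEstimate",
    "fit_conditional_poisson",
    "estimate_dispersion",
    "rr_per_iqr",
]


@dataclasses.dataclass(frozen=True)
class RiskEstimate:
    """Relative risk per one-IQR exposure increase, with its 95% CI."""

    rr: float
    ci_low: float
    ci_high: float
    iqr: float
    pollutant: str = ""
    lag: int | None = None
    subgroup: str = ""

    def __post_init__(self):
        if not (0 < self.ci_low <= self.rr <= self.ci_high):
            raise ValueError("inconsistent risk estimate (need 0 < low <= rr <= high)")


class ConditionalPoissonModel:
    """Stratum-conditional Poisson model for daily counts and one exposure.

    Parameters
    ----------
    counts : array-like of int
        Daily outcome counts, one value per study day.
    exposure : array-like
        Exposure at the analysis lag, aligned with *counts*.
    strata : array-like of str
        Stratum label per day (year-month-weekday labels from
        :mod:`aircrossover.strata`).
    temperature : array-like, optional
        Temperature at the same lag; entered as a natural cubic spline with
        *spline_df* degrees of freedom (period-wide knot quantiles).
    spline_df : int
        Temperature spline degrees of freedom (default 3).

    Days with a missing count, exposure or temperature are excluded, then
    strata left with fewer than two days or a zero total count are dropped
    (they carry no conditional information); both exclusions are reported on
    the results object.
    """

    def __init__(
        self,
        counts,
        exposure,
        strata,
        temperature=None,
        spline_df: int = 3,
        exposure_name: str = "exposure",
    ):
        counts = np.asarray(counts, dtype=float)
        exposure = np.asarray(exposure, dtype=float)
        strata = np.asarray(strata)
        if not (counts.shape == exposure.shape == strata.shape):
            raise ValueError("counts, exposure and strata must be aligned 1-d arrays")
        keep = np.isfinite(counts) & np.isfinite(exposure)
        if temperature is not None:
            temperature = np.asarray(temperature, dtype=float)
            keep &= np.isfinite(temperature)
        if (counts[np.isfinite(counts)] < 0).any():
            raise ValueError("counts must be non-negative")
        self.n_days_dropped_missing = int((~keep).sum())
        n_strata_initial = np.unique(strata).size

        counts, exposure, strata = counts[keep], exposure[keep], strata[keep]
        if temperature is not None:
            temperature = temperature[keep]

        # drop non-informative strata (singleton after exclusions, or all-zero)
        order = np.argsort(strata, kind="stable")
        counts, exposure, strata = counts[order], exposure[order], strata[order]
        if temperature is not None:
            temperature = temperature[order]
        labels, starts, sizes = _groups(strata)
        totals = np.add.reduceat(counts, starts)
        bad = (sizes < 2) | (totals <= 0)
        if bad.any():
            drop = np.repeat(bad, sizes)
            counts, exposure, strata = counts[~drop], exposure[~drop], strata[~drop]
            if temperature is not None:
                temperature = temperature[~drop]
            labels, starts, sizes = _groups(strata)
        # dropped = non-informative plus strata that lost every day to missingness
        self.n_strata_dropped = n_strata_initial - labels.size
        if counts.size == 0:
            raise ValueError("no informative strata remain after exclusions")

        # within-stratum exposure variation is what identifies beta
        gmean = np.repeat(np.add.reduceat(exposure, starts) / sizes, sizes)
        if np.abs(exposure - gmean).max() < 1e-12:
            raise ValueError(
                "exposure is constant within every stratum; the conditional "
                "likelihood does not involve beta (inestimable)"
            )

        self.endog = counts
        self.strata = strata
        self._starts = starts
        self._sizes = sizes
        self._totals = np.add.reduceat(counts, starts)
        self.spline_df = int(spline_df) if temperature is not None else 0
        self.exposure_name = exposure_name

        cols = [exposure]
        names = [exposure_name]
        self.temperature_basis = None
        if temperature is not None:
            self.temperature_basis = NaturalSplineBasis(temperature, df=spline_df)
            B = self.temperature_basis.design(temperature)
            cols.extend(B.T)
            names.extend(f"ns(temp,{spline_df})[{j + 1}]" for j in range(spline_df))
        X = np.column_stack(cols)
        # a global column shift is stratum-constant, so it leaves the
        # conditional likelihood untouched while improving conditioning
        self._xmean = X.mean(axis=0)
        self.exog = X - self._xmean
        self.param_names = names

        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            raise ValueError("collinear design: exposure and spline columns are rank-deficient")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        count_col: str = "count",
        exposure_col: str = "exposure",
        temperature_col: str | None = "temp_c",
        stratum_col: str = "stratum",
        spline_df: int = 3,
    ) -> "ConditionalPoissonModel":
        temp = None
        if temperature_col is not None and temperature_col in data.columns:
            temp = data[temperature_col].to_numpy(dtype=float)
        return cls(
            data[count_col].to_numpy(dtype=float),
            data[exposure_col].to_numpy(dtype=float),
            data[stratum_col].to_numpy(),
            temperature=temp,
            spline_df=spline_df,
            exposure_name=exposure_col,
        )

    # -- conditional likelihood pieces --------------------------------------
    def _eta_parts(self, params: np.ndarray):
        eta = self.exog @ params
        emax = np.repeat(np.maximum.reduceat(eta, self._starts), self._sizes)
        w = np.exp(eta - emax)
        denom = np.add.reduceat(w, self._starts)
        w /= np.repeat(denom, self._sizes)
        logz = np.maximum.reduceat(eta, self._starts) + np.log(denom)
        return eta, w, logz

    def loglike(self, params) -> float:
        params = np.asarray(params, dtype=float)
        eta, _, logz = self._eta_parts(params)
        return float(self.endog @ eta - self._totals @ logz)

    def score(self, params) -> np.ndarray:
        _, w, _ = self._eta_parts(np.asarray(params, dtype=float))
        mu = np.repeat(self._totals, self._sizes) * w
        return self.exog.T @ (self.endog - mu)

    def hessian(self, params) -> np.ndarray:
        _, w, _ = self._eta_parts(np.asarray(params, dtype=float))
        mu = np.repeat(self._totals, self._sizes) * w
        a = self.exog.T @ (mu[:, None] * self.exog)
        wx = w[:, None] * self.exog
        xbar = np.add.reduceat(wx, self._starts, axis=0)
        b = (self._totals[:, None] * xbar).T @ xbar
        return -(a - b)

    def fitted_means(self, params) -> np.ndarray:
        """Stratum totals distributed over days by the fitted probabilities."""
        _, w, _ = self._eta_parts(np.asarray(params, dtype=float))
        return np.repeat(self._totals, self._sizes) * w

    def fit(
        self,
        start_params=None,
        maxiter: int = 100,
        ll_tol: float = 1e-10,
        score_tol: float = 1e-8,
    ) -> "ConditionalPoissonResults":
        """Newton maximisation of the conditional log-likelihood."""
        p = self.exog.shape[1]
        params = np.zeros(p) if start_params is None else np.asarray(start_params, float).copy()
        ll = self.loglike(params)
        converged = False
        for it in range(1, maxiter + 1):
            g = self.score(params)
            h = self.hessian(params)
            try:
                step = np.linalg.solve(-h, g)
            except np.linalg.LinAlgError as err:
                raise ValueError("singular Hessian (collinear or degenerate design)") from err
            # damped Newton: halve until the log-likelihood does not decrease
            scale = 1.0
            for _ in range(40):
                cand = params + scale * step
                ll_new = self.loglike(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            params, ll_prev, ll = cand, ll, ll_new
            g = self.score(params)
            if (
                abs(ll - ll_prev) < ll_tol * (abs(ll) + 1.0)
                and np.abs(g).max() < score_tol * (1.0 + self._totals.sum())
            ):
                converged = True
                break
        return ConditionalPoissonResults(self, params, ll, converged, it)


def _groups(sorted_labels: np.ndarray):
    labels, starts = np.unique(sorted_labels, return_index=True)
    starts = np.sort(starts)
    sizes = np.diff(np.append(starts, sorted_labels.size))
    return labels, starts, sizes


class ConditionalPoissonResults:
    """Fit of a :class:`ConditionalPoissonModel`.

    Exposes the exposure slope ``beta`` (log-RR per unit), its
    dispersion-scaled standard error ``se_beta``, the Pearson dispersion
    ``phi``, Wald ``pvalue``, convergence diagnostics, and
    :meth:`rr_per_iqr` for IQR-scaled relative risks.
    """

    def __init__(self, model, params, llf, converged, niter):
        self.model = model
        self.params = np.asarray(params)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.niter = int(niter)

        self.n_days_used = int(model.endog.size)
        self.n_strata_used = int(model._totals.size)
        self.n_strata_dropped = model.n_strata_dropped
        self.n_days_dropped_missing = model.n_days_dropped_missing

        info = -model.hessian(self.params)
        self._info = info
        self.phi = self._pearson_dispersion()
        self.cov_params = self.phi * np.linalg.inv(info)
        self.bse = np.sqrt(np.diag(self.cov_params))
        # a perfectly fitted (saturated) stratum set can drive phi, and with
        # it the SEs, to zero; the Wald z is then infinite by convention
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues = self.params / self.bse
        self.pvalues = 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def _pearson_dispersion(self) -> float:
        model = self.model
        mu = model.fitted_means(self.params)
        pearson = float(((model.endog - mu) ** 2 / mu).sum())
        df_resid = self.n_days_used - self.n_strata_used - self.params.size
        self.pearson_chi2 = pearson
        self.df_resid = df_resid
        # with no residual df the dispersion is undefined; fall back to the
        # plain Poisson scale so tiny fixtures still report model-based SEs
        self.phi_defined = df_resid > 0
        return pearson / df_resid if self.phi_defined else 1.0

    # -- headline quantities -------------------------------------------------
    @property
    def beta(self) -> float:
        """Exposure slope: log relative risk per unit concentration."""
        return float(self.params[0])

    @property
    def se_beta(self) -> float:
        return float(self.bse[0])

    @property
    def pvalue(self) -> float:
        return float(self.pvalues[0])

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.fitted_means(self.params)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def rr_per_iqr(
        self,
        scaling: ScalingSpec | float,
        pollutant: str = "",
        lag: int | None = None,
        subgroup: str = "",
    ) -> RiskEstimate:
        """Relative risk (with Wald 95% CI) per one-IQR exposure increase."""
        if not self.converged:
            raise ValueError("cannot report a relative risk from a non-converged fit")
        if isinstance(scaling, ScalingSpec):
            iqr, pollutant = scaling.iqr, pollutant or scaling.pollutant
        else:
            iqr = float(scaling)
        if iqr <= 0:
            raise ValueError("IQR must be positive")
        lo, hi = (self.beta - 1.96 * self.se_beta, self.beta + 1.96 * self.se_beta)
        return RiskEstimate(
            rr=float(np.exp(self.beta * iqr)),
            ci_low=float(np.exp(lo * iqr)),
            ci_high=float(np.exp(hi * iqr)),
            iqr=iqr,
            pollutant=pollutant,
            lag=lag,
            subgroup=subgroup,
        )

    def summary(self) -> str:
        lines = [
            "Conditional Poisson regression (stratum effects eliminated)",
            "=" * 66,
            f"days used:        {self.n_days_used:>8d}    strata used:    {self.n_strata_used:>6d}",
            f"days dropped:     {self.n_days_dropped_missing:>8d}    strata dropped: {self.n_strata_dropped:>6d}",
            f"log-likelihood:   {self.llf:>14.4f}    dispersion phi: {self.phi:>8.4f}",
            f"converged:        {str(self.converged):>8s}    iterations:     {self.niter:>6d}",
            "-" * 66,
            f"{'term':<18s}{'coef':>10s}{'std err':>10s}{'z':>8s}{'P>|z|':>9s}{'[0.025':>9s}{'0.975]':>9s}",
        ]
        ci = self.conf_int()
        for j, name in enumerate(self.model.param_names):
            lines.append(
                f"{name:<18s}{self.params[j]:>10.5f}{self.bse[j]:>10.5f}"
                f"{self.zvalues[j]:>8.2f}{self.pvalues[j]:>9.4f}{ci[j, 0]:>9.4f}{ci[j, 1]:>9.4f}"
            )
        lines.append("=" * 66)
        return "\n".join(lines)

    def to_row(self) -> dict:
        """Flat record mirroring the results-file schema."""
        return {
            "beta": self.beta,
            "se_beta": self.se_beta,
            "p": self.pvalue,
            "n_days": self.n_days_used,
            "n_strata": self.n_strata_used,
            "phi": self.phi,
        }


def fit_conditional_poisson(
    data: pd.DataFrame,
    spline_df: int = 3,
    count_col: str = "count",
    exposure_col: str = "exposure",
    temperature_col: str | None = "temp_c",
    stratum_col: str = "stratum",
) -> ConditionalPoissonResults:
    """One-call fit from a prepared analysis frame."""
    model = ConditionalPoissonModel.from_dataframe(
        data,
        count_col=count_col,
        exposure_col=exposure_col,
        temperature_col=temperature_col,
        stratum_col=stratum_col,
        spline_df=spline_df,
    )
    return model.fit()


def estimate_dispersion(results: ConditionalPoissonResults) -> float:
    """Pearson dispersion of a fit (variance inflation factor phi)."""
    if not results.phi_defined:
        raise ValueError(
            "non-positive residual degrees of freedom: dispersion is undefined "
            f"(n_days={results.n_days_used}, n_strata={results.n_strata_used}, "
            f"p={results.params.size})"
        )
    return results.phi


def rr_per_iqr(results: ConditionalPoissonResults, scaling: ScalingSpec | float, **kw) -> RiskEstimate:
    """Functional form of :meth:`ConditionalPoissonResults.rr_per_iqr`."""
    return results.rr_per_iqr(scaling, **kw)
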