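"""Hierarchical Bayesian estimation of a predictor's intrinsic error.

The model deconvolves three noise sources contaminating an observed
benchmark of M mutations:

* a normal background of true free-energy changes,
  ΔΔG_i^true ~ N(μ_mut, σ_mut²), with μ_mut ~ U(−6, 6) and a flat prior on
  σ_mut (truncated to (0, σ_cap]);
* the predictor's intrinsic error, ΔΔG_i^method ~ N(ΔΔG_i^true, RMSE²),
  where RMSE (the estimand) also carries a flat prior on (0, σ_cap];
* per-mutation statistical noise σ_stat,i on the *observed* prediction for
  stochastic predictors (zero for deterministic rescoring, whose observed
  value *is* the latent prediction);
* known experimental noise σ_exp on the observed experimental value.

Everything is jointly normal given (μ_mut, σ_mut, RMSE), so the M latent
true values are marginalized analytically: each record contributes a
bivariate-normal likelihood for (ΔΔG_i^exp, ΔΔG_i^obs) with covariance
``[[σ_mut²+σ_exp², σ_mut²], [σ_mut², σ_mut²+RMSE²+σ_stat,i²]]``. The
3-parameter posterior is sampled with an affine-invariant ensemble sampler
(emcee); latent true values are recovered afterwards by exact conditional
normal draws. This marginal formulation is mathematically identical to
sampling the full hierarchy but mixes far faster.

Under the zero-bias normal error model the intrinsic MUE follows from the
intrinsic RMSE in closed form: MUE = √(2/π)·RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError
from .records import PredictionRecord
from .transform import ClassificationThreshold

PARAM_NAMES = ("mu_mut", "sigma_mut", "rmse_method")
_LOG_2PI = math.log(2.0 * math.pi)


def mue_from_rmse(rmse: float) -> float:
    """Closed-form MUE implied by an RMSE under zero-bias normal errors.

    E|X| = σ√(2/π) for X ~ N(0, σ²), hence MUE = √(2/π)·RMSE
    (0.99 kcal/mol -> 0.79 kcal/mol).
    """
    if rmse < 0:
        raise ValueError(f"rmse must be non-negative, got {rmse}")
    return math.sqrt(2.0 / math.pi) * rmse


@dataclass
class SamplerSettings:
    """MCMC budget and convergence thresholds.

    ``n_draws`` is the total number of retained posterior samples pooled
    across walkers; ``n_burn`` is the number of discarded adaptation steps
    per walker. ``thin`` keeps every thin-th ensemble step so the retained
    draws are close to independent despite the sampler's autocorrelation.
    """

    n_draws: int = 5000
    n_burn: int = 500
    n_walkers: int = 20
    thin: int = 10
    max_rhat: float = 1.05
    min_ess: float = 400.0
    max_retries: int = 2

    def __post_init__(self) -> None:
        if self.n_draws < 1 or self.n_burn < 0 or self.thin < 1:
            raise ValueError("n_draws must be >= 1, n_burn >= 0, thin >= 1")
        if self.n_walkers < 8:
            raise ValueError("need at least 8 walkers for a 3-d ensemble")


class IntrinsicErrorModel:
    """Measurement-error model for one predictor on one benchmark.

    Parameters
    ----------
    exp_values : array-like, shape (M,)
        Observed experimental ΔΔG values (kcal/mol), non-censored.
    pred_values : array-like, shape (M,)
        Observed predicted ΔΔG values for the method under study.
    sigma_exp : float
        Known experimental noise s.d. (kcal/mol), e.g. 0.57 from the
        between-source RMSE of 0.81 via σ = RMSE/√2.
    sigma_stat : array-like or None
        Per-record statistical s.d. of the observed prediction (standard
        error of the replicate mean). None or zeros for deterministic
        predictors.
    mu_bound : float
        Half-width of the uniform prior on μ_mut (kcal/mol).
    sigma_cap : float
        Upper truncation of the flat priors on σ_mut and RMSE; 10 kcal/mol
        is far above the ~5 kcal/mol dynamic range of kinase benchmarks,
        keeping the prior effectively non-informative yet proper.
    """

    def __init__(
        self,
        exp_values,
        pred_values,
        sigma_exp: float,
        sigma_stat=None,
        mu_bound: float = 6.0,
        sigma_cap: float = 10.0,
    ) -> None:
        self.exp_values = np.asarray(exp_values, dtype=float)
        self.pred_values = np.asarray(pred_values, dtype=float)
        if self.exp_values.shape != self.pred_values.shape:
            raise ValueError("experimental and predicted vectors differ in length")
        self.M = self.exp_values.size
        if self.M < 5:
            raise ValueError(f"need at least 5 records, got {self.M}")
        if sigma_exp <= 0:
            raise ValueError(f"sigma_exp must be positive, got {sigma_exp}")
        self.sigma_exp = float(sigma_exp)
        if sigma_stat is None:
            self.sigma_stat = np.zeros(self.M)
        else:
            self.sigma_stat = np.broadcast_to(
                np.asarray(sigma_stat, dtype=float), (self.M,)
            ).copy()
        if np.any(self.sigma_stat < 0):
            raise ValueError("sigma_stat entries must be non-negative")
        self.mu_bound = float(mu_bound)
        self.sigma_cap = float(sigma_cap)

    @classmethod
    def from_records(
        cls,
        records: Sequence[PredictionRecord],
        method: str,
        sigma_exp: float,
        **kwargs,
    ) -> "IntrinsicErrorModel":
        """Build the model from benchmark records.

        Censored experimental records are excluded (the likelihood needs a
        point value). For stochastic predictors the per-record statistical
        s.d. is the standard error of the replicate mean: sd/√n when raw
        replicates are stored, otherwise the prediction's own sigma.
        """
        usable = [
            r for r in records
            if not r.experimental.censored and method in r.predictions
        ]
        exp_vals = [r.experimental.value for r in usable]
        pred_vals = [r.predictions[method].value for r in usable]
        sig = []
        for r in usable:
            pred = r.predictions[method]
            reps = (r.replicates or {}).get(method)
            if reps and len(reps) >= 2 and pred.sigma > 0:
                sig.append(pred.sigma / math.sqrt(len(reps)))
            else:
                sig.append(pred.sigma)
        return cls(exp_vals, pred_vals, sigma_exp, sig, **kwargs)

    # ----- likelihood ---------------------------------------------------

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        """Marginal log posterior; vectorized over leading walker axis."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        mu, s_mut, rmse = theta[:, 0], theta[:, 1], theta[:, 2]
        out = np.full(theta.shape[0], -np.inf)
        ok = (
            (np.abs(mu) <= self.mu_bound)
            & (s_mut > 0) & (s_mut <= self.sigma_cap)
            & (rmse > 0) & (rmse <= self.sigma_cap)
        )
        if not np.any(ok):
            return out
        a = (s_mut[ok, None]) ** 2                         # σ_mut²
        e = self.sigma_exp**2
        cv = (rmse[ok, None]) ** 2 + self.sigma_stat[None, :] ** 2
        dy = self.exp_values[None, :] - mu[ok, None]
        dc = self.pred_values[None, :] - mu[ok, None]
        det = (a + e) * (a + cv) - a * a
        quad = ((a + cv) * dy * dy - 2.0 * a * dy * dc + (a + e) * dc * dc) / det
        out[ok] = np.sum(-_LOG_2PI - 0.5 * np.log(det) - 0.5 * quad, axis=1)
        return out

    def _initial_guess(self) -> np.ndarray:
        """Method-of-moments start: covariance of (exp, pred) splits the noise."""
        y, c = self.exp_values, self.pred_values
        mu0 = float(np.clip(0.5 * (y.mean() + c.mean()),
                            -self.mu_bound + 0.1, self.mu_bound - 0.1))
        cov = float(np.cov(y, c)[0, 1])
        s_mut0 = math.sqrt(min(max(cov, 0.05), self.sigma_cap**2 * 0.25))
        resid = float(np.var(c, ddof=1) - cov - np.mean(self.sigma_stat**2))
        rmse0 = math.sqrt(min(max(resid, 0.05), self.sigma_cap**2 * 0.25))
        return np.array([mu0, s_mut0, rmse0])

    # ----- sampling -----------------------------------------------------

    def fit(
        self,
        settings: SamplerSettings | None = None,
        seed: int | None = None,
    ) -> "IntrinsicErrorResults":
        """Sample the posterior; retries with a longer burn-in on poor mixing."""
        import emcee

        settings = settings or SamplerSettings()
        rng = np.random.default_rng(seed)
        ndim = 3
        steps_keep = math.ceil(settings.n_draws / settings.n_walkers)
        last_diag = None
        for attempt in range(settings.max_retries + 1):
            # each retry doubles both the burn-in and the thinning interval,
            # so the chain lengthens while the retained draw count is fixed
            burn = settings.n_burn * (2**attempt)
            thin = settings.thin * (2**attempt)
            p0 = self._initial_guess()[None, :] + 0.05 * rng.standard_normal(
                (settings.n_walkers, ndim)
            )
            p0[:, 1:] = np.clip(np.abs(p0[:, 1:]), 1e-3, self.sigma_cap)
            p0[:, 0] = np.clip(p0[:, 0], -self.mu_bound + 1e-3,
                               self.mu_bound - 1e-3)
            sampler = emcee.EnsembleSampler(
                settings.n_walkers, ndim, self.log_posterior, vectorize=True
            )
            sampler.random_state = np.random.RandomState(
                rng.integers(0, 2**32 - 1)
            ).get_state()
            sampler.run_mcmc(p0, burn + steps_keep * thin, progress=False)
            chain = sampler.get_chain(discard=burn, thin=thin)
            diagnostics = _diagnostics(chain)
            last_diag = diagnostics
            converged = bool(
                (diagnostics["rhat"] < settings.max_rhat).all()
                and (diagnostics["ess"] > settings.min_ess).all()
            )
            if converged:
                break
        else:
            raise ConvergenceError(
                "posterior did not converge within the retry budget "
                f"(split-Rhat/ESS thresholds {settings.max_rhat}/{settings.min_ess})",
                diagnostics=last_diag,
            )
        flat = chain.reshape(-1, ndim)[-settings.n_draws:]
        draws = pd.DataFrame(flat, columns=list(PARAM_NAMES))
        return IntrinsicErrorResults(
            model=self,
            draws=draws,
            n_draws=settings.n_draws,
            n_burn=settings.n_burn,
            diagnostics=diagnostics,
            converged=converged,
            seed=seed,
        )


def _diagnostics(chain: np.ndarray) -> pd.DataFrame:
    """Split-Rhat and bulk ESS per parameter from a (steps, walkers, dim) chain."""
    import arviz as az

    posterior = {
        name: np.swapaxes(chain[:, :, i], 0, 1) for i, name in enumerate(PARAM_NAMES)
    }
    idata = az.from_dict(posterior=posterior)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    return pd.DataFrame(
        {
            "rhat": [float(rhat[p].values) for p in PARAM_NAMES],
            "ess": [float(ess[p].values) for p in PARAM_NAMES],
        },
        index=list(PARAM_NAMES),
    )


@dataclass
class IntrinsicErrorResults:
    """Posterior draws, diagnostics and posterior-predictive summaries."""

    model: IntrinsicErrorModel
    draws: pd.DataFrame
    n_draws: int
    n_burn: int
    diagnostics: pd.DataFrame
    converged: bool
    seed: int | None = None
    _latent_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        """Posterior means of (mu_mut, sigma_mut, rmse_method)."""
        return self.draws.mean()

    def credible_interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        tail = 100 * (1 - level) / 2
        lo, hi = np.percentile(self.draws[param], [tail, 100 - tail])
        return float(lo), float(hi)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior summary table (mean, sd, interval, diagnostics)."""
        tail = 100 * (1 - level) / 2
        rows = {}
        for p in PARAM_NAMES:
            d = self.draws[p].to_numpy()
            lo, hi = np.percentile(d, [tail, 100 - tail])
            rows[p] = {
                "mean": d.mean(),
                "sd": d.std(ddof=1),
                f"{tail:g}%": lo,
                f"{100 - tail:g}%": hi,
                "rhat": self.diagnostics.loc[p, "rhat"],
                "ess": self.diagnostics.loc[p, "ess"],
            }
        mue = mue_from_rmse(1.0) * self.draws["rmse_method"].to_numpy()
        lo, hi = np.percentile(mue, [tail, 100 - tail])
        rows["mue_method"] = {
            "mean": mue.mean(), "sd": mue.std(ddof=1),
            f"{tail:g}%": lo, f"{100 - tail:g}%": hi,
            "rhat": np.nan, "ess": np.nan,
        }
        return pd.DataFrame(rows).T

    def __str__(self) -> str:
        lines = [
            "Intrinsic-error posterior",
            f"  records: {self.model.M}   draws: {len(self.draws)}   "
            f"burn-in: {self.n_burn}   converged: {self.converged}",
            self.summary().to_string(float_format=lambda x: f"{x:10.4f}"),
        ]
        return "\n".join(lines)

    # ----- latent true values -------------------------------------------

    def sample_latent_truth(self, seed: int | None = None) -> np.ndarray:
        """Exact conditional draws of ΔΔG_true, shape (n_draws, M).

        Given (μ_mut, σ_mut, RMSE), each latent true value is normal with
        precision 1/σ_mut² + 1/σ_exp² + 1/(RMSE²+σ_stat,i²) and mean the
        precision-weighted blend of prior mean, experimental and predicted
        observations.
        """
        rng = np.random.default_rng(seed)
        m = self.model
        mu = self.draws["mu_mut"].to_numpy()[:, None]
        a = self.draws["sigma_mut"].to_numpy()[:, None] ** 2
        cv = (
            self.draws["rmse_method"].to_numpy()[:, None] ** 2
            + m.sigma_stat[None, :] ** 2
        )
        e = m.sigma_exp**2
        prec = 1.0 / a + 1.0 / e + 1.0 / cv
        mean = (mu / a + m.exp_values[None, :] / e + m.pred_values[None, :] / cv) / prec
        return mean + rng.standard_normal(mean.shape) / np.sqrt(prec)

    # ----- posterior-predictive performance metrics ---------------------

    def posterior_metrics(
        self,
        threshold: ClassificationThreshold,
        replicates_per_draw: int = 1,
        seed: int | None = None,
        n_records: int | None = None,
    ) -> pd.DataFrame:
        """Posterior-predictive intrinsic performance metrics.

        For every posterior draw, simulate ``replicates_per_draw`` synthetic
        benchmarks of ``n_records`` mutations from the generative model at
        that draw's parameters — true values from the mutation background,
        latent predictions offset by N(0, RMSE²) — and score the latent
        predictions against the true values: MUE, RMSE, and the
        classification metrics at ``threshold``. Summaries are means and
        2.5/97.5 percentiles pooled over draws × replicates; sensitivity and
        specificity are skipped (not coerced to 0) on replicates lacking the
        relevant class.
        """
        if replicates_per_draw < 1:
            raise ValueError("replicates_per_draw must be >= 1")
        rng = np.random.default_rng(seed)
        m = n_records or self.model.M
        mu = np.repeat(self.draws["mu_mut"].to_numpy(), replicates_per_draw)[:, None]
        s_mut = np.repeat(
            self.draws["sigma_mut"].to_numpy(), replicates_per_draw
        )[:, None]
        rmse = np.repeat(
            self.draws["rmse_method"].to_numpy(), replicates_per_draw
        )[:, None]
        truth = mu + s_mut * rng.standard_normal((mu.shape[0], m))
        pred = truth + rmse * rng.standard_normal(truth.shape)

        err = pred - truth
        mue_rows = np.mean(np.abs(err), axis=1)
        rmse_rows = np.sqrt(np.mean(err**2, axis=1))
        cut = threshold.cutoff
        res_true = truth > cut
        res_pred = pred > cut
        tp = np.sum(res_true & res_pred, axis=1)
        fn = np.sum(res_true & ~res_pred, axis=1)
        fp = np.sum(~res_true & res_pred, axis=1)
        tn = np.sum(~res_true & ~res_pred, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = (tp + tn) / m
            sens = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan)
            spec = np.where(fp + tn > 0, tn / np.maximum(fp + tn, 1), np.nan)

        def _summarize(x: np.ndarray) -> dict[str, float]:
            return {
                "mean": float(np.nanmean(x)),
                "ci_low": float(np.nanpercentile(x, 2.5)),
                "ci_high": float(np.nanpercentile(x, 97.5)),
            }

        return pd.DataFrame(
            {
                "MUE": _summarize(mue_rows),
                "RMSE": _summarize(rmse_rows),
                "accuracy": _summarize(acc),
                "sensitivity": _summarize(sens),
                "specificity": _summarize(spec),
            }
        ).T

    def plot_posterior(self, ax=None):
        """Histogram of the intrinsic-RMSE posterior (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.draws["rmse_method"], bins=60, density=True, alpha=0.8)
        ax.set_xlabel("intrinsic RMSE (kcal/mol)")
        ax.set_ylabel("posterior density")
        return ax
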