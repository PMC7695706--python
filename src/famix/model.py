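"""Bayesian FA diet-mixing model: Dirichlet diet proportions, normal tracer
likelihood with Residual*Process variance, ensemble MCMC, diagnostics.

The consumer's tracer value for FA ``j`` is modelled as a proportion-weighted
combination of predator-space source means::

    y_ij ~ Normal(mu_ij, sigma_ij)
    mu_ij      = sum_k p_lk * mu'_jk
    sigma_ij^2 = eps_j * sum_k p_lk^2 * sigma'_jk^2

where ``p_l`` is the diet-proportion vector for the factor level ``l`` of
consumer ``i`` (a point on the (K-1)-simplex with a Dirichlet prior,
independent across levels), ``mu'``/``sigma'`` are CC-multiplied source
summaries, and ``eps_j`` is a per-tracer multiplicative residual term scaling
the process (source-mixing) variance — the "Residual*Process" error
structure. Trophic modification is additive in this parameterisation and is
fixed at zero because calibration coefficients are applied to the sources
beforehand (see :func:`famix.fa_data.apply_ccs`).

Usage follows the model/results pattern::

    model = FattyAcidMixingModel(consumers, predator_sources, factor="day")
    res = model.fit(n_chains=3, n_iter=60_000, n_burnin=30_000, seed=1)
    print(res.summary())
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd

from .diagnostics import ConvergenceReport, gelman_rubin, geweke
from .fa_data import ConsumerDataset, SourceSummary

__all__ = [
    "MixingModelSpec",
    "FattyAcidMixingModel",
    "DietEstimationResults",
    "build_model",
    "informative_alpha",
]

_LOG_2PI = math.log(2.0 * math.pi)


def informative_alpha(weights, floor: float = 0.01) -> np.ndarray:
    """Dirichlet concentration vector from prior diet-mass proportions.

    ``alpha_k = K * w_k`` keeps the total concentration equal to K, matching
    the weight of the non-informative Dirichlet(1, ..., 1) prior, so the
    prior's overall strength is unchanged and only its shape moves. Zero
    weights are floored at ``floor`` (a Dirichlet concentration must be
    positive).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("weights must be a 1-D vector with at least two sources")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("all-zero weights carry no prior information")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    return np.maximum(w.size * w, floor)


@dataclass
class MixingModelSpec:
    """Declarative description of one mixing-model fit.

    ``prior_alpha`` may be a single concentration vector (shared by all
    factor levels) or a mapping level -> vector. ``trophic_modification`` is
    an additive per-FA offset retained for completeness; it must be zero when
    sources are already in predator space.
    """

    sources: list[SourceSummary]
    fa_names: list[str] | None = None
    factor_name: str | None = None
    prior_alpha: np.ndarray | dict | None = None
    error_structure: str = "residual_times_process"
    trophic_modification: np.ndarray | None = None
    epsilon_upper: float = 20.0
    variance_floor: float = 1e-6

    def __post_init__(self):
        if len(self.sources) < 2:
            raise ValueError("mixing needs at least two sources (K >= 2)")
        if self.error_structure != "residual_times_process":
            raise ValueError("only the Residual*Process error structure is supported")
        if self.trophic_modification is not None and np.any(
            np.asarray(self.trophic_modification) != 0
        ):
            raise ValueError(
                "additive trophic modification must be zero: apply calibration "
                "coefficients to the sources instead"
            )


def build_model(consumers: ConsumerDataset | None, spec: MixingModelSpec):
    """Construct a fit-ready :class:`FattyAcidMixingModel` from a spec."""
    return FattyAcidMixingModel(
        consumers,
        spec.sources,
        fa_names=spec.fa_names,
        factor=spec.factor_name,
        prior_alpha=spec.prior_alpha,
        epsilon_upper=spec.epsilon_upper,
        variance_floor=spec.variance_floor,
    )


class FattyAcidMixingModel:
    """Bayesian diet-proportion model for proportional FA tracers.

    Parameters
    ----------
    consumers
        Consumer profiles (raw percent data). ``None`` gives a prior-only
        model whose posterior equals the prior — useful for prior checks.
    sources
        Predator-space source summaries (means and SDs already multiplied by
        calibration coefficients). At least two.
    fa_names
        Retained tracer list; defaults to the consumers' FA order (or the
        first source's, for prior-only models).
    factor
        Optional fixed factor: an independent diet vector (and prior) is
        estimated for every level. Without it, one diet vector is shared.
    prior_alpha
        Dirichlet concentration(s); default non-informative (all ones).
    epsilon_upper
        Upper bound of the Uniform prior on the per-tracer residual variance
        multiplier; vague relative to percent-scale tracers.
    variance_floor
        Lower bound applied to predator-space source variances so the
        likelihood stays proper when a source SD is zero.
    """

    def __init__(
        self,
        consumers: ConsumerDataset | None,
        sources: list[SourceSummary],
        fa_names=None,
        factor: str | None = None,
        prior_alpha=None,
        epsilon_upper: float = 20.0,
        variance_floor: float = 1e-6,
    ):
        if len(sources) < 2:
            raise ValueError("mixing needs at least two sources (K >= 2)")
        for s in sources:
            if s.space != "predator":
                raise ValueError(
                    f"source {s.source_name!r} is in prey space; apply calibration "
                    "coefficients (apply_ccs) first"
                )
        if fa_names is None:
            fa_names = consumers.fa_names if consumers is not None else sources[0].fa_names
        self.fa_names = list(fa_names)
        self.source_names = [s.source_name for s in sources]
        if len(set(self.source_names)) != len(sources):
            raise ValueError("source names must be unique")
        self.K = len(sources)
        self.J = len(self.fa_names)
        if self.J < self.K - 1:
            warnings.warn(
                f"only {self.J} tracers for {self.K} sources: mixing geometry is "
                "under-determined and the posterior will lean on the prior",
                stacklevel=2,
            )
        self.mu = np.column_stack([s.restrict(self.fa_names).means for s in sources])
        sds = np.column_stack([s.restrict(self.fa_names).sds for s in sources])
        self.sig2 = np.maximum(sds**2, variance_floor)  # (J, K)
        self.epsilon_upper = float(epsilon_upper)
        if self.epsilon_upper <= 0:
            raise ValueError("epsilon_upper must be positive")

        self.factor = factor
        if consumers is None:
            self.levels = ["all"]
            self._n_l = np.zeros(1)
            self._sumY = np.zeros((1, self.J))
            self._sumY2 = np.zeros((1, self.J))
            self.n_consumers = 0
        else:
            data = consumers.restrict(self.fa_names)
            if factor is not None:
                if factor not in data.factor_names:
                    raise KeyError(f"consumers do not declare factor {factor!r}")
                lv = data.factor_values(factor)
                self.levels = sorted(set(lv), key=_level_key)
            else:
                lv = ["all"] * data.n
                self.levels = ["all"]
            Y = data.to_matrix()
            self.n_consumers = data.n
            L = len(self.levels)
            self._n_l = np.zeros(L)
            self._sumY = np.zeros((L, self.J))
            self._sumY2 = np.zeros((L, self.J))
            for i, level in enumerate(lv):
                l = self.levels.index(level)
                self._n_l[l] += 1
                self._sumY[l] += Y[i]
                self._sumY2[l] += Y[i] ** 2
        self.L = len(self.levels)

        # per-level Dirichlet concentrations
        if prior_alpha is None:
            alpha = {lev: np.ones(self.K) for lev in self.levels}
        elif isinstance(prior_alpha, dict):
            alpha = {lev: np.asarray(prior_alpha[lev], float) for lev in self.levels}
        else:
            a = np.asarray(prior_alpha, float)
            alpha = {lev: a for lev in self.levels}
        for lev, a in alpha.items():
            if a.shape != (self.K,) or np.any(a <= 0):
                raise ValueError(f"prior_alpha for level {lev!r} must be {self.K} positive values")
        self.prior_alpha = alpha
        self._alpha_mat = np.vstack([alpha[lev] for lev in self.levels])  # (L, K)

        self.ndim = self.L * (self.K - 1) + self.J

    # -- parameter transform -------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        """theta (W, ndim) -> (log_p (W, L, K), eps (W, J), log_jacobian (W,))."""
        W = theta.shape[0]
        z = theta[:, : self.L * (self.K - 1)].reshape(W, self.L, self.K - 1)
        z_full = np.concatenate([z, np.zeros((W, self.L, 1))], axis=2)
        z_full -= z_full.max(axis=2, keepdims=True)
        log_p = z_full - np.log(np.exp(z_full).sum(axis=2, keepdims=True))
        w = theta[:, self.L * (self.K - 1):]
        log_sig = -np.logaddexp(0.0, -w)
        log_1msig = -np.logaddexp(0.0, w)
        eps = self.epsilon_upper * np.exp(log_sig)
        # Jacobians: softmax-with-reference |J| = prod_k p_k per level;
        # scaled-sigmoid d(eps)/dw = eps * (1 - eps/upper)
        log_jac = log_p.sum(axis=(1, 2)) + np.sum(log_sig + log_1msig, axis=1)
        return log_p, eps, log_jac

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        """Unnormalised log posterior density, vectorised over walkers.

        Accepts (ndim,) or (W, ndim); returns scalar or (W,).
        """
        theta_in = np.asarray(theta, dtype=float)
        scalar = theta_in.ndim == 1
        theta = np.atleast_2d(theta_in)
        log_p, eps, log_jac = self._unpack(theta)
        p = np.exp(log_p)  # (W, L, K)
        # Dirichlet prior plus transform Jacobian: sum_k (alpha_k-1+1) log p_k
        lp = np.einsum("lk,wlk->w", self._alpha_mat - 1.0, log_p) + log_jac
        # eps ~ Uniform(0, upper): flat, bounds enforced by the transform
        if self.n_consumers > 0:
            m = np.einsum("jk,wlk->wlj", self.mu, p)            # (W, L, J)
            proc = np.einsum("jk,wlk->wlj", self.sig2, p**2)    # (W, L, J)
            var = np.maximum(eps[:, None, :] * proc, 1e-300)
            # sum over consumers via per-level sufficient statistics
            quad = (
                self._sumY2[None]
                - 2.0 * m * self._sumY[None]
                + self._n_l[None, :, None] * m**2
            )
            lp = lp + np.sum(
                -0.5 * self._n_l[None, :, None] * (_LOG_2PI + np.log(var))
                - 0.5 * quad / var,
                axis=(1, 2),
            )
        return float(lp[0]) if scalar else lp

    # -- fitting ---------------------------------------------------------------

    def _initial_state(self, rng: np.random.Generator, n_walkers: int, scale: float):
        theta0 = np.zeros(self.ndim)
        # start eps near 1 (sigmoid^-1(1/upper)); diet at the prior mean (z = 0)
        w0 = math.log(1.0 / (self.epsilon_upper - 1.0)) if self.epsilon_upper > 1 else 0.0
        theta0[self.L * (self.K - 1):] = w0
        return theta0 + scale * rng.standard_normal((n_walkers, self.ndim))

    def fit(
        self,
        n_chains: int = 3,
        n_iter: int = 100_000,
        n_burnin: int = 50_000,
        thin: int = 50,
        seed: int | None = None,
        n_walkers: int | None = None,
        progress: bool = False,
        rhat_threshold: float = 1.05,
        max_init_retries: int = 20,
    ) -> "DietEstimationResults":
        """Sample the posterior with an affine-invariant ensemble sampler.

        Each chain is an independent ensemble run; ``n_iter``/``n_burnin``
        count scalar draws per chain (ensemble steps x walkers), and ``thin``
        keeps every ``thin``-th retained draw. The run is reproducible from
        ``seed``.
        """
        if n_chains < 2:
            raise ValueError("diagnostics need at least two chains")
        if n_iter <= n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        if n_walkers is None:
            n_walkers = max(2 * self.ndim + 2, 16)
        n_walkers += n_walkers % 2
        steps = max(2, math.ceil(n_iter / n_walkers))
        burn = math.ceil(n_burnin / n_walkers)
        if burn >= steps:
            burn = steps // 2

        master = np.random.default_rng(seed)
        chain_draws = []
        chain_steps = []
        for _ in range(n_chains):
            chain_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(chain_seed)
            state = None
            for attempt in range(max_init_retries):
                cand = self._initial_state(rng, n_walkers, 0.1 * (1.0 + attempt))
                if np.all(np.isfinite(self.log_posterior(cand))):
                    state = cand
                    break
            if state is None:
                raise RuntimeError(
                    "could not find a finite-posterior initial ensemble; "
                    "check source summaries and data scaling"
                )
            sampler = emcee.EnsembleSampler(
                n_walkers,
                self.ndim,
                self.log_posterior,
                vectorize=True,
                # differential-evolution moves mix far faster than the default
                # stretch move on these tightly correlated simplex posteriors
                moves=[
                    (emcee.moves.DEMove(), 0.8),
                    (emcee.moves.DESnookerMove(), 0.2),
                ],
            )
            sampler._random = np.random.RandomState(chain_seed)
            sampler.run_mcmc(state, steps, progress=progress)
            chain = sampler.get_chain(discard=burn)          # (S, W, ndim)
            flat = chain.reshape(-1, self.ndim)              # step-major
            chain_draws.append(flat[:: max(1, thin)])
            chain_steps.append(chain)
        draws_theta = np.stack(chain_draws)                  # (C, D, ndim)
        steps_theta = np.stack(chain_steps)                  # (C, S, W, ndim)

        return self._results_from_theta(
            draws_theta,
            steps_theta,
            settings={
                "n_chains": n_chains,
                "n_iter": n_iter,
                "n_burnin": n_burnin,
                "thin": thin,
                "n_walkers": n_walkers,
                "steps": steps,
                "seed": seed,
            },
            rhat_threshold=rhat_threshold,
        )

    def _transform_draws(self, theta_flat: np.ndarray) -> np.ndarray:
        """theta (N, ndim) -> interpretable parameters (N, L*K + J)."""
        log_p, eps, _ = self._unpack(theta_flat)
        N = theta_flat.shape[0]
        return np.concatenate(
            [np.exp(log_p).reshape(N, self.L * self.K), eps], axis=1
        )

    def _results_from_theta(self, draws_theta, steps_theta, settings,
                            rhat_threshold=1.05):
        C, D, _ = draws_theta.shape
        names = [
            f"p[{lev}:{src}]" for lev in self.levels for src in self.source_names
        ] + [f"eps[{fa}]" for fa in self.fa_names]
        P = len(names)
        draws = self._transform_draws(
            draws_theta.reshape(C * D, self.ndim)
        ).reshape(C, D, P)
        rhat = gelman_rubin(draws)
        # Geweke on the per-step ensemble-mean trace: a scalar time series per
        # chain whose stationarity reflects burn-in adequacy, with far milder
        # autocorrelation pathologies than interleaved walker draws
        if steps_theta is not None:
            Cc, S, W, _ = steps_theta.shape
            tr = self._transform_draws(
                steps_theta.reshape(Cc * S * W, self.ndim)
            ).reshape(Cc, S, W, P).mean(axis=2)
            gz = geweke(tr)
        else:
            gz = geweke(draws)
        report = ConvergenceReport(
            names, rhat, gz, rhat_threshold=rhat_threshold
        )
        return DietEstimationResults(
            model=self,
            draws=draws,
            param_names=names,
            diagnostics=report,
            settings=settings,
        )


def _level_key(level: str):
    """Sort factor levels numerically when possible, lexically otherwise."""
    try:
        return (0, float(level), level)
    except ValueError:
        return (1, 0.0, level)


@dataclass
class DietEstimationResults:
    """Posterior draws of diet proportions with summaries and diagnostics.

    ``draws`` has shape (chains, draws_per_chain, parameters); the first
    ``L*K`` parameters are diet proportions per factor level (each level's
    block sums to 1 in every draw), the remaining ``J`` are per-tracer
    residual variance multipliers.
    """

    model: FattyAcidMixingModel
    draws: np.ndarray
    param_names: list[str]
    diagnostics: ConvergenceReport
    settings: dict = field(default_factory=dict)
    _summary: pd.DataFrame | None = field(default=None, repr=False)

    # -- accessors -----------------------------------------------------------

    @property
    def levels(self) -> list[str]:
        return self.model.levels

    @property
    def source_names(self) -> list[str]:
        return self.model.source_names

    def p_draws(self, level: str | None = None) -> np.ndarray:
        """Pooled (all chains) diet-proportion draws, shape (n_draws, K)."""
        L, K = self.model.L, self.model.K
        if level is None:
            if L != 1:
                raise ValueError("specify a level for multi-level fits")
            level = self.levels[0]
        l = self.levels.index(str(level))
        block = self.draws[:, :, l * K:(l + 1) * K]
        return block.reshape(-1, K)

    def epsilon_draws(self) -> np.ndarray:
        return self.draws[:, :, self.model.L * self.model.K:].reshape(
            -1, self.model.J
        )

    def median(self, level: str | None = None) -> dict[str, float]:
        med = np.median(self.p_draws(level), axis=0)
        return dict(zip(self.source_names, med))

    # -- summaries -----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Median and central credible intervals per factor level and source."""
        if self._summary is None:
            rows = []
            for lev in self.levels:
                P = self.p_draws(lev)
                q = np.percentile(P, [2.5, 25, 50, 75, 97.5], axis=0)
                for k, src in enumerate(self.source_names):
                    rows.append(
                        {
                            "level": lev,
                            "source": src,
                            "median": q[2, k],
                            "q2.5": q[0, k],
                            "q25": q[1, k],
                            "q75": q[3, k],
                            "q97.5": q[4, k],
                            "mean": P[:, k].mean(),
                            "sd": P[:, k].std(ddof=1),
                        }
                    )
            self._summary = pd.DataFrame(rows)
        return self._summary

    def summary_text(self) -> str:
        lines = ["Fatty-acid mixing model — posterior diet proportions", ""]
        factor = self.model.factor or "(no factor)"
        lines.append(
            f"sources K={self.model.K}, tracers J={self.model.J}, "
            f"consumers n={self.model.n_consumers}, factor: {factor}"
        )
        lines.append(str(self.diagnostics))
        lines.append("")
        df = self.summary().copy()
        for c in ("median", "q2.5", "q25", "q75", "q97.5", "mean", "sd"):
            df[c] = df[c].map(lambda v: f"{v:.3f}")
        lines.append(df.to_string(index=False))
        return "\n".join(lines)

    def __str__(self):
        return self.summary_text()

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)

    def draws_to_frame(self) -> pd.DataFrame:
        """Plain chains x iterations x parameters table."""
        C, D, P = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(C * D, P), columns=self.param_names)
        df.insert(0, "chain", np.repeat(np.arange(C), D))
        df.insert(1, "iteration", np.tile(np.arange(D), C))
        return df

    def plot_posterior(self, level: str | None = None, ax=None):
        """Violin plot of posterior diet proportions per source."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        P = self.p_draws(level)
        ax.violinplot([P[:, k] for k in range(P.shape[1])], showmedians=True)
        ax.set_xticks(np.arange(1, P.shape[1] + 1), self.source_names, rotation=45)
        ax.set_ylabel("diet proportion")
        ax.set_ylim(0, 1)
        title = f"level {level}" if level is not None else None
        if title:
            ax.set_title(title)
        return ax
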