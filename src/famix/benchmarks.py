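"""Known-truth benchmarks exercising the whole pipeline.

Each function builds a synthetic feeding trial, runs the standard analysis
chain (calibration coefficients -> predator space -> mixing model) and
returns the quantities a validation study reports: recovery of single-prey
and mixed diets, detection of an absent source, the pull of informative
priors, PERMANOVA type-I calibration, agreement of the MCMC with a
brute-force quadrature posterior, and the monotone tracking of a diet
switch. All randomness is controlled by the ``seed`` argument.

MCMC run lengths here are scaled for toy dimensions (K <= 5 sources,
J <= 15 tracers, n <= 10 consumers per level); see the methods notes for the
reasoning behind the sizes.
"""

from __future__ import annotations

import numpy as np

from .fa_data import apply_ccs, average_ccs, compute_ccs
from .model import FattyAcidMixingModel, informative_alpha
from .separation import permanova
from .simulate import (
    absent_source_scenario,
    confusable_pair_scenario,
    scenario_preset,
    simulate_trial,
)

__all__ = [
    "identity_recovery",
    "mixture_recovery",
    "absent_source_detection",
    "prior_pull",
    "permanova_type1_rate",
    "grid_posterior_mean",
    "mcmc_vs_grid",
    "eider_diet_switch",
]

# scaled-down run for toy dimensions: 3 chains x 150k draws, half burn-in
_MCMC = dict(n_chains=3, n_iter=150_000, n_burnin=75_000, thin=50)


def _rng(seed):
    return np.random.default_rng(seed)


def _sub_seed(rng):
    return int(rng.integers(0, 2**31 - 1))


def identity_recovery(seed: int = 0) -> dict:
    """Single-prey truth with CCs computed from the very consumers being fit.

    Uses the low-fat seal design at day 0: a year on herring, CCs = consumer
    means / herring means, sources taken to predator space with those CCs.
    The predator-space herring mean then equals the consumer mean exactly, so
    the fitted share of herring should approach 1.
    """
    rng = _rng(seed)
    sc = scenario_preset("harpseal_lowfat", seed=_sub_seed(rng))
    trial = simulate_trial(sc)
    day0 = trial.consumers.subset("day", "0")
    herring = sc.sources[0]
    cc_hat = compute_ccs(day0, [(herring, 1.0)])
    pred = apply_ccs(sc.sources, cc_hat)
    res = FattyAcidMixingModel(day0, pred).fit(seed=_sub_seed(rng), **_MCMC)
    med = res.median()
    return {
        "true_source_median": med["herring"],
        "n_consumers": day0.n,
        "summary": med,
    }


def mixture_recovery(seed: int = 0) -> dict:
    """Two-oil 70:30 mixture with CCs averaged across the single-oil trials.

    Mirrors the combined-CC treatment: CCs are computed separately from the
    groups fed pure herring oil and pure krill oil, averaged, applied to both
    sources, and the 70:30 group's diet is estimated.
    """
    rng = _rng(seed)
    sc = scenario_preset("salmon_cc", seed=_sub_seed(rng))
    trial = simulate_trial(sc)
    cc_h = compute_ccs(trial.consumers.subset("group", "H100"), [(sc.sources[0], 1.0)])
    cc_k = compute_ccs(trial.consumers.subset("group", "K100"), [(sc.sources[1], 1.0)])
    pred = apply_ccs(sc.sources, average_ccs([cc_h, cc_k]))
    group = trial.consumers.subset("group", "H70K30")
    res = FattyAcidMixingModel(group, pred).fit(seed=_sub_seed(rng), **_MCMC)
    med = res.median()
    truth = dict(zip(sc.source_names, trial.truth_tissue["H70K30"]))
    return {
        "herring_median": med["herring_oil"],
        "krill_median": med["krill_oil"],
        "truth": truth,
        "max_abs_error_pp": 100.0
        * max(abs(med[f"{s}_oil"] - truth[f"{s}_oil"]) for s in ("herring", "krill")),
        "n_consumers": group.n,
    }


def absent_source_detection(seed: int = 0) -> dict:
    """Five-source diet in which one source is never eaten.

    A Bayesian mixing model cannot return an exact zero, so the absent
    source should show the smallest posterior median, close to zero.
    """
    rng = _rng(seed)
    sc = absent_source_scenario(seed=_sub_seed(rng))
    trial = simulate_trial(sc)
    cons = trial.consumers.subset("day", "60")
    cc_hat = compute_ccs(cons, list(zip(sc.sources, sc.initial_diet)))
    pred = apply_ccs(sc.sources, cc_hat)
    res = FattyAcidMixingModel(cons, pred).fit(seed=_sub_seed(rng), **_MCMC)
    med = res.median()
    absent = sc.absent_source
    return {
        "absent_source": absent,
        "absent_median": med[absent],
        "is_minimum": med[absent] == min(med.values()),
        "summary": med,
        "n_consumers": cons.n,
    }


def prior_pull(seed: int = 0) -> dict:
    """Informative versus flat Dirichlet prior on a confusable source pair.

    The scenario's two near-identical sources leave their split almost
    unidentified, so an informative prior (dominant weight 0.72 on source A)
    should move A's posterior median substantially relative to the flat fit.
    """
    rng = _rng(seed)
    sc = confusable_pair_scenario(seed=_sub_seed(rng))
    trial = simulate_trial(sc)
    cons = trial.consumers.subset("day", "60")
    cc_hat = compute_ccs(cons, list(zip(sc.sources, sc.initial_diet)))
    pred = apply_ccs(sc.sources, cc_hat)
    flat = FattyAcidMixingModel(cons, pred).fit(seed=_sub_seed(rng), **_MCMC)
    alpha = informative_alpha(sc.prior_weights)
    informed = FattyAcidMixingModel(cons, pred, prior_alpha=alpha).fit(
        seed=_sub_seed(rng), **_MCMC
    )
    a_flat = flat.median()["A"]
    a_inf = informed.median()["A"]
    return {
        "dominant_flat_median": a_flat,
        "dominant_informed_median": a_inf,
        "pull_points": 100.0 * (a_inf - a_flat),
        "n_consumers": cons.n,
    }


def permanova_type1_rate(
    seed: int = 0,
    n_datasets: int = 1000,
    n_permutations: int = 199,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of the PERMANOVA under a true null.

    Each dataset is one homogeneous population split into two arbitrary
    groups; the rejection rate at the nominal level should match it.
    """
    rng = _rng(seed)
    rejections = 0
    for _ in range(n_datasets):
        X = np.abs(rng.normal(10.0, 2.0, size=(12, 8)))
        res = permanova(
            X,
            ["g1"] * 6 + ["g2"] * 6,
            n_permutations=n_permutations,
            seed=_sub_seed(rng),
        )
        rejections += res.p_value <= alpha
    return {
        "rate": rejections / n_datasets,
        "n_datasets": n_datasets,
        "nominal": alpha,
    }


def grid_posterior_mean(Y, mu, sd, epsilon_upper=20.0, n_grid=2001) -> float:
    """Posterior mean of the first source's share in a 2-source model, by
    brute-force quadrature on the 1-simplex.

    Deterministic and entirely independent of the MCMC code path: for each
    grid point p the per-tracer residual multiplier is marginalised by
    numerical integration over its Uniform(0, upper) prior, and the flat
    Dirichlet(1,1) prior contributes nothing. Serves as the reference in the
    MCMC-versus-quadrature cross-check.
    """
    Y = np.asarray(Y, dtype=float)
    n, J = Y.shape
    pgrid = np.linspace(1e-4, 1 - 1e-4, n_grid)
    eps = np.concatenate(
        [np.linspace(1e-6, 0.5, 1500), np.linspace(0.5, epsilon_upper, 1500)[1:]]
    )
    logpost = np.empty_like(pgrid)
    for i, p in enumerate(pgrid):
        w = np.array([p, 1.0 - p])
        m = mu @ w
        v = (sd**2) @ (w**2)
        total = 0.0
        for j in range(J):
            q = np.sum((Y[:, j] - m[j]) ** 2)
            ll = -0.5 * n * np.log(2 * np.pi * eps * v[j]) - q / (2 * eps * v[j])
            mx = ll.max()
            total += mx + np.log(
                np.trapezoid(np.exp(ll - mx), eps) / epsilon_upper
            )
        logpost[i] = total
    f = np.exp(logpost - logpost.max())
    z = np.trapezoid(f, pgrid)
    return float(np.trapezoid(pgrid * f, pgrid) / z)


def mcmc_vs_grid(seed: int = 0) -> dict:
    """Posterior-mean agreement between the sampler and the quadrature
    reference on a small 2-source problem, in Monte-Carlo standard errors
    (between-chain spread of the chain means)."""
    from .fa_data import CCSet, ConsumerDataset, FAProfile, SourceSummary

    rng = _rng(seed)
    fa = ["a", "b", "c"]
    sources = [
        SourceSummary("A", fa, [30.0, 8.0, 12.0], [3.0, 1.0, 2.0]),
        SourceSummary("B", fa, [6.0, 25.0, 15.0], [2.0, 3.0, 2.0]),
    ]
    pred = apply_ccs(sources, CCSet(fa, np.ones(3)))
    mu = np.column_stack([s.means for s in pred])
    sd = np.column_stack([s.sds for s in pred])
    w = np.array([0.6, 0.4])
    n = 6
    Y = rng.normal(mu @ w, sd @ w, size=(n, 3))
    Y = np.abs(Y)
    cons = ConsumerDataset([FAProfile(fa, Y[i], f"c{i}") for i in range(n)])
    grid_mean = grid_posterior_mean(Y, mu, sd)
    res = FattyAcidMixingModel(cons, pred).fit(
        n_chains=4, n_iter=200_000, n_burnin=100_000, thin=50, seed=_sub_seed(rng)
    )
    chain_means = res.draws[:, :, 0].mean(axis=1)
    mcmc_mean = float(chain_means.mean())
    se = float(chain_means.std(ddof=1) / np.sqrt(chain_means.size))
    return {
        "grid_mean": grid_mean,
        "mcmc_mean": mcmc_mean,
        "mc_se": se,
        "diff_in_se": abs(mcmc_mean - grid_mean) / se,
        "n_consumers": n,
    }


def eider_diet_switch(seed: int = 0) -> dict:
    """Diet-switch tracking in the sea-duck scenario.

    Both post-switch diets contain less of the initial staple (the
    formulated feed) than the maintenance diet did, so under incomplete
    turnover the tissue share of that staple falls monotonically across
    biopsy days 0 -> 21 -> 50 and the estimated share of the combined new
    diets rises. CCs are computed from the day-0 consumers on the known
    maintenance diet, as in the original design.
    """
    rng = _rng(seed)
    sc = scenario_preset("eider_switch", seed=_sub_seed(rng))
    trial = simulate_trial(sc)
    day0 = trial.consumers.subset("day", "0")
    cc_hat = compute_ccs(day0, list(zip(sc.sources, sc.initial_diet)))
    pred = apply_ccs(sc.sources, cc_hat)
    res = FattyAcidMixingModel(trial.consumers, pred, factor="day").fit(
        seed=_sub_seed(rng), **_MCMC
    )
    staple = "mazuri"
    new_share = {d: 1.0 - res.median(d)[staple] for d in ("0", "21", "50")}
    return {
        "new_diet_share": new_share,
        "strictly_increasing": new_share["0"] < new_share["21"] < new_share["50"],
        "medians": {d: res.median(d) for d in ("0", "21", "50")},
        "truth_tissue": {
            d: dict(zip(sc.source_names, trial.truth_tissue[d]))
            for d in ("0", "21", "50")
        },
        "n_consumers": trial.consumers.n,
    }
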