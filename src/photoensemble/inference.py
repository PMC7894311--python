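"""Bayesian estimation of V_cmax,25, J_max,25 and θ_cj from an A-Ci curve.

The fitted model is the two-limitation (carboxylation / RuBP-regeneration)
demand-side model with quadratic smoothing between the two rates, evaluated
at each record's *measured* Ci (standard A-Ci practice: the instrument
reports Ci, so no stomatal solve enters the likelihood).  Residuals are iid
Gaussian with an unknown scale σ sampled as a nuisance parameter.

Sampling uses DREAM (DiffeRential Evolution Adaptive Metropolis): multiple
chains propose jumps from scaled differences of randomly chosen chain pairs,
update random parameter subsets ("crossover") with adapted probabilities,
periodically take unit-scale mode-jumping steps, and reset outlier chains.
Convergence is monitored with the Gelman-Rubin R statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .params import Environment, PhotoParams
from .photo_core import (
    ac_gross,
    aj_gross,
    electron_transport,
    gamma_star,
    net_assimilation,
    smaller_root,
)
from .synthetic import AciCurve

__all__ = [
    "PriorSet",
    "ChainEnsemble",
    "FitSettings",
    "log_likelihood",
    "truncate_tpu_region",
    "dream_sample",
    "gelman_rubin",
    "fit_aci",
]


@dataclass
class PriorSet:
    """Independent uniform priors (lower, upper) per sampled parameter."""

    bounds: dict = field(default_factory=lambda: {
        "vcmax25": (100.0, 200.0),
        "jmax25": (70.0, 400.0),
        "theta_cj": (0.9, 1.0),
        "sigma": (1e-3, 5.0),
    })

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid prior bounds for {name}: ({lo}, {hi})")

    @property
    def names(self) -> tuple:
        return tuple(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds.values()])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds.values()])

    def sample(self, n, rng) -> np.ndarray:
        return self.lower + (self.upper - self.lower) * rng.random((n, len(self.bounds)))

    def in_support(self, x: np.ndarray) -> np.ndarray:
        return np.all((x >= self.lower) & (x <= self.upper), axis=-1)


@dataclass
class ChainEnsemble:
    """Full sampling history of a DREAM run."""

    samples: np.ndarray        # (n_iter, n_chains, d)
    log_post: np.ndarray       # (n_iter, n_chains)
    names: tuple
    crossover_probs: np.ndarray
    acceptance_rate: float
    outlier_resets: int
    seed: object = None


def predict_a(vcmax25, jmax25, theta_cj, ci_pa, template: PhotoParams,
              env: Environment):
    """Demand-side A at measured Ci for the two-limitation smoothed model.

    ``vcmax25``/``jmax25``/``theta_cj`` broadcast against ``ci_pa``; kinetic
    constants, the light response curvature θ_j and the R_d scaling come from
    ``template``.
    """
    p = template.replace(vcmax25=vcmax25, jmax25_fixed=jmax25, theta_cj=theta_cj)
    gstar = gamma_star(p, env)
    ac = ac_gross(ci_pa, p, env)
    j = electron_transport(env.irradiance, p, "nonrect_fw")
    aj = aj_gross(ci_pa, j, gstar)
    ag = smaller_root(theta_cj, ac, aj)
    return net_assimilation(ag, ci_pa, gstar, p.rd)


def make_log_likelihood(curve: AciCurve, template: PhotoParams | None = None,
                        env: Environment | None = None) -> Callable:
    """Vectorized Gaussian iid log-likelihood over (vcmax, jmax, θ_cj, σ) rows."""
    template = template or PhotoParams()
    env = env or curve.env
    ci = curve.data["ci_pa"].to_numpy(dtype=float)
    a_obs = curve.data["a_umol_m2_s"].to_numpy(dtype=float)
    usable = np.isfinite(ci) & np.isfinite(a_obs) & (ci > 0)
    ci, a_obs = ci[usable], a_obs[usable]
    n_rec = len(ci)

    def loglik(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        vc, jm, tcj, sig = (theta[:, i][:, None] for i in range(4))
        with np.errstate(all="ignore"):
            pred = predict_a(vc, jm, tcj, ci[None, :], template, env)
            ss = np.sum((a_obs[None, :] - pred) ** 2, axis=1)
            out = -0.5 * n_rec * np.log(2.0 * np.pi * sig[:, 0] ** 2) \
                - ss / (2.0 * sig[:, 0] ** 2)
        out = np.where(np.isfinite(out), out, -np.inf)
        return out if theta.ndim == 2 else out[0]

    loglik.n_records = n_rec
    return loglik


def log_likelihood(theta, curve: AciCurve, template: PhotoParams | None = None,
                   env: Environment | None = None):
    """Gaussian iid log-likelihood of one (vcmax, jmax, θ_cj, σ) vector."""
    return float(make_log_likelihood(curve, template, env)(np.asarray(theta))[0])


def truncate_tpu_region(curve: AciCurve, k: int = 5, window: int = 5) -> AciCurve:
    """Drop records above the onset of a sustained decline of A with Ca.

    A decline of ``k`` consecutive smoothed points flags TPU-affected (or
    otherwise non-monotone) high-Ca behaviour; records above the detected
    onset are removed.  No-op when the smoothed curve never declines.
    """
    df = curve.data
    order = df["ca_set_umol_mol"].to_numpy(dtype=float).argsort(kind="stable")
    ca_sorted = df["ca_set_umol_mol"].to_numpy(dtype=float)[order]
    a_sorted = df["a_umol_m2_s"].to_numpy(dtype=float)[order]
    smooth = pd.Series(a_sorted).rolling(window, center=True, min_periods=1).mean().to_numpy()
    dec = np.diff(smooth) < 0
    run = 0
    onset = None
    for i, d in enumerate(dec):
        run = run + 1 if d else 0
        if run >= k:
            onset = i - k + 1
            break
    if onset is None:
        return curve
    ca_cut = ca_sorted[onset]
    return curve.subset(df["ca_set_umol_mol"] <= ca_cut)


def dream_sample(loglik: Callable, priors: PriorSet, n_chains: int = 7,
                 n_iter: int = 5000, seed=0, n_cr: int = 3,
                 delta_max: int = 3, adapt_frac: float = 0.2,
                 jitter: float = 1e-6) -> ChainEnsemble:
    """DREAM sampler with adaptive crossover and outlier-chain resets.

    Proposals: x* = x + (1+e)·γ(δ,d')·Σ_{j=1..δ}(x_r1j - x_r2j) + ε on a
    random subset of d' dimensions, γ = 2.38/sqrt(2δd'), with γ = 1 every
    fifth generation (mode jumps).  Crossover probabilities are adapted over
    the first ``adapt_frac`` of the run from normalized squared jump
    distances; outlier chains (mean log-posterior below Q1 - 2·IQR over the
    second half of history) are reset to the state of a random healthy chain
    during the adaptation phase.
    """
    if n_chains < 3:
        raise ValueError("need at least 3 chains")
    rng = np.random.default_rng(seed)
    lo, hi = priors.lower, priors.upper
    width = hi - lo
    d = len(lo)

    delta_max = max(1, min(delta_max, (n_chains - 1) // 2))
    x = priors.sample(n_chains, rng)
    lp = loglik(x)
    samples = np.empty((n_iter, n_chains, d))
    log_post = np.empty((n_iter, n_chains))

    cr_values = (np.arange(n_cr) + 1) / n_cr
    p_cr = np.full(n_cr, 1.0 / n_cr)
    j_dist = np.zeros(n_cr)
    n_use = np.zeros(n_cr)
    n_accept = 0
    n_total = 0
    outlier_resets = 0
    adapt_until = int(adapt_frac * n_iter)

    for t in range(n_iter):
        gamma_unit = (t % 5) == 4
        proposals = np.empty_like(x)
        cr_idx = rng.choice(n_cr, size=n_chains, p=p_cr)
        masks = np.zeros((n_chains, d), dtype=bool)
        for i in range(n_chains):
            delta = rng.integers(1, delta_max + 1)
            others = np.delete(np.arange(n_chains), i)
            pick = rng.choice(others, size=2 * delta, replace=False)
            diff = x[pick[:delta]].sum(axis=0) - x[pick[delta:]].sum(axis=0)
            mask = rng.random(d) < cr_values[cr_idx[i]]
            if not mask.any():
                mask[rng.integers(d)] = True
            masks[i] = mask
            d_eff = mask.sum()
            gamma = 1.0 if gamma_unit else 2.38 / np.sqrt(2.0 * delta * d_eff)
            e = rng.uniform(-0.1, 0.1, d)
            step = (1.0 + e) * gamma * diff + rng.normal(0.0, jitter * width, d)
            prop = x[i].copy()
            prop[mask] += step[mask]
            proposals[i] = prop
        # reflect proposals at the prior bounds
        over = proposals > hi
        under = proposals < lo
        proposals = np.where(over, 2 * hi - proposals, proposals)
        proposals = np.where(under, 2 * lo - proposals, proposals)
        proposals = np.clip(proposals, lo, hi)

        lp_prop = loglik(proposals)
        accept = np.log(rng.random(n_chains)) < (lp_prop - lp)
        if not gamma_unit:
            # track normalized squared jump distance for CR adaptation
            var = x.var(axis=0) + 1e-12
            sq = (((proposals - x) ** 2) / var).sum(axis=1)
            for m in range(n_cr):
                sel = (cr_idx == m) & accept
                j_dist[m] += sq[sel].sum()
                n_use[m] += (cr_idx == m).sum()
        x = np.where(accept[:, None], proposals, x)
        lp = np.where(accept, lp_prop, lp)
        n_accept += int(accept.sum())
        n_total += n_chains
        samples[t] = x
        log_post[t] = lp

        if t < adapt_until and t > 0 and (t + 1) % 50 == 0:
            if (n_use > 0).all() and j_dist.sum() > 0:
                p_new = (j_dist / np.maximum(n_use, 1))
                if p_new.sum() > 0:
                    p_cr = 0.9 * p_cr + 0.1 * p_new / p_new.sum()
                    p_cr /= p_cr.sum()
            # outlier chains: mean log-posterior over the second half so far
            half = log_post[(t + 1) // 2: t + 1]
            means = half.mean(axis=0)
            q1, q3 = np.percentile(means, [25, 75])
            bad = means < q1 - 2.0 * (q3 - q1)
            if bad.any() and not bad.all():
                good = np.flatnonzero(~bad)
                for i in np.flatnonzero(bad):
                    src = rng.choice(good)
                    x[i] = x[src]
                    lp[i] = lp[src]
                    outlier_resets += 1

    if n_accept == 0:
        raise RuntimeError("DREAM failure: no proposal accepted in the whole run")
    return ChainEnsemble(samples=samples, log_post=log_post, names=priors.names,
                         crossover_probs=p_cr,
                         acceptance_rate=n_accept / n_total,
                         outlier_resets=outlier_resets, seed=seed)


def gelman_rubin(samples: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor R-hat per parameter.

    ``samples`` has shape (n_iter, n_chains, d).  R-hat = sqrt(V̂/W) with
    V̂ the pooled posterior-variance estimate from within- (W) and between-
    chain (B) variances.
    """
    n, m, d = samples.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains and >= 10 retained samples")
    chain_means = samples.mean(axis=0)
    chain_vars = samples.var(axis=0, ddof=1)
    w = chain_vars.mean(axis=0)
    b_over_n = chain_means.var(axis=0, ddof=1)
    v_hat = (n - 1) / n * w + (1.0 + 1.0 / m) * b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(v_hat / w)
    return np.where(w > 0, rhat, 1.0)


@dataclass
class FitSettings:
    n_chains: int = 7
    n_iter: int = 4000
    seed: int = 0
    rhat_threshold: float = 1.1
    thin_to: float = 0.01     # retain this fraction of post-convergence draws
    min_retained: int = 400   # floor on retained draws at short test budgets
    truncate_k: int = 5


@dataclass
class AciFit:
    converged: bool
    rhat: np.ndarray
    summary: pd.DataFrame | None
    posterior: pd.DataFrame | None
    ensemble: ChainEnsemble
    n_records: int


def fit_aci(curve: AciCurve, priors: PriorSet | None = None,
            settings: FitSettings | None = None,
            template: PhotoParams | None = None) -> AciFit:
    """Truncate, sample, check convergence, thin, and summarize.

    Posterior summaries (mean, SD, 2.5/97.5 percentiles) are withheld when
    R-hat exceeds the threshold at the end of the budget.
    """
    priors = priors or PriorSet()
    settings = settings or FitSettings()
    curve = truncate_tpu_region(curve, k=settings.truncate_k)
    if len(curve) < 20:
        raise ValueError("need at least 20 usable records to fit")
    loglik = make_log_likelihood(curve, template=template)
    ens = dream_sample(loglik, priors, n_chains=settings.n_chains,
                       n_iter=settings.n_iter, seed=settings.seed)

    # earliest checkpoint from which the remaining history is converged
    n_iter = ens.samples.shape[0]
    start = None
    for frac in (0.1, 0.2, 0.3, 0.4, 0.5):
        s = int(frac * n_iter)
        rhat = gelman_rubin(ens.samples[s:])
        if np.all(rhat < settings.rhat_threshold):
            start = s
            break
    final_rhat = gelman_rubin(ens.samples[n_iter // 2:])
    if start is None:
        return AciFit(converged=False, rhat=final_rhat, summary=None,
                      posterior=None, ensemble=ens, n_records=loglik.n_records)

    post = ens.samples[start:]
    n_post = post.shape[0] * post.shape[1]
    keep = max(int(round(settings.thin_to * n_post)), min(settings.min_retained, n_post))
    stride = max(1, post.shape[0] * post.shape[1] // keep // post.shape[1])
    thinned = post[::stride].reshape(-1, post.shape[2])
    posterior = pd.DataFrame(thinned, columns=ens.names)
    summary = posterior.agg(["mean", "std"]).T
    summary["q2.5"] = posterior.quantile(0.025)
    summary["q97.5"] = posterior.quantile(0.975)
    return AciFit(converged=True, rhat=final_rhat, summary=summary,
                  posterior=posterior, ensemble=ens, n_records=loglik.n_records)
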