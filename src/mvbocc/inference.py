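"""Bayesian inference utilities: posterior sampling, convergence diagnostics,
WAIC model comparison and candidate-set construction/ranking.

Priors are independent standard logistic distributions on every coefficient
(a weakly informative choice on the logit scale: the implied probability is
uniform when a single intercept is transformed).  Sampling uses independent
affine-invariant ensembles (emcee); each "chain" is one ensemble whose
post-warmup walker draws are pooled, which preserves the multi-chain
structure the split-Rhat diagnostic needs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import emcee
import numpy as np
import pandas as pd

from .model import MultispeciesOccupancyModel, MultispeciesOccupancyResults
from .modelspec import PAIR_SEP, ModelSpec

__all__ = [
    "PosteriorDraws",
    "log_posterior",
    "sample_posterior",
    "rhat",
    "waic",
    "WAICResult",
    "waic_weights",
    "build_candidate_set",
    "rank_models",
    "ModelRanking",
]


@dataclass
class PosteriorDraws:
    """Posterior sample with chain structure.

    ``draws`` has shape (chains, draws_per_chain, n_params); within a chain,
    draws are ordered by sampler step (walkers interleaved within a step) so
    split-half diagnostics compare early against late portions of the run.
    """

    draws: np.ndarray
    names: tuple[str, ...]
    seed: int
    warmup: int

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        self.names = tuple(self.names)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, draws, params)")
        if self.draws.shape[2] != len(self.names):
            raise ValueError("parameter name count mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])


def log_posterior(params, model: MultispeciesOccupancyModel) -> float:
    """Sum of site log-likelihoods plus logistic(0, 1) log prior density."""
    return model.logposterior(params)


def _chain_seed(seed: int, index: int) -> int:
    # derived per-chain seeds kept below 2**31
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


def sample_posterior(
    model: MultispeciesOccupancyModel,
    chains: int = 3,
    iterations: int = 2000,
    warmup: int = 1000,
    *,
    seed: int,
    nwalkers: int | None = None,
    progress: bool = False,
) -> PosteriorDraws:
    """Draw from the posterior with independent ensemble-MCMC chains.

    Each chain runs an affine-invariant ensemble of walkers for
    ``iterations`` steps, discarding the first ``warmup``.  The same seed
    always yields identical draws.
    """
    if chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    if not (0 < warmup < iterations):
        raise ValueError("need 0 < warmup < iterations")
    ndim = model.n_params
    if nwalkers is None:
        nwalkers = max(2 * ndim + 2, 8)
    nwalkers += nwalkers % 2

    all_chains = []
    for c in range(chains):
        rs = np.random.RandomState(_chain_seed(seed, c))
        p0 = 0.5 * rs.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, model.logposterior)
        sampler.random_state = rs.get_state()
        sampler.run_mcmc(p0, iterations, progress=progress)
        chain = sampler.get_chain(discard=warmup)  # (steps, walkers, ndim)
        all_chains.append(chain.reshape(-1, ndim))  # step-major ordering
    draws = PosteriorDraws(
        np.stack(all_chains), tuple(model.param_names), seed=int(seed), warmup=int(warmup)
    )
    r = rhat(draws.draws)
    if np.any(r > MultispeciesOccupancyResults.RHAT_THRESHOLD):
        worst = model.param_names[int(np.argmax(r))]
        warnings.warn(
            f"possible non-convergence: max Rhat {r.max():.3f} ({worst}); "
            "consider more iterations"
        )
    return draws


def rhat(draws) -> np.ndarray:
    """Split-chain potential scale reduction factor (Brooks-Gelman-Rubin).

    Each chain is split in half; Rhat per parameter is
    ``sqrt(((n-1)/n * W + B/n) / W)`` with ``W`` the mean within-sequence
    variance and ``B/n`` the between-sequence variance of sequence means.
    Parameters with zero total variance are reported as 1.0 with a warning.
    """
    x = draws.draws if isinstance(draws, PosteriorDraws) else np.asarray(draws, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    c, n, k = x.shape
    if c < 2:
        raise ValueError("need >= 2 chains")
    half = n // 2
    if half < 2:
        raise ValueError("need >= 4 draws per chain for split Rhat")
    seqs = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)  # (2c, half, k)
    means = seqs.mean(axis=1)
    W = seqs.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    out = np.ones(k)
    ok = W > 0
    var_hat = (half - 1) / half * W[ok] + B_over_n[ok]
    out[ok] = np.sqrt(var_hat / W[ok])
    if not ok.all():
        warnings.warn("zero within-chain variance; Rhat reported as 1.0")
    return out


class WAICResult(NamedTuple):
    waic: float
    p_waic: float
    lppd: float


def waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """Watanabe-Akaike information criterion from a (draws, sites) matrix.

    ``lppd = sum_s log mean_d exp(ll[d, s])``; the effective parameter count
    uses the variance form ``p_waic = sum_s var_d(ll[d, s])``;
    ``WAIC = -2 (lppd - p_waic)`` (deviance scale, smaller is better).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, sites)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihood")
    from scipy.special import logsumexp

    d = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(d)))
    p = float(np.sum(ll.var(axis=0, ddof=1))) if d > 1 else 0.0
    return WAICResult(waic=-2.0 * (lppd - p), p_waic=p, lppd=lppd)


def waic_weights(waics: Sequence[float]) -> np.ndarray:
    """Akaike-style weights ``exp(-0.5 dWAIC_i) / sum_j exp(-0.5 dWAIC_j)``,
    with differences taken against the minimum for numerical stability."""
    w = np.asarray(list(waics), dtype=float)
    if w.size < 1:
        raise ValueError("need at least one model")
    lik = np.exp(-0.5 * (w - w.min()))
    return lik / lik.sum()


def build_candidate_set(grammar: Mapping) -> list[ModelSpec]:
    """Enumerate a candidate model set from a structural grammar.

    The grammar declares the species list, a ``base`` block (occurrence and
    detection terms always present) and ``axes``: named lists of options,
    each option optionally contributing pairwise occurrence terms and/or
    detection modifiers.  The candidate set is the deterministic cartesian
    product over axes; structurally duplicate models are dropped with a
    warning.  An optional ``expected_count`` is checked.
    """
    species = tuple(grammar["species"])
    base = grammar["base"]
    axes = grammar.get("axes", [])
    specs: list[ModelSpec] = []
    seen = set()
    for combo in itertools.product(*[ax["options"] for ax in axes]) if axes else [()]:
        pairs: dict[tuple[str, str], tuple[str, ...]] = {}
        modifiers: list[tuple[str, str]] = []
        labels = []
        for ax, opt in zip(axes, combo):
            labels.append(f"{ax['name']}={opt['label']}")
            for key, terms in (opt.get("pairs") or {}).items():
                a, _, b = key.partition(PAIR_SEP)
                pairs[(a, b)] = tuple(terms)
            for m in opt.get("modifiers") or []:
                modifiers.append((m[0], m[1]))
        spec = ModelSpec(
            species=species,
            occurrence={sp: tuple(t) for sp, t in base["occurrence"].items()},
            detection={sp: tuple(t) for sp, t in base["detection"].items()},
            pairs=pairs,
            modifiers=tuple(modifiers),
            name=", ".join(labels) or str(grammar.get("name", "base")),
        )
        k = spec.key()
        if k in seen:
            warnings.warn(f"duplicate candidate model dropped: {spec.name}")
            continue
        seen.add(k)
        specs.append(spec)
    expected = grammar.get("expected_count")
    if expected is not None and len(specs) != int(expected):
        warnings.warn(
            f"candidate set has {len(specs)} models but grammar declares {expected}"
        )
    return specs


@dataclass
class ModelRanking:
    """WAIC-ordered candidate-set ranking with per-model convergence flags."""

    table: pd.DataFrame
    results: dict[str, MultispeciesOccupancyResults]

    @property
    def top(self) -> MultispeciesOccupancyResults:
        return self.results[self.table.index[0]]


def rank_models(
    specs: Sequence[ModelSpec],
    history,
    site_covariates: pd.DataFrame,
    *,
    chains: int = 3,
    iterations: int = 2000,
    warmup: int = 1000,
    seed: int,
    standardize: bool = True,
    nwalkers: int | None = None,
    exclude_nonconverged: bool = False,
    max_waic_draws: int = 2000,
    progress: bool = False,
) -> ModelRanking:
    """Fit every candidate, compute WAIC and weights, return the ordered table.

    Non-convergent fits are flagged; they only lose their weight (set to 0,
    others renormalised) when ``exclude_nonconverged`` is set.
    """
    if len(specs) == 0:
        raise ValueError("empty candidate set")
    rows = []
    results: dict[str, MultispeciesOccupancyResults] = {}
    for m, spec in enumerate(specs):
        name = spec.name or f"model_{m}"
        model = MultispeciesOccupancyModel(history, site_covariates, spec, standardize=standardize)
        res = model.fit(
            chains=chains,
            iterations=iterations,
            warmup=warmup,
            seed=_chain_seed(seed, 10_000 + m),
            nwalkers=nwalkers,
            progress=progress,
        )
        w = res.waic(max_draws=max_waic_draws)
        rows.append(
            {
                "model": name,
                "waic": w.waic,
                "p_waic": w.p_waic,
                "lppd": w.lppd,
                "max_rhat": float(res.rhat.max()),
                "converged": res.converged,
                "n_params": model.n_params,
            }
        )
        results[name] = res
    table = pd.DataFrame(rows).set_index("model")
    weights = np.zeros(len(table))
    use = table["converged"].to_numpy() if exclude_nonconverged else np.ones(len(table), bool)
    if not use.any():
        raise ValueError("no converged models to weight")
    weights[use] = waic_weights(table.loc[use, "waic"])
    table["weight"] = weights
    table = table.sort_values("waic")
    table.insert(1, "delta_waic", table["waic"] - table["waic"].min())
    return ModelRanking(table=table, results=results)
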