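"""Core multivariate Bernoulli (MVB) occupancy quantities.

The joint latent presence-absence of ``S`` interacting species at one site is
modelled as a log-linear multivariate Bernoulli distribution over the
``2**S`` joint states ``z``::

    P(Z = z)  propto  exp( sum_i z_i f_i  +  sum_{i<j} z_i z_j f_ij )

where ``f_i`` are per-species natural parameters (the log odds of species *i*
occurring alone relative to the all-absent state) and ``f_ij`` are pairwise
natural parameters (log odds-ratios of co-occurrence; 0 means the two species
occur independently, negative means spatial avoidance).  Third- and
higher-order terms are fixed at zero throughout this package.

Observations are per-occasion binary detections.  Conditional on the latent
state, species *i* is detected in an occasion with probability ``p_i`` -- for
trail cameras better read as an *intensity of use* than a nuisance detection
probability -- modelled on the logit scale with optional additive modifiers
keyed to the latent presence of other species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "StateSpace",
    "state_log_probs",
    "state_probs",
    "marginal_prob",
    "conditional_prob",
    "natural_params",
    "DetectionModel",
    "intensity_of_use",
    "site_loglik",
]


class StateSpace:
    """Enumeration of all ``2**S`` joint presence-absence states.

    Species ``i`` occupies bit ``i`` of the state index: a state with presence
    vector ``z`` has index ``sum_i z_i * 2**i``.  Index 0 is therefore the
    all-absent state; for species ``("grizzly", "black")`` index 1 is
    grizzly-only, index 2 black-only and index 3 both present.
    """

    def __init__(self, species: Sequence[str]):
        species = tuple(str(s) for s in species)
        if len(species) == 0:
            raise ValueError("at least one species required")
        if len(set(species)) != len(species):
            raise ValueError(f"duplicate species names: {species}")
        self.species = species
        self.n_species = len(species)
        self.n_states = 1 << self.n_species
        idx = np.arange(self.n_states)
        self.states = ((idx[:, None] >> np.arange(self.n_species)[None, :]) & 1).astype(float)

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}; have {self.species}") from None

    def index(self, z: Sequence[int]) -> int:
        """State index of a presence vector ``z``."""
        z = np.asarray(z, dtype=int)
        if z.shape != (self.n_species,):
            raise ValueError(f"z must have length {self.n_species}")
        return int((z * (1 << np.arange(self.n_species))).sum())

    def pair_products(self, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
        """Matrix ``(2**S, n_pairs)`` of ``z_i * z_j`` per state and pair."""
        if len(pairs) == 0:
            return np.zeros((self.n_states, 0))
        return np.stack(
            [self.states[:, i] * self.states[:, j] for i, j in pairs], axis=1
        )


def _as_pair_dict(
    f_pairs: Mapping[tuple[int, int], float] | None, n_species: int
) -> dict[tuple[int, int], float]:
    out: dict[tuple[int, int], float] = {}
    if f_pairs is None:
        return out
    for (i, j), v in f_pairs.items():
        if i == j:
            raise ValueError(f"pair ({i},{j}) must involve two distinct species")
        if not (0 <= i < n_species and 0 <= j < n_species):
            raise ValueError(f"pair ({i},{j}) out of range for S={n_species}")
        key = (min(i, j), max(i, j))
        out[key] = out.get(key, 0.0) + float(v)
    return out


def state_log_probs(
    f_single: Sequence[float],
    f_pairs: Mapping[tuple[int, int], float] | None = None,
) -> np.ndarray:
    """Log state probabilities from natural parameter values for one site.

    Parameters
    ----------
    f_single : array-like, shape (S,)
        First-order natural parameters ``f_i = log(psi_{only i}/psi_{none})``.
    f_pairs : mapping (i, j) -> float, optional
        Pairwise natural parameters ``f_ij`` (symmetric in ``i, j``);
        unspecified pairs are 0 (independence).

    Returns
    -------
    ndarray, shape (2**S,)
        Log probabilities, normalised with log-sum-exp for stability.
    """
    f1 = np.asarray(f_single, dtype=float)
    if f1.ndim != 1:
        raise ValueError("f_single must be one-dimensional")
    if not np.all(np.isfinite(f1)):
        raise ValueError("non-finite first-order natural parameter")
    pairs = _as_pair_dict(f_pairs, f1.size)
    vals = np.fromiter(pairs.values(), dtype=float, count=len(pairs))
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite pairwise natural parameter")
    space = StateSpace([f"s{i}" for i in range(f1.size)])
    energy = space.states @ f1
    if pairs:
        energy = energy + space.pair_products(list(pairs)) @ vals
    return energy - logsumexp(energy)


def state_probs(
    f_single: Sequence[float],
    f_pairs: Mapping[tuple[int, int], float] | None = None,
) -> np.ndarray:
    """State probability vector ``psi`` (length ``2**S``); see state_log_probs."""
    return np.exp(state_log_probs(f_single, f_pairs))


def _check_psi(psi: np.ndarray) -> tuple[np.ndarray, int]:
    psi = np.asarray(psi, dtype=float)
    n_states = psi.size
    S = int(round(np.log2(n_states)))
    if (1 << S) != n_states:
        raise ValueError(f"psi length {n_states} is not a power of two")
    if np.any(psi < -1e-12) or abs(psi.sum() - 1.0) > 1e-8:
        raise ValueError("psi must be a probability vector")
    return psi, S


def marginal_prob(psi: Sequence[float], i: int) -> float:
    """Marginal occurrence probability of species ``i``: sum of ``psi`` over
    states with ``z_i = 1`` (e.g. for two species ``P(z1=1) = psi11 + psi10``)."""
    psi, S = _check_psi(np.asarray(psi, dtype=float))
    mask = (np.arange(psi.size) >> i) & 1
    return float(psi[mask == 1].sum())


def conditional_prob(psi: Sequence[float], i: int, j: int, z_j: int) -> float:
    """Occurrence probability of species ``i`` conditional on species ``j``'s
    latent state, e.g. ``P(z1=1 | z2=1) = psi11 / (psi11 + psi01)``.

    Raises
    ------
    ValueError
        If the conditioning event ``z_j = z_j-value`` has probability zero.
    """
    psi, S = _check_psi(np.asarray(psi, dtype=float))
    if i == j:
        raise ValueError("conditioning species must differ from target species")
    idx = np.arange(psi.size)
    cond = ((idx >> j) & 1) == int(z_j)
    denom = psi[cond].sum()
    if denom <= 0.0:
        raise ValueError(f"conditioning event z_{j}={z_j} has probability 0")
    num = psi[cond & (((idx >> i) & 1) == 1)].sum()
    return float(num / denom)


def natural_params(psi: Sequence[float]) -> tuple[np.ndarray, dict[tuple[int, int], float]]:
    """Recover natural parameters from a strictly positive state-probability
    vector (pairwise log-linear model assumed exact).

    ``f_i = log(psi(e_i)/psi(0))`` and
    ``f_ij = log( psi(e_i + e_j) psi(0) / (psi(e_i) psi(e_j)) )``.
    """
    psi, S = _check_psi(np.asarray(psi, dtype=float))
    if np.any(psi <= 0):
        raise ValueError("natural parameters undefined for zero-probability states")
    lp = np.log(psi)
    f1 = np.array([lp[1 << i] - lp[0] for i in range(S)])
    f2 = {
        (i, j): float(lp[(1 << i) | (1 << j)] + lp[0] - lp[1 << i] - lp[1 << j])
        for i in range(S)
        for j in range(i + 1, S)
    }
    return f1, f2


@dataclass
class DetectionModel:
    """Per-occasion detection (intensity-of-use) model on the logit scale.

    Each species has a coefficient per named covariate term (``"const"`` is
    the intercept; other terms are looked up in the covariate row), plus
    optional additive *modifiers*: ``modifiers[(focal, conditioning)]`` is
    added to the focal species' logit when the conditioning species' latent
    presence is 1.  With a single modifier this is exactly the two-parameter
    ``{p(z=1), p(z=0)}`` formulation of state-dependent intensity of use.
    """

    species: tuple[str, ...]
    coef: Mapping[str, Mapping[str, float]]
    modifiers: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        self.species = tuple(self.species)
        for sp in self.species:
            if sp not in self.coef:
                raise ValueError(f"no detection coefficients for species {sp!r}")
        for (focal, cond) in self.modifiers:
            if focal not in self.species or cond not in self.species:
                raise ValueError(f"modifier ({focal!r}, {cond!r}) names unknown species")
            if focal == cond:
                raise ValueError("a species cannot modify its own detection")

    def logit(
        self,
        species: str,
        covariate_row: Mapping[str, float] | None = None,
        z_others: Mapping[str, int] | None = None,
    ) -> float:
        covariate_row = covariate_row or {}
        z_others = z_others or {}
        eta = 0.0
        for term, beta in self.coef[species].items():
            if not np.isfinite(beta):
                raise ValueError(f"non-finite coefficient for {species}:{term}")
            x = 1.0 if term == "const" else float(covariate_row[term])
            eta += beta * x
        for (focal, cond), delta in self.modifiers.items():
            if focal == species and int(z_others.get(cond, 0)) == 1:
                eta += delta
        return eta

    def prob(self, species, covariate_row=None, z_others=None) -> float:
        return float(expit(self.logit(species, covariate_row, z_others)))


def intensity_of_use(
    model: DetectionModel,
    species: str,
    covariate_row: Mapping[str, float] | None = None,
    z_others: Mapping[str, int] | None = None,
) -> float:
    """Per-occasion intensity of use (inverse-logit of intercept + covariate
    terms + active modifiers for latently present other species)."""
    return model.prob(species, covariate_row, z_others)


def site_loglik(
    y_site: np.ndarray,
    psi: Sequence[float],
    det: DetectionModel,
    covariate_row: Mapping[str, float] | None = None,
) -> float:
    """Marginal log-likelihood of one site's detection history.

    Mixture over latent states::

        log sum_z psi_z  prod_i prod_t Bernoulli( y[i,t] | z_i * p_i(z) )

    A state with ``z_i = 0`` contributes only if species *i* was never
    detected at the site; missing occasions (NaN) contribute a factor of 1.
    This is a clarity-first reference implementation that loops over the
    ``2**S`` states; the model class has an equivalent vectorised path.

    Parameters
    ----------
    y_site : ndarray, shape (S, T)
        Detections in {0, 1}, with NaN marking unsurveyed occasions.
    psi : array-like, shape (2**S,)
        Latent state probabilities for the site.
    det : DetectionModel
    covariate_row : mapping, optional
        Site covariates for the detection model.
    """
    y = np.asarray(y_site, dtype=float)
    if y.ndim != 2:
        raise ValueError("y_site must be (species, occasions)")
    psi, S = _check_psi(np.asarray(psi, dtype=float))
    if y.shape[0] != S:
        raise ValueError(f"y_site has {y.shape[0]} species but psi implies {S}")
    species = det.species
    if len(species) != S:
        raise ValueError("detection model species count mismatch")

    observed = ~np.isnan(y)
    any_det = np.nansum(y, axis=1) > 0
    terms = []
    with np.errstate(divide="ignore"):
        log_psi = np.log(psi)
    for k in range(1 << S):
        z = [(k >> i) & 1 for i in range(S)]
        lp = log_psi[k]
        for i in range(S):
            if z[i] == 0:
                if any_det[i]:
                    lp = -np.inf
                continue
            z_others = {species[j]: z[j] for j in range(S) if j != i}
            p = det.prob(species[i], covariate_row, z_others)
            yi = y[i, observed[i]]
            with np.errstate(divide="ignore"):
                # select per-occasion terms to avoid 0 * -inf at p in {0, 1}
                lp += float(np.sum(np.where(yi == 1.0, np.log(p), np.log1p(-p))))
        terms.append(lp)
    return float(logsumexp(terms))
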