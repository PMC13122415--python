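"""Generative process and densities of the interval consensus model (ICM).

Each item ``j`` carries a latent consensus interval represented on the
unbounded ILR scale as ``T_j = (T_loc, T_wid)``.  Respondent ``i`` forms a
latent appraisal ``A_ij ~ N2(T_j, Sigma_ij)`` whose precision grows with the
respondent's proficiency ``E_i = (E_loc, E_wid)`` and the item's
discernibility ``lam_j = (lam_loc, lam_wid)`` (both parameterised so that
*larger* values mean *smaller* error SDs).  The observed transformed response
adds person-level response biases: a multiplicative scaling bias ``a_i``
acting on the location dimension only (an extremity bias, entering both the
mean and the location error SD) and additive shifting biases
``b_i = (b_loc, b_wid)``:

    mean  = (a_i * T_loc + b_loc,  T_wid + b_wid)
    sd    = (a_i / (E_loc * lam_loc),  1 / (E_wid * lam_wid))

with an item-specific residual correlation ``rho_j`` between the two error
dimensions.  Identifiability follows hard centring: mean(log lam) = 0 and
mean(b) = 0 per dimension (sum-to-zero), and mean(a) = 1 exactly (a is the
softmax pushforward of a centred normal, scaled by N).

The consensus prior is specified on the *bounded* scale: a Beta prior on the
interval width ``w`` and a Beta prior on an auxiliary location multiplier
``lamstar`` with ``lower = lamstar * (1 - w)``; the resulting composition is
mapped through the ILR to give ``T``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .transform import ilr, ilr_inverse, to_interval

__all__ = [
    "ConsensusParam",
    "PersonParams",
    "ItemParams",
    "Hyperparams",
    "response_mean",
    "response_cov",
    "loglik_obs",
    "bvn_logpdf",
    "consensus_prior_logpdf",
    "consensus_prior_dirichlet_logpdf",
    "hier_prior_logpdf",
    "bounded_consensus_to_unbounded",
    "sample_consensus",
    "sample_persons",
    "sample_items",
    "simulate_responses",
]


@dataclass(frozen=True)
class ConsensusParam:
    """Latent consensus interval of one or more items on the unbounded scale."""

    T_loc: np.ndarray
    T_wid: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "T_loc", np.asarray(self.T_loc, dtype=float))
        object.__setattr__(self, "T_wid", np.asarray(self.T_wid, dtype=float))
        if not (np.all(np.isfinite(self.T_loc)) and np.all(np.isfinite(self.T_wid))):
            raise ValueError("consensus parameters must be finite")


@dataclass(frozen=True)
class PersonParams:
    """Per-person proficiencies and response biases (vectorised over persons)."""

    E_loc: np.ndarray
    E_wid: np.ndarray
    a: np.ndarray
    b_loc: np.ndarray
    b_wid: np.ndarray

    def __post_init__(self) -> None:
        for name in ("E_loc", "E_wid", "a", "b_loc", "b_wid"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.E_loc <= 0) or np.any(self.E_wid <= 0):
            raise ValueError("proficiencies must be strictly positive")
        if np.any(self.a <= 0):
            raise ValueError("scaling biases must be strictly positive")


@dataclass(frozen=True)
class ItemParams:
    """Per-item discernibilities and residual correlation (vectorised over items)."""

    lam_loc: np.ndarray
    lam_wid: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lam_loc", "lam_wid", "rho"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.lam_loc <= 0) or np.any(self.lam_wid <= 0):
            raise ValueError("discernibilities must be strictly positive")
        if np.any(np.abs(self.rho) >= 1):
            raise ValueError("residual correlation must lie in (-1, 1)")


@dataclass(frozen=True)
class Hyperparams:
    """Hyperparameters of the hierarchical priors / data-generating process.

    Scale parameters act on the log scale of the respective positive
    parameters.  The means of log-discernibility and of the shifting biases
    are fixed at 0, and the mean scaling bias at 1 (identifiability), so only
    the spreads appear here.  ``alpha_w/beta_w`` shape the Beta prior on the
    bounded consensus width (default Beta(2, 4): mean 1/3, mode 1/4, ruling
    out near-full-scale consensus intervals a priori without excluding them);
    ``alpha_l/beta_l`` shape the location multiplier (default uniform).
    ``rho_shape`` is the symmetric shape of the scaled-Beta prior on the
    residual correlation (s = 2 shrinks mildly toward 0).
    """

    mu_E: tuple[float, float] = (0.0, 0.0)
    sigma_E: tuple[float, float] = (0.5, 0.5)
    omega_E: float = 0.0
    sigma_lam: tuple[float, float] = (0.5, 0.5)
    omega_lam: float = 0.0
    sigma_a: float = 0.2
    sigma_b: tuple[float, float] = (0.25, 0.25)
    alpha_w: float = 2.0
    beta_w: float = 4.0
    alpha_l: float = 1.0
    beta_l: float = 1.0
    rho_shape: float = 2.0

    def __post_init__(self) -> None:
        scales = (*self.sigma_E, *self.sigma_lam, self.sigma_a, *self.sigma_b)
        if any(s <= 0 for s in scales):
            raise ValueError("all scale hyperparameters must be strictly positive")
        if abs(self.omega_E) >= 1 or abs(self.omega_lam) >= 1:
            raise ValueError("correlation hyperparameters must lie in (-1, 1)")
        shapes = (self.alpha_w, self.beta_w, self.alpha_l, self.beta_l, self.rho_shape)
        if any(s <= 0 for s in shapes):
            raise ValueError("Beta shape hyperparameters must be strictly positive")


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def response_mean(T: ConsensusParam, p: PersonParams) -> np.ndarray:
    """Expected transformed response: biases applied to the consensus.

    The scaling bias multiplies the location only; the width origin is not a
    meaningful anchor for an extremity bias, so the width mean is shifted only.
    """
    loc = p.a * T.T_loc + p.b_loc
    wid = T.T_wid + p.b_wid
    return np.stack(np.broadcast_arrays(loc, wid), axis=-1)


def response_cov(p: PersonParams, it: ItemParams) -> np.ndarray:
    """Error covariance of the transformed response.

    SDs are reciprocal in proficiency and discernibility (higher values ->
    higher precision), and the scaling bias re-enters the location SD so that
    scaling an appraisal scales its whole location error distribution.
    """
    sd_loc = p.a / (p.E_loc * it.lam_loc)
    sd_wid = 1.0 / (p.E_wid * it.lam_wid)
    sd_loc, sd_wid, rho = np.broadcast_arrays(sd_loc, sd_wid, it.rho)
    cov = np.empty(sd_loc.shape + (2, 2))
    cov[..., 0, 0] = sd_loc**2
    cov[..., 1, 1] = sd_wid**2
    cov[..., 0, 1] = cov[..., 1, 0] = rho * sd_loc * sd_wid
    return cov


def bvn_logpdf(y, mean, sd_loc, sd_wid, rho) -> np.ndarray:
    """Bivariate normal log-density in (SD, SD, correlation) parameterisation."""
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if np.any(np.abs(rho) >= 1):
        raise ValueError("singular covariance: |rho| must be < 1")
    dl = (y[..., 0] - mean[..., 0]) / sd_loc
    dw = (y[..., 1] - mean[..., 1]) / sd_wid
    q = 1.0 / (1.0 - np.asarray(rho) ** 2)
    quad = q * (dl**2 - 2.0 * np.asarray(rho) * dl * dw + dw**2)
    return (
        -np.log(2.0 * np.pi)
        - np.log(sd_loc)
        - np.log(sd_wid)
        + 0.5 * np.log(q)
        - 0.5 * quad
    )


def loglik_obs(y, T: ConsensusParam, p: PersonParams, it: ItemParams) -> np.ndarray:
    """Log-likelihood of transformed response(s) ``y`` given all parameters."""
    sd_loc = p.a / (p.E_loc * it.lam_loc)
    sd_wid = 1.0 / (p.E_wid * it.lam_wid)
    return bvn_logpdf(y, response_mean(T, p), sd_loc, sd_wid, it.rho)


# ---------------------------------------------------------------------------
# consensus priors
# ---------------------------------------------------------------------------

def bounded_consensus_to_unbounded(w, lamstar) -> np.ndarray:
    """Map the bounded consensus parameterisation (width, multiplier) to T.

    ``lower = lamstar * (1 - w)``, ``upper = lower + w``; the induced
    composition is strictly positive for interior (w, lamstar), so no padding
    is needed before the ILR.
    """
    w = np.asarray(w, dtype=float)
    lamstar = np.asarray(lamstar, dtype=float)
    lower = lamstar * (1.0 - w)
    comp = np.stack([lower, w, 1.0 - w - lower], axis=-1)
    return ilr(comp)


def consensus_prior_logpdf(w, lamstar, hp: Hyperparams) -> np.ndarray:
    """Log prior density of the bounded consensus parameterisation."""
    w = np.asarray(w, dtype=float)
    lamstar = np.asarray(lamstar, dtype=float)
    if np.any((w <= 0) | (w >= 1)) or np.any((lamstar <= 0) | (lamstar >= 1)):
        raise ValueError("w and lamstar must lie strictly inside (0, 1)")
    return stats.beta.logpdf(w, hp.alpha_w, hp.beta_w) + stats.beta.logpdf(
        lamstar, hp.alpha_l, hp.beta_l
    )


def consensus_prior_dirichlet_logpdf(comp, alpha) -> float:
    """Alternative consensus prior directly on the simplex (Dirichlet)."""
    comp = np.asarray(comp, dtype=float)
    if np.any(comp <= 0):
        raise ValueError("Dirichlet prior requires strictly positive parts")
    return stats.dirichlet.logpdf(comp / comp.sum(), np.asarray(alpha, dtype=float))


def _bvn_logpdf_std(x1, x2, mu1, mu2, s1, s2, omega) -> np.ndarray:
    y = np.stack(np.broadcast_arrays(x1, x2), axis=-1)
    mean = np.stack(np.broadcast_arrays(mu1 + 0.0 * x1, mu2 + 0.0 * x2), axis=-1)
    return bvn_logpdf(y, mean, s1, s2, omega)


def hier_prior_logpdf(p: PersonParams, it: ItemParams, hp: Hyperparams) -> float:
    """Joint log prior density of person and item parameters.

    Densities are evaluated on the unconstrained representatives: bivariate
    normal on log-proficiencies, bivariate normal (mean 0) on
    log-discernibilities, normal (mean 0) on log scaling biases and on the
    shifting biases, and a scaled Beta on the residual correlations.  The hard
    sum-to-zero / mean-one identifiability constraints are enforced by the
    sampler's parameterisation, not by this density.
    """
    lp = np.sum(
        _bvn_logpdf_std(
            np.log(p.E_loc), np.log(p.E_wid),
            hp.mu_E[0], hp.mu_E[1], hp.sigma_E[0], hp.sigma_E[1], hp.omega_E,
        )
    )
    lp += np.sum(
        _bvn_logpdf_std(
            np.log(it.lam_loc), np.log(it.lam_wid),
            0.0, 0.0, hp.sigma_lam[0], hp.sigma_lam[1], hp.omega_lam,
        )
    )
    lp += np.sum(stats.norm.logpdf(np.log(p.a), 0.0, hp.sigma_a))
    lp += np.sum(stats.norm.logpdf(p.b_loc, 0.0, hp.sigma_b[0]))
    lp += np.sum(stats.norm.logpdf(p.b_wid, 0.0, hp.sigma_b[1]))
    # rho = 2*Beta(s, s) - 1  =>  density Beta((rho+1)/2; s, s) / 2
    s = hp.rho_shape
    lp += np.sum(stats.beta.logpdf((it.rho + 1.0) / 2.0, s, s) - np.log(2.0))
    return float(lp)


# ---------------------------------------------------------------------------
# generative draws
# ---------------------------------------------------------------------------

def sample_consensus(J: int, hp: Hyperparams, rng: np.random.Generator):
    """Draw J consensus intervals from the bounded-scale prior.

    Returns ``(w, lamstar, T)`` with ``T`` of shape (J, 2) on the unbounded
    scale.
    """
    w = rng.beta(hp.alpha_w, hp.beta_w, size=J)
    lamstar = rng.beta(hp.alpha_l, hp.beta_l, size=J)
    T = bounded_consensus_to_unbounded(w, lamstar)
    return w, lamstar, T


def _centered(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=-1, keepdims=True)


def _bvn_draws(n, mu, sigma, omega, rng):
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x1 = mu[0] + sigma[0] * z1
    x2 = mu[1] + sigma[1] * (omega * z1 + np.sqrt(1.0 - omega**2) * z2)
    return x1, x2


def sample_persons(N: int, hp: Hyperparams, rng: np.random.Generator) -> PersonParams:
    """Draw person parameters; identifiability constraints hold exactly."""
    log_E_loc, log_E_wid = _bvn_draws(N, hp.mu_E, hp.sigma_E, hp.omega_E, rng)
    u = hp.sigma_a * rng.standard_normal(N)
    e = np.exp(u - u.max())
    a = N * e / e.sum()  # mean(a) = 1 exactly
    b_loc = hp.sigma_b[0] * _centered(rng.standard_normal(N))
    b_wid = hp.sigma_b[1] * _centered(rng.standard_normal(N))
    return PersonParams(np.exp(log_E_loc), np.exp(log_E_wid), a, b_loc, b_wid)


def sample_items(J: int, hp: Hyperparams, rng: np.random.Generator) -> ItemParams:
    """Draw item parameters; mean log-discernibility is zero exactly."""
    z1 = _centered(rng.standard_normal(J))
    z2 = _centered(rng.standard_normal(J))
    log_lam_loc = hp.sigma_lam[0] * z1
    log_lam_wid = hp.sigma_lam[1] * (
        hp.omega_lam * z1 + np.sqrt(1.0 - hp.omega_lam**2) * z2
    )
    rho = 2.0 * rng.beta(hp.rho_shape, hp.rho_shape, size=J) - 1.0
    return ItemParams(np.exp(log_lam_loc), np.exp(log_lam_wid), rho)


def simulate_responses(
    T: ConsensusParam,
    persons: PersonParams,
    items: ItemParams,
    design=None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate interval responses for (respondent, item) pairs.

    ``design`` is an iterable of ``(i, j)`` index pairs; ``None`` means fully
    crossed.  Transformed responses are drawn from the bivariate normal
    observation model and mapped back to bounded intervals through the inverse
    ILR (no padding: generated compositions are strictly positive almost
    surely).  Returns a long-format frame with both scales.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    N = persons.E_loc.shape[0]
    J = items.lam_loc.shape[0]
    if design is None:
        ii, jj = np.meshgrid(np.arange(N), np.arange(J), indexing="ij")
        ii, jj = ii.ravel(), jj.ravel()
    else:
        design = np.asarray(list(design), dtype=int)
        if design.size == 0:
            raise ValueError("design must contain at least one (i, j) pair")
        ii, jj = design[:, 0], design[:, 1]

    a, bl, bw = persons.a[ii], persons.b_loc[ii], persons.b_wid[ii]
    mu_loc = a * T.T_loc[jj] + bl
    mu_wid = T.T_wid[jj] + bw
    sd_loc = a / (persons.E_loc[ii] * items.lam_loc[jj])
    sd_wid = 1.0 / (persons.E_wid[ii] * items.lam_wid[jj])
    rho = items.rho[jj]

    z1 = rng.standard_normal(ii.shape[0])
    z2 = rng.standard_normal(ii.shape[0])
    y_loc = mu_loc + sd_loc * z1
    y_wid = mu_wid + sd_wid * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)

    y = np.stack([y_loc, y_wid], axis=-1)
    bounds = to_interval(ilr_inverse(y))
    return pd.DataFrame(
        {
            "respondent_id": [f"r{i:04d}" for i in ii],
            "item_id": [f"item{j:03d}" for j in jj],
            "lower": bounds[:, 0],
            "upper": bounds[:, 1],
            "loc": y_loc,
            "wid": y_wid,
        }
    )
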