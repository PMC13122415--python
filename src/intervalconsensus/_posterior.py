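"""Unconstrained log-posterior of the ICM with analytic gradients.

The sampler works on a flat unconstrained vector ``theta``.  Blocks:

* ``xi = logit(w)`` and ``zeta = logit(lamstar)`` per item — the bounded
  consensus parameterisation.  Note ``T_loc = k1 * zeta`` and
  ``T_wid = k2 * (xi - 0.5*(log lamstar + log(1 - lamstar)))`` follow in
  closed form from the ILR of the induced composition.
* Non-centred standard-normal innovations for log-discernibilities (sum-zero
  across items), log-proficiencies, scaling biases (softmax with mean(a) = 1)
  and shifting biases (sum-zero across persons).  Sum-to-zero blocks carry
  J-1 / N-1 free coordinates mapped through the orthonormal Helmert basis of
  the constraint subspace, so an iid standard-normal prior on the free
  coordinates is exactly the centred iid normal law used for data generation.
* ``atanh``-parameterised correlations and ``log``-parameterised scale
  hyperparameters, with scaled-Beta and half-normal hyperpriors.

``logp_and_grad`` returns the joint log-density (including all Jacobians and
normalising constants) and its exact gradient; gradients are verified against
finite differences in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, expit

from .transform import K1, K2

__all__ = ["PosteriorConfig", "ICMPosterior"]

_LOG_2PI = np.log(2.0 * np.pi)
_HALFNORMAL_CONST = 0.5 * np.log(2.0 / np.pi)


@dataclass(frozen=True)
class PosteriorConfig:
    """Prior constants and model-variant switches for one fit."""

    alpha_w: float = 2.0
    beta_w: float = 4.0
    alpha_l: float = 1.0
    beta_l: float = 1.0
    rho_shape: float = 2.0
    omega_shape: float = 2.0  # scaled-Beta shape for estimated correlations
    hyper_scale: float = 1.0  # half-normal scale for all sigma hyperpriors
    include_a: bool = True
    include_b_loc: bool = True
    include_b_wid: bool = True
    estimate_correlations: bool = False
    omega_E: float = 0.0   # fixed values when not estimated
    omega_lam: float = 0.0


def _slice_sample_1d(logd, x0: float, rng: np.random.Generator, w: float = 1.0) -> float:
    """Univariate slice sampler (stepping-out + shrinkage, Neal 2003)."""
    log_y = logd(x0) + np.log(rng.uniform())
    u = rng.uniform()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(50):
        if logd(lo) < log_y:
            break
        lo -= w
    for _ in range(50):
        if logd(hi) < log_y:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logd(x1) >= log_y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _helmert_expand(z: np.ndarray) -> np.ndarray:
    """Map M free coordinates to an (M+1)-vector summing to zero.

    Columns of the implicit basis are the orthonormal Helmert contrasts, so an
    iid standard-normal prior on the free coordinates is exactly the centred
    iid normal law on the constraint subspace, with perfectly conditioned
    geometry for the sampler.  O(M) via suffix sums.
    """
    m = z.shape[0]
    k = np.arange(1, m + 1)
    t = z / np.sqrt(k * (k + 1))
    s = np.zeros(m + 1)
    s[:m] = np.cumsum(t[::-1])[::-1]
    out = s.copy()
    out[1:] -= k * t
    return out


def _helmert_contract(g: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_helmert_expand` (gradient pull-back)."""
    m = g.shape[0] - 1
    k = np.arange(1, m + 1)
    prefix = np.cumsum(g)[:m]
    return (prefix - k * g[1:]) / np.sqrt(k * (k + 1))


class ICMPosterior:
    """Joint log-density and gradient for one dataset.

    Parameters
    ----------
    y : (n, 2) array of ILR-transformed responses.
    obs_i, obs_j : person / item index per observation.
    N, J : numbers of persons and items.
    cfg : prior constants and variant switches.
    """

    def __init__(self, y, obs_i, obs_j, N, J, cfg: PosteriorConfig | None = None):
        self.y = np.asarray(y, dtype=float)
        self.obs_i = np.asarray(obs_i, dtype=np.intp)
        self.obs_j = np.asarray(obs_j, dtype=np.intp)
        self.N = int(N)
        self.J = int(J)
        self.cfg = cfg or PosteriorConfig()
        if self.N < 2 or self.J < 2:
            raise ValueError("the ICM needs at least 2 respondents and 2 items")
        self._build_layout()
        self._setup_fast_path()

    def _build_layout(self) -> None:
        cfg, N, J = self.cfg, self.N, self.J
        blocks: list[tuple[str, int]] = [
            ("xi", J),
            ("zeta", J),
            ("z_lam_loc", J - 1),
            ("z_lam_wid", J - 1),
            ("r_rho", J),
            ("z_E_loc", N),
            ("z_E_wid", N),
        ]
        if cfg.include_a:
            blocks.append(("z_a", N - 1))
        if cfg.include_b_loc:
            blocks.append(("z_b_loc", N - 1))
        if cfg.include_b_wid:
            blocks.append(("z_b_wid", N - 1))
        blocks += [("mu_E", 2), ("log_sigma_E", 2), ("log_sigma_lam", 2)]
        if cfg.include_a:
            blocks.append(("log_sigma_a", 1))
        if cfg.include_b_loc:
            blocks.append(("log_sigma_b_loc", 1))
        if cfg.include_b_wid:
            blocks.append(("log_sigma_b_wid", 1))
        if cfg.estimate_correlations:
            blocks += [("t_omega_E", 1), ("t_omega_lam", 1)]
        self.slices: dict[str, slice] = {}
        pos = 0
        for name, size in blocks:
            self.slices[name] = slice(pos, pos + size)
            pos += size
        self.dim = pos

    def _setup_fast_path(self) -> None:
        """Precompute normalising constants and offsets for the compiled kernel."""
        from ._kernel import HAVE_NUMBA

        cfg, N, J = self.cfg, self.N, self.J
        const = 0.0
        const -= J * (betaln(cfg.alpha_w, cfg.beta_w) + betaln(cfg.alpha_l, cfg.beta_l))
        const -= J * ((2 * cfg.rho_shape - 1) * np.log(2.0) + betaln(cfg.rho_shape, cfg.rho_shape))
        const -= (J - 1) * _LOG_2PI  # discernibility innovations (two (J-1)-vectors)
        const -= N * _LOG_2PI  # proficiency innovations
        const -= _LOG_2PI      # mu_E
        n_scales = 4
        if cfg.include_a:
            const -= 0.5 * (N - 1) * _LOG_2PI
            n_scales += 1
        if cfg.include_b_loc:
            const -= 0.5 * (N - 1) * _LOG_2PI
            n_scales += 1
        if cfg.include_b_wid:
            const -= 0.5 * (N - 1) * _LOG_2PI
            n_scales += 1
        const += n_scales * (_HALFNORMAL_CONST - np.log(cfg.hyper_scale))
        if cfg.estimate_correlations:
            const -= 2 * (
                (2 * cfg.omega_shape - 1) * np.log(2.0)
                + betaln(cfg.omega_shape, cfg.omega_shape)
            )
        self._const = const

        def off(name):
            return self.slices[name].start if name in self.slices else -1

        self._offsets = tuple(
            off(n)
            for n in (
                "xi", "zeta", "z_lam_loc", "z_lam_wid", "r_rho", "z_E_loc", "z_E_wid",
                "z_a", "z_b_loc", "z_b_wid", "mu_E", "log_sigma_E", "log_sigma_lam",
                "log_sigma_a", "log_sigma_b_loc", "log_sigma_b_wid",
                "t_omega_E", "t_omega_lam",
            )
        )
        self.use_numba = HAVE_NUMBA
        self._grad_buf = np.empty(self.dim)

    def logp_and_grad_fast(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Compiled twin of :meth:`logp_and_grad` (identical up to roundoff)."""
        from ._kernel import logp_grad_kernel

        cfg = self.cfg
        lp = logp_grad_kernel(
            theta, self.y, self.obs_i, self.obs_j, self.N, self.J,
            cfg.alpha_w, cfg.beta_w, cfg.alpha_l, cfg.beta_l,
            cfg.rho_shape, cfg.omega_shape, cfg.hyper_scale,
            cfg.include_a, cfg.include_b_loc, cfg.include_b_wid,
            cfg.estimate_correlations, cfg.omega_E, cfg.omega_lam,
            K1, K2, *self._offsets, self._grad_buf,
        )
        return float(lp) + self._const, self._grad_buf.copy()

    # -- parameter bookkeeping ------------------------------------------------

    def split(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        return {k: theta[s] for k, s in self.slices.items()}

    def constrained(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Map an unconstrained vector to all interpretable parameters."""
        cfg, N, J = self.cfg, self.N, self.J
        p = self.split(theta)
        w = expit(p["xi"])
        lamstar = expit(p["zeta"])
        log_ls = np.log(lamstar) + np.log1p(-lamstar)
        T_loc = K1 * p["zeta"]
        T_wid = K2 * (p["xi"] - 0.5 * log_ls)
        sigma_E = np.exp(p["log_sigma_E"])
        sigma_lam = np.exp(p["log_sigma_lam"])
        if cfg.estimate_correlations:
            omega_E = np.tanh(p["t_omega_E"][0])
            omega_lam = np.tanh(p["t_omega_lam"][0])
        else:
            omega_E, omega_lam = cfg.omega_E, cfg.omega_lam

        zfl = _helmert_expand(p["z_lam_loc"])
        zfw = _helmert_expand(p["z_lam_wid"])
        v_loc = sigma_lam[0] * zfl
        v_wid = sigma_lam[1] * (omega_lam * zfl + np.sqrt(1 - omega_lam**2) * zfw)
        rho = np.tanh(p["r_rho"])

        sqE = np.sqrt(1 - omega_E**2)
        el = p["mu_E"][0] + sigma_E[0] * p["z_E_loc"]
        ew = p["mu_E"][1] + sigma_E[1] * (omega_E * p["z_E_loc"] + sqE * p["z_E_wid"])

        out = {
            "w": w, "lamstar": lamstar, "T_loc": T_loc, "T_wid": T_wid,
            "lam_loc": np.exp(v_loc), "lam_wid": np.exp(v_wid), "rho": rho,
            "E_loc": np.exp(el), "E_wid": np.exp(ew),
            "mu_E": p["mu_E"], "sigma_E": sigma_E, "sigma_lam": sigma_lam,
            "omega_E": np.atleast_1d(omega_E), "omega_lam": np.atleast_1d(omega_lam),
        }
        if cfg.include_a:
            sigma_a = np.exp(p["log_sigma_a"][0])
            ua = sigma_a * _helmert_expand(p["z_a"])
            e = np.exp(ua - ua.max())
            out["a"] = N * e / e.sum()
            out["sigma_a"] = np.atleast_1d(sigma_a)
        else:
            out["a"] = np.ones(N)
        if cfg.include_b_loc:
            sb = np.exp(p["log_sigma_b_loc"][0])
            out["b_loc"] = sb * _helmert_expand(p["z_b_loc"])
            out["sigma_b_loc"] = np.atleast_1d(sb)
        else:
            out["b_loc"] = np.zeros(N)
        if cfg.include_b_wid:
            sb = np.exp(p["log_sigma_b_wid"][0])
            out["b_wid"] = sb * _helmert_expand(p["z_b_wid"])
            out["sigma_b_wid"] = np.atleast_1d(sb)
        else:
            out["b_wid"] = np.zeros(N)
        return out

    def random_init(self, rng: np.random.Generator, scale: float = 0.5) -> np.ndarray:
        """Uniform initial values on the unconstrained scale (±scale)."""
        return rng.uniform(-scale, scale, size=self.dim)

    # -- interweaving rejuvenation -------------------------------------------

    @property
    def _helmert_matrix(self) -> np.ndarray:
        """Dense (N, N-1) Helmert basis, built lazily for the Gibbs update."""
        H = getattr(self, "_H_cache", None)
        if H is None:
            m = self.N - 1
            H = np.empty((self.N, m))
            eye = np.eye(m)
            for k in range(m):
                H[:, k] = _helmert_expand(eye[k])
            self._H_cache = H
        return H

    def gibbs_shift_biases(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Exact conjugate draw of the shifting-bias innovations.

        Given every other parameter, the observation means are linear in the
        shifting biases and the innovations have a standard-normal prior, so
        their full conditional is Gaussian: per-person 2x2 data precisions
        (correlated across the two dimensions through rho) plus the identity
        in Helmert coordinates.  Sampling it exactly removes the biases'
        random-walk autocorrelation entirely.
        """
        cfg = self.cfg
        if not (cfg.include_b_loc or cfg.include_b_wid):
            return theta
        th = theta.copy()
        c = self.constrained(th)
        oi, oj = self.obs_i, self.obs_j
        N = self.N

        A = c["a"][oi]
        sl = A / (c["E_loc"][oi] * c["lam_loc"][oj])
        sw = 1.0 / (c["E_wid"][oi] * c["lam_wid"][oj])
        rho = c["rho"][oj]
        q = 1.0 / (1.0 - rho**2)
        p11 = q / sl**2
        p12 = -q * rho / (sl * sw)
        p22 = q / sw**2
        # residuals with the biases removed
        r_l = self.y[:, 0] - A * c["T_loc"][oj]
        r_w = self.y[:, 1] - c["T_wid"][oj]

        def acc(x):
            return np.bincount(oi, weights=x, minlength=N)

        d11, d12, d22 = acc(p11), acc(p12), acc(p22)
        c1 = acc(p11 * r_l + p12 * r_w)
        c2 = acc(p12 * r_l + p22 * r_w)

        H = self._helmert_matrix
        blocks = []
        if cfg.include_b_loc:
            blocks.append(("z_b_loc", float(c["sigma_b_loc"][0]), d11, c1))
        if cfg.include_b_wid:
            blocks.append(("z_b_wid", float(c["sigma_b_wid"][0]), d22, c2))
        m = N - 1
        k = len(blocks)
        Q = np.eye(k * m)
        rhs = np.empty(k * m)
        for bi, (_, sig, dii, ci) in enumerate(blocks):
            sl_ = slice(bi * m, (bi + 1) * m)
            Q[sl_, sl_] += sig**2 * (H.T * dii) @ H
            rhs[sl_] = sig * (H.T @ ci)
        if k == 2:
            cross = (
                blocks[0][1] * blocks[1][1] * (H.T * d12) @ H
            )
            Q[:m, m:] += cross
            Q[m:, :m] += cross.T
        # extreme transient states (warmup) can overflow the data precisions;
        # the trigger depends only on conditioned-on coordinates, so skipping
        # the update there keeps the kernel invariant
        if not (np.all(np.isfinite(Q)) and np.all(np.isfinite(rhs))):
            return theta
        try:
            L = np.linalg.cholesky(Q)
        except np.linalg.LinAlgError:
            return theta
        mean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
        u = mean + np.linalg.solve(L.T, rng.standard_normal(k * m))
        for bi, (zname, _, _, _) in enumerate(blocks):
            th[self.slices[zname]] = u[bi * m : (bi + 1) * m]
        return th

    def mh_scan_scaling(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Single-site Metropolis scan over the scaling-bias innovations.

        The scaling biases sit in the regime where prior and likelihood carry
        comparable information per person, which both centred and non-centred
        HMC explore slowly.  Independence proposals from the standard-normal
        prior decorrelate each coordinate directly; acceptance uses the full
        joint density, so the softmax coupling across persons is exact.
        """
        if not self.cfg.include_a:
            return theta
        th = theta.copy()
        logp = self.logp_and_grad_fast if self.use_numba else self.logp_and_grad
        start = self.slices["z_a"].start
        m = self.slices["z_a"].stop - start
        e_start = self.slices["z_E_loc"].start
        lp, _ = logp(th)
        prop_a = rng.standard_normal(m)
        prop_e = rng.standard_normal(m)
        log_us = np.log(rng.uniform(size=m))
        # random-scan over half the coordinates per invocation; repeated
        # applications cover all persons in expectation at half the cost
        for k in rng.permutation(m)[: (m + 1) // 2]:
            # joint proposal for the person's scaling-bias and location-
            # proficiency innovations: their product sets the location error
            # SD, leaving a weakly identified ridge that single-coordinate
            # moves cross slowly
            old_a = th[start + k]
            old_e = th[e_start + k]
            th[start + k] = prop_a[k]
            th[e_start + k] = prop_e[k]
            lp_new, _ = logp(th)
            if log_us[k] < lp_new - lp:
                lp = lp_new
            else:
                th[start + k] = old_a
                th[e_start + k] = old_e
        return th

    def slice_scale_noncentred(
        self, theta: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Slice-sample log sigma_a with the innovations held fixed.

        This is the non-centred counterpart of the ASIS scale update: with z
        fixed the conditional of the scale is prior-dominated whenever the
        data only weakly identify the spread of the scaling biases, so the
        move crosses the whole funnel in one step.  Together with the centred
        update in :meth:`asis_rejuvenate` it forms a full interweaving pair.
        """
        if not self.cfg.include_a:
            return theta
        th = theta.copy()
        logp = self.logp_and_grad_fast if self.use_numba else self.logp_and_grad
        idx = self.slices["log_sigma_a"].start

        def logd(v):
            th[idx] = v
            return logp(th)[0]

        new = _slice_sample_1d(logd, th[idx], rng, w=0.5)
        th[idx] = new
        return th

    def funnel_slice(
        self,
        theta: np.ndarray,
        rng: np.random.Generator,
        zname: str,
        lsname: str,
        ls_offset: int = 0,
        alpha: float = 0.5,
    ) -> np.ndarray:
        """Slice-sample along the funnel diagonal of a scale block.

        Moves ``t`` along ``log sigma -> log sigma + t``, ``z -> z *
        exp(-alpha*t)``; the rescaling's log-Jacobian ``-m*alpha*t`` is folded
        into the slice target.  Being rejection-free and self-tuning, this
        traverses the weakly constrained diagonal in one update where
        fixed-step Metropolis moves only diffuse.
        """
        if zname not in self.slices:
            return theta
        th = theta.copy()
        logp = self.logp_and_grad_fast if self.use_numba else self.logp_and_grad
        zsl = self.slices[zname]
        ls_idx = self.slices[lsname].start + ls_offset
        m = zsl.stop - zsl.start
        ls0 = th[ls_idx]
        z0 = th[zsl].copy()

        def logd(t):
            th[ls_idx] = ls0 + t
            th[zsl] = z0 * np.exp(-alpha * t)
            return logp(th)[0] - m * alpha * t

        t_new = _slice_sample_1d(logd, 0.0, rng, w=1.0)
        th[ls_idx] = ls0 + t_new
        th[zsl] = z0 * np.exp(-alpha * t_new)
        return th

    def rejuvenate(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Extra kernel between HMC trajectories.

        Sequence: funnel-diagonal slices (random compromise angle) for the
        discernibility, proficiency and shifting-bias scale blocks; an
        intensified treatment of the scaling-bias block (funnel slices and a
        non-centred scale slice interleaved with a single-site joint
        Metropolis scan over each person's scaling-bias and
        location-proficiency innovations); an exact conjugate Gibbs draw of
        the shifting-bias innovations; and the centred ASIS sweep.  Each
        component leaves the posterior invariant.
        """
        for zname, lsname, off in (
            ("z_b_loc", "log_sigma_b_loc", 0),
            ("z_b_wid", "log_sigma_b_wid", 0),
            ("z_lam_loc", "log_sigma_lam", 0),
            ("z_lam_wid", "log_sigma_lam", 1),
            ("z_E_loc", "log_sigma_E", 0),
            ("z_E_wid", "log_sigma_E", 1),
        ):
            theta = self.funnel_slice(
                theta, rng, zname, lsname, off, alpha=rng.uniform(0.2, 0.8)
            )
        # the scaling-bias scale is the slowest-mixing quantity in the model;
        # interleave scale moves with an innovation refresh so successive
        # moves are not tied to one innovation pattern
        theta = self.funnel_slice(
            theta, rng, "z_a", "log_sigma_a", 0, alpha=rng.uniform(0.2, 0.8)
        )
        theta = self.slice_scale_noncentred(theta, rng)
        theta = self.mh_scan_scaling(theta, rng)
        theta = self.funnel_slice(
            theta, rng, "z_a", "log_sigma_a", 0, alpha=rng.uniform(0.2, 0.8)
        )
        theta = self.gibbs_shift_biases(theta, rng)
        return self.asis_rejuvenate(theta, rng)

    def asis_rejuvenate(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One ancillarity–sufficiency interweaving sweep over the hierarchy.

        For every non-centred block the centred quantities (e.g. the shifting
        biases themselves) are held fixed while the corresponding scale
        hyperparameter — and for proficiencies also ``mu_E`` — is redrawn
        from its exact univariate conditional (conjugate normal for the mean,
        slice sampling on the log-scale otherwise); the innovations are then
        recomputed.  Leaves the posterior invariant and decorrelates the
        scale hyperparameters, which mix slowly under pure HMC in either
        parameterisation.  Skipped when dimension correlations are active
        (the centred block is then not a scalar-scale family).
        """
        cfg = self.cfg
        if cfg.estimate_correlations or cfg.omega_E != 0.0 or cfg.omega_lam != 0.0:
            return theta
        th = theta.copy()
        hs2 = cfg.hyper_scale**2

        blocks = [("z_lam_loc", "log_sigma_lam", 0), ("z_lam_wid", "log_sigma_lam", 1)]
        if cfg.include_a:
            blocks.append(("z_a", "log_sigma_a", 0))
        if cfg.include_b_loc:
            blocks.append(("z_b_loc", "log_sigma_b_loc", 0))
        if cfg.include_b_wid:
            blocks.append(("z_b_wid", "log_sigma_b_wid", 0))
        for zname, lsname, k in blocks:
            zsl = self.slices[zname]
            ls_idx = self.slices[lsname].start + k
            z = th[zsl]
            m = z.shape[0]
            c = np.exp(th[ls_idx]) * z  # centred coordinates, held fixed
            ss = float(c @ c)

            def logd(l, ss=ss, m=m):
                s2 = np.exp(2.0 * l)
                return -0.5 * ss / s2 - m * l - 0.5 * s2 / hs2 + l

            ls_new = _slice_sample_1d(logd, th[ls_idx], rng)
            th[ls_idx] = ls_new
            th[zsl] = c * np.exp(-ls_new)

        for zname, k in (("z_E_loc", 0), ("z_E_wid", 1)):
            zsl = self.slices[zname]
            mu_idx = self.slices["mu_E"].start + k
            ls_idx = self.slices["log_sigma_E"].start + k
            z = th[zsl]
            n = z.shape[0]
            sigma = np.exp(th[ls_idx])
            c = th[mu_idx] + sigma * z  # log-proficiencies, held fixed
            # conjugate normal draw for mu (prior N(0,1))
            prec = n / sigma**2 + 1.0
            mu_new = rng.normal((c.sum() / sigma**2) / prec, np.sqrt(1.0 / prec))
            ss = float(np.sum((c - mu_new) ** 2))

            def logd(l, ss=ss, n=n):
                s2 = np.exp(2.0 * l)
                return -0.5 * ss / s2 - n * l - 0.5 * s2 / hs2 + l

            ls_new = _slice_sample_1d(logd, th[ls_idx], rng)
            th[mu_idx] = mu_new
            th[ls_idx] = ls_new
            th[zsl] = (c - mu_new) * np.exp(-ls_new)
        return th

    # -- density --------------------------------------------------------------

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        cfg, N, J = self.cfg, self.N, self.J
        oi, oj = self.obs_i, self.obs_j
        p = self.split(theta)
        grad = np.zeros_like(theta)
        g = {k: grad[s] for k, s in self.slices.items()}  # views
        lp = 0.0

        # --- constrained values ---
        xi, zeta = p["xi"], p["zeta"]
        w = expit(xi)
        lamstar = expit(zeta)
        T_loc = K1 * zeta
        T_wid = K2 * (xi - 0.5 * (np.log(lamstar) + np.log1p(-lamstar)))

        sigma_E = np.exp(p["log_sigma_E"])
        sigma_lam = np.exp(p["log_sigma_lam"])
        if cfg.estimate_correlations:
            om_E = np.tanh(p["t_omega_E"][0])
            om_L = np.tanh(p["t_omega_lam"][0])
        else:
            om_E, om_L = cfg.omega_E, cfg.omega_lam
        sqE = np.sqrt(1.0 - om_E**2)
        sqL = np.sqrt(1.0 - om_L**2)

        zfl = _helmert_expand(p["z_lam_loc"])
        zfw = _helmert_expand(p["z_lam_wid"])
        v_loc = sigma_lam[0] * zfl
        v_wid = sigma_lam[1] * (om_L * zfl + sqL * zfw)
        rho = np.tanh(p["r_rho"])

        z1, z2 = p["z_E_loc"], p["z_E_wid"]
        el = p["mu_E"][0] + sigma_E[0] * z1
        ew = p["mu_E"][1] + sigma_E[1] * (om_E * z1 + sqE * z2)

        if cfg.include_a:
            sigma_a = np.exp(p["log_sigma_a"][0])
            zfa = _helmert_expand(p["z_a"])
            ua = sigma_a * zfa
            lse = np.logaddexp.reduce(ua)
            loga = np.log(N) + ua - lse
            a = np.exp(loga)
            prob = a / N
        else:
            a = np.ones(N)
            loga = np.zeros(N)
        if cfg.include_b_loc:
            sigma_bl = np.exp(p["log_sigma_b_loc"][0])
            zfbl = _helmert_expand(p["z_b_loc"])
            bl = sigma_bl * zfbl
        else:
            bl = np.zeros(N)
        if cfg.include_b_wid:
            sigma_bw = np.exp(p["log_sigma_b_wid"][0])
            zfbw = _helmert_expand(p["z_b_wid"])
            bw = sigma_bw * zfbw
        else:
            bw = np.zeros(N)

        # --- likelihood ---
        A, LogA = a[oi], loga[oi]
        Tl, Tw = T_loc[oj], T_wid[oj]
        log_sl = LogA - el[oi] - v_loc[oj]
        log_sw = -ew[oi] - v_wid[oj]
        sl, sw = np.exp(log_sl), np.exp(log_sw)
        R = rho[oj]
        q = 1.0 / (1.0 - R**2)
        mu_l = A * Tl + bl[oi]
        mu_w = Tw + bw[oi]
        dl = (self.y[:, 0] - mu_l) / sl
        dw = (self.y[:, 1] - mu_w) / sw
        S = dl * dl - 2.0 * R * dl * dw + dw * dw
        lp += np.sum(-_LOG_2PI - log_sl - log_sw + 0.5 * np.log(q) - 0.5 * q * S)

        gm_l = q * (dl - R * dw) / sl
        gm_w = q * (dw - R * dl) / sw
        gls_l = -1.0 + q * dl * (dl - R * dw)
        gls_w = -1.0 + q * dw * (dw - R * dl)
        g_R = R * q - R * q * q * S + q * dl * dw

        def by_person(x):
            return np.bincount(oi, weights=x, minlength=N)

        def by_item(x):
            return np.bincount(oj, weights=x, minlength=J)

        g_el = -by_person(gls_l)
        g_ew = -by_person(gls_w)
        g_bl = by_person(gm_l)
        g_bw = by_person(gm_w)
        g_vl = -by_item(gls_l)
        g_vw = -by_item(gls_w)
        g_Tl = by_item(A * gm_l)
        g_Tw = by_item(gm_w)
        g_rho = by_item(g_R)

        # --- consensus priors (Beta on w and lamstar, logit Jacobian) ---
        aw, bw_, al, bl_ = cfg.alpha_w, cfg.beta_w, cfg.alpha_l, cfg.beta_l
        lp += np.sum(aw * np.log(w) + bw_ * np.log1p(-w)) - J * betaln(aw, bw_)
        lp += np.sum(al * np.log(lamstar) + bl_ * np.log1p(-lamstar)) - J * betaln(al, bl_)
        g["xi"][:] = K2 * g_Tw + aw - (aw + bw_) * w
        g["zeta"][:] = (
            K1 * g_Tl - 0.5 * K2 * (1.0 - 2.0 * lamstar) * g_Tw
            + al - (al + bl_) * lamstar
        )

        # --- residual correlations: rho = tanh(r), prior 2*Beta(s,s)-1 ---
        s_rho = cfg.rho_shape
        lp += np.sum(s_rho * np.log1p(-rho**2)) - J * (
            (2.0 * s_rho - 1.0) * np.log(2.0) + betaln(s_rho, s_rho)
        )
        g["r_rho"][:] = (1.0 - rho**2) * g_rho - 2.0 * s_rho * rho

        # --- discernibilities (non-centred, sum-zero) ---
        lp += (
            -0.5 * (p["z_lam_loc"] @ p["z_lam_loc"] + p["z_lam_wid"] @ p["z_lam_wid"])
            - (J - 1) * _LOG_2PI
        )
        g["z_lam_loc"][:] = _helmert_contract(
            sigma_lam[0] * g_vl + sigma_lam[1] * om_L * g_vw
        ) - p["z_lam_loc"]
        g["z_lam_wid"][:] = _helmert_contract(sigma_lam[1] * sqL * g_vw) - p["z_lam_wid"]
        g["log_sigma_lam"][0] = g_vl @ v_loc
        g["log_sigma_lam"][1] = g_vw @ v_wid

        # --- proficiencies (non-centred bivariate) ---
        lp += -0.5 * (z1 @ z1 + z2 @ z2) - N * _LOG_2PI
        g["z_E_loc"][:] = sigma_E[0] * g_el + sigma_E[1] * om_E * g_ew - z1
        g["z_E_wid"][:] = sigma_E[1] * sqE * g_ew - z2
        # hyperprior N(0,1) on mu_E
        lp += -0.5 * (p["mu_E"] @ p["mu_E"]) - _LOG_2PI
        g["mu_E"][0] = g_el.sum() - p["mu_E"][0]
        g["mu_E"][1] = g_ew.sum() - p["mu_E"][1]
        g["log_sigma_E"][0] = sigma_E[0] * (g_el @ z1)
        g["log_sigma_E"][1] = sigma_E[1] * (g_ew @ (om_E * z1 + sqE * z2))

        # --- scaling biases ---
        if cfg.include_a:
            g_loga = by_person(A * Tl * gm_l + gls_l)
            gu = g_loga - prob * g_loga.sum()
            lp += -0.5 * (p["z_a"] @ p["z_a"]) - 0.5 * (N - 1) * _LOG_2PI
            g["z_a"][:] = sigma_a * _helmert_contract(gu) - p["z_a"]
            g["log_sigma_a"][0] = gu @ ua

        # --- shifting biases ---
        if cfg.include_b_loc:
            lp += -0.5 * (p["z_b_loc"] @ p["z_b_loc"]) - 0.5 * (N - 1) * _LOG_2PI
            g["z_b_loc"][:] = sigma_bl * _helmert_contract(g_bl) - p["z_b_loc"]
            g["log_sigma_b_loc"][0] = sigma_bl * (g_bl @ zfbl)
        if cfg.include_b_wid:
            lp += -0.5 * (p["z_b_wid"] @ p["z_b_wid"]) - 0.5 * (N - 1) * _LOG_2PI
            g["z_b_wid"][:] = sigma_bw * _helmert_contract(g_bw) - p["z_b_wid"]
            g["log_sigma_b_wid"][0] = sigma_bw * (g_bw @ zfbw)

        # --- half-normal hyperpriors on all scales (log parameterisation) ---
        hs = cfg.hyper_scale
        targets = [("log_sigma_E", 0), ("log_sigma_E", 1),
                   ("log_sigma_lam", 0), ("log_sigma_lam", 1)]
        if cfg.include_a:
            targets.append(("log_sigma_a", 0))
        if cfg.include_b_loc:
            targets.append(("log_sigma_b_loc", 0))
        if cfg.include_b_wid:
            targets.append(("log_sigma_b_wid", 0))
        for name, k in targets:
            log_s = p[name][k]
            s_val = np.exp(log_s)
            lp += _HALFNORMAL_CONST - np.log(hs) - 0.5 * (s_val / hs) ** 2 + log_s
            g[name][k] += 1.0 - (s_val / hs) ** 2

        # --- estimated correlations ---
        if cfg.estimate_correlations:
            s_om = cfg.omega_shape
            for om, t_name, extra in (
                (om_E, "t_omega_E",
                 (1.0 - om_E**2) * sigma_E[1]
                 * (g_ew @ (z1 - (om_E / sqE) * z2))),
                (om_L, "t_omega_lam",
                 (1.0 - om_L**2) * sigma_lam[1]
                 * (g_vw @ (zfl - (om_L / sqL) * zfw))),
            ):
                lp += s_om * np.log1p(-om**2) - (
                    (2.0 * s_om - 1.0) * np.log(2.0) + betaln(s_om, s_om)
                )
                g[t_name][0] = extra - 2.0 * s_om * om

        return float(lp), grad
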