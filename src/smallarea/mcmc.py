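"""Metropolis-within-Gibbs engine for the BYM Poisson spatial models.

All three hierarchical models share one likelihood structure per city
block: stratified Poisson counts ``O ~ Poisson(E * exp(u))`` where the
log-relative-risk surface decomposes as ``u = Z b + S + H`` with ``Z`` a
fixed design (intercept / deprivation / period / interaction columns),
``S`` an intrinsic-CAR spatial field per city-period (sum-to-zero) and
``H`` iid Normal heterogeneity.  The sampler exploits that everything
except the Poisson likelihood is Gaussian:

* ``u`` — elementwise random-walk Metropolis, vectorised over strata (the
  full conditional of ``u`` factorises across strata given ``b`` and
  ``S``); proposal scales adapt per stratum during burn-in only.
* ``b`` — exact Gibbs: given ``u`` and ``S`` the coefficients follow a
  weighted Bayesian linear regression with known noise ``sigma_H``.
* translation ("interweaving") move — proposes a joint shift of ``b_k``
  and ``u`` along the design column, leaving ``H`` unchanged, so the
  acceptance ratio involves only the Poisson terms.  This breaks the
  slow-mixing coupling between coefficients and the latent surface when
  ``sigma_H`` is small.
* ``S`` — exact Gibbs from a Gaussian Markov random field with precision
  ``L/sigma_S^2 + I/sigma_H^2`` (L the graph Laplacian), constrained to
  sum to zero per connected component by conditioning (kriging).
* variances — exact Gibbs: truncated-Gamma draws for the precisions under
  the Uniform(0, upper) prior on each SD.
* hyper-level (random-coefficients model) — exact Gibbs for the
  population means (flat prior) and between-city SDs.

Proposal adaptation stops at the end of burn-in, so retained draws come
from a fixed, valid Markov kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

__all__ = ["BlockData", "GibbsResult", "run_sampler"]

_SIGMA_MIN = 1e-3  # numerical floor on SD draws (avoids singular weights)
_ADAPT_WINDOW = 50


@dataclass
class BlockData:
    """Immutable data of one likelihood block (a city, or a city-period)."""

    label: str
    n: int                       # tracts
    n_periods: int               # 1 (per-period intercept model) or 2
    O: np.ndarray                # (m,) observed deaths, m = n * n_periods
    E: np.ndarray                # (m,) expected deaths, all > 0
    Z: np.ndarray                # (m, p) design matrix
    L: np.ndarray                # (n, n) graph Laplacian
    comps: list[np.ndarray]      # connected components (index arrays)
    periods: list[int] = field(default_factory=list)  # period labels, len n_periods

    def __post_init__(self) -> None:
        if np.any(self.E <= 0):
            raise ValueError(
                f"block {self.label!r}: expected counts must be strictly positive "
                "(drop or merge strata with zero population)"
            )
        if self.O.shape != self.E.shape or self.Z.shape[0] != self.O.size:
            raise ValueError(f"block {self.label!r}: inconsistent array shapes")

    @property
    def m(self) -> int:
        return self.n * self.n_periods

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    @property
    def icar_rank(self) -> int:
        return self.n - len(self.comps)


@dataclass
class GibbsResult:
    """Raw posterior draws of one multi-chain run (chain axis first)."""

    b: np.ndarray                    # (chains, keep, n_blocks, p)
    sigma_s: np.ndarray              # (chains, keep, n_blocks, n_periods)
    sigma_h: np.ndarray              # (chains, keep, n_blocks, n_periods)
    beta: np.ndarray | None          # (chains, keep, p) — hierarchical model only
    sigma_b: np.ndarray | None       # (chains, keep, p)
    u: np.ndarray | None             # (chains, keep, total strata)
    S: np.ndarray | None             # (chains, keep, total strata)


def _sample_sd_trunc(rank: int, quad: float, upper: float, rng: np.random.Generator) -> float:
    """Draw an SD whose density is ``sigma^-rank * exp(-quad/(2 sigma^2))``
    truncated to ``(_SIGMA_MIN, upper)`` (Uniform(0, upper) prior on sigma).

    Equivalent to a truncated Gamma draw for the precision with shape
    ``(rank - 1)/2`` and rate ``quad/2``.
    """
    shape = 0.5 * (rank - 1)
    if shape <= 0 or quad <= 0:
        return float(rng.uniform(_SIGMA_MIN, upper))
    rate = 0.5 * quad
    tau_lo, tau_hi = upper**-2, _SIGMA_MIN**-2
    for _ in range(64):  # rejection is near-certain to succeed in practice
        tau = rng.gamma(shape, 1.0 / rate)
        if tau_lo < tau < tau_hi:
            return float(tau**-0.5)
    dist = stats.gamma(shape, scale=1.0 / rate)
    lo, hi = dist.cdf(tau_lo), dist.cdf(tau_hi)
    tau = dist.ppf(lo + (hi - lo) * rng.uniform())
    return float(np.clip(tau, tau_lo, tau_hi) ** -0.5)


class _BlockState:
    """Mutable chain state and update rules of one block."""

    def __init__(self, data: BlockData, rng: np.random.Generator, upper: float):
        self.d = data
        m, p, T = data.m, data.p, data.n_periods
        u0 = np.log((data.O + 0.5) / data.E)
        self.u = u0 + 0.05 * rng.standard_normal(m)
        coef, *_ = np.linalg.lstsq(data.Z, self.u, rcond=None)
        self.b = coef + 0.05 * rng.standard_normal(p)
        self.S = np.zeros(m)
        self.sig_s = np.clip(0.1 * np.exp(0.3 * rng.standard_normal(T)), _SIGMA_MIN, upper)
        self.sig_h = np.clip(0.1 * np.exp(0.3 * rng.standard_normal(T)), _SIGMA_MIN, upper)
        self.step_u = np.full(m, 0.1)
        self.step_shift = np.full(p, 0.05)
        self.step_scale = np.full(3 * T, 0.4)  # scale moves per period (see update_scales)
        self.acc_u = np.zeros(m)
        self.acc_shift = np.zeros(p)
        self.acc_scale = np.zeros(3 * T)
        self.upper = upper
        # strata are period-major: stratum t*n + i is tract i in period t
        self._slices = [slice(t * data.n, (t + 1) * data.n) for t in range(T)]

    # -- helpers -----------------------------------------------------------
    def _sig_h_stratum(self) -> np.ndarray:
        return np.repeat(self.sig_h, self.d.n)

    def mean_surface(self) -> np.ndarray:
        return self.d.Z @ self.b + self.S

    # -- updates -----------------------------------------------------------
    def update_u(self, rng: np.random.Generator) -> None:
        d = self.d
        mu = self.mean_surface()
        sd = self._sig_h_stratum()
        prop = self.u + self.step_u * rng.standard_normal(d.m)
        with np.errstate(over="ignore"):
            dll = (
                d.O * (prop - self.u)
                - d.E * (np.exp(prop) - np.exp(self.u))
                - 0.5 * ((prop - mu) ** 2 - (self.u - mu) ** 2) / sd**2
            )
        acc = np.log(rng.random(d.m)) < dll
        self.u[acc] = prop[acc]
        self.acc_u += acc

    def update_shift(self, rng, beta=None, sigma_b=None) -> None:
        """Joint translation of (b_k, u) along design column k; H unchanged."""
        d = self.d
        for k in range(d.p):
            delta = self.step_shift[k] * rng.standard_normal()
            du = d.Z[:, k] * delta
            with np.errstate(over="ignore"):
                dll = float(np.sum(d.O * du - d.E * (np.exp(self.u + du) - np.exp(self.u))))
            if beta is not None:
                bk = self.b[k]
                dll -= 0.5 * ((bk + delta - beta[k]) ** 2 - (bk - beta[k]) ** 2) / sigma_b[k] ** 2
            if np.log(rng.random()) < dll:
                self.b[k] += delta
                self.u = self.u + du
                self.acc_shift[k] += 1

    def update_b(self, rng, beta=None, sigma_b=None) -> None:
        d = self.d
        w = self._sig_h_stratum() ** -2
        r = self.u - self.S
        A = d.Z.T @ (d.Z * w[:, None])
        rhs = d.Z.T @ (w * r)
        if beta is not None:
            prior_prec = np.asarray(sigma_b, float) ** -2
            A = A + np.diag(prior_prec)
            rhs = rhs + prior_prec * np.asarray(beta, float)
        A = A + 1e-10 * np.eye(d.p)
        cf = sla.cho_factor(A, lower=True)
        mean = sla.cho_solve(cf, rhs)
        z = rng.standard_normal(d.p)
        self.b = mean + sla.solve_triangular(cf[0], z, lower=True, trans="T")

    def update_S(self, rng) -> None:
        d = self.d
        fixed = d.Z @ self.b
        for t, sl in enumerate(self._slices):
            prec_h = self.sig_h[t] ** -2
            Q = d.L / self.sig_s[t] ** 2 + prec_h * np.eye(d.n)
            cf = sla.cho_factor(Q, lower=True)
            resid = self.u[sl] - fixed[sl]
            mean = sla.cho_solve(cf, prec_h * resid)
            x = mean + sla.solve_triangular(cf[0], rng.standard_normal(d.n), lower=True, trans="T")
            # sum-to-zero per connected component, by conditioning
            for comp in d.comps:
                if comp.size == 1:
                    x[comp] = 0.0
                    continue
                ones = np.zeros(d.n)
                ones[comp] = 1.0
                qi = sla.cho_solve(cf, ones)
                x -= qi * (x[comp].sum() / (ones @ qi))
            self.S[sl] = x

    def update_sigmas(self, rng) -> None:
        d = self.d
        fixed = d.Z @ self.b
        for t, sl in enumerate(self._slices):
            h = self.u[sl] - fixed[sl] - self.S[sl]
            self.sig_h[t] = _sample_sd_trunc(d.n, float(h @ h), self.upper, rng)
            s = self.S[sl]
            quad = float(s @ (d.L @ s))
            self.sig_s[t] = _sample_sd_trunc(d.icar_rank, quad, self.upper, rng)

    def update_scales(self, rng) -> None:
        """Joint multiplicative moves on (field, SD) pairs.

        Rescaling a zero-mean Gaussian field together with its SD leaves
        the field's own prior invariant, so the acceptance ratio reduces
        to the terms the field feeds into (plus the Jacobian).  These
        moves traverse the scale "funnel" that single-site updates cannot,
        keeping the SD chains mixing even when the posterior concentrates
        near zero variance.
        """
        d = self.d
        fixed = d.Z @ self.b
        for t, sl in enumerate(self._slices):
            # (a) spatial field scale against H: (S, sigma_S) -> (c S, c sigma_S)
            z = self.step_scale[3 * t] * rng.standard_normal()
            c = np.exp(z)
            new_sig = self.sig_s[t] * c
            if _SIGMA_MIN < new_sig < self.upper:
                h_old = self.u[sl] - fixed[sl] - self.S[sl]
                h_new = self.u[sl] - fixed[sl] - c * self.S[sl]
                dll = z - 0.5 * float(h_new @ h_new - h_old @ h_old) / self.sig_h[t] ** 2
                if np.log(rng.random()) < dll:
                    self.S[sl] *= c
                    self.sig_s[t] = new_sig
                    self.acc_scale[3 * t] += 1
            # (b) spatial field scale against the likelihood:
            # (S, sigma_S, u) -> (c S, c sigma_S, u + (c-1) S); H unchanged
            z = self.step_scale[3 * t + 1] * rng.standard_normal()
            c = np.exp(z)
            new_sig = self.sig_s[t] * c
            if _SIGMA_MIN < new_sig < self.upper:
                du = (c - 1.0) * self.S[sl]
                u_old = self.u[sl]
                with np.errstate(over="ignore"):
                    dll = z + float(
                        np.sum(d.O[sl] * du - d.E[sl] * (np.exp(u_old + du) - np.exp(u_old)))
                    )
                if np.log(rng.random()) < dll:
                    self.u[sl] = u_old + du
                    self.S[sl] *= c
                    self.sig_s[t] = new_sig
                    self.acc_scale[3 * t + 1] += 1
            # (c) heterogeneous scale: (H, sigma_H) -> (c H, c sigma_H), H = u - Zb - S
            z = self.step_scale[3 * t + 2] * rng.standard_normal()
            c = np.exp(z)
            new_sig = self.sig_h[t] * c
            if _SIGMA_MIN < new_sig < self.upper:
                mu = fixed[sl] + self.S[sl]
                u_old = self.u[sl]
                u_new = mu + c * (u_old - mu)
                with np.errstate(over="ignore"):
                    dll = z + float(
                        np.sum(d.O[sl] * (u_new - u_old) - d.E[sl] * (np.exp(u_new) - np.exp(u_old)))
                    )
                if np.log(rng.random()) < dll:
                    self.u[sl] = u_new
                    self.sig_h[t] = new_sig
                    self.acc_scale[3 * t + 2] += 1

    def dh_change(self, b_new: np.ndarray) -> float:
        """Change in the heterogeneity log-density if ``b`` became ``b_new``."""
        d = self.d
        sd = self._sig_h_stratum()
        h_old = self.u - d.Z @ self.b - self.S
        h_new = self.u - d.Z @ b_new - self.S
        return -0.5 * float(np.sum((h_new**2 - h_old**2) / sd**2))

    def adapt(self) -> None:
        rate_u = self.acc_u / _ADAPT_WINDOW
        self.step_u *= np.clip(np.exp(0.66 * (rate_u - 0.44)), 0.5, 2.0)
        self.step_u = np.clip(self.step_u, 1e-4, 10.0)
        rate_s = self.acc_shift / _ADAPT_WINDOW
        self.step_shift *= np.clip(np.exp(0.66 * (rate_s - 0.44)), 0.5, 2.0)
        self.step_shift = np.clip(self.step_shift, 1e-5, 10.0)
        rate_c = self.acc_scale / _ADAPT_WINDOW
        self.step_scale *= np.clip(np.exp(0.66 * (rate_c - 0.30)), 0.5, 2.0)
        self.step_scale = np.clip(self.step_scale, 1e-3, 5.0)
        self.acc_u[:] = 0.0
        self.acc_shift[:] = 0.0
        self.acc_scale[:] = 0.0


def _run_chain(blocks, hierarchical, spec, seed, store_fields):
    rng = np.random.default_rng(seed)
    upper = spec.prior_sd_upper
    states = [_BlockState(bd, rng, upper) for bd in blocks]
    J, p = len(blocks), blocks[0].p
    T = blocks[0].n_periods
    total_m = sum(bd.m for bd in blocks)

    if hierarchical:
        B0 = np.array([st.b for st in states])
        beta = B0.mean(axis=0)
        sigma_b = np.clip(B0.std(axis=0, ddof=0), 0.05, upper)
        hyper_step = np.full(p, 0.4)
        hyper_acc = np.zeros(p)
    else:
        beta = sigma_b = None

    keep = (spec.iterations - spec.burn_in + spec.thinning - 1) // spec.thinning
    out_b = np.empty((keep, J, p))
    out_ss = np.empty((keep, J, T))
    out_sh = np.empty((keep, J, T))
    out_beta = np.empty((keep, p)) if hierarchical else None
    out_sb = np.empty((keep, p)) if hierarchical else None
    out_u = np.empty((keep, total_m)) if store_fields else None
    out_S = np.empty((keep, total_m)) if store_fields else None

    kept = 0
    for it in range(spec.iterations):
        for st in states:
            st.update_u(rng)
            st.update_shift(rng, beta, sigma_b)
            st.update_b(rng, beta, sigma_b)
            st.update_S(rng)
            st.update_sigmas(rng)
            st.update_scales(rng)
        if hierarchical:
            B = np.array([st.b for st in states])
            for k in range(p):
                beta[k] = rng.normal(B[:, k].mean(), sigma_b[k] / np.sqrt(J))
                quad = float(np.sum((B[:, k] - beta[k]) ** 2))
                sigma_b[k] = _sample_sd_trunc(J, quad, upper, rng)
            # joint group-scale move: (b_k - beta_k, sigma_bk) -> (c*, c sigma_bk)
            for k in range(p):
                z = hyper_step[k] * rng.standard_normal()
                c = float(np.exp(z))
                new_sig = sigma_b[k] * c
                if not (_SIGMA_MIN < new_sig < upper):
                    continue
                proposals = []
                dll = z
                for st in states:
                    b_new = st.b.copy()
                    b_new[k] = beta[k] + c * (st.b[k] - beta[k])
                    dll += st.dh_change(b_new)
                    proposals.append(b_new)
                if np.log(rng.random()) < dll:
                    sigma_b[k] = new_sig
                    for st, b_new in zip(states, proposals):
                        st.b = b_new
                    hyper_acc[k] += 1
        if it < spec.burn_in:
            if (it + 1) % _ADAPT_WINDOW == 0:
                for st in states:
                    st.adapt()
                if hierarchical:
                    rate = hyper_acc / _ADAPT_WINDOW
                    hyper_step *= np.clip(np.exp(0.66 * (rate - 0.30)), 0.5, 2.0)
                    hyper_step = np.clip(hyper_step, 1e-3, 5.0)
                    hyper_acc[:] = 0.0
        elif (it - spec.burn_in) % spec.thinning == 0:
            out_b[kept] = [st.b for st in states]
            out_ss[kept] = [st.sig_s for st in states]
            out_sh[kept] = [st.sig_h for st in states]
            if hierarchical:
                out_beta[kept] = beta
                out_sb[kept] = sigma_b
            if store_fields:
                out_u[kept] = np.concatenate([st.u for st in states])
                out_S[kept] = np.concatenate([st.S for st in states])
            kept += 1
    assert kept == keep
    return out_b, out_ss, out_sh, out_beta, out_sb, out_u, out_S


def run_sampler(blocks, hierarchical, spec, store_fields=True) -> GibbsResult:
    """Run ``spec.chains`` independent chains and stack their draws."""
    if not blocks:
        raise ValueError("no likelihood blocks")
    if len({bd.p for bd in blocks}) != 1 or len({bd.n_periods for bd in blocks}) != 1:
        raise ValueError("all blocks must share design width and period count")
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    per_chain = [
        _run_chain(blocks, hierarchical, spec, s, store_fields) for s in seeds
    ]
    stack = lambda i: (
        np.stack([c[i] for c in per_chain]) if per_chain[0][i] is not None else None
    )
    return GibbsResult(
        b=stack(0), sigma_s=stack(1), sigma_h=stack(2),
        beta=stack(3), sigma_b=stack(4), u=stack(5), S=stack(6),
    )
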