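"""Bayesian spatio-temporal negative-binomial model for district MMR.

Death counts ``y`` observed by source *s* for a geographic unit (district,
division, or state) in year *t* are modelled as negative binomial with
mean

    E[y] = exp(delta_s) * sum_{d in unit} MMR_{d,t} * B_{d,t} / 1e5

where ``B`` are live births and the latent log MMR surface is

    log MMR_{d,t} = mu + x_d' beta                      (covariates)
                  + a_{v(d)} + a_d                      (nested intercepts)
                  + (z + z_{v(d)} + z_d) * (t - tbar)   (nested linear trends)
                  + xi_t                                (smooth non-linear trend)

with districts nested in divisions nested in the state.  ``delta_s`` is a
source effect capturing each source's reporting bias, identified by
constraining a designated reference (gold-standard) source to zero; the
non-linear component ``xi`` carries a second-order random-walk prior and
is constrained orthogonal to the constant and linear trend.  The
negative-binomial dispersion uses the mean-size parameterization
``Var[y] = m + m^2 / k``.

Inference is a Gaussian (Laplace) approximation at the joint posterior
mode, taken over all latent effects and log-transformed hyperparameters;
posterior draws are samples from that Gaussian, and predicted MMR
excludes the source effects (it is the latent "true" MMR).  Because every
latent component enters ``log MMR`` linearly, the whole surface is one
design matrix applied to the parameter vector, which keeps both the
analytic gradient and the per-draw surfaces cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, null_space, solve_triangular
from scipy.special import gammaln

from jsyimpact.data_io import DomainError

log = logging.getLogger("jsyimpact.stage1")

_DEFAULT_PRIORS = {
    "mu_mean": 5.7, "mu_sd": 3.0,       # weak prior on state log MMR
    "beta_sd": 1.0,                      # covariates are standardized internally
    "z0_sd": 0.5,                        # state log-trend per year
    "delta_sd": 1.0,
    "log_phi_mean": 3.0, "log_phi_sd": 2.0,
    "sigma_a_div": 0.3, "sigma_a": 0.3,  # half-normal scales for random-effect sds
    "sigma_z_div": 0.05, "sigma_z": 0.05,
    "sigma_xi": 0.05,
}


def nb_log_likelihood(deaths, expected_deaths, dispersion):
    """Log pmf of the negative binomial, mean/size parameterization.

    ``mean = expected_deaths`` and ``size = dispersion`` (k), so that
    ``Var = m + m^2/k``; the Poisson pmf is the ``k -> inf`` limit.
    """
    y = np.asarray(deaths, dtype=float)
    if np.any(np.abs(y - np.rint(y)) > 1e-8) or np.any(y < 0):
        raise DomainError("deaths must be non-negative integers")
    m = np.asarray(expected_deaths, dtype=float)
    if np.any(m <= 0):
        raise DomainError("expected_deaths must be > 0")
    k = float(dispersion)
    if k <= 0:
        raise DomainError("dispersion must be > 0")
    out = (
        gammaln(y + k) - gammaln(k) - gammaln(y + 1)
        + k * (np.log(k) - np.log(k + m))
        + y * (np.log(m) - np.log(k + m))
    )
    if np.ndim(out) == 0:
        return float(out)
    return out


def percent_change(mmr_start: float, mmr_end: float, ndigits: int = 0):
    """Percent decline from start to end (decline positive).

    Headline summaries round to the nearest integer; district tables use
    one decimal (``ndigits=1``).
    """
    if mmr_start <= 0:
        raise DomainError("mmr_start must be > 0")
    value = (mmr_start - mmr_end) / mmr_start * 100.0
    rounded = round(value, ndigits)
    return int(rounded) if ndigits == 0 else rounded


@dataclass(frozen=True)
class Stage1Spec:
    """Configuration of one candidate estimation model."""

    covariates: tuple = ("tfr", "hdi")
    trend: str = "linear_plus_nonlinear"   # or "linear_only"
    source_effects: bool = True
    reference_source: str | None = None    # default: a state-level source
    draws: int = 1000
    seed: int = 0
    priors: dict = field(default_factory=dict)
    maxiter: int = 1000

    def __post_init__(self) -> None:
        if self.trend not in ("linear_only", "linear_plus_nonlinear"):
            raise ValueError(f"unknown trend {self.trend!r}")
        if self.draws < 1:
            raise ValueError("draws must be >= 1")

    def prior(self, key: str) -> float:
        return self.priors.get(key, _DEFAULT_PRIORS[key])


class Stage1Data:
    """Observation arrays and the latent-surface design matrix."""

    def __init__(self, observations: pd.DataFrame, covariates: pd.DataFrame,
                 live_births: pd.DataFrame, membership: dict[str, str],
                 spec: Stage1Spec):
        self.districts = list(live_births.index)
        self.years = [int(c) for c in live_births.columns]
        self.divisions = sorted(set(membership[d] for d in self.districts))
        self.membership = membership
        self.D, self.T = len(self.districts), len(self.years)
        self.V = len(self.divisions)
        self.tc = np.asarray(self.years, dtype=float)
        self.tc -= self.tc.mean()

        cov = covariates.set_index("district_id").loc[self.districts]
        self.cov_names = list(spec.covariates)
        X = cov[self.cov_names].to_numpy(dtype=float) if self.cov_names else \
            np.zeros((self.D, 0))
        self.cov_mean = X.mean(axis=0) if X.size else np.zeros(0)
        self.cov_sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0) \
            if X.size else np.zeros(0)
        self.X = (X - self.cov_mean) / self.cov_sd if X.size else X

        self.W_lb = live_births.to_numpy(dtype=float) / 1e5   # (D, T)

        obs = observations.reset_index(drop=True)
        self.sources = sorted(obs["source_id"].unique())
        src_level = {
            s: obs.loc[obs["source_id"] == s, "level"].iloc[0]
            for s in self.sources
        }
        if spec.reference_source is not None:
            if spec.reference_source not in self.sources:
                raise DomainError(
                    f"reference source {spec.reference_source!r} not in data"
                )
            self.ref_source = spec.reference_source
        else:
            state_sources = [s for s in self.sources if src_level[s] == "state"]
            self.ref_source = state_sources[0] if state_sources else self.sources[0]

        n = len(obs)
        self.y = np.empty(n)
        self.source_idx = np.empty(n, dtype=int)
        self.Wf = np.zeros((n, self.D * self.T))   # obs -> live-birth weights
        year_pos = {y: j for j, y in enumerate(self.years)}
        dist_pos = {d: i for i, d in enumerate(self.districts)}
        for i, row in obs.iterrows():
            year = int(row["year"])
            if year not in year_pos:
                raise DomainError(f"observation year {year} outside panel years")
            j = year_pos[year]
            if pd.notna(row.get("deaths")):
                self.y[i] = float(row["deaths"])
            else:
                if pd.isna(row.get("live_births")):
                    raise DomainError(
                        "direct-MMR observation without live_births cannot be "
                        f"converted to a pseudo-count (unit {row['unit_id']}, "
                        f"year {year}, source {row['source_id']})"
                    )
                self.y[i] = float(np.rint(row["mmr"] * row["live_births"] / 1e5))
            self.source_idx[i] = self.sources.index(row["source_id"])
            level, unit = row["level"], row["unit_id"]
            if level == "district":
                members = [unit]
            elif level == "division":
                members = [d for d in self.districts if membership[d] == unit]
            else:
                members = self.districts
            if not members or any(d not in dist_pos for d in members):
                raise DomainError(f"unit {unit!r} has no known districts")
            for d in members:
                self.Wf[i, dist_pos[d] * self.T + j] = self.W_lb[dist_pos[d], j]
        self.obs = obs

    def drop_observation(self, i: int) -> "Stage1Data":
        """A copy of the data with observation ``i`` removed (for LOO)."""
        import copy
        new = copy.copy(self)
        keep = np.ones(len(self.y), dtype=bool)
        keep[i] = False
        new.y = self.y[keep]
        new.source_idx = self.source_idx[keep]
        new.Wf = self.Wf[keep]
        new.obs = self.obs[keep].reset_index(drop=True)
        return new


class _ParamIndex:
    """Name -> slice layout of the packed parameter vector."""

    def __init__(self, data: Stage1Data, spec: Stage1Spec):
        self.blocks: dict[str, slice] = {}
        p = 0

        def add(name: str, size: int) -> None:
            nonlocal p
            if size > 0:
                self.blocks[name] = slice(p, p + size)
                p += size

        add("mu", 1)
        add("beta", data.X.shape[1])
        add("a_div", data.V if data.V > 1 else 0)
        add("a_d", data.D if data.D > 1 else 0)
        add("z0", 1)
        add("z_div", data.V if data.V > 1 else 0)
        add("z_d", data.D if data.D > 1 else 0)
        self.nonlinear = spec.trend == "linear_plus_nonlinear" and data.T >= 4
        add("xi", data.T - 2 if self.nonlinear else 0)
        n_delta = len(data.sources) - 1 if spec.source_effects else 0
        add("delta", n_delta)
        add("log_phi", 1)
        for name in ("a_div", "a_d", "z_div", "z_d"):
            if name in self.blocks:
                add(f"log_sig_{name}", 1)
        if self.nonlinear:
            add("log_sig_xi", 1)
        self.size = p
        # latent field first, hyperparameters (log_phi, log sds) last
        self.n_latent = self.blocks["log_phi"].start
        self.hyper_names = [n for n in self.blocks
                            if n == "log_phi" or n.startswith("log_sig")]
        self.hyper_pos = {
            n: self.blocks[n].start - self.n_latent for n in self.hyper_names
        }
        self.n_hyper = self.size - self.n_latent

    def get(self, theta: np.ndarray, name: str) -> np.ndarray:
        if name not in self.blocks:
            return np.zeros(0)
        return theta[self.blocks[name]]

    def __contains__(self, name: str) -> bool:
        return name in self.blocks


class Stage1Model:
    """Joint log posterior of the latent surface, source effects and
    hyperparameters, with analytic gradient."""

    def __init__(self, data: Stage1Data, spec: Stage1Spec):
        self.data = data
        self.spec = spec
        self.idx = _ParamIndex(data, spec)
        if self.idx.nonlinear:
            T = data.T
            D2 = np.zeros((T - 2, T))
            for t in range(T - 2):
                D2[t, t], D2[t, t + 1], D2[t, t + 2] = 1.0, -2.0, 1.0
            basis = np.vstack([np.ones(T), data.tc]).T
            self.B_xi = null_space(basis.T)       # (T, T-2), orthonormal
            self.Q_xi = self.B_xi.T @ (D2.T @ D2) @ self.B_xi
            self._logdet_Q_xi = float(np.linalg.slogdet(self.Q_xi)[1])
        self.A = self._build_design()            # (D*T, p)
        self.A_lat = self.A[:, : self.idx.n_latent]
        self._delta_map = self._build_delta_map()

    def _build_design(self) -> np.ndarray:
        d, idx = self.data, self.idx
        A = np.zeros((d.D * d.T, idx.size))
        div_of = np.array(
            [d.divisions.index(d.membership[dd]) for dd in d.districts]
        )
        rows = np.arange(d.D * d.T)
        dist_of_row = rows // d.T
        year_of_row = rows % d.T
        tcr = d.tc[year_of_row]
        A[:, idx.blocks["mu"]] = 1.0
        if "beta" in idx:
            A[:, idx.blocks["beta"]] = d.X[dist_of_row]
        if "a_div" in idx:
            for v in range(d.V):
                A[div_of[dist_of_row] == v, idx.blocks["a_div"].start + v] = 1.0
        if "a_d" in idx:
            A[rows, idx.blocks["a_d"].start + dist_of_row] = 1.0
        A[:, idx.blocks["z0"]] = tcr[:, None]
        if "z_div" in idx:
            for v in range(d.V):
                mask = div_of[dist_of_row] == v
                A[mask, idx.blocks["z_div"].start + v] = tcr[mask]
        if "z_d" in idx:
            A[rows, idx.blocks["z_d"].start + dist_of_row] = tcr
        if idx.nonlinear:
            A[:, idx.blocks["xi"]] = self.B_xi[year_of_row]
        return A

    def _build_delta_map(self) -> np.ndarray | None:
        """(n_obs,) index into the delta block, -1 for the reference source."""
        if "delta" not in self.idx:
            return None
        d = self.data
        free = [s for s in d.sources if s != d.ref_source]
        lookup = {d.sources.index(s): j for j, s in enumerate(free)}
        return np.array([lookup.get(si, -1) for si in d.source_idx])

    # -- log posterior ----------------------------------------------------

    def _obs_delta(self, theta: np.ndarray) -> np.ndarray:
        if self._delta_map is None:
            return np.zeros(len(self.data.y))
        delta = self.idx.get(theta, "delta")
        full = np.concatenate([delta, [0.0]])
        return full[self._delta_map]

    def eta(self, theta: np.ndarray) -> np.ndarray:
        """Latent log-MMR surface, shape (D, T)."""
        return (self.A @ theta).reshape(self.data.D, self.data.T)

    def obs_mean(self, theta: np.ndarray) -> np.ndarray:
        lam = np.exp(self.A @ theta)
        return np.exp(self._obs_delta(theta)) * (self.data.Wf @ lam)

    def obs_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-observation NB log likelihood at one parameter point."""
        k = np.exp(self.idx.get(theta, "log_phi")[0])
        return nb_log_likelihood(self.data.y, self.obs_mean(theta), k)

    def log_joint(self, theta: np.ndarray) -> float:
        """Joint log posterior density (latents + hyperparameters).

        Used by external samplers for cross-checking; the fitting path
        itself goes through the nested Laplace scheme below.
        """
        psi = theta[: self.idx.n_latent]
        kappa = theta[self.idx.n_latent:]
        k = float(np.exp(kappa[self.idx.hyper_pos["log_phi"]]))
        parts = self._loglik_parts(psi, k, hessian=False)
        if parts is None:
            return -np.inf
        ll, _, _ = parts
        P, mp, logdetP = self._prior(kappa)
        r = psi - mp
        return float(
            ll - 0.5 * r @ P @ r + 0.5 * logdetP + self._log_hyperprior(kappa)
        )

    # -- nested Laplace machinery ----------------------------------------

    def _log_hyperprior(self, kappa: np.ndarray) -> float:
        spec, idx = self.spec, self.idx
        lp = 0.0
        u_phi = kappa[idx.hyper_pos["log_phi"]]
        lp += -0.5 * ((u_phi - spec.prior("log_phi_mean"))
                      / spec.prior("log_phi_sd")) ** 2
        scale_of = {"log_sig_a_div": "sigma_a_div", "log_sig_a_d": "sigma_a",
                    "log_sig_z_div": "sigma_z_div", "log_sig_z_d": "sigma_z",
                    "log_sig_xi": "sigma_xi"}
        for name, pos in idx.hyper_pos.items():
            if name == "log_phi":
                continue
            u = kappa[pos]
            s = spec.prior(scale_of[name])
            # half-normal on sigma with the log-scale Jacobian
            lp += -0.5 * np.exp(2 * u) / s ** 2 + u
        return float(lp)

    def _prior(self, kappa: np.ndarray):
        """Gaussian prior of the latent field given hyperparameters.

        Returns (precision matrix P, prior mean, log det P).
        """
        idx, spec = self.idx, self.spec
        n = idx.n_latent
        P = np.zeros((n, n))
        mp = np.zeros(n)
        logdet = 0.0

        def set_diag(name: str, prec: float) -> None:
            nonlocal logdet
            sl = idx.blocks[name]
            for i in range(sl.start, sl.stop):
                P[i, i] = prec
            logdet += (sl.stop - sl.start) * np.log(prec)

        set_diag("mu", 1.0 / spec.prior("mu_sd") ** 2)
        mp[idx.blocks["mu"]] = spec.prior("mu_mean")
        if "beta" in idx:
            set_diag("beta", 1.0 / spec.prior("beta_sd") ** 2)
        set_diag("z0", 1.0 / spec.prior("z0_sd") ** 2)
        if "delta" in idx:
            set_diag("delta", 1.0 / spec.prior("delta_sd") ** 2)
        for name in ("a_div", "a_d", "z_div", "z_d"):
            if name in idx:
                u = kappa[idx.hyper_pos[f"log_sig_{name}"]]
                set_diag(name, float(np.exp(-2 * u)))
        if idx.nonlinear:
            sl = idx.blocks["xi"]
            u = kappa[idx.hyper_pos["log_sig_xi"]]
            P[sl, sl] = self.Q_xi * np.exp(-2 * u)
            logdet += self._logdet_Q_xi - 2 * (sl.stop - sl.start) * u
        return P, mp, logdet

    def _loglik_parts(self, psi: np.ndarray, k: float, hessian: bool = True):
        """NB log likelihood with gradient and Hessian in latent coords.

        Returns None if the linear predictor overflows (line-search guard).
        """
        d, idx = self.data, self.idx
        y = d.y
        s_lin = self.A_lat @ psi
        if np.max(s_lin) > 40.0:
            return None
        lam = np.exp(s_lin)
        ed = self._obs_delta_psi(psi)
        base = d.Wf @ lam
        m = np.exp(ed) * base
        if np.any(m <= 0) or not np.all(np.isfinite(m)):
            return None
        ll = float(np.sum(
            gammaln(y + k) - gammaln(k) - gammaln(y + 1)
            + k * (np.log(k) - np.log(k + m))
            + y * (np.log(m) - np.log(k + m))
        ))
        dllm = y / m - (y + k) / (k + m)
        g = np.zeros(idx.n_latent)
        S = d.Wf * lam[None, :] * np.exp(ed)[:, None]     # d m_i / d eta_c
        g_eta = S.T @ dllm
        g += self.A_lat.T @ g_eta
        if self._delta_map is not None:
            sl = idx.blocks["delta"]
            contrib = dllm * m
            for j in range(sl.stop - sl.start):
                g[sl.start + j] = contrib[self._delta_map == j].sum()
        if not hessian:
            return ll, g, None
        d2llm = -y / m ** 2 + (y + k) / (k + m) ** 2
        H_eta = S.T @ (S * d2llm[:, None])
        H_eta[np.diag_indices_from(H_eta)] += g_eta
        H = self.A_lat.T @ H_eta @ self.A_lat
        if self._delta_map is not None:
            sl = idx.blocks["delta"]
            for j in range(sl.stop - sl.start):
                mask = self._delta_map == j
                w = (d2llm * m + dllm)[mask]
                cross = self.A_lat.T @ (S[mask].T @ w)
                H[sl.start + j, :] += cross
                H[:, sl.start + j] += cross
                H[sl.start + j, sl.start + j] += float(
                    ((d2llm * m * m + dllm * m)[mask]).sum()
                )
        return ll, g, H

    def _obs_delta_psi(self, psi: np.ndarray) -> np.ndarray:
        if self._delta_map is None:
            return np.zeros(len(self.data.y))
        delta = psi[self.idx.blocks["delta"]]
        full = np.concatenate([delta, [0.0]])
        return full[self._delta_map]

    def _psi_start(self) -> np.ndarray:
        psi = np.zeros(self.idx.n_latent)
        base0 = self.data.Wf @ np.ones(self.data.D * self.data.T)
        rate = max(self.data.y.sum() / base0.sum(), 1e-6)
        psi[self.idx.blocks["mu"]] = np.log(rate)
        return psi

    def _kappa_start(self) -> np.ndarray:
        kappa = np.zeros(self.idx.n_hyper)
        kappa[self.idx.hyper_pos["log_phi"]] = np.log(20.0)
        for name, pos in self.idx.hyper_pos.items():
            if name != "log_phi":
                kappa[pos] = np.log(0.1)
        return kappa

    def _inner_newton(self, kappa: np.ndarray, psi0: np.ndarray | None = None,
                      tol: float = 1e-8, maxiter: int = 100):
        """Mode and curvature of the latent field given hyperparameters.

        The NB log likelihood is concave in the latent field under the
        log link, so damped Newton converges globally here.
        """
        P, mp, logdetP = self._prior(kappa)
        k = float(np.exp(kappa[self.idx.hyper_pos["log_phi"]]))
        psi = psi0.copy() if psi0 is not None else self._psi_start()

        def evaluate(p_vec):
            parts = self._loglik_parts(p_vec, k)
            if parts is None:
                return None
            ll, g, H = parts
            r = p_vec - mp
            return ll - 0.5 * r @ P @ r, g - P @ r, P - H

        state = evaluate(psi)
        if state is None:
            psi = self._psi_start()
            state = evaluate(psi)
        f, g, Prec = state
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            if np.max(np.abs(g)) < tol:
                break
            ridge = 0.0
            while True:
                try:
                    c = cho_factor(
                        Prec + ridge * np.eye(len(psi)), lower=True
                    )
                    break
                except np.linalg.LinAlgError:
                    ridge = max(ridge * 10, 1e-8)
            step = cho_solve(c, g)
            t = 1.0
            accepted = False
            for _ in range(40):
                cand = evaluate(psi + t * step)
                if cand is not None and cand[0] >= f - 1e-12:
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                break
            psi = psi + t * step
            f, g, Prec = cand
        return psi, f, Prec, logdetP, n_iter

    def conditional_gaussian(self, kappa: np.ndarray,
                             psi0: np.ndarray | None = None):
        """Mode and precision of the latent field at fixed ``kappa``."""
        psi_m, _, Prec, _, _ = self._inner_newton(kappa, psi0)
        return psi_m, Prec

    def conditional_draws(self, kappa: np.ndarray, n: int, seed: int,
                          psi0: np.ndarray | None = None) -> np.ndarray:
        """Draws of the latent field from its Gaussian approximation at
        fixed hyperparameters ``kappa``."""
        psi_m, Prec = self.conditional_gaussian(kappa, psi0)
        L = np.linalg.cholesky(Prec)
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, len(psi_m)))
        return psi_m + solve_triangular(L, z.T, trans="T", lower=True).T

    def loglik_matrix(self, psi_draws: np.ndarray,
                      kappa: np.ndarray) -> np.ndarray:
        """(draws, n_obs) per-observation log likelihoods at fixed kappa."""
        k = float(np.exp(kappa[self.idx.hyper_pos["log_phi"]]))
        lam = np.exp(psi_draws @ self.A_lat.T)          # (M, D*T)
        base = lam @ self.data.Wf.T                     # (M, n)
        if self._delta_map is None:
            ed = 0.0
        else:
            sl = self.idx.blocks["delta"]
            full = np.hstack([psi_draws[:, sl], np.zeros((len(psi_draws), 1))])
            ed = full[:, self._delta_map]
        m = np.exp(ed) * base
        y = self.data.y[None, :]
        return (
            gammaln(y + k) - gammaln(k) - gammaln(y + 1)
            + k * (np.log(k) - np.log(k + m))
            + y * (np.log(m) - np.log(k + m))
        )

    def _neg_marginal(self, kappa: np.ndarray) -> float:
        """Laplace-approximate -log posterior of the hyperparameters."""
        psi0 = getattr(self, "_warm_psi", None)
        psi, f, Prec, logdetP, _ = self._inner_newton(kappa, psi0)
        self._warm_psi = psi
        sign, ld = np.linalg.slogdet(Prec)
        if sign <= 0:
            return 1e12
        return -(f + 0.5 * logdetP - 0.5 * ld + self._log_hyperprior(kappa))

    def fit(self) -> "Stage1Fit":
        idx = self.idx
        bounds = []
        for name in idx.hyper_names:
            bounds.append((-2.0, 12.0) if name == "log_phi" else (-6.0, 2.0))
        self._warm_psi = self._psi_start()
        res = optimize.minimize(
            self._neg_marginal,
            self._kappa_start(),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.spec.maxiter, "ftol": 1e-11},
        )
        kappa = res.x
        psi, f, Prec, logdetP, inner_iters = self._inner_newton(
            kappa, self._warm_psi
        )
        self._warm_psi = psi

        # curvature over the hyperparameters (finite differences of the
        # Laplace marginal), for propagating hyperparameter uncertainty
        nh = idx.n_hyper
        Hk = np.empty((nh, nh))
        h = 1e-3
        f0 = self._neg_marginal(kappa)
        for i in range(nh):
            for j in range(i, nh):
                kpp = kappa.copy(); kpp[i] += h; kpp[j] += h
                kpm = kappa.copy(); kpm[i] += h; kpm[j] -= h
                kmp = kappa.copy(); kmp[i] -= h; kmp[j] += h
                kmm = kappa.copy(); kmm[i] -= h; kmm[j] -= h
                Hk[i, j] = Hk[j, i] = (
                    self._neg_marginal(kpp) - self._neg_marginal(kpm)
                    - self._neg_marginal(kmp) + self._neg_marginal(kmm)
                ) / (4 * h * h)
        eigval, eigvec = np.linalg.eigh(0.5 * (Hk + Hk.T))
        clipped = int((eigval < 1e-6).sum())
        eigval = np.maximum(eigval, 1e-6)
        cov_k = (eigvec / eigval) @ eigvec.T

        converged = bool(res.success) and np.isfinite(f)
        if not converged:
            log.warning("stage-1 fit flagged non-converged: %s", res.message)

        rng = np.random.default_rng(self.spec.seed)
        M = self.spec.draws
        zk = rng.standard_normal((M, nh))
        Lk = np.linalg.cholesky(cov_k + 1e-12 * np.eye(nh))
        kappa_draws = kappa + zk @ Lk.T
        sign_k, logdet_cov_k = np.linalg.slogdet(cov_k)
        z_lat = rng.standard_normal((M, idx.n_latent))
        psi_draws = np.empty((M, idx.n_latent))
        log_q = np.empty(M)     # proposal density (up to constants)
        for mdraw in range(M):
            psi_m, _, Prec_m, _, _ = self._inner_newton(
                kappa_draws[mdraw], psi, tol=1e-6, maxiter=30
            )
            Lm = np.linalg.cholesky(Prec_m)
            psi_draws[mdraw] = psi_m + solve_triangular(
                Lm, z_lat[mdraw], trans="T", lower=True
            )
            log_q[mdraw] = (
                -0.5 * zk[mdraw] @ zk[mdraw] - 0.5 * logdet_cov_k
                + float(np.sum(np.log(np.diag(Lm))))
                - 0.5 * z_lat[mdraw] @ z_lat[mdraw]
            )
        theta_map = np.concatenate([psi, kappa])
        theta_draws = np.hstack([psi_draws, kappa_draws])
        # self-normalized importance weights correcting the Laplace
        # proposal to the exact (unnormalized) joint posterior
        log_p = np.array([self.log_joint(t) for t in theta_draws])
        log_w = np.where(np.isfinite(log_p), log_p - log_q, -np.inf)
        log_w = log_w - np.max(log_w[np.isfinite(log_w)])
        log_mmr_draws = (psi_draws @ self.A_lat.T).reshape(
            M, self.data.D, self.data.T
        )
        cov = np.zeros((idx.size, idx.size))
        cov[: idx.n_latent, : idx.n_latent] = np.linalg.inv(Prec)
        cov[idx.n_latent:, idx.n_latent:] = cov_k
        w = np.exp(log_w)
        ess_w = float(w.sum() ** 2 / (w ** 2).sum())
        return Stage1Fit(
            model=self,
            theta_map=theta_map,
            cov=cov,
            theta_draws=theta_draws,
            log_mmr_draws=log_mmr_draws,
            log_weights=log_w,
            diagnostics={
                "optimizer_success": bool(res.success),
                "message": str(res.message),
                "neg_marginal": float(f0),
                "inner_newton_iterations": int(inner_iters),
                "hyper_hessian_eigenvalues_clipped": clipped,
                "importance_weight_ess": ess_w,
            },
            converged=converged,
        )


@dataclass
class Stage1Fit:
    """Laplace-approximate posterior of the estimation model."""

    model: Stage1Model
    theta_map: np.ndarray
    cov: np.ndarray
    theta_draws: np.ndarray          # (draws, p)
    log_mmr_draws: np.ndarray        # (draws, D, T)
    log_weights: np.ndarray          # importance correction to the exact joint
    diagnostics: dict
    converged: bool

    @property
    def weights(self) -> np.ndarray:
        """Normalized importance weights of the posterior draws."""
        w = np.exp(self.log_weights)
        return w / w.sum()

    @property
    def data(self) -> Stage1Data:
        return self.model.data

    @property
    def spec(self) -> Stage1Spec:
        return self.model.spec

    @property
    def n_draws(self) -> int:
        return self.theta_draws.shape[0]

    @property
    def dispersion(self) -> float:
        return float(np.exp(self.model.idx.get(self.theta_map, "log_phi")[0]))

    def param_map(self, name: str) -> np.ndarray:
        return self.model.idx.get(self.theta_map, name)

    def param_draws(self, name: str) -> np.ndarray:
        if name not in self.model.idx:
            return np.zeros((self.n_draws, 0))
        return self.theta_draws[:, self.model.idx.blocks[name]]

    def source_effects(self) -> pd.DataFrame:
        """Posterior summary of delta_s (reference source fixed at 0)."""
        d = self.data
        free = [s for s in d.sources if s != d.ref_source]
        draws = self.param_draws("delta")
        rows = [{"source_id": d.ref_source, "mean": 0.0, "sd": 0.0,
                 "reference": True}]
        for j, s in enumerate(free):
            rows.append({
                "source_id": s,
                "mean": float(draws[:, j].mean()),
                "sd": float(draws[:, j].std(ddof=1)),
                "reference": False,
            })
        return pd.DataFrame(rows)


def fit_stage1(
    observations: pd.DataFrame,
    covariates: pd.DataFrame,
    live_births: pd.DataFrame,
    membership: dict[str, str],
    spec: Stage1Spec | None = None,
) -> Stage1Fit:
    """Fit the district MMR model.  See module docstring for the model."""
    spec = spec or Stage1Spec()
    if spec.source_effects and observations["source_id"].nunique() < 2:
        spec = replace(spec, source_effects=False)
        log.warning("single source in data: source effects disabled")
    data = Stage1Data(observations, covariates, live_births, membership, spec)
    return Stage1Model(data, spec).fit()


def predict_mmr(fit: Stage1Fit, quantiles=(0.025, 0.975)) -> pd.DataFrame:
    """Posterior median and interval of the latent MMR per district-year.

    Source effects are excluded: this is the model's "true" MMR, not any
    single source's reported level.  Quantiles use numpy's default
    (linear-interpolation) definition on the exponentiated draws.
    """
    mmr = np.exp(fit.log_mmr_draws)
    med = np.median(mmr, axis=0)
    lo = np.quantile(mmr, quantiles[0], axis=0)
    hi = np.quantile(mmr, quantiles[1], axis=0)
    rows = []
    for i, d in enumerate(fit.data.districts):
        for j, year in enumerate(fit.data.years):
            rows.append({
                "district_id": d, "year": year,
                "median": med[i, j], "lower": lo[i, j], "upper": hi[i, j],
            })
    return pd.DataFrame(rows)


def sample_mmr_draws(fit: Stage1Fit, n: int, seed: int = 0) -> np.ndarray:
    """Jointly drawn MMR surfaces, shape ``(n, D, T)``.

    Whole surfaces are drawn together so the posterior correlation across
    district-years is preserved.  If ``n`` equals the fit's stored number
    of draws the fit's own draws are returned in order; otherwise draws
    are resampled with replacement.
    """
    if n <= 0:
        raise DomainError("number of draws must be positive")
    if n == fit.n_draws:
        return np.exp(fit.log_mmr_draws)
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, fit.n_draws, size=n)
    return np.exp(fit.log_mmr_draws[pick])
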