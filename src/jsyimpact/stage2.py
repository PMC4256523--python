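"""Multilevel impact regression of log MMR on program exposure.

For each posterior MMR surface the model

    log(MMR_{d,t}) = b0 + b1*Urban_d + b2*Lit_d + b3*ANC3_{d,t}
                   + b4*NJSY_{d,t} + b5*Exposure_{d,t}
                   + alpha_t + eta_d + phi_d * Exposure_{d,t} + e_{d,t}

is fitted, where the exposure is either the JSY-supported delivery
proportion (``jsy_prop``, on the 0-1 scale) or annual JSY expenditure in
lakh, ``alpha_t`` is a year random intercept, ``eta_d`` a district random
intercept and ``phi_d`` a district random exposure slope (independent
components).  Percent covariates (urban, literacy, ANC3) stay on the
0-100 scale so coefficient magnitudes are per percentage point.

Estimation is restricted maximum likelihood over the log variance
components with analytic gradients and a deterministic optimizer; best
linear unbiased predictions of the district slopes and their standard
errors come from Henderson's mixed-model equations.  With no random
terms the fit reduces exactly to ordinary least squares.

Posterior uncertainty in the MMR estimates is propagated by fitting the
model to each of *n* sampled surfaces and pooling with Rubin-style
rules: the pooled estimate is the mean of per-draw estimates and the
pooled variance is the mean within-draw variance plus ``(1 + 1/n)``
times the between-draw variance; intervals and p-values use the normal
reference.  Empirical 2.5/97.5 percentiles of the per-draw estimates
are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from jsyimpact.reporting import format_estimate, format_interval, format_p

log = logging.getLogger("jsyimpact.stage2")

RANDOM_TERMS = ("year_intercept", "district_intercept", "district_exposure_slope")


class CollinearityError(ValueError):
    """The fixed-effect design is rank deficient."""


@dataclass(frozen=True)
class Stage2Spec:
    """Configuration of the impact regression."""

    exposure: str = "jsy_prop"            # or "expenditure"
    fixed_terms: tuple = ("literacy", "urban", "anc3", "njsy_prop")
    random_terms: tuple = RANDOM_TERMS
    n_draws: int = 1000
    seed: int = 0
    var_lower: float = 1e-10              # variance-component boundary

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        unknown = set(self.random_terms) - set(RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms {sorted(unknown)}")

    @property
    def term_order(self) -> list[str]:
        # Intercept, Literacy, Urban, ANC3, NJSY, exposure
        return ["Intercept", *self.fixed_terms, self.exposure]


@dataclass
class _Design:
    """Fixed design shared by every per-draw fit on the same panel."""

    districts: list[str]
    years: list[int]
    terms: list[str]
    X: np.ndarray
    names: list[str]                   # random-term names, in order
    Zs: list[np.ndarray]
    ZZt: list[np.ndarray]


def _build_design(
    covariates: pd.DataFrame,
    exposure_panel: pd.DataFrame,
    spec: Stage2Spec,
    districts: list[str],
    years: list[int],
) -> _Design:
    if len(years) < 2 or len(districts) < 3:
        raise ValueError("need at least 3 districts and 2 years")
    n = len(districts) * len(years)
    panel = exposure_panel.set_index(["district_id", "year"]).sort_index()
    cov = covariates.set_index("district_id")
    cols: dict[str, np.ndarray] = {}
    for term in spec.fixed_terms + (spec.exposure,):
        vals = np.empty(n)
        pos = 0
        for d in districts:
            for t in years:
                if term in panel.columns:
                    vals[pos] = float(panel.at[(d, t), term])
                elif term in cov.columns:
                    vals[pos] = float(cov.at[d, term])
                else:
                    raise KeyError(f"fixed term {term!r} not found in inputs")
                pos += 1
        cols[term] = vals
    terms = spec.term_order
    X = np.column_stack([np.ones(n)] + [cols[t] for t in terms[1:]])
    for j, t in enumerate(terms[1:], start=1):
        if np.ptp(X[:, j]) == 0:
            raise CollinearityError(
                f"term {t!r} is constant across all district-years"
            )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            f"fixed-effect design is rank deficient (terms {terms})"
        )
    D, T = len(districts), len(years)
    dist_ind = np.repeat(np.eye(D), T, axis=0)
    year_ind = np.tile(np.eye(T), (D, 1))
    Z: dict[str, np.ndarray] = {}
    if "year_intercept" in spec.random_terms:
        Z["year_intercept"] = year_ind
    if "district_intercept" in spec.random_terms:
        Z["district_intercept"] = dist_ind
    if "district_exposure_slope" in spec.random_terms:
        Z["district_exposure_slope"] = dist_ind * cols[spec.exposure][:, None]
    names = list(Z.keys())
    Zs = [Z[k] for k in names]
    return _Design(
        districts=list(districts), years=[int(t) for t in years],
        terms=terms, X=X, names=names, Zs=Zs,
        ZZt=[Zk @ Zk.T for Zk in Zs],
    )


def _surface_to_y(surface: pd.DataFrame, districts, years) -> np.ndarray:
    return surface.loc[districts, years].to_numpy(dtype=float).reshape(-1)


@dataclass
class SingleFit:
    """One mixed-model fit to one log-MMR surface."""

    params: pd.Series                  # fixed effects
    se: pd.Series
    vcov: np.ndarray
    varcomps: dict                     # variances incl. "residual"
    phi: pd.DataFrame | None           # district slope = b5 + BLUP, with se
    converged: bool
    boundary: list = field(default_factory=list)
    theta: np.ndarray | None = None    # log-variance params (warm starts)
    reml: float = np.nan


def _reml_value_grad(logvars: np.ndarray, y: np.ndarray, X: np.ndarray,
                     ZZt: list[np.ndarray]):
    """-2 restricted log likelihood (up to a constant) and its gradient.

    Components are parameterized as log variances.  The gradient uses
    ``dC/dlog v_j = v_j * (tr(P G_j) - y'P G_j P y)`` with
    ``P = Vinv - Vinv X (X'Vinv X)^-1 X'Vinv``.
    """
    n, p = X.shape
    v = np.exp(logvars)
    V = v[0] * np.eye(n)
    for k, G in enumerate(ZZt):
        V += v[k + 1] * G
    try:
        cf = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(logvars)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cf))))
    Vinv = np.linalg.inv(V)
    XtVi = X.T @ Vinv
    XtViX = XtVi @ X
    sign, logdetXVX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e10, np.zeros_like(logvars)
    beta = np.linalg.solve(XtViX, XtVi @ y)
    r = y - X @ beta
    Vir = Vinv @ r
    value = float(logdetV + logdetXVX + r @ Vir)
    P = Vinv - XtVi.T @ np.linalg.solve(XtViX, XtVi)
    Py = Vir                    # P y = Vinv (y - X beta_gls)
    grad = np.empty_like(logvars)
    grad[0] = v[0] * (np.trace(P) - Py @ Py)
    for k, G in enumerate(ZZt):
        grad[k + 1] = v[k + 1] * (float(np.sum(P * G)) - Py @ (G @ Py))
    return value, grad


def _fit_prepared(
    y: np.ndarray,
    design: _Design,
    spec: Stage2Spec,
    start_theta: np.ndarray | None = None,
) -> SingleFit:
    X, terms = design.X, design.terms
    n, p = X.shape
    if not design.Zs:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sig2 = float(r @ r) / (n - p)
        vcov = sig2 * np.linalg.inv(X.T @ X)
        return SingleFit(
            params=pd.Series(beta, index=terms),
            se=pd.Series(np.sqrt(np.diag(vcov)), index=terms),
            vcov=vcov,
            varcomps={"residual": sig2},
            phi=None,
            converged=True,
        )

    names, Zs, ZZt = design.names, design.Zs, design.ZZt
    var_y = max(float(np.var(y)), 1e-12)
    if start_theta is None:
        start = np.log(np.r_[var_y / 2, [var_y / 4] * len(Zs)])
    else:
        start = np.asarray(start_theta, dtype=float)
    lo = np.log(spec.var_lower * var_y)
    hi = np.log(var_y * 1e3)
    start = np.clip(start, lo + 1e-3, hi - 1e-3)
    res = optimize.minimize(
        _reml_value_grad, start, args=(y, X, ZZt), jac=True,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * (len(Zs) + 1),
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8},
    )
    logvars = res.x
    sig2 = float(np.exp(logvars[0]))
    taus = np.exp(logvars[1:])
    boundary = [names[k] for k in range(len(Zs))
                if logvars[k + 1] < lo + 1e-6]
    if boundary:
        log.debug("variance components at boundary (~0): %s", boundary)

    V = sig2 * np.eye(n)
    for k in range(len(Zs)):
        V += taus[k] * ZZt[k]
    Vinv = np.linalg.inv(V)
    XtVi = X.T @ Vinv
    XtViX = XtVi @ X
    beta = np.linalg.solve(XtViX, XtVi @ y)
    vcov = np.linalg.inv(XtViX)

    # Henderson mixed-model equations for BLUPs and their uncertainty
    Zall = np.hstack(Zs)
    q = Zall.shape[1]
    Ginv = np.diag(
        np.concatenate([np.full(Zk.shape[1], 1.0 / taus[k])
                        for k, Zk in enumerate(Zs)])
    )
    C = np.zeros((p + q, p + q))
    C[:p, :p] = X.T @ X / sig2
    C[:p, p:] = X.T @ Zall / sig2
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Zall.T @ Zall / sig2 + Ginv
    rhs = np.concatenate([X.T @ y, Zall.T @ y]) / sig2
    Cinv = np.linalg.inv(C)
    sol = Cinv @ rhs
    u = sol[p:]

    phi = None
    if "district_exposure_slope" in names:
        off = p
        for k, nm in enumerate(names):
            if nm == "district_exposure_slope":
                break
            off += Zs[k].shape[1]
        j5 = terms.index(spec.exposure)
        est, ses = [], []
        for i in range(len(design.districts)):
            ui = off + i
            var = Cinv[j5, j5] + Cinv[ui, ui] + 2 * Cinv[j5, ui]
            est.append(beta[j5] + u[ui - p])
            ses.append(np.sqrt(max(var, 0.0)))
        phi = pd.DataFrame(
            {"district_id": design.districts, "estimate": est, "se": ses}
        )

    varcomps = {"residual": sig2}
    varcomps.update({names[k]: float(taus[k]) for k in range(len(Zs))})
    return SingleFit(
        params=pd.Series(beta, index=terms),
        se=pd.Series(np.sqrt(np.diag(vcov)), index=terms),
        vcov=vcov,
        varcomps=varcomps,
        phi=phi,
        converged=bool(res.success),
        boundary=boundary,
        theta=logvars,
        reml=float(res.fun),
    )


def fit_single(
    log_mmr_surface: pd.DataFrame,
    covariates: pd.DataFrame,
    exposure_panel: pd.DataFrame,
    spec: Stage2Spec | None = None,
    start_theta: np.ndarray | None = None,
) -> SingleFit:
    """REML fit of the impact model to one log-MMR surface.

    ``log_mmr_surface`` is a wide table (district x year) of log MMR.
    With ``spec.random_terms == ()`` the fit is ordinary least squares.
    Variance components that run into the lower boundary are reported at
    (effectively) zero and flagged in ``boundary``.
    """
    spec = spec or Stage2Spec()
    districts = list(log_mmr_surface.index)
    years = [int(c) for c in log_mmr_surface.columns]
    design = _build_design(covariates, exposure_panel, spec, districts, years)
    y = _surface_to_y(log_mmr_surface, districts, log_mmr_surface.columns)
    return _fit_prepared(y, design, spec, start_theta)


@dataclass
class Stage2Result:
    """Rubin-pooled coefficients and district slopes across MMR draws."""

    coefficients: pd.DataFrame      # term, estimate, se, lower, upper, p, ...
    phi: pd.DataFrame | None        # district_id, estimate, se, lower, upper
    varcomps: dict
    n_draws_used: int
    n_failed: int
    spec: Stage2Spec
    draw_estimates: pd.DataFrame | None = None   # per-draw coefficient archive


def _rubin_pool(est: np.ndarray, se: np.ndarray, level: float = 0.95):
    """Pool a (n_draws, k) matrix of estimates and standard errors."""
    n = est.shape[0]
    qbar = est.mean(axis=0)
    W = (se ** 2).mean(axis=0)
    B = est.var(axis=0, ddof=1) if n > 1 else np.zeros(est.shape[1])
    Tvar = W + (1 + 1 / n) * B
    sd = np.sqrt(Tvar)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    lower = qbar - zcrit * sd
    upper = qbar + zcrit * sd
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, qbar / np.where(sd > 0, sd, 1.0),
                     np.inf * np.sign(qbar))
    p = 2 * stats.norm.sf(np.abs(z))
    return qbar, sd, lower, upper, p


def fit_propagated(
    mmr_draws,
    covariates: pd.DataFrame,
    exposure_panel: pd.DataFrame,
    spec: Stage2Spec | None = None,
    districts: list[str] | None = None,
    years: list[int] | None = None,
) -> Stage2Result:
    """Fit the impact model to each MMR surface and pool across draws.

    ``mmr_draws`` is an ``(n_draws, D, T)`` array on the MMR scale (as
    produced by :func:`jsyimpact.stage1.sample_mmr_draws`) or a list of
    wide DataFrames.  Aborts if more than 5% of the per-draw fits fail.
    """
    spec = spec or Stage2Spec()
    if isinstance(mmr_draws, np.ndarray):
        if districts is None or years is None:
            raise ValueError(
                "districts and years are required with an array of draws"
            )
        ys = np.log(mmr_draws).reshape(mmr_draws.shape[0], -1)
    else:
        districts = list(mmr_draws[0].index)
        years = [int(c) for c in mmr_draws[0].columns]
        ys = np.array([
            np.log(_surface_to_y(s, districts, s.columns)) for s in mmr_draws
        ])
    design = _build_design(covariates, exposure_panel, spec, districts, years)

    ests, ses, phis, phise = [], [], [], []
    varcomps_acc: dict[str, list] = {}
    failures = []
    theta = None
    terms = None
    for i in range(ys.shape[0]):
        try:
            f = _fit_prepared(ys[i], design, spec, start_theta=theta)
        except (np.linalg.LinAlgError, ValueError) as exc:
            failures.append((i, str(exc)))
            continue
        theta = f.theta
        terms = list(f.params.index)
        ests.append(f.params.to_numpy())
        ses.append(f.se.to_numpy())
        if f.phi is not None:
            phis.append(f.phi["estimate"].to_numpy())
            phise.append(f.phi["se"].to_numpy())
        for k, v in f.varcomps.items():
            varcomps_acc.setdefault(k, []).append(v)
    n_ok = len(ests)
    if n_ok == 0 or len(failures) > 0.05 * ys.shape[0]:
        msgs = "; ".join(f"draw {i}: {m}" for i, m in failures[:5])
        raise RuntimeError(
            f"{len(failures)}/{ys.shape[0]} per-draw fits failed: {msgs}"
        )

    est = np.vstack(ests)
    se = np.vstack(ses)
    qbar, sd, lower, upper, p = _rubin_pool(est, se)
    emp_lo = np.percentile(est, 2.5, axis=0)
    emp_hi = np.percentile(est, 97.5, axis=0)
    coef = pd.DataFrame({
        "term": terms, "estimate": qbar, "se": sd,
        "lower": lower, "upper": upper, "p": p,
        "emp_lower": emp_lo, "emp_upper": emp_hi,
    })

    phi_df = None
    if phis:
        pest = np.vstack(phis)
        pse = np.vstack(phise)
        pq, psd, plo, phi_up, pp = _rubin_pool(pest, pse)
        phi_df = pd.DataFrame({
            "district_id": design.districts, "estimate": pq, "se": psd,
            "lower": plo, "upper": phi_up, "p": pp,
            "excludes_zero": (plo > 0) | (phi_up < 0),
        })

    return Stage2Result(
        coefficients=coef,
        phi=phi_df,
        varcomps={k: float(np.mean(v)) for k, v in varcomps_acc.items()},
        n_draws_used=n_ok,
        n_failed=len(failures),
        spec=spec,
        draw_estimates=pd.DataFrame(est, columns=terms),
    )


def district_slope_report(result: Stage2Result) -> tuple[pd.DataFrame, str]:
    """Per-district pooled exposure slopes with a significance summary."""
    if result.phi is None:
        raise ValueError(
            "no district exposure slopes in this fit: include "
            "'district_exposure_slope' in Stage2Spec.random_terms"
        )
    table = result.phi.copy()
    k = int(table["excludes_zero"].sum())
    n = len(table)
    summary = (
        f"{k} of {n} districts have a 95% interval for the exposure slope "
        f"excluding zero"
    )
    return table, summary


def make_coefficient_table(result: Stage2Result) -> pd.DataFrame:
    """Publication-style formatted coefficient table.

    Estimates to 3 decimals, intervals in scientific notation when they
    would round to 0.000, p-values to 3 decimals with values below
    0.0005 printed as "0".
    """
    rows = []
    for _, r in result.coefficients.iterrows():
        rows.append({
            "term": r["term"],
            "estimate": format_estimate(r["estimate"]),
            "95% CI": format_interval(r["lower"], r["upper"]),
            "p": format_p(r["p"]),
        })
    return pd.DataFrame(rows)
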