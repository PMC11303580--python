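"""FOCE-with-interaction hierarchical estimation.

Each subject's empirical Bayes eta mode eta_hat minimizes the conditional
-2 log-likelihood

    g_i(eta) = sum_j [ log(2 pi v_ij) + (y_ij - f_ij)^2 / v_ij ]
               + log det(2 pi Omega) + eta' Omega^-1 eta,

with f_ij the subject's model prediction and v_ij the residual variance
evaluated at the conditional prediction (interaction).  The objective then
expands the prediction to first order about eta_hat, under which the
subject's data are Gaussian with covariance V_i = J_i Omega J_i' +
diag(v_i) and the contribution is

    OFV_i = log det(2 pi V_i) + r_i' V_i^-1 r_i,
    r_i   = y_i - f_i(eta_hat) + J_i eta_hat,

the conventional first-order-conditional-with-interaction objective.
Missing observations contribute nothing; subjects with no usable
observations contribute exactly zero.

Inner (eta) optimization is a damped Newton iteration with the exact
gradient of g (prediction Jacobians by complex-step differentiation) and
exact finite-difference Hessians, run for all subjects in a batch
simultaneously.  Outer optimization runs L-BFGS-B on transformed
parameters (log for positive quantities, logit for inhibition fractions,
Fisher-z for the CL-Vc correlation, identity for covariate exponents),
with a stacked evaluation of all finite-difference gradient perturbations
and a short derivative-free polish.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize

from ecupop.dataset_io import StudyDataset
from ecupop.modelspec import STAGE_DVID, ModelSpec
from ecupop.structural import (
    OmegaBlock, SigmaModel, conc_from_geometry, infusion_geometry, tca_response,
)

__all__ = [
    "EstimationOptions", "FitResult", "FoceProblem",
    "conditional_neg2ll", "ebe_estimate", "foce_objective", "fit",
    "cwres", "ipp_link",
]

_CSTEP = 1e-20                 # complex-step size; derivatives are exact to O(h^2)
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class EstimationOptions:
    """Tolerances and iteration limits for the two-level optimization."""

    inner_tol: float = 1e-4        # max-norm of the eta gradient at the mode
    inner_maxiter: int = 150
    outer_maxiter: int = 300
    outer_maxfun: int = 4000
    outer_ftol: float = 1e-9       # relative OFV change (L-BFGS-B ftol)
    outer_gtol: float = 0.05
    outer_restarts: int = 2        # re-runs from the incumbent optimum
    restart_min_improvement: float = 0.01   # OFV units
    polish_maxfev: int = 300       # derivative-free (Powell) polish budget
    compute_se: bool = True
    se_step: float = 1e-3          # FD step (transformed scale) for the Hessian
    n_multistart: int = 0          # extra perturbed starts of the outer search
    multistart_perturb: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.inner_tol <= 0 or self.outer_ftol <= 0:
            raise ValueError("tolerances must be positive")


# ---------------------------------------------------------------------------
# batches
# ---------------------------------------------------------------------------

@dataclass
class _Batch:
    """Padded per-study arrays for vectorized subject-level evaluation."""

    study: str
    ids: np.ndarray                # (n,)
    times: np.ndarray              # (n, T)
    y: np.ndarray                  # (n, T)
    mask: np.ndarray               # (n, T) bool
    rows: np.ndarray               # (n, T) original df row index, -1 padding
    doses: list                    # [(start, amt, dur)] arrays (n, 1) each
    cov_num: dict                  # column -> (n, 1) float
    cov_cat: dict                  # column -> (n, 1) object
    reg: np.ndarray | None = None  # (n, T) fixed regressor (CIPP / TCAIPP)
    eta: np.ndarray | None = None  # warm-start eta store (n, d)
    geom: tuple | None = None      # cached infusion geometry (PK stage)
    H_newton: np.ndarray | None = None   # cached inner step-Hessians (n, d, d)

    @property
    def n(self) -> int:
        return len(self.ids)


def _tile_geometry(geom, m: int):
    """Stack m copies of a dose geometry along the subject axis."""
    if geom is None:
        return None
    from ecupop.structural import _TrainGeometry
    if isinstance(geom, _TrainGeometry):
        rep = (m,) + (1,) * (geom.m.ndim - 1)
        return _TrainGeometry(geom.trains, np.tile(geom.m, rep),
                              np.tile(geom.t_rel, rep),
                              np.tile(geom.part_mask, rep),
                              np.tile(geom.t_part, rep))
    return tuple(np.tile(g, (m,) + (1,) * (g.ndim - 1)) for g in geom)


def _subject_table(df: pd.DataFrame) -> pd.DataFrame:
    """First-row-per-subject covariate table, in first-appearance order."""
    return df.groupby("ID", sort=False).first().reset_index()


def _build_batches(df: pd.DataFrame, spec: ModelSpec, row_mask: np.ndarray,
                   reg_col: str | None, need_doses: bool) -> list[_Batch]:
    """Group target observation rows by study and pad to rectangular arrays."""
    batches = []
    num_covs = {t.covariate for t in spec.covariate_terms if t.form == "power"}
    num_covs.add("WT")
    cat_covs = {t.covariate for t in spec.covariate_terms if t.form == "categorical"}
    cat_covs.update({"POP", "TRT"})

    for study, sdf in df.groupby("STUDY", sort=False):
        subs = sdf["ID"].unique()
        tdf = sdf[row_mask.reindex(sdf.index, fill_value=False)] \
            if isinstance(row_mask, pd.Series) else sdf.loc[row_mask[sdf.index]]
        per = {sid: tdf[tdf["ID"] == sid] for sid in subs}
        T = max((len(v) for v in per.values()), default=0)
        T = max(T, 1)
        n = len(subs)
        times = np.zeros((n, T))
        y = np.zeros((n, T))
        mask = np.zeros((n, T), dtype=bool)
        rows = np.full((n, T), -1, dtype=int)
        reg = np.ones((n, T)) if reg_col else None
        for i, sid in enumerate(subs):
            r = per[sid]
            k = len(r)
            times[i, :k] = r["TIME"].to_numpy()
            y[i, :k] = r["DV"].to_numpy()
            mask[i, :k] = True
            rows[i, :k] = r.index.to_numpy()
            if reg_col:
                vals = r[reg_col].to_numpy(float) if reg_col in r else np.full(k, np.nan)
                if np.isnan(vals).any():
                    raise ValueError(
                        f"subject {sid} lacks the linked regressor {reg_col!r}; "
                        "run ipp_link with the upstream fit first")
                reg[i, :k] = vals

        doses = []
        if need_doses:
            dmax = int(sdf[sdf["EVID"] == 1].groupby("ID").size().max() or 0)
            start = np.zeros((n, dmax))
            amt = np.zeros((n, dmax))
            dur = np.ones((n, dmax))
            for i, sid in enumerate(subs):
                d = sdf[(sdf["ID"] == sid) & (sdf["EVID"] == 1)]
                k = len(d)
                start[i, :k] = d["TIME"].to_numpy()
                amt[i, :k] = d["AMT"].to_numpy()
                dur[i, :k] = (d["AMT"] / d["RATE"]).to_numpy()
            doses = [(start[:, j:j + 1], amt[:, j:j + 1], dur[:, j:j + 1])
                     for j in range(dmax)]

        st = _subject_table(sdf)
        st = st.set_index("ID").loc[subs].reset_index()
        cov_num = {c: st[c].to_numpy(float).reshape(-1, 1)
                   for c in num_covs if c in st}
        cov_cat = {c: st[c].to_numpy(object).reshape(-1, 1)
                   for c in cat_covs if c in st}
        geom = infusion_geometry(times, doses) if need_doses else None
        batches.append(_Batch(study=str(study), ids=subs, times=times, y=y,
                              mask=mask, rows=rows, doses=doses,
                              cov_num=cov_num, cov_cat=cov_cat, reg=reg,
                              geom=geom))
    return batches


# ---------------------------------------------------------------------------
# parameter resolution and prediction
# ---------------------------------------------------------------------------

def _theta_col(value, n):
    """A theta value as an (n, 1) column; accepts scalars or per-row arrays."""
    v = np.asarray(value, dtype=float)
    if v.ndim == 0:
        return np.full((n, 1), float(v))
    return v.reshape(n, 1)


def _resolve(spec: ModelSpec, theta: dict, batch: _Batch, eta) -> dict:
    """Per-subject structural parameters from thetas, covariates and etas."""
    out = {}
    eta_idx = {name: k for k, name in enumerate(spec.eta_names)}
    for p in spec.params:
        tv = _theta_col(theta[p], batch.n)
        for t in spec.covariate_terms:    # categorical: replace typical value
            if t.param == p and t.form == "categorical":
                ind = batch.cov_cat[t.covariate] == t.level
                tv = np.where(ind, _theta_col(theta[t.name], batch.n), tv)
        val = tv
        for t in spec.covariate_terms:    # power: multiplicative factor
            if t.param == p and t.form == "power":
                x = batch.cov_num[t.covariate]
                val = val * (x / t.ref) ** _theta_col(theta[t.name], batch.n)
        if p in eta_idx:
            val = val * np.exp(eta[:, eta_idx[p]:eta_idx[p] + 1])
        out[p] = val
    return out


def _predict(spec: ModelSpec, batch: _Batch, params: dict):
    if spec.stage == "pk":
        return conc_from_geometry(batch.geom, params["cl"], params["vc"],
                                  params["vp"], params["q"])
    if spec.stage == "pd":
        return tca_response(batch.reg, params["e0"], params["imax"],
                            params["ic50"], params["hill"])
    # ldh stage
    from ecupop.structural import ldh_response
    return ldh_response(batch.reg, params["ll0"], params["lmax"],
                        params["lc50"], params["lgam"])


def _pred_fn(spec: ModelSpec, theta: dict, batch: _Batch) -> Callable:
    def f(eta):
        return _predict(spec, batch, _resolve(spec, theta, batch, eta))
    return f


# ---------------------------------------------------------------------------
# conditional likelihood and the inner Newton iteration
# ---------------------------------------------------------------------------

def _sigma_var(f, sigma: SigmaModel):
    return _res_var(f, sigma.prop, sigma.add)


def _res_var(f, prop, add):
    """Residual variance; ``prop``/``add`` may be scalars or (N, 1) arrays."""
    return (prop * f) ** 2 + np.square(add)


def _prior_quad(om_inv, eta):
    if om_inv.ndim == 2:
        return np.einsum("nk,kl,nl->n", eta, om_inv, eta)
    return np.einsum("nk,nkl,nl->n", eta, om_inv, eta)


def _prior_grad(om_inv, eta):
    if om_inv.ndim == 2:
        return eta @ om_inv
    return np.einsum("nk,nkl->nl", eta, om_inv)


def _cond_g(f, batch: _Batch, prop, add, om_inv, logdet2piom, eta):
    """Per-subject conditional -2 log-likelihood g(eta) (n,)."""
    v = _res_var(np.real(f), prop, add)
    v_safe = np.where(batch.mask, v, 1.0)
    r = np.where(batch.mask, batch.y - np.real(f), 0.0)
    bad = (batch.mask & (v <= 0)).any(axis=1)
    data = np.sum(np.where(batch.mask, np.log(2 * np.pi * v_safe), 0.0)
                  + r * r / v_safe, axis=1)
    g = data + _prior_quad(om_inv, eta) + logdet2piom
    g[bad | ~np.isfinite(g)] = np.inf
    return g


def _jacobian(pred, eta, d):
    """Complex-step Jacobian df/deta, shape (n, T, d)."""
    n = eta.shape[0]
    f0 = None
    J = None
    for k in range(d):
        ec = eta.astype(complex)
        ec[:, k] += 1j * _CSTEP
        fk = pred(ec)
        if J is None:
            J = np.empty(fk.shape + (d,))
            f0 = np.real(fk)
        J[:, :, k] = np.imag(fk) / _CSTEP
    return f0, J


def _grad_g(pred, batch: _Batch, prop, add, om_inv, eta, d):
    """Exact gradient of g(eta), with f and J at eta as by-products."""
    f, J = _jacobian(pred, eta, d)
    v = _res_var(f, prop, add)
    v_safe = np.where(batch.mask, v, 1.0)
    r = np.where(batch.mask, batch.y - f, 0.0)
    w = batch.mask / v_safe
    grad = -2.0 * np.einsum("nt,ntk->nk", r * w, J) \
        + 2.0 * _prior_grad(om_inv, eta)
    if np.any(np.asarray(prop) > 0):
        dv_fac = 2.0 * np.square(prop) * f              # dv/df (interaction)
        grad += np.einsum("nt,ntk->nk",
                          dv_fac * w * (1.0 - r * r / v_safe), J)
    return grad, f, J, w


def _inner_newton(pred, batch: _Batch, prop, add, om_inv, logdet2piom, eta0,
                  tol, maxiter, fd_h: float = 1e-5, H_cache=None):
    """Vectorized modified-Newton iteration to the eta mode of every subject.

    Steps use the exact Hessian of g (forward differences of the exact
    gradient, eigenvalue-clipped saddle-free), optionally warm-started from
    a cached Hessian; the returned Laplace curvature is the FOCE-I form —
    the prediction linearized in eta with the residual-variance
    (interaction) derivative terms retained analytically.
    """
    d = om_inv.shape[-1]
    eta = eta0.copy()
    g = _cond_g(pred(eta), batch, prop, add, om_inv, logdet2piom, eta)
    # invalid warm starts (e.g. after a big outer step) fall back to zero
    if not np.all(np.isfinite(g)):
        bad = ~np.isfinite(g)
        eta[bad] = 0.0
        g = _cond_g(pred(eta), batch, prop, add, om_inv, logdet2piom, eta)

    def exact_h(grad_at, eta_at):
        Hx = np.empty((eta_at.shape[0], d, d))
        for k in range(d):
            ek = eta_at.copy()
            ek[:, k] += fd_h
            gk, *_ = _grad_g(pred, batch, prop, add, om_inv, ek, d)
            Hx[:, :, k] = (gk - grad_at) / fd_h
        return 0.5 * (Hx + np.transpose(Hx, (0, 2, 1)))

    stalls = np.zeros(eta.shape[0], dtype=int)
    H = H_cache if (H_cache is not None
                    and H_cache.shape == (eta.shape[0], d, d)) else None
    eta_h = eta0 if H is not None else None   # where H was (assumed) built
    f = J = w = None
    eta_eval = None
    for it in range(maxiter):
        grad, f, J, w = _grad_g(pred, batch, prop, add, om_inv, eta, d)
        eta_eval = eta
        # a cached Hessian covers the first (warm) steps; rebuild once real
        # iteration work proves necessary
        if H is None or it >= 2:
            H = exact_h(grad, eta)
            eta_h = eta

        finite = np.isfinite(grad).all(axis=1) & np.isfinite(H).all(axis=(1, 2))
        if not finite.all():
            grad = np.where(finite[:, None], grad, 0.0)
            H = np.where(finite[:, None, None], H, np.eye(d))
            stalls = np.where(finite, stalls, 5)

        gnorm = np.max(np.abs(grad), axis=1)
        active = (gnorm > tol) & (stalls < 5)
        if not active.any():
            break
        # saddle-free modification: replace eigenvalues by |lam| clipped
        # away from zero, then take the Newton step
        lam, V = np.linalg.eigh(H)
        lam_abs = np.abs(lam)
        floor = np.maximum(1e-6 * lam_abs.max(axis=1, keepdims=True), 1e-10)
        lam_mod = np.maximum(lam_abs, floor)
        step = -np.einsum("nkl,nl,nml,nm->nk", V, 1.0 / lam_mod, V, 2.0 * grad) / 2.0
        # cap the step: |eta| beyond a few units is physically absurd and
        # risks exp underflow in trial evaluations
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        step = step * np.minimum(1.0, 8.0 / np.maximum(norm, 1e-300))
        descent = np.einsum("nk,nk->n", grad, step)
        # scale-invariant stop: the Newton decrement bounds the remaining
        # improvement in g, so tiny decrements mean the mode is found even
        # when raw gradients are huge (e.g. near-noise-free data)
        decrement_ok = -descent < 1e-10 * (1.0 + np.abs(g))
        active &= ~decrement_ok
        if not active.any():
            break
        alpha = np.where(active, 1.0, 0.0)
        accepted = ~active
        for _ls in range(25):
            trial = eta + alpha[:, None] * step
            g_try = _cond_g(pred(trial), batch, prop, add, om_inv, logdet2piom, trial)
            ok = active & (g_try <= g + 1e-4 * alpha * descent)
            eta = np.where(ok[:, None], trial, eta)
            g = np.where(ok, g_try, g)
            accepted |= ok
            active &= ~ok
            if not active.any():
                break
            alpha = np.where(active, alpha * 0.5, alpha)
        # subjects whose line search found no decrease sit on a (numerically)
        # flat spot; retire them after three consecutive stalls
        stalls = np.where(accepted, 0, stalls + 1)
    if eta is not eta_eval:
        _, f, J, w = _grad_g(pred, batch, prop, add, om_inv, eta, d)
    g = _cond_g(f, batch, prop, add, om_inv, logdet2piom, eta)
    return eta, g, J, f, H


def _ofv_terms(batch: _Batch, eta, J, f, prop, add, om_cov):
    """Per-subject FOCE-I objective contributions.

    The prediction is linearized about the conditional mode eta_hat, so the
    subject's marginal distribution is Gaussian with mean
    ``f(eta_hat) - J eta_hat`` and covariance ``V = J Omega J' + diag(v)``;
    the contribution is ``log det(2 pi V) + r' V^-1 r`` with residual
    ``r = y - f(eta_hat) + J eta_hat`` — the conventional conditional
    (FOCE-with-interaction) approximation.
    """
    mask = batch.mask
    v = _res_var(f, prop, add)
    Jm = np.where(mask[..., None], J, 0.0)
    v_m = np.where(mask, v, 1.0)
    r = np.where(mask, batch.y - f + np.einsum("ntk,nk->nt", Jm, eta), 0.0)
    V = np.einsum("ntk,kl,nsl->nts", Jm, om_cov, Jm) if om_cov.ndim == 2 \
        else np.einsum("ntk,nkl,nsl->nts", Jm, om_cov, Jm)
    T = mask.shape[1]
    V = V + v_m[:, :, None] * np.eye(T)
    bad = ~np.isfinite(V).all(axis=(1, 2)) | (mask & (v <= 0)).any(axis=1)
    V = np.where(bad[:, None, None], np.eye(T), V)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        eigs = np.linalg.eigvalsh(V)
        bad = bad | (eigs[:, 0] <= 0)
        V = np.where(bad[:, None, None], np.eye(T), V)
        L = np.linalg.cholesky(V)
    logdet_V = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    z = np.linalg.solve(L, r[:, :, None])[:, :, 0]
    quad = np.sum(z * z, axis=1)
    n_obs = mask.sum(axis=1)
    out = logdet_V + quad + n_obs * _LOG2PI
    out = np.where(bad | ~np.isfinite(out), np.inf, out)
    # padded slots contribute log(1) + 0 to the determinant and quadratic
    return out


# ---------------------------------------------------------------------------
# outer parameter packing
# ---------------------------------------------------------------------------

def _pack(spec: ModelSpec, theta_vec, omega: OmegaBlock, sigma: SigmaModel):
    x = []
    for name, val in zip(spec.theta_names, theta_vec):
        kind = spec.theta_transform(name)
        if kind == "log":
            x.append(np.log(val))
        elif kind == "logit":
            x.append(np.log(val / (1.0 - val)))
        else:
            x.append(val)
    sd = omega.sd
    x.extend(np.log(sd))
    for (a, b) in spec.omega_corr_init:
        x.append(np.arctanh(omega.correlation(a, b)))
    if sigma.kind in ("proportional", "combined"):
        x.append(np.log(sigma.prop))
    if sigma.kind in ("additive", "combined"):
        x.append(np.log(sigma.add))
    return np.asarray(x, dtype=float)


def _unpack(spec: ModelSpec, x: np.ndarray):
    nt = len(spec.theta_names)
    theta = {}
    for name, xi in zip(spec.theta_names, x[:nt]):
        kind = spec.theta_transform(name)
        if kind == "log":
            theta[name] = float(np.exp(xi))
        elif kind == "logit":
            theta[name] = float(1.0 / (1.0 + np.exp(-xi)))
        else:
            theta[name] = float(xi)
    pos = nt
    d = len(spec.eta_names)
    sd = np.exp(x[pos:pos + d])
    pos += d
    corr = {}
    for pair in spec.omega_corr_init:
        corr[pair] = float(np.tanh(x[pos]))
        pos += 1
    omega = OmegaBlock.from_sd_corr(spec.eta_names, sd, corr)
    kind = spec.sigma.kind
    prop = add = 0.0
    if kind in ("proportional", "combined"):
        prop = float(np.exp(x[pos])); pos += 1
    if kind in ("additive", "combined"):
        add = float(np.exp(x[pos])); pos += 1
    return theta, omega, SigmaModel(kind, prop=prop, add=add)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, uncertainty, EBEs and diagnostics from one FOCE fit."""

    spec: ModelSpec
    theta: dict
    omega: OmegaBlock
    sigma: SigmaModel
    ofv: float
    converged: bool
    message: str
    n_iter: int
    trace: list
    ebes: pd.DataFrame                     # ID + one column per eta
    obs_table: pd.DataFrame                # DV, PRED, IPRED, CWRES per obs
    theta_rse: dict = field(default_factory=dict)
    omega_rse: dict = field(default_factory=dict)
    sigma_rse: dict = field(default_factory=dict)
    shrinkage: dict = field(default_factory=dict)

    @property
    def iiv_percent(self) -> dict:
        return dict(zip(self.omega.names, self.omega.iiv_percent))

    def to_inits(self) -> dict:
        """Estimates in the layout accepted by ``ModelSpec.with_inits``."""
        return {
            "theta": dict(self.theta),
            "omega_sd": dict(zip(self.omega.names, self.omega.sd)),
            "omega_corr": {p: self.omega.correlation(*p)
                           for p in self.spec.omega_corr_init},
            "sigma": self.sigma,
        }

    def parameter_table(self) -> pd.DataFrame:
        """Estimate / RSE% / shrinkage% table mirroring a report layout."""
        rows = []
        for name, val in self.theta.items():
            rows.append({"parameter": name, "kind": "fixed effect",
                         "estimate": val,
                         "rse_pct": self.theta_rse.get(name, np.nan),
                         "shrinkage_pct": np.nan})
        for name, pct in self.iiv_percent.items():
            rows.append({"parameter": f"omega_{name}", "kind": "IIV (%)",
                         "estimate": pct,
                         "rse_pct": self.omega_rse.get(name, np.nan),
                         "shrinkage_pct": self.shrinkage.get(name, np.nan)})
        for pair in self.spec.omega_corr_init:
            rows.append({"parameter": f"corr_{pair[0]}_{pair[1]}",
                         "kind": "IIV correlation",
                         "estimate": self.omega.correlation(*pair),
                         "rse_pct": self.omega_rse.get(f"corr_{pair[0]}_{pair[1]}", np.nan),
                         "shrinkage_pct": np.nan})
        if self.sigma.kind in ("proportional", "combined"):
            rows.append({"parameter": "sigma_prop", "kind": "residual (%)",
                         "estimate": 100.0 * self.sigma.prop,
                         "rse_pct": self.sigma_rse.get("prop", np.nan),
                         "shrinkage_pct": np.nan})
        if self.sigma.kind in ("additive", "combined"):
            rows.append({"parameter": "sigma_add", "kind": "residual (DV units)",
                         "estimate": self.sigma.add,
                         "rse_pct": self.sigma_rse.get("add", np.nan),
                         "shrinkage_pct": np.nan})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the estimation problem
# ---------------------------------------------------------------------------

class FoceProblem:
    """One estimation stage bound to a dataset."""

    def __init__(self, dataset: StudyDataset, spec: ModelSpec,
                 options: EstimationOptions | None = None):
        self.dataset = dataset
        self.spec = spec
        self.options = options or EstimationOptions()
        df = dataset.df
        dvid = STAGE_DVID[spec.stage]
        row_mask = pd.Series(
            (df["EVID"] == 0) & (df["DVID"] == dvid) & (df["MDV"] == 0)
            & (df["SCREEN"] == 0), index=df.index)
        reg_col = {"pk": None, "pd": "CIPP", "ldh": "TCAIPP"}[spec.stage]
        self.batches = _build_batches(df, spec, row_mask, reg_col,
                                      need_doses=(spec.stage == "pk"))
        d = len(spec.eta_names)
        for b in self.batches:
            b.eta = np.zeros((b.n, d))
        self.n_obs = int(sum(b.mask.sum() for b in self.batches))
        self.n_subjects = int(sum(b.n for b in self.batches))
        self._best_f, self._best_x = np.inf, None
        self._tile_cache: dict = {}

    # -- likelihood pieces --------------------------------------------------
    def _om_terms(self, omega: OmegaBlock):
        om_inv = np.linalg.inv(omega.cov)
        _, logdet = np.linalg.slogdet(omega.cov)
        d = omega.cov.shape[0]
        return om_inv, logdet + d * _LOG2PI

    def conditional_neg2ll(self, eta_by_subject: dict, theta=None, omega=None,
                           sigma=None) -> pd.Series:
        """g_i(eta) per subject at externally supplied etas."""
        theta, omega, sigma = self._params(theta, omega, sigma)
        om_inv, logdet2piom = self._om_terms(omega)
        out = {}
        for b in self.batches:
            eta = np.vstack([np.asarray(eta_by_subject[s], dtype=float)
                             for s in b.ids])
            f = _pred_fn(self.spec, theta, b)(eta)
            g = _cond_g(f, b, sigma.prop, sigma.add, om_inv, logdet2piom, eta)
            out.update(dict(zip(b.ids, g)))
        return pd.Series(out, name="conditional_neg2ll")

    def _params(self, theta, omega, sigma):
        base_theta = dict(zip(self.spec.theta_names, self.spec.theta_init_vector()))
        if theta:
            base_theta.update(theta)
        return (base_theta,
                omega if omega is not None else self.spec.omega_init(),
                sigma if sigma is not None else self.spec.sigma)

    def _solve_inner(self, theta, omega, sigma, tol=None):
        om_inv, logdet2piom = self._om_terms(omega)
        tol = tol or self.options.inner_tol
        results = []
        for b in self.batches:
            pred = _pred_fn(self.spec, theta, b)
            eta, g, J, f, H = _inner_newton(
                pred, b, sigma.prop, sigma.add, om_inv, logdet2piom, b.eta, tol,
                self.options.inner_maxiter, H_cache=b.H_newton)
            b.eta = eta
            b.H_newton = H
            results.append((b, eta, g, J, f))
        return results

    def ofv(self, theta=None, omega=None, sigma=None) -> float:
        theta, omega, sigma = self._params(theta, omega, sigma)
        total = 0.0
        for b, eta, g, J, f in self._solve_inner(theta, omega, sigma):
            total += float(np.sum(_ofv_terms(b, eta, J, f, sigma.prop,
                                             sigma.add, omega.cov)))
        return total

    def ebe(self, theta=None, omega=None, sigma=None) -> pd.DataFrame:
        theta, omega, sigma = self._params(theta, omega, sigma)
        rows = []
        for b, eta, *_ in self._solve_inner(theta, omega, sigma):
            for i, sid in enumerate(b.ids):
                rows.append({"ID": sid, **{f"eta_{n}": eta[i, k]
                                           for k, n in enumerate(self.spec.eta_names)}})
        return pd.DataFrame(rows)

    # -- outer optimization -------------------------------------------------
    def _objective(self, x):
        try:
            theta, omega, sigma = _unpack(self.spec, x)
            with np.errstate(over="ignore", invalid="ignore", divide="ignore",
                             under="ignore"):
                val = self.ofv(theta, omega, sigma)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        val = val if np.isfinite(val) else 1e12
        if val < self._best_f:
            self._best_f, self._best_x = val, np.asarray(x, dtype=float).copy()
        return val

    def _objective_and_grad(self, x, fd_step: float = 1e-5):
        """Objective with a central-difference gradient.

        The explicit step keeps the finite difference well above the tiny
        path dependence introduced by warm-started inner modes; central
        differences avoid the curvature bias that would stall convergence
        in stiff directions.
        """
        f0 = self._objective(x)
        g = np.zeros_like(x)
        if f0 >= 1e12:
            return f0, g
        for i in range(x.size):
            e = np.zeros_like(x)
            e[i] = fd_step
            g[i] = (self._objective(x + e) - self._objective(x - e)) \
                / (2 * fd_step)
        return f0, g

    # -- stacked multi-parameter evaluation ---------------------------------
    def _tiled(self, m: int) -> list:
        """Tiled copies of every batch for evaluating m parameter sets at
        once; the subject axis holds m stacked replicas of the data."""
        if m not in self._tile_cache:
            d = len(self.spec.eta_names)
            tiled = []
            for b in self.batches:
                geom = _tile_geometry(b.geom, m)
                nb = _Batch(
                    study=b.study, ids=np.tile(b.ids, m),
                    times=np.tile(b.times, (m, 1)), y=np.tile(b.y, (m, 1)),
                    mask=np.tile(b.mask, (m, 1)), rows=np.tile(b.rows, (m, 1)),
                    doses=[],
                    cov_num={k: np.tile(v, (m, 1)) for k, v in b.cov_num.items()},
                    cov_cat={k: np.tile(v, (m, 1)) for k, v in b.cov_cat.items()},
                    reg=None if b.reg is None else np.tile(b.reg, (m, 1)),
                    geom=geom)
                nb.eta = np.zeros((m * b.n, d))
                tiled.append(nb)
            self._tile_cache[m] = tiled
        return self._tile_cache[m]

    def _ofv_stack(self, X: np.ndarray) -> np.ndarray:
        """OFV at each row of ``X`` (transformed parameter vectors) using one
        stacked inner solve per batch."""
        m = X.shape[0]
        spec = self.spec
        d = len(spec.eta_names)
        params = []
        bad = np.zeros(m, dtype=bool)
        for j in range(m):
            try:
                th, om, sg = _unpack(spec, X[j])
                params.append((th, om, sg, np.linalg.inv(om.cov)))
            except (ValueError, FloatingPointError, np.linalg.LinAlgError):
                params.append(None)
                bad[j] = True
        ref = next((p for p in params if p is not None), None)
        if ref is None:
            return np.full(m, 1e12)
        params = [p if p is not None else ref for p in params]

        theta_m = {name: np.array([p[0][name] for p in params])
                   for name in spec.theta_names}
        om_inv_m = np.stack([p[3] for p in params])
        om_cov_m = np.stack([p[1].cov for p in params])
        logdet_m = np.array([np.linalg.slogdet(p[1].cov)[1] for p in params]) \
            + d * _LOG2PI
        prop_m = np.array([p[2].prop for p in params])
        add_m = np.array([p[2].add for p in params])

        total = np.zeros(m)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore",
                         under="ignore"):
            for b, tb in zip(self.batches, self._tiled(m)):
                n = b.n
                rep = np.repeat(np.arange(m), n)
                theta_rows = {k: v[rep] for k, v in theta_m.items()}
                om_inv = om_inv_m[rep]
                logdet = logdet_m[rep]
                prop = prop_m[rep].reshape(-1, 1)
                add = add_m[rep].reshape(-1, 1)
                pred = _pred_fn(spec, theta_rows, tb)
                eta, g, J, f, H = _inner_newton(
                    pred, tb, prop, add, om_inv, logdet, tb.eta,
                    self.options.inner_tol, self.options.inner_maxiter,
                    H_cache=tb.H_newton)
                tb.eta = eta
                tb.H_newton = H
                terms = _ofv_terms(tb, eta, J, f, prop, add,
                                   om_cov_m[rep]).reshape(m, n)
                total += terms.sum(axis=1)
        total = np.where(np.isfinite(total), total, 1e12)
        total[bad] = 1e12
        for j in range(m):
            if total[j] < self._best_f:
                self._best_f, self._best_x = total[j], X[j].copy()
        return total

    def _objective_and_grad_stacked(self, x, fd_step: float = 1e-5):
        """Objective and central-difference gradient via one stacked pass.

        The unperturbed point is solved on the per-point warm state first;
        its converged modes then seed every stacked copy, so the perturbed
        solves need only a Newton step or two each.
        """
        p = x.size
        f0 = self._objective(x)
        if f0 >= 1e12:
            return f0, np.zeros_like(x)
        m = 2 * p
        for b, tb in zip(self.batches, self._tiled(m)):
            tb.eta = np.tile(b.eta, (m, 1))
            tb.H_newton = None if b.H_newton is None \
                else np.tile(b.H_newton, (m, 1, 1))
        X = np.tile(x, (m, 1))
        for i in range(p):
            X[i, i] += fd_step
            X[p + i, i] -= fd_step
        vals = self._ofv_stack(X)
        g = (vals[:p] - vals[p:]) / (2 * fd_step)
        g[~np.isfinite(g)] = 0.0
        return f0, g

    def fit(self) -> FitResult:
        opts = self.options
        x0 = _pack(self.spec, self.spec.theta_init_vector(),
                   self.spec.omega_init(), self.spec.sigma)
        starts = [x0]
        if opts.n_multistart:
            rng = np.random.default_rng(opts.seed)
            for _ in range(opts.n_multistart):
                starts.append(x0 + opts.multistart_perturb
                              * rng.standard_normal(x0.size))
        best = None
        for x_start in starts:
            trace = []
            for b in self.batches:
                b.eta = np.zeros_like(b.eta)
            self._best_f, self._best_x = np.inf, None

            def cb(xk):
                trace.append(float(self._ofv_stack(xk[None])[0]))

            res = None
            x_cur = x_start
            for _restart in range(1 + opts.outer_restarts):
                prev = res
                res = optimize.minimize(
                    self._objective_and_grad_stacked, x_cur, jac=True,
                    method="L-BFGS-B", callback=cb,
                    options={"maxiter": opts.outer_maxiter,
                             "maxfun": opts.outer_maxfun,
                             "ftol": opts.outer_ftol, "gtol": opts.outer_gtol})
                # the optimizer may abort a line search past the best
                # evaluated point; fall back to the best point seen so far
                if self._best_x is not None and self._best_f < res.fun:
                    res.x, res.fun = self._best_x.copy(), self._best_f
                if prev is not None:
                    res.nit += prev.nit
                    if prev.fun - res.fun < opts.restart_min_improvement:
                        break
                x_cur = res.x
            if opts.polish_maxfev:
                # gradient-based searches stall in the flat curved valleys of
                # these likelihoods; a short Powell pass digs the last bit
                pol = optimize.minimize(
                    self._objective, res.x, method="Powell",
                    options={"maxfev": opts.polish_maxfev,
                             "xtol": 1e-6, "ftol": 1e-9})
                if pol.fun < res.fun:
                    res.x, res.fun = pol.x, pol.fun
            if self._best_x is not None and self._best_f < res.fun:
                res.x, res.fun = self._best_x.copy(), self._best_f
            if best is None or res.fun < best[0].fun:
                best = (res, trace)
        res, trace = best
        theta, omega, sigma = _unpack(self.spec, res.x)
        result = self._finalize(theta, omega, sigma, converged=bool(res.success),
                                message=str(res.message), n_iter=int(res.nit),
                                trace=trace)
        if opts.compute_se:
            self._standard_errors(result, res.x)
        return result

    def evaluate(self, theta=None, omega=None, sigma=None) -> FitResult:
        """EBEs, OFV and diagnostics at fixed population parameters."""
        theta, omega, sigma = self._params(theta, omega, sigma)
        return self._finalize(theta, omega, sigma, converged=True,
                              message="evaluated at fixed parameters",
                              n_iter=0, trace=[])

    def _finalize(self, theta, omega, sigma, converged, message, n_iter, trace):
        opts = self.options
        for b in self.batches:       # drop warm starts from rejected proposals
            b.eta = np.zeros_like(b.eta)
            b.H_newton = None
        with np.errstate(over="ignore", invalid="ignore", divide="ignore",
                         under="ignore"):
            inner = self._solve_inner(theta, omega, sigma,
                                      tol=opts.inner_tol * 0.1)
        ofv = float(sum(np.sum(_ofv_terms(b, eta, J, f, sigma.prop,
                                          sigma.add, omega.cov))
                        for b, eta, g, J, f in inner))

        ebe_rows, obs_rows = [], []
        for b, eta, g, J, f in inner:
            theta_pred = _pred_fn(self.spec, theta, b)
            f_pop = np.real(theta_pred(np.zeros_like(eta)))
            cw = _cwres_batch(b, eta, J, f, omega, sigma)
            for i, sid in enumerate(b.ids):
                ebe_rows.append({"ID": sid,
                                 **{f"eta_{n}": eta[i, k]
                                    for k, n in enumerate(self.spec.eta_names)}})
                sel = b.mask[i]
                for j in np.where(sel)[0]:
                    obs_rows.append({
                        "row": int(b.rows[i, j]), "ID": sid,
                        "TIME": b.times[i, j], "STUDY": b.study,
                        "DV": b.y[i, j], "PRED": f_pop[i, j],
                        "IPRED": f[i, j], "CWRES": cw[i][j]})
        ebes = pd.DataFrame(ebe_rows)
        obs_table = pd.DataFrame(obs_rows).sort_values("row").reset_index(drop=True)

        shrink = {}
        for k, name in enumerate(self.spec.eta_names):
            sd_ebe = float(np.std(ebes[f"eta_{name}"], ddof=1)) if len(ebes) > 1 else 0.0
            shrink[name] = 100.0 * (1.0 - sd_ebe / omega.sd[k]) \
                if omega.sd[k] > 0 else np.nan

        return FitResult(
            spec=self.spec, theta=theta, omega=omega, sigma=sigma, ofv=ofv,
            converged=converged, message=message, n_iter=n_iter, trace=trace,
            ebes=ebes, obs_table=obs_table, shrinkage=shrink)

    def _standard_errors(self, result: FitResult, x_opt: np.ndarray) -> None:
        """RSE% from the finite-difference Hessian of OFV/2 (delta method)."""
        p = x_opt.size
        h = self.options.se_step
        # all evaluation points in one stacked pass
        points = [x_opt]
        for i in range(p):
            for sgn in (h, -h):
                e = np.zeros(p); e[i] = sgn
                points.append(x_opt + e)
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        for i, j in pairs:
            for sgn in (h, -h):
                e = np.zeros(p); e[i] = sgn; e[j] = sgn
                points.append(x_opt + e)
        X = np.asarray(points)
        vals = np.concatenate([self._ofv_stack(X[k:k + 32])
                               for k in range(0, len(X), 32)])
        f0 = vals[0]
        fp = vals[1:1 + 2 * p:2]
        fm = vals[2:2 + 2 * p:2]
        H = np.empty((p, p))
        for i in range(p):
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h ** 2
        base = 1 + 2 * p
        for k, (i, j) in enumerate(pairs):
            fpp = vals[base + 2 * k]
            fmm = vals[base + 2 * k + 1]
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0
                                 - fm[i] - fm[j] + fmm) / (2 * h ** 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cov = np.linalg.pinv(H / 2.0)   # covariance on transformed scale
            except np.linalg.LinAlgError:
                return
        se_t = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

        spec = self.spec
        nt = len(spec.theta_names)
        for i, name in enumerate(spec.theta_names):
            kind = spec.theta_transform(name)
            val = result.theta[name]
            if kind == "log":
                se = se_t[i] * abs(val)
            elif kind == "logit":
                se = se_t[i] * val * (1.0 - val)
            else:
                se = se_t[i]
            result.theta_rse[name] = 100.0 * se / abs(val) if val else np.nan
        pos = nt
        for k, name in enumerate(spec.eta_names):
            result.omega_rse[name] = 100.0 * se_t[pos + k]   # log-sd scale
        pos += len(spec.eta_names)
        for pair in spec.omega_corr_init:
            rho = result.omega.correlation(*pair)
            se = se_t[pos] * (1.0 - rho ** 2)
            result.omega_rse[f"corr_{pair[0]}_{pair[1]}"] = \
                100.0 * se / abs(rho) if rho else np.nan
            pos += 1
        if spec.sigma.kind in ("proportional", "combined"):
            result.sigma_rse["prop"] = 100.0 * se_t[pos]
            pos += 1
        if spec.sigma.kind in ("additive", "combined"):
            result.sigma_rse["add"] = 100.0 * se_t[pos]


def _cwres_batch(batch: _Batch, eta, J, f, omega: OmegaBlock, sigma):
    """Conditional weighted residuals via the FOCE linearization."""
    n, T = batch.y.shape
    v = _sigma_var(f, sigma)
    out = []
    for i in range(n):
        sel = batch.mask[i]
        cw = np.full(T, np.nan)
        if sel.any():
            Ji = J[i][sel]
            mean = f[i, sel] - Ji @ eta[i]
            cov = Ji @ omega.cov @ Ji.T + np.diag(v[i, sel])
            try:
                L = np.linalg.cholesky(cov)
                cw[sel] = np.linalg.solve(L, batch.y[i, sel] - mean)
            except np.linalg.LinAlgError:
                cw[sel] = np.nan
        out.append(cw)
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def conditional_neg2ll(dataset: StudyDataset, spec: ModelSpec,
                       eta_by_subject: dict, theta=None, omega=None,
                       sigma=None, options=None) -> pd.Series:
    """Per-subject conditional -2 log-likelihood at fixed etas.

    Includes the eta prior term; missing-flagged observations contribute
    nothing.
    """
    return FoceProblem(dataset, spec, options).conditional_neg2ll(
        eta_by_subject, theta, omega, sigma)


def ebe_estimate(dataset: StudyDataset, spec: ModelSpec, theta=None,
                 omega=None, sigma=None, options=None) -> pd.DataFrame:
    """Empirical Bayes eta modes for every subject."""
    return FoceProblem(dataset, spec, options).ebe(theta, omega, sigma)


def foce_objective(dataset: StudyDataset, spec: ModelSpec, theta=None,
                   omega=None, sigma=None, options=None) -> float:
    """FOCE-I objective function value at the given population parameters."""
    return FoceProblem(dataset, spec, options).ofv(theta, omega, sigma)


def fit(dataset: StudyDataset, spec: ModelSpec,
        options: EstimationOptions | None = None) -> FitResult:
    """Estimate a stage model by FOCE-I and return the full fit result."""
    return FoceProblem(dataset, spec, options).fit()


def cwres(fit_result: FitResult, dataset: StudyDataset | None = None) -> pd.Series:
    """Conditional weighted residuals of a converged fit, by dataset row."""
    t = fit_result.obs_table
    return pd.Series(t["CWRES"].to_numpy(), index=t["row"].to_numpy(), name="CWRES")


def ipp_link(fit_result: FitResult, dataset: StudyDataset) -> StudyDataset:
    """Attach individual population predictions (IPP) as fixed regressors.

    A PK fit adds ``CIPP`` — the subject's model-predicted concentration at
    every observation row — for downstream PD estimation; a PD fit adds
    ``TCAIPP`` — the predicted terminal complement activity at LDH rows
    (requires ``CIPP`` there, i.e. a prior PK link).  Upstream parameters
    are not re-estimated downstream.
    """
    spec = fit_result.spec
    if spec.stage == "ldh":
        raise ValueError("the efficacy stage has no downstream model to link")
    df = dataset.df.copy()
    obs_mask = pd.Series((df["EVID"] == 0) & (df["SCREEN"] == 0), index=df.index)
    target_ids = set(df.loc[obs_mask, "ID"].unique())
    have = set(fit_result.ebes["ID"])
    missing = target_ids - have
    if missing:
        raise ValueError(f"subjects missing upstream EBEs: {sorted(missing)[:5]}")

    eta_cols = [f"eta_{n}" for n in spec.eta_names]
    eta_map = fit_result.ebes.set_index("ID")[eta_cols]

    reg_col = "CIPP" if spec.stage == "pk" else None
    if spec.stage == "pd":
        if "CIPP" not in df.columns:
            raise ValueError("PD link requires a CIPP column (run the PK link first)")
        reg_col = "CIPP"
    batches = _build_batches(df, spec, obs_mask,
                             reg_col if spec.stage == "pd" else None,
                             need_doses=(spec.stage == "pk"))
    out_col = "CIPP" if spec.stage == "pk" else "TCAIPP"
    if out_col not in df.columns:
        df[out_col] = np.nan
    for b in batches:
        eta = eta_map.loc[b.ids].to_numpy(float)
        f = np.real(_pred_fn(spec, fit_result.theta, b)(eta))
        sel = b.mask & (b.rows >= 0)
        df.loc[b.rows[sel], out_col] = f[sel]
    out = StudyDataset(df, dataset.lloq_pk, dict(dataset.metadata))
    return out
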