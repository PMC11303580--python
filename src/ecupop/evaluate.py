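"""Model qualification: prediction-corrected VPC, bootstrap, GOF tables.

The pcVPC simulates ``n_sim`` replicates of the observed design from the
fitted model (same subjects, covariates, dosing histories and sampling
times), rescales every observed and simulated value by the ratio of its
time-bin's median population prediction to the subject's own population
prediction, and compares observed percentile curves with simulation-based
95% confidence bands.  PK values below the LLOQ are discarded from both
observed and simulated sides (M1-consistent comparison).

The bootstrap resamples subjects with replacement — stratified by study so
the healthy/patient mix of the pooled dataset is preserved — refits the
model per replicate (initialized at the original estimates, standard
practice to cut runtime) and reports percentile confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ecupop.dataset_io import StudyDataset
from ecupop.foce import (
    EstimationOptions, FitResult, FoceProblem, _pred_fn, _sigma_var,
)
from ecupop.modelspec import ModelSpec

__all__ = ["VPCResult", "BootstrapResult", "pc_vpc", "bootstrap", "gof_table"]


@dataclass
class VPCResult:
    """Binned pcVPC summaries: observed percentiles and simulated bands."""

    table: pd.DataFrame            # one row per (study, bin)
    n_sim: int
    endpoint: str

    def coverage(self, percentile: str = "p50") -> float:
        """Fraction of bins whose observed percentile falls in its 95% band."""
        t = self.table.dropna(subset=[f"obs_{percentile}",
                                      f"sim_{percentile}_lo",
                                      f"sim_{percentile}_hi"])
        if not len(t):
            return np.nan
        inside = ((t[f"obs_{percentile}"] >= t[f"sim_{percentile}_lo"])
                  & (t[f"obs_{percentile}"] <= t[f"sim_{percentile}_hi"]))
        return float(inside.mean())


def pc_vpc(dataset: StudyDataset, fit_result: FitResult, n_sim: int = 1000,
           bins: np.ndarray | None = None, seed=None,
           min_bin_obs: int = 3) -> VPCResult:
    """Prediction-corrected visual predictive check of one fitted stage.

    ``bins``: optional bin edges over time; by default each nominal
    sampling time (trough samples merge with their nominal visit time) is
    its own bin — in simulated trials actual and nominal times coincide.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    spec = fit_result.spec
    problem = FoceProblem(dataset, spec, EstimationOptions(compute_se=False))
    theta, omega, sigma = fit_result.theta, fit_result.omega, fit_result.sigma
    lloq = dataset.lloq_pk if spec.stage == "pk" else None

    records = []
    for b in problem.batches:
        if not b.mask.any():
            continue
        pred = _pred_fn(spec, theta, b)
        d = omega.cov.shape[0]
        f_pop = np.real(pred(np.zeros((b.n, d))))

        tvals = np.round(b.times, 3)
        if bins is None:
            bin_of = tvals
        else:
            edges = np.asarray(bins, dtype=float)
            bin_of = edges[np.clip(np.digitize(tvals, edges) - 1, 0, len(edges) - 1)]

        sel = b.mask & (f_pop > 0)
        dropped = b.mask & ~(f_pop > 0)
        if dropped.any():
            warnings.warn(f"{int(dropped.sum())} observations with zero "
                          "population prediction excluded from the pcVPC")
        obs_bin = bin_of[sel]
        pred_obs = f_pop[sel]
        y_obs = b.y[sel]

        uniq = np.unique(obs_bin)
        med_pred = {u: np.median(pred_obs[obs_bin == u]) for u in uniq}
        corr_fac = np.array([med_pred[u] for u in obs_bin]) / pred_obs
        y_pc = y_obs * corr_fac

        # simulate replicates of the same design
        L = np.linalg.cholesky(omega.cov + 1e-12 * np.eye(d))
        sim_perc = {u: {q: [] for q in (5, 50, 95)} for u in uniq}
        for _ in range(n_sim):
            eta = rng.standard_normal((b.n, d)) @ L.T
            f = np.real(pred(eta))
            eps = rng.standard_normal(f.shape)
            dv = f + np.sqrt(_sigma_var(f, sigma)) * np.sign(eps) * np.abs(eps)
            dv_sel = dv[sel]
            keep = np.ones(dv_sel.size, dtype=bool)
            if lloq is not None:
                keep = dv_sel >= lloq
            dv_pc = dv_sel * corr_fac
            for u in uniq:
                m = (obs_bin == u) & keep
                if m.sum() >= 2:
                    q5, q50, q95 = np.percentile(dv_pc[m], [5, 50, 95])
                else:
                    q5 = q50 = q95 = np.nan
                sim_perc[u][5].append(q5)
                sim_perc[u][50].append(q50)
                sim_perc[u][95].append(q95)

        for u in uniq:
            m = obs_bin == u
            row = {"study": b.study, "bin": float(u), "n_obs": int(m.sum())}
            if m.sum() >= min_bin_obs:
                row["obs_p5"], row["obs_p50"], row["obs_p95"] = \
                    np.percentile(y_pc[m], [5, 50, 95])
            else:
                row["obs_p5"] = row["obs_p50"] = row["obs_p95"] = np.nan
            for q in (5, 50, 95):
                arr = np.asarray(sim_perc[u][q], dtype=float)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lo, hi = np.nanpercentile(arr, [2.5, 97.5]) \
                        if np.isfinite(arr).any() else (np.nan, np.nan)
                row[f"sim_p{q}_lo"], row[f"sim_p{q}_hi"] = lo, hi
            records.append(row)

    table = pd.DataFrame(records).sort_values(["study", "bin"]).reset_index(drop=True)
    # percentile ordering is guaranteed within rows where all are defined
    return VPCResult(table=table, n_sim=n_sim, endpoint=spec.stage)


@dataclass
class BootstrapResult:
    """Replicate estimates and percentile confidence intervals."""

    replicates: pd.DataFrame       # one row per converged replicate
    summary: pd.DataFrame          # median + 2.5/97.5 percentiles
    n_requested: int
    n_failed: int


def bootstrap(dataset: StudyDataset, model_spec: ModelSpec, n_rep: int = 1000,
              seed=None, stratify: str | None = "STUDY",
              options: EstimationOptions | None = None,
              base_fit: FitResult | None = None) -> BootstrapResult:
    """Nonparametric subject-level bootstrap of one estimation stage.

    Subjects are resampled with replacement within strata (by default the
    study, preserving the healthy/patient counts).  Each replicate refits
    the model starting from the original estimates; replicates whose outer
    search fails to converge are excluded and counted.
    """
    rng = np.random.default_rng(seed)
    opts = options or EstimationOptions()
    fit_opts = EstimationOptions(
        inner_tol=opts.inner_tol, inner_maxiter=opts.inner_maxiter,
        outer_maxiter=opts.outer_maxiter, outer_maxfun=opts.outer_maxfun,
        outer_ftol=opts.outer_ftol, outer_gtol=opts.outer_gtol,
        outer_restarts=opts.outer_restarts,
        polish_maxfev=opts.polish_maxfev, compute_se=False)
    if base_fit is None:
        base_fit = FoceProblem(dataset, model_spec, fit_opts).fit()
    inits = base_fit.to_inits()
    warm = model_spec.with_inits(theta=inits["theta"],
                                 omega_sd=inits["omega_sd"],
                                 omega_corr=inits["omega_corr"],
                                 sigma=inits["sigma"])

    df = dataset.df
    strata_of = df.groupby("ID", sort=False)[stratify].first() if stratify \
        else pd.Series("all", index=df["ID"].unique())
    groups = {sid: g for sid, g in df.groupby("ID", sort=False)}
    strata = {}
    for sid, s in strata_of.items():
        strata.setdefault(s, []).append(sid)

    rows = []
    n_failed = 0
    for rep in range(n_rep):
        pieces = []
        new_id = 0
        for s, ids in strata.items():
            draw = rng.choice(ids, size=len(ids), replace=True)
            for sid in draw:
                new_id += 1
                block = groups[sid].copy()
                block["ID"] = new_id
                pieces.append(block)
        rep_df = pd.concat(pieces, ignore_index=True)
        try:
            rep_ds = StudyDataset(rep_df, dataset.lloq_pk)
            res = FoceProblem(rep_ds, warm, fit_opts).fit()
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not np.isfinite(res.ofv):
            n_failed += 1
            continue
        row = {"replicate": rep, **res.theta}
        for name, pct in res.iiv_percent.items():
            row[f"omega_{name}_pct"] = pct
        for pair in model_spec.omega_corr_init:
            row[f"corr_{pair[0]}_{pair[1]}"] = res.omega.correlation(*pair)
        row["sigma_prop_pct"] = 100.0 * res.sigma.prop
        rows.append(row)

    replicates = pd.DataFrame(rows)
    summ_rows = []
    for col in replicates.columns:
        if col == "replicate":
            continue
        v = replicates[col].to_numpy(float)
        summ_rows.append({"parameter": col, "median": float(np.median(v)),
                          "ci_lo": float(np.percentile(v, 2.5)),
                          "ci_hi": float(np.percentile(v, 97.5))})
    summary = pd.DataFrame(summ_rows)
    return BootstrapResult(replicates=replicates, summary=summary,
                           n_requested=n_rep, n_failed=n_failed)


def gof_table(fit_result: FitResult, dataset: StudyDataset) -> pd.DataFrame:
    """Per-observation goodness-of-fit table.

    Columns: subject, time, study, endpoint, DV, population prediction
    (PRED), individual prediction (IPRED) and conditional weighted residual
    (CWRES) — the numeric substrate of the standard GOF panels.
    """
    t = fit_result.obs_table.copy()
    t["endpoint"] = fit_result.spec.stage
    return t[["row", "ID", "TIME", "STUDY", "endpoint",
              "DV", "PRED", "IPRED", "CWRES"]]
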