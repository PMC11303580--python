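"""Data-driven initial estimates for the nonlinear stages.

Hierarchical sigmoid-Emax likelihoods are ridge-shaped when started far
from the well: the eta variances absorb structural misfit and the outer
search stalls.  The standard remedy is to initialize from a naive pooled
curve fit — ordinary least squares of the structural model through all
(regressor, observation) pairs, ignoring the hierarchy — which lands the
fixed effects inside the basin of attraction at negligible cost.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from ecupop.dataset_io import DVID_LDH, DVID_PD, StudyDataset

__all__ = ["pd_curve_inits", "ldh_curve_inits"]


def _pooled_points(dataset: StudyDataset, dvid: int, reg_col: str):
    df = dataset.df
    rows = df[(df["EVID"] == 0) & (df["DVID"] == dvid) & (df["MDV"] == 0)
              & (df["SCREEN"] == 0)]
    if reg_col not in rows or rows[reg_col].isna().any():
        raise ValueError(f"stage regressor {reg_col!r} missing; run ipp_link first")
    return (rows[reg_col].to_numpy(float), rows["DV"].to_numpy(float),
            (rows["POP"] == "PNH").to_numpy())


def pd_curve_inits(dataset: StudyDataset) -> dict:
    """Pooled-least-squares starting values for the TCA sigmoid Emax model.

    Returns a theta mapping for the final PD model layout (population
    covariate on baseline and maximal inhibition).  Falls back to generic
    values if the pooled fit does not converge.
    """
    conc, tca, is_pat = _pooled_points(dataset, DVID_PD, "CIPP")

    def model(x, e0h, e0p, imh, imp, ic50, hill):
        c, pat = x
        e0 = np.where(pat > 0.5, e0p, e0h)
        im = np.where(pat > 0.5, imp, imh)
        ch = np.where(c > 0, c, 1e-12) ** hill
        return e0 * (1 - im * ch / (ic50 ** hill + ch))

    base_h = np.median(tca[(conc < 1.0) & ~is_pat]) if ((conc < 1.0) & ~is_pat).any() else 90.0
    base_p = np.median(tca[(conc < 1.0) & is_pat]) if ((conc < 1.0) & is_pat).any() else base_h
    p0 = (base_h, base_p, 0.9, 0.9, 30.0, 3.0)
    bounds = ([20, 20, 0.5, 0.5, 1.0, 0.5], [200, 200, 0.999, 0.999, 300, 15])
    try:
        popt, _ = curve_fit(model, (conc, is_pat.astype(float)), tca,
                            p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        popt = p0
    e0h, e0p, imh, imp, ic50, hill = popt
    return {"e0": float(e0h), "e0:POP=PNH": float(e0p),
            "imax": float(imh), "imax:POP=PNH": float(imp),
            "ic50": float(ic50), "hill": float(hill)}


def ldh_curve_inits(dataset: StudyDataset) -> dict:
    """Pooled-least-squares starting values for the TCA -> LDH model."""
    tca, ldh, _ = _pooled_points(dataset, DVID_LDH, "TCAIPP")

    def model(t, ll0, lmax, lc50, gam):
        tg = np.where(t > 0, t, 1e-12) ** gam
        return ll0 + lmax * tg / (lc50 ** gam + tg)

    low = ldh[tca < 30.0]
    ll0_guess = float(np.median(low)) if low.size else 250.0
    lmax_guess = max(float(np.percentile(ldh, 95)) - ll0_guess, 100.0)
    p0 = (ll0_guess, lmax_guess, 40.0, 3.0)
    bounds = ([10, 10, 5, 0.5], [2000, 10000, 150, 15])
    try:
        popt, _ = curve_fit(model, tca, ldh, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        popt = p0
    ll0, lmax, lc50, gam = popt
    return {"ll0": float(ll0), "lmax": float(lmax),
            "lc50": float(lc50), "lgam": float(gam)}
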