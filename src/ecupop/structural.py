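"""Structural PK, PD and efficacy models.

Pharmacokinetics: two-compartment disposition with zero-order (infusion)
input into the central compartment and first-order elimination from it,
parameterized as (CL, Vc, Vp, Q).  The concentration-time profile is the
exact biexponential solution; multiple doses superpose (linear kinetics).

Pharmacodynamics: terminal complement activity (TCA, %) follows a direct
inhibitory sigmoid Emax model in serum concentration,

    TCA(C) = E0 * (1 - Imax * C^H / (IC50^H + C^H)).

Efficacy: lactate dehydrogenase (LDH, U/L) follows a direct stimulatory
sigmoid Emax model in TCA,

    LDH(T) = LL0 + LMAX * T^gamma / (LC50^gamma + T^gamma).

Between-subject variability enters exponentially, p_i = TV_p * exp(eta_p).
Typical values carry covariate effects: weight as a power model centred on
the 80.9 kg reference, and population (healthy vs PNH patient) as separate
typical values for Vc, E0 and Imax.

All model functions accept numpy arrays and are complex-step safe (the
estimation engine differentiates through them with complex perturbations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PKThetas", "PDThetas", "EffThetas", "OmegaBlock", "SigmaModel",
    "IndividualParameters", "resolve_individual", "pk_concentration",
    "two_compartment_conc", "tca_response", "ldh_response", "residual_variance",
]

WT_REF_DEFAULT = 80.9  # kg, reference weight for the power covariate model


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKThetas:
    """Fixed effects of the two-compartment PK model.

    CL and Vc carry weight as ``theta * (WT/wt_ref)**exponent``; Vc has a
    separate typical value for PNH patients.
    """

    cl: float                      # L/h, typical clearance at wt_ref
    vc_healthy: float              # L, central volume, healthy subjects
    vc_patient: float              # L, central volume, PNH patients
    vp: float                      # L, peripheral volume
    q: float                       # L/h, inter-compartmental clearance
    exp_cl_wt: float               # weight exponent on CL
    exp_vc_wt: float               # weight exponent on Vc
    wt_ref: float = WT_REF_DEFAULT

    def __post_init__(self) -> None:
        for name in ("cl", "vc_healthy", "vc_patient", "vp", "q", "wt_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PKThetas.{name} must be positive")


@dataclass(frozen=True)
class PDThetas:
    """Fixed effects of the inhibitory sigmoid Emax TCA model."""

    e0_healthy: float              # % baseline TCA, healthy
    e0_patient: float              # % baseline TCA, PNH patients
    imax_healthy: float            # maximal inhibition fraction, healthy
    imax_patient: float            # maximal inhibition fraction, patients
    ic50: float                    # ug/mL at half-maximal inhibition
    hill: float                    # sigmoidicity

    def __post_init__(self) -> None:
        if self.e0_healthy <= 0 or self.e0_patient <= 0:
            raise ValueError("baseline TCA must be positive")
        for imax in (self.imax_healthy, self.imax_patient):
            if not 0 < imax <= 1:
                raise ValueError("Imax must lie in (0, 1]")
        if self.ic50 <= 0 or self.hill <= 0:
            raise ValueError("IC50 and Hill coefficient must be positive")


@dataclass(frozen=True)
class EffThetas:
    """Fixed effects of the TCA -> LDH sigmoid Emax efficacy model."""

    ll0: float                     # U/L, LDH floor at fully suppressed TCA
    lmax: float                    # U/L, maximal LDH elevation
    lc50: float                    # % TCA at half-maximal elevation
    lgam: float                    # sigmoidicity

    def __post_init__(self) -> None:
        if self.ll0 <= 0 or self.lmax < 0 or self.lc50 <= 0 or self.lgam <= 0:
            raise ValueError("invalid efficacy fixed effects")


@dataclass(frozen=True)
class OmegaBlock:
    """Between-subject variance block for one model stage.

    ``names`` lists the parameters carrying an eta, ``cov`` is the
    corresponding covariance matrix of the (log-scale) etas.  The only
    off-diagonal element used by the final models is the CL-Vc correlation
    of the PK stage; PD and efficacy blocks are diagonal.
    """

    names: tuple
    cov: np.ndarray

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "cov", cov)
        if cov.shape != (len(self.names), len(self.names)):
            raise ValueError("omega covariance shape does not match names")
        if not np.allclose(cov, cov.T):
            raise ValueError("omega covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) < -1e-10):
            raise ValueError("omega covariance must be positive semidefinite")

    @classmethod
    def from_sd_corr(cls, names: Sequence[str], sd: Sequence[float],
                     corr: dict | None = None) -> "OmegaBlock":
        """Build from per-parameter SDs and named pairwise correlations.

        ``sd`` is on the eta (log) scale, so IIV% = 100*sd.
        """
        names = tuple(names)
        sd = np.asarray(sd, dtype=float)
        R = np.eye(len(names))
        for (a, b), rho in (corr or {}).items():
            i, j = names.index(a), names.index(b)
            if not -1 < rho < 1:
                raise ValueError("correlation must lie in (-1, 1)")
            R[i, j] = R[j, i] = rho
        return cls(names, R * np.outer(sd, sd))

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def iiv_percent(self) -> np.ndarray:
        """NONMEM-style approximate CV%: 100*sqrt(omega^2)."""
        return 100.0 * self.sd

    def correlation(self, a: str, b: str) -> float:
        i, j = self.names.index(a), self.names.index(b)
        return float(self.cov[i, j] / (self.sd[i] * self.sd[j]))


@dataclass(frozen=True)
class SigmaModel:
    """Residual error model: proportional, additive or combined."""

    kind: str = "proportional"
    prop: float = 0.0              # fractional SD of the proportional term
    add: float = 0.0               # SD of the additive term, DV units

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "additive", "combined"):
            raise ValueError(f"unknown residual model kind {self.kind!r}")
        if self.prop < 0 or self.add < 0:
            raise ValueError("residual error components must be non-negative")
        # zero total variance is allowed only for degenerate (noise-free)
        # simulation settings; estimation rejects it at likelihood time


def residual_variance(pred, sigma: SigmaModel):
    """Residual variance at a (non-negative) model prediction.

    Proportional: sigma_prop^2 * pred^2; additive: sigma_add^2; combined is
    their sum.  A proportional-only variance of zero (pred == 0) is returned
    as-is; likelihood code must treat it as degenerate.
    """
    pred = np.asarray(pred)
    if np.any(np.real(pred) < 0):
        raise ValueError("residual_variance requires non-negative predictions")
    var = np.zeros_like(pred, dtype=pred.dtype)
    if sigma.kind in ("proportional", "combined"):
        var = var + (sigma.prop * pred) ** 2
    if sigma.kind in ("additive", "combined"):
        var = var + sigma.add ** 2
    return var


# ---------------------------------------------------------------------------
# individual parameter resolution
# ---------------------------------------------------------------------------

PK_ETA_NAMES = ("cl", "vc", "vp")
PD_ETA_NAMES = ("e0", "imax", "ic50")
EFF_ETA_NAMES = ("ll0", "lmax", "lgam")


@dataclass(frozen=True)
class IndividualParameters:
    """Covariate- and eta-resolved parameters for one subject."""

    cl: float
    vc: float
    vp: float
    q: float
    e0: float = np.nan
    imax: float = np.nan
    ic50: float = np.nan
    hill: float = np.nan
    ll0: float = np.nan
    lmax: float = np.nan
    lc50: float = np.nan
    lgam: float = np.nan
    eta_pk: np.ndarray = field(default_factory=lambda: np.zeros(3))
    eta_pd: np.ndarray = field(default_factory=lambda: np.zeros(3))
    eta_eff: np.ndarray = field(default_factory=lambda: np.zeros(3))


def resolve_individual(pk: PKThetas, weight: float, population: str,
                       eta_pk=None, pd: PDThetas | None = None, eta_pd=None,
                       eff: EffThetas | None = None, eta_eff=None) -> IndividualParameters:
    """Resolve one subject's parameters from covariates and etas.

    ``population`` selects the healthy vs PNH-patient typical values of Vc,
    E0 and Imax; weight scales CL and Vc through the power model; etas are
    applied exponentially in the order (CL, Vc, Vp) / (E0, Imax, IC50) /
    (LL0, LMAX, LGAM).
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if population not in ("healthy", "PNH"):
        raise ValueError(f"unknown population {population!r}")
    eta_pk = np.zeros(3) if eta_pk is None else np.asarray(eta_pk, dtype=float)
    eta_pd = np.zeros(3) if eta_pd is None else np.asarray(eta_pd, dtype=float)
    eta_eff = np.zeros(3) if eta_eff is None else np.asarray(eta_eff, dtype=float)
    if eta_pk.shape != (3,) or eta_pd.shape != (3,) or eta_eff.shape != (3,):
        raise ValueError("eta vectors must have length 3 per stage")

    wt_frac = weight / pk.wt_ref
    vc_typ = pk.vc_healthy if population == "healthy" else pk.vc_patient
    out = dict(
        cl=pk.cl * wt_frac ** pk.exp_cl_wt * np.exp(eta_pk[0]),
        vc=vc_typ * wt_frac ** pk.exp_vc_wt * np.exp(eta_pk[1]),
        vp=pk.vp * np.exp(eta_pk[2]),
        q=pk.q,
    )
    if pd is not None:
        e0 = pd.e0_healthy if population == "healthy" else pd.e0_patient
        imax = pd.imax_healthy if population == "healthy" else pd.imax_patient
        out.update(
            e0=e0 * np.exp(eta_pd[0]),
            imax=imax * np.exp(eta_pd[1]),
            ic50=pd.ic50 * np.exp(eta_pd[2]),
            hill=pd.hill,
        )
    if eff is not None:
        out.update(
            ll0=eff.ll0 * np.exp(eta_eff[0]),
            lmax=eff.lmax * np.exp(eta_eff[1]),
            lc50=eff.lc50,
            lgam=eff.lgam * np.exp(eta_eff[2]),
        )
    return IndividualParameters(eta_pk=eta_pk, eta_pd=eta_pd, eta_eff=eta_eff, **out)


# ---------------------------------------------------------------------------
# two-compartment infusion kinetics
# ---------------------------------------------------------------------------

def two_compartment_conc(times, doses, cl, vc, vp, q):
    """Central-compartment concentration for zero-order infusions.

    Exact biexponential solution of the two-compartment model with
    micro-constants k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp and hybrid rate
    constants alpha/beta from the characteristic quadratic
    ``lam^2 - (k10+k12+k21) lam + k10 k21 = 0``.  Multiple doses superpose.

    Parameters
    ----------
    times : array of sampling times (h); any shape broadcastable with the
        parameter arrays (parameters of shape ``(n, 1)`` with times ``(n, t)``
        evaluate ``n`` subjects at once).
    doses : sequence of ``(start_h, amount_mg, duration_h)`` triples; each
        element may be a scalar or an array broadcastable with ``times``.
    cl, vc, vp, q : scalars or arrays (may be complex for derivative passes).
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(times < -1e-9):
        raise ValueError("negative sampling times")
    cl = np.asarray(cl)
    vc = np.asarray(vc)
    vp = np.asarray(vp)
    q = np.asarray(q)
    if np.any(np.real(vc) <= 0) or np.any(np.real(vp) <= 0):
        raise ValueError("volumes must be positive")

    consts = _hybrid_constants(cl, vc, vp, q)
    geom = infusion_geometry(times, doses)
    if geom is None:
        return np.zeros(np.broadcast(times, cl).shape)
    if isinstance(geom, _TrainGeometry):
        return _conc_from_trains(geom, *consts)
    return _conc_from_geometry(geom, *consts)


def infusion_geometry(times, doses, allow_trains: bool = True):
    """Precompute the dose-time geometry for repeated parameter evaluation.

    When the dosing history is shared across subjects and contains regular
    trains of identical infusions (e.g. a q2w maintenance schedule), the
    superposition over each train collapses to a geometric series and the
    geometry shrinks from one slab per dose to one per train; otherwise
    dense per-dose arrays (t_in, t_post, rate) are returned.
    """
    times = np.asarray(times, dtype=float)
    doses = list(doses)
    if not doses:
        return None
    if allow_trains and len(doses) >= 6:
        trains = _detect_trains(times, doses)
        if trains is not None:
            return trains
    start = np.stack([np.broadcast_to(np.asarray(s, dtype=float), times.shape)
                      for s, _, _ in doses], axis=-1)
    amount = np.stack([np.broadcast_to(np.asarray(a, dtype=float), times.shape)
                       for _, a, _ in doses], axis=-1)
    duration = np.stack([np.broadcast_to(np.asarray(du, dtype=float), times.shape)
                         for _, _, du in doses], axis=-1)
    if np.any(duration <= 0):
        raise ValueError("infusion duration must be positive")
    rate = amount / duration
    tau = times[..., None] - start
    t_in = np.clip(np.minimum(tau, duration), 0.0, None)   # time infused
    t_post = np.clip(tau - duration, 0.0, None)            # time since end
    return t_in, t_post, rate


def _hybrid_constants(cl, vc, vp, q):
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21 + 0j) if np.iscomplexobj(s) \
        else np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    denom = alpha - beta
    coef_a = (alpha - k21) / (vc * denom)
    coef_b = (k21 - beta) / (vc * denom)
    return alpha, beta, coef_a, coef_b


def conc_from_geometry(geom, cl, vc, vp, q):
    """Concentration from precomputed geometry and disposition parameters."""
    if geom is None:
        return 0.0
    consts = _hybrid_constants(cl, vc, vp, q)
    if isinstance(geom, _TrainGeometry):
        return _conc_from_trains(geom, *consts)
    return _conc_from_geometry(geom, *consts)


class _TrainGeometry:
    """Regular infusion trains: per-train scalars plus per-time integer
    completion counts, enabling geometric-series superposition."""

    def __init__(self, trains, m, t_rel, part_mask, t_part):
        self.trains = trains          # [(rate, tau, delta)] per train
        self.m = m                    # (n, T, G) completed doses
        self.t_rel = t_rel            # (n, T, G) time since end of last dose
        self.part_mask = part_mask    # (n, T, G) time falls inside an infusion
        self.t_part = t_part          # (n, T, G) time since that dose start


def _detect_trains(times, doses):
    """Recognize a dosing history shared by all subjects as regular trains.

    Returns None when subjects differ or spacing/amount is irregular, in
    which case the dense per-dose geometry is used instead.
    """
    starts, amts, durs = [], [], []
    for s, a, du in doses:
        s = np.asarray(s, dtype=float).ravel()
        a = np.asarray(a, dtype=float).ravel()
        du = np.asarray(du, dtype=float).ravel()
        if np.ptp(s) > 1e-9 or np.ptp(a) > 1e-9 or np.ptp(du) > 1e-9:
            return None
        starts.append(s.flat[0]); amts.append(a.flat[0]); durs.append(du.flat[0])
    order = np.argsort(starts)
    starts = np.asarray(starts)[order]
    amts = np.asarray(amts)[order]
    durs = np.asarray(durs)[order]
    if np.any(durs <= 0):
        raise ValueError("infusion duration must be positive")

    # greedily extend trains of constant (amount, duration, spacing)
    groups = []
    i = 0
    while i < len(starts):
        j = i + 1
        while j < len(starts) and amts[j] == amts[i] and durs[j] == durs[i]:
            if j - i >= 2 and not np.isclose(starts[j] - starts[j - 1],
                                             starts[i + 1] - starts[i]):
                break
            j += 1
        groups.append((starts[i:j], amts[i], durs[i]))
        i = j

    t = np.asarray(times, dtype=float)[..., None]
    trains, m_list, trel_list, pmask_list, tpart_list = [], [], [], [], []
    for s_grp, amt, tau in groups:
        k = len(s_grp)
        t0 = s_grp[0]
        delta = s_grp[1] - s_grp[0] if k > 1 else 1.0
        if delta <= 0:
            return None
        m = np.clip(np.floor((t[..., 0] - tau - t0) / delta) + 1, 0, k)
        e_last = t0 + (m - 1) * delta
        t_rel = np.maximum(t[..., 0] - e_last - tau, 0.0)
        j_p = np.floor((t[..., 0] - t0) / delta)
        s_p = t0 + j_p * delta
        part = (j_p >= 0) & (j_p <= k - 1) & (t[..., 0] >= s_p) \
            & (t[..., 0] < s_p + tau)
        t_part = np.where(part, t[..., 0] - s_p, 0.0)
        trains.append((amt / tau, tau, delta))
        m_list.append(m); trel_list.append(t_rel)
        pmask_list.append(part); tpart_list.append(t_part)
    return _TrainGeometry(trains,
                          np.stack(m_list, axis=-1),
                          np.stack(trel_list, axis=-1),
                          np.stack(pmask_list, axis=-1),
                          np.stack(tpart_list, axis=-1))


def _conc_from_trains(geom: _TrainGeometry, alpha, beta, coef_a, coef_b):
    """Superpose regular infusion trains via stable geometric series.

    For m completed doses spaced delta apart, the sum of shifted
    monoexponentials collapses to
    ``exp(-lam*(t - t_last - tau)) * (1 - exp(-lam*delta*m))/(1 - exp(-lam*delta))``
    — every exponent non-positive, so the evaluation never overflows.
    """
    conc = 0.0
    for gix, (rate, tau, delta) in enumerate(geom.trains):
        m = geom.m[..., gix]
        t_rel = geom.t_rel[..., gix]
        part = geom.part_mask[..., gix]
        t_part = geom.t_part[..., gix]
        done = m > 0
        contrib = 0.0
        for lam, c in ((alpha, coef_a), (beta, coef_b)):
            series = (1.0 - _exp(-lam * delta * m)) / (1.0 - _exp(-lam * delta))
            complete = (c / lam * (1.0 - _exp(-lam * tau))
                        * _exp(-lam * t_rel) * series * done)
            partial = c / lam * (1.0 - _exp(-lam * t_part)) * part
            contrib = contrib + complete + partial
        conc = conc + rate * contrib
    return conc


def _exp(z):
    """exp for arrays that may carry (near-)infinitesimal imaginary parts.

    Complex exponentials are assembled from real exp/cos/sin, which is
    several-fold faster than numpy's complex exp for the derivative passes
    of the estimation engine and exact for all arguments.
    """
    if not np.iscomplexobj(z):
        return np.exp(z)
    er = np.exp(z.real)
    return er * np.cos(z.imag) + 1j * (er * np.sin(z.imag))


def _conc_from_geometry(geom, alpha, beta, coef_a, coef_b):
    t_in, t_post, rate = geom
    a = alpha[..., None] if np.ndim(alpha) else alpha
    b = beta[..., None] if np.ndim(beta) else beta
    ca = coef_a[..., None] if np.ndim(coef_a) else coef_a
    cb = coef_b[..., None] if np.ndim(coef_b) else coef_b
    term = (ca / a * (1.0 - _exp(-a * t_in)) * _exp(-a * t_post)
            + cb / b * (1.0 - _exp(-b * t_in)) * _exp(-b * t_post))
    return np.sum(rate * term, axis=-1)


def pk_concentration(times, doses, ind: IndividualParameters):
    """Concentration-time profile (ug/mL) for one subject.

    ``doses`` is a sequence of ``(start_h, amount_mg, duration_h)``.
    Returns zero for times before the first dose start.
    """
    return two_compartment_conc(times, doses, ind.cl, ind.vc, ind.vp, ind.q)


# ---------------------------------------------------------------------------
# PD and efficacy response models
# ---------------------------------------------------------------------------

def tca_response(conc, e0, imax=None, ic50=None, hill=None):
    """Terminal complement activity (%) at serum concentration ``conc``.

    ``TCA = E0 * (1 - Imax * C^H / (IC50^H + C^H))`` — monotone
    non-increasing in C; equals E0 at C = 0 and E0*(1 - Imax) as C -> inf.

    The first argument may instead be an :class:`IndividualParameters` in
    the second position, i.e. ``tca_response(conc, ind)``.
    """
    if isinstance(e0, IndividualParameters):
        ind = e0
        e0, imax, ic50, hill = ind.e0, ind.imax, ind.ic50, ind.hill
    conc = np.asarray(conc)
    if np.any(np.real(conc) < 0):
        raise ValueError("concentration must be non-negative")
    # C^H with C possibly zero: compute via masked exp(log) to stay
    # complex-step safe in (e0, imax, ic50).
    hill = np.asarray(hill)
    ch = np.where(np.real(conc) > 0,
                  np.exp(hill * np.log(np.where(np.real(conc) > 0, conc, 1.0))),
                  0.0)
    ic50h = np.exp(hill * np.log(ic50))
    return e0 * (1.0 - imax * ch / (ic50h + ch))


def ldh_response(tca, ll0, lmax=None, lc50=None, lgam=None):
    """Lactate dehydrogenase (U/L) at terminal complement activity ``tca``.

    ``LDH = LL0 + LMAX * T^g / (LC50^g + T^g)`` — monotone non-decreasing
    in TCA; equals LL0 at TCA = 0 and approaches LL0 + LMAX as TCA -> inf.
    """
    if isinstance(ll0, IndividualParameters):
        ind = ll0
        ll0, lmax, lc50, lgam = ind.ll0, ind.lmax, ind.lc50, ind.lgam
    tca = np.asarray(tca)
    if np.any(np.real(tca) < 0):
        raise ValueError("TCA must be non-negative")
    lgam = np.asarray(lgam)
    tg = np.where(np.real(tca) > 0,
                  np.exp(lgam * np.log(np.where(np.real(tca) > 0, tca, 1.0))),
                  0.0)
    lc50g = np.exp(lgam * np.log(lc50))
    return ll0 + lmax * tg / (lc50g + tg)
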