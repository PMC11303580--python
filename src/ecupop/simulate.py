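"""Clinical-trial simulator for the phase I and phase III designs.

Phase I: 240 healthy subjects, three equal arms (SB12, EU-ECU, US-ECU),
a single 300 mg IV infusion over 35 min, serial PK sampling to 1512 h and
ten PD (terminal complement activity) samples.

Phase III: 49 PNH patients in a two-sequence cross-over (SB12->ECU /
ECU->SB12, switch at week 26), 600 mg weekly for four weeks then 900 mg at
week 4 and every two weeks until week 50; trough PK at 17 visits, PD at 13
visits and LDH at 29 visits.

Observations are drawn from the structural models with exponential
between-subject variability and proportional residual error, then passed
through the LLOQ/pre-dose missingness rules.  Treatment labels carry no
effect on any parameter unless one is injected explicitly
(:func:`inject_treatment_effect`), so treatment similarity is the
generative truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from ecupop.dataset_io import (
    DVID_LDH, DVID_PD, DVID_PK, StudyDataset, apply_missingness_rules,
)
from ecupop.structural import (
    EffThetas, OmegaBlock, PKThetas, PDThetas, SigmaModel,
    ldh_response, resolve_individual, tca_response, two_compartment_conc,
)

__all__ = [
    "TrialDesign", "TruthParameters", "default_truth",
    "phase1_design", "phase3_design", "sample_covariates",
    "simulate_study", "inject_treatment_effect", "TROUGH_OFFSET_H",
]

HOURS_PER_WEEK = 168.0
INFUSION_H = 0.583            # 35 min
TROUGH_OFFSET_H = 1e-6        # trough samples sit just before the dose

# nominal sampling schedules (hours)
PHASE1_PK_H = (0.0, 0.58, 4, 8, 12, 24, 48, 96, 168, 240, 336, 504, 672,
               840, 1008, 1176, 1344, 1512)
PHASE1_PD_H = (0.0, 0.58, 4, 24, 48, 96, 168, 240, 336, 1512)
PHASE3_PK_WEEKS = (0, 2, 4, 6, 10, 14, 18, 22, 26, 28, 30, 32, 36, 40, 44, 48, 52)
PHASE3_PD_WEEKS = (0, 2, 4, 6, 10, 14, 26, 28, 30, 32, 36, 40, 52)
PHASE3_LDH_WEEKS = (0, 1, 2, 3, 4) + tuple(range(6, 54, 2))


@dataclass(frozen=True)
class TrialDesign:
    """Regimen, sampling schedules, arms and covariate distributions."""

    study: str                                # "phase1" | "phase3"
    n_subjects: int
    arms: tuple                               # ((label, count), ...) or sequences
    regimen: tuple                            # ((start_h, amount_mg, duration_h), ...)
    pk_times: tuple                           # hours
    pd_times: tuple
    ldh_times: tuple = ()
    population: str = "healthy"
    weight_median: float = 82.4               # kg (phase I default)
    weight_range: tuple = (70.0, 94.3)
    weight_log_sd: float = 0.06
    lloq_pk: float = 0.8                      # ug/mL
    crossover_time: float | None = None       # h (phase III: week 26)

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        horizon = max(t for t, _, _ in self.regimen) + 2 * HOURS_PER_WEEK * 52
        for t in (*self.pk_times, *self.pd_times, *self.ldh_times):
            if not 0 <= t <= horizon:
                raise ValueError("sampling times must lie within the study horizon")


@dataclass(frozen=True)
class TruthParameters:
    """Generative truth: fixed effects, eta blocks and residual models."""

    pk: PKThetas
    pd: PDThetas
    eff: EffThetas
    omega_pk: OmegaBlock
    omega_pd: OmegaBlock
    omega_eff: OmegaBlock
    sigma_pk: SigmaModel
    sigma_pd: SigmaModel
    sigma_ldh: SigmaModel
    sb12_fold: dict = field(default_factory=dict)   # param -> fold on SB12 arm

    def scaled_pk(self, treatment: str) -> PKThetas:
        return self._scaled(self.pk, treatment)

    def scaled_pd(self, treatment: str) -> PDThetas:
        return self._scaled(self.pd, treatment)

    def scaled_eff(self, treatment: str) -> EffThetas:
        return self._scaled(self.eff, treatment)

    def _scaled(self, thetas, treatment):
        if treatment != "SB12" or not self.sb12_fold:
            return thetas
        changes = {}
        for param, fold in self.sb12_fold.items():
            targets = _FOLD_TARGETS.get(param, (param,))
            for name in targets:
                if hasattr(thetas, name):
                    changes[name] = getattr(thetas, name) * fold
        return replace(thetas, **changes) if changes else thetas


# parameter aliases for treatment-effect injection: folding "cl" scales the
# single clearance theta; folding "vc"/"e0"/"imax" scales both population TVs
_FOLD_TARGETS = {
    "cl": ("cl",),
    "vc": ("vc_healthy", "vc_patient"),
    "e0": ("e0_healthy", "e0_patient"),
    "imax": ("imax_healthy", "imax_patient"),
}
_KNOWN_FOLD_PARAMS = {"cl", "vc", "vp", "q", "e0", "imax", "ic50", "hill",
                      "ll0", "lmax", "lc50", "lgam"}


def default_truth() -> TruthParameters:
    """The final published model estimates, used as generative truth."""
    return TruthParameters(
        pk=PKThetas(cl=0.0174, vc_healthy=3.47, vc_patient=5.68, vp=0.79,
                    q=0.0134, exp_cl_wt=1.14, exp_vc_wt=0.863),
        pd=PDThetas(e0_healthy=85.9, e0_patient=101.0, imax_healthy=0.93,
                    imax_patient=0.88, ic50=36.6, hill=4.56),
        eff=EffThetas(ll0=206.0, lmax=1680.0, lc50=39.0, lgam=4.30),
        omega_pk=OmegaBlock.from_sd_corr(
            ("cl", "vc", "vp"), (0.1562, 0.1274, 0.3680),
            {("cl", "vc"): 0.54}),
        omega_pd=OmegaBlock.from_sd_corr(
            ("e0", "imax", "ic50"), (0.1529, 0.0265, 0.2274)),
        omega_eff=OmegaBlock.from_sd_corr(
            ("ll0", "lmax", "lgam"), (0.2897, 0.8157, 0.5591)),
        sigma_pk=SigmaModel("proportional", prop=0.117),
        sigma_pd=SigmaModel("proportional", prop=0.186),
        sigma_ldh=SigmaModel("proportional", prop=0.320),
    )


def inject_treatment_effect(truth: TruthParameters, param: str,
                            fold: float) -> TruthParameters:
    """Multiply one parameter's typical value by ``fold`` for SB12 subjects.

    Used for power analyses of the treatment-similarity test; ``fold=1``
    returns an unchanged truth.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if param not in _KNOWN_FOLD_PARAMS:
        raise ValueError(f"unknown parameter {param!r}")
    if fold == 1.0:
        return truth
    if param == "imax":
        worst = max(truth.pd.imax_healthy, truth.pd.imax_patient) * fold
        if worst > 1:
            raise ValueError("folded Imax would exceed 1")
    return replace(truth, sb12_fold={**truth.sb12_fold, param: fold})


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

def phase1_design(n: int = 240) -> TrialDesign:
    """Single-dose healthy-volunteer study, three equal treatment arms."""
    if n <= 0:
        raise ValueError("n must be positive")
    counts = [n // 3] * 3
    for i in range(n - sum(counts)):
        counts[i] += 1
    return TrialDesign(
        study="phase1",
        n_subjects=n,
        arms=tuple(zip(("SB12", "EU-ECU", "US-ECU"), counts)),
        regimen=((0.0, 300.0, INFUSION_H),),
        pk_times=PHASE1_PK_H,
        pd_times=PHASE1_PD_H,
        population="healthy",
        weight_median=82.4, weight_range=(70.0, 94.3), weight_log_sd=0.06,
    )


def phase3_design(n: int = 49) -> TrialDesign:
    """Multiple-dose cross-over study in PNH patients.

    Doses: 600 mg at weeks 0-3, 900 mg at week 4 and every second week to
    week 50 (28 infusions).  PK is sampled at trough only.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    doses = [(w * HOURS_PER_WEEK, 600.0, INFUSION_H) for w in range(4)]
    doses.append((4 * HOURS_PER_WEEK, 900.0, INFUSION_H))
    doses += [(w * HOURS_PER_WEEK, 900.0, INFUSION_H) for w in range(6, 52, 2)]
    n_seq1 = n // 2
    return TrialDesign(
        study="phase3",
        n_subjects=n,
        arms=(("I", n_seq1), ("II", n - n_seq1)),
        regimen=tuple(doses),
        pk_times=tuple(w * HOURS_PER_WEEK for w in PHASE3_PK_WEEKS),
        pd_times=tuple(w * HOURS_PER_WEEK for w in PHASE3_PD_WEEKS),
        ldh_times=tuple(w * HOURS_PER_WEEK for w in PHASE3_LDH_WEEKS),
        population="PNH",
        weight_median=63.0, weight_range=(43.0, 111.0), weight_log_sd=0.18,
        crossover_time=26 * HOURS_PER_WEEK,
    )


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def sample_covariates(design: TrialDesign, seed) -> pd.DataFrame:
    """Draw per-subject covariates and arm/sequence assignments.

    Weight is log-normal centred on the design median and truncated to the
    design range.  Age, height, sex and race are generated for realism but
    are not used by the final models.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = design.n_subjects
    wt = _trunc_lognormal(rng, n, design.weight_median, design.weight_log_sd,
                          design.weight_range)
    if design.study == "phase1":
        age = np.round(_trunc_lognormal(rng, n, 40.0, 0.2, (19, 55)))
        ht = _trunc_lognormal(rng, n, 181.0, 0.03, (162, 198))
        sex = np.where(rng.random(n) < 0.958, "M", "F")
        race = rng.choice(["White", "Asian", "Other"], size=n, p=[0.958, 0.004, 0.038])
    else:
        age = np.round(_trunc_lognormal(rng, n, 36.0, 0.3, (18, 79)))
        ht = _trunc_lognormal(rng, n, 164.9, 0.04, (146, 190))
        sex = np.where(rng.random(n) < 0.449, "M", "F")
        race = rng.choice(["White", "Asian", "Other"], size=n, p=[0.367, 0.531, 0.102])
    labels = np.concatenate([[label] * count for label, count in design.arms])
    assign = "TRT" if design.study == "phase1" else "SEQ"
    return pd.DataFrame({
        "ID": np.arange(1, n + 1),
        "WT": wt, "AGE": age, "HT": ht, "SEX": sex, "RACE": race,
        "POP": design.population, assign: labels,
    })


def _trunc_lognormal(rng, n, median, log_sd, bounds):
    lo, hi = bounds
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = np.exp(np.log(median) + log_sd * rng.standard_normal(todo.size))
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_study(design: TrialDesign, truth: TruthParameters, seed,
                   id_offset: int = 0) -> StudyDataset:
    """Simulate one study dataset under the given generative truth.

    Deterministic in (design, truth, seed).  Sampling times that coincide
    with a dose are shifted ``TROUGH_OFFSET_H`` earlier (trough sampling);
    the baseline sample at t = 0 stays at the dose time and is flagged
    missing by the pre-dose rule.  LLOQ censoring and the missingness rules
    are applied before returning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = sample_covariates(design, rng)
    dose_starts = np.array([t for t, _, _ in design.regimen])

    rows = []
    truth_rows = []
    for i in range(design.n_subjects):
        sid = int(cov.loc[i, "ID"]) + id_offset
        wt = float(cov.loc[i, "WT"])
        base = {
            "ID": sid, "WT": wt, "POP": design.population,
            "STUDY": design.study,
            "AGE": cov.loc[i, "AGE"], "SEX": cov.loc[i, "SEX"],
            "HT": round(float(cov.loc[i, "HT"]), 1), "RACE": cov.loc[i, "RACE"],
        }
        if design.study == "phase1":
            seq = "I"
            trt_of = {1: cov.loc[i, "TRT"], 2: cov.loc[i, "TRT"]}
        else:
            seq = cov.loc[i, "SEQ"]
            trt_of = ({1: "SB12", 2: "EU-ECU"} if seq == "I"
                      else {1: "EU-ECU", 2: "SB12"})
        label_trt = trt_of[1]      # treatment label driving any injected effect

        eta_pk = rng.multivariate_normal(np.zeros(3), truth.omega_pk.cov)
        eta_pd = rng.multivariate_normal(np.zeros(3), truth.omega_pd.cov)
        imax_typ = (truth.pd.imax_healthy if design.population == "healthy"
                    else truth.pd.imax_patient)
        # keep individual Imax <= 1 so TCA stays non-negative
        while imax_typ * np.exp(eta_pd[1]) > 1.0:
            eta_pd = rng.multivariate_normal(np.zeros(3), truth.omega_pd.cov)
        eta_eff = rng.multivariate_normal(np.zeros(3), truth.omega_eff.cov)

        ind = resolve_individual(
            truth.scaled_pk(label_trt), wt, design.population, eta_pk,
            pd=truth.scaled_pd(label_trt), eta_pd=eta_pd,
            eff=truth.scaled_eff(label_trt), eta_eff=eta_eff)
        truth_rows.append({"ID": sid, "WT": wt, "TRT": label_trt,
                           "cl": ind.cl, "vc": ind.vc, "vp": ind.vp,
                           "e0": ind.e0, "imax": ind.imax, "ic50": ind.ic50,
                           "ll0": ind.ll0, "lmax": ind.lmax, "lgam": ind.lgam})

        def period(t):
            if design.crossover_time is None:
                return 1
            return 1 if t < design.crossover_time else 2

        for start, amount, duration in design.regimen:
            rows.append({**base, "TIME": start, "EVID": 1, "AMT": amount,
                         "RATE": amount / duration, "PER": period(start),
                         "TRT": trt_of[period(start)], "SEQ": seq})

        obs_specs = [(design.pk_times, DVID_PK), (design.pd_times, DVID_PD)]
        if design.ldh_times:
            obs_specs.append((design.ldh_times, DVID_LDH))
        doses = [(s, a, d) for s, a, d in design.regimen]
        for times, dvid in obs_specs:
            t_nom = np.asarray(times, dtype=float)
            at_dose = np.isclose(t_nom[:, None], dose_starts[None, :]).any(axis=1)
            t_obs = np.where(at_dose & (t_nom > 0), t_nom - TROUGH_OFFSET_H, t_nom)
            conc = np.asarray(two_compartment_conc(
                t_obs, doses, ind.cl, ind.vc, ind.vp, ind.q), dtype=float)
            if dvid == DVID_PK:
                pred, sig = conc, truth.sigma_pk
            elif dvid == DVID_PD:
                pred, sig = np.asarray(tca_response(conc, ind), dtype=float), truth.sigma_pd
            else:
                tca = np.asarray(tca_response(conc, ind), dtype=float)
                pred, sig = np.asarray(ldh_response(tca, ind), dtype=float), truth.sigma_ldh
            eps = rng.standard_normal(pred.size)
            dv = pred * (1.0 + sig.prop * eps) if sig.kind == "proportional" else \
                pred + np.sqrt(residual_sd2(pred, sig)) * eps
            for t, v in zip(t_obs, dv):
                rows.append({**base, "TIME": t, "EVID": 0, "DV": v,
                             "DVID": dvid, "PER": period(t),
                             "TRT": trt_of[period(t)], "SEQ": seq})

    df = pd.DataFrame(rows)
    ds = StudyDataset(df, lloq_pk=design.lloq_pk, metadata={"study": design.study})
    ds, _ = apply_missingness_rules(ds)
    # per-subject realized parameters: not part of the analysis dataset, but
    # kept in metadata so simulation studies can verify the generator
    ds.metadata["true_individual_parameters"] = pd.DataFrame(truth_rows)
    return ds


def residual_sd2(pred, sigma: SigmaModel):
    from ecupop.structural import residual_variance
    return residual_variance(np.abs(pred), sigma)


def simulate_pooled(truth: TruthParameters, seed, n_phase1: int = 240,
                    n_phase3: int = 49) -> StudyDataset:
    """Simulate both studies and pool them into one dataset."""
    rng = np.random.default_rng(seed)
    ds1 = simulate_study(phase1_design(n_phase1), truth, rng)
    if n_phase3 <= 0:
        return ds1
    ds3 = simulate_study(phase3_design(n_phase3), truth, rng, id_offset=n_phase1)
    df = pd.concat([ds1.df, ds3.df], ignore_index=True)
    pooled = StudyDataset(df, lloq_pk=ds1.lloq_pk,
                          metadata={"study": "pooled"})
    pooled, _ = apply_missingness_rules(pooled)
    pooled.metadata["true_individual_parameters"] = pd.concat(
        [ds1.metadata["true_individual_parameters"],
         ds3.metadata["true_individual_parameters"]], ignore_index=True)
    return pooled
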