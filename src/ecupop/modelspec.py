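"""Estimation model specifications.

A :class:`ModelSpec` describes one stage of the sequential analysis — PK,
PD (TCA) or efficacy (LDH) — as the FOCE engine sees it: the fixed effects
and their initial values, covariate terms, the eta block, and the residual
error model.  Builders for the final published model structures and for the
covariate-free base models are provided.

Covariate terms follow the two standard pharmacometric forms:

* ``power``: TV = theta_base * (X / X_ref)**theta_term, continuous X
  centred on a reference (weight is centred on 80.9 kg);
* ``categorical``: a separate typical value is estimated for each
  non-reference category level (the reference level keeps theta_base).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from ecupop.dataset_io import DVID_PK, DVID_PD, DVID_LDH
from ecupop.structural import OmegaBlock, SigmaModel

__all__ = [
    "CovariateTerm", "ModelSpec",
    "pk_base_spec", "pk_final_spec", "pd_base_spec", "pd_final_spec",
    "ldh_final_spec", "STAGE_DVID", "STAGE_PARAMS",
]

STAGE_DVID = {"pk": DVID_PK, "pd": DVID_PD, "ldh": DVID_LDH}
STAGE_PARAMS = {
    "pk": ("cl", "vc", "vp", "q"),
    "pd": ("e0", "imax", "ic50", "hill"),
    "ldh": ("ll0", "lmax", "lc50", "lgam"),
}
# outer-transform kinds; imax-like parameters are logit-bounded in (0, 1)
_LOGIT_PARAMS = {"imax"}


@dataclass(frozen=True)
class CovariateTerm:
    """One covariate effect on one structural parameter."""

    param: str                     # structural parameter carrying the effect
    covariate: str                 # dataset column (WT, POP, TRT, AGE, ...)
    form: str                      # "power" | "categorical"
    ref: float | None = None       # power: reference value (None -> data median)
    level: str | None = None       # categorical: the non-reference level
    init: float | None = None      # initial theta (exponent or level TV)

    def __post_init__(self) -> None:
        if self.form not in ("power", "categorical"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "categorical" and self.level is None:
            raise ValueError("categorical terms need a level")

    @property
    def name(self) -> str:
        if self.form == "power":
            return f"{self.param}:{self.covariate}"
        return f"{self.param}:{self.covariate}={self.level}"


@dataclass(frozen=True)
class ModelSpec:
    """Full specification of one estimation stage."""

    stage: str
    theta_init: dict
    covariate_terms: tuple = ()
    eta_names: tuple = ()
    omega_sd_init: dict = field(default_factory=dict)
    omega_corr_init: dict = field(default_factory=dict)   # (a, b) -> rho
    sigma: SigmaModel = SigmaModel("proportional", prop=0.15)
    label: str = ""

    def __post_init__(self) -> None:
        if self.stage not in STAGE_PARAMS:
            raise ValueError(f"unknown stage {self.stage!r}")
        params = STAGE_PARAMS[self.stage]
        missing = set(params) - set(self.theta_init)
        if missing:
            raise ValueError(f"theta_init missing {sorted(missing)}")
        for name in self.eta_names:
            if name not in params:
                raise ValueError(f"eta on unknown parameter {name!r}")
            if name not in self.omega_sd_init:
                raise ValueError(f"omega_sd_init missing {name!r}")
        object.__setattr__(self, "covariate_terms", tuple(self.covariate_terms))

    # -- parameter vector layout -------------------------------------------
    @property
    def params(self) -> tuple:
        return STAGE_PARAMS[self.stage]

    @property
    def theta_names(self) -> tuple:
        return self.params + tuple(t.name for t in self.covariate_terms)

    def theta_transform(self, name: str) -> str:
        """Outer-optimization transform for a theta: log / logit / identity."""
        if name in self.params:
            return "logit" if name in _LOGIT_PARAMS else "log"
        term = next(t for t in self.covariate_terms if t.name == name)
        if term.form == "power":
            return "identity"      # exponents may take either sign
        return "logit" if term.param in _LOGIT_PARAMS else "log"

    def theta_init_vector(self) -> np.ndarray:
        vals = []
        for name in self.theta_names:
            if name in self.params:
                vals.append(self.theta_init[name])
            else:
                term = next(t for t in self.covariate_terms if t.name == name)
                if term.init is not None:
                    vals.append(term.init)
                elif term.form == "power":
                    vals.append(0.5)
                else:
                    vals.append(self.theta_init[term.param])
        return np.asarray(vals, dtype=float)

    def omega_init(self) -> OmegaBlock:
        sd = [self.omega_sd_init[n] for n in self.eta_names]
        return OmegaBlock.from_sd_corr(self.eta_names, sd, self.omega_corr_init)

    def with_term(self, term: CovariateTerm) -> "ModelSpec":
        if term.param not in self.params:
            raise ValueError(f"unknown parameter {term.param!r} for stage {self.stage}")
        return replace(self, covariate_terms=self.covariate_terms + (term,))

    def without_term(self, name: str) -> "ModelSpec":
        kept = tuple(t for t in self.covariate_terms if t.name != name)
        if len(kept) == len(self.covariate_terms):
            raise ValueError(f"no covariate term named {name!r}")
        return replace(self, covariate_terms=kept)

    def with_inits(self, theta: dict | None = None,
                   omega_sd: dict | None = None,
                   omega_corr: dict | None = None,
                   sigma: SigmaModel | None = None) -> "ModelSpec":
        """Return a copy with (some) initial values replaced."""
        new = self
        if theta:
            base = {k: v for k, v in theta.items() if k in self.params}
            new = replace(new, theta_init={**self.theta_init, **base})
            terms = []
            for t in new.covariate_terms:
                terms.append(replace(t, init=theta.get(t.name, t.init)))
            new = replace(new, covariate_terms=tuple(terms))
        if omega_sd:
            new = replace(new, omega_sd_init={**new.omega_sd_init, **omega_sd})
        if omega_corr:
            new = replace(new, omega_corr_init={**new.omega_corr_init, **omega_corr})
        if sigma is not None:
            new = replace(new, sigma=sigma)
        return new


# ---------------------------------------------------------------------------
# builders for the analysis model structures
# ---------------------------------------------------------------------------

def pk_base_spec() -> ModelSpec:
    """Two-compartment PK model before covariate search.

    The healthy/patient difference in Vc is part of the base structure
    (population differences are reflected prior to the covariate analysis);
    weight effects are left to the stepwise search.
    """
    return ModelSpec(
        stage="pk",
        theta_init={"cl": 0.02, "vc": 4.0, "vp": 1.0, "q": 0.02},
        covariate_terms=(
            CovariateTerm("vc", "POP", "categorical", level="PNH", init=5.0),
        ),
        eta_names=("cl", "vc", "vp"),
        omega_sd_init={"cl": 0.2, "vc": 0.2, "vp": 0.3},
        omega_corr_init={("cl", "vc"): 0.3},
        sigma=SigmaModel("proportional", prop=0.15),
        label="PK base (two-compartment, population on Vc)",
    )


def pk_final_spec() -> ModelSpec:
    """Final PK model: weight on CL and Vc, population on Vc."""
    spec = pk_base_spec()
    spec = spec.with_term(CovariateTerm("cl", "WT", "power", ref=80.9, init=0.75))
    spec = spec.with_term(CovariateTerm("vc", "WT", "power", ref=80.9, init=0.75))
    return replace(spec, label="PK final (weight on CL and Vc, population on Vc)")


def pd_base_spec() -> ModelSpec:
    """Inhibitory sigmoid Emax TCA model without population covariates."""
    return ModelSpec(
        stage="pd",
        theta_init={"e0": 90.0, "imax": 0.9, "ic50": 30.0, "hill": 2.0},
        eta_names=("e0", "imax", "ic50"),
        omega_sd_init={"e0": 0.2, "imax": 0.05, "ic50": 0.25},
        sigma=SigmaModel("proportional", prop=0.2),
        label="PD base (inhibitory sigmoid Emax)",
    )


def pd_final_spec() -> ModelSpec:
    """Final TCA model: subject group (healthy vs PNH) on E0 and Imax."""
    spec = pd_base_spec()
    spec = spec.with_term(CovariateTerm("e0", "POP", "categorical", level="PNH", init=95.0))
    spec = spec.with_term(CovariateTerm("imax", "POP", "categorical", level="PNH", init=0.9))
    return replace(spec, label="PD final (population on E0 and Imax)")


def ldh_final_spec() -> ModelSpec:
    """Final efficacy model: stimulatory sigmoid Emax of LDH in TCA."""
    return ModelSpec(
        stage="ldh",
        theta_init={"ll0": 300.0, "lmax": 1500.0, "lc50": 50.0, "lgam": 2.0},
        eta_names=("ll0", "lmax", "lgam"),
        omega_sd_init={"ll0": 0.3, "lmax": 0.5, "lgam": 0.4},
        sigma=SigmaModel("proportional", prop=0.3),
        label="Efficacy final (sigmoid Emax of LDH in TCA)",
    )
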