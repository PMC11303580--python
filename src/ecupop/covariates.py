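"""Stepwise covariate model building and treatment-similarity testing.

Covariate selection follows the standard pharmacometric stepwise procedure:
greedy forward inclusion by likelihood-ratio test at p < 0.05, then backward
elimination keeping only covariates whose removal is significant at
p < 0.01.  Nested models differing by k thetas are compared on a
chi-square(k) scale of the OFV difference.

The biosimilarity question — does the treatment label (biosimilar vs
originator) explain any between-subject variability? — is asked the same
way: the final model is extended with a categorical treatment covariate on
one parameter and refit; a non-significant LRT plus overlapping eta
distributions across arms (:func:`eta_by_group`) support similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ecupop.dataset_io import StudyDataset
from ecupop.foce import EstimationOptions, FitResult, FoceProblem
from ecupop.modelspec import CovariateTerm, ModelSpec

__all__ = [
    "CovariateCandidate", "StepwiseTrace", "TreatmentEffectResult",
    "lrt", "stepwise", "treatment_effect_test", "eta_by_group",
]


@dataclass(frozen=True)
class CovariateCandidate:
    """One candidate covariate-parameter relationship for the search.

    Continuous candidates use the power form centred on ``ref`` (the
    pooled-data median when ``ref`` is None; weight conventionally uses the
    fixed 80.9 kg reference).  Categorical candidates estimate a separate
    typical value per non-reference level.
    """

    param: str
    covariate: str
    form: str = "power"
    ref: float | None = None
    levels: tuple = ()

    def __post_init__(self) -> None:
        if self.form not in ("power", "categorical"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "categorical" and not self.levels:
            raise ValueError("categorical candidates need explicit levels")

    @property
    def name(self) -> str:
        suffix = self.covariate if self.form == "power" \
            else f"{self.covariate}({','.join(self.levels)})"
        return f"{self.param}~{suffix}"

    def terms(self, dataset: StudyDataset) -> list[CovariateTerm]:
        if self.form == "power":
            ref = self.ref
            if ref is None:
                per_subject = dataset.df.groupby("ID", sort=False)[self.covariate].first()
                ref = float(per_subject.median())
            return [CovariateTerm(self.param, self.covariate, "power",
                                  ref=ref, init=0.1)]
        return [CovariateTerm(self.param, self.covariate, "categorical",
                              level=lv) for lv in self.levels]

    @property
    def df(self) -> int:
        return max(1, len(self.levels)) if self.form == "categorical" else 1


def lrt(ofv_reduced: float, ofv_full: float, df: int, slack: float = 0.5) -> float:
    """Likelihood-ratio p-value for nested models fit by the same engine.

    ``delta = OFV_reduced - OFV_full`` is referred to chi-square(df).  A
    slightly negative delta (within numerical ``slack``) is treated as zero
    improvement (p = 1); a strongly negative delta indicates a failed fit
    of the full model and raises.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = ofv_reduced - ofv_full
    if delta < -slack:
        raise ValueError(
            f"full model has higher OFV than reduced by {-delta:.3f}; "
            "check convergence")
    return float(stats.chi2.sf(max(delta, 0.0), df))


@dataclass
class StepwiseTrace:
    """Record of every forward/backward step and the selected model."""

    steps: pd.DataFrame
    final_spec: ModelSpec
    final_fit: FitResult
    base_ofv: float


def _fast_options(options: EstimationOptions | None) -> EstimationOptions:
    opts = options or EstimationOptions()
    return EstimationOptions(
        inner_tol=opts.inner_tol, inner_maxiter=opts.inner_maxiter,
        outer_maxiter=opts.outer_maxiter, outer_maxfun=opts.outer_maxfun,
        outer_ftol=opts.outer_ftol, outer_gtol=opts.outer_gtol,
        outer_restarts=opts.outer_restarts,
        polish_maxfev=opts.polish_maxfev, compute_se=False)


def _warm_spec(spec: ModelSpec, fit: FitResult | None) -> ModelSpec:
    if fit is None:
        return spec
    inits = fit.to_inits()
    return spec.with_inits(theta=inits["theta"], omega_sd=inits["omega_sd"],
                           omega_corr=inits["omega_corr"], sigma=inits["sigma"])


def stepwise(dataset: StudyDataset, base_spec: ModelSpec,
             candidates: list, options: EstimationOptions | None = None,
             forward_alpha: float = 0.05,
             backward_alpha: float = 0.01) -> StepwiseTrace:
    """Forward-inclusion / backward-elimination covariate search.

    Deterministic given the dataset and engine options; at equal p-values
    the earlier-listed candidate wins.
    """
    opts = _fast_options(options)
    current_spec = base_spec
    current_fit = FoceProblem(dataset, current_spec, opts).fit()
    base_ofv = current_fit.ofv
    steps = []
    included: list[CovariateCandidate] = []
    remaining = list(candidates)

    step_no = 0
    while remaining:
        step_no += 1
        results = []
        for cand in remaining:
            try:
                spec_c = _warm_spec(current_spec, current_fit)
                for term in cand.terms(dataset):
                    spec_c = spec_c.with_term(term)
                fit_c = FoceProblem(dataset, spec_c, opts).fit()
                p = lrt(current_fit.ofv, fit_c.ofv, cand.df)
            except (ValueError, np.linalg.LinAlgError) as exc:
                steps.append({"phase": "forward", "step": step_no,
                              "candidate": cand.name, "dofv": np.nan,
                              "df": cand.df, "p": np.nan,
                              "decision": f"skipped ({exc})"})
                continue
            results.append((p, cand, fit_c, spec_c))
            steps.append({"phase": "forward", "step": step_no,
                          "candidate": cand.name,
                          "dofv": current_fit.ofv - fit_c.ofv,
                          "df": cand.df, "p": p, "decision": "tested"})
        winners = [r for r in results if r[0] < forward_alpha]
        if not winners:
            break
        p, cand, fit_c, spec_c = min(winners, key=lambda r: r[0])
        steps.append({"phase": "forward", "step": step_no,
                      "candidate": cand.name,
                      "dofv": current_fit.ofv - fit_c.ofv, "df": cand.df,
                      "p": p, "decision": "included"})
        included.append(cand)
        remaining.remove(cand)
        current_spec, current_fit = spec_c, fit_c

    # backward elimination: drop, one at a time, every included covariate
    # whose removal is not significant at backward_alpha
    changed = True
    while changed and included:
        changed = False
        results = []
        for cand in included:
            spec_r = _warm_spec(current_spec, current_fit)
            for term in cand.terms(dataset):
                spec_r = spec_r.without_term(term.name)
            fit_r = FoceProblem(dataset, spec_r, opts).fit()
            p = lrt(fit_r.ofv, current_fit.ofv, cand.df)
            results.append((p, cand, fit_r, spec_r))
        worst = max(results, key=lambda r: r[0])
        for p, cand, *_ in results:
            steps.append({"phase": "backward", "step": step_no,
                          "candidate": cand.name, "dofv": np.nan,
                          "df": cand.df, "p": p, "decision": "tested"})
        p, cand, fit_r, spec_r = worst
        if p >= backward_alpha:
            steps.append({"phase": "backward", "step": step_no,
                          "candidate": cand.name, "dofv": np.nan,
                          "df": cand.df, "p": p, "decision": "removed"})
            included.remove(cand)
            current_spec, current_fit = spec_r, fit_r
            changed = True

    trace = pd.DataFrame(steps, columns=["phase", "step", "candidate",
                                         "dofv", "df", "p", "decision"])
    return StepwiseTrace(steps=trace, final_spec=current_spec,
                         final_fit=current_fit, base_ofv=base_ofv)


@dataclass
class TreatmentEffectResult:
    """LRT of a treatment covariate on one parameter."""

    param: str
    grouping: str
    dofv: float
    df: int
    p: float
    decision: str
    base_fit: FitResult
    extended_fit: FitResult


def treatment_effect_test(dataset: StudyDataset, final_spec: ModelSpec,
                          param: str, grouping: str = "SB12-vs-ECU",
                          options: EstimationOptions | None = None,
                          base_fit: FitResult | None = None) -> TreatmentEffectResult:
    """Test whether the treatment label explains variability in ``param``.

    ``grouping`` is either ``"SB12-vs-ECU"`` (both originator sources
    pooled; 1 df) or ``"3-level"`` (SB12 / EU-ECU / US-ECU; 2 df).  The
    subject's treatment is the label of their first study period.  Returns
    the LRT outcome; ``decision`` is "no treatment effect" when p >= 0.05.
    """
    if grouping not in ("SB12-vs-ECU", "3-level"):
        raise ValueError(f"unknown grouping {grouping!r}")
    df = dataset.df.copy()
    if grouping == "SB12-vs-ECU":
        df["TRTGROUP"] = np.where(df["TRT"] == "SB12", "SB12", "ECU")
        levels = ("ECU",)
    else:
        df["TRTGROUP"] = df["TRT"]
        levels = ("EU-ECU", "US-ECU")
    per_subject = df.groupby("ID", sort=False)["TRTGROUP"].first()
    present = set(per_subject.unique())
    needed = {"SB12", *levels}
    if not needed <= present:
        raise ValueError(f"grouping levels absent from data: {sorted(needed - present)}")

    ds = StudyDataset(df, dataset.lloq_pk, dict(dataset.metadata))
    opts = _fast_options(options)
    if base_fit is None:
        base_fit = FoceProblem(ds, final_spec, opts).fit()
    spec_ext = _warm_spec(final_spec, base_fit)
    for lv in levels:
        spec_ext = spec_ext.with_term(
            CovariateTerm(param, "TRTGROUP", "categorical", level=lv))
    ext_fit = FoceProblem(ds, spec_ext, opts).fit()
    k = len(levels)
    # the extended model nests the base and starts at its optimum, so any
    # negative delta is numerical; clamp generously rather than fail
    p = lrt(base_fit.ofv, ext_fit.ofv, k, slack=5.0)
    dofv = base_fit.ofv - ext_fit.ofv
    decision = "no treatment effect" if p >= 0.05 else "treatment effect"
    return TreatmentEffectResult(param=param, grouping=grouping, dofv=dofv,
                                 df=k, p=p, decision=decision,
                                 base_fit=base_fit, extended_fit=ext_fit)


def eta_by_group(fit_result: FitResult, dataset: StudyDataset,
                 group: str = "TRT") -> pd.DataFrame:
    """Per-group five-number summaries of the empirical Bayes etas.

    ``group`` names a subject-level dataset column (e.g. TRT, RACE, SEX).
    This is the numeric substrate of the eta boxplots stratified by
    treatment used to inspect biosimilarity.
    """
    df = dataset.df
    if group not in df.columns:
        raise ValueError(f"unknown grouping column {group!r}")
    labels = df.groupby("ID", sort=False)[group].first()
    ebes = fit_result.ebes.copy()
    ebes["group"] = ebes["ID"].map(labels)
    if ebes["group"].isna().any():
        warnings.warn("subjects without a group label omitted from summaries")
        ebes = ebes.dropna(subset=["group"])
    eta_cols = [c for c in ebes.columns if c.startswith("eta_")]
    rows = []
    for (g, ), sub in ebes.groupby(["group"], sort=False):
        for c in eta_cols:
            v = sub[c].to_numpy(float)
            rows.append({"group": g, "eta": c, "n": len(v),
                         "median": float(np.median(v)),
                         "q1": float(np.percentile(v, 25)),
                         "q3": float(np.percentile(v, 75)),
                         "min": float(v.min()), "max": float(v.max())})
    return pd.DataFrame(rows)
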