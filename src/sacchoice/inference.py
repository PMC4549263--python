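"""Mixed-effects inference workflow for accuracy and saccade latency.

The workflow mirrors standard practice for saccadic-choice data:

1. *Random-effect selection.* Two candidate random-intercept structures
   are fit by maximum likelihood — fully crossed (subject, target item,
   distractor item) versus subject-combination (subject, subject:target,
   subject:distractor). They have equal parameter counts, so the one
   with the higher log-likelihood wins; each retained effect must then
   survive a log-likelihood ratio test of the reduced against the full
   model.
2. *Fixed effects.* Task, target position, their interaction, and the
   z-scored trial number, tested by Type III Wald chi-square with
   sum-to-zero contrasts.
3. *Estimates.* The model is refit without intercept (cell means for
   Task at a reference target position) so each task's parameter is its
   log-odds (accuracy) or log-latency directly contrasted against
   chance / the grand scale; the reference level of target position is
   switched to obtain per-hemifield estimates.
4. *Parametric bootstrap.* Confidence intervals come from refitting the
   model to responses simulated from its own estimates (percentile
   method, 10,000 draws for release runs).

Accuracy uses a logit mixed model on trial correctness; latency uses a
linear mixed model on log SRT of correct trials, excluding any task
whose accuracy is at chance, with REML for the final estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .glmm import (
    LinearMixedModel,
    LogitMixedModel,
    MixedFit,
    RandomFactor,
    interaction_factor,
    lrt,
)

ALPHA = 0.05
POSITIONS = ("left", "right")


# ---------------------------------------------------------------------------
# Data preparation and design matrices


def prepare_trials(results: pd.DataFrame) -> pd.DataFrame:
    """Accepted trials with a z-scored trial-number covariate."""
    data = results
    if "status" in data.columns:
        data = data[data["status"] == "accepted"]
    data = data.copy()
    tn = data["trial_index"].astype(float)
    sd = tn.std(ddof=0)
    data["scaled_trial"] = (tn - tn.mean()) / (sd if sd > 0 else 1.0)
    return data


def _task_levels(data: pd.DataFrame) -> list[str]:
    return sorted(data["task"].unique())


def build_fixed_design(
    data: pd.DataFrame,
    no_intercept: bool = False,
    position_ref: str = "left",
    include_trial: bool = True,
    drop_terms: frozenset | set = frozenset(),
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Fixed-effects design matrix for Task * TargetPosition + trial.

    With an intercept, factors use sum-to-zero contrasts (the coding
    under which Type III Wald tests are meaningful). Without intercept,
    Task is cell-means coded and TargetPosition treatment-coded against
    ``position_ref``, so each Task column estimates that task's cell at
    the reference position.

    Returns ``(X, names, terms)`` where ``terms`` maps term name to the
    column indices it spans.
    """
    tasks = _task_levels(data)
    task = np.asarray(data["task"])
    pos = np.asarray(data["target_hemifield"])
    other = [p for p in POSITIONS if p != position_ref][0]
    n = len(data)
    cols: list[np.ndarray] = []
    names: list[str] = []
    terms: dict[str, list[int]] = {}

    def add(term, col, name):
        terms.setdefault(term, []).append(len(cols))
        cols.append(col.astype(float))
        names.append(name)

    if no_intercept:
        for t in tasks:
            add("Task", task == t, f"Task[{t}]")
        if "TargetPosition" not in drop_terms:
            add("TargetPosition", pos == other, f"TargetPosition[{other}]")
        if "Task:TargetPosition" not in drop_terms:
            for t in tasks[1:]:
                add("Task:TargetPosition", (task == t) & (pos == other),
                    f"Task[{t}]:TargetPosition[{other}]")
    else:
        add("Intercept", np.ones(n), "(Intercept)")
        task_sum = {}
        if "Task" not in drop_terms:
            for t in tasks[:-1]:
                c = np.where(task == t, 1.0, np.where(task == tasks[-1], -1.0, 0.0))
                task_sum[t] = c
                add("Task", c, f"Task[S.{t}]")
        pos_c = np.where(pos == POSITIONS[0], 1.0, -1.0)
        if "TargetPosition" not in drop_terms:
            add("TargetPosition", pos_c, "TargetPosition[S.left]")
        if "Task:TargetPosition" not in drop_terms:
            for t in tasks[:-1]:
                c = np.where(task == t, 1.0, np.where(task == tasks[-1], -1.0, 0.0))
                add("Task:TargetPosition", c * pos_c,
                    f"Task[S.{t}]:TargetPosition[S.left]")
    if include_trial and "TrialNumber" not in drop_terms:
        add("TrialNumber", np.asarray(data["scaled_trial"], dtype=float), "scaled_trial")
    return np.column_stack(cols), names, terms


def build_random_factors(data: pd.DataFrame, structure: str) -> list[RandomFactor]:
    """Random-intercept factors for a named candidate structure."""
    subj = np.asarray(data["subject"], dtype=str)
    tgt = np.asarray(data["target_image"], dtype=str)
    dst = np.asarray(data["distractor_image"], dtype=str)
    if structure == "crossed":
        return [
            RandomFactor.from_labels("subject", subj),
            RandomFactor.from_labels("target_item", tgt),
            RandomFactor.from_labels("distractor_item", dst),
        ]
    if structure == "subject_combination":
        return [
            RandomFactor.from_labels("subject", subj),
            interaction_factor("subject:target_item", subj, tgt),
            interaction_factor("subject:distractor_item", subj, dst),
        ]
    raise ValueError(f"unknown structure {structure!r}")


def _make_model(data, response, X, names, factors):
    if response == "correct":
        y = np.asarray(data["correct"], dtype=float)
        return LogitMixedModel(X, y, factors, beta_names=names)
    srt = np.asarray(data["srt"], dtype=float)
    if np.any(srt <= 0):
        raise ValueError("non-positive SRT: log transform undefined")
    return LinearMixedModel(X, np.log(srt), factors, beta_names=names)


# ---------------------------------------------------------------------------
# Random-effect selection


@dataclass
class RandomSelection:
    """Outcome of the random-effect selection procedure."""

    structure: str
    factors: list[RandomFactor]
    retained: list[str]
    lrt_table: pd.DataFrame
    candidate_logliks: list[tuple[str, float]]
    full_fit: MixedFit


def select_random_effects(
    data: pd.DataFrame,
    response: str = "correct",
    candidates: tuple[str, ...] = ("crossed", "subject_combination"),
    alpha: float = ALPHA,
    boundary_mixture: bool = False,
) -> RandomSelection:
    """Choose the random-intercept structure and test each component.

    Candidate structures (equal parameter counts) are fit by ML and
    compared by log-likelihood, the first of any exact ties winning.
    Each random effect of the winning structure is then removed one at
    a time and the reduced model tested against the full one by LRT;
    effects with p < alpha are retained.
    """
    X, names, _ = build_fixed_design(data)
    fits: list[MixedFit] = []
    factor_sets: list[list[RandomFactor]] = []
    for cand in candidates:
        factors = build_random_factors(data, cand)
        model = _make_model(data, response, X, names, factors)
        fits.append(model.fit() if response == "correct" else model.fit("ML"))
        factor_sets.append(factors)
    logliks = [(c, f.loglik) for c, f in zip(candidates, fits)]
    best_ll = max(ll for _, ll in logliks)
    # first candidate wins exact ties
    best_i = next(i for i, (_, ll) in enumerate(logliks) if ll >= best_ll - 1e-9)
    best = candidates[best_i]
    factors = factor_sets[best_i]
    full = fits[best_i]
    rows = []
    retained = []
    for k, f in enumerate(factors):
        reduced_factors = [g for j, g in enumerate(factors) if j != k]
        model = _make_model(data, response, X, names, reduced_factors)
        red = model.fit() if response == "correct" else model.fit("ML")
        stat, df, p = lrt(full, red, boundary_mixture=boundary_mixture)
        rows.append({"random_effect": f.name, "statistic": stat, "df": df, "p": p})
        if p < alpha:
            retained.append(f.name)
    table = pd.DataFrame(rows)
    kept = [f for f in factors if f.name in retained] or factors[:1]
    return RandomSelection(
        structure=best, factors=kept, retained=retained,
        lrt_table=table, candidate_logliks=logliks, full_fit=full,
    )


# ---------------------------------------------------------------------------
# Type III tests and bootstrap


def type3_table(fit: MixedFit, terms: dict[str, list[int]]) -> pd.DataFrame:
    """Type III Wald chi-square test for each fixed-effect term.

    Requires the sum-contrast parameterization (with intercept). Each
    term's statistic is ``b' V^{-1} b`` over its coefficient block.
    """
    rows = []
    for term, idx in terms.items():
        if term == "Intercept":
            continue
        b = fit.beta[idx]
        V = fit.vcov_beta[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        rows.append({"term": term, "statistic": stat, "df": df,
                     "p": float(chi2.sf(stat, df))})
    return pd.DataFrame(rows)


def parametric_bootstrap_ci(
    model,
    fit: MixedFit,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_failure_rate: float = 0.10,
) -> pd.DataFrame:
    """Percentile bootstrap CIs by simulate-and-refit from the fit.

    Responses are simulated from the fitted parameters, the model refit
    to each (warm-started at the fitted variance parameters), and the
    percentile interval taken per fixed-effect parameter. Refits that
    fail are dropped; more than ``max_failure_rate`` failures is an
    error.
    """
    rng = np.random.default_rng(seed)
    draws = np.full((n_boot, len(fit.beta)), np.nan)
    failures = 0
    kwargs = {"coarse": True}
    if fit.method in ("ML", "REML"):
        kwargs["method"] = fit.method
    for b in range(n_boot):
        y_sim = model.simulate(fit, rng)
        try:
            refit = model.refit(y_sim, theta0=fit.theta.copy(), **kwargs)
            draws[b] = refit.beta
        except (np.linalg.LinAlgError, ValueError):
            failures += 1
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    good = draws[~np.isnan(draws).any(axis=1)]
    alpha2 = (1.0 - level) / 2.0
    lo = np.quantile(good, alpha2, axis=0)
    hi = np.quantile(good, 1.0 - alpha2, axis=0)
    return pd.DataFrame(
        {"parameter": fit.beta_names, "estimate": fit.beta, "ci_lo": lo,
         "ci_hi": hi, "n_boot": n_boot - failures}
    )


# ---------------------------------------------------------------------------
# Top-level model fits


@dataclass
class FitReport:
    """A fitted mixed model with tests, estimates and bootstrap CIs."""

    response: str
    structure: str
    random_effects: list[str]
    type3: pd.DataFrame
    estimates: pd.DataFrame  # per reference level, with bootstrap CIs
    fits_by_ref: dict[str, MixedFit]
    selection: RandomSelection | None = None
    above_chance: dict[str, bool] | None = None
    n_boot: int = 0
    seed: int = 0

    @property
    def log_likelihood(self) -> float:
        return self.fits_by_ref[POSITIONS[0]].loglik

    def chance_tasks(self) -> set[str]:
        if self.above_chance is None:
            return set()
        return {t for t, above in self.above_chance.items() if not above}


def _estimate_table(model, fit, n_boot, seed, ref):
    ci = parametric_bootstrap_ci(model, fit, n_boot=n_boot, seed=seed)
    ci.insert(1, "position_ref", ref)
    return ci


def fit_accuracy_model(
    data: pd.DataFrame,
    structure: str | RandomSelection | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = ALPHA,
) -> FitReport:
    """Logit mixed model on trial correctness.

    Runs random-effect selection (unless a structure is supplied), Type
    III Wald tests on the sum-coded ML fit, then the no-intercept
    reparameterization at both target-position reference levels with
    parametric-bootstrap CIs. A task is above chance if its log-odds CI
    excludes 0 in both hemifields. Cells with 0% or 100% accuracy are
    flagged (complete separation: the log-odds estimate diverges).
    """
    data = prepare_trials(data)
    selection = None
    if structure is None:
        selection = select_random_effects(data, "correct", alpha=alpha)
        factors = selection.factors
        structure_name = selection.structure
    elif isinstance(structure, RandomSelection):
        selection = structure
        factors = selection.factors
        structure_name = selection.structure
    else:
        factors = build_random_factors(data, structure)
        structure_name = structure

    _warn_separation(data)
    X, names, terms = build_fixed_design(data)
    full = _make_model(data, "correct", X, names, factors).fit()
    t3 = type3_table(full, terms)

    fits, tables = {}, []
    for i, ref in enumerate(POSITIONS):
        Xr, nr, _ = build_fixed_design(data, no_intercept=True, position_ref=ref)
        model = _make_model(data, "correct", Xr, nr, factors)
        fit = model.fit(theta0=full.theta.copy())
        fits[ref] = fit
        tables.append(_estimate_table(model, fit, n_boot, seed + i, ref))
    estimates = pd.concat(tables, ignore_index=True)

    above = {}
    for task in _task_levels(data):
        rows = estimates[estimates["parameter"] == f"Task[{task}]"]
        above[task] = bool(np.all(rows["ci_lo"] > 0) or np.all(rows["ci_hi"] < 0))
    return FitReport(
        response="correct", structure=structure_name,
        random_effects=[f.name for f in factors], type3=t3,
        estimates=estimates, fits_by_ref=fits, selection=selection,
        above_chance=above, n_boot=n_boot, seed=seed,
    )


def _warn_separation(data: pd.DataFrame) -> None:
    import warnings

    cell = data.groupby(["task", "target_hemifield"])["correct"].mean()
    bad = cell[(cell == 0.0) | (cell == 1.0)]
    if len(bad):
        warnings.warn(
            "complete separation in cells "
            f"{list(bad.index)}: log-odds estimates unbounded"
        )


def fit_rt_model(
    data: pd.DataFrame,
    chance_tasks: set[str] | frozenset = frozenset(),
    structure: str | RandomSelection | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = ALPHA,
) -> FitReport:
    """Linear mixed model on log SRT of correct trials.

    Tasks in ``chance_tasks`` (accuracy indistinguishable from chance)
    are excluded. Selection and Type III tests use ML; final estimates
    use REML. Estimates are reported on the log scale and exponentiated
    to the millisecond / ratio scale.
    """
    data = prepare_trials(data)
    data = data[data["correct"].astype(bool)]
    if chance_tasks:
        data = data[~data["task"].isin(chance_tasks)]
    if len(data) == 0:
        raise ValueError("no correct trials left after exclusions")

    selection = None
    if structure is None:
        selection = select_random_effects(data, "log_srt", alpha=alpha)
        factors = selection.factors
        structure_name = selection.structure
    elif isinstance(structure, RandomSelection):
        selection = structure
        factors = selection.factors
        structure_name = selection.structure
    else:
        factors = build_random_factors(data, structure)
        structure_name = structure

    X, names, terms = build_fixed_design(data)
    ml_fit = _make_model(data, "log_srt", X, names, factors).fit("ML")
    t3 = type3_table(ml_fit, terms)

    fits, tables = {}, []
    for i, ref in enumerate(POSITIONS):
        Xr, nr, _ = build_fixed_design(data, no_intercept=True, position_ref=ref)
        model = _make_model(data, "log_srt", Xr, nr, factors)
        fit = model.fit("REML", theta0=ml_fit.theta.copy())
        fits[ref] = fit
        tab = _estimate_table(model, fit, n_boot, seed + i, ref)
        tab["exp_estimate"] = np.exp(tab["estimate"])
        tab["exp_ci_lo"] = np.exp(tab["ci_lo"])
        tab["exp_ci_hi"] = np.exp(tab["ci_hi"])
        tables.append(tab)
    estimates = pd.concat(tables, ignore_index=True)
    return FitReport(
        response="log_srt", structure=structure_name,
        random_effects=[f.name for f in factors], type3=t3,
        estimates=estimates, fits_by_ref=fits, selection=selection,
        n_boot=n_boot, seed=seed,
    )
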