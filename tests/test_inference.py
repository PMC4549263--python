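import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import sacchoice as sc
from sacchoice.glmm import RandomFactor
from sacchoice.inference import (
    build_fixed_design,
    build_random_factors,
    fit_accuracy_model,
    fit_rt_model,
    parametric_bootstrap_ci,
    prepare_trials,
    select_random_effects,
    type3_table,
    _make_model,
)

from conftest import make_results_frame


def planted_accuracy_frame(rng, n, task_p, subject_sd=0.0, item_sd=0.0,
                           trial_slope=0.0, n_subjects=6, n_images=9):
    """Per-trial correctness from a planted logistic model."""
    tasks = list(task_p)
    subj_eff = rng.normal(0, subject_sd, n_subjects)
    item_eff = rng.normal(0, item_sd, n_images)
    rows = []
    k = len(tasks)
    for i in range(n):
        task = tasks[i % k]
        subject = (i // (2 * k)) % n_subjects
        d_img = rng.integers(n_images)
        scaled = (i - n / 2) / (n / np.sqrt(12))
        p0 = task_p[task]
        eta = (np.log(p0 / (1 - p0)) + subj_eff[subject] + item_eff[d_img]
               + trial_slope * scaled)
        rows.append({
            "subject": f"s{subject}", "task": task,
            "target_hemifield": "left" if (i // k) % 2 == 0 else "right",
            "target_image": f"t{rng.integers(n_images)}",
            "distractor_image": f"d{d_img}",
            "trial_index": i + 1, "status": "accepted",
            "correct": bool(rng.random() < expit(eta)),
            "srt": float(max(80.0, rng.normal(190, 20))),
        })
    return pd.DataFrame(rows)


def test_trial_number_is_z_scored():
    rng = np.random.default_rng(0)
    df = prepare_trials(make_results_frame(rng, 300, {"A vs. B": (0.8, 180.0)}))
    assert df["scaled_trial"].mean() == pytest.approx(0.0, abs=1e-12)
    assert df["scaled_trial"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)


def test_design_matrix_shapes_and_rank():
    rng = np.random.default_rng(1)
    df = prepare_trials(make_results_frame(
        rng, 600, {t: (0.8, 180.0) for t in ["A vs. B", "B vs. A", "C vs. D"]}
    ))
    X, names, terms = build_fixed_design(df)
    assert X.shape[1] == 1 + 2 + 1 + 2 + 1  # intercept, task, pos, interaction, trial
    assert np.linalg.matrix_rank(X) == X.shape[1]
    Xn, names_n, _ = build_fixed_design(df, no_intercept=True)
    assert Xn.shape[1] == X.shape[1]
    assert np.linalg.matrix_rank(Xn) == Xn.shape[1]
    # same column space: projection residuals vanish
    proj = Xn @ np.linalg.lstsq(Xn, X, rcond=None)[0]
    assert np.allclose(proj, X, atol=1e-8)


def test_reparameterization_invariance_lmm_and_glmm():
    """Intercept/no-intercept and either reference level give one likelihood."""
    rng = np.random.default_rng(2)
    df = prepare_trials(make_results_frame(
        rng, 900, {"A vs. B": (0.9, 170.0), "B vs. A": (0.8, 200.0)},
        subject_sd=0.3,
    ))
    factors = build_random_factors(df, "crossed")
    lls = {"correct": [], "log_srt": []}
    for response in lls:
        data = df if response == "correct" else df[df["correct"]]
        for kwargs in ({}, {"no_intercept": True, "position_ref": "left"},
                       {"no_intercept": True, "position_ref": "right"}):
            X, names, _ = build_fixed_design(data, **kwargs)
            fr = build_random_factors(data, "crossed")
            model = _make_model(data, response, X, names, fr)
            fit = model.fit() if response == "correct" else model.fit("ML")
            lls[response].append(fit.loglik)
    assert np.ptp(lls["log_srt"]) < 1e-6
    assert np.ptp(lls["correct"]) < 1e-3


def test_accuracy_model_recovers_planted_log_odds():
    rng = np.random.default_rng(3)
    df = planted_accuracy_frame(rng, 2400, {"chance": 0.5, "easy": 0.731})
    rep = fit_accuracy_model(df, structure="crossed", n_boot=150, seed=1)
    est = rep.estimates
    left = est[est.position_ref == "left"].set_index("parameter")
    # logit(0.5) = 0 and logit(0.731) ~ 1.0
    assert left.loc["Task[chance]", "estimate"] == pytest.approx(0.0, abs=0.25)
    assert left.loc["Task[easy]", "estimate"] == pytest.approx(1.0, abs=0.25)
    assert left.loc["Task[chance]", "ci_lo"] < 0 < left.loc["Task[chance]", "ci_hi"]
    assert rep.above_chance == {"chance": False, "easy": True}
    assert rep.chance_tasks() == {"chance"}


def test_accuracy_model_recovers_negative_trial_slope():
    rng = np.random.default_rng(4)
    df = planted_accuracy_frame(rng, 2400, {"A": 0.8}, trial_slope=-0.5)
    rep = fit_accuracy_model(df, structure="crossed", n_boot=80, seed=2)
    est = rep.estimates
    sl = est[(est.parameter == "scaled_trial") & (est.position_ref == "left")].iloc[0]
    assert sl.estimate < 0
    assert sl.ci_hi < 0


def test_rt_model_recovers_planted_task_ratio():
    rng = np.random.default_rng(5)
    df = make_results_frame(
        rng, 3000, {"fast": (1.0, 170.0), "slow": (1.0, 200.0)}, latency_sd=5.0
    )
    rep = fit_rt_model(df, structure="crossed", n_boot=80, seed=3)
    est = rep.estimates
    left = est[est.position_ref == "left"].set_index("parameter")
    ratio = left.loc["Task[slow]", "exp_estimate"] / left.loc["Task[fast]", "exp_estimate"]
    assert ratio == pytest.approx(200.0 / 170.0, rel=0.01)
    assert left.loc["Task[fast]", "exp_estimate"] == pytest.approx(170.0, rel=0.01)


def test_rt_model_excludes_chance_task_and_incorrect_trials():
    rng = np.random.default_rng(6)
    df = make_results_frame(
        rng, 1200, {"good": (0.9, 180.0), "chance": (0.5, 195.0)}
    )
    rep = fit_rt_model(df, chance_tasks={"chance"}, structure="crossed",
                       n_boot=50, seed=4)
    assert not rep.estimates.parameter.str.contains("chance").any()


def test_rt_model_rejects_nonpositive_latencies():
    rng = np.random.default_rng(7)
    df = make_results_frame(rng, 200, {"A": (0.9, 180.0)})
    df.loc[0, "srt"] = 0.0
    with pytest.raises(ValueError, match="log"):
        fit_rt_model(df, structure="crossed", n_boot=10, seed=0)


def test_random_selection_tie_break_prefers_first_candidate():
    rng = np.random.default_rng(8)
    df = prepare_trials(make_results_frame(rng, 500, {"A": (0.85, 180.0)}))
    sel = select_random_effects(df, "log_srt", candidates=("crossed", "crossed"))
    assert sel.structure == "crossed"
    lls = [ll for _, ll in sel.candidate_logliks]
    assert lls[0] == pytest.approx(lls[1], abs=1e-9)


def test_planted_item_variance_is_retained():
    rng = np.random.default_rng(9)
    retained = 0
    for rep in range(8):
        df = make_results_frame(rng, 700, {"A": (0.8, 190.0)})
        item_eff = {f"d{i}": rng.normal(0, 0.25) for i in range(9)}
        df["srt"] = df["srt"] * np.exp([item_eff[d] for d in df.distractor_image])
        sel = select_random_effects(prepare_trials(df), "log_srt")
        if "distractor_item" in sel.retained:
            retained += 1
    assert retained >= 6  # SD 0.25 on log scale is a large planted effect


def test_null_subject_variance_rarely_significant():
    rng = np.random.default_rng(10)
    significant = 0
    n_rep = 20
    for rep in range(n_rep):
        df = make_results_frame(rng, 400, {"A": (0.8, 190.0)})
        sel = select_random_effects(prepare_trials(df), "log_srt")
        if "subject" in sel.retained:
            significant += 1
    # naive chi-square(1) on a boundary-null true rate is ~2.5%
    assert significant <= 4


def test_bootstrap_ci_degenerates_without_noise():
    rng = np.random.default_rng(11)
    df = prepare_trials(make_results_frame(
        rng, 400, {"A": (1.0, 180.0)}, latency_sd=1e-9
    ))
    X, names, _ = build_fixed_design(df)
    model = _make_model(df, "log_srt", X, names, [])
    fit = model.fit("ML")
    ci = parametric_bootstrap_ci(model, fit, n_boot=50, seed=0)
    assert np.allclose(ci.ci_lo, ci.estimate, atol=1e-6)
    assert np.allclose(ci.ci_hi, ci.estimate, atol=1e-6)


def test_bootstrap_ci_deterministic_given_seed():
    rng = np.random.default_rng(12)
    df = prepare_trials(make_results_frame(rng, 400, {"A": (0.8, 180.0)}))
    X, names, _ = build_fixed_design(df)
    factors = build_random_factors(df, "crossed")
    model = _make_model(df, "log_srt", X, names, factors)
    fit = model.fit("REML")
    a = parametric_bootstrap_ci(model, fit, n_boot=40, seed=9)
    b = parametric_bootstrap_ci(model, fit, n_boot=40, seed=9)
    assert a.equals(b)


def test_type3_detects_planted_task_effect_and_not_position():
    rng = np.random.default_rng(13)
    df = make_results_frame(
        rng, 2000, {"fast": (1.0, 170.0), "slow": (1.0, 210.0)}, latency_sd=15.0
    )
    data = prepare_trials(df)
    X, names, terms = build_fixed_design(data)
    model = _make_model(data, "log_srt", X, names, [])
    tab = type3_table(model.fit("ML"), terms)
    tab = tab.set_index("term")
    assert tab.loc["Task", "p"] < 1e-10
    assert tab.loc["TargetPosition", "p"] > 0.001  # nothing planted
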