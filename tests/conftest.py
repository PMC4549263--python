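import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def one_subject_design():
    import sacchoice as sc

    return sc.build_design(1, seed=101)


@pytest.fixture(scope="session")
def detected_battery():
    """A detected 2-subject simulated experiment at default noise."""
    import sacchoice as sc

    design = sc.build_design(2, seed=11)
    dataset = sc.simulate_experiment(design, seed=11)
    results = sc.detect_all(dataset)
    return dataset, results


def make_results_frame(
    rng: np.random.Generator,
    n_trials: int,
    tasks: dict[str, tuple[float, float]],
    n_subjects: int = 4,
    n_images: int = 9,
    subject_sd: float = 0.0,
    latency_sd: float = 25.0,
) -> pd.DataFrame:
    """Planted per-trial results (no traces): accuracy and mean SRT per task.

    ``tasks`` maps task label -> (p_correct, mean_srt_ms). Latencies are
    normal, truncated at 80 ms. ``subject_sd`` adds a per-subject
    log-odds shift to the planted accuracy.
    """
    task_names = list(tasks)
    rows = []
    subj_eff = rng.normal(0.0, subject_sd, n_subjects)
    k = len(task_names)
    for i in range(n_trials):
        # cycle task, hemifield and subject at different rates so the
        # factors stay crossed, not confounded
        task = task_names[i % k]
        p, srt_mean = tasks[task]
        subject = (i // (2 * k)) % n_subjects
        logit = np.log(p / (1 - p)) if 0 < p < 1 else np.inf * np.sign(p - 0.5)
        p_eff = 1.0 / (1.0 + np.exp(-(logit + subj_eff[subject]))) if np.isfinite(logit) else p
        rows.append(
            {
                "subject": f"s{subject}",
                "task": task,
                "target_hemifield": "left" if (i // k) % 2 == 0 else "right",
                "target_image": f"t{rng.integers(n_images)}",
                "distractor_image": f"d{rng.integers(n_images)}",
                "trial_index": i + 1,
                "status": "accepted",
                "correct": bool(rng.random() < p_eff),
                "srt": float(max(80.0, rng.normal(srt_mean, latency_sd))),
            }
        )
    return pd.DataFrame(rows)
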