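"""Experimental design generator for the saccadic-choice task.

The design crosses three stimulus categories (familiar faces, unknown
faces, objects), each represented by 9 images (3 identities x 3 head
orientations). A session has 6 blocks, one per ordered (target category,
distractor category) pair. Each block presents every target image x
distractor image combination (81) once in each hemifield: 162 trials,
18 appearances of each image in the target role per block.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("FamiliarFace", "UnknownFace", "Object")

#: Ordered (target, distractor) category pairs, one block each.
TASKS = tuple(
    (t, d) for t, d in itertools.permutations(CATEGORIES, 2)
)

BLOCKS_PER_SUBJECT = 6
TRIALS_PER_BLOCK = 162
IMAGES_PER_CATEGORY = 9

FIXATION_RANGE_MS = (800, 1600)
BLANK_MS = 200
STIMULUS_MS = 400


def category_images(category: str) -> list[str]:
    """The 9 image IDs of a category: 3 identities x 3 orientations."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return [
        f"{category}_id{i}_or{o}"
        for i in range(1, 4)
        for o in range(1, 4)
    ]


@dataclass(frozen=True)
class TrialSpec:
    """Metadata for a single trial."""

    subject: str
    block: int
    trial_index: int  # 1..972 within subject
    task: tuple[str, str]  # (target category, distractor category)
    target_hemifield: str  # "left" | "right"
    target_image: str
    distractor_image: str
    fixation_duration: int  # ms, uniform in [800, 1600]
    blank_duration: int = BLANK_MS
    stimulus_duration: int = STIMULUS_MS

    @property
    def task_label(self) -> str:
        return f"{self.task[0]} vs. {self.task[1]}"


@dataclass
class ExperimentDesign:
    """Full trial list for one or more subjects."""

    subjects: list[str]
    trials: list[TrialSpec]
    blocks_per_subject: int = BLOCKS_PER_SUBJECT
    categories: tuple[str, ...] = CATEGORIES
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Trial table as a tidy DataFrame (one row per trial)."""
        return pd.DataFrame(
            {
                "subject": [t.subject for t in self.trials],
                "block": [t.block for t in self.trials],
                "trial_index": [t.trial_index for t in self.trials],
                "target_category": [t.task[0] for t in self.trials],
                "distractor_category": [t.task[1] for t in self.trials],
                "target_hemifield": [t.target_hemifield for t in self.trials],
                "target_image": [t.target_image for t in self.trials],
                "distractor_image": [t.distractor_image for t in self.trials],
                "fixation_duration": [t.fixation_duration for t in self.trials],
                "blank_duration": [t.blank_duration for t in self.trials],
                "stimulus_duration": [t.stimulus_duration for t in self.trials],
            }
        )


def build_design(n_subjects: int, seed: int) -> ExperimentDesign:
    """Generate the full crossed design for ``n_subjects`` subjects.

    Per subject: 6 blocks in a seeded random order, one per ordered
    category pair; within each block a seeded random permutation of the
    162 (target image, distractor image, hemifield) combinations; the
    fixation duration of every trial drawn uniformly from 800-1600 ms.

    Parameters
    ----------
    n_subjects : int
        Number of subjects (the study used 7).
    seed : int
        Seed for the design randomization.

    Returns
    -------
    ExperimentDesign
        ``n_subjects * 972`` trials.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = [f"s{i:02d}" for i in range(1, n_subjects + 1)]
    trials: list[TrialSpec] = []
    for subject in subjects:
        block_order = rng.permutation(len(TASKS))
        trial_index = 0
        for block_num, task_i in enumerate(block_order, start=1):
            target_cat, distractor_cat = TASKS[task_i]
            combos = [
                (ti, di, hemi)
                for ti in category_images(target_cat)
                for di in category_images(distractor_cat)
                for hemi in ("left", "right")
            ]
            order = rng.permutation(len(combos))
            for k in order:
                ti, di, hemi = combos[k]
                trial_index += 1
                trials.append(
                    TrialSpec(
                        subject=subject,
                        block=block_num,
                        trial_index=trial_index,
                        task=(target_cat, distractor_cat),
                        target_hemifield=hemi,
                        target_image=ti,
                        distractor_image=di,
                        fixation_duration=int(
                            rng.integers(FIXATION_RANGE_MS[0], FIXATION_RANGE_MS[1] + 1)
                        ),
                    )
                )
    return ExperimentDesign(subjects=subjects, trials=trials, seed=seed)
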