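"""Experimental designs and trial-table construction.

Two designs are modelled after the study layout:

* a **pattern localizer** with intact scenes — indoor/outdoor x old/new,
  30 trials per condition per run, 12 one-back repeats, 4 runs
  (132 trials/run);
* a **main experiment** with degraded stimuli — indoor/outdoor x
  scene / scene-with-object / object, 30 trials per condition per run,
  18 one-back repeats, 4 runs (198 trials/run).

Within a subject the 30 scene exemplars per category are split into two
fixed sets of 15: one set is shown as scene-with-object, the other as
scene-alone, with the assignment swapped on odd subject indices so the
split is counterbalanced across subjects.  Objects-alone carry the
foreground objects of the scene-alone set, so no pixel content repeats
between scene-with-object and object-alone within a subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TRIAL_COLUMNS

CATEGORIES = ("indoor", "outdoor")

MAIN_CONDITIONS = ("scene", "scene_with_object", "object")
LOCALIZER_CONDITIONS = ("old", "new")


@dataclass
class ExperimentDesign:
    """Trial structure of one experiment.

    ``conditions`` holds (condition-label, category-label) pairs;
    ``exemplars`` maps each pair to the list of exemplar ids it draws
    from.  Every exemplar of a condition is shown equally often per run,
    so ``trials_per_condition_per_run`` must be divisible by the number
    of exemplars.
    """

    experiment_name: str
    conditions: list[tuple[str, str]]
    exemplars: dict[tuple[str, str], list[str]]
    n_runs: int = 4
    trials_per_condition_per_run: int = 30
    onebacks_per_run: int = 18
    fixation_ms: float = 500.0
    stimulus_ms: float = 83.0
    iti_min_ms: float = 1200.0
    iti_max_ms: float = 1600.0

    def __post_init__(self) -> None:
        for key in self.conditions:
            n_ex = len(self.exemplars[key])
            if n_ex == 0 or self.trials_per_condition_per_run % n_ex:
                raise ValueError(
                    f"trials_per_condition_per_run="
                    f"{self.trials_per_condition_per_run} is not an integer "
                    f"multiple of the {n_ex} exemplars of condition {key}; "
                    "each exemplar must repeat equally often per run"
                )
        if self.onebacks_per_run < 0:
            raise ValueError("onebacks_per_run must be >= 0")
        if self.iti_max_ms < self.iti_min_ms:
            raise ValueError("iti_max_ms < iti_min_ms")

    @property
    def n_nontarget_per_run(self) -> int:
        return self.trials_per_condition_per_run * len(self.conditions)

    @property
    def n_trials_per_run(self) -> int:
        return self.n_nontarget_per_run + self.onebacks_per_run


def _scene_ids(category: str, lo: int, hi: int, prefix: str = "s") -> list[str]:
    return [f"{category[:3]}_{prefix}{i:02d}" for i in range(lo, hi + 1)]


def main_experiment_design(subject_parity: int = 0, n_runs: int = 4) -> ExperimentDesign:
    """Degraded-stimulus experiment: 6 conditions, 198 trials/run.

    ``subject_parity`` (0 or 1) swaps which half of the 30 scenes per
    category is shown with its foreground object.
    """
    exemplars: dict[tuple[str, str], list[str]] = {}
    conditions: list[tuple[str, str]] = []
    for cat in CATEGORIES:
        half_a = _scene_ids(cat, 1, 15)
        half_b = _scene_ids(cat, 16, 30)
        if subject_parity % 2:
            half_a, half_b = half_b, half_a
        # scenes from half_a appear with their object; half_b scenes appear
        # alone and donate their objects to the object-alone condition.
        assignment = {
            "scene_with_object": half_a,
            "scene": half_b,
            "object": [e.replace("_s", "_obj") for e in half_b],
        }
        for cond in MAIN_CONDITIONS:
            conditions.append((cond, cat))
            exemplars[(cond, cat)] = assignment[cond]
    return ExperimentDesign(
        experiment_name="main",
        conditions=conditions,
        exemplars=exemplars,
        n_runs=n_runs,
        onebacks_per_run=18,
    )


def localizer_design(n_runs: int = 4) -> ExperimentDesign:
    """Intact-scene pattern localizer: 4 conditions, 132 trials/run."""
    exemplars: dict[tuple[str, str], list[str]] = {}
    conditions: list[tuple[str, str]] = []
    for cat in CATEGORIES:
        exemplars[("old", cat)] = _scene_ids(cat, 1, 30, prefix="old")
        exemplars[("new", cat)] = _scene_ids(cat, 1, 30, prefix="new")
        conditions.extend([("old", cat), ("new", cat)])
    return ExperimentDesign(
        experiment_name="localizer",
        conditions=conditions,
        exemplars=exemplars,
        n_runs=n_runs,
        onebacks_per_run=12,
    )


def build_trial_table(design: ExperimentDesign, seed: int) -> pd.DataFrame:
    """Randomized trial table over all runs of a design.

    Non-target trials of each condition cover that condition's exemplars
    equally often per run, randomly intermixed within run.  One-back
    target rows are then inserted as immediate repeats of randomly chosen
    preceding trials (same exemplar and condition).  Inter-trial
    intervals are drawn uniformly from [iti_min_ms, iti_max_ms].
    """
    rng = np.random.default_rng(seed)
    frames = []
    for run in range(1, design.n_runs + 1):
        rows = []
        for cond, cat in design.conditions:
            ex = design.exemplars[(cond, cat)]
            reps = design.trials_per_condition_per_run // len(ex)
            for e in ex:
                rows.extend([(cond, cat, e)] * reps)
        order = rng.permutation(len(rows))
        rows = [rows[i] for i in order]
        if design.onebacks_per_run:
            bases = np.sort(
                rng.choice(len(rows), size=design.onebacks_per_run, replace=False)
            )[::-1]
            for b in bases:  # insert from the back so indices stay valid
                rows.insert(int(b) + 1, rows[int(b)] + ("oneback",))
        table = pd.DataFrame(
            {
                "trial_index": np.arange(len(rows)),
                "run": run,
                "condition": [r[0] for r in rows],
                "category": [r[1] for r in rows],
                "exemplar_id": [r[2] for r in rows],
                "is_oneback": [len(r) == 4 for r in rows],
                "iti_ms": rng.uniform(design.iti_min_ms, design.iti_max_ms, len(rows)),
            }
        )
        frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]
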