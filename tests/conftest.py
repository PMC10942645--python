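import numpy as np
import pandas as pd
import pytest

from conflictspace import behavior_sim, task_design


@pytest.fixture(scope="session")
def profiles6():
    return task_design.make_profiles(6, 3)


@pytest.fixture(scope="session")
def profiles8():
    return task_design.make_profiles(8, 4)


@pytest.fixture(scope="session")
def exp1_small_schedule(profiles6):
    """Experiment-1 structure at a reduced cohort size (6 subjects)."""
    return task_design.build_experiment({"experiment": "exp1", "seed": 7}, profiles6)


@pytest.fixture(scope="session")
def exp2_small_schedule(profiles8):
    return task_design.build_experiment({"experiment": "exp2", "seed": 7}, profiles8)


@pytest.fixture(scope="session")
def small_trials(exp1_small_schedule):
    params = behavior_sim.BehaviorGenParams(seed=21)
    return behavior_sim.simulate_trials(params, exp1_small_schedule)


def make_toy_trials(rows, subject=0, run=0):
    """Tiny trial table from (conflict_type, congruency, rt, accuracy) rows."""
    recs = []
    for i, (ct, congr, rt, acc) in enumerate(rows):
        recs.append(
            dict(
                subject=subject,
                group="TR-BL",
                mapping="up-right",
                session=0,
                run=run,
                trial=i,
                conflict_type=ct,
                congruency=congr,
                direction="up" if i % 2 == 0 else "down",
                polar_angle_deg=0.0,
                correct_response="right" if i % 2 == 0 else "left",
                rt=rt,
                accuracy=acc,
            )
        )
    return pd.DataFrame(recs)
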