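import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_trials(
    subject_id="S1",
    cohort="intervention",
    occasion=1,
    test_id="stroop",
    correct=(True,) * 8 + (False,) * 2,
    rts=None,
    scorable=None,
):
    """Hand-built single-cell trial table."""
    n = len(correct)
    if rts is None:
        rts = [0.5] * n
    if scorable is None:
        scorable = [True] * n
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "cohort": cohort,
            "occasion": occasion,
            "test_id": test_id,
            "trial_index": np.arange(n),
            "stimulus_kind": "congruent",
            "scorable": list(scorable),
            "response_correct": list(correct),
            "rt_seconds": list(rts),
        }
    )


def make_scores(n_subjects=5, occasions=(1, 2, 3, 4), tests=("nback1", "stroop"),
                cohort="control", seed=0, prefix="C"):
    """Random but well-behaved score table covering a full grid."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for occ in occasions:
            for t in tests:
                rows.append(
                    {
                        "subject_id": f"{prefix}{i + 1:02d}",
                        "cohort": cohort,
                        "occasion": occ,
                        "test_id": t,
                        "accuracy": rng.uniform(0.5, 1.0),
                        "mean_rt": rng.uniform(0.4, 1.2),
                        "n_scorable": 28,
                    }
                )
    return pd.DataFrame(rows)
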