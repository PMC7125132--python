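import numpy as np
import pandas as pd
import pytest

from metahistory import GeneratorConfig, TrialTable, simulate_experiment


@pytest.fixture(scope="session")
def default_experiment() -> TrialTable:
    """Full-size default simulation: 15 subjects x 12 blocks x 50 trials."""
    return simulate_experiment(GeneratorConfig(seed=20))


@pytest.fixture(scope="session")
def small_experiment() -> TrialTable:
    """Three subjects with shorter sessions, for fast structural tests."""
    cfg = GeneratorConfig(n_subjects=3, n_blocks=4, trials_per_block=50, seed=11)
    return simulate_experiment(cfg)


def toy_table(
    prospective,
    stimulus=None,
    response=None,
    awareness=None,
    confidence=None,
    subject="s01",
    experiment="belief",
    trials_per_block=None,
) -> TrialTable:
    """Hand-rolled single-subject table from per-trial value lists."""
    n = len(prospective)
    if stimulus is None:
        stimulus = ["left", "right"] * (n // 2 + 1)
        stimulus = stimulus[:n]
    if response is None:
        response = stimulus  # all correct
    if awareness is None:
        awareness = [1, 0] * (n // 2 + 1)
        awareness = awareness[:n]
    if confidence is None:
        confidence = [0, 1] * (n // 2 + 1)
        confidence = confidence[:n]
    tpb = trials_per_block or n
    df = pd.DataFrame(
        {
            "subject": subject,
            "experiment": experiment,
            "block": [i // tpb + 1 for i in range(n)],
            "trial": [i % tpb + 1 for i in range(n)],
            "prospective": prospective,
            "stimulus": stimulus,
            "response": response,
            "correct": [int(r == s) for r, s in zip(response, stimulus)],
            "awareness": awareness,
            "confidence": confidence,
        }
    )
    return TrialTable(df)


def auc_by_pair_enumeration(y, scores) -> float:
    """Exhaustive concordant-pair AUC: independent oracle for ROC AUC."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
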