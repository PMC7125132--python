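"""Cross-experiment transfer decoding.

Trains the lagged logistic decoder on pooled trials from one experiment
(the source) and tests it on pooled trials from the other (the target),
quantifying how much of the history-to-prospective-decision mapping is
shared between decision types.  Per iteration, a random 80% of the
pooled source lag-k design forms the training set and a random 20% of
the pooled target design forms the test set; 100 iterations give the
transfer-AUC distribution, and a permutation null built by independently
shuffling the target design gives the p-value against chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .decoding import (
    DEFAULT_LAGS,
    LaggedDesign,
    _fit_logistic,
    build_lagged_design,
)
from .exceptions import SplitError
from .trial_io import TrialTable


def pooled_design(table: TrialTable, lag: int) -> LaggedDesign:
    """Concatenate every subject's lag-k design into one pooled design.

    Lagged pairs never span subjects: each subject's design is built
    separately, then rows are stacked.
    """
    parts = [build_lagged_design(table, s, lag) for s in table.subjects]
    X = np.concatenate([p.features for p in parts])
    y = np.concatenate([p.target for p in parts])
    return LaggedDesign(lag=lag, features=X, target=y, subject="pooled")


@dataclass
class TransferResult:
    """Transfer decoding outcome for one direction and lag."""

    direction: str
    lag: int
    iteration_aucs: np.ndarray
    null_aucs: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(self.iteration_aucs.mean())

    @property
    def p_value(self) -> float:
        """Permutation p against chance: fraction of null >= observed mean."""
        return float(
            (1 + np.sum(self.null_aucs >= self.mean_auc)) / (1 + len(self.null_aucs))
        )


def _transfer_iterations(
    source: LaggedDesign,
    target: LaggedDesign,
    n_iterations: int,
    train_fraction: float,
    test_fraction: float,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> np.ndarray:
    n_src, n_tgt = len(source), len(target)
    n_train = max(2, round(n_src * train_fraction))
    n_test = max(2, round(n_tgt * test_fraction))
    aucs = np.empty(n_iterations)
    for i in range(n_iterations):
        for _ in range(max_attempts):
            train = rng.permutation(n_src)[:n_train]
            test = rng.permutation(n_tgt)[:n_test]
            if (
                len(np.unique(source.target[train])) == 2
                and len(np.unique(target.target[test])) == 2
            ):
                break
        else:
            raise SplitError("could not draw class-complete transfer sets")
        clf = _fit_logistic(source.features[train], source.target[train])
        scores = clf.predict_proba(target.features[test])[
            :, list(clf.classes_).index(1)
        ]
        aucs[i] = roc_auc_score(target.target[test], scores)
    return aucs


def transfer_decode(
    source: TrialTable,
    target: TrialTable,
    lag: int,
    n_iterations: int = 100,
    train_fraction: float = 0.8,
    test_fraction: float = 0.2,
    seed=None,
) -> TransferResult:
    """Train on the pooled source experiment, test on the pooled target.

    Subjects are concatenated into one dataset per experiment before any
    splitting; draws are fresh each iteration on both sides.  The
    permutation null repeats the procedure after independently shuffling
    the target's feature rows and target entries.
    """
    rng = np.random.default_rng(seed)
    src = pooled_design(source, lag)
    tgt = pooled_design(target, lag)
    direction = f"{source.experiment}->{target.experiment}"

    aucs = _transfer_iterations(
        src, tgt, n_iterations, train_fraction, test_fraction, rng
    )
    # null: destroy the target's feature/target association
    n_tgt = len(tgt)
    shuffled = LaggedDesign(
        lag,
        tgt.features[rng.permutation(n_tgt)],
        tgt.target[rng.permutation(n_tgt)],
        tgt.subject,
    )
    null = _transfer_iterations(
        src, shuffled, n_iterations, train_fraction, test_fraction, rng
    )
    return TransferResult(
        direction=direction, lag=lag, iteration_aucs=aucs, null_aucs=null
    )


class TransferDecodingModel:
    """Bidirectional transfer decoding across the two experiments."""

    def __init__(
        self,
        belief: TrialTable,
        attention: TrialTable,
        lags=DEFAULT_LAGS,
        n_iterations: int = 100,
        train_fraction: float = 0.8,
        test_fraction: float = 0.2,
    ):
        self.belief = belief
        self.attention = attention
        self.lags = tuple(lags)
        self.n_iterations = n_iterations
        self.train_fraction = train_fraction
        self.test_fraction = test_fraction

    def fit(self, seed=None) -> "TransferDecodingResults":
        root = np.random.SeedSequence(seed)
        results = []
        for src, tgt in ((self.belief, self.attention), (self.attention, self.belief)):
            for lag in self.lags:
                results.append(
                    transfer_decode(
                        src,
                        tgt,
                        lag,
                        n_iterations=self.n_iterations,
                        train_fraction=self.train_fraction,
                        test_fraction=self.test_fraction,
                        seed=root.spawn(1)[0],
                    )
                )
        return TransferDecodingResults(self, results, seed)


class TransferDecodingResults:
    def __init__(self, model, results: list[TransferResult], seed):
        self.model = model
        self.results = results
        self.seed = seed

    def transfer_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "direction": r.direction,
                "lag": r.lag,
                "mean_auc": r.mean_auc,
                "p": r.p_value,
            }
            for r in self.results
        )

    def summary(self) -> str:
        lines = [
            "Cross-experiment transfer decoding",
            f"  iterations: {self.model.n_iterations}",
            "",
            f"  {'direction':<22} {'lag':>3} {'mean AUC':>9} {'p':>10}",
        ]
        for r in self.results:
            lines.append(
                f"  {r.direction:<22} {r.lag:>3} {r.mean_auc:>9.4f} {r.p_value:>10.4g}"
            )
        return "\n".join(lines)
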