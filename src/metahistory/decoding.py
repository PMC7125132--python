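"""Trial-history decoding of prospective decisions.

The central analysis: for each subject and each lag k in 1..4, a logistic
model predicts the current prospective decision from the binary triplet
(correctness, awareness, confidence) of the trial k back.  Decoding is
scored by ROC AUC under repeated 80/20 shuffle-split cross-validation
(100 splits), significance is assessed against a permutation null built
by shuffling feature rows and target entries independently, and feature
attribution uses odds ratios from the fold-averaged logistic
coefficients.

The logistic fits use a vanishingly small L2 penalty so the coefficients
are interpretable as (near) maximum-likelihood estimates; the liblinear
coordinate-descent solver is used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .exceptions import ConstantColumnError, SplitError
from .trial_io import TrialTable

FEATURE_COLUMNS = ("correct", "awareness", "confidence")
DEFAULT_LAGS = (1, 2, 3, 4)

#: near-zero regularization: penalty weight 1e-9 relative to the likelihood
_INVERSE_PENALTY = 1e9
_SOLVER_TOL = 1e-8
_MAX_ITER = 10_000


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class LaggedDesign:
    """Single-lag design: features of trial t-k paired with the target at t.

    ``features`` is an (n, 3) binary matrix with columns (correctness,
    awareness, confidence); rows never span subjects.
    """

    lag: int
    features: np.ndarray
    target: np.ndarray
    subject: str

    def __post_init__(self):
        self.features = np.asarray(self.features)
        self.target = np.asarray(self.target)
        if self.features.shape != (len(self.target), len(FEATURE_COLUMNS)):
            raise ValueError("features must be n x 3 aligned with target")

    def __len__(self) -> int:
        return len(self.target)


def build_lagged_design(
    table: TrialTable, subject: str, lag: int, within_block: bool = False
) -> LaggedDesign:
    """Pair the features of trial t-lag with the prospective decision at t.

    Lags run over the subject's concatenated session order; block
    boundaries are not breaks unless ``within_block`` is set, in which
    case pairs spanning a block boundary are dropped.
    """
    g = table.subject(subject)
    n = len(g)
    if not 1 <= lag <= 4:
        raise ValueError(f"lag must be in 1..4, got {lag}")
    if lag >= n:
        raise ValueError(f"subject {subject} has {n} trials, need more than lag={lag}")
    X = g.loc[:, FEATURE_COLUMNS].to_numpy()[:-lag]
    y = g["prospective"].to_numpy()[lag:]
    if within_block:
        same_block = g["block"].to_numpy()[:-lag] == g["block"].to_numpy()[lag:]
        X, y = X[same_block], y[same_block]
    return LaggedDesign(lag=lag, features=X, target=y, subject=subject)


# ---------------------------------------------------------------------------
# logistic fitting and cross-validated AUC
# ---------------------------------------------------------------------------


def _aggregate_binary(X: np.ndarray, y: np.ndarray):
    """Collapse duplicate (row, label) pairs into sample weights.

    The design rows are binary triplets, so a training set has at most 16
    distinct (pattern, label) pairs; fitting the weighted aggregate is
    exactly equivalent to fitting the raw rows and much faster.
    """
    code = X @ (1 << np.arange(X.shape[1])) * 2 + y
    counts = np.bincount(code, minlength=(1 << X.shape[1]) * 2)
    nz = np.nonzero(counts)[0]
    patterns = (nz // 2)[:, None] >> np.arange(X.shape[1]) & 1
    return patterns.astype(np.float64), nz % 2, counts[nz].astype(np.float64)


def _fit_logistic(X_train: np.ndarray, y_train: np.ndarray) -> LogisticRegression:
    clf = LogisticRegression(
        C=_INVERSE_PENALTY,
        solver="liblinear",
        tol=_SOLVER_TOL,
        max_iter=_MAX_ITER,
    )
    is_binary = X_train.dtype.kind in "iub" or np.isin(X_train, (0, 1)).all()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if is_binary and X_train.shape[1] <= 16:
            Xa, ya, w = _aggregate_binary(
                X_train.astype(np.int64), y_train.astype(np.int64)
            )
            clf.fit(Xa, ya, sample_weight=w)
        else:
            clf.fit(X_train, y_train)
    return clf


def _draw_split(rng: np.random.Generator, y: np.ndarray, n_test: int, max_attempts: int):
    """Random 80/20 split; redrawn until both sets contain both classes."""
    n = len(y)
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        if len(np.unique(y[train])) == 2 and len(np.unique(y[test])) == 2:
            return train, test
    raise SplitError(
        f"could not draw a split with both classes in train and test "
        f"within {max_attempts} attempts"
    )


@dataclass
class CVScores:
    """Fold-level output of shuffle-split cross-validated decoding."""

    fold_aucs: np.ndarray  # (n_splits,)
    coefficients: np.ndarray  # (n_splits, 3)
    intercepts: np.ndarray  # (n_splits,)
    fold_targets: list[np.ndarray] | None = None  # held-out targets per fold
    fold_scores: list[np.ndarray] | None = None  # held-out predicted P(1) per fold

    @property
    def mean_auc(self) -> float:
        return float(self.fold_aucs.mean())


def cross_validated_auc(
    design: LaggedDesign,
    n_splits: int = 100,
    test_fraction: float = 0.2,
    seed=None,
    max_attempts: int = 1000,
    record_folds: bool = False,
) -> CVScores:
    """Shuffle-split cross-validated logistic decoding scored by ROC AUC.

    Each of ``n_splits`` folds shuffles the rows, trains the
    near-unregularized logistic model on 80% and scores its probabilistic
    predictions on the held-out 20% by ROC AUC.  Splits lacking a target
    class in either set are redrawn.
    """
    X, y = design.features, design.target
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both target classes must be present in the design")
    rng = np.random.default_rng(seed)
    n_test = max(1, round(len(y) * test_fraction))
    if n_test >= len(y):
        raise ValueError("test_fraction leaves no training rows")

    aucs = np.empty(n_splits)
    coefs = np.empty((n_splits, X.shape[1]))
    intercepts = np.empty(n_splits)
    fold_targets = [] if record_folds else None
    fold_scores = [] if record_folds else None
    for i in range(n_splits):
        train, test = _draw_split(rng, y, n_test, max_attempts)
        clf = _fit_logistic(X[train], y[train])
        scores = clf.predict_proba(X[test])[:, list(clf.classes_).index(1)]
        aucs[i] = roc_auc_score(y[test], scores)
        coefs[i] = clf.coef_[0] if clf.classes_[1] == 1 else -clf.coef_[0]
        intercepts[i] = clf.intercept_[0] if clf.classes_[1] == 1 else -clf.intercept_[0]
        if record_folds:
            fold_targets.append(y[test].copy())
            fold_scores.append(scores.copy())
    return CVScores(aucs, coefs, intercepts, fold_targets, fold_scores)


def empirical_null(
    design: LaggedDesign,
    n_permutations: int = 100,
    n_splits: int = 100,
    test_fraction: float = 0.2,
    seed=None,
) -> np.ndarray:
    """Permutation null for the cross-validated AUC.

    Each iteration permutes the feature rows and the target entries
    independently (destroying any association while preserving both
    marginals) and reruns the full shuffle-split cross-validation; the
    returned array holds each iteration's mean fold AUC.  Its grand mean
    is the empirical chance level, centred on 0.5.
    """
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        Xp = design.features[rng.permutation(len(design))]
        yp = design.target[rng.permutation(len(design))]
        shuffled = LaggedDesign(design.lag, Xp, yp, design.subject)
        null[i] = cross_validated_auc(
            shuffled, n_splits=n_splits, test_fraction=test_fraction,
            seed=rng.integers(2**31),
        ).mean_auc
    return null


# ---------------------------------------------------------------------------
# per-subject decoding result
# ---------------------------------------------------------------------------


@dataclass
class DecodingResult:
    """Decoding outcome for one subject at one lag."""

    subject: str
    lag: int
    fold_aucs: np.ndarray
    coefficients: np.ndarray
    intercepts: np.ndarray
    null_aucs: np.ndarray
    full_data_coefficients: np.ndarray | None = None

    @property
    def mean_auc(self) -> float:
        return float(self.fold_aucs.mean())

    @property
    def empirical_chance(self) -> float:
        return float(self.null_aucs.mean())

    @property
    def p_uncorrected(self) -> float:
        """Subject-level permutation p: fraction of null >= observed (+1 corrected)."""
        return float(
            (1 + np.sum(self.null_aucs >= self.mean_auc)) / (1 + len(self.null_aucs))
        )

    @property
    def p_bonferroni(self) -> float:
        return min(1.0, len(DEFAULT_LAGS) * self.p_uncorrected)


# ---------------------------------------------------------------------------
# group-level inference
# ---------------------------------------------------------------------------


def group_significance(
    results: list[DecodingResult],
    n_resamples: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Group-level permutation t-test of decoding above empirical chance.

    Per lag, the subject-level differences (mean AUC minus empirical
    chance) enter a two-sided sign-flip permutation test:
    ``p = (1 + #{resamples with |mean| >= |observed|}) / (1 + n_resamples)``.
    Bonferroni correction multiplies by the number of lags, capped at 1.
    """
    rng = np.random.default_rng(seed)
    lags = sorted({r.lag for r in results})
    rows = []
    for lag in lags:
        diffs = np.array(
            [r.mean_auc - r.empirical_chance for r in results if r.lag == lag]
        )
        if len(diffs) < 2:
            raise ValueError(f"lag {lag}: need at least 2 subjects")
        observed = abs(diffs.mean())
        signs = rng.choice([-1.0, 1.0], size=(n_resamples, len(diffs)))
        resampled = np.abs((signs * diffs).mean(axis=1))
        p = float((1 + np.sum(resampled >= observed)) / (1 + n_resamples))
        rows.append(
            {
                "lag": lag,
                "n_subjects": len(diffs),
                "mean_diff": float(diffs.mean()),
                "p": p,
                "p_bonferroni": min(1.0, len(lags) * p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# odds ratios
# ---------------------------------------------------------------------------


def bootstrap_ci(
    values: np.ndarray, n_resamples: int = 1000, seed=None, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI of the across-subject mean."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    idx = rng.integers(0, len(values), size=(n_resamples, len(values)))
    means = values[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)


def odds_ratios(
    results: list[DecodingResult],
    n_resamples: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Per-feature odds ratios from the fold-averaged logistic coefficients.

    OR = exp(mean over folds of the coefficient), per subject, lag and
    feature; a feature with no influence has OR near 1.  Across-subject
    percentile-bootstrap 95% CIs (1000 resamples) accompany the
    across-subject mean OR per lag and feature.
    """
    rng = np.random.default_rng(seed)
    per_subject = []
    for r in results:
        mean_coef = r.coefficients.mean(axis=0)
        for j, feature in enumerate(FEATURE_COLUMNS):
            per_subject.append(
                {
                    "subject": r.subject,
                    "lag": r.lag,
                    "feature": feature,
                    "odds_ratio": float(np.exp(mean_coef[j])),
                }
            )
    df = pd.DataFrame(per_subject)
    rows = []
    for (lag, feature), g in df.groupby(["lag", "feature"], sort=True):
        ors = g["odds_ratio"].to_numpy()
        lo, hi = bootstrap_ci(ors, n_resamples=n_resamples, seed=rng.integers(2**31))
        rows.append(
            {
                "lag": lag,
                "feature": feature,
                "mean_or": float(ors.mean()),
                "ci_low": lo,
                "ci_high": hi,
                "n_subjects": len(ors),
            }
        )
    summary = pd.DataFrame(rows)
    return df.merge(summary, on=["lag", "feature"], how="left")


# ---------------------------------------------------------------------------
# univariate diagnostics
# ---------------------------------------------------------------------------


def phi_correlation(x, y) -> float:
    """Phi coefficient between two binary vectors.

    Equals the Pearson correlation, or (ad - bc) / sqrt of the product of
    the 2x2 margins.  Raises ConstantColumnError when either vector is
    constant (the coefficient is then undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("phi requires two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantColumnError("phi undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def atanh_phi(phi: float) -> float:
    """Fisher z (arc-hyperbolic tangent) transform used before t-tests."""
    return float(np.arctanh(phi))


def conditional_probabilities(table: TrialTable, lag: int = 1) -> pd.DataFrame:
    """P(prospective high | lag-1 correctness x awareness x confidence).

    Long-format grid per subject with one row per (correct, aware, conf)
    cell; cells with no qualifying trial pairs are reported with n = 0 and
    a missing probability, never imputed.
    """
    rows = []
    full_index = [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    for subject in table.subjects:
        g = table.subject(subject)
        prev = g.loc[:, FEATURE_COLUMNS].to_numpy()[:-lag]
        target = g["prospective"].to_numpy()[lag:]
        cells = pd.DataFrame(prev, columns=["correct", "awareness", "confidence"])
        cells["target"] = target
        grouped = cells.groupby(["correct", "awareness", "confidence"])["target"].agg(
            ["mean", "size"]
        )
        for key in full_index:
            if key in grouped.index:
                p_high, n = grouped.loc[key, "mean"], grouped.loc[key, "size"]
            else:
                p_high, n = np.nan, 0
            rows.append(
                {
                    "subject": subject,
                    "correct": key[0],
                    "aware": key[1],
                    "conf": key[2],
                    "p_high": float(p_high) if n else np.nan,
                    "n": int(n),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------


class HistoryDecodingModel:
    """Per-subject lagged decoding of the prospective decision.

    Parameters
    ----------
    table
        Validated trial table (one experiment).
    lags
        Lags to decode, a subset of (1, 2, 3, 4).
    n_splits, test_fraction
        Shuffle-split cross-validation settings (default 100 folds, 80/20).
    n_permutations
        Iterations of the independent-shuffle permutation null per subject
        and lag.
    within_block
        Restrict lagged pairs to within-block neighbours (sensitivity
        analysis; default off — lags run over the concatenated session).
    """

    def __init__(
        self,
        table: TrialTable,
        lags=DEFAULT_LAGS,
        n_splits: int = 100,
        test_fraction: float = 0.2,
        n_permutations: int = 100,
        within_block: bool = False,
    ):
        self.table = table
        self.lags = tuple(lags)
        self.n_splits = n_splits
        self.test_fraction = test_fraction
        self.n_permutations = n_permutations
        self.within_block = within_block

    def fit(self, seed=None, refit_full_data: bool = True) -> "HistoryDecodingResults":
        """Run decoding and its permutation null for every subject and lag."""
        root = np.random.SeedSequence(seed)
        results = []
        for subject in self.table.subjects:
            for lag in self.lags:
                cv_seed, null_seed = root.spawn(2)
                design = build_lagged_design(
                    self.table, subject, lag, within_block=self.within_block
                )
                cv = cross_validated_auc(
                    design,
                    n_splits=self.n_splits,
                    test_fraction=self.test_fraction,
                    seed=cv_seed,
                )
                null = empirical_null(
                    design,
                    n_permutations=self.n_permutations,
                    n_splits=self.n_splits,
                    test_fraction=self.test_fraction,
                    seed=null_seed,
                )
                full_coef = None
                if refit_full_data:
                    clf = _fit_logistic(design.features, design.target)
                    full_coef = (
                        clf.coef_[0] if clf.classes_[1] == 1 else -clf.coef_[0]
                    )
                results.append(
                    DecodingResult(
                        subject=subject,
                        lag=lag,
                        fold_aucs=cv.fold_aucs,
                        coefficients=cv.coefficients,
                        intercepts=cv.intercepts,
                        null_aucs=null,
                        full_data_coefficients=full_coef,
                    )
                )
        return HistoryDecodingResults(self, results, seed)


class HistoryDecodingResults:
    """Fitted decoding results with group-level inference and exports."""

    def __init__(self, model: HistoryDecodingModel, results: list[DecodingResult], seed):
        self.model = model
        self.results = results
        self.seed = seed

    def decoding_table(self) -> pd.DataFrame:
        """Per subject x lag: mean AUC, empirical chance, permutation p-values."""
        return pd.DataFrame(
            {
                "subject": r.subject,
                "lag": r.lag,
                "mean_auc": r.mean_auc,
                "chance": r.empirical_chance,
                "p": r.p_uncorrected,
                "p_bonf": r.p_bonferroni,
            }
            for r in self.results
        )

    def group_table(self, n_resamples: int = 10_000, seed=None) -> pd.DataFrame:
        if seed is None:
            seed = _derive_seed(self.seed, "group")
        return group_significance(self.results, n_resamples=n_resamples, seed=seed)

    def odds_ratio_table(self, n_resamples: int = 1000, seed=None) -> pd.DataFrame:
        if seed is None:
            seed = _derive_seed(self.seed, "bootstrap")
        return odds_ratios(self.results, n_resamples=n_resamples, seed=seed)

    def conditional_probability_table(self) -> pd.DataFrame:
        return conditional_probabilities(self.model.table)

    def summary(self, n_resamples: int = 10_000) -> str:
        """Readable group-level summary of decoding performance per lag."""
        dec = self.decoding_table()
        grp = self.group_table(n_resamples=n_resamples)
        lines = [
            "History decoding of the prospective decision",
            f"  experiment: {self.model.table.experiment}, "
            f"subjects: {len(self.model.table.subjects)}, "
            f"splits: {self.model.n_splits}, "
            f"permutations: {self.model.n_permutations}",
            "",
            f"  {'lag':>3} {'mean AUC':>9} {'chance':>8} {'p':>10} {'p(Bonf)':>10}",
        ]
        for _, row in grp.iterrows():
            lag = int(row["lag"])
            mean_auc = dec.loc[dec["lag"] == lag, "mean_auc"].mean()
            chance = dec.loc[dec["lag"] == lag, "chance"].mean()
            lines.append(
                f"  {lag:>3} {mean_auc:>9.4f} {chance:>8.4f} "
                f"{row['p']:>10.4g} {row['p_bonferroni']:>10.4g}"
            )
        return "\n".join(lines)

    def plot_auc(self, ax=None):
        """Mean AUC per lag with bootstrapped 95% CIs across subjects."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dec = self.decoding_table()
        lags = sorted(dec["lag"].unique())
        means, lo, hi = [], [], []
        for lag in lags:
            vals = dec.loc[dec["lag"] == lag, "mean_auc"].to_numpy()
            means.append(vals.mean())
            ci = bootstrap_ci(vals, seed=_derive_seed(self.seed, f"plot{lag}"))
            lo.append(means[-1] - ci[0])
            hi.append(ci[1] - means[-1])
        ax.errorbar(lags, means, yerr=[lo, hi], fmt="o-", capsize=4)
        ax.axhline(0.5, ls="--", color="grey", lw=1)
        ax.set_xlabel("trials back")
        ax.set_ylabel("ROC AUC")
        ax.set_xticks(list(lags))
        return ax


def _derive_seed(seed, label: str) -> int:
    """Deterministic substream seed from a pipeline seed and a stage label."""
    base = 0 if seed is None else int(seed)
    h = base & 0xFFFFFFFFFFFFFFFF
    for ch in label.encode():
        h = ((h * 1099511628211) ^ ch) & 0xFFFFFFFFFFFFFFFF
    return h % 2**31
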