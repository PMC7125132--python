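"""Synthetic generator for prospective-metacognition trial sequences.

The generator emulates the structure of a masked-Gabor orientation
discrimination session in which every trial begins with a binary
prospective decision (belief of success, or decision to engage attention)
and ends with binary awareness and confidence ratings.

Per-trial generative model (one subject)
----------------------------------------
* stimulus ``s`` is left/right with equal probability, coded +1 (left) / -1
  (right);
* awareness ``a ~ Bernoulli(p_aware)`` is exogenous: the luminance
  staircase of the emulated task holds the aware rate near 0.5 by design,
  so awareness is drawn rather than thresholded from evidence;
* perceptual evidence ``e ~ Normal(s * d / 2, 1)`` with sensitivity
  ``d = dprime_aware`` on aware trials and ``dprime_unaware`` otherwise;
* the orientation response is ``sign(e - type1_criterion)`` and
  correctness follows;
* confidence is high when ``|e - type1_criterion| + Normal(0,
  conf_noise_sd)`` exceeds ``conf_threshold - a * conf_aware_shift`` — an
  absolute-evidence rule whose threshold relaxes on aware trials;
* the prospective decision is Bernoulli with
  ``logit p = beta0 + sum_k sum_f beta[k][f] * (x[f, t-k] - 0.5)``
  over lags k = 1..4 and features f in (correct, awareness, confidence),
  optionally plus autoregressive weights on past prospective decisions.

Lagged predictors are centred at 0.5 so absent history contributes zero
log-odds; ``warmup_trials`` lead-in trials are simulated and then
discarded so every retained trial has a full history.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, ConstantColumnError
from .trial_io import TrialTable, SCHEMA, EXPERIMENTS

FEATURES = ("correct", "awareness", "confidence")
LAGS = (1, 2, 3, 4)


def default_lag_weights(
    or_correct: float = 1.2,
    or_awareness: float = 3.0,
    or_confidence: float = 3.0,
    decay: float = 0.5,
) -> dict[int, dict[str, float]]:
    """Log-odds weights decaying geometrically across lags 1..4.

    Lag-1 odds ratios default to ~3 for awareness and confidence and a
    much weaker effect of correctness, the configuration in which the two
    subjective ratings dominate the prospective decision; the geometric
    decay reproduces decodability that falls off with lag.
    """
    base = {
        "correct": math.log(or_correct),
        "awareness": math.log(or_awareness),
        "confidence": math.log(or_confidence),
    }
    return {k: {f: base[f] * decay ** (k - 1) for f in FEATURES} for k in LAGS}


def zero_lag_weights() -> dict[int, dict[str, float]]:
    return {k: {f: 0.0 for f in FEATURES} for k in LAGS}


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic experiment.

    Defaults are calibrated to the belief-of-success experiment:
    15 subjects x 12 blocks x 50 trials, aware rate 0.5, sensitivity 1.2
    (aware) vs 0.3 (unaware), and a confidence rule tuned so the three
    pairwise Phi correlations among correctness, awareness and confidence
    sit near 0.17-0.23 with both rating base rates near 0.5.
    """

    n_subjects: int = 15
    n_blocks: int = 12
    trials_per_block: int = 50
    p_aware: float = 0.5
    dprime_aware: float = 1.2
    dprime_unaware: float = 0.3
    type1_criterion: float = 0.0
    conf_threshold: float = 0.9
    conf_noise_sd: float = 0.3
    conf_aware_shift: float = 0.3
    beta0: float = 0.0
    beta: dict[int, dict[str, float]] = field(default_factory=default_lag_weights)
    beta_prospective: dict[int, float] = field(
        default_factory=lambda: {k: 0.0 for k in LAGS}
    )
    warmup_trials: int = 4
    seed: int = 0
    experiment: str = "belief"

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for name in ("n_subjects", "n_blocks", "trials_per_block"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(name, "must be a positive count")
        if not 0.0 <= self.p_aware <= 1.0:
            raise ConfigError("p_aware", "must lie in [0, 1]")
        if self.dprime_unaware < 0:
            raise ConfigError("dprime_unaware", "must be >= 0")
        if self.dprime_aware < self.dprime_unaware:
            raise ConfigError("dprime_aware", "must be >= dprime_unaware")
        if self.conf_noise_sd < 0:
            raise ConfigError("conf_noise_sd", "must be >= 0")
        if self.experiment not in EXPERIMENTS:
            raise ConfigError("experiment", f"must be one of {EXPERIMENTS}")
        for k, weights in self.beta.items():
            if k not in LAGS:
                raise ConfigError("beta", f"lag {k} outside {LAGS}")
            unknown = set(weights) - set(FEATURES)
            if unknown:
                raise ConfigError("beta", f"unknown feature(s) {sorted(unknown)}")
        for k in self.beta_prospective:
            if k not in LAGS:
                raise ConfigError("beta_prospective", f"lag {k} outside {LAGS}")
        if self.warmup_trials < self.max_lag:
            raise ConfigError(
                "warmup_trials",
                f"must be >= max lag with nonzero weight ({self.max_lag})",
            )

    @property
    def max_lag(self) -> int:
        lags = [
            k
            for k, w in self.beta.items()
            if any(v != 0.0 for v in w.values())
        ] + [k for k, v in self.beta_prospective.items() if v != 0.0]
        return max(lags, default=0)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta"] = {str(k): dict(v) for k, v in self.beta.items()}
        d["beta_prospective"] = {str(k): v for k, v in self.beta_prospective.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "beta" in d:
            d["beta"] = {int(k): dict(v) for k, v in d["beta"].items()}
        if "beta_prospective" in d:
            d["beta_prospective"] = {
                int(k): float(v) for k, v in d["beta_prospective"].items()
            }
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def attention_config(**overrides) -> GeneratorConfig:
    """Default configuration for the simulated attention experiment.

    Shares the generative lag weights with the belief experiment — the
    scenario in which history biases transfer across decision types — and
    differs only in the label and subject count (16 retained subjects).
    """
    defaults = dict(experiment="attention", n_subjects=16, seed=1)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_subject(
    config: GeneratorConfig, subject_id: str, substream_seed
) -> TrialTable:
    """Simulate one subject's full session.

    ``substream_seed`` may be an integer or a ``numpy.random.SeedSequence``;
    identical (config, seed) reproduce identical tables.  The returned
    table has ``n_blocks * trials_per_block`` rows: ``warmup_trials``
    lead-in trials are simulated (to give the first retained trial a full
    lag history) and dropped.
    """
    config.validate()
    rng = np.random.default_rng(substream_seed)
    n_total = config.warmup_trials + config.n_trials

    stim = np.empty(n_total, dtype=np.int64)
    aware = np.empty(n_total, dtype=np.int64)
    correct = np.empty(n_total, dtype=np.int64)
    conf = np.empty(n_total, dtype=np.int64)
    prosp = np.empty(n_total, dtype=np.int64)
    resp = np.empty(n_total, dtype=np.int64)

    c1 = config.type1_criterion
    beta = {k: config.beta.get(k, {}) for k in LAGS}
    beta_ar = {k: config.beta_prospective.get(k, 0.0) for k in LAGS}

    for t in range(n_total):
        # prospective decision first (it precedes the stimulus)
        logit = config.beta0
        for k in LAGS:
            if t - k < 0:
                continue
            w = beta[k]
            if w:
                logit += w.get("correct", 0.0) * (correct[t - k] - 0.5)
                logit += w.get("awareness", 0.0) * (aware[t - k] - 0.5)
                logit += w.get("confidence", 0.0) * (conf[t - k] - 0.5)
            if beta_ar[k]:
                logit += beta_ar[k] * (prosp[t - k] - 0.5)
        prosp[t] = rng.random() < _logistic(logit)

        s = 1 if rng.random() < 0.5 else -1
        a = 1 if rng.random() < config.p_aware else 0
        d = config.dprime_aware if a else config.dprime_unaware
        e = rng.normal(s * d / 2.0, 1.0)
        r = 1 if e > c1 else -1
        noise = rng.normal(0.0, config.conf_noise_sd) if config.conf_noise_sd else 0.0
        threshold = config.conf_threshold - a * config.conf_aware_shift
        stim[t] = s
        aware[t] = a
        resp[t] = r
        correct[t] = int(r == s)
        conf[t] = int(abs(e - c1) + noise > threshold)

    keep = slice(config.warmup_trials, n_total)
    n = config.n_trials
    side = {1: "left", -1: "right"}
    df = pd.DataFrame(
        {
            "subject": str(subject_id),
            "experiment": config.experiment,
            "block": np.repeat(
                np.arange(1, config.n_blocks + 1), config.trials_per_block
            ),
            "trial": np.tile(
                np.arange(1, config.trials_per_block + 1), config.n_blocks
            ),
            "prospective": prosp[keep],
            "stimulus": [side[s] for s in stim[keep]],
            "response": [side[r] for r in resp[keep]],
            "correct": correct[keep],
            "awareness": aware[keep],
            "confidence": conf[keep],
        },
        columns=SCHEMA,
    )
    assert len(df) == n
    return TrialTable(df)


def simulate_experiment(config: GeneratorConfig) -> TrialTable:
    """Simulate all subjects with independent substreams derived from the seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects)
    width = max(2, len(str(config.n_subjects)))
    frames = []
    for i, child in enumerate(children):
        sid = f"s{i + 1:0{width}d}"
        frames.append(simulate_subject(config, sid, child).data)
    return TrialTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# calibration summary
# ---------------------------------------------------------------------------


@dataclass
class PairStat:
    """Across-subject summary of one per-subject statistic."""

    mean: float
    sd: float
    n: int
    t: float | None = None  # t statistic of atanh-transformed values vs null
    p: float | None = None


@dataclass
class CalibrationSummary:
    """Summary statistics matching the generator's calibration targets."""

    phi_aw_conf: PairStat
    phi_corr_aw: PairStat
    phi_corr_conf: PairStat
    p_high_prospective: PairStat
    p_aware: float
    n_subjects: int
    dropped: dict[str, list[str]] = field(default_factory=dict)


def summarize_calibration(table: TrialTable) -> CalibrationSummary:
    """Per-subject Phi correlations and base rates, summarised across subjects.

    Phi is computed on same-trial feature pairs subject by subject.  The
    across-subject t-tests use the arc-hyperbolic-tangent (Fisher z)
    transform, since Phi is bounded in [-1, 1]; means and SDs are reported
    back on the Phi scale.  A subject with a constant column is excluded
    from the affected pair with a warning.
    """
    from .decoding import phi_correlation

    subjects = table.subjects
    if len(subjects) < 2:
        raise ValueError("calibration summary needs at least 2 subjects")

    pairs = {
        "phi_aw_conf": ("awareness", "confidence"),
        "phi_corr_aw": ("correct", "awareness"),
        "phi_corr_conf": ("correct", "confidence"),
    }
    values: dict[str, list[float]] = {k: [] for k in pairs}
    dropped: dict[str, list[str]] = {k: [] for k in pairs}
    p_high = []
    p_aware = []
    for subject in subjects:
        g = table.subject(subject)
        p_high.append(float(g["prospective"].mean()))
        p_aware.append(float(g["awareness"].mean()))
        for key, (a, b) in pairs.items():
            try:
                values[key].append(
                    phi_correlation(g[a].to_numpy(), g[b].to_numpy())
                )
            except ConstantColumnError:
                dropped[key].append(subject)
                warnings.warn(
                    f"subject {subject}: constant column in pair {a}/{b}; "
                    f"Phi undefined, subject excluded from that pair",
                    stacklevel=2,
                )

    def pair_stat(vals: list[float], null: float = 0.0, transform=np.arctanh) -> PairStat:
        arr = np.asarray(vals, dtype=float)
        if len(arr) == 0:
            return PairStat(float("nan"), float("nan"), 0, None, None)
        t, p = (None, None)
        with np.errstate(divide="ignore"):
            tr = transform(arr) if transform is not None else arr
        tr = tr[np.isfinite(tr)]  # |phi| = 1 transforms to +/-inf; drop from the test
        if len(tr) >= 2 and np.ptp(tr) > 0:
            t_res = stats.ttest_1samp(tr, null)
            t, p = float(t_res.statistic), float(t_res.pvalue)
        sd = float(arr.std(ddof=1)) if len(arr) >= 2 else float("nan")
        return PairStat(float(arr.mean()), sd, len(arr), t, p)

    return CalibrationSummary(
        phi_aw_conf=pair_stat(values["phi_aw_conf"]),
        phi_corr_aw=pair_stat(values["phi_corr_aw"]),
        phi_corr_conf=pair_stat(values["phi_corr_conf"]),
        p_high_prospective=pair_stat(p_high, null=0.5, transform=None),
        p_aware=float(np.mean(p_aware)),
        n_subjects=len(subjects),
        dropped={k: v for k, v in dropped.items() if v},
    )
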