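"""Type-1 and type-2 signal-detection estimation.

Type-1 sensitivity (d') indexes discrimination of the Gabor orientation
itself; the left-oriented stimulus is the 'signal' (S1), so a hit is a
correct 'left' response to a left stimulus and a correct rejection is a
correct 'right' response to a right stimulus.  Type-2 (metacognitive)
sensitivity is meta-d': the type-1 sensitivity an SDT-ideal observer
would need in order to produce the observed confidence data.  It is
estimated by maximum likelihood of the confidence counts under an
equal-variance Gaussian model in which the type-1 criterion is rescaled
proportionally (c' = c * meta-d'/d') and one type-2 criterion per
response side is fitted jointly.  The M-ratio meta-d'/d' indexes
metacognitive efficiency.

Estimates are computed within cells of the awareness x prospective-
decision grid, matching the 2x2 designs the condition tables feed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .exceptions import ConvergenceError, EmptyCellError
from .trial_io import TrialTable

#: default cell padding: 1/(2K) with K = 4 response categories per stimulus
DEFAULT_PADDING = 0.125

#: |d'| below which the M-ratio is flagged undefined
M_RATIO_EPSILON = 0.1

META_D_BOUNDS = (-5.0, 5.0)


@dataclass(frozen=True)
class Type1Counts:
    """2x2 stimulus-by-response counts with the left/S1 hit convention."""

    hits: float
    misses: float
    false_alarms: float
    correct_rejections: float

    @property
    def n_signal(self) -> float:
        return self.hits + self.misses

    @property
    def n_noise(self) -> float:
        return self.false_alarms + self.correct_rejections

    def rates(self) -> tuple[float, float]:
        return self.hits / self.n_signal, self.false_alarms / self.n_noise


@dataclass(frozen=True)
class Type2Counts:
    """Stimulus x response x confidence counts (2 x 2 x 2).

    Axis order: stimulus (S1=left, S2=right), response (S1, S2),
    confidence (low, high).  Marginalizing over confidence recovers the
    Type1Counts used for d'.
    """

    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=float)
        if arr.shape != (2, 2, 2):
            raise ValueError("Type2Counts requires a 2x2x2 array")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def type1(self) -> Type1Counts:
        c = self.counts.sum(axis=2)
        return Type1Counts(
            hits=float(c[0, 0]),
            misses=float(c[0, 1]),
            false_alarms=float(c[1, 0]),
            correct_rejections=float(c[1, 1]),
        )

    def padded(self, padding: float = DEFAULT_PADDING) -> "Type2Counts":
        return Type2Counts(self.counts + padding)

    def swap_stimulus_labels(self) -> "Type2Counts":
        """Relabel S1<->S2 (stimulus and response axes both flip)."""
        return Type2Counts(self.counts[::-1, ::-1, :])


@dataclass
class SDTEstimates:
    """Type-1 and type-2 estimates for one condition cell."""

    dprime: float
    criterion: float
    meta_dprime: float
    m_ratio: float
    m_ratio_defined: bool
    log_likelihood: float
    converged: bool

    def __repr__(self) -> str:
        mr = f"{self.m_ratio:.3f}" if self.m_ratio_defined else "undefined"
        return (
            f"SDTEstimates(d'={self.dprime:.3f}, c={self.criterion:.3f}, "
            f"meta-d'={self.meta_dprime:.3f}, M-ratio={mr})"
        )


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------


def tabulate_counts(
    table: TrialTable,
    awareness_level: int | None = None,
    prospective_level: int | None = None,
    subject: str | None = None,
) -> Type2Counts:
    """Stimulus x response x confidence counts for one condition cell.

    Restricts to trials matching the requested awareness and prospective
    levels (either may be None to marginalize).  Raises EmptyCellError
    when the filtered cell has no trials of one stimulus class; the
    caller decides between padding and exclusion.
    """
    df = table.subject(subject) if subject is not None else table.data
    if awareness_level is not None:
        df = df[df["awareness"] == awareness_level]
    if prospective_level is not None:
        df = df[df["prospective"] == prospective_level]
    counts = np.zeros((2, 2, 2))
    stim_idx = (df["stimulus"] == "right").astype(int).to_numpy()  # left -> S1 = 0
    resp_idx = (df["response"] == "right").astype(int).to_numpy()
    conf_idx = df["confidence"].to_numpy()
    np.add.at(counts, (stim_idx, resp_idx, conf_idx), 1)
    if counts.sum(axis=(1, 2)).min() == 0:
        raise EmptyCellError(
            f"no trials for at least one stimulus class in cell "
            f"(awareness={awareness_level}, prospective={prospective_level})"
        )
    return Type2Counts(counts)


# ---------------------------------------------------------------------------
# type-1 estimation
# ---------------------------------------------------------------------------


def type1_sensitivity(counts: Type1Counts) -> tuple[float, float]:
    """d' and criterion from hit and false-alarm rates.

    d' = z(HR) - z(FAR); c = -(z(HR) + z(FAR)) / 2.  Rates of exactly 0
    or 1 are a domain error: pad the counts first.
    """
    hr, far = counts.rates()
    if not (0.0 < hr < 1.0 and 0.0 < far < 1.0):
        raise ValueError(
            f"hit/false-alarm rates must lie strictly in (0, 1), got "
            f"HR={hr}, FAR={far}; pad the counts first"
        )
    z_hr, z_far = norm.ppf(hr), norm.ppf(far)
    return float(z_hr - z_far), float(-0.5 * (z_hr + z_far))


# ---------------------------------------------------------------------------
# meta-d' likelihood
# ---------------------------------------------------------------------------


def _type2_cell_probabilities(meta_d: float, c1_rel: float, t2_s1: float, t2_s2: float):
    """Model joint P(response, confidence | stimulus) under meta-d'.

    Stimulus means are +/- meta_d / 2 (S1 positive); response is S1 when
    evidence falls below... — here the convention is: respond S1 (left)
    when evidence exceeds the rescaled criterion is *not* used; instead
    S1 evidence is centred at +meta_d/2 and the S1 response corresponds
    to evidence above c1_rel.  High confidence on S1 responses requires
    evidence above t2_s1 >= c1_rel; high confidence on S2 responses
    requires evidence below t2_s2 <= c1_rel.

    Returns an array p[stimulus, response, confidence].
    """
    p = np.empty((2, 2, 2))
    for s, mu in enumerate((meta_d / 2.0, -meta_d / 2.0)):
        sf_c1 = norm.sf(c1_rel - mu)  # P(respond S1 | stimulus)
        sf_t2s1 = norm.sf(t2_s1 - mu)
        cdf_c1 = 1.0 - sf_c1
        cdf_t2s2 = norm.cdf(t2_s2 - mu)
        p[s, 0, 1] = sf_t2s1  # S1 response, high confidence
        p[s, 0, 0] = sf_c1 - sf_t2s1  # S1 response, low confidence
        p[s, 1, 1] = cdf_t2s2  # S2 response, high confidence
        p[s, 1, 0] = cdf_c1 - cdf_t2s2  # S2 response, low confidence
    return p


def _type2_conditional_loglike(
    params: np.ndarray, counts: np.ndarray, d1: float, c1: float
) -> float:
    """Negative log-likelihood of confidence given (stimulus, response)."""
    meta_d, da, db = params
    c1_rel = c1 * meta_d / d1
    t2_s1 = c1_rel + da
    t2_s2 = c1_rel - db
    p = _type2_cell_probabilities(meta_d, c1_rel, t2_s1, t2_s2)
    p = np.clip(p, 1e-300, None)
    p_resp = p.sum(axis=2, keepdims=True)
    cond = p / p_resp
    cond = np.clip(cond, 1e-300, 1.0)
    return -float(np.sum(counts * np.log(cond)))


def fit_meta_d(
    counts: Type2Counts,
    padding: float = DEFAULT_PADDING,
    m_ratio_epsilon: float = M_RATIO_EPSILON,
) -> SDTEstimates:
    """Maximum-likelihood meta-d' with proportionally rescaled criterion.

    Pads every cell by ``padding`` (default 1/(2K), K = 4 response
    categories per stimulus), takes d' and c from the padded type-1
    marginals, then maximizes the multinomial likelihood of the
    confidence counts conditional on the type-1 response, over meta-d' in
    [-5, 5] and one type-2 criterion offset per response side.
    """
    padded = counts.padded(padding) if padding else counts
    d1, c1 = type1_sensitivity(padded.type1())
    n = padded.counts

    def objective(params):
        return _type2_conditional_loglike(params, n, d1, c1)

    # high-confidence rates give a rough starting offset
    hi_rate = float(n[:, :, 1].sum() / n.sum())
    start_offset = max(0.1, abs(norm.ppf(np.clip(hi_rate, 0.01, 0.99))))
    best = None
    for meta0 in (d1, 0.5 * d1, 0.0):
        res = minimize(
            objective,
            x0=np.array([meta0, start_offset, start_offset]),
            method="L-BFGS-B",
            bounds=[META_D_BOUNDS, (0.0, 10.0), (0.0, 10.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("meta-d' optimization failed", best_value=None)

    meta_d = float(best.x[0])
    m_defined = abs(d1) >= m_ratio_epsilon
    m_ratio = meta_d / d1 if m_defined else float("nan")
    return SDTEstimates(
        dprime=d1,
        criterion=c1,
        meta_dprime=meta_d,
        m_ratio=m_ratio,
        m_ratio_defined=m_defined,
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
    )


def fit_meta_d_grid(
    counts: Type2Counts,
    padding: float = DEFAULT_PADDING,
    step: float = 0.001,
    bounds: tuple[float, float] = META_D_BOUNDS,
) -> float:
    """Profile-likelihood grid search over meta-d' (independent oracle).

    At each grid value of meta-d' the two type-2 criterion offsets are
    optimized separately (the conditional likelihood factorizes over
    response sides), and the meta-d' with the highest profile likelihood
    is returned.  Slow but free of joint-optimization failure modes; used
    to cross-check :func:`fit_meta_d`.
    """
    from scipy.optimize import minimize_scalar

    padded = counts.padded(padding) if padding else counts
    d1, c1 = type1_sensitivity(padded.type1())
    n = padded.counts

    def profile_nll(meta_d: float) -> float:
        c1_rel = c1 * meta_d / d1 if d1 != 0 else c1

        def side_nll(offset_a=None, offset_b=None):
            da = offset_a if offset_a is not None else 0.0
            db = offset_b if offset_b is not None else 0.0
            return _type2_conditional_loglike(
                np.array([meta_d, da, db]), n, d1, c1
            )

        # S1-response side depends only on da, S2 side only on db
        ra = minimize_scalar(
            lambda a: side_nll(offset_a=a), bounds=(0.0, 10.0), method="bounded",
            options={"xatol": 1e-6},
        )
        rb = minimize_scalar(
            lambda b: side_nll(offset_b=b), bounds=(0.0, 10.0), method="bounded",
            options={"xatol": 1e-6},
        )
        # side_nll(a, 0) + side_nll(0, b) double-counts the fixed parts; the
        # decomposition below recomputes the joint at the two optima instead.
        return _type2_conditional_loglike(
            np.array([meta_d, ra.x, rb.x]), n, d1, c1
        )

    grid = np.arange(bounds[0], bounds[1] + step / 2, step)
    # coarse pass then refine: evaluate every 50th point, then the
    # neighbourhoods of the best few coarse points at full resolution
    coarse = grid[::50]
    coarse_nll = np.array([profile_nll(m) for m in coarse])
    order = np.argsort(coarse_nll)[:3]
    candidates = []
    for idx in order:
        lo = max(0, idx * 50 - 50)
        hi = min(len(grid), idx * 50 + 51)
        candidates.append(grid[lo:hi])
    cand = np.unique(np.concatenate(candidates))
    nll = np.array([profile_nll(m) for m in cand])
    return float(cand[np.argmin(nll)])


# ---------------------------------------------------------------------------
# condition grid
# ---------------------------------------------------------------------------


def condition_sdt_grid(
    table: TrialTable,
    padding: float = DEFAULT_PADDING,
    m_ratio_epsilon: float = M_RATIO_EPSILON,
) -> pd.DataFrame:
    """Per-subject SDT estimates in each awareness x prospective cell.

    Returns a tidy long-format table (one row per subject x cell) ready
    for downstream repeated-measures tests.  Cells with no trials of one
    stimulus class are reported as missing (NaN estimates), never
    imputed.
    """
    rows = []
    for subject in table.subjects:
        for aware in (0, 1):
            for prospective in (0, 1):
                row = {
                    "subject": subject,
                    "awareness": aware,
                    "prospective": prospective,
                }
                try:
                    counts = tabulate_counts(
                        table, awareness_level=aware, prospective_level=prospective,
                        subject=subject,
                    )
                except EmptyCellError:
                    row.update(
                        dprime=np.nan, criterion=np.nan, meta_dprime=np.nan,
                        m_ratio=np.nan, defined=False,
                    )
                    rows.append(row)
                    continue
                est = fit_meta_d(
                    counts, padding=padding, m_ratio_epsilon=m_ratio_epsilon
                )
                row.update(
                    dprime=est.dprime,
                    criterion=est.criterion,
                    meta_dprime=est.meta_dprime,
                    m_ratio=est.m_ratio,
                    defined=est.m_ratio_defined,
                )
                rows.append(row)
    return pd.DataFrame(rows)


class MetaDPrimeModel:
    """Model facade for meta-d' estimation from one cell of counts."""

    def __init__(
        self,
        counts: Type2Counts,
        padding: float = DEFAULT_PADDING,
        m_ratio_epsilon: float = M_RATIO_EPSILON,
    ):
        self.counts = counts
        self.padding = padding
        self.m_ratio_epsilon = m_ratio_epsilon

    @classmethod
    def from_table(cls, table: TrialTable, **cell) -> "MetaDPrimeModel":
        return cls(tabulate_counts(table, **cell))

    def fit(self) -> SDTEstimates:
        return fit_meta_d(
            self.counts, padding=self.padding, m_ratio_epsilon=self.m_ratio_epsilon
        )
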