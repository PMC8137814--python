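"""Significance of cross-brain predictions via a moving-block bootstrap.

Prediction accuracy is the Spearman rank correlation between the predicted
and observed student test series. Its null distribution cannot come from an
i.i.d. permutation: band-limited hemodynamic series are strongly
autocorrelated, and sample-wise shuffling destroys that structure, yielding
an over-narrow null and inflated false positives. Instead the teacher
series is cut into contiguous blocks whose length is the lag at which the
teacher's autocorrelation first falls to (approximately) zero; the blocks
are shuffled jointly across channels and the whole train/predict/test
pipeline is re-run per replicate. The student series is never permuted.

The p-value is the literal exceedance ratio
``#(null coefficients > observed) / B``; Benjamini-Hochberg FDR correction
is applied across the channels of one dyad and family by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tsa.stattools import acf as _acf

from interbrain.core import DyadDataset
from interbrain.models import (
    DEFAULT_COST,
    DEFAULT_EPSILON,
    ModelGrid,
    SplitSpec,
    fit_all_channels,
    fit_svr,
    predict,
)

__all__ = [
    "LagEstimate",
    "NullDistribution",
    "DyadEvaluation",
    "spearman",
    "find_block_lag",
    "block_shuffle",
    "bootstrap_null",
    "bootstrap_pvalue",
    "fdr_adjust",
    "evaluate_dyad",
]

DEFAULT_ACF_THRESHOLD = 0.05
DEFAULT_B = 1000
DEFAULT_ALPHA = 0.01


# ---------------------------------------------------------------------------
# Accuracy metric
# ---------------------------------------------------------------------------

def spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises ``ValueError`` on constant input (the correlation is undefined);
    callers report such channels as NA.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("series must share length")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman correlation is undefined for constant input")
    rho = sps.spearmanr(a, b).statistic
    return float(rho)


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Ordinal column ranks via double argsort.

    Much faster than average-rank ranking and identical for continuous
    (tie-free) data, which is all the bootstrap inner loop ever sees;
    constant columns are handled separately by the callers.
    """
    idx = np.argsort(x, axis=0)
    r = np.empty(x.shape, dtype=float)
    np.put_along_axis(
        r, idx, np.broadcast_to(np.arange(x.shape[0], dtype=float)[:, None], x.shape),
        axis=0,
    )
    return r


def _spearman_columns(pred: np.ndarray, obs_ranks_z: np.ndarray) -> np.ndarray:
    """Column-wise Spearman between ``pred`` and pre-ranked, z-scored ``obs``.

    ``obs_ranks_z`` must be the observed matrix's column ranks, centered and
    scaled to unit norm. Constant prediction columns yield NaN.
    """
    const = np.ptp(pred, axis=0) == 0
    r = _rank_columns(pred)
    r -= r.mean(axis=0)
    norm = np.sqrt((r**2).sum(axis=0))
    norm[const] = np.nan
    rho = (r * obs_ranks_z).sum(axis=0) / norm
    return rho


def _z_ranks(x: np.ndarray) -> np.ndarray:
    r = sps.rankdata(x, axis=0)
    r = r - r.mean(axis=0)
    norm = np.sqrt((r**2).sum(axis=0))
    norm[norm == 0] = np.nan
    return r / norm


# ---------------------------------------------------------------------------
# Block length from the autocorrelation function
# ---------------------------------------------------------------------------

@dataclass
class LagEstimate:
    """Block length for the bootstrap: first near-zero ACF lag, aggregated."""

    lag: int
    per_channel_lags: list[int]
    aggregation: str = "median-ceil"
    acf_threshold: float = DEFAULT_ACF_THRESHOLD


def find_block_lag(
    values: np.ndarray,
    threshold: float = DEFAULT_ACF_THRESHOLD,
    max_lag: int = 200,
    aggregation: str = "median-ceil",
) -> LagEstimate:
    """Smallest positive lag where each channel's |ACF| falls to ``threshold``.

    Per channel, the first lag k >= 1 with ``|acf(k)| <= threshold``;
    channel lags are aggregated to one block length per dyad by the median,
    rounded up. Raises if some channel never crosses within ``max_lag``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n <= 2 * max_lag:
        raise ValueError(
            f"segment length {n} must exceed twice max_lag ({2 * max_lag}); "
            "reduce max_lag"
        )
    lags: list[int] = []
    for k in range(x.shape[1]):
        a = _acf(x[:, k], nlags=max_lag, fft=True)
        hit = np.nonzero(np.abs(a[1:]) <= threshold)[0]
        if hit.size == 0:
            raise ValueError(
                f"channel {k + 1}: |ACF| never reaches {threshold} within "
                f"{max_lag} lags; increase max_lag"
            )
        lags.append(int(hit[0]) + 1)
    if aggregation == "median-ceil":
        agg = int(math.ceil(float(np.median(lags))))
    elif aggregation == "max":
        agg = int(max(lags))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return LagEstimate(lag=agg, per_channel_lags=lags, aggregation=aggregation,
                       acf_threshold=threshold)


# ---------------------------------------------------------------------------
# Block shuffling
# ---------------------------------------------------------------------------

def block_shuffle(
    teacher: np.ndarray, lag: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Cut the series into ``floor(n/lag)`` contiguous blocks and permute them.

    The same permutation is applied jointly to every channel, preserving the
    instantaneous inter-channel covariance the regression models rely on.
    Remainder samples beyond the last full block are dropped, so the output
    has ``floor(n/lag) * lag`` rows; ``lag = n`` returns the input unchanged.
    """
    x = np.asarray(teacher, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    n, k = x.shape
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if lag > n:
        raise ValueError(f"lag ({lag}) exceeds series length ({n})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nblocks = n // lag
    m = nblocks * lag
    blocks = x[:m].reshape(nblocks, lag, k)
    out = blocks[rng.permutation(nblocks)].reshape(m, k)
    return out[:, 0] if one_d else out


# ---------------------------------------------------------------------------
# Bootstrap null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """B bootstrap Spearman coefficients for one channel and family."""

    coefficients: np.ndarray
    lag: int
    n_blocks: int
    family: str
    response_channel: int
    master_seed: int
    failed_replicates: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()

    @property
    def B(self) -> int:
        return self.coefficients.size


def _ols_fit_predict_multi(
    x_tr: np.ndarray, y_tr: np.ndarray, x_ts: np.ndarray
) -> np.ndarray:
    """Multi-response OLS via normal equations; raises LinAlgError if singular."""
    mx = x_tr.mean(axis=0)
    my = y_tr.mean(axis=0)
    xc = x_tr - mx
    g = xc.T @ xc
    w = np.linalg.solve(g, xc.T @ (y_tr - my))
    return (x_ts - mx) @ w + my


def _null_matrix(
    teacher: np.ndarray,
    student: np.ndarray,
    boundary: int,
    family: str,
    B: int,
    lag: int,
    seed: int,
    epsilon: float = DEFAULT_EPSILON,
    cost: float = DEFAULT_COST,
    max_failure_fraction: float = 0.05,
    response_indices: list[int] | None = None,
) -> tuple[np.ndarray, int]:
    """(B, n_responses) matrix of null Spearman coefficients.

    Per replicate the full-length teacher matrix is block-shuffled (train and
    test resampled as one series), split at the original boundary, the family
    refitted per channel on the real student train, and the Spearman computed
    against the real student test (tail-trimmed to the retained length).
    ``response_indices`` restricts the refitted student channels (0-based);
    the default is all of them.
    """
    n, k = teacher.shape
    if response_indices is not None:
        student = student[:, response_indices]
    if not 0 < boundary < n:
        raise ValueError("boundary must fall inside the series")
    if B < 1:
        raise ValueError("need at least one replicate")
    nblocks = n // lag
    m = nblocks * lag
    if boundary >= m:
        raise ValueError("block truncation removed the whole test segment")
    y_tr = student[:boundary]
    y_ts = student[boundary:m]
    n_resp = student.shape[1]
    obs_z = _z_ranks(y_ts)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = np.full((B, n_resp), np.nan)
    failures = 0
    for rep in range(B):
        shuffled = block_shuffle(teacher, lag, rng)
        x_tr, x_ts = shuffled[:boundary], shuffled[boundary:]
        try:
            if family == "OLS":
                pred = _ols_fit_predict_multi(x_tr, y_tr, x_ts)
            elif family == "SVR":
                pred = np.empty((x_ts.shape[0], n_resp))
                for j in range(n_resp):
                    mdl = fit_svr(y_tr[:, j], x_tr, epsilon=epsilon, cost=cost)
                    pred[:, j] = predict(mdl, x_ts)
            else:
                raise ValueError(f"unknown family {family!r}")
        except np.linalg.LinAlgError:
            failures += 1
            continue
        out[rep] = _spearman_columns(pred, obs_z)
    if failures > max_failure_fraction * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap replicates failed to fit; "
            "the dyad is too degenerate for inference"
        )
    return out, failures


def bootstrap_null(
    dyad: DyadDataset,
    family: str,
    response_channel: int,
    B: int = DEFAULT_B,
    lag: int | None = None,
    seed: int = 0,
    split: SplitSpec | None = None,
    epsilon: float = DEFAULT_EPSILON,
    cost: float = DEFAULT_COST,
    acf_threshold: float = DEFAULT_ACF_THRESHOLD,
    max_lag: int = 200,
) -> NullDistribution:
    """Null distribution of the Spearman accuracy for one response channel.

    ``lag=None`` estimates the block length from the teacher's training
    segment via :func:`find_block_lag`. The student series is never
    permuted.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for any p-value report")
    split = split or SplitSpec()
    boundary = split.boundary(dyad.n_samples)
    teacher = dyad.teacher.values
    student = dyad.student.values
    if lag is None:
        lag = find_block_lag(teacher[:boundary], threshold=acf_threshold, max_lag=max_lag).lag
    k = dyad.montage.channel_ids.index(response_channel)
    coeffs, failures = _null_matrix(
        teacher, student, boundary, family, B, lag, seed, epsilon, cost,
        response_indices=[k],
    )
    return NullDistribution(
        coefficients=coeffs[:, 0],
        lag=lag,
        n_blocks=dyad.n_samples // lag,
        family=family,
        response_channel=response_channel,
        master_seed=seed,
        failed_replicates=failures,
    )


def bootstrap_pvalue(
    observed_rho: float, null: NullDistribution | np.ndarray, corrected: bool = False
) -> float:
    """One-sided exceedance p-value.

    Literal rule (default): ``#(null > observed) / B``. The ``corrected``
    variant ``(#+1)/(B+1)`` never returns exactly zero and is the standard
    finite-sample permutation estimator; it is off by default to match the
    literal ratio definition.
    """
    coeffs = null.coefficients if isinstance(null, NullDistribution) else np.asarray(null)
    coeffs = coeffs[np.isfinite(coeffs)]
    if coeffs.size == 0:
        raise ValueError("empty null distribution")
    exceed = int(np.sum(coeffs > observed_rho))
    if corrected:
        return (exceed + 1) / (coeffs.size + 1)
    return exceed / coeffs.size


def fdr_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries propagate as NaN and do not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# Whole-dyad evaluation
# ---------------------------------------------------------------------------

@dataclass
class DyadEvaluation:
    """Per-channel results table plus the bootstrap bookkeeping."""

    table: pd.DataFrame
    lag: LagEstimate
    alpha: float
    nulls: dict[str, np.ndarray] = field(default_factory=dict)  # family -> (B, K)


def evaluate_dyad(
    dyad: DyadDataset,
    models: ModelGrid | None = None,
    B: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    families: tuple[str, ...] = ("SVR", "OLS"),
    split: SplitSpec | None = None,
    epsilon: float = DEFAULT_EPSILON,
    cost: float = DEFAULT_COST,
    acf_threshold: float = DEFAULT_ACF_THRESHOLD,
    max_lag: int = 200,
    seed: int = 0,
    lag: int | None = None,
    corrected_pvalues: bool = False,
    keep_nulls: bool = False,
) -> DyadEvaluation:
    """Score and test every channel x family of one dyad.

    Produces a table with columns (dyad, channel, region, family, rho, p, q,
    sig_uncorrected, sig_fdr, lag, note) mirroring the per-dyad S / P / FDR
    layout of a per-dyad channel report. FDR correction is applied within one dyad
    and family (18 tests) by default.
    """
    split = split or SplitSpec()
    if models is None:
        models = fit_all_channels(dyad, split, families=families, epsilon=epsilon, cost=cost)
    if len(models) == 0:
        warnings.warn("empty model grid: nothing to evaluate", stacklevel=2)
        cols = ["dyad", "channel", "region", "family", "rho", "p", "q",
                "sig_uncorrected", "sig_fdr", "lag", "note"]
        return DyadEvaluation(
            table=pd.DataFrame(columns=cols),
            lag=LagEstimate(lag=1, per_channel_lags=[], aggregation="none",
                            acf_threshold=acf_threshold),
            alpha=alpha,
        )
    boundary = models.boundary
    teacher = dyad.teacher.values
    student = dyad.student.values
    if lag is None:
        lag_est = find_block_lag(teacher[:boundary], threshold=acf_threshold, max_lag=max_lag)
    else:
        lag_est = LagEstimate(lag=int(lag), per_channel_lags=[], aggregation="fixed",
                              acf_threshold=acf_threshold)
    t_ts = teacher[boundary:]
    s_ts = student[boundary:]
    rows = []
    nulls: dict[str, np.ndarray] = {}
    for fam in families:
        coeffs, _ = _null_matrix(
            teacher, student, boundary, fam, B, lag_est.lag, seed, epsilon, cost
        )
        if keep_nulls:
            nulls[fam] = coeffs
        pvals: list[float] = []
        rhos: list[float] = []
        notes: list[str] = []
        for k, ch in enumerate(dyad.montage.channel_ids):
            mdl = models.get(ch, fam)
            if mdl is None:
                reason = next(
                    (s["reason"] for s in models.skipped
                     if s["channel"] == ch and s["family"] == fam),
                    "not fitted",
                )
                rhos.append(np.nan)
                pvals.append(np.nan)
                notes.append(reason)
                continue
            try:
                rho = spearman(predict(mdl, t_ts), s_ts[:, k])
                p = bootstrap_pvalue(rho, coeffs[:, k], corrected=corrected_pvalues)
            except ValueError as exc:
                rhos.append(np.nan)
                pvals.append(np.nan)
                notes.append(str(exc))
                continue
            rhos.append(rho)
            pvals.append(p)
            notes.append("")
        qvals = fdr_adjust(pvals)
        for k, ch in enumerate(dyad.montage.channel_ids):
            rows.append(
                {
                    "dyad": dyad.dyad_id,
                    "channel": ch,
                    "region": dyad.montage.regions[k],
                    "family": fam,
                    "rho": rhos[k],
                    "p": pvals[k],
                    "q": qvals[k],
                    "sig_uncorrected": bool(np.isfinite(pvals[k]) and pvals[k] <= alpha),
                    "sig_fdr": bool(np.isfinite(qvals[k]) and qvals[k] <= alpha),
                    "lag": lag_est.lag,
                    "note": notes[k],
                }
            )
    table = pd.DataFrame(rows)
    return DyadEvaluation(table=table, lag=lag_est, alpha=alpha, nulls=nulls)
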