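"""Per-channel cross-brain regression: student channel on all teacher channels.

For each student response channel j the model is

    S_j(t) = sum_i w_i * T_i(t) + b,        i = 1..18,

fitted on the first half of the recording and applied to the teacher's
second half to predict the student's unseen signal. Two families share this
linear class: ordinary least squares (OLS), and epsilon-insensitive support
vector regression (SVR) with a linear kernel, whose norm penalty guards
against the heavy predictor multicollinearity typical of fNIRS montages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from sklearn.svm import SVR as _SkSVR

from interbrain.core import DyadDataset

__all__ = [
    "SplitSpec",
    "PredictionModelSpec",
    "ModelGrid",
    "split_series",
    "fit_ols",
    "fit_svr",
    "predict",
    "fit_all_channels",
]

#: Default SVR hyperparameters: the defaults of the canonical epsilon-SVR
#: implementations (libsvm and its R wrapper e1071): cost C = 1, epsilon = 0.1
#: on the standardized response.
DEFAULT_EPSILON = 0.1
DEFAULT_COST = 1.0


@dataclass(frozen=True)
class SplitSpec:
    """Contiguous chronological train/test split; train first.

    ``boundary(n)`` = ceil(fraction_train * n): odd lengths put the extra
    sample in the training half.
    """

    fraction_train: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_train < 1.0:
            raise ValueError("fraction_train must lie strictly between 0 and 1")

    def boundary(self, n_samples: int) -> int:
        b = math.ceil(self.fraction_train * n_samples)
        if b <= 0 or b >= n_samples:
            raise ValueError(
                f"fraction_train={self.fraction_train} leaves an empty segment "
                f"for {n_samples} samples"
            )
        return b


def split_series(
    dyad: DyadDataset, spec: SplitSpec | None = None
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Split both subjects at the same boundary.

    Returns ``((teacher_train, student_train), (teacher_test, student_test))``.
    """
    spec = spec or SplitSpec()
    n = dyad.n_samples
    b = spec.boundary(n)
    t, s = dyad.teacher.values, dyad.student.values
    return (t[:b], s[:b]), (t[b:], s[b:])


@dataclass
class PredictionModelSpec:
    """Fitted weights of one response channel's linear model."""

    family: str  # "SVR" | "OLS"
    response_channel: int
    weights: np.ndarray
    intercept: float
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.family not in {"SVR", "OLS"}:
            raise ValueError(f"unknown model family {self.family!r}")
        if not (np.all(np.isfinite(self.weights)) and np.isfinite(self.intercept)):
            raise ValueError("model parameters must be finite")

    @property
    def n_predictors(self) -> int:
        return self.weights.size


def _as_xy(response: np.ndarray, predictors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(response, dtype=float).ravel()
    X = np.asarray(predictors, dtype=float)
    if X.ndim != 2:
        raise ValueError("predictors must be 2-D (time x channel)")
    if X.shape[0] != y.shape[0]:
        raise ValueError("response and predictors must share length")
    return y, X


def _collinear_columns(X: np.ndarray, tol_factor: float = 1e-10) -> list[int]:
    """0-based indices of columns implicated in rank deficiency (QR pivoting)."""
    Xc = X - X.mean(axis=0)
    _, r, piv = sla.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    thresh = tol_factor * max(diag.max(), 1.0) * max(X.shape)
    deficient = diag <= thresh
    return sorted(int(piv[k]) for k in np.nonzero(deficient)[0])


def fit_ols(
    response: np.ndarray,
    predictors: np.ndarray,
    response_channel: int = 0,
    min_samples: int = 20,
) -> PredictionModelSpec:
    """Ordinary least squares with intercept.

    Rank-deficient predictor matrices raise (naming the implicated channels)
    rather than silently falling back to a pseudo-inverse: a degenerate fit
    would quietly corrupt the downstream SVR/OLS bootstrap comparison.
    """
    y, X = _as_xy(response, predictors)
    if X.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {X.shape[0]}")
    bad = _collinear_columns(X)
    if bad:
        cols = [c + 1 for c in bad]
        raise ValueError(
            f"predictor matrix is rank deficient; collinear teacher channels: {cols}"
        )
    A = np.column_stack([X, np.ones(X.shape[0])])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return PredictionModelSpec(
        family="OLS",
        response_channel=response_channel,
        weights=coef[:-1],
        intercept=float(coef[-1]),
    )


def fit_svr(
    response: np.ndarray,
    predictors: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    cost: float = DEFAULT_COST,
    response_channel: int = 0,
    standardize: bool = True,
    tol: float = 1e-3,
    max_iter: int = 1_000_000,
    check_convergence: bool = True,
) -> PredictionModelSpec:
    """Linear-kernel epsilon-insensitive SVR.

    With ``standardize=True`` (default, matching the canonical
    implementations) predictors and response are z-scored internally and the
    solution is algebraically mapped back to the original scale, so the
    returned ``(weights, intercept)`` apply directly to raw teacher series.
    Note that ``epsilon`` is then a tube width on the *standardized*
    response.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if cost <= 0:
        raise ValueError("cost must be positive")
    y, X = _as_xy(response, predictors)
    if standardize:
        mx, sx = X.mean(axis=0), X.std(axis=0)
        my, sy = y.mean(), y.std()
        sx = np.where(sx > 0, sx, 1.0)
        sy = sy if sy > 0 else 1.0
        Xs, ys = (X - mx) / sx, (y - my) / sy
    else:
        mx, sx = np.zeros(X.shape[1]), np.ones(X.shape[1])
        my, sy = 0.0, 1.0
        Xs, ys = X, y
    svr = _SkSVR(kernel="linear", C=cost, epsilon=epsilon, tol=tol, max_iter=max_iter)
    svr.fit(Xs, ys)
    if svr.fit_status_ != 0 and check_convergence:
        # near-interpolation settings (epsilon -> 0, very large cost) leave
        # the SMO solver cycling below tol although the iterate is already
        # essentially optimal; check_convergence=False accepts that iterate
        raise RuntimeError(
            f"SVR solver did not converge (fit_status={svr.fit_status_}, "
            f"n={X.shape[0]}, C={cost}, epsilon={epsilon}, tol={tol})"
        )
    ws = svr.coef_.ravel()
    bs = float(svr.intercept_[0])
    w = sy * ws / sx
    b = sy * bs + my - float(w @ mx)
    return PredictionModelSpec(
        family="SVR",
        response_channel=response_channel,
        weights=w,
        intercept=b,
        hyperparameters={"epsilon": epsilon, "cost": cost, "standardize": standardize},
    )


def predict(model: PredictionModelSpec, teacher: np.ndarray) -> np.ndarray:
    """Apply a fitted model to a teacher (time x channel) matrix."""
    X = np.asarray(teacher, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_predictors:
        raise ValueError(
            f"teacher matrix must have {model.n_predictors} channels, "
            f"got shape {X.shape}"
        )
    return X @ model.weights + model.intercept


@dataclass
class ModelGrid:
    """One dyad's fitted models: channel x family, plus skip records."""

    models: dict[tuple[int, str], PredictionModelSpec]
    skipped: list[dict]
    boundary: int
    families: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.models)

    def get(self, channel: int, family: str) -> PredictionModelSpec | None:
        return self.models.get((channel, family))


def fit_all_channels(
    dyad: DyadDataset,
    spec: SplitSpec | None = None,
    families: tuple[str, ...] = ("SVR", "OLS"),
    epsilon: float = DEFAULT_EPSILON,
    cost: float = DEFAULT_COST,
    exclude_channels: tuple[int, ...] = (),
) -> ModelGrid:
    """Fit every student response channel with every requested family.

    Per-channel failures (and QC exclusions passed via ``exclude_channels``)
    are recorded, not raised — one bad channel must not abort a dyad.
    Fitting is deterministic: no randomness enters either family.
    """
    spec = spec or SplitSpec()
    (t_tr, s_tr), _ = split_series(dyad, spec)
    models: dict[tuple[int, str], PredictionModelSpec] = {}
    skipped: list[dict] = []
    for k, ch in enumerate(dyad.montage.channel_ids):
        for fam in families:
            if ch in exclude_channels:
                skipped.append({"channel": ch, "family": fam, "reason": "qc-excluded"})
                continue
            try:
                if fam == "OLS":
                    m = fit_ols(s_tr[:, k], t_tr, response_channel=ch)
                elif fam == "SVR":
                    m = fit_svr(s_tr[:, k], t_tr, epsilon=epsilon, cost=cost, response_channel=ch)
                else:
                    raise ValueError(f"unknown family {fam!r}")
            except (ValueError, RuntimeError) as exc:
                skipped.append({"channel": ch, "family": fam, "reason": str(exc)})
                continue
            models[(ch, fam)] = m
    return ModelGrid(
        models=models,
        skipped=skipped,
        boundary=spec.boundary(dyad.n_samples),
        families=tuple(families),
    )
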