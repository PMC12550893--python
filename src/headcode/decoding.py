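"""Population decoding of HD and AHV with feedforward networks.

A multilayer perceptron (three hidden layers of 64, 128 and 64 ReLU units,
Adam, L2 weight decay 5e-2 for HD and 5e-3 for AHV) maps instantaneous
population rates to the behavioral variable under 5-fold cross-validation.
Decoding skill is the Pearson correlation r between predicted and actual
values; HD predictions are wrapped modulo 2pi and both sides are
cosine-transformed before correlating, to respect circularity.

The regressor itself is scikit-learn's ``MLPRegressor``; this module owns
the target parameterization (the HD network regresses (cos, sin) and the
angle is reconstructed by atan2), the temporal fold structure, and the
scoring conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .session import Session

__all__ = ["DecoderSpec", "DecodingResult", "decode", "mvl_threshold_sweep"]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class DecoderSpec:
    """Decoder architecture and training settings.

    ``weight_decay=None`` selects the per-target default (5e-2 for HD,
    5e-3 for AHV).  Folds are contiguous temporal blocks by default, which
    limits leakage through autocorrelation; ``fold_mode="random"`` shuffles
    samples instead.  ``max_samples`` caps the number of (evenly spaced)
    samples used, for bounded runtimes on long sessions.
    """

    target: str = "hd"                       # "hd" or "ahv"
    hidden: tuple[int, ...] = (64, 128, 64)
    weight_decay: float | None = None
    folds: int = 5
    fold_mode: str = "blocked"
    max_iter: int = 120
    learning_rate_init: float = 1e-3
    batch_size: int = 256
    early_stopping: bool = True
    n_iter_no_change: int = 8
    max_samples: int | None = None

    def __post_init__(self):
        if self.target not in {"hd", "ahv"}:
            raise ValueError(f"unknown target {self.target!r}")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.fold_mode not in {"blocked", "random"}:
            raise ValueError(f"unknown fold_mode {self.fold_mode!r}")

    @property
    def alpha(self) -> float:
        if self.weight_decay is not None:
            return self.weight_decay
        return 5e-2 if self.target == "hd" else 5e-3


@dataclass
class DecodingResult:
    """Cross-validated decoding skill of one population for one target."""

    target: str
    r_folds: list[float]
    n_units: int
    n_samples: int
    population_label: str = "custom"

    @property
    def r(self) -> float:
        """Mean Pearson r over folds (NaN-skipping)."""
        return float(np.nanmean(self.r_folds))


def _fold_slices(n: int, folds: int, mode: str, rng) -> list[np.ndarray]:
    idx = np.arange(n)
    if mode == "random":
        idx = rng.permutation(n)
    return [chunk for chunk in np.array_split(idx, folds)]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def decode(
    session: Session,
    units,
    spec: DecoderSpec,
    seed: int = 0,
    population_label: str = "custom",
) -> DecodingResult:
    """Cross-validated decoding of HD or AHV from a unit population.

    For HD the network regresses ``(cos theta, sin theta)``; the predicted
    angle ``atan2(sin, cos) mod 2pi`` is scored by the Pearson correlation
    of ``cos`` of predicted vs actual angles.  For AHV the raw value is
    regressed and scored.  Inputs are standardized per unit on the training
    fold only.  Folds whose target is constant are skipped.
    """
    if len(units) == 0:
        raise ValueError("need at least one unit to decode from")
    sub = session.select_units(units)
    v = sub.valid
    X = sub.rates[:, v].T
    if spec.target == "hd":
        theta = sub.hd[v]
        Y = np.column_stack([np.cos(theta), np.sin(theta)])
        truth = theta
    else:
        truth = sub.ahv[v]
        Y = truth.reshape(-1, 1)

    if spec.max_samples is not None and len(X) > spec.max_samples:
        pick = np.linspace(0, len(X) - 1, spec.max_samples).astype(int)
        X, Y, truth = X[pick], Y[pick], truth[pick]

    rng = np.random.default_rng(seed)
    fold_idx = _fold_slices(len(X), spec.folds, spec.fold_mode, rng)
    r_folds: list[float] = []
    for k, test in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(len(X)), test)
        if np.allclose(Y[train].std(axis=0), 0) or np.allclose(
            Y[test].std(axis=0), 0
        ):
            r_folds.append(float("nan"))
            continue
        scaler = StandardScaler().fit(X[train])
        mlp = MLPRegressor(
            hidden_layer_sizes=spec.hidden,
            activation="relu",
            solver="adam",
            alpha=spec.alpha,
            learning_rate_init=spec.learning_rate_init,
            batch_size=min(spec.batch_size, len(train)),
            max_iter=spec.max_iter,
            early_stopping=spec.early_stopping,
            n_iter_no_change=spec.n_iter_no_change,
            random_state=int(rng.integers(2**31)),
        )
        ytr = Y[train] if Y.shape[1] > 1 else Y[train].ravel()
        import warnings

        with warnings.catch_warnings():
            # bounded iteration budget: non-convergence is acceptable
            warnings.simplefilter("ignore")
            mlp.fit(scaler.transform(X[train]), ytr)
        pred = np.atleast_2d(mlp.predict(scaler.transform(X[test])))
        if pred.shape[0] == 1 and Y.shape[1] == 1:
            pred = pred.T
        if spec.target == "hd":
            theta_hat = np.mod(np.arctan2(pred[:, 1], pred[:, 0]), TWO_PI)
            r_folds.append(_pearson(np.cos(theta_hat), np.cos(truth[test])))
        else:
            r_folds.append(_pearson(pred[:, 0], truth[test]))
    return DecodingResult(
        target=spec.target,
        r_folds=r_folds,
        n_units=len(units),
        n_samples=len(X),
        population_label=population_label,
    )


def mvl_threshold_sweep(
    session: Session,
    metrics: pd.DataFrame,
    thresholds,
    spec: DecoderSpec | None = None,
    seed: int = 0,
    targets=("hd", "ahv"),
) -> pd.DataFrame:
    """Decoding skill as the SP/MP boundary moves along the MVL axis.

    At each threshold, HD-significant units with MVL above it form the SP
    population and those below form the MP population; each non-empty
    population is decoded for each target.  Empty populations produce a
    flagged row (NaN r), not an error.
    """
    base = spec or DecoderSpec()
    tuned = metrics[metrics["label"].isin(["SP", "MP"])]
    rows = []
    rng = np.random.default_rng(seed)
    for thr in thresholds:
        if not (0 < thr < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        groups = {
            "SP": list(tuned.index[tuned["mvl"] >= thr]),
            "MP": list(tuned.index[tuned["mvl"] < thr]),
        }
        for label, units in groups.items():
            for target in targets:
                tspec = replace(base, target=target)
                if not units:
                    rows.append(
                        dict(threshold=thr, population=label, target=target,
                             n_units=0, r=np.nan)
                    )
                    continue
                res = decode(
                    session, units, tspec,
                    seed=int(rng.integers(2**31)),
                    population_label=label,
                )
                rows.append(
                    dict(threshold=thr, population=label, target=target,
                         n_units=len(units), r=res.r)
                )
    return pd.DataFrame(rows)
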