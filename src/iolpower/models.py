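"""Regression models predicting the ideal IOL power from normalized biometry.

Two model families are provided:

``fit_svm_rm``
    epsilon-insensitive support vector regression with a polynomial kernel
    (defaults: order 2, epsilon 0.0282, box constraint 0.0049 on the
    [-1, 1]-normalized table), fitted on a 70% partition with a 30% holdout
    for validation MSE reporting.  The convex solver is scikit-learn's SVR.

``fit_mlnn_em``
    a median ensemble of small multilayer networks (5 inputs -> H tanh
    units -> 1 linear output), each trained by Levenberg-Marquardt on
    sum-of-squares loss with Nguyen-Widrow initialization and early
    stopping (patience 20 epochs on a held-out validation partition,
    70:15:15 member-level splits).  The network is tiny (36 parameters at
    H = 5) so the exact Jacobian is formed analytically and the damped
    Gauss-Newton step solved directly.

All randomness flows through numpy Generators derived from explicit seeds,
so fits are bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .cohort import MinMaxNormalizer, PREDICTOR_COLUMNS, TARGET_COLUMN

__all__ = [
    "SvmConfig",
    "MlnnConfig",
    "TrainingReport",
    "MlnnNetwork",
    "SvmModel",
    "MlnnEnsemble",
    "fit_svm_rm",
    "nguyen_widrow_init",
    "train_mlnn_lm",
    "fit_mlnn_em",
    "topology_search",
    "select_topology",
    "predict_iol",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SvmConfig:
    """Support-vector-regression hyperparameters (defaults from the study)."""

    polynomial_order: int = 2
    epsilon: float = 0.0282
    box_constraint: float = 0.0049
    kernel_scale: float = 1.0
    holdout_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.box_constraint <= 0:
            raise ValueError("epsilon and box_constraint must be positive")
        if self.polynomial_order < 1:
            raise ValueError("polynomial_order must be >= 1")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class MlnnConfig:
    """Configuration of the Levenberg-Marquardt network ensemble."""

    hidden_neurons: int = 5
    ensemble_size: int = 10
    train_fraction: float = 0.70
    val_fraction: float = 0.15
    test_fraction: float = 0.15
    patience_epochs: int = 20
    max_epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_neurons < 1 or self.ensemble_size < 1:
            raise ValueError("hidden_neurons and ensemble_size must be >= 1")
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("train/val/test fractions must sum to 1")


@dataclass
class MemberReport:
    """Per-member training record."""

    train_mse: float
    val_mse: float
    test_mse: float
    epoch: int


@dataclass
class TrainingReport:
    """Ensemble-level aggregation of member train/val/test MSE and epochs."""

    members: List[MemberReport]

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(m) for m in self.members])
        return df.agg(["mean", "median", "std", "min", "max"])


# ---------------------------------------------------------------------------
# small tanh network
# ---------------------------------------------------------------------------

class MlnnNetwork:
    """Single-hidden-layer tanh network with a linear output unit.

    f(x) = w2 . tanh(W1 x + b1) + b2, parameters held as flat arrays for
    the Levenberg-Marquardt solver.
    """

    def __init__(self, w1: np.ndarray, b1: np.ndarray, w2: np.ndarray, b2: float):
        self.w1 = np.asarray(w1, dtype=float)       # (H, n)
        self.b1 = np.asarray(b1, dtype=float)       # (H,)
        self.w2 = np.asarray(w2, dtype=float)       # (H,)
        self.b2 = float(b2)

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[0]

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        h = np.tanh(x @ self.w1.T + self.b1)
        return h @ self.w2 + self.b2

    # -- flat parameter vector ------------------------------------------------
    def get_params(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2, [self.b2]])

    def set_params(self, theta: np.ndarray) -> None:
        H, n = self.w1.shape
        k = 0
        self.w1 = theta[k:k + H * n].reshape(H, n); k += H * n
        self.b1 = theta[k:k + H].copy(); k += H
        self.w2 = theta[k:k + H].copy(); k += H
        self.b2 = float(theta[k])

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """d f / d theta, shape (m, n_params), analytic."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        m = x.shape[0]
        h = np.tanh(x @ self.w1.T + self.b1)            # (m, H)
        dh = 1.0 - h * h                                # (m, H)
        g = dh * self.w2                                # (m, H)  df/dz_i
        j_w1 = g[:, :, None] * x[:, None, :]            # (m, H, n)
        return np.concatenate(
            [j_w1.reshape(m, -1), g, h, np.ones((m, 1))], axis=1
        )

    def copy(self) -> "MlnnNetwork":
        return MlnnNetwork(self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2)


def nguyen_widrow_init(
    n_inputs: int, n_hidden: int, seed: int | np.random.Generator
) -> MlnnNetwork:
    """Nguyen-Widrow initialization for the hidden layer.

    Each hidden unit's input-weight row is a random direction scaled to
    magnitude beta = 0.7 * H^(1/n); biases are uniformly spread over
    [-beta, beta] with alternating sign, so the units' active regions tile
    the input domain.  The output layer starts small and random.
    """
    if n_inputs < 1 or n_hidden < 1:
        raise ValueError("n_inputs and n_hidden must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = 0.7 * n_hidden ** (1.0 / n_inputs)
    w1 = rng.standard_normal((n_hidden, n_inputs))
    norms = np.linalg.norm(w1, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    w1 = w1 / norms * beta
    if n_hidden > 1:
        positions = np.linspace(-beta, beta, n_hidden)
    else:
        positions = np.zeros(1)
    signs = np.where(np.arange(n_hidden) % 2 == 0, 1.0, -1.0)
    b1 = positions * signs
    w2 = rng.standard_normal(n_hidden) * 0.1
    b2 = float(rng.standard_normal() * 0.1)
    return MlnnNetwork(w1, b1, w2, b2)


def train_mlnn_lm(
    net: MlnnNetwork,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: MlnnConfig = MlnnConfig(),
    lambda0: float = 1e-3,
    lambda_cap: float = 1e10,
) -> Tuple[MlnnNetwork, Dict[str, float]]:
    """Levenberg-Marquardt training with validation-based early stopping.

    One epoch = one accepted damped Gauss-Newton step (the damping factor
    is divided by 10 on acceptance, multiplied by 10 on rejection).
    Training stops when the validation MSE has not strictly decreased for
    ``patience_epochs`` consecutive epochs, when ``max_epochs`` is reached,
    or when the damping factor exceeds its cap; the weights at the
    validation minimum are returned (the early-stopping contract).
    """
    x_train = np.atleast_2d(np.asarray(x_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float).ravel()
    x_val = np.atleast_2d(np.asarray(x_val, dtype=float))
    y_val = np.asarray(y_val, dtype=float).ravel()

    net = net.copy()
    lam = lambda0

    def val_mse(n: MlnnNetwork) -> float:
        r = y_val - n.predict(x_val)
        return float(np.mean(r * r))

    best = net.copy()
    best_val = val_mse(net)
    best_epoch = 0
    since_best = 0
    epoch = 0
    val_history = [best_val]  # index = epoch (0 = initial weights)

    resid = y_train - net.predict(x_train)
    sse = float(resid @ resid)
    warned = False

    while epoch < config.max_epochs:
        jac = net.jacobian(x_train)
        jtj = jac.T @ jac
        jtr = jac.T @ resid
        accepted = False
        while lam <= lambda_cap:
            try:
                step = np.linalg.solve(jtj + lam * np.eye(jtj.shape[0]), jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            theta_new = net.get_params() + step
            trial = net.copy()
            trial.set_params(theta_new)
            r_new = y_train - trial.predict(x_train)
            sse_new = float(r_new @ r_new)
            if sse_new < sse:
                net, resid, sse = trial, r_new, sse_new
                lam = max(lam / 10.0, 1e-15)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            warnings.warn("LM damping cap reached; returning best-so-far weights")
            warned = True
            break
        epoch += 1
        v = val_mse(net)
        val_history.append(v)
        if v < best_val:
            best, best_val, best_epoch = net.copy(), v, epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience_epochs:
                break
        if sse / max(len(y_train), 1) < 1e-14:
            break

    r_tr = y_train - best.predict(x_train)
    info = {
        "train_mse": float(np.mean(r_tr * r_tr)),
        "val_mse": best_val,
        "epoch": best_epoch,
        "epochs_run": epoch,
        "damping_capped": warned,
        "val_history": val_history,
    }
    return best, info


# ---------------------------------------------------------------------------
# fitted model wrappers
# ---------------------------------------------------------------------------

@dataclass
class SvmModel:
    """Fitted SVR plus its configuration and holdout diagnostics."""

    svr: SVR
    config: SvmConfig
    holdout_mse: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.svr.predict(np.atleast_2d(np.asarray(x, dtype=float)))


@dataclass
class MlnnEnsemble:
    """Median ensemble of trained networks."""

    members: List[MlnnNetwork]
    config: MlnnConfig
    report: TrainingReport

    def predict(self, x: np.ndarray) -> np.ndarray:
        preds = np.stack([m.predict(x) for m in self.members])
        return np.median(preds, axis=0)


def _holdout_split(n: int, holdout_fraction: float, rng: np.random.Generator):
    n_hold = int(round(holdout_fraction * n))
    n_hold = min(max(n_hold, 1), n - 1)
    perm = rng.permutation(n)
    return perm[n_hold:], perm[:n_hold]


def fit_svm_rm(
    training_table: pd.DataFrame,
    config: SvmConfig = SvmConfig(),
) -> SvmModel:
    """Fit the polynomial-kernel epsilon-SVR with a seeded 30% holdout.

    The model is fitted on the 70% partition; the reported MSE is measured
    on the untouched 30% holdout.  Kernel form:
    (kernel_scale * <x, x'> + 1)^order.
    """
    x = training_table[PREDICTOR_COLUMNS].to_numpy(dtype=float)
    y = training_table[TARGET_COLUMN].to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)
    fit_idx, hold_idx = _holdout_split(len(y), config.holdout_fraction, rng)
    svr = SVR(
        kernel="poly",
        degree=config.polynomial_order,
        gamma=config.kernel_scale,
        coef0=1.0,
        C=config.box_constraint,
        epsilon=config.epsilon,
        tol=1e-5,
        max_iter=-1,
    )
    svr.fit(x[fit_idx], y[fit_idx])
    resid = y[hold_idx] - svr.predict(x[hold_idx])
    return SvmModel(svr=svr, config=config, holdout_mse=float(np.mean(resid * resid)))


def _three_way_split(n: int, cfg: MlnnConfig, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_tr = int(round(cfg.train_fraction * n))
    n_val = int(round(cfg.val_fraction * n))
    n_tr = max(1, min(n_tr, n - 2))
    n_val = max(1, min(n_val, n - n_tr - 1))
    return perm[:n_tr], perm[n_tr:n_tr + n_val], perm[n_tr + n_val:]


def fit_mlnn_em(
    training_table: pd.DataFrame,
    config: MlnnConfig = MlnnConfig(),
) -> MlnnEnsemble:
    """Train the median ensemble on the normalized selection table.

    Each member draws its own 70:15:15 train/validation/test split and its
    own Nguyen-Widrow initialization from an independent seeded stream.
    A member that fails to train is recorded and dropped; the ensemble is
    valid while at least half the members survive.
    """
    x = training_table[PREDICTOR_COLUMNS].to_numpy(dtype=float)
    y = training_table[TARGET_COLUMN].to_numpy(dtype=float)
    n = len(y)
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.ensemble_size)
    members: List[MlnnNetwork] = []
    reports: List[MemberReport] = []
    failures = 0
    for child in children:
        rng = np.random.default_rng(child)
        tr, va, te = _three_way_split(n, config, rng)
        net0 = nguyen_widrow_init(x.shape[1], config.hidden_neurons, rng)
        try:
            net, info = train_mlnn_lm(net0, x[tr], y[tr], x[va], y[va], config)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"ensemble member failed to train: {exc}")
            failures += 1
            continue
        r_te = y[te] - net.predict(x[te])
        members.append(net)
        reports.append(
            MemberReport(
                train_mse=info["train_mse"],
                val_mse=info["val_mse"],
                test_mse=float(np.mean(r_te * r_te)),
                epoch=info["epoch"],
            )
        )
    if len(members) < (config.ensemble_size + 1) // 2:
        raise RuntimeError(
            f"too many ensemble members failed ({failures}/{config.ensemble_size})"
        )
    return MlnnEnsemble(members=members, config=config, report=TrainingReport(reports))


def select_topology(scores: Mapping[int, float]) -> int:
    """Smallest hidden size minimizing the supplied score (ties -> fewer)."""
    if not scores:
        raise ValueError("empty score map")
    best = min(scores.values())
    return min(h for h, s in scores.items() if s == best)


def topology_search(
    training_table: pd.DataFrame,
    h_range: Sequence[int] = range(1, 351),
    config: MlnnConfig = MlnnConfig(),
) -> Tuple[int, Dict[int, Dict[str, float]]]:
    """Hidden-layer size search minimizing median + 1 STD of test MSE.

    Trains a full ensemble per candidate size and scores it by the median
    plus one standard deviation of the member test MSEs; returns the
    argmin (ties broken toward fewer neurons) and the per-size summary.
    """
    h_range = list(h_range)
    if not h_range:
        raise ValueError("h_range must be non-empty")
    summaries: Dict[int, Dict[str, float]] = {}
    scores: Dict[int, float] = {}
    for h in h_range:
        cfg = MlnnConfig(
            hidden_neurons=h,
            ensemble_size=config.ensemble_size,
            train_fraction=config.train_fraction,
            val_fraction=config.val_fraction,
            test_fraction=config.test_fraction,
            patience_epochs=config.patience_epochs,
            max_epochs=config.max_epochs,
            seed=config.seed + h,
        )
        ens = fit_mlnn_em(training_table, cfg)
        test = np.array([m.test_mse for m in ens.report.members])
        med = float(np.median(test))
        std = float(np.std(test, ddof=1)) if len(test) > 1 else 0.0
        score = med + std
        summaries[h] = {"median_test_mse": med, "std_test_mse": std, "score": score}
        scores[h] = score
    return select_topology(scores), summaries


def predict_iol(
    model: SvmModel | MlnnEnsemble,
    predictors: pd.DataFrame,
    params: MinMaxNormalizer,
    check_range: bool = True,
) -> np.ndarray:
    """Predict IOL power in diopters from raw (unnormalized) predictors.

    Predictors are normalized with the selection-set parameters, passed
    through the model, and the output denormalized back to diopters.
    Out-of-range inputs raise, mirroring the verification-set clearing
    policy (disable with ``check_range=False``).
    """
    raw = predictors[PREDICTOR_COLUMNS].astype(float)
    if check_range:
        for col in PREDICTOR_COLUMNS:
            x = raw[col]
            if ((x < params.mins_[col]) | (x > params.maxs_[col])).any():
                raise ValueError(
                    f"predictor {col!r} outside the selection-set range; "
                    "clear out-of-range cases first"
                )
    xn = params.transform(raw).to_numpy()
    yn = model.predict(xn)
    return params.inverse_transform_column(TARGET_COLUMN, yn)


# ---------------------------------------------------------------------------
# serialization (versioned JSON; text-only on-disk format)
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(
    path: str | Path,
    model: SvmModel | MlnnEnsemble,
    normalizer: MinMaxNormalizer,
) -> None:
    """Serialize a fitted model + normalizer to a versioned JSON file."""
    path = Path(path)
    if isinstance(model, MlnnEnsemble):
        payload = {
            "format_version": _FORMAT_VERSION,
            "kind": "mlnn_em",
            "config": asdict(model.config),
            "normalizer": normalizer.to_dict(),
            "report": [asdict(m) for m in model.report.members],
            "members": [
                {
                    "w1": m.w1.tolist(),
                    "b1": m.b1.tolist(),
                    "w2": m.w2.tolist(),
                    "b2": m.b2,
                }
                for m in model.members
            ],
        }
    elif isinstance(model, SvmModel):
        svr = model.svr
        payload = {
            "format_version": _FORMAT_VERSION,
            "kind": "svm_rm",
            "config": asdict(model.config),
            "normalizer": normalizer.to_dict(),
            "holdout_mse": model.holdout_mse,
            "svr": {
                "support_vectors": svr.support_vectors_.tolist(),
                "dual_coef": svr.dual_coef_.tolist(),
                "intercept": svr.intercept_.tolist(),
                "degree": svr.degree,
                "gamma": float(svr._gamma),
                "coef0": svr.coef0,
            },
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model)!r}")
    path.write_text(json.dumps(payload))


class _KernelSvm:
    """Deserialized SVR evaluated directly from its dual representation."""

    def __init__(self, d: Mapping[str, object]):
        self.sv = np.asarray(d["support_vectors"], dtype=float)
        self.dual = np.asarray(d["dual_coef"], dtype=float).ravel()
        self.intercept = float(np.asarray(d["intercept"]).ravel()[0])
        self.degree = int(d["degree"])
        self.gamma = float(d["gamma"])
        self.coef0 = float(d["coef0"])

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        k = (self.gamma * (x @ self.sv.T) + self.coef0) ** self.degree
        return k @ self.dual + self.intercept


def load_model(path: str | Path) -> Tuple[object, MinMaxNormalizer]:
    """Load a model serialized by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')!r}")
    normalizer = MinMaxNormalizer.from_dict(payload["normalizer"])
    if payload["kind"] == "mlnn_em":
        members = [
            MlnnNetwork(np.array(m["w1"]), np.array(m["b1"]), np.array(m["w2"]), m["b2"])
            for m in payload["members"]
        ]
        report = TrainingReport([MemberReport(**r) for r in payload["report"]])
        model = MlnnEnsemble(
            members=members, config=MlnnConfig(**payload["config"]), report=report
        )
    elif payload["kind"] == "svm_rm":
        model = SvmModel(
            svr=_KernelSvm(payload["svr"]),  # type: ignore[arg-type]
            config=SvmConfig(**payload["config"]),
            holdout_mse=payload["holdout_mse"],
        )
    else:
        raise ValueError(f"unknown model kind {payload['kind']!r}")
    return model, normalizer
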