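"""3-D convolutional regression of porphyrin distortion from pocket voxels.

The network takes a binary occupancy cube (side 17, 20 or 24; one or four
element channels) and regresses the NSD amplitude of one mode, or all twelve
at once.  Architecture (fixed):

    conv 64, k2, pad 1  ->  conv 128, k2, pad 1  ->  batch-norm
    -> conv 128, k2, no pad -> ReLU -> batch-norm -> max-pool k2 s2
    -> flatten -> linear 128 -> ReLU -> dropout 0.4 -> linear 64
    -> batch-norm -> ReLU -> linear out

For a 20 A four-channel input the spatial trace is 20 -> 21 -> 22 -> 21 -> 10
and the flattened width is 128 * 10^3 = 128000.

Training uses Adam (learning rate 0.01), batch size 32, mean-square-error
loss; the parameters from the epoch with the minimal validation loss are
retained (earliest epoch on ties).  Evaluation uses the coefficient of
determination R^2 = 1 - SS_res / SS_tot and the RMSE in angstroms.  Five-fold
cross-validation splits each held-out subset 0.2 / 0.8 into validation and
test parts.  The masking ablation re-evaluates trained fold models on inputs
with the outer or inner cubic region discarded.

Exposed both as plain functions and as the ``DistortionCNN`` model object
whose ``fit`` returns a ``DistortionCNNResults`` with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import nnet
from .voxel import MaskSpec, mask_batch, retained_volume

STANDARD_EDGES = (17, 20, 24)


@dataclass(frozen=True)
class ModelSpec:
    """Input geometry and output dimensionality of the regressor."""

    edge: int = 20
    channels_in: int = 4
    out_dim: int = 1

    def __post_init__(self) -> None:
        if self.channels_in not in (1, 4):
            raise ValueError(f"channels_in must be 1 or 4, got {self.channels_in}")
        if self.out_dim not in (1, 12):
            raise ValueError(f"out_dim must be 1 or 12, got {self.out_dim}")
        if self.edge < 4:
            raise ValueError(
                f"input side {self.edge} is too small: the conv/pool trace underflows (minimum 4)"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; defaults follow the study settings."""

    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 300
    seed: int = 0
    dropout: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")


def shape_trace(edge: int) -> dict[str, int]:
    """Spatial side after each stage of the convolution/pooling stack."""
    c1 = edge + 1       # conv k2 pad1
    c2 = c1 + 1         # conv k2 pad1
    c3 = c2 - 1         # conv k2 no pad
    pool = c3 // 2      # max-pool k2 s2
    if pool < 1:
        raise ValueError(f"max-pool underflow for input side {edge}")
    return {"conv1": c1, "conv2": c2, "conv3": c3, "pool": pool}


def flat_feature_count(edge: int) -> int:
    """Flattened feature width after the convolution stack: 128 * s^3."""
    if edge < 4:
        raise ValueError(f"input side must be >= 4, got {edge}")
    s = (edge + 1 - 2) // 2 + 1
    return 128 * s ** 3


def build_model(spec: ModelSpec, rng: np.random.Generator | None = None) -> nnet.Sequential:
    """Instantiate the regressor for a given input geometry.

    ``rng`` seeds the weight initialization; a fresh default generator is
    used when omitted.
    """
    if rng is None:
        rng = np.random.default_rng()
    trace = shape_trace(spec.edge)
    flat = 128 * trace["pool"] ** 3
    assert flat == flat_feature_count(spec.edge)
    # the input layer needs no input gradient; volumetric batch-norm/ReLU
    # run in place on the pooled conv outputs to halve activation memory
    return nnet.Sequential([
        nnet.Conv3d(spec.channels_in, 64, pad=1, rng=rng, input_grad=False),
        nnet.Conv3d(64, 128, pad=1, rng=rng),
        nnet.BatchNorm(128, inplace=True),
        nnet.Conv3d(128, 128, pad=0, rng=rng),
        nnet.ReLU(inplace=True),
        nnet.BatchNorm(128, inplace=True),
        nnet.MaxPool3d(),
        nnet.Flatten(),
        nnet.Linear(flat, 128, rng=rng),
        nnet.ReLU(),
        nnet.Dropout(0.4),
        nnet.Linear(128, 64, rng=rng),
        nnet.BatchNorm(64),
        nnet.ReLU(),
        nnet.Linear(64, spec.out_dim, rng=rng),
    ])


def _to_channels_last(x: np.ndarray) -> np.ndarray:
    """(n, C, L, L, L) -> float32 (n, L, L, L, C)."""
    if x.ndim != 5:
        raise ValueError(f"expected (n, channels, L, L, L) input, got shape {x.shape}")
    return np.ascontiguousarray(np.moveaxis(x, 1, -1), dtype=np.float32)


def predict(model: nnet.Sequential, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Evaluation-mode forward pass over a (n, C, L, L, L) batch."""
    xc = _to_channels_last(x)
    outs = [model.forward(xc[i:i + batch_size]) for i in range(0, len(xc), batch_size)]
    return np.concatenate(outs, axis=0)


def r2_score(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot (at most 1).

    The reference mean is taken over the evaluated set itself.  Raises on
    zero total variance, where the score is undefined.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("r2_score needs two equal-length vectors of length >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values are all equal; R^2 is undefined")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root-mean-square error in the units of the inputs (angstroms here)."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape or observed.size < 1:
        raise ValueError("rmse needs two equal-length nonempty vectors")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def train_model(
    model: nnet.Sequential,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[nnet.Sequential, pd.DataFrame, int]:
    """Train with Adam/MSE and return the minimum-validation-loss model.

    Returns ``(model, history, best_epoch)`` where ``history`` has one row
    per epoch (train and validation loss) and ``best_epoch`` is the earliest
    epoch attaining the minimal validation loss (0-based).  The model is left
    holding the best epoch's parameters and running statistics.  Aborts with
    a diagnostic if the loss turns non-finite.
    """
    xtr, ytr = train_set
    xval, yval = val_set
    if len(xtr) == 0 or len(xval) == 0:
        raise ValueError("training and validation sets must be nonempty")
    ytr = np.asarray(ytr, dtype=np.float32).reshape(len(xtr), -1)
    yval = np.asarray(yval, dtype=np.float32).reshape(len(xval), -1)
    if not (np.all(np.isfinite(ytr)) and np.all(np.isfinite(yval))):
        raise ValueError("labels contain non-finite values")
    xtr = _to_channels_last(xtr)
    xval_cl = _to_channels_last(xval)

    rng = np.random.default_rng(cfg.seed)
    opt = nnet.Adam(model.params(), lr=cfg.learning_rate)
    if not cfg.dropout:
        for layer in model.layers:
            if isinstance(layer, nnet.Dropout):
                layer.p = 0.0

    history = []
    best_state = model.state()
    best_val = np.inf
    best_epoch = 0
    n = len(xtr)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        running = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            pred = model.forward(xtr[idx], training=True, rng=rng)
            loss, dpred = nnet.mse_loss(pred, ytr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch}")
            model.backward(dpred)
            opt.step(model.grads())
            running += loss * len(idx)
        train_loss = running / n
        val_pred = np.concatenate(
            [model.forward(xval_cl[i:i + cfg.batch_size]) for i in range(0, len(xval_cl), cfg.batch_size)]
        )
        val_loss = float(np.mean((val_pred - yval) ** 2))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"training diverged: non-finite validation loss at epoch {epoch}")
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = model.state()
    model.load_state(best_state)
    return model, pd.DataFrame(history), best_epoch


@dataclass
class CVReport:
    """Per-fold metrics of a k-fold cross-validation run."""

    fold_r2: list[float]
    fold_rmse: list[float]
    best_epochs: list[int]
    splits: list[dict[str, np.ndarray]]        # train / val / test index arrays per fold
    per_type_rmse: pd.DataFrame | None = None  # heme type x fold
    histories: list[pd.DataFrame] = field(default_factory=list)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def sd_r2(self) -> float:
        return float(np.std(self.fold_r2, ddof=1)) if len(self.fold_r2) > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        rows = [
            {"fold": i, "r2": r, "rmse": e, "best_epoch": b,
             "n_train": len(s["train"]), "n_val": len(s["val"]), "n_test": len(s["test"])}
            for i, (r, e, b, s) in enumerate(zip(self.fold_r2, self.fold_rmse, self.best_epochs, self.splits))
        ]
        return pd.DataFrame(rows)


def make_cv_splits(n: int, k: int, seed: int, val_fraction: float = 0.2) -> list[dict[str, np.ndarray]]:
    """Shuffle, partition into k subsets, split each subset 0.2/0.8 val/test.

    The k (validation + test) subsets are pairwise disjoint and cover the
    dataset; the train block of fold i is the union of the other k-1 subsets.
    """
    if n < 5 * k:
        raise ValueError(f"cross-validation needs n >= 5k (= {5 * k}), got n = {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    subsets = np.array_split(perm, k)
    splits = []
    for i, sub in enumerate(subsets):
        n_val = int(round(val_fraction * len(sub)))
        n_val = min(max(n_val, 1), len(sub) - 1)
        train = np.concatenate([s for j, s in enumerate(subsets) if j != i])
        splits.append({"train": train, "val": sub[:n_val], "test": sub[n_val:]})
    return splits


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    k: int = 5,
    spec: ModelSpec | None = None,
    heme_types: Sequence[str] | None = None,
    keep_models: bool = False,
) -> CVReport | tuple[CVReport, list[nnet.Sequential], list[dict[str, np.ndarray]]]:
    """k-fold cross-validation with the per-subset 0.2/0.8 val/test split.

    ``x`` is (n, C, L, L, L), ``y`` is (n,) or (n, out_dim).  When
    ``heme_types`` labels are given, per-type RMSE over test samples is
    tabulated per fold.  With ``keep_models`` the trained fold models and
    splits are returned as well (used by the masking ablation).
    """
    y = np.asarray(y, dtype=np.float32)
    y2 = y.reshape(len(y), -1)
    if spec is None:
        spec = ModelSpec(edge=x.shape[-1], channels_in=x.shape[1], out_dim=y2.shape[1])
    splits = make_cv_splits(len(x), k, cfg.seed)
    fold_r2, fold_rmse, best_epochs, histories, models = [], [], [], [], []
    type_rows: dict[str, dict[int, float]] = {}
    for fold, sp in enumerate(splits):
        rng = np.random.default_rng((cfg.seed, fold))
        model = build_model(spec, rng=rng)
        fold_cfg = replace(cfg, seed=int(np.random.default_rng((cfg.seed, fold, 1)).integers(2 ** 31)))
        model, hist, best = train_model(model, (x[sp["train"]], y2[sp["train"]]),
                                        (x[sp["val"]], y2[sp["val"]]), fold_cfg)
        pred = predict(model, x[sp["test"]], batch_size=cfg.batch_size)
        obs = y2[sp["test"]]
        fold_r2.append(float(np.mean([r2_score(obs[:, j], pred[:, j]) for j in range(obs.shape[1])])))
        fold_rmse.append(rmse(obs, pred))
        best_epochs.append(best)
        histories.append(hist)
        if heme_types is not None:
            types = np.asarray(heme_types)[sp["test"]]
            for t in np.unique(types):
                sel = types == t
                type_rows.setdefault(str(t), {})[fold] = rmse(obs[sel], pred[sel])
        if keep_models:
            models.append(model)
    per_type = pd.DataFrame(type_rows).T if type_rows else None
    report = CVReport(fold_r2, fold_rmse, best_epochs, splits, per_type, histories)
    if keep_models:
        return report, models, splits
    return report


def ablation_curve(
    models: Sequence[nnet.Sequential],
    test_sets: Sequence[tuple[np.ndarray, np.ndarray]],
    mode: str,
    r_values: Sequence[float],
    batch_size: int = 32,
) -> pd.DataFrame:
    """Discard a cubic region of the test inputs and re-score each fold model.

    ``models`` are fold models trained on unmasked 24 A grids and
    ``test_sets`` the matching per-fold (x, y) test data.  One row per r:
    retained volume, mean R^2 over folds and its standard deviation.  At
    r = 0 the grids pass through unchanged, so the row equals the baseline
    evaluation exactly.
    """
    rows = []
    for r in r_values:
        spec = MaskSpec(mode=mode, r=r)
        scores = []
        for model, (x, y) in zip(models, test_sets):
            xm = mask_batch(x, spec)
            pred = predict(model, xm, batch_size=batch_size)
            scores.append(r2_score(np.asarray(y).ravel(), pred.ravel()))
        rows.append({
            "r": r,
            "retained_volume": retained_volume(spec),
            "mean_r2": float(np.mean(scores)),
            "sd_r2": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results objects


class DistortionCNN:
    """Pocket-voxel -> distortion regressor with a fit/results interface.

    Parameters
    ----------
    grids : (n, channels, L, L, L) binary occupancy grids.
    amplitudes : (n,) or (n, 12) NSD amplitudes in angstroms.
    cfg : training protocol; defaults to the study protocol.
    heme_types : optional per-sample heme type labels for stratified RMSE.
    """

    def __init__(
        self,
        grids: np.ndarray,
        amplitudes: np.ndarray,
        cfg: TrainConfig | None = None,
        heme_types: Sequence[str] | None = None,
    ):
        self.x = np.asarray(grids)
        self.y = np.asarray(amplitudes, dtype=np.float32).reshape(len(grids), -1)
        if len(self.x) != len(self.y):
            raise ValueError("grids and amplitudes disagree in length")
        self.cfg = cfg or TrainConfig()
        self.heme_types = list(heme_types) if heme_types is not None else None
        self.spec = ModelSpec(edge=self.x.shape[-1], channels_in=self.x.shape[1],
                              out_dim=self.y.shape[1])

    @classmethod
    def from_dataframe(cls, grids: np.ndarray, manifest: pd.DataFrame,
                       mode: str = "saddling", cfg: TrainConfig | None = None) -> "DistortionCNN":
        """Build from a curation manifest carrying per-mode amplitude columns."""
        types = manifest["heme_type"].tolist() if "heme_type" in manifest else None
        return cls(grids, manifest[mode].to_numpy(), cfg=cfg, heme_types=types)

    def fit(self, val_fraction: float = 0.2, test_fraction: float = 0.0,
            seed: int | None = None) -> "DistortionCNNResults":
        """Train once on a shuffled train/validation(/test) split."""
        seed = self.cfg.seed if seed is None else seed
        n = len(self.x)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        n_test = int(round(test_fraction * n))
        val_idx, test_idx, train_idx = perm[:n_val], perm[n_val:n_val + n_test], perm[n_val + n_test:]
        model = build_model(self.spec, rng=np.random.default_rng((seed, 1)))
        cfg = replace(self.cfg, seed=seed)
        model, history, best = train_model(
            model, (self.x[train_idx], self.y[train_idx]), (self.x[val_idx], self.y[val_idx]), cfg)
        return DistortionCNNResults(self, model, history, best,
                                    {"train": train_idx, "val": val_idx, "test": test_idx})

    def cross_validate(self, k: int = 5, keep_models: bool = False):
        return cross_validate(self.x, self.y, self.cfg, k=k, spec=self.spec,
                              heme_types=self.heme_types, keep_models=keep_models)


class DistortionCNNResults:
    """Fitted regressor: predictions, scores, training history, summary."""

    def __init__(self, model_obj: DistortionCNN, net: nnet.Sequential,
                 history: pd.DataFrame, best_epoch: int, splits: Mapping[str, np.ndarray]):
        self.model = model_obj
        self.net = net
        self.history = history
        self.best_epoch = best_epoch
        self.splits = dict(splits)

    def predict(self, grids: np.ndarray) -> np.ndarray:
        return predict(self.net, grids, batch_size=self.model.cfg.batch_size)

    def score(self, grids: np.ndarray, amplitudes: np.ndarray) -> dict[str, float]:
        pred = self.predict(grids).ravel()
        obs = np.asarray(amplitudes, dtype=float).ravel()
        return {"r2": r2_score(obs, pred), "rmse": rmse(obs, pred)}

    def test_score(self) -> dict[str, float]:
        idx = self.splits["test"]
        if len(idx) == 0:
            raise ValueError("no test split was reserved at fit time")
        return self.score(self.model.x[idx], self.model.y[idx])

    def summary(self) -> str:
        cfg = self.model.cfg
        spec = self.model.spec
        lines = [
            "Pocket-voxel distortion regression (3-D CNN)",
            "=" * 46,
            f"input                {spec.channels_in} x {spec.edge}^3 voxels (1 A cells)",
            f"output dim           {spec.out_dim}",
            f"flat features        {flat_feature_count(spec.edge)}",
            f"optimizer            Adam, lr {cfg.learning_rate}, batch {cfg.batch_size}",
            f"epochs               {cfg.epochs} (best: {self.best_epoch})",
            f"best val MSE         {self.history['val_loss'].min():.5f} A^2",
            f"n train/val/test     {len(self.splits['train'])}/{len(self.splits['val'])}/{len(self.splits['test'])}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training and validation loss curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train")
        ax.plot(self.history["epoch"], self.history["val_loss"], label="validation")
        ax.axvline(self.best_epoch, ls=":", c="k", lw=0.8)
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE loss (A$^2$)")
        ax.legend()
        return ax
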