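"""Site classifier estimator, fold construction, and cross-validation.

:class:`ConvGRUSiteClassifier` is a scikit-learn-style estimator whose input
``X`` is a list of L×29 matrices (or :class:`SiteFeatureMatrix` objects) of
varying L.  The positive class is "physiological"; its contribution to the
training loss is scaled by ``class_weight_positive`` (default 1.7) to
compensate for the class imbalance of curated metal-site datasets.

Model selection follows the rotation protocol of 10-fold cross-validation:
each fold serves once as the held-out test set, the next fold in rotation
order is the validation set driving early stopping, and the remaining folds
train the network.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .features import SiteFeatureMatrix
from .network import Adam, ConvGRUNet, NetParams, clip_gradients

__all__ = [
    "POSITIVE_CLASS",
    "NEGATIVE_CLASS",
    "Prediction",
    "ConvGRUSiteClassifier",
    "FoldSplit",
    "RotationResult",
    "CVResult",
    "make_folds",
    "cross_validate",
    "predictions_to_tsv",
]

POSITIVE_CLASS = "physiological"
NEGATIVE_CLASS = "adventitious"

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class Prediction:
    """Two-class output for one site.

    ``confidence`` is the absolute difference of the two class probabilities
    (equivalently |2·p_physiological − 1|); the class is called positive iff
    p_physiological strictly exceeds the decision threshold β.
    """

    site_id: str
    p_physiological: float
    p_adventitious: float
    assigned_class: str
    fold: int = -1

    def __post_init__(self):
        s = self.p_physiological + self.p_adventitious
        if not (abs(s - 1.0) < 1e-6):
            raise ValueError(f"probabilities sum to {s}, expected 1")

    @property
    def confidence(self) -> float:
        return abs(self.p_physiological - self.p_adventitious)


def _matrices(X) -> list[np.ndarray]:
    out = []
    for x in X:
        arr = x.values if isinstance(x, SiteFeatureMatrix) else np.asarray(x, float)
        if arr.ndim != 2:
            raise ValueError("each site must be a 2-D (L × n_features) matrix")
        if arr.shape[0] < 1:
            raise ValueError("zero-length site matrix")
        out.append(arr)
    return out


def _site_ids(X, n: int) -> list[str]:
    ids = []
    for i, x in enumerate(X):
        ids.append(x.site_id if isinstance(x, SiteFeatureMatrix) else f"site_{i}")
    return ids


class ConvGRUSiteClassifier(BaseEstimator, ClassifierMixin):
    """Conv1D → GRU → linear classifier for variable-length site matrices.

    Parameters
    ----------
    conv_width : odd window size w of the 1-D convolution (default 7).
    conv_channels, hidden_size : layer widths; defaults (64, 128) are
        configurable conventions, scaled down freely for small problems.
    class_weight_positive : loss multiplier for physiological sites (1.7).
    input_noise : training-time augmentation — per-element Gaussian noise
        with sd = input_noise × (feature's training-data range).  Makes the
        network robust to (and hence diagnostic under) domain-scaled
        perturbations of uninformative features; 0 disables.
    threshold : decision threshold β on p_physiological; a tie classifies
        as adventitious (strict ``>`` for the positive call).
    validation_fraction : held-out fraction used for early stopping when no
        explicit validation set is passed to :meth:`fit`.
    """

    def __init__(
        self,
        conv_width: int = 7,
        conv_channels: int = 64,
        hidden_size: int = 128,
        class_weight_positive: float = 1.7,
        learning_rate: float = 5e-3,
        weight_decay: float = 1.5,
        dropout: float = 0.3,
        input_noise: float = 0.3,
        max_epochs: int = 250,
        patience: int = 40,
        batch_size: int = 32,
        threshold: float = 0.5,
        validation_fraction: float = 0.1,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.conv_width = conv_width
        self.conv_channels = conv_channels
        self.hidden_size = hidden_size
        self.class_weight_positive = class_weight_positive
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.input_noise = input_noise
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.threshold = threshold
        self.validation_fraction = validation_fraction
        self.standardize = standardize
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, X_val=None, y_val=None):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        mats = _matrices(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        if set(classes) - {POSITIVE_CLASS, NEGATIVE_CLASS}:
            raise ValueError(f"labels must be {POSITIVE_CLASS!r}/{NEGATIVE_CLASS!r}")
        self.classes_ = np.array([NEGATIVE_CLASS, POSITIVE_CLASS])
        self.n_features_in_ = mats[0].shape[1]
        if any(m.shape[1] != self.n_features_in_ for m in mats):
            raise ValueError("inconsistent feature counts across sites")

        rng = np.random.default_rng(self.random_state)

        if X_val is None:
            idx = np.arange(len(mats))
            val_idx = self._stratified_holdout(y, rng)
            train_idx = np.setdiff1d(idx, val_idx)
            mats_val = [mats[i] for i in val_idx]
            yv = y[val_idx]
            mats = [mats[i] for i in train_idx]
            y = y[train_idx]
        else:
            mats_val = _matrices(X_val)
            yv = np.asarray(y_val)

        stacked = np.vstack(mats)
        if self.standardize:
            self.scaler_mean_ = stacked.mean(axis=0)
            std = stacked.std(axis=0)
            std[std == 0] = 1.0
            self.scaler_std_ = std
        else:
            self.scaler_mean_ = np.zeros(self.n_features_in_)
            self.scaler_std_ = np.ones(self.n_features_in_)
        # training-noise scale: a fraction of each feature's domain magnitude
        # (max − min over training residues), in standardized units
        col_range = stacked.max(axis=0) - stacked.min(axis=0)
        noise_scale = self.input_noise * col_range / self.scaler_std_

        yi = (y == POSITIVE_CLASS).astype(int)
        yvi = (yv == POSITIVE_CLASS).astype(int)
        net = ConvGRUNet(self.n_features_in_, self.conv_width,
                         self.conv_channels, self.hidden_size)
        params = net.init_params(rng)
        opt = Adam(params, lr=self.learning_rate,
                   weight_decay=self.weight_decay)
        weights = np.where(yi == 1, self.class_weight_positive, 1.0)

        lengths = np.array([m.shape[0] for m in mats])
        order0 = np.argsort(lengths, kind="stable")

        best_loss = np.inf
        best_params = params.copy()
        history = []
        stall = 0
        for epoch in range(self.max_epochs):
            # batch same-ish lengths together; batch order shuffled per epoch
            perm = rng.permutation(len(mats))
            order = perm[np.argsort(lengths[perm], kind="stable")]
            batches = [order[i:i + self.batch_size]
                       for i in range(0, len(order), self.batch_size)]
            rng.shuffle(batches)
            train_loss = 0.0
            nb = 0
            for b in batches:
                Xb, lb = self._pad([mats[i] for i in b])
                if self.input_noise > 0:
                    noise = rng.standard_normal(Xb.shape) * noise_scale
                    for i, L in enumerate(lb):
                        noise[i, L:] = 0.0  # keep padding rows zero
                    Xb = Xb + noise
                masks = net.dropout_masks(len(b), self.dropout, rng)
                loss, grads = net.loss_and_grads(Xb, lb, yi[b], weights[b],
                                                 params, masks=masks)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        f"learning_rate={self.learning_rate}"
                    )
                clip_gradients(grads, 5.0)
                opt.step(params, grads)
                train_loss += loss
                nb += 1
            val_loss = self._weighted_loss(net, params, mats_val, yvi)
            history.append((train_loss / max(nb, 1), val_loss))
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = params.copy()
                stall = 0
            else:
                stall += 1
                # plateau: restart from the best parameters at a lower rate
                if stall in (self.patience // 3, 2 * self.patience // 3):
                    params = best_params.copy()
                    opt = Adam(params, lr=opt.lr / 3.0,
                               weight_decay=self.weight_decay)
                if stall >= self.patience:
                    break

        self.net_ = net
        self.params_ = best_params
        self.history_ = history
        self.best_val_loss_ = best_loss
        return self

    def _stratified_holdout(self, y, rng) -> np.ndarray:
        val_idx = []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            k = max(1, int(round(self.validation_fraction * len(idx))))
            val_idx.extend(rng.permutation(idx)[:k])
        return np.sort(np.array(val_idx))

    def _pad(self, mats: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        lengths = np.array([m.shape[0] for m in mats])
        Lmax = lengths.max()
        X = np.zeros((len(mats), Lmax, self.n_features_in_))
        for i, m in enumerate(mats):
            X[i, :m.shape[0]] = (m - self.scaler_mean_) / self.scaler_std_
        return X, lengths

    def _weighted_loss(self, net, params, mats, yi) -> float:
        probs = self._batched_probs(net, params, mats)
        w = np.where(yi == 1, self.class_weight_positive, 1.0)
        eps = 1e-12
        return float(-(w * np.log(probs[np.arange(len(yi)), yi] + eps)).sum()
                     / w.sum())

    def _batched_probs(self, net, params, mats) -> np.ndarray:
        lengths = np.array([m.shape[0] for m in mats])
        order = np.argsort(lengths, kind="stable")
        probs = np.zeros((len(mats), 2))
        for i in range(0, len(order), self.batch_size):
            b = order[i:i + self.batch_size]
            Xb, lb = self._pad([mats[j] for j in b])
            probs[b] = net.forward(Xb, lb, params)
        return probs

    # ---------------------------------------------------------- prediction
    def predict_proba(self, X) -> np.ndarray:
        """Columns follow ``classes_``: [adventitious, physiological]."""
        check_is_fitted(self, "params_")
        mats = _matrices(X)
        if any(m.shape[1] != self.n_features_in_ for m in mats):
            raise ValueError(
                f"expected {self.n_features_in_} features per residue"
            )
        p1 = self._batched_probs(self.net_, self.params_, mats)[:, 1]
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return np.where(p > self.threshold, POSITIVE_CLASS, NEGATIVE_CLASS)

    def predict_sites(self, X, fold: int = -1) -> list[Prediction]:
        probs = self.predict_proba(X)
        ids = _site_ids(X, len(probs))
        out = []
        for sid, (pa, pp) in zip(ids, probs):
            out.append(Prediction(
                site_id=sid, p_physiological=float(pp), p_adventitious=float(pa),
                assigned_class=(POSITIVE_CLASS if pp > self.threshold
                                else NEGATIVE_CLASS),
                fold=fold,
            ))
        return out

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    # ---------------------------------------------------------- checkpoint
    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "params_")
        path = Path(path)
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "params": self.get_params(),
            "best_val_loss": self.best_val_loss_,
            "n_features_in": int(self.n_features_in_),
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            import io

            buf = io.BytesIO()
            np.savez(buf, scaler_mean=self.scaler_mean_,
                     scaler_std=self.scaler_std_, **self.params_.as_dict())
            zf.writestr("tensors.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "ConvGRUSiteClassifier":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta["schema"] != CHECKPOINT_SCHEMA:
                raise ValueError(
                    f"unsupported checkpoint schema {meta['schema']}"
                )
            import io

            data = np.load(io.BytesIO(zf.read("tensors.npz")))
            est = cls(**meta["params"])
            est.classes_ = np.array([NEGATIVE_CLASS, POSITIVE_CLASS])
            est.n_features_in_ = meta["n_features_in"]
            est.scaler_mean_ = data["scaler_mean"]
            est.scaler_std_ = data["scaler_std"]
            est.net_ = ConvGRUNet(est.n_features_in_, est.conv_width,
                                  est.conv_channels, est.hidden_size)
            est.params_ = NetParams(
                **{k: data[k] for k in NetParams.__dataclass_fields__}
            )
            est.best_val_loss_ = meta["best_val_loss"]
            est.history_ = []
        return est


# ----------------------------------------------------------------- folding
@dataclass
class FoldSplit:
    k: int
    assignment: dict[str, int]  # site_id -> fold index

    def fold_of(self, site_id: str) -> int:
        return self.assignment[site_id]

    def indices(self, site_ids: list[str], fold: int) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(site_ids) if self.assignment[s] == fold]
        )


def make_folds(site_ids, y, k: int = 10, seed: int = 0,
               groups=None) -> FoldSplit:
    """Stratified k-fold assignment; grouped sites never split across folds."""
    if k < 3:
        raise ValueError("k must be >= 3 (train/validation/test roles)")
    y = np.asarray(y)
    site_ids = list(site_ids)
    if groups is not None:
        groups = np.asarray(groups)
        if k > len(np.unique(groups)):
            raise ValueError("k exceeds the number of groups")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed)
        split = splitter.split(np.zeros(len(y)), y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(y)), y)
    assignment = {}
    for fold, (_, test_idx) in enumerate(split):
        for i in test_idx:
            assignment[site_ids[i]] = fold
    return FoldSplit(k=k, assignment=assignment)


@dataclass
class RotationResult:
    test_fold: int
    val_fold: int
    model: ConvGRUSiteClassifier
    predictions: list[Prediction]
    test_indices: np.ndarray
    train_indices: np.ndarray
    test_accuracy: float


@dataclass
class CVResult:
    folds: FoldSplit
    rotations: list[RotationResult]
    site_ids: list[str]

    @property
    def pooled_predictions(self) -> list[Prediction]:
        return [p for r in self.rotations for p in r.predictions]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.test_accuracy for r in self.rotations])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1))


def cross_validate(X, y, k: int = 10, seed: int = 0, groups=None,
                   estimator: ConvGRUSiteClassifier | None = None,
                   site_ids=None) -> CVResult:
    """Rotate every fold through the test role (validation = next fold).

    Returns per-rotation trained models and test predictions; each site is
    predicted exactly once as a test point.
    """
    y = np.asarray(y)
    if site_ids is None:
        site_ids = _site_ids(X, len(y))
    folds = make_folds(site_ids, y, k=k, seed=seed, groups=groups)
    proto = estimator if estimator is not None else ConvGRUSiteClassifier()
    rotations = []
    for f in range(k):
        test_idx = folds.indices(site_ids, f)
        val_idx = folds.indices(site_ids, (f + 1) % k)
        train_idx = np.setdiff1d(
            np.arange(len(y)), np.concatenate([test_idx, val_idx])
        )
        model = ConvGRUSiteClassifier(**proto.get_params())
        model.set_params(random_state=(proto.random_state + 1000 * f) % (2**31))
        model.fit(
            [X[i] for i in train_idx], y[train_idx],
            X_val=[X[i] for i in val_idx], y_val=y[val_idx],
        )
        X_test = [X[i] for i in test_idx]
        preds = model.predict_sites(X_test, fold=f)
        # predict_sites may lack real ids when X is a plain list of arrays
        preds = [
            Prediction(site_id=site_ids[i], p_physiological=p.p_physiological,
                       p_adventitious=p.p_adventitious,
                       assigned_class=p.assigned_class, fold=f)
            for i, p in zip(test_idx, preds)
        ]
        acc = float(np.mean(
            [p.assigned_class for p in preds] == y[test_idx]
        ))
        rotations.append(RotationResult(
            test_fold=f, val_fold=(f + 1) % k, model=model, predictions=preds,
            test_indices=test_idx, train_indices=train_idx, test_accuracy=acc,
        ))
    return CVResult(folds=folds, rotations=rotations, site_ids=list(site_ids))


def predictions_to_tsv(predictions: list[Prediction], path: str | Path) -> None:
    lines = ["site_id\tp_physiological\tp_adventitious\tconfidence"
             "\tassigned_class\tfold"]
    for p in predictions:
        lines.append(
            f"{p.site_id}\t{p.p_physiological:.6f}\t{p.p_adventitious:.6f}"
            f"\t{p.confidence:.6f}\t{p.assigned_class}\t{p.fold}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
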