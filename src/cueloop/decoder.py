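"""Per-subject linear-SVM decoder with probabilistic output.

Features are standardized, a linear SVM (C = 1) is fit, and a Platt sigmoid
maps decision values onto (0, 1) "smoking-likeness" scores.  Cross-validation
is stratified 5-fold (each test fold holds out 20% of the trials) and, in
the pipeline variant, refits feature selection and standardization inside
every training fold so no information leaks from the test trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import (
    BandSet,
    ClusterFeatureSet,
    assemble_features,
    select_features,
)
from .io import EpochSet

__all__ = [
    "TrainedDecoder",
    "train",
    "score",
    "crossvalidate",
    "crossvalidate_epochs",
    "build_decoder",
]

POSITIVE_LABEL = "smoking"  # label convention: 1 = smoking-like


@dataclass
class TrainedDecoder:
    """Feature recipe + linear SVM + sigmoid calibration."""

    weights: np.ndarray
    bias: float
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    sigmoid_a: float
    sigmoid_b: float
    clusters: ClusterFeatureSet | None = None
    bands: BandSet = field(default_factory=BandSet)
    cv_accuracy: float | None = None
    positive_label: str = POSITIVE_LABEL

    @property
    def n_features(self) -> int:
        return len(self.weights)

    def decision_value(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature vector length {x.shape[1]} != expected {self.n_features}"
            )
        z = (x - self.feat_mean) / self.feat_sd
        return z @ self.weights + self.bias

    def to_json(self, path=None) -> str:
        payload = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "sigmoid_a": self.sigmoid_a,
            "sigmoid_b": self.sigmoid_b,
            "cv_accuracy": self.cv_accuracy,
            "positive_label": self.positive_label,
            "clusters": json.loads(self.clusters.to_json()) if self.clusters else None,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "TrainedDecoder":
        try:
            payload = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        clusters = None
        if payload.get("clusters") is not None:
            clusters = ClusterFeatureSet.from_json(json.dumps(payload["clusters"]))
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            feat_mean=np.asarray(payload["feat_mean"], dtype=float),
            feat_sd=np.asarray(payload["feat_sd"], dtype=float),
            sigmoid_a=float(payload["sigmoid_a"]),
            sigmoid_b=float(payload["sigmoid_b"]),
            clusters=clusters,
            cv_accuracy=payload.get("cv_accuracy"),
            positive_label=payload.get("positive_label", POSITIVE_LABEL),
        )


def _to_binary(labels: np.ndarray, positive: str = POSITIVE_LABEL) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "biuf":
        return labels.astype(int)
    return (labels == positive).astype(int)


def _platt_fit(decision: np.ndarray, y: np.ndarray, max_iter: int = 100) -> tuple[float, float]:
    """Newton fit of P(y=1|f) = sigmoid(a*f + b) with Platt's target smoothing."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    t = np.where(y == 1, (n1 + 1.0) / (n1 + 2.0), 1.0 / (n0 + 2.0))
    a, b = 1.0, 0.0
    for _ in range(max_iter):
        p = expit(a * decision + b)
        g_a = np.sum((p - t) * decision)
        g_b = np.sum(p - t)
        w = np.clip(p * (1 - p), 1e-12, None)
        h_aa = np.sum(w * decision**2) + 1e-9
        h_ab = np.sum(w * decision)
        h_bb = np.sum(w) + 1e-9
        det = h_aa * h_bb - h_ab**2
        da = (h_bb * g_a - h_ab * g_b) / det
        db = (h_aa * g_b - h_ab * g_a) / det
        a -= da
        b -= db
        if abs(da) < 1e-10 and abs(db) < 1e-10:
            break
    return float(a), float(b)


def train(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    calibration_folds: int = 3,
    seed: int = 0,
    clusters: ClusterFeatureSet | None = None,
    bands: BandSet | None = None,
) -> TrainedDecoder:
    """Fit standardization + linear SVM + held-out Platt calibration.

    Calibration decision values come from internal stratified folds of the
    training data (falling back to the training fit itself when a class is
    too small to split), so the sigmoid is not fit on in-sample margins.
    """
    X = np.asarray(features, dtype=np.float64)
    y = _to_binary(labels)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("features must be (trials x d) matching labels")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd < 1e-12] = 1.0
    Z = (X - mean) / sd

    svm = SVC(kernel="linear", C=C)
    svm.fit(Z, y)
    w = svm.coef_.ravel().copy()
    b = float(svm.intercept_[0])

    min_class = min(np.bincount(y))
    k = min(calibration_folds, min_class)
    if k >= 2:
        dec = np.empty(len(y))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for tr, te in skf.split(Z, y):
            m = SVC(kernel="linear", C=C)
            m.fit(Z[tr], y[tr])
            dec[te] = m.decision_function(Z[te])
    else:
        dec = svm.decision_function(Z)
    a, bb = _platt_fit(dec, y)

    return TrainedDecoder(
        weights=w,
        bias=b,
        feat_mean=mean,
        feat_sd=sd,
        sigmoid_a=a,
        sigmoid_b=bb,
        clusters=clusters,
        bands=bands or BandSet(),
    )


def score(decoder: TrainedDecoder, features: np.ndarray) -> np.ndarray | float:
    """Probabilistic smoking-likeness score(s) in (0, 1)."""
    x = np.asarray(features, dtype=np.float64)
    single = x.ndim == 1
    s = expit(decoder.sigmoid_a * decoder.decision_value(x) + decoder.sigmoid_b)
    return float(s[0]) if single else s


def crossvalidate(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> dict:
    """Stratified k-fold accuracy on a fixed feature matrix.

    Standardization and the SVM are refit inside each training fold.  Returns
    per-fold accuracies, their mean, and the fold assignment.
    """
    X = np.asarray(features, dtype=np.float64)
    y = _to_binary(labels)
    if min(np.bincount(y)) < k:
        raise ValueError(f"need at least k={k} trials per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, folds = [], np.empty(len(y), dtype=int)
    for fi, (tr, te) in enumerate(skf.split(X, y)):
        folds[te] = fi
        dec = train(X[tr], y[tr], C=C, seed=seed)
        pred = (score(dec, X[te]) >= 0.5).astype(int)
        accs.append(float((pred == y[te]).mean()))
    return {"fold_accuracies": accs, "mean_accuracy": float(np.mean(accs)), "folds": folds}


def crossvalidate_epochs(
    epochs: EpochSet,
    k: int = 5,
    seed: int = 0,
    conditions: tuple[str, str] = ("smoking", "neutral"),
    domains: tuple[str, ...] = ("amplitude",),
    bands: BandSet | None = None,
    adjacency="montage",
    n_perm: int = 500,
    alpha: float = 0.05,
    unsafe_whole_data_selection: bool = False,
    C: float = 1.0,
) -> dict:
    """Full-pipeline cross-validation on an epoch set.

    By default feature selection runs inside each training fold only
    (leakage-safe).  ``unsafe_whole_data_selection=True`` selects clusters
    once on all trials before splitting - provided for comparison studies
    only, since it inflates accuracy.  Folds where selection returns no
    cluster fall back to majority-class prediction.
    """
    kept = epochs.kept_only()
    use = kept.select(np.isin(kept.labels, conditions))
    y = _to_binary(use.labels, positive=conditions[0])
    if min(np.bincount(y)) < k:
        raise ValueError(f"need at least k={k} trials per class")
    bands = bands or BandSet()

    whole_clusters = None
    if unsafe_whole_data_selection:
        whole_clusters = select_features(
            use, conditions, domains, bands, adjacency, n_perm, alpha, seed
        )

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, n_feats = [], []
    for fi, (tr, te) in enumerate(skf.split(use.data, y)):
        train_ep = use.select(np.isin(np.arange(use.n_trials), tr))
        if unsafe_whole_data_selection:
            clusters = whole_clusters
        else:
            clusters = select_features(
                train_ep, conditions, domains, bands, adjacency, n_perm, alpha,
                None if seed is None else seed + 1000 * (fi + 1),
            )
        n_feats.append(len(clusters))
        if len(clusters) == 0:
            majority = int(np.bincount(y[tr]).argmax())
            accs.append(float((y[te] == majority).mean()))
            continue
        Xtr = assemble_features(train_ep, clusters, bands)
        test_ep = use.select(np.isin(np.arange(use.n_trials), te))
        Xte = assemble_features(test_ep, clusters, bands)
        dec = train(Xtr, y[tr], C=C, seed=seed)
        pred = (score(dec, Xte) >= 0.5).astype(int)
        accs.append(float((pred == y[te]).mean()))
    return {
        "fold_accuracies": accs,
        "mean_accuracy": float(np.mean(accs)),
        "n_features_per_fold": n_feats,
    }


def build_decoder(
    rec,
    domains: tuple[str, ...] = ("amplitude",),
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    reject_threshold_uv: float = 100.0,
) -> TrainedDecoder:
    """Full offline phase on a continuous recording: clean, select, fit.

    High-pass -> RLS blink removal -> 60-channel policy -> epoch -> amplitude
    rejection -> cluster selection on the requested domains -> SVM training.
    """
    from . import io as _io
    from . import preprocess as _pre

    clean = _pre.highpass(rec, mode="offline")
    if all(r in [l.upper() for l in rec.channel_labels] for r in ("VEOG", "HEOG")):
        clean = _pre.remove_blinks_rls(clean)
    clean = _io.extract_channels(clean, "model60")
    epochs = _pre.reject_epochs(_io.epoch(clean), reject_threshold_uv)
    kept = epochs.kept_only()
    use = kept.select(np.isin(kept.labels, ["smoking", "neutral"]))
    clusters = select_features(use, domains=domains, n_perm=n_perm, alpha=alpha, seed=seed)
    X = assemble_features(use, clusters)
    return train(X, use.labels, seed=seed, clusters=clusters)
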