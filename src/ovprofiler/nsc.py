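"""Nearest-shrunken-centroids (diagonal-covariance, soft-thresholded)
classification of 1 MB copy-number profiles into BRCA-like vs non-BRCA-like.

Training: class centroids are shrunk toward the overall centroid by delta in
units of m_k * (s_i + s0), with m_k = sqrt(1/n_k - 1/n), pooled within-class
SD s_i, and fudge s0 = median(s_i).  Scoring: discriminant
delta_k(x) = sum_i (x_i - shrunk_ik)^2 / (s_i + s0)^2 - 2 log pi_k, with
posteriors softmax(-delta_k / 2).  A sample is called BRCA-like only when its
posterior strictly exceeds 0.5 (a tie goes to non-BRCA-like).
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["NSCModel", "HRDCall", "train_nsc", "choose_delta", "classify",
           "BRCA_LIKE", "NON_BRCA_LIKE"]

BRCA_LIKE = "BRCA_like"
NON_BRCA_LIKE = "non_BRCA_like"
MODEL_VERSION = "1"


@dataclass
class NSCModel:
    feature_ids: list
    class_labels: list
    overall_centroid: np.ndarray       # (n_features,)
    shrunken_centroids: np.ndarray     # (n_classes, n_features)
    shrunken_offsets: np.ndarray       # d'_ik, (n_classes, n_features)
    pooled_sd: np.ndarray              # s_i
    s0: float
    priors: np.ndarray
    delta: float
    posterior_threshold: float = 0.5

    @property
    def n_nonzero_features(self) -> int:
        return int(np.sum(np.any(self.shrunken_offsets != 0.0, axis=0)))

    def to_json(self, path) -> None:
        obj = {
            "version": MODEL_VERSION,
            "feature_ids": list(self.feature_ids),
            "class_labels": list(self.class_labels),
            "overall_centroid": self.overall_centroid.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "shrunken_offsets": self.shrunken_offsets.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "priors": self.priors.tolist(),
            "delta": self.delta,
            "posterior_threshold": self.posterior_threshold,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "NSCModel":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("version") != MODEL_VERSION:
            raise ValueError(f"unsupported model version {obj.get('version')!r}")
        return cls(
            feature_ids=obj["feature_ids"],
            class_labels=obj["class_labels"],
            overall_centroid=np.asarray(obj["overall_centroid"]),
            shrunken_centroids=np.asarray(obj["shrunken_centroids"]),
            shrunken_offsets=np.asarray(obj["shrunken_offsets"]),
            pooled_sd=np.asarray(obj["pooled_sd"]),
            s0=float(obj["s0"]),
            priors=np.asarray(obj["priors"]),
            delta=float(obj["delta"]),
            posterior_threshold=float(obj["posterior_threshold"]),
        )


@dataclass
class HRDCall:
    sample_id: str
    posterior_brca_like: float
    label: str | None       # "nonBRCAmutHRD", "non_BRCA_like", or None when withheld
    qc_pass: bool = True


def train_nsc(X, y, delta: float, feature_ids=None, priors=None) -> NSCModel:
    """Fit the shrunken-centroids model at shrinkage ``delta``.

    Missing entries (NaN) are ignored per-feature when computing means and
    pooled variances; a feature missing in every sample is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if delta < 0:
        raise ValueError("delta must be >= 0")
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    if np.any(np.all(~np.isfinite(X), axis=0)):
        raise ValueError("feature with no observed values")
    overall = np.nanmean(X, axis=0)
    K = len(classes)
    centroids = np.zeros((K, p))
    ss = np.zeros(p)          # pooled within-class sum of squares
    n_k = np.zeros(K)
    for k, c in enumerate(classes):
        Xk = X[y == c]
        n_k[k] = len(Xk)
        if n_k[k] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        centroids[k] = np.nanmean(Xk, axis=0)
        ss += np.nansum((Xk - centroids[k]) ** 2, axis=0)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    denom = m_k[:, None] * (s + s0)[None, :]
    d = (centroids - overall[None, :]) / denom
    d_shrunk = np.sign(d) * np.maximum(0.0, np.abs(d) - delta)
    shrunken = overall[None, :] + denom * d_shrunk
    priors = n_k / n if priors is None else np.asarray(priors, dtype=float)
    return NSCModel(
        feature_ids=list(feature_ids) if feature_ids is not None else list(range(p)),
        class_labels=classes,
        overall_centroid=overall,
        shrunken_centroids=shrunken,
        shrunken_offsets=d_shrunk,
        pooled_sd=s,
        s0=s0,
        priors=priors,
        delta=float(delta),
    )


def posterior(model: NSCModel, x: np.ndarray) -> np.ndarray:
    """Class posteriors for one feature vector; NaNs are imputed with the
    overall centroid value before evaluating the discriminants."""
    x = np.asarray(x, dtype=float).copy()
    miss = ~np.isfinite(x)
    x[miss] = model.overall_centroid[miss]
    w = (model.pooled_sd + model.s0) ** 2
    disc = np.array([
        np.sum((x - model.shrunken_centroids[k]) ** 2 / w) - 2.0 * np.log(model.priors[k])
        for k in range(len(model.class_labels))
    ])
    z = -0.5 * (disc - disc.min())
    e = np.exp(z)
    return e / e.sum()


def classify(model: NSCModel, profile_1mb, sample_id: str | None = None) -> HRDCall:
    """Score one 1 MB profile.  ``profile_1mb`` may be a RatioProfile or a
    plain feature vector aligned to the model.  More than 50% missing
    features fails QC and the label is withheld."""
    if hasattr(profile_1mb, "log2_ratios"):
        x = np.asarray(profile_1mb.log2_ratios, dtype=float)
        sample_id = sample_id or profile_1mb.sample_id
    else:
        x = np.asarray(profile_1mb, dtype=float)
        sample_id = sample_id or "sample"
    if len(x) != len(model.feature_ids):
        raise ValueError("profile features not aligned to model")
    frac_missing = float(np.mean(~np.isfinite(x)))
    post = posterior(model, x)
    k = model.class_labels.index(BRCA_LIKE)
    p_brca = float(post[k])
    if frac_missing > 0.5:
        return HRDCall(sample_id=sample_id, posterior_brca_like=p_brca,
                       label=None, qc_pass=False)
    label = "nonBRCAmutHRD" if p_brca > model.posterior_threshold else NON_BRCA_LIKE
    return HRDCall(sample_id=sample_id, posterior_brca_like=p_brca,
                   label=label, qc_pass=True)


def choose_delta(X, y, folds: int = 5, delta_grid=None,
                 rng: np.random.Generator | int | None = 0) -> float:
    """Stratified cross-validation over a delta grid; returns the largest
    delta whose mean misclassification error is within one standard error of
    the minimum."""
    if delta_grid is None or len(delta_grid) == 0:
        raise ValueError("delta grid is empty")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    assignment = np.zeros(len(y), dtype=int)
    for c in sorted(set(y.tolist())):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    delta_grid = np.asarray(sorted(delta_grid), dtype=float)
    errors = np.zeros((len(delta_grid), folds))
    for f in range(folds):
        tr, te = assignment != f, assignment == f
        for gi, d in enumerate(delta_grid):
            model = train_nsc(X[tr], y[tr], d)
            pred = [
                model.class_labels[int(np.argmax(posterior(model, x)))] for x in X[te]
            ]
            errors[gi, f] = np.mean(np.asarray(pred) != y[te])
    mean_err = errors.mean(axis=1)
    best = int(np.argmin(mean_err))
    se = errors[best].std(ddof=1) / np.sqrt(folds)
    ok = np.flatnonzero(mean_err <= mean_err[best] + se)
    return float(delta_grid[ok.max()])
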