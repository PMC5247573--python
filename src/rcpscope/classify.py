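"""14-feature random-forest discrimination of true RCPs from artifacts.

Thresholding alone cannot separate genuine amplification products from
auto-fluorescent debris of similar brightness.  Each detected object is
therefore summarised by a fixed panel of 14 intensity, shape and local-
context features and classified by a bagged random forest (bootstrap
resampling plus random feature subsets per split), trained on objects of
known class.  The feature order is versioned by a hash so a persisted model
refuses feature vectors assembled in a different order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import joblib
import numpy as np
from skimage import measure
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .detect import DetectedObject, annulus_pixels
from .preprocess import ChannelImage

FEATURE_NAMES: tuple[str, ...] = (
    "mean_intensity",
    "max_intensity",
    "min_intensity",
    "integrated_intensity",
    "intensity_sd",
    "intensity_median",
    "area_px",
    "equivalent_diameter_px",
    "perimeter_px",
    "eccentricity",
    "solidity",
    "compactness",
    "local_background_contrast",
    "peak_snr",
)

FEATURE_ORDER_HASH = hashlib.sha1(
    ",".join(FEATURE_NAMES).encode()
).hexdigest()[:12]

LABEL_RCP = "rcp"
LABEL_NOT_RCP = "not_rcp"

_MODEL_FORMAT_VERSION = 1


def extract_features(obj: DetectedObject, img: ChannelImage) -> np.ndarray:
    """The 14-feature vector of one object measured on one channel image.

    Intensity features come from the object's own pixels; shape features
    from its binary mask; the two context features compare the object with
    a 2-px annulus 2 px outside it (falling back to a global background
    estimate when the annulus is clipped away at the image border).
    """
    px = obj.pixels
    vals = img.data[px[:, 0], px[:, 1]]

    rmin, cmin = px[:, 0].min(), px[:, 1].min()
    local = np.zeros((px[:, 0].max() - rmin + 1, px[:, 1].max() - cmin + 1),
                     dtype=np.uint8)
    local[px[:, 0] - rmin, px[:, 1] - cmin] = 1
    region = measure.regionprops(local)[0]
    perimeter = float(region.perimeter)
    area = float(obj.area_px)
    compactness = perimeter ** 2 / (4 * np.pi * area) if perimeter > 0 else 0.0

    rr, cc = annulus_pixels(px, img.shape)
    if rr.size >= 4:
        bg_mean = float(img.data[rr, cc].mean())
        bg_sd = float(img.data[rr, cc].std())
    else:  # border object: fall back to a global robust background
        bg_mean = float(np.median(img.data))
        bg_sd = float(1.4826 * np.median(np.abs(img.data - bg_mean)))
    bg_sd = max(bg_sd, 1e-9)

    fv = np.array([
        float(vals.mean()),
        float(vals.max()),
        float(vals.min()),
        float(vals.sum()),
        float(vals.std()),
        float(np.median(vals)),
        area,
        float(obj.equivalent_diameter_px),
        perimeter,
        float(region.eccentricity),
        float(region.solidity),
        compactness,
        float(vals.mean()) - bg_mean,
        float(vals.max()) / bg_sd,
    ])
    if not np.all(np.isfinite(fv)):
        raise ValueError("non-finite feature value")
    return fv


@dataclass
class TrainingSet:
    """Labelled feature vectors with their source channel."""

    X: np.ndarray                 # (n, 14)
    labels: np.ndarray            # {"rcp", "not_rcp"}
    channels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"X must be (n, {len(FEATURE_NAMES)})")
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X and labels must have equal length")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")
        if len(set(self.labels.tolist())) < 2:
            raise ValueError("training set must contain both classes")

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class ForestModel:
    """A trained forest plus the metadata needed to re-apply it safely."""

    estimator: RandomForestClassifier
    n_trees: int
    features_per_split: int
    seed: int
    feature_hash: str = FEATURE_ORDER_HASH
    oob_accuracy: float | None = None

    def save(self, path) -> None:
        joblib.dump({"format_version": _MODEL_FORMAT_VERSION,
                     "model": self}, path)

    @staticmethod
    def load(path) -> "ForestModel":
        blob = joblib.load(path)
        if blob.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError("unrecognised model file format")
        return blob["model"]


def _canonical_order(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Stable row order independent of how the training rows arrived."""
    keys = [labels.astype(str)] + [X[:, j] for j in range(X.shape[1])]
    return np.lexsort(keys[::-1])


def train(ts: TrainingSet, n_trees: int = 100, seed: int = 0) -> ForestModel:
    """Fit a bagged random forest on a canonically ordered training set.

    Rows are sorted by (label, features) before fitting so the bootstrap
    draws — and hence the model — do not depend on the order the examples
    were collected in.  Uses ceil(sqrt(14)) = 4 features per split and
    unbounded depth; out-of-bag accuracy is recorded on the model.
    """
    counts = {lab: int((ts.labels == lab).sum()) for lab in set(ts.labels.tolist())}
    if min(counts.values()) < 10:
        raise ValueError(f"need >= 10 examples per class, got {counts}")
    order = _canonical_order(ts.X, ts.labels)
    features_per_split = int(np.ceil(np.sqrt(len(FEATURE_NAMES))))
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=features_per_split,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(ts.X[order], ts.labels[order])
    return ForestModel(
        estimator=est,
        n_trees=n_trees,
        features_per_split=features_per_split,
        seed=seed,
        oob_accuracy=float(est.oob_score_),
    )


def _tree_votes(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting "rcp" for each row."""
    classes = model.estimator.classes_
    rcp_idx = int(np.where(classes == LABEL_RCP)[0][0])
    votes = np.zeros(X.shape[0])
    for tree in model.estimator.estimators_:
        votes += (tree.predict(X) == rcp_idx)
    return votes / len(model.estimator.estimators_)


def predict(model: ForestModel, fv: np.ndarray,
            feature_hash: str = FEATURE_ORDER_HASH) -> tuple[str, float]:
    """Majority-vote label and the winning vote fraction for one object.

    An exact tie is resolved to ``not_rcp``: a spot the forest cannot commit
    to is treated as background, since spurious counts are the costly error.
    """
    labels, fractions = predict_batch(model, np.asarray(fv, dtype=float)[None, :],
                                      feature_hash)
    return labels[0], float(fractions[0])


def predict_batch(model: ForestModel, X: np.ndarray,
                  feature_hash: str = FEATURE_ORDER_HASH
                  ) -> tuple[np.ndarray, np.ndarray]:
    if feature_hash != model.feature_hash:
        raise ValueError("feature order hash does not match the model")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"X must be (n, {len(FEATURE_NAMES)})")
    frac_rcp = _tree_votes(model, X)
    labels = np.where(frac_rcp > 0.5, LABEL_RCP, LABEL_NOT_RCP)
    winning = np.where(frac_rcp > 0.5, frac_rcp, 1.0 - frac_rcp)
    return labels, winning


def evaluate(model: ForestModel, ts: TrainingSet, k_folds: int = 5,
             seed: int = 0) -> tuple[float, float]:
    """Stratified k-fold cross-validated accuracy (mean, s.d.).

    A fresh forest with the model's hyper-parameters is refit on each
    training fold; the persisted model itself is not touched.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(ts.X, ts.labels):
        if len(set(ts.labels[train_idx].tolist())) < 2:
            raise ValueError("a fold lost one of the classes; reduce k_folds")
        est = clone(model.estimator)
        order = _canonical_order(ts.X[train_idx], ts.labels[train_idx])
        est.fit(ts.X[train_idx][order], ts.labels[train_idx][order])
        accs.append(float((est.predict(ts.X[test_idx]) == ts.labels[test_idx]).mean()))
    return float(np.mean(accs)), float(np.std(accs))


def labelled_set_from_scene(stacks, truth, *, gaussian_sigma: float = 1.0,
                            intensity_threshold: float = 0.1,
                            max_diameter_px: float = 16.0,
                            match_tol_px: float = 2.5) -> TrainingSet:
    """Detect objects on a rendered scene and label them from ground truth.

    Detection runs on the pixel-wise maximum over the signal channels with a
    widened size gate so that large artifacts enter the labelled set as
    negative examples.  Detections matched to a true RCP are labelled
    ``rcp``; everything else (matched artifacts and unmatched spurious
    detections) is ``not_rcp``.  Features are extracted from the denoised
    max-projection image.
    """
    from . import detect as _detect
    from . import preprocess as _pre

    signal = [ch for ch in stacks if ch != "anchor"]
    imgs = {ch: _pre.gaussian_denoise(_pre.average_frames(stacks[ch]),
                                      gaussian_sigma)
            for ch in signal}
    proj = np.max([imgs[ch].data for ch in signal], axis=0)
    proj_img = _pre.ChannelImage("signal_max", proj,
                                 {"source_channels": signal})
    enhanced = _detect.enhance_spots(proj_img, radius_px=5)
    cfg = _detect.DetectionConfig(intensity_threshold=intensity_threshold,
                                  max_diameter_px=max_diameter_px)
    objects = _detect.identify_objects(enhanced, cfg)
    _, _, matched = _detect.match_to_truth(objects, truth, tol_px=match_tol_px)
    truth_class = dict(zip(truth["object_id"], truth["class"]))
    match_map = dict(matched)
    X, labels = [], []
    for obj in objects:
        X.append(extract_features(obj, proj_img))
        cls = truth_class.get(match_map.get(obj.object_id), "none")
        labels.append(LABEL_RCP if cls == "rcp" else LABEL_NOT_RCP)
    return TrainingSet(np.array(X), np.array(labels),
                       channels=np.array(["signal_max"] * len(labels)))


__all__ = [
    "FEATURE_NAMES", "FEATURE_ORDER_HASH", "LABEL_RCP", "LABEL_NOT_RCP",
    "extract_features", "TrainingSet", "ForestModel", "train", "predict",
    "predict_batch", "evaluate", "labelled_set_from_scene",
]
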