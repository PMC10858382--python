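"""Histology segmentation into background, soft tissue, and bone.

Follows the two-stage scheme used for the biopsy sections: image subtiles
are described by four statistical moments (mean, SD, skewness, excess
kurtosis) of each CIE-L*a*b* channel and clustered by k-means to separate
non-osseous tissue from slide background, while bone is delineated by a
trained per-pixel classifier.  The classifier interface is deliberately
pluggable: the reference implementation is logistic regression on local
color/texture features, and any model exposing the same ``fit``/``predict``
surface (e.g. a convolutional network) can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2lab
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SectionImage",
    "CompartmentLabelMap",
    "BoneClassifier",
    "rgb_to_lab",
    "extract_tile_features",
    "cluster_tissue",
    "train_bone_classifier",
    "segment_section",
    "LABEL_BACKGROUND",
    "LABEL_SOFT_TISSUE",
    "LABEL_BONE",
]

LABEL_BACKGROUND, LABEL_SOFT_TISSUE, LABEL_BONE = 0, 1, 2

_CLF_FORMAT_TAG = "dardose-bone-classifier-v1"


@dataclass
class SectionImage:
    """An RGB histology raster with its physical pixel pitch (um)."""

    rgb: np.ndarray
    pitch_um: float

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H x W x 3")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be > 0")


@dataclass
class CompartmentLabelMap:
    """Per-pixel labels: background=0, soft tissue=1, bone=2."""

    labels: np.ndarray
    pitch_um: float

    def __post_init__(self):
        if not np.isin(self.labels, [0, 1, 2]).all():
            raise ValueError("label codes must be in {0, 1, 2}")


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """sRGB (8-bit, D65) to CIE L*a*b*; accepts a pixel triplet or an image."""
    arr = np.asarray(rgb, dtype=float)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channels must lie in [0, 255]")
    single = arr.ndim == 1
    if single:
        arr = arr.reshape(1, 1, 3)
    lab = rgb2lab(arr / 255.0)
    return lab[0, 0] if single else lab


def _moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean/SD/skewness/excess kurtosis; higher moments 0 at SD=0."""
    mean = float(values.mean())
    sd = float(values.std())  # population (ddof=0)
    if sd < 1e-12:
        return mean, 0.0, 0.0, 0.0
    z = (values - mean) / sd
    return mean, sd, float(np.mean(z ** 3)), float(np.mean(z ** 4) - 3.0)


def extract_tile_features(image: SectionImage, tile_px: int = 16) -> pd.DataFrame:
    """Twelve Lab-moment features per non-overlapping subtile.

    Tiles are ``tile_px`` square; ragged edge tiles are kept when at least
    half-size along each axis.  Columns: ``tile_row``, ``tile_col`` (pixel
    origin) and ``{mean,sd,skew,kurt}_{L,a,b}``.
    """
    if tile_px < 2:
        raise ValueError("tile_px must be >= 2")
    H, W = image.rgb.shape[:2]
    if tile_px > H or tile_px > W:
        raise ValueError("tile larger than image")
    lab = rgb_to_lab(image.rgb)
    rows = []
    half = tile_px / 2.0
    for r0 in range(0, H, tile_px):
        if H - r0 < half:
            break
        for c0 in range(0, W, tile_px):
            if W - c0 < half:
                break
            tile = lab[r0:r0 + tile_px, c0:c0 + tile_px]
            rec = {"tile_row": r0, "tile_col": c0}
            for ci, ch in enumerate("Lab"):
                m, sd, sk, ku = _moments(tile[..., ci].ravel())
                rec.update({f"mean_{ch}": m, f"sd_{ch}": sd,
                            f"skew_{ch}": sk, f"kurt_{ch}": ku})
            rows.append(rec)
    return pd.DataFrame(rows)


def cluster_tissue(features: pd.DataFrame, k: int = 3, seed: int = 0,
                   background_delta_L: float = 5.0) -> np.ndarray:
    """K-means tile clustering into background vs non-osseous tissue.

    Features are z-scored, clustered with ``n_init=10``, and clusters mapped
    to classes by mean L*: the brightest cluster — and any cluster within
    ``background_delta_L`` of it — is slide background, the rest non-osseous
    tissue.  Returns one label per tile row (0 background, 1 non-osseous).
    """
    cols = [c for c in features.columns if c not in ("tile_row", "tile_col")]
    X = features[cols].to_numpy(dtype=float)
    if len(X) < 1:
        raise ValueError("no tiles to cluster")
    sd = X.std(axis=0)
    if (sd < 1e-12).all():
        # all tiles identical: one cluster, brightest by construction -> background
        return np.zeros(len(X), dtype=int)
    mu = X.mean(axis=0)
    Z = (X - mu) / np.where(sd < 1e-12, 1.0, sd)
    k_eff = min(k, len(X))
    labels = None
    for attempt in range(5):
        km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed + attempt)
        cand = km.fit_predict(Z)
        if len(np.unique(cand)) == k_eff:
            labels = cand
            break
        labels = cand
    else:
        warnings.warn("k-means produced fewer than k clusters after 5 attempts",
                      stacklevel=2)
    tile_L = features["mean_L"].to_numpy()
    mean_L = np.full(k_eff, -np.inf)
    for c in np.unique(labels):
        mean_L[c] = tile_L[labels == c].mean()
    is_bg_cluster = mean_L >= mean_L.max() - background_delta_L
    return np.where(is_bg_cluster[labels], 0, 1)


def _pixel_features(rgb: np.ndarray, window: int = 5) -> np.ndarray:
    """Per-pixel Lab values plus local mean and SD in a window, per channel."""
    lab = rgb_to_lab(rgb)
    feats = [lab[..., i] for i in range(3)]
    for i in range(3):
        ch = lab[..., i]
        mu = ndimage.uniform_filter(ch, size=window)
        mu2 = ndimage.uniform_filter(ch ** 2, size=window)
        feats.append(mu)
        feats.append(np.sqrt(np.maximum(mu2 - mu ** 2, 0.0)))
    return np.stack(feats, axis=-1)


class BoneClassifier:
    """Pluggable per-pixel bone segmenter.

    Wraps any scikit-learn style estimator over the 9 local color/texture
    features (L*, a*, b* and their 5x5 local mean/SD).  The default model is
    logistic regression; a convolutional model can be dropped in by passing
    any estimator with ``fit(X, y)`` / ``predict(X)``.
    """

    def __init__(self, model=None, window: int = 5):
        self.window = window
        self.model = model if model is not None else Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=1000)),
        ])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BoneClassifier":
        self.model.fit(X, y)
        return self

    def predict_mask(self, image: SectionImage) -> np.ndarray:
        feats = _pixel_features(image.rgb, self.window)
        pred = self.model.predict(feats.reshape(-1, feats.shape[-1]))
        return pred.reshape(image.rgb.shape[:2]).astype(bool)

    def save(self, path) -> None:
        joblib.dump({"format": _CLF_FORMAT_TAG, "window": self.window,
                     "model": self.model}, path)

    @classmethod
    def load(cls, path) -> "BoneClassifier":
        blob = joblib.load(path)
        if blob.get("format") != _CLF_FORMAT_TAG:
            raise ValueError(f"unrecognized classifier file format: {blob.get('format')!r}")
        return cls(model=blob["model"], window=blob["window"])


def train_bone_classifier(images: list[SectionImage], truth_masks: list[np.ndarray],
                          seed: int = 0, max_px_per_section: int = 20000,
                          model=None) -> BoneClassifier:
    """Train the per-pixel bone classifier on labeled sections.

    ``truth_masks`` are label rasters (0 background, 1 soft tissue, 2 bone);
    training is bone-vs-rest on a random pixel subsample of each section.
    """
    if len(images) < 1 or len(images) != len(truth_masks):
        raise ValueError("need >= 1 image with a matching truth mask")
    rng = np.random.default_rng(seed)
    Xs, ys = [], []
    for img, mask in zip(images, truth_masks):
        mask = np.asarray(mask)
        feats = _pixel_features(img.rgb).reshape(-1, 9)
        y = (mask.ravel() == LABEL_BONE).astype(int)
        n = len(y)
        idx = rng.choice(n, size=min(max_px_per_section, n), replace=False)
        Xs.append(feats[idx])
        ys.append(y[idx])
    X, y = np.concatenate(Xs), np.concatenate(ys)
    classes = np.unique(y)
    if len(classes) < 2:
        missing = "bone" if 1 not in classes else "non-bone"
        raise ValueError(f"training labels are missing the {missing} class")
    return BoneClassifier(model=model).fit(X, y)


def _absorb_small_components(labels: np.ndarray, min_px: int) -> np.ndarray:
    """Reassign connected components smaller than ``min_px`` to the majority
    label of their border, iterating until none remain."""
    labels = labels.copy()
    st = np.ones((3, 3), bool)
    for _ in range(10):
        changed = False
        for code in np.unique(labels):
            mask = labels == code
            comp, n = ndimage.label(mask, structure=st)
            if n == 0:
                continue
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
            for ci in np.nonzero(sizes < min_px)[0] + 1:
                blob = comp == ci
                border = ndimage.binary_dilation(blob, st) & ~blob
                if not border.any():
                    continue
                vals, counts = np.unique(labels[border], return_counts=True)
                labels[blob] = vals[np.argmax(counts)]
                changed = True
        if not changed:
            break
    return labels


def segment_section(image: SectionImage, clf: BoneClassifier, tile_px: int = 16,
                    k: int = 3, min_object_px: int = 50, seed: int = 0) -> CompartmentLabelMap:
    """Full three-class segmentation of a histology section.

    Tile-level k-means separates background from non-osseous tissue
    (upsampled to pixels); the trained classifier marks bone per pixel with
    precedence bone > soft tissue > background; components smaller than
    ``min_object_px`` are absorbed into their surroundings.
    """
    H, W = image.rgb.shape[:2]
    feats = extract_tile_features(image, tile_px)
    tile_cls = cluster_tissue(feats, k=k, seed=seed)
    nonosseous = np.zeros((H, W), dtype=bool)
    for (r0, c0), cls in zip(feats[["tile_row", "tile_col"]].to_numpy(), tile_cls):
        if cls == 1:
            nonosseous[r0:r0 + tile_px, c0:c0 + tile_px] = True
    bone = clf.predict_mask(image)
    labels = np.zeros((H, W), dtype=np.uint8)
    labels[nonosseous] = LABEL_SOFT_TISSUE
    labels[bone] = LABEL_BONE
    labels = _absorb_small_components(labels, min_object_px)
    return CompartmentLabelMap(labels=labels, pitch_um=image.pitch_um)
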