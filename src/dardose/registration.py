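"""Histology-to-autoradiography registration.

The autoradiograph is acquired on a different physical frame than the
histology scan of the same section: the section is re-handled between the
phosphor plate and the slide scanner, producing an unknown similarity
misalignment (isotropic scale, rotation, translation).  Registration is
performed at DAR resolution: the segmented histology is downsampled to the
DAR pitch, a coarse similarity transform is estimated from foreground
moments, and the estimate is refined by maximizing the mutual information
of the joint intensity histogram.

Transform convention
--------------------
``RigidScaleTransform`` maps *output-frame* (histology-aligned) pixel
coordinates ``p = (row, col)`` to *input-frame* (DAR) coordinates:

    T(p) = s * R(theta) @ (p - c) + c + t

with scale ``s``, rotation ``theta`` (degrees, about center ``c``) and
translation ``t`` in DAR pixels.  ``apply_transform(raster, T)`` therefore
pulls DAR intensities into the histology-aligned frame:
``out[p] = raster[T(p)]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

from .grid import block_resample, resample_labels

__all__ = [
    "RigidScaleTransform",
    "RegistrationResult",
    "downsample_to_dar",
    "section_bounding_box",
    "mutual_information",
    "coarse_register",
    "refine_register",
    "apply_transform",
]


@dataclass
class RigidScaleTransform:
    """Similarity transform (scale, rotation, translation) about a center.

    Maps output-frame points to input-frame points; see module docstring.
    """

    scale: float = 1.0
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        return self.scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        """Apply to an (N, 2) array of (row, col) points."""
        pts = np.atleast_2d(pts)
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        return (pts - c) @ self.matrix.T + c + t

    def inverse(self) -> "RigidScaleTransform":
        Ainv = np.linalg.inv(self.matrix)
        t = np.asarray(self.translation, dtype=float)
        return RigidScaleTransform(
            scale=1.0 / self.scale,
            rotation_deg=-self.rotation_deg,
            translation=tuple(-(Ainv @ t)),
            center=self.center,
        )

    def compose(self, other: "RigidScaleTransform") -> "RigidScaleTransform":
        """Return the transform ``p -> self(other(p))``."""
        A1, A2 = self.matrix, other.matrix
        c1 = np.asarray(self.center, float)
        c2 = np.asarray(other.center, float)
        t1 = np.asarray(self.translation, float)
        t2 = np.asarray(other.translation, float)
        t = A1 @ (c2 + t2 - c1) + c1 + t1 - c2
        return RigidScaleTransform(
            scale=self.scale * other.scale,
            rotation_deg=self.rotation_deg + other.rotation_deg,
            translation=tuple(t),
            center=tuple(c2),
        )

    def to_dict(self) -> dict:
        return {
            "scale": float(self.scale),
            "rotation_deg": float(self.rotation_deg),
            "translation": [float(v) for v in self.translation],
            "center": [float(v) for v in self.center],
            "frame": "row/col, 0-based, pixel-center",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidScaleTransform":
        return cls(
            scale=d["scale"],
            rotation_deg=d["rotation_deg"],
            translation=tuple(d["translation"]),
            center=tuple(d["center"]),
        )


@dataclass
class RegistrationResult:
    transform: RigidScaleTransform
    mi_initial: float
    mi_final: float
    n_evaluations: int
    converged: bool = True


def downsample_to_dar(raster: np.ndarray, hist_pitch_um: float, dar_pitch_um: float,
                      labels: bool | None = None) -> np.ndarray:
    """Resample a histology-pitch raster to the DAR pitch.

    Intensities are area-weighted block means; label maps (integer dtype, or
    ``labels=True``) are downsampled as per-class occupancy fractions followed
    by argmax, ties to the lower code.
    """
    if dar_pitch_um < hist_pitch_um:
        raise ValueError("dar_pitch_um must be >= hist_pitch_um")
    ratio = dar_pitch_um / hist_pitch_um
    if labels is None:
        labels = np.issubdtype(np.asarray(raster).dtype, np.integer) or raster.dtype == bool
    if abs(ratio - 1.0) < 1e-12:
        return np.asarray(raster).copy()
    if labels:
        return resample_labels(np.asarray(raster).astype(int), ratio)
    return block_resample(raster, ratio, reduce="mean")


def section_bounding_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tightest half-open box ``(row_min, col_min, row_max, col_max)`` of a mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1


def mutual_information(img_a: np.ndarray, img_b: np.ndarray,
                       overlap_mask: np.ndarray | None = None,
                       n_bins: int = 64) -> float:
    """Mutual information (nats) of two images from their joint histogram.

    Equal-width bins over each image's range within the overlap; empty joint
    bins contribute nothing.  A constant image carries no information: MI is
    returned as 0.0 with a warning.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if overlap_mask is not None:
        a, b = a[overlap_mask], b[overlap_mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 100:
        raise ValueError("overlap must contain at least 100 pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant image in mutual_information; returning 0", stacklevel=2)
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=n_bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (pa @ pb)[nz])))


def _foreground(img: np.ndarray, name: str) -> np.ndarray:
    """Section footprint of an image.

    Label maps: any non-background pixel.  Intensity images: thresholded at
    a tenth of the Otsu level — the autoradiograph's dynamic range is
    dominated by hot interface voxels, and plain Otsu would crop the faint
    soft-tissue background out of the footprint — then closed, hole-filled
    and reduced to the largest connected component.
    """
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer) or img.dtype == bool:
        fg = img > 0
    else:
        if np.ptp(img) == 0:
            raise ValueError(f"foreground detection failed on constant image {name!r}")
        fg = img > 0.1 * threshold_otsu(img.astype(float))
        st = np.ones((3, 3), bool)
        fg = ndimage.binary_fill_holes(ndimage.binary_closing(fg, st, iterations=2))
        comp, n = ndimage.label(fg)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
            fg = comp == (1 + np.argmax(sizes))
    if not fg.any():
        raise ValueError(f"foreground detection failed: no foreground in {name!r}")
    return fg


def _moments(fg: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Centroid, principal-axis orientation (deg) and box diagonal of a mask."""
    rows, cols = np.nonzero(fg)
    centroid = np.array([rows.mean(), cols.mean()])
    dr, dc = rows - centroid[0], cols - centroid[1]
    mu20, mu02, mu11 = np.mean(dr * dr), np.mean(dc * dc), np.mean(dr * dc)
    theta = 0.5 * np.degrees(np.arctan2(2 * mu11, mu20 - mu02))
    r0, c0, r1, c1 = section_bounding_box(fg)
    diag = float(np.hypot(r1 - r0, c1 - c0))
    return centroid, float(theta), diag


def coarse_register(hist_down: np.ndarray, dar_image: np.ndarray) -> RigidScaleTransform:
    """Initial similarity estimate from foreground moments.

    Scale from the ratio of foreground bounding-box diagonals, translation
    from centroids, rotation from the principal-axis orientation of the
    foreground second moments; the 180-degree axis ambiguity is resolved by
    keeping the candidate with the higher mutual information.
    """
    fg_h = _foreground(hist_down, "hist_down")
    fg_d = _foreground(dar_image, "dar_image")
    cen_h, th_h, diag_h = _moments(fg_h)
    cen_d, th_d, diag_d = _moments(fg_d)
    scale = diag_d / diag_h
    best, best_mi = None, -np.inf
    for rot in (th_d - th_h, th_d - th_h + 180.0):
        rot = (rot + 180.0) % 360.0 - 180.0
        t = RigidScaleTransform(scale=scale, rotation_deg=rot,
                                translation=tuple(cen_d - cen_h), center=tuple(cen_h))
        warped = apply_transform(np.asarray(dar_image, float), t, "bilinear",
                                 out_shape=np.asarray(hist_down).shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mi = mutual_information(np.asarray(hist_down, float), warped)
        if mi > best_mi:
            best, best_mi = t, mi
    return best


def apply_transform(raster: np.ndarray, t: RigidScaleTransform,
                    interpolation: str = "bilinear",
                    out_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Resample ``raster`` into the output frame: ``out[p] = raster[T(p)]``.

    ``bilinear`` for intensities, ``nearest`` for label maps; points mapping
    outside the input frame become 0 / background.
    """
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    arr = np.asarray(raster)
    shape = arr.shape if out_shape is None else tuple(out_shape)
    A = t.matrix
    c = np.asarray(t.center, float)
    offset = c + np.asarray(t.translation, float) - A @ c
    out = ndimage.affine_transform(arr.astype(float), A, offset=offset,
                                   output_shape=shape, order=order,
                                   mode="constant", cval=0.0)
    if order == 0:
        out = out.astype(arr.dtype)
    return out


def _warp_with_mask(raster: np.ndarray, t: RigidScaleTransform,
                    grid: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear pull-warp plus in-frame validity mask (for MI overlap)."""
    A = t.matrix
    c = np.asarray(t.center, float)
    coords = A @ grid + (c + np.asarray(t.translation, float) - A @ c)[:, None]
    vals = ndimage.map_coordinates(np.asarray(raster, float), coords, order=1,
                                   mode="constant", cval=0.0)
    H, W = raster.shape
    valid = ((coords[0] >= 0) & (coords[0] <= H - 1)
             & (coords[1] >= 0) & (coords[1] <= W - 1))
    return vals.reshape(shape), valid.reshape(shape)


def refine_register(hist_down: np.ndarray, dar_image: np.ndarray,
                    init: RigidScaleTransform,
                    n_bins: int = 64, max_evaluations: int = 2000,
                    presmooth_sigma_px: float = 1.0) -> RegistrationResult:
    """Refine a similarity transform by derivative-free MI maximization.

    Multi-start local search (Powell) over (scale, rotation, tx, ty) from the
    coarse estimate and small perturbations of it (+-2 px, +-2 deg); the
    best-evaluated transform is retained, so ``mi_final >= mi_initial``.

    Both images are mildly Gaussian-smoothed (``presmooth_sigma_px``) before
    the MI evaluation: counting noise in the autoradiograph otherwise biases
    the MI optimum toward transforms that shrink the moving image, pulling
    the recovered scale off by a few percent.
    """
    ref = np.asarray(hist_down, float)
    mov = np.asarray(dar_image, float)
    if presmooth_sigma_px > 0:
        ref = ndimage.gaussian_filter(ref, presmooth_sigma_px)
        mov = ndimage.gaussian_filter(mov, presmooth_sigma_px)
    shape = ref.shape
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    grid = np.stack([rr.ravel(), cc.ravel()]).astype(float)
    center = init.center
    n_eval = 0
    best_x, best_mi = None, -np.inf

    def mi_of(x) -> float:
        nonlocal n_eval, best_x, best_mi
        s, rot, tr, tc = x
        if s <= 0:
            return -1e3  # finite penalty keeps the line search well-posed
        t = RigidScaleTransform(s, rot, (tr, tc), center)
        warped, valid = _warp_with_mask(mov, t, grid, shape)
        if valid.sum() < 100:
            return -1e3
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mi = mutual_information(ref, warped, overlap_mask=valid, n_bins=n_bins)
        n_eval += 1
        if mi > best_mi:
            best_mi, best_x = mi, np.array(x, dtype=float)
        return mi

    x0 = np.array([init.scale, init.rotation_deg, *init.translation], dtype=float)
    mi_initial = mi_of(x0)
    # the 180-degree start guards against a wrongly resolved axis ambiguity
    # upstream and must run before the budget is spent on local perturbations
    starts = [x0, x0 + [0, 180.0, 0, 0]]
    for d in (+2.0, -2.0):
        starts.append(x0 + [0, 0, d, 0])
        starts.append(x0 + [0, 0, 0, d])
        starts.append(x0 + [0, d, 0, 0])
    converged = True
    for st in starts:
        budget = max_evaluations - n_eval
        if budget < 50:
            converged = False
            break
        try:
            optimize.minimize(
                lambda x: -mi_of(x), st, method="Powell",
                options={"xtol": 1e-3, "ftol": 1e-6, "maxfev": budget},
            )
        except StopIteration:  # pragma: no cover - scipy internal guard
            pass
    s, rot, tr, tc = best_x
    rot = (rot + 180.0) % 360.0 - 180.0
    final = RigidScaleTransform(float(s), float(rot), (float(tr), float(tc)), center)
    return RegistrationResult(transform=final, mi_initial=float(mi_initial),
                              mi_final=float(best_mi), n_evaluations=n_eval,
                              converged=converged)
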