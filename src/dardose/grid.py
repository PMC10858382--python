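"""Area-weighted resampling between the histology and DAR pixel grids.

The two modalities live on square grids of different physical pitch
(histology ~8 um/px, storage-phosphor autoradiography ~43.2 um/px).  The
pitch ratio is generally non-integer, so block averaging is expressed with
explicit 1-D overlap matrices: output pixel ``j`` covers the interval
``[j*r, (j+1)*r)`` of input-pixel coordinates (``r = pitch_out/pitch_in``),
and the weight of input pixel ``i`` is the length of its overlap with that
interval.  Separability makes the 2-D resampling a pair of matrix products.
"""

from __future__ import annotations

import numpy as np

__all__ = ["overlap_matrix", "block_resample", "resample_labels"]


def overlap_matrix(n_in: int, ratio: float) -> np.ndarray:
    """1-D overlap-weight matrix for downsampling by ``ratio`` (>= 1).

    Returns ``W`` of shape ``(n_out, n_in)`` with ``W[j, i]`` the length (in
    input-pixel units) of the overlap between output pixel ``j`` and input
    pixel ``i``.  Only fully covered output pixels are kept
    (``n_out = floor(n_in / ratio)``), so every row sums to ``ratio``.
    """
    if ratio < 1.0:
        raise ValueError(f"pitch ratio must be >= 1, got {ratio}")
    n_out = int(np.floor(n_in / ratio + 1e-9))
    if n_out < 1:
        raise ValueError(f"input of length {n_in} yields no full output pixel at ratio {ratio}")
    W = np.zeros((n_out, n_in))
    for j in range(n_out):
        lo, hi = j * ratio, (j + 1) * ratio
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi - 1e-9))
        for i in range(i0, min(i1, n_in)):
            W[j, i] = min(hi, i + 1) - max(lo, i)
    return W


def block_resample(arr: np.ndarray, ratio: float, reduce: str = "mean") -> np.ndarray:
    """Area-weighted downsampling of a 2-D array by the same ratio per axis.

    ``reduce='mean'`` averages (intensities, occupancies); ``reduce='sum'``
    conserves totals (activities in Bq), counting each input pixel's area at
    most once.
    """
    if arr.ndim != 2:
        raise ValueError("expected a 2-D raster")
    Wr = overlap_matrix(arr.shape[0], ratio)
    Wc = overlap_matrix(arr.shape[1], ratio)
    out = Wr @ np.asarray(arr, dtype=float) @ Wc.T
    if reduce == "sum":
        return out
    if reduce == "mean":
        return out / (ratio * ratio)
    raise ValueError(f"unknown reduce {reduce!r}")


def resample_labels(labels: np.ndarray, ratio: float) -> np.ndarray:
    """Downsample an integer label raster by per-class occupancy + argmax.

    Each output pixel takes the class occupying the largest area fraction of
    its footprint; ties go to the lower label code.
    """
    labels = np.asarray(labels)
    codes = np.unique(labels)
    occ = np.stack([block_resample((labels == c).astype(float), ratio) for c in codes])
    return codes[np.argmax(occ, axis=0)]
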