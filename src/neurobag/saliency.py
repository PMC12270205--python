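"""Gradient-based 3D saliency maps for the brain-age regressor.

Voxel importance is the first-order Taylor sensitivity of the scalar
brain-age output to each input voxel: the gradient of the prediction with
respect to the input volume, taken in evaluation mode. Because the head
is a single scalar, the gradient target is that output (a hook point
exists for multi-output heads, where the maximal-activation output would
be selected). Maps default to absolute values (importance, sign-free)
followed by Gaussian smoothing with reflective boundaries; sigma=0 is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter


@dataclass
class SaliencyVolume:
    values: np.ndarray
    sigma: float = 0.0
    scan_id: str = ""


@dataclass
class RegionAtlas:
    labels: np.ndarray           # integer region IDs; 0 = background
    names: dict                  # region id -> name


def saliency_volume(model, volume, sigma: float = 2.0, signed: bool = False,
                    scan_id: str = "") -> SaliencyVolume:
    """Saliency map of one scan: |d(brain age)/d(voxel)|, smoothed.

    ``model`` must expose ``input_gradient(volume)`` returning the exact
    gradient of its scalar output. ``signed=True`` skips the absolute
    value. Computed per scan, so results are independent of batching.
    """
    vox = np.asarray(getattr(volume, "voxels", volume), dtype=float)
    grad = model.input_gradient(vox)
    if not signed:
        grad = np.abs(grad)
    if sigma > 0:
        grad = gaussian_filter(grad, sigma=sigma, mode="reflect")
    return SaliencyVolume(values=grad, sigma=sigma, scan_id=scan_id)


def group_mean_saliency(maps) -> SaliencyVolume:
    """Voxelwise arithmetic mean of saliency maps (all same shape)."""
    maps = list(maps)
    if not maps:
        raise ValueError("cannot average an empty list of maps")
    arrs = [np.asarray(m.values if isinstance(m, SaliencyVolume) else m) for m in maps]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("saliency maps must share a common shape")
    sigma = maps[0].sigma if isinstance(maps[0], SaliencyVolume) else 0.0
    return SaliencyVolume(values=np.mean(arrs, axis=0), sigma=sigma)


def difference_map(mean_a: SaliencyVolume, mean_b: SaliencyVolume) -> SaliencyVolume:
    """Signed A - B map; positive where saliency is stronger in A."""
    a = np.asarray(mean_a.values if isinstance(mean_a, SaliencyVolume) else mean_a)
    b = np.asarray(mean_b.values if isinstance(mean_b, SaliencyVolume) else mean_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return SaliencyVolume(values=a - b)


def region_summary(smap: SaliencyVolume, atlas: RegionAtlas) -> pd.DataFrame:
    """Mean saliency within each labeled atlas region (background excluded)."""
    values = np.asarray(smap.values if isinstance(smap, SaliencyVolume) else smap)
    labels = np.asarray(atlas.labels if isinstance(atlas, RegionAtlas) else atlas)
    if values.shape != labels.shape:
        raise ValueError(f"atlas grid {labels.shape} does not match map {values.shape}")
    names = atlas.names if isinstance(atlas, RegionAtlas) else {}
    flat_l = labels.ravel()
    flat_v = values.ravel()
    counts = np.bincount(flat_l)
    sums = np.bincount(flat_l, weights=flat_v)
    rows = []
    for rid in np.nonzero(counts)[0]:
        if rid == 0:
            continue
        rows.append({"region_id": int(rid),
                     "region": names.get(int(rid), f"region{rid}"),
                     "n_voxels": int(counts[rid]),
                     "mean_saliency": sums[rid] / counts[rid]})
    return pd.DataFrame(rows, columns=["region_id", "region", "n_voxels",
                                       "mean_saliency"])


def finite_difference_gradient(model, volume, voxels, eps: float = 1e-3) -> np.ndarray:
    """Central finite differences of the model output at selected voxels.

    Independent oracle for the analytic input gradient; ``voxels`` is a
    sequence of index tuples.
    """
    vox = np.asarray(getattr(volume, "voxels", volume), dtype=float)
    out = np.empty(len(voxels))
    for i, idx in enumerate(voxels):
        vp, vm = vox.copy(), vox.copy()
        vp[tuple(idx)] += eps
        vm[tuple(idx)] -= eps
        fp = model.forward(vp[None, None], training=False)[0, 0]
        fm = model.forward(vm[None, None], training=False)[0, 0]
        out[i] = (fp - fm) / (2 * eps)
    return out
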