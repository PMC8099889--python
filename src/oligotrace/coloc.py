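"""Myelin/axon colocalization on two-channel image stacks.

Quantifies axonal density as the NF200 (neurofilament) pixel fraction of
a thresholded maximum projection, and myelination as the overlap of the
MBP (myelin basic protein) mask with the NF200 mask, normalised to the
NF200 mask area.  Normalising to axonal density makes the myelination
ratio insensitive to MBP signal lying outside axons and to changes in
axon density itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk


@dataclass
class ChannelStack:
    """A single-channel image stack (planes x rows x cols)."""

    data: np.ndarray
    pixel_size_um: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, :, :]
        if arr.ndim != 3:
            raise ValueError(f"expected 2-D or 3-D image data, got ndim={arr.ndim}")
        if arr.min() < 0:
            raise ValueError("negative intensities")
        self.data = arr

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]


@dataclass
class MaskResult:
    mask: np.ndarray
    method: str
    threshold: float


@dataclass
class ColocResult:
    """The two reported metrics plus threshold provenance.

    ``mbp_nf200_ratio`` is None when the NF200 mask is empty (undefined
    normalisation).
    """

    nf200_pixel_fraction: float  # percent of image area
    mbp_nf200_ratio: float | None  # 0..1
    nf200_threshold: MaskResult | None = None
    mbp_threshold: MaskResult | None = None


def read_stack(path: str | Path, pixel_size_um: float = 1.0, label: str = "") -> ChannelStack:
    """Read a single- or multi-page TIFF as one channel stack."""
    return ChannelStack(
        data=tifffile.imread(str(path)), pixel_size_um=pixel_size_um, label=label
    )


def max_project(stack: ChannelStack | np.ndarray) -> np.ndarray:
    """Per-pixel maximum across planes."""
    data = stack.data if isinstance(stack, ChannelStack) else np.asarray(stack, float)
    if data.ndim == 2:
        return data.copy()
    if data.shape[0] < 1:
        raise ValueError("stack has no planes")
    return data.max(axis=0)


def make_mask(plane: np.ndarray, method: str = "otsu") -> MaskResult:
    """Threshold a single plane into a boolean mask.

    ``method`` is ``"otsu"`` or ``"fixed:<t>"``.  Otsu on a constant
    image is undefined and raises with a hint to use a fixed threshold.
    The threshold value actually applied is recorded in the result.
    """
    plane = np.asarray(plane, dtype=float)
    if method == "otsu":
        if np.ptp(plane) == 0:
            raise ValueError(
                "Otsu threshold undefined on a constant image; "
                "use method='fixed:<t>' instead"
            )
        t = float(threshold_otsu(plane))
        return MaskResult(mask=plane > t, method="otsu", threshold=t)
    if method.startswith("fixed:"):
        t = float(method.split(":", 1)[1])
        return MaskResult(mask=plane > t, method="fixed", threshold=t)
    raise ValueError(f"unknown threshold method {method!r}")


def coloc_metrics(
    nf200_mask: np.ndarray | MaskResult,
    mbp_mask: np.ndarray | MaskResult,
    dilation_radius: int = 0,
) -> ColocResult:
    """Compute NF200 pixel fraction (%) and the MBP/NF200 overlap ratio.

    Overlap is counted at pixel level; ``dilation_radius`` (pixels,
    default 0) optionally dilates the MBP mask before overlap to absorb
    chromatic offset between channels.
    """
    nf_res = nf200_mask if isinstance(nf200_mask, MaskResult) else None
    mbp_res = mbp_mask if isinstance(mbp_mask, MaskResult) else None
    nf = np.asarray(nf_res.mask if nf_res else nf200_mask, dtype=bool)
    mbp = np.asarray(mbp_res.mask if mbp_res else mbp_mask, dtype=bool)
    if nf.shape != mbp.shape:
        raise ValueError(f"mask shapes differ: {nf.shape} vs {mbp.shape}")
    if dilation_radius > 0:
        mbp = dilation(mbp, disk(dilation_radius))
    n_nf = int(nf.sum())
    fraction = 100.0 * n_nf / nf.size
    if n_nf == 0:
        warnings.warn("empty NF200 mask: MBP/NF200 ratio undefined", stacklevel=2)
        ratio = None
    else:
        ratio = float(np.logical_and(nf, mbp).sum() / n_nf)
    return ColocResult(
        nf200_pixel_fraction=fraction,
        mbp_nf200_ratio=ratio,
        nf200_threshold=nf_res,
        mbp_threshold=mbp_res,
    )


def analyze_pair(
    nf200: ChannelStack,
    mbp: ChannelStack,
    method: str = "otsu",
    dilation_radius: int = 0,
) -> ColocResult:
    """Full per-image-pair pipeline: max-project, threshold, overlap."""
    if nf200.data.shape[1:] != mbp.data.shape[1:]:
        raise ValueError("channel stacks must share in-plane dimensions")
    nf_mask = make_mask(max_project(nf200), method)
    mbp_mask = make_mask(max_project(mbp), method)
    return coloc_metrics(nf_mask, mbp_mask, dilation_radius=dilation_radius)
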