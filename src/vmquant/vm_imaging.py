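"""Vasculogenic-mimicry quantification from two-channel histology rasters.

The pipeline detects bright tubular structures on the basement-membrane
(PAS) channel with a multi-scale Hessian ridge ("tubeness") filter, segments
them within the tissue, segments the endothelial (CD31) channel, subtracts
(dilated) vessel networks from the PAS networks, and scores the remaining
PAS-positive / CD31-negative area as a percentage of tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage import filters, morphology

__all__ = [
    "TwoChannelImage",
    "TubenessField",
    "NetworkMask",
    "VMQuantification",
    "ThresholdPolicy",
    "PASCategory",
    "hessian_eigenvalues",
    "tubeness",
    "detect_tissue",
    "segment_networks",
    "segment_cd31",
    "subtract_vessels",
    "compute_vm_score",
    "classify_pas_category",
    "compare_vm_by_group",
    "quantify_vm",
    "DEFAULT_SCALES_PX",
]

#: Default detection scales (Gaussian sigma, px) for the tubeness filter.
DEFAULT_SCALES_PX = (2.0, 3.0, 4.0, 6.0)


@dataclass
class TwoChannelImage:
    """PAS-fluorescence and CD31 rasters of one tissue field."""

    pas: np.ndarray
    cd31: np.ndarray
    pixel_size_um: float | None = None
    tissue_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pas = np.asarray(self.pas, dtype=float)
        self.cd31 = np.asarray(self.cd31, dtype=float)
        if self.pas.shape != self.cd31.shape:
            raise ValueError(
                f"channel shapes differ: pas {self.pas.shape}, cd31 {self.cd31.shape}"
            )
        for name, ch in (("pas", self.pas), ("cd31", self.cd31)):
            if not np.isfinite(ch).all():
                raise ValueError(f"{name} channel contains non-finite pixels")
            if (ch < 0).any():
                raise ValueError(f"{name} channel contains negative intensities")
        if self.tissue_mask is not None:
            self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
            if self.tissue_mask.shape != self.pas.shape:
                raise ValueError("tissue mask shape differs from channels")


@dataclass
class TubenessField:
    response: np.ndarray
    scales_px: list
    per_scale: np.ndarray | None = None  # (n_scales, H, W)


@dataclass
class NetworkMask:
    mask: np.ndarray
    min_component_px: int
    threshold_used: float
    n_components: int
    largest_component_px: int


class ThresholdPolicy(str, Enum):
    FIXED = "fixed"
    QUANTILE = "quantile"
    OTSU = "otsu"


class PASCategory(str, Enum):
    NEG = "PAS-neg"
    LOW = "PAS-low"
    HIGH = "PAS-high"


@dataclass
class VMQuantification:
    pas_network_mask: np.ndarray
    cd31_network_mask: np.ndarray
    vm_mask: np.ndarray
    vm_score: float  # percent of tissue area
    pas_area_fraction: float
    category: PASCategory
    params: dict = field(default_factory=dict)


def hessian_eigenvalues(
    raster: np.ndarray, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of the Gaussian-scale Hessian, sorted by magnitude.

    The Hessian at scale ``sigma`` is computed by convolution with second-
    order Gaussian derivative kernels (reflective boundary). Returns
    ``(lam1, lam2)`` with ``|lam1| <= |lam2|`` pixelwise.
    """
    raster = np.asarray(raster, dtype=float)
    if not np.isfinite(raster).all():
        raise ValueError("raster contains non-finite pixels")
    if sigma < 0.5:
        raise ValueError(f"sigma must be >= 0.5 px, got {sigma}")
    # truncate=8: the default 4-sigma support leaves derivative kernels that
    # do not annihilate constants/linears to float precision
    hrr = ndimage.gaussian_filter(raster, sigma, order=(2, 0), mode="reflect", truncate=8.0)
    hcc = ndimage.gaussian_filter(raster, sigma, order=(0, 2), mode="reflect", truncate=8.0)
    hrc = ndimage.gaussian_filter(raster, sigma, order=(1, 1), mode="reflect", truncate=8.0)
    # closed-form eigenvalues of the symmetric 2x2 Hessian
    half_tr = 0.5 * (hrr + hcc)
    disc = np.sqrt(0.25 * (hrr - hcc) ** 2 + hrc**2)
    ev_lo, ev_hi = half_tr - disc, half_tr + disc
    swap = np.abs(ev_lo) > np.abs(ev_hi)
    lam1 = np.where(swap, ev_hi, ev_lo)
    lam2 = np.where(swap, ev_lo, ev_hi)
    return lam1, lam2


def tubeness(
    image_channel: np.ndarray, scales_px: Sequence[float] = DEFAULT_SCALES_PX
) -> TubenessField:
    """Multi-scale bright-ridge response.

    Per scale sigma the response is ``sigma^2 * |lam2|`` where the larger-
    magnitude Hessian eigenvalue ``lam2`` is negative (bright line on dark
    background) and 0 elsewhere; sigma^2 normalizes response across scales.
    The field response is the pixelwise maximum over scales.
    """
    scales = [float(s) for s in scales_px]
    if not scales:
        raise ValueError("scales_px must be non-empty")
    per_scale = []
    for s in scales:
        _, lam2 = hessian_eigenvalues(image_channel, s)
        per_scale.append(s * s * np.maximum(0.0, -lam2))
    stack = np.stack(per_scale)
    return TubenessField(response=stack.max(axis=0), scales_px=scales, per_scale=stack)


def detect_tissue(
    image: TwoChannelImage,
    closing_radius: int = 5,
    min_tissue_px: int = 64,
) -> np.ndarray:
    """Tissue-extent mask from combined-channel intensity.

    If the image carries an explicit tissue mask it is returned unchanged.
    Otherwise the summed channels are Otsu-thresholded, morphologically
    closed and hole-filled.
    """
    if image.tissue_mask is not None:
        return image.tissue_mask
    combined = image.pas + image.cd31
    if combined.max() <= 0 or np.allclose(combined, combined.ravel()[0]):
        raise ValueError("no tissue detected: image is constant/background only")
    smoothed = ndimage.gaussian_filter(combined, 4.0, mode="reflect")
    # three classes: glass (near-black), tissue background, stained structures.
    # The lowest multi-Otsu cut separates glass from tissue; a guard detects
    # frames without glass (dark class not near-black), which are all tissue.
    try:
        t1, t2 = filters.threshold_multiotsu(smoothed, classes=3)
    except ValueError:  # fewer than 3 distinct levels
        t1 = t2 = float(filters.threshold_otsu(smoothed))
    dark = smoothed < t1
    mid = (smoothed >= t1) & (smoothed < t2)
    m0 = float(smoothed[dark].mean()) if dark.any() else 0.0
    m1 = float(smoothed[mid].mean()) if mid.any() else float(smoothed.mean())
    if m1 > 0 and m0 < 0.25 * m1:
        mask = smoothed >= t1
    else:
        mask = np.ones_like(smoothed, dtype=bool)
    mask = morphology.closing(mask, morphology.disk(closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    if mask.sum() < min_tissue_px:
        raise ValueError("no tissue detected")
    return mask


def _resolve_threshold(
    response: np.ndarray,
    tissue: np.ndarray,
    policy: ThresholdPolicy,
    value: float,
) -> float:
    in_tissue = response[tissue]
    if in_tissue.size == 0 or in_tissue.max() <= 0:
        return np.inf
    if policy is ThresholdPolicy.FIXED:
        return float(value)
    if policy is ThresholdPolicy.QUANTILE:
        # keep the top `value` fraction of in-tissue response
        return float(np.quantile(in_tissue, 1.0 - value))
    if in_tissue.min() == in_tissue.max():
        return np.inf  # flat response: nothing to segment
    return float(filters.threshold_otsu(in_tissue))


def _remove_small_components(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def _label_stats(mask: np.ndarray) -> tuple[int, int]:
    labels, n = ndimage.label(mask)
    if n == 0:
        return 0, 0
    sizes = np.bincount(labels.ravel())[1:]
    return n, int(sizes.max())


def segment_networks(
    field: TubenessField,
    tissue: np.ndarray,
    threshold_policy: ThresholdPolicy | str = ThresholdPolicy.QUANTILE,
    threshold_value: float = 0.05,
    min_component_px: int = 30,
) -> NetworkMask:
    """Binarize a tubeness field inside the tissue and drop small components."""
    policy = ThresholdPolicy(threshold_policy)
    tissue = np.asarray(tissue, dtype=bool)
    if field.response.shape != tissue.shape:
        raise ValueError("field and tissue mask shapes differ")
    thr = _resolve_threshold(field.response, tissue, policy, threshold_value)
    if np.isfinite(thr):
        # exclude exact zeros so a degenerate threshold of 0 stays empty
        mask = (field.response >= thr) & (field.response > 0) & tissue
    else:
        mask = np.zeros_like(tissue)
    if min_component_px > 1:
        mask = _remove_small_components(mask, min_component_px)
    n, largest = _label_stats(mask)
    return NetworkMask(
        mask=mask,
        min_component_px=min_component_px,
        threshold_used=float(thr) if np.isfinite(thr) else float("inf"),
        n_components=n,
        largest_component_px=largest,
    )


def segment_cd31(
    cd31: np.ndarray,
    tissue: np.ndarray,
    threshold_policy: ThresholdPolicy | str = ThresholdPolicy.QUANTILE,
    threshold_value: float = 0.05,
    min_component_px: int = 30,
    use_tubeness: bool = False,
    scales_px: Sequence[float] = DEFAULT_SCALES_PX,
) -> NetworkMask:
    """Segment the endothelial channel.

    Vessels are solid-stained, so by default raw intensity is thresholded;
    ``use_tubeness`` applies the ridge filter first instead.
    """
    cd31 = np.asarray(cd31, dtype=float)
    resp = tubeness(cd31, scales_px).response if use_tubeness else cd31
    return segment_networks(
        TubenessField(response=resp, scales_px=list(scales_px) if use_tubeness else []),
        tissue,
        threshold_policy,
        threshold_value,
        min_component_px,
    )


def subtract_vessels(
    pas_mask: np.ndarray, cd31_mask: np.ndarray, dilation_px: int = 2
) -> np.ndarray:
    """PAS network minus the (dilated) vessel network.

    Dilation absorbs registration offset between the two stains.
    """
    if dilation_px < 0:
        raise ValueError(f"dilation_px must be >= 0, got {dilation_px}")
    pas_mask = np.asarray(pas_mask, dtype=bool)
    cd31_mask = np.asarray(cd31_mask, dtype=bool)
    if pas_mask.shape != cd31_mask.shape:
        raise ValueError("mask shapes differ")
    vessels = (
        morphology.dilation(cd31_mask, morphology.disk(dilation_px))
        if dilation_px > 0
        else cd31_mask
    )
    return pas_mask & ~vessels


def compute_vm_score(vm_mask: np.ndarray, tissue: np.ndarray) -> float:
    """Percent of tissue area covered by the VM mask."""
    tissue = np.asarray(tissue, dtype=bool)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("empty tissue mask")
    return 100.0 * int((np.asarray(vm_mask, dtype=bool) & tissue).sum()) / n_tissue


def _has_branch_point(mask: np.ndarray) -> bool:
    """True if the skeleton of any component contains a branch point."""
    if not mask.any():
        return False
    skel = morphology.skeletonize(mask)
    if not skel.any():
        return False
    kernel = np.ones((3, 3))
    neighbor_count = ndimage.convolve(
        skel.astype(int), kernel, mode="constant", cval=0
    ) - skel.astype(int)
    return bool(np.any(skel & (neighbor_count >= 3)))


def classify_pas_category(
    pas_network_mask: np.ndarray,
    pas_area_fraction: float,
    low_area_fraction: float = 0.10,
) -> PASCategory:
    """Negative if no network; low if sparse (<10% of area) or the network
    has no branching component (disconnected arcs only); high otherwise."""
    mask = np.asarray(pas_network_mask, dtype=bool)
    if not mask.any():
        return PASCategory.NEG
    if pas_area_fraction < low_area_fraction or not _has_branch_point(mask):
        return PASCategory.LOW
    return PASCategory.HIGH


def quantify_vm(
    image: TwoChannelImage,
    scales_px: Sequence[float] = DEFAULT_SCALES_PX,
    threshold_policy: ThresholdPolicy | str = ThresholdPolicy.QUANTILE,
    threshold_value: float = 0.05,
    min_component_px: int = 30,
    dilation_px: int = 2,
) -> VMQuantification:
    """Run the full single-image pipeline: tissue, tubeness, segmentation,
    vessel subtraction, area scoring and categorization."""
    tissue = detect_tissue(image)
    field = tubeness(image.pas, scales_px)
    pas_net = segment_networks(
        field, tissue, threshold_policy, threshold_value, min_component_px
    )
    cd31_net = segment_cd31(
        image.cd31, tissue, threshold_policy, threshold_value, min_component_px
    )
    vm_mask = subtract_vessels(pas_net.mask, cd31_net.mask, dilation_px)
    score = compute_vm_score(vm_mask, tissue)
    pas_frac = float((pas_net.mask & tissue).sum() / tissue.sum())
    category = classify_pas_category(pas_net.mask, pas_frac)
    return VMQuantification(
        pas_network_mask=pas_net.mask,
        cd31_network_mask=cd31_net.mask,
        vm_mask=vm_mask,
        vm_score=score,
        pas_area_fraction=pas_frac,
        category=category,
        params={
            "scales_px": list(scales_px),
            "threshold_policy": str(ThresholdPolicy(threshold_policy).value),
            "threshold_value": threshold_value,
            "min_component_px": min_component_px,
            "dilation_px": dilation_px,
            "pas_threshold_used": pas_net.threshold_used,
            "cd31_threshold_used": cd31_net.threshold_used,
        },
    )


def compare_vm_by_group(
    scores: Sequence[tuple[float, str]]
) -> tuple[float, float, float]:
    """Unpaired two-sided t-test between two labelled score groups.

    Returns (mean of first label group, mean of second, p). Labels are the
    two distinct group names found in the input (sorted; e.g. DSG2+ / DSG2-).
    """
    labels = sorted({g for _, g in scores})
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    ga = np.array([s for s, g in scores if g == labels[0]], dtype=float)
    gb = np.array([s for s, g in scores if g == labels[1]], dtype=float)
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs >= 2 observations")
    res = stats.ttest_ind(ga, gb, equal_var=True)
    p = float(res.pvalue)
    if np.isnan(p) and ga.mean() == gb.mean():
        p = 1.0  # degenerate zero-variance identical groups
    return float(ga.mean()), float(gb.mean()), p
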