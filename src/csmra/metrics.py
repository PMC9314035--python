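"""Angiographic image-quality metrics.

Quality of a reconstruction is scored on maximum intensity projections
(MIPs) normalized to their 99th intensity percentile:

* **vessel-masked SSIM** — the mean structural similarity restricted to
  a vessel mask derived from the fully sampled reference MIP, which
  removes sensitivity to background variations;
* **peak counting** — the number of vessel crossings detected along
  cross-sectional intensity profiles (left-right lines covering the
  central fraction of the field of view in the anteroposterior
  direction), using topographic peak prominence. Fewer peaks than the
  fully sampled reference means vessels were lost to undersampling.

Axis semantics for 2D MIPs: "anteroposterior" runs along image rows,
"left-right" along image columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.signal import find_peaks
from skimage import morphology
from skimage.metrics import structural_similarity

_AXIS_OF = {"axial": 2, "coronal": 0}


@dataclass
class MIPImage:
    """A maximum intensity projection.

    Rows are anteroposterior, columns left-right (axial view).
    ``normalized`` records whether the image was divided by its 99th
    percentile (values above 1 may remain; SSIM clips internally).
    """

    image: NDArray[np.float64]
    axis: str = "axial"
    normalized: bool = False


@dataclass
class VesselMask2D:
    """Binary vessel mask over a MIP, with its construction parameters."""

    mask: NDArray[np.bool_]
    threshold: float = 0.25
    dilation_px: int = 2
    min_size_px: int = 5


@dataclass
class PeakCountResult:
    """Total and per-line peak counts of the cross-sectional-line metric."""

    n_peaks: int
    per_line_counts: list[int] = field(default_factory=list)
    line_rows: list[int] = field(default_factory=list)


def mip(volume: NDArray, axis: str = "axial") -> MIPImage:
    """Per-pixel maximum of a nonnegative magnitude volume along one axis.

    ``axial`` projects along the head-foot axis (volume axis 2) leaving
    (anteroposterior, left-right); ``coronal`` projects along volume
    axis 0.
    """
    if axis not in _AXIS_OF:
        raise ValueError(f"unknown projection axis {axis!r}; use axial|coronal")
    vol = np.asarray(volume)
    if np.any(vol < 0):
        raise ValueError("volume must be a nonnegative magnitude image")
    return MIPImage(image=vol.max(axis=_AXIS_OF[axis]), axis=axis, normalized=False)


def normalize_p99(image: MIPImage | NDArray) -> MIPImage:
    """Divide a MIP by its 99th intensity percentile."""
    if isinstance(image, MIPImage):
        arr, axis = image.image, image.axis
    else:
        arr, axis = np.asarray(image, dtype=float), "axial"
    if arr.size < 100:
        raise ValueError("image must have at least 100 pixels for a stable p99")
    p99 = np.percentile(arr, 99)
    if p99 == 0:
        raise ValueError("cannot normalize an (almost) all-zero image")
    return MIPImage(image=arr / p99, axis=axis, normalized=True)


def make_vessel_mask(
    reference: MIPImage,
    threshold: float = 0.25,
    dilation_px: int = 2,
    min_size_px: int = 5,
) -> VesselMask2D:
    """Vessel mask from a normalized reference MIP.

    Pixels at or above ``threshold`` are kept, small connected
    components (< ``min_size_px`` pixels) removed, and the result
    dilated by ``dilation_px`` so near-vessel context enters the
    masked SSIM.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if dilation_px < 0:
        raise ValueError("dilation_px must be >= 0")
    if not reference.normalized:
        raise ValueError("reference MIP must be p99-normalized first")
    mask = reference.image >= threshold
    if min_size_px > 1:
        # removes components strictly smaller than min_size_px
        mask = morphology.remove_small_objects(mask, max_size=min_size_px - 1)
    if dilation_px > 0:
        mask = morphology.dilation(mask, morphology.disk(dilation_px))
    return VesselMask2D(
        mask=mask,
        threshold=threshold,
        dilation_px=dilation_px,
        min_size_px=min_size_px,
    )


def masked_ssim(
    ref: MIPImage, test: MIPImage, mask: VesselMask2D | NDArray
) -> float:
    """Mean structural similarity over vessel-mask pixels only.

    The SSIM map uses a Gaussian window (sigma = 1.5, 11x11 support)
    and stabilizers C1 = (0.01 L)^2, C2 = (0.03 L)^2 with dynamic
    range L = 1 on p99-normalized images (clipped to [0, 1] for the
    SSIM computation only). Returns a value in [-1, 1]; 1 means
    perfect agreement on the masked region.
    """
    if not (ref.normalized and test.normalized):
        raise ValueError("both MIPs must be p99-normalized")
    if ref.image.shape != test.image.shape:
        raise ValueError(
            f"shape mismatch: ref {ref.image.shape} vs test {test.image.shape}"
        )
    m = mask.mask if isinstance(mask, VesselMask2D) else np.asarray(mask, dtype=bool)
    if m.shape != ref.image.shape:
        raise ValueError("mask shape does not match the images")
    if not m.any():
        raise ValueError("vessel mask is empty")
    a = np.clip(ref.image, 0.0, 1.0)
    b = np.clip(test.image, 0.0, 1.0)
    _, ssim_map = structural_similarity(
        a,
        b,
        data_range=1.0,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        full=True,
    )
    return float(ssim_map[m].mean())


def count_profile_peaks(profile: NDArray, min_prominence: float = 0.15) -> int:
    """Number of local maxima with topographic prominence ≥ ``min_prominence``.

    Prominence is the height of a peak above the higher of the two
    lowest saddles separating it from higher terrain. Plateaus count
    once; profile endpoints are never peaks.
    """
    prof = np.asarray(profile, dtype=float).ravel()
    if prof.size == 0:
        raise ValueError("profile is empty")
    if not np.all(np.isfinite(prof)):
        raise ValueError("profile contains non-finite values")
    if min_prominence < 0:
        raise ValueError("min_prominence must be nonnegative")
    peaks, _ = find_peaks(prof, prominence=min_prominence)
    return int(len(peaks))


def peak_count_metric(
    mip_img: MIPImage,
    n_lines: int = 100,
    coverage: float = 0.5,
    min_prominence: float = 0.15,
) -> PeakCountResult:
    """Count vessel-crossing peaks along cross-sectional lines.

    ``n_lines`` equally spaced left-right intensity profiles are taken
    from the rows spanning the central ``coverage`` fraction of the
    anteroposterior extent of a normalized MIP; peaks are counted per
    line with :func:`count_profile_peaks` and summed.
    """
    if not mip_img.normalized:
        raise ValueError("MIP must be p99-normalized before peak counting")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    n_rows = mip_img.image.shape[0]
    span = int(round(coverage * n_rows))
    start = (n_rows - span) // 2
    if n_lines > span:
        raise ValueError(
            f"n_lines={n_lines} exceeds the {span} rows in the central "
            f"{coverage:.0%} of the field of view"
        )
    # spacing >= 1 pixel, so rounded rows are strictly increasing
    rows = np.round(np.linspace(start, start + span - 1, n_lines)).astype(int)
    counts = [
        count_profile_peaks(mip_img.image[r, :], min_prominence) for r in rows
    ]
    return PeakCountResult(
        n_peaks=int(sum(counts)),
        per_line_counts=counts,
        line_rows=[int(r) for r in rows],
    )


def relative_peak_change(test: PeakCountResult, ref: PeakCountResult) -> float:
    """Percent change in detected peaks relative to the reference."""
    if ref.n_peaks <= 0:
        raise ValueError("reference peak count must be positive")
    return 100.0 * (test.n_peaks - ref.n_peaks) / ref.n_peaks
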