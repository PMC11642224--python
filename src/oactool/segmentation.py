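"""Ellipsoid-zone boundary detection and fixed-thickness slab projection.

The ellipsoid zone (EZ) is the hyper-reflective outer-retinal band just
above the much brighter retinal pigment epithelium (RPE). The reference
detector here exploits that anatomy: per A-scan, the global intensity
maximum anchors the RPE, and the most prominent local maximum within a
physical search band above it is taken as the EZ peak; the EZ upper
boundary is the peak's upper half-maximum crossing. The surface is cleaned
laterally with nearest-valid in-filling and a 5x5 median filter.

An externally supplied, manually corrected boundary surface (see
``oct_io.read_boundary``) can be used in place of this detector; clinical
segmentation of diseased eyes typically needs expert review.

The slab itself is a fixed physical thickness below the boundary
(default 15.6 um) averaged along depth into an en face map — of
attenuation coefficients (OAC arm) or of raw intensity (intensity arm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .attenuation import AttenuationVolume
from .errors import DataError, SegmentationFailure
from .oct_io import BoundarySurface, EnFaceImage, OCTVolume

#: Default physical search band for the EZ peak above the RPE anchor, in um.
DEFAULT_SEARCH_BAND_UM = (20.0, 80.0)

#: Minimum peak prominence relative to its own height for a column to count
#: as segmented; scale-invariant, so vessel shadows do not move the boundary.
PROMINENCE_FRACTION = 0.3


@dataclass
class SlabSpec:
    """Physical extent of the en face slab below the detected boundary.

    thickness_um defaults to 15.6 um — a fixed sub-band of the foveal EZ
    (full foveal EZ thickness is about 24 um); offset_um shifts the slab
    start below the boundary.
    """

    thickness_um: float = 15.6
    offset_um: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise DataError("slab thickness must be positive")

    def n_pixels(self, dz_um: float) -> int:
        """Slab thickness in depth pixels: round-half-away-from-zero, min 1."""
        return max(1, int(math.floor(self.thickness_um / dz_um + 0.5)))

    def offset_pixels(self, dz_um: float) -> int:
        return int(math.floor(self.offset_um / dz_um + 0.5))


def detect_ez_boundary(volume: OCTVolume, smooth_sigma_px: float = 2.0,
                       lateral_sigma_px: float = 1.5,
                       search_band_um: tuple[float, float] = DEFAULT_SEARCH_BAND_UM,
                       max_invalid_fraction: float = 0.5) -> BoundarySurface:
    """Locate the EZ band's upper boundary in every A-scan.

    Per column: (1) smooth axially with a Gaussian of ``smooth_sigma_px``
    (plus mild lateral smoothing, ``lateral_sigma_px``, to knock down
    speckle — spatially white, unlike the layered signal); (2) anchor the
    RPE at the global maximum; (3) pick the tallest sufficiently prominent
    local maximum within ``search_band_um`` above the anchor as the EZ
    peak; (4) the boundary is the depth where the profile last crossed
    half the peak value above the peak. Columns with no qualifying peak
    are flagged invalid, in-filled from the nearest valid neighbour, and
    the surface is median-filtered 5x5.

    Raises
    ------
    SegmentationFailure
        If more than ``max_invalid_fraction`` of columns have no qualifying
        peak — the volume lacks a usable outer-retinal complex.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    nz = volume.nz
    s = ndi.gaussian_filter(data, (smooth_sigma_px, lateral_sigma_px, lateral_sigma_px),
                            mode="nearest")

    rpe_z = np.argmax(s, axis=0)  # (nx, ny)
    lo_px = max(1, int(round(search_band_um[0] / volume.dz)))
    hi_px = int(round(search_band_um[1] / volume.dz))
    if hi_px <= lo_px:
        raise DataError("search band is empty at this axial pitch")

    zgrid = np.arange(nz)[:, None, None]
    band = (zgrid >= rpe_z[None] - hi_px) & (zgrid <= rpe_z[None] - lo_px) & (zgrid >= 0)

    # strict/loose pair breaks plateau ties toward the shallower sample
    prev_ = np.roll(s, 1, axis=0)
    next_ = np.roll(s, -1, axis=0)
    prev_[0] = -np.inf
    next_[-1] = -np.inf
    local_max = (s >= prev_) & (s > next_) & band

    neg_inf = np.full_like(s, -np.inf)
    peaks = np.where(local_max, s, neg_inf)
    peak_z = np.argmax(peaks, axis=0)
    has_peak = local_max.any(axis=0)
    peak_val = np.take_along_axis(s, peak_z[None], axis=0)[0]

    # prominence against the saddles separating the peak from the RPE below
    # and from whatever lies one band-height above
    pos_inf = np.full_like(s, np.inf)
    between = (zgrid > peak_z[None]) & (zgrid <= rpe_z[None])
    saddle_below = np.where(between, s, pos_inf).min(axis=0)
    above = (zgrid < peak_z[None]) & (zgrid >= peak_z[None] - (hi_px - lo_px))
    saddle_above = np.where(above, s, pos_inf).min(axis=0)
    base = np.maximum(saddle_below, saddle_above)
    base = np.where(np.isfinite(base), base, peak_val)
    with np.errstate(invalid="ignore", divide="ignore"):
        prominence_ok = (peak_val - base) >= PROMINENCE_FRACTION * peak_val

    valid = has_peak & prominence_ok & (peak_val > 0)

    invalid_fraction = 1.0 - valid.mean()
    if invalid_fraction > max_invalid_fraction:
        raise SegmentationFailure(
            f"no qualifying EZ peak in {invalid_fraction:.0%} of columns; "
            "supply an external boundary surface instead"
        )

    # upper half-maximum crossing: last depth above the peak below half height
    below_half = (s < 0.5 * peak_val[None]) & (zgrid <= peak_z[None])
    cross = np.where(below_half, zgrid, -1).max(axis=0)
    boundary = np.where(cross >= 0, cross + 1, np.maximum(peak_z - (hi_px - lo_px), 0))
    boundary = boundary.astype(np.int64)

    if not valid.all():
        # nearest-valid in-fill keeps the surface defined under vessels etc.
        _, (ix, iy) = ndi.distance_transform_edt(~valid, return_indices=True)
        boundary = boundary[ix, iy]
    boundary = ndi.median_filter(boundary, size=5, mode="nearest")
    boundary = np.clip(boundary, 0, nz - 1)
    return BoundarySurface(z_index=boundary, valid_mask=valid)


def extract_slab_enface(source: OCTVolume | AttenuationVolume,
                        boundary: BoundarySurface,
                        spec: SlabSpec | None = None) -> EnFaceImage:
    """Average a fixed-thickness slab below the boundary into an en face map.

    The slab spans ``n = max(1, round(thickness_um / dz))`` depth pixels
    from ``boundary + offset``; columns whose slab would run past the volume
    bottom are clamped (averaging only the available depths) with a warning
    recording the clamped-column count. The output ``kind`` follows the
    source: attenuation volumes yield attenuation maps (mm^-1), intensity
    volumes yield intensity maps.
    """
    spec = spec or SlabSpec()
    if isinstance(source, AttenuationVolume):
        data, kind, units = source.mu, "attenuation", "mm^-1"
    else:
        data, kind, units = source.data, "intensity", "arbitrary"
    nz = data.shape[0]
    if boundary.z_index.shape != data.shape[1:]:
        raise DataError("boundary lateral shape does not match the volume")
    if np.any((boundary.z_index < 0) | (boundary.z_index >= nz)):
        raise DataError("boundary z indices fall outside the volume depth range")

    n_slab = spec.n_pixels(source.dz)
    start = np.clip(boundary.z_index + spec.offset_pixels(source.dz), 0, nz - 1)

    offs = np.arange(n_slab)[:, None, None]
    zidx = start[None] + offs  # (n_slab, nx, ny)
    inside = zidx < nz
    vals = np.take_along_axis(data, np.minimum(zidx, nz - 1), axis=0)
    counts = inside.sum(axis=0)
    enface = np.where(inside, vals, 0.0).sum(axis=0) / counts

    n_clamped = int((counts < n_slab).sum())
    if n_clamped:
        warnings.warn(f"slab clamped at the volume bottom in {n_clamped} columns")
    return EnFaceImage(enface, kind=kind, units=units)
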