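"""One-call orchestration of the two en face quantification arms.

Both arms share the stage order

    volume -> [attenuation coefficients]? -> EZ boundary -> slab en face
           -> nonlocal-means denoise -> normalize -> Phansalkar threshold
           -> percent white/black area

and differ only in (a) whether the slab averages attenuation coefficients
(``oac_plus``) or raw intensity (``oac_minus``) and (b) the Phansalkar
``k`` default (0.475 vs 1.0). The boundary is always detected on the
intensity volume (or loaded from a file) so both arms quantify the same
anatomy. Every run emits a provenance record with all resolved parameters
and input checksums; reruns on identical inputs are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np

from . import __version__
from .attenuation import DEFAULT_MU_CAP, AttenuationVolume, compute_oac
from .enface_processing import (DEFAULT_K_INTENSITY, DEFAULT_K_OAC,
                                DEFAULT_MU_DISPLAY_RANGE, DEFAULT_NLM_H,
                                DEFAULT_P, DEFAULT_Q, DEFAULT_R, DEFAULT_SMALL_R,
                                AreaMetrics, BinaryEZMap, display_scale,
                                nlm_denoise, phansalkar_threshold, quantify_area)
from .errors import ConfigurationError
from .oct_io import (BoundarySurface, EnFaceImage, OCTVolume, read_boundary,
                     read_volume, write_enface, write_metrics)
from .segmentation import SlabSpec, detect_ez_boundary, extract_slab_enface

METHODS = ("oac_plus", "oac_minus")

STAGE_ORDER = ("slab_enface", "display_scale", "nlm_denoise",
               "phansalkar_threshold", "quantify_area")


def default_k(method: str) -> float:
    return DEFAULT_K_OAC if method == "oac_plus" else DEFAULT_K_INTENSITY


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    method: str = "oac_plus"
    volume_path: str | None = None
    sidecar_path: str | None = None
    boundary_source: str = "auto"  # "auto" | "file"
    boundary_path: str | None = None
    out_dir: str | None = None
    slab: SlabSpec = field(default_factory=SlabSpec)
    nlm: dict[str, float] = field(default_factory=lambda: {"H": DEFAULT_NLM_H,
                                                           "patch": 7, "search": 21})
    threshold: dict[str, float] = field(default_factory=dict)
    display_range: tuple[float, float] | None = None
    mu_cap: float = DEFAULT_MU_CAP
    smooth_sigma_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.boundary_source not in ("auto", "file"):
            raise ConfigurationError("boundary_source must be 'auto' or 'file'")
        if self.boundary_source == "file" and not self.boundary_path:
            raise ConfigurationError("boundary_source='file' needs boundary_path")
        thr = {"R": DEFAULT_R, "k": default_k(self.method), "p": DEFAULT_P,
               "q": DEFAULT_Q, "r": DEFAULT_SMALL_R}
        thr.update(self.threshold)
        self.threshold = thr

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "slab" in raw:
            raw["slab"] = SlabSpec(**raw["slab"])
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    enface: EnFaceImage
    enface_denoised: EnFaceImage
    mask: BinaryEZMap
    metrics: AreaMetrics
    provenance: dict[str, Any]


def _sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_arrays(volume: OCTVolume, method: str, boundary: BoundarySurface | None = None,
               slab: SlabSpec | None = None, nlm: dict | None = None,
               threshold: dict | None = None,
               display_range: tuple[float, float] | None = None,
               mu_cap: float = DEFAULT_MU_CAP,
               smooth_sigma_px: float = 2.0) -> PipelineResult:
    """Run one arm fully in memory (no file I/O).

    ``boundary`` may be supplied (e.g. a phantom's ground truth or a
    manually corrected surface); otherwise it is detected on the intensity
    volume. ``display_range`` fixes the normalization bounds; the default
    is the physical attenuation window (0-15 mm^-1) for the attenuation
    arm and per-image robust percentiles for the unitless intensity arm.
    """
    if method not in METHODS:
        raise ConfigurationError(f"method must be one of {METHODS}")
    slab = slab or SlabSpec()
    nlm_params = {"H": DEFAULT_NLM_H, "patch": 7, "search": 21}
    nlm_params.update(nlm or {})
    thr_params = {"R": DEFAULT_R, "k": default_k(method), "p": DEFAULT_P,
                  "q": DEFAULT_Q, "r": DEFAULT_SMALL_R}
    thr_params.update(threshold or {})
    if display_range is None and method == "oac_plus":
        display_range = DEFAULT_MU_DISPLAY_RANGE

    external_boundary = boundary is not None
    if boundary is None:
        boundary = detect_ez_boundary(volume, smooth_sigma_px=smooth_sigma_px)

    source: OCTVolume | AttenuationVolume
    if method == "oac_plus":
        source = compute_oac(volume, mu_cap=mu_cap)
    else:
        source = volume
    enface = extract_slab_enface(source, boundary, slab)
    normalized, bounds = display_scale(enface, bounds=display_range)
    denoised = nlm_denoise(normalized, H=nlm_params["H"], patch=int(nlm_params["patch"]),
                           search=int(nlm_params["search"]), value_range=(0.0, 1.0))
    mask = phansalkar_threshold(denoised, normalize=False, **thr_params)
    metrics = quantify_area(mask)

    provenance: dict[str, Any] = {
        "oactool_version": __version__,
        "method": method,
        "stage_order": list(STAGE_ORDER),
        "slab_source": "attenuation" if method == "oac_plus" else "intensity",
        "slab": asdict(slab),
        "nlm": nlm_params,
        "threshold": thr_params,
        "display_bounds": list(bounds),
        "display_bounds_source": "fixed" if display_range is not None else "percentile",
        "mu_cap": mu_cap,
        "boundary_source": "external" if external_boundary else "auto",
        "metrics": metrics.as_dict(),
    }
    return PipelineResult(enface=enface, enface_denoised=denoised, mask=mask,
                          metrics=metrics, provenance=provenance)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run one arm from files to files, per the config.

    Writes ``enface.tif``, ``enface_denoised.tif``, ``mask.png``,
    ``metrics.json`` and ``provenance.json`` into ``config.out_dir``
    (if set); returns the in-memory result as well.
    """
    if not config.volume_path:
        raise ConfigurationError("config.volume_path is required")
    volume = read_volume(config.volume_path, config.sidecar_path)

    boundary = None
    if config.boundary_source == "file":
        boundary = read_boundary(config.boundary_path)

    result = run_arrays(volume, config.method, boundary=boundary, slab=config.slab,
                        nlm=config.nlm, threshold=config.threshold,
                        display_range=config.display_range,
                        mu_cap=config.mu_cap, smooth_sigma_px=config.smooth_sigma_px)

    checksums = {"volume": _sha256_of(config.volume_path)}
    if config.boundary_path:
        checksums["boundary"] = _sha256_of(config.boundary_path)
    result.provenance.update({
        "input_checksums": checksums,
        "boundary_source": config.boundary_source,
        "config": {**asdict(config), "slab": asdict(config.slab)},
    })

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_enface(result.enface, out / "enface.tif", bit_depth="float")
        write_enface(result.enface_denoised, out / "enface_denoised.tif", bit_depth="float")
        iio.imwrite(out / "mask.png", (result.mask.mask * np.uint8(255)))
        write_metrics({**result.metrics.as_dict(), "params": result.mask.params},
                      out / "metrics.json")
        write_metrics(result.provenance, out / "provenance.json")
    return result
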