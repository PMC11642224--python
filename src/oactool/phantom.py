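"""Synthetic layered-retina OCT phantoms with known ground truth.

The forward model is single-scattering Beer-Lambert: each voxel's
noise-free signal is its local backscatter reflectivity times the
round-trip attenuation accumulated above it,

    I(z, x, y) = R(z, x, y) * exp(-2 * integral_0^z mu dz'),

with reflectivity and attenuation coefficient piecewise constant over a
table of horizontal layers (inner retina, ellipsoid zone, RPE, choroid by
default). Default reflectivities are proportional to layer mu — the
backscattered fraction of what a layer removes from the beam — which is
the consistency condition under which the depth-resolved attenuation
estimator recovers each layer's mu.

Three phenomena of real data are emulated on top:

* **vessel shadows** — lateral discs that multiply the signal by a
  transmission factor c for every depth below the vessel (pure projection
  artifact, the mechanism the attenuation arm is designed to cancel);
* **fully developed speckle** — i.i.d. unit-mean exponential multiplicative
  noise on the linear intensity;
* **EZ defects** — lateral discs over which the ellipsoid-zone layer's
  reflectivity and mu are scaled down, with the exact pixel-level defect
  mask and area fraction returned as ground truth.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import PhantomSpecError
from .oct_io import BoundarySurface, OCTVolume


@dataclass
class Layer:
    """One horizontal slab of tissue: extent in depth, reflectivity, mu (mm^-1)."""

    name: str
    z_center_um: float
    thickness_um: float
    reflectivity: float
    mu: float

    @property
    def z_top_um(self) -> float:
        return self.z_center_um - self.thickness_um / 2.0

    @property
    def z_bottom_um(self) -> float:
        return self.z_center_um + self.thickness_um / 2.0


@dataclass
class Vessel:
    """A retinal vessel modelled as a pure multiplicative shadow.

    With ``angle_deg`` None the shadow is a disc of ``radius_um`` around
    (x_um, y_um); otherwise it is a stripe of half-width ``radius_um``
    along a line through (x_um, y_um) at that orientation — the en face
    footprint of a vessel running across the field. Shadowed columns are
    multiplied by ``transmission`` for every depth at and below ``z_um``.
    """

    x_um: float
    y_um: float
    radius_um: float
    transmission: float
    z_um: float = 300.0
    angle_deg: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.transmission < 1.0:
            raise PhantomSpecError("vessel transmission must lie in (0, 1)")


@dataclass
class Defect:
    """A lateral disc over which the EZ layer's reflectivity and mu are scaled."""

    x_um: float
    y_um: float
    radius_um: float
    reflectivity_scale: float = 0.2
    mu_scale: float = 0.2


def default_layer_table() -> list[Layer]:
    """Healthy outer-retina geometry for the default 1.33 mm deep volume.

    Reflectivities are 0.05 * mu so backscatter tracks extinction.
    """
    c = 0.05
    return [
        Layer("inner_retina", z_center_um=300.0, thickness_um=400.0,
              reflectivity=c * 1.5, mu=1.5),
        Layer("ez", z_center_um=560.0, thickness_um=20.0,
              reflectivity=c * 10.0, mu=10.0),
        Layer("rpe", z_center_um=600.0, thickness_um=25.0,
              reflectivity=c * 20.0, mu=20.0),
        Layer("choroid", z_center_um=960.0, thickness_um=690.0,
              reflectivity=c * 6.0, mu=6.0),
    ]


def default_vessels(n: int = 4, seed: int = 0, field_um: float = 1500.0,
                    radius_um: float = 40.0, transmission: float = 0.35) -> list[Vessel]:
    """Vessel stripes crossing the field at random positions and orientations.

    Defaults emulate a macular field traversed by a few small vessels
    (80 um calibre, strong shadowing); deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        x, y = rng.uniform(0.1 * field_um, 0.9 * field_um, size=2)
        out.append(Vessel(x_um=float(x), y_um=float(y), radius_um=radius_um,
                          transmission=transmission, z_um=300.0,
                          angle_deg=float(rng.uniform(0.0, 180.0))))
    return out


@dataclass
class PhantomSpec:
    """Full description of one synthetic eye.

    Defaults give a desk-scale 512 x 128 x 128 volume at dz = 2.6 um,
    lateral field 1.5 x 1.5 mm (the clinical frame at reduced lateral
    sampling); speckle off, no vessels, no defects.
    """

    shape: tuple[int, int, int] = (512, 128, 128)
    dz: float = 2.6
    dx: float = 1500.0 / 128
    dy: float = 1500.0 / 128
    layers: list[Layer] = field(default_factory=default_layer_table)
    vessels: list[Vessel] = field(default_factory=list)
    defects: list[Defect] = field(default_factory=list)
    background_reflectivity: float = 0.01
    background_mu: float = 0.5
    speckle: str = "none"
    seed: int = 0

    def ez_layer(self) -> Layer:
        for layer in self.layers:
            if layer.name == "ez":
                return layer
        raise PhantomSpecError("layer table has no 'ez' layer")


def healthy_spec(shape: tuple[int, int, int] = (512, 128, 128), seed: int = 0,
                 speckle: str = "exponential") -> PhantomSpec:
    """The canonical healthy vesselled eye: default layers, 4 vessel stripes."""
    return PhantomSpec(shape=shape, speckle=speckle, seed=seed,
                       vessels=default_vessels(seed=seed))


def defect_spec(defect_fraction: float, shape: tuple[int, int, int] = (512, 128, 128),
                seed: int = 0, speckle: str = "exponential") -> PhantomSpec:
    """A vesselled eye with one circular EZ defect of the given area fraction.

    ``defect_fraction`` is the target fraction in [0, 1); the realized
    pixel-level fraction is reported in the returned phantom's truth.
    """
    spec = healthy_spec(shape=shape, seed=seed, speckle=speckle)
    field_x = shape[1] * spec.dx
    field_y = shape[2] * spec.dy
    radius = float(np.sqrt(defect_fraction * field_x * field_y / np.pi))
    spec.defects = [Defect(x_um=field_x / 2, y_um=field_y / 2, radius_um=radius)]
    return spec


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    ez_boundary: BoundarySurface
    defect_mask: np.ndarray
    defect_fraction: float  # percent of lateral pixels inside a defect
    vessel_mask: np.ndarray


def _lateral_disc_mask(spec: PhantomSpec, x_um: float, y_um: float,
                       radius_um: float) -> np.ndarray:
    nx, ny = spec.shape[1], spec.shape[2]
    xg = (np.arange(nx) + 0.5) * spec.dx
    yg = (np.arange(ny) + 0.5) * spec.dy
    return ((xg[:, None] - x_um) ** 2 + (yg[None, :] - y_um) ** 2) <= radius_um ** 2


def _vessel_footprint(spec: PhantomSpec, vessel: Vessel) -> np.ndarray:
    if vessel.angle_deg is None:
        return _lateral_disc_mask(spec, vessel.x_um, vessel.y_um, vessel.radius_um)
    nx, ny = spec.shape[1], spec.shape[2]
    xg = (np.arange(nx) + 0.5) * spec.dx
    yg = (np.arange(ny) + 0.5) * spec.dy
    theta = np.deg2rad(vessel.angle_deg)
    # signed distance to the line through (x_um, y_um) with direction theta
    d = (-(xg[:, None] - vessel.x_um) * np.sin(theta)
         + (yg[None, :] - vessel.y_um) * np.cos(theta))
    return np.abs(d) <= vessel.radius_um


def _validate_layers(spec: PhantomSpec) -> None:
    nz = spec.shape[0]
    depth_um = nz * spec.dz
    ordered = sorted(spec.layers, key=lambda L: L.z_top_um)
    for layer in ordered:
        if layer.z_top_um < 0 or layer.z_bottom_um > depth_um:
            raise PhantomSpecError(f"layer {layer.name!r} does not fit inside the volume")
    for upper, lower in zip(ordered, ordered[1:]):
        if upper.z_bottom_um > lower.z_top_um + 1e-9:
            raise PhantomSpecError(
                f"layers {upper.name!r} and {lower.name!r} overlap in depth")


def generate_phantom(spec: PhantomSpec) -> tuple[OCTVolume, PhantomTruth]:
    """Render one phantom volume and its ground truth.

    Deterministic given ``spec.seed``; speckle uses an independent stream
    derived from it.
    """
    _validate_layers(spec)
    nz, nx, ny = spec.shape
    z_um = (np.arange(nz) + 0.5) * spec.dz

    # per-column 3-D reflectivity and attenuation fields
    R = np.full((nz, nx, ny), spec.background_reflectivity, dtype=np.float64)
    mu = np.full((nz, nx, ny), spec.background_mu, dtype=np.float64)

    defect_mask = np.zeros((nx, ny), dtype=bool)
    ez = spec.ez_layer()
    for layer in spec.layers:
        inside = (z_um >= layer.z_top_um) & (z_um < layer.z_bottom_um)
        R[inside] = layer.reflectivity
        mu[inside] = layer.mu
    for defect in spec.defects:
        lat = _lateral_disc_mask(spec, defect.x_um, defect.y_um, defect.radius_um)
        defect_mask |= lat
        inside_ez = (z_um >= ez.z_top_um) & (z_um < ez.z_bottom_um)
        sel = inside_ez[:, None, None] & lat[None]
        R[sel] *= defect.reflectivity_scale
        mu[sel] *= defect.mu_scale

    # round-trip attenuation accumulated above each voxel's top face
    dz_mm = spec.dz / 1000.0
    optical_depth = np.cumsum(mu, axis=0) * dz_mm
    above = optical_depth - mu * dz_mm
    signal = R * np.exp(-2.0 * above)

    vessel_mask = np.zeros((nx, ny), dtype=bool)
    for vessel in spec.vessels:
        lat = _vessel_footprint(spec, vessel)
        vessel_mask |= lat
        below = z_um >= vessel.z_um
        signal[below] = np.where(lat[None], signal[below] * vessel.transmission,
                                 signal[below])

    if spec.speckle == "exponential":
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5bec]))
        signal = signal * rng.exponential(1.0, size=signal.shape)
    elif spec.speckle != "none":
        raise PhantomSpecError(f"unknown speckle model {spec.speckle!r}")

    volume = OCTVolume(signal, dz=spec.dz, dx=spec.dx, dy=spec.dy,
                       meta={"phantom": True, "seed": spec.seed})

    ez_top_idx = int(np.searchsorted(z_um, ez.z_top_um))
    boundary = BoundarySurface(
        z_index=np.full((nx, ny), ez_top_idx, dtype=np.int64),
        valid_mask=np.ones((nx, ny), dtype=bool),
    )
    truth = PhantomTruth(
        ez_boundary=boundary,
        defect_mask=defect_mask,
        defect_fraction=100.0 * int(defect_mask.sum()) / defect_mask.size,
        vessel_mask=vessel_mask,
    )
    return volume, truth


def generate_cohort(base_spec: PhantomSpec, n_eyes: int, variability: float = 0.3,
                    seed: int = 0) -> list[tuple[OCTVolume, PhantomTruth]]:
    """Generate a cohort of eyes by perturbing the base spec.

    ``variability`` in [0, 1] scales between-eye anatomical variation:
    layer depths jitter with sd ``variability * 25 um`` and vessel/defect
    positions are re-drawn per eye (radii and transmissions kept). With
    ``variability == 0`` geometry is identical across eyes and only the
    speckle realization differs (none at all if speckle is off).
    Deterministic given ``seed``.
    """
    if n_eyes < 2:
        raise PhantomSpecError("a cohort needs at least 2 eyes")
    field_x = base_spec.shape[1] * base_spec.dx
    field_y = base_spec.shape[2] * base_spec.dy
    cohort = []
    depth_um = base_spec.shape[0] * base_spec.dz
    shift_lo = -min(L.z_top_um for L in base_spec.layers)
    shift_hi = depth_um - max(L.z_bottom_um for L in base_spec.layers)
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_eyes)):
        rng = np.random.default_rng(child)
        # clipped so jittered layers always fit inside the volume
        shift = float(np.clip(rng.normal(0.0, variability * 25.0), shift_lo, shift_hi))
        layers = [replace(L, z_center_um=L.z_center_um + shift) for L in base_spec.layers]
        if variability > 0:
            vessels = [replace(v,
                               x_um=float(rng.uniform(0.05 * field_x, 0.95 * field_x)),
                               y_um=float(rng.uniform(0.05 * field_y, 0.95 * field_y)),
                               angle_deg=(float(rng.uniform(0.0, 180.0))
                                          if v.angle_deg is not None else None))
                       for v in base_spec.vessels]
            defects = [replace(d,
                               x_um=float(rng.uniform(d.radius_um, field_x - d.radius_um)),
                               y_um=float(rng.uniform(d.radius_um, field_y - d.radius_um)))
                       for d in base_spec.defects]
        else:
            vessels = list(base_spec.vessels)
            defects = list(base_spec.defects)
        eye_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(base_spec, layers=layers, vessels=vessels, defects=defects,
                       seed=eye_seed)
        cohort.append(generate_phantom(spec))
    return cohort
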