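"""Metal-artifact simulation: material weighting, polychromatic forward
projection, FBP reconstruction, triplet assembly and dataset building.

The artifact model follows the standard CT beam-hardening simulation
pipeline: an artifact-free HU slice is decomposed into soft-threshold
water/bone/metal weights, mapped to energy-dependent attenuation, projected
with a polychromatic source spectrum, and reconstructed with filtered back
projection.  The nonlinearity of ``-ln(sum_e S(e) exp(-mu(e) L))`` in the
path length produces the dark bands and streaks characteristic of metal
implants; subtracting the original slice yields the artifact residual that
the network is trained to predict.

Geometry is parallel-beam throughout: 180 view angles over [0, 180) and a
detector row spanning the image diagonal.  Projection and reconstruction
are delegated to ``skimage.transform.radon``/``iradon``; this module owns
the physics (spectra, attenuation tables, noise) and the bookkeeping.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import iradon as _sk_iradon

from .phantom import ImageGrid, MetalMask, generate_phantom, generate_metal_mask, APPLICATORS

logger = logging.getLogger(__name__)

__all__ = [
    "Sinogram",
    "MaterialMap",
    "TripletSample",
    "Spectrum",
    "SimConfig",
    "DatasetConfig",
    "Dataset",
    "default_angles",
    "default_n_detectors",
    "segment_materials",
    "forward_project",
    "polychromatic_project",
    "reconstruct_fbp",
    "simulate_artifact_insert",
    "build_dataset",
]

# ---------------------------------------------------------------------------
# Attenuation model
# ---------------------------------------------------------------------------

#: Energy grid (keV) of the shipped attenuation tables.
ENERGIES_KEV = np.array([40.0, 60.0, 80.0, 100.0, 120.0])

#: Linear attenuation coefficients (1/cm) per material on ENERGIES_KEV.
#: Water and cortical bone follow tabulated photon cross sections; "metal"
#: is titanium-like (density 4.5 g/cm^3).
MU_TABLES = {
    "water": np.array([0.2683, 0.2059, 0.1837, 0.1707, 0.1614]),
    "bone": np.array([1.2780, 0.6040, 0.4280, 0.3560, 0.3180]),
    "metal": np.array([4.9800, 1.8200, 1.2200, 0.9700, 0.8330]),
}

#: Reference energy (keV) at which HU values are defined, and the per-
#: material attenuation there (linear interpolation of the tables).
E_REF_KEV = 70.0
MU_REF = {
    "water": 0.1948,
    "bone": 0.5160,
    "metal": 1.5200,
}

MATERIALS = ("water", "bone", "metal")

#: Transmission floor: intensities below this are clamped (with a warning)
#: before taking the log, emulating a finite detector dynamic range.
TRANSMISSION_FLOOR = 1e-12


def hu_to_mu(hu: np.ndarray) -> np.ndarray:
    """HU -> linear attenuation (1/cm) at the reference energy (clipped >= 0)."""
    return np.clip(MU_REF["water"] * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0), 0.0, None)


def mu_to_hu(mu: np.ndarray) -> np.ndarray:
    """Linear attenuation (1/cm) at the reference energy -> HU."""
    return 1000.0 * (np.asarray(mu, dtype=np.float64) / MU_REF["water"] - 1.0)


@dataclass
class Spectrum:
    """Discrete X-ray source spectrum: energy bins (keV) and weights summing to 1."""

    energies_kev: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.energies_kev = np.asarray(self.energies_kev, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.energies_kev.shape != self.weights.shape or self.energies_kev.ndim != 1:
            raise ValueError("energies and weights must be 1-D and equally long")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("spectrum weights must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.weights)


def default_spectrum(hardness: float = 0.5) -> Spectrum:
    """Tube-shaped 5-bin spectrum on the shipped energy grid.

    ``hardness`` in [0, 1] interpolates between a soft (low-kVp-like) and a
    hard (heavily filtered) weight profile; 0.5 resembles a 120-kVp beam.
    """
    soft = np.array([0.30, 0.34, 0.22, 0.10, 0.04])
    hard = np.array([0.06, 0.20, 0.30, 0.26, 0.18])
    w = (1.0 - hardness) * soft + hardness * hard
    return Spectrum(ENERGIES_KEV.copy(), w / w.sum())


def monoenergetic_spectrum(energy_kev: float) -> Spectrum:
    """Single-bin spectrum; collapses the polychromatic model."""
    return Spectrum(np.array([energy_kev]), np.array([1.0]))


def mu_table_at(energies_kev: np.ndarray) -> np.ndarray:
    """Interpolated (3, n_bins) attenuation table on arbitrary energies."""
    out = np.empty((3, len(energies_kev)))
    for i, m in enumerate(MATERIALS):
        out[i] = np.interp(energies_kev, ENERGIES_KEV, MU_TABLES[m])
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Sinogram:
    """Parallel-beam projection data: ``(n_angles, n_detectors)`` line integrals."""

    values: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2-D (n_angles, n_detectors)")
        if len(self.angles_deg) != self.values.shape[0]:
            raise ValueError("angle list length must match n_angles")
        if len(self.angles_deg) == 0:
            raise ValueError("at least one projection angle is required")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles_deg[0] < 0 or self.angles_deg[-1] >= 180.0:
            raise ValueError("angles must lie in [0, 180)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")

    @property
    def n_angles(self) -> int:
        return self.values.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.values.shape[1]


@dataclass
class MaterialMap:
    """Per-pixel soft material weights plus the attenuation model.

    ``weights[..., m]`` are the water/bone/metal fractions (summing to 1 at
    every pixel); ``mu_ref_image`` is the per-pixel attenuation (1/cm) at
    the reference energy, carrying the within-class HU contrast that the
    class-wise tables alone cannot.
    """

    weights: np.ndarray  # (H, W, 3)
    mu_ref_image: np.ndarray  # (H, W), 1/cm at E_REF_KEV
    spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.mu_ref_image = np.asarray(self.mu_ref_image, dtype=np.float64)
        if self.weights.ndim != 3 or self.weights.shape[2] != 3:
            raise ValueError("weights must be (H, W, 3)")
        if self.mu_ref_image.shape != self.weights.shape[:2]:
            raise ValueError("mu_ref_image shape mismatch")
        s = self.weights.sum(axis=2)
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("material weights must sum to 1 at every pixel")

    def equivalent_thickness_maps(self) -> np.ndarray:
        """(3, H, W) material-equivalent thickness per pixel (dimensionless;
        multiply by the pixel size along a ray to get cm of material)."""
        t = np.empty((3,) + self.mu_ref_image.shape)
        for i, m in enumerate(MATERIALS):
            t[i] = self.weights[..., i] * self.mu_ref_image / MU_REF[m]
        return t


@dataclass
class TripletSample:
    """(artifact-free, artifact-insert, artifact-residual) image triple.

    Invariant: ``residual = insert - free`` elementwise; the trained network
    predicts the residual and the clean image is recovered by subtraction.
    """

    artifact_free: ImageGrid
    artifact_insert: ImageGrid
    artifact_residual: ImageGrid
    metal_mask: MetalMask

    def __post_init__(self) -> None:
        shapes = {
            self.artifact_free.shape,
            self.artifact_insert.shape,
            self.artifact_residual.shape,
            self.metal_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError("triplet grids and mask must share one shape")
        window = self.artifact_free.hu_window[1] - self.artifact_free.hu_window[0]
        err = np.abs(
            self.artifact_residual.values
            - (self.artifact_insert.values - self.artifact_free.values)
        ).max()
        if err > 1e-6 * window:
            raise ValueError(f"residual != insert - free (max error {err:.3g} HU)")


# ---------------------------------------------------------------------------
# Projection geometry
# ---------------------------------------------------------------------------


def default_angles(n_angles: int = 180) -> np.ndarray:
    """Evenly spaced view angles over [0, 180)."""
    if n_angles < 1:
        raise ValueError("need at least one angle")
    return np.linspace(0.0, 180.0, n_angles, endpoint=False)


def default_n_detectors(size: tuple[int, int]) -> int:
    """Detector count covering the image diagonal, ceil(sqrt(2) * max(H, W)),
    rounded up to odd so the rotation center falls on a pixel center for
    both projection and back projection."""
    n = int(np.ceil(np.sqrt(2.0) * max(size)))
    return n if n % 2 == 1 else n + 1


def _embed(values: np.ndarray, n_det: int) -> np.ndarray:
    h, w = values.shape
    if n_det < int(np.ceil(np.hypot(h, w))):
        raise ValueError(
            f"n_detectors={n_det} smaller than image diagonal {np.hypot(h, w):.1f}"
        )
    canvas = np.zeros((n_det, n_det), dtype=np.float64)
    r0 = (n_det - h) // 2
    c0 = (n_det - w) // 2
    canvas[r0 : r0 + h, c0 : c0 + w] = values
    return canvas


def forward_project(
    image: ImageGrid | np.ndarray,
    angles_deg: np.ndarray | None = None,
    n_detectors: int | None = None,
    order: int = 3,
) -> Sinogram:
    """Parallel-beam Radon transform (length-weighted line integrals).

    The image is embedded centered on an odd square canvas, rotated by
    ``-angle`` with spline interpolation of the given ``order`` and summed
    along columns; detector coordinate ``s = x cos(a) + y sin(a)`` (y up)
    relative to the canvas center.  Integrals are in pixel-length units;
    callers carrying physical attenuation fold in the pixel spacing
    themselves.  Linear in the image; order 3 (default) keeps projections
    of smooth radially symmetric images angle-invariant to ~1e-6, order 1
    is faster for bulk simulation.
    """
    values = image.values if isinstance(image, ImageGrid) else np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("image must be finite")
    if angles_deg is None:
        angles_deg = default_angles()
    angles_deg = np.asarray(angles_deg, dtype=np.float64)
    if angles_deg.size == 0:
        raise ValueError("empty angle list")
    if n_detectors is None:
        n_detectors = default_n_detectors(values.shape)
    canvas = _embed(values, n_detectors)
    filtered = ndimage.spline_filter(canvas, order=order) if order > 1 else canvas
    out = np.empty((len(angles_deg), n_detectors))
    for i, a in enumerate(angles_deg):
        rot = ndimage.rotate(
            filtered, -a, reshape=False, order=order, prefilter=False, mode="constant"
        )
        out[i] = rot.sum(axis=0)
    return Sinogram(out, angles_deg)


def reconstruct_fbp(
    sinogram: Sinogram,
    size: tuple[int, int],
    filter_name: str = "ramp",
    interpolation: str = "linear",
) -> np.ndarray:
    """Filtered back projection onto an ``(H, W)`` grid (inverse of
    :func:`forward_project` up to discretization)."""
    if filter_name not in ("ramp", "hann"):
        raise ValueError("filter must be 'ramp' or 'hann'")
    n_det = sinogram.n_detectors
    if n_det < int(np.ceil(np.hypot(*size))):
        raise ValueError(f"n_detectors={n_det} inconsistent with size diagonal {np.hypot(*size):.1f}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        recon = _sk_iradon(
            sinogram.values.T,
            theta=sinogram.angles_deg,
            filter_name=filter_name,
            circle=True,
            output_size=n_det,
            interpolation=interpolation,
        )
    h, w = size
    r0 = (n_det - h) // 2
    c0 = (n_det - w) // 2
    return recon[r0 : r0 + h, c0 : c0 + w].copy()


# ---------------------------------------------------------------------------
# Material segmentation and polychromatic projection
# ---------------------------------------------------------------------------


def segment_materials(
    image: ImageGrid,
    mask: MetalMask | None = None,
    t_water: float = 300.0,
    t_bone: float = 700.0,
    metal_hu: float = 10000.0,
) -> MaterialMap:
    """Soft-threshold water/bone/metal weighting of an HU slice.

    The bone weight ramps linearly from 0 at ``t_water`` to 1 at ``t_bone``
    (water weight is the complement); pixels inside the metal mask are pure
    metal and their reference attenuation is set from ``metal_hu``.
    """
    if t_water >= t_bone:
        raise ValueError("t_water must be below t_bone")
    hu = image.values
    if not np.all(np.isfinite(hu)):
        raise ValueError("non-finite pixels in input image")
    w_bone = np.clip((hu - t_water) / (t_bone - t_water), 0.0, 1.0)
    w_water = 1.0 - w_bone
    w_metal = np.zeros_like(hu)
    mu_ref = hu_to_mu(hu)
    if mask is not None and not mask.is_empty:
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image")
        m = mask.mask
        w_water[m] = 0.0
        w_bone[m] = 0.0
        w_metal[m] = 1.0
        mu_ref[m] = hu_to_mu(metal_hu)
    weights = np.stack([w_water, w_bone, w_metal], axis=2)
    return MaterialMap(weights, mu_ref, spacing_mm=image.spacing_mm)


def polychromatic_project(
    materials: MaterialMap,
    spectrum: Spectrum,
    angles_deg: np.ndarray | None = None,
    n_detectors: int | None = None,
    photons: float | None = None,
    rng: np.random.Generator | None = None,
    order: int = 3,
) -> Sinogram:
    """Beam-hardening forward projection.

    Per detector element ``p = -ln( sum_e S(e) exp(-sum_m mu_m(e) L_m) )``
    with ``L_m`` the material-m equivalent path length (cm), obtained by
    forward-projecting each material's equivalent-thickness map.  A single
    energy bin at the reference energy reduces exactly to the monoenergetic
    projection of the per-pixel attenuation map.

    ``photons`` switches on Poisson noise at that incident photon count.
    """
    t_maps = materials.equivalent_thickness_maps()
    px_cm = float(materials.spacing_mm[0]) / 10.0
    if abs(materials.spacing_mm[0] - materials.spacing_mm[1]) > 1e-12:
        raise ValueError("anisotropic pixels are not supported by the projector")
    if angles_deg is None:
        angles_deg = default_angles()
    if n_detectors is None:
        n_detectors = default_n_detectors(t_maps[0].shape)
    mu = mu_table_at(spectrum.energies_kev)  # (3, n_bins)
    paths = np.stack(
        [
            forward_project(t_maps[i] * px_cm, angles_deg, n_detectors, order=order).values
            for i in range(3)
        ]
    )  # (3, A, D) in cm of material
    # Transmission summed over the spectrum, log'd back to a line integral.
    trans = np.zeros_like(paths[0])
    for e in range(spectrum.n_bins):
        trans += spectrum.weights[e] * np.exp(-np.einsum("m,mad->ad", mu[:, e], paths))
    if photons is not None:
        if rng is None:
            rng = np.random.default_rng()
        counts = rng.poisson(photons * trans).astype(np.float64)
        trans = np.maximum(counts, 1.0) / photons
    n_clamped = int(np.count_nonzero(trans < TRANSMISSION_FLOOR))
    if n_clamped:
        logger.warning("clamped %d detector bins at the transmission floor", n_clamped)
        trans = np.maximum(trans, TRANSMISSION_FLOOR)
    return Sinogram(-np.log(trans), np.asarray(angles_deg, dtype=np.float64))


# ---------------------------------------------------------------------------
# Triplet simulation
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Configuration of one artifact-insert simulation."""

    t_water: float = 300.0
    t_bone: float = 700.0
    metal_hu: float = 10000.0
    n_angles: int = 180
    filter_name: str = "ramp"
    hardness: float = 0.5
    n_bins: int = 5
    photons: float | None = None  # Poisson noise off by default
    projector_order: int = 1  # spline order for bulk simulation; oracles use 3

    def spectrum(self) -> Spectrum:
        if self.n_bins == 1:
            return monoenergetic_spectrum(E_REF_KEV)
        return default_spectrum(self.hardness)


def simulate_artifact_insert(
    free: ImageGrid,
    mask: MetalMask,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TripletSample:
    """Run the full simulation pipeline on one artifact-free slice.

    segmentation -> polychromatic projection (optional Poisson noise) ->
    FBP -> HU rescale -> metal reinsertion; the residual is the elementwise
    difference insert - free.  Reconstructed values are clamped to
    ``[-1000, metal_hu]``, emulating the scanner's finite HU range.
    """
    config = config or SimConfig()
    if mask.shape != free.shape:
        raise ValueError("mask and image shapes differ")
    materials = segment_materials(free, mask, config.t_water, config.t_bone, config.metal_hu)
    angles = default_angles(config.n_angles)
    sino = polychromatic_project(
        materials,
        config.spectrum(),
        angles,
        photons=config.photons,
        rng=rng,
        order=config.projector_order,
    )
    px_cm = float(free.spacing_mm[0]) / 10.0
    mu_eff = reconstruct_fbp(sino, free.shape, config.filter_name) / px_cm
    insert = mu_to_hu(mu_eff)
    insert[mask.mask] = config.metal_hu
    insert = np.clip(insert, -1000.0, max(config.metal_hu, free.hu_window[1]))
    window = (-1000.0, max(config.metal_hu, free.hu_window[1]))
    insert_grid = ImageGrid(insert, free.spacing_mm, window)
    residual = insert - free.values
    res_lo = min(float(residual.min()), -1.0)
    res_hi = max(float(residual.max()), 1.0)
    residual_grid = ImageGrid(residual, free.spacing_mm, (res_lo, res_hi))
    return TripletSample(free, insert_grid, residual_grid, mask)


# ---------------------------------------------------------------------------
# Dataset building
# ---------------------------------------------------------------------------


@dataclass
class DatasetConfig:
    """Study conditions of the synthetic triplet dataset.

    Subjects emulate patients: each contributes several slices sharing one
    acquisition condition (spectrum hardness, metal value), drawn per
    subject when ``randomize_subjects`` is on — echoing diversified
    reconstruction parameters across the training corpus.
    """

    size: tuple[int, int] = (128, 128)
    complexity: int = 3
    sim: SimConfig = field(default_factory=SimConfig)
    randomize_subjects: bool = True
    hardness_range: tuple[float, float] = (0.25, 0.75)
    metal_hu_range: tuple[float, float] = (6000.0, 12000.0)
    split_fractions: tuple[float, float, float] = (0.75, 0.17, 0.08)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class Dataset:
    """In-memory triplet dataset with subject-disjoint splits."""

    triplets: list[TripletSample]
    subject_of: list[int]
    splits: dict[str, list[int]]  # split name -> triplet indices
    manifest: dict

    def split(self, name: str) -> list[TripletSample]:
        return [self.triplets[i] for i in self.splits[name]]

    def save(self, out_dir: str | Path) -> None:
        from . import io as mio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, t in enumerate(self.triplets):
            mio.write_raw(t.artifact_free, out / f"slice{i:04d}_free.raw")
            mio.write_raw(t.artifact_insert, out / f"slice{i:04d}_insert.raw")
            mio.write_raw(t.artifact_residual, out / f"slice{i:04d}_residual.raw")
            np.save(out / f"slice{i:04d}_mask.npy", t.metal_mask.mask)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _split_subjects(n_subjects: int, fractions: tuple[float, float, float]) -> dict[str, list[int]]:
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for subject-disjoint splits")
    n_test = max(1, round(fractions[2] * n_subjects))
    n_val = max(1, round(fractions[1] * n_subjects))
    n_train = n_subjects - n_val - n_test
    if n_train < 1:
        raise ValueError(f"split fractions {fractions} infeasible for {n_subjects} subjects")
    subs = list(range(n_subjects))
    return {
        "train": subs[:n_train],
        "val": subs[n_train : n_train + n_val],
        "test": subs[n_train + n_val :],
    }


def build_dataset(
    n_subjects: int,
    slices_per_subject: int,
    seed: int,
    config: DatasetConfig | None = None,
) -> Dataset:
    """Simulate a subject-grouped triplet dataset with 75/17/8 subject-
    disjoint train/val/test splits.  Fully reproducible from (seed, config)."""
    config = config or DatasetConfig()
    sub_split = _split_subjects(n_subjects, config.split_fractions)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)

    triplets: list[TripletSample] = []
    subject_of: list[int] = []
    records = []
    for subj, child in enumerate(children):
        srng = np.random.default_rng(child)
        sim = SimConfig(**asdict(config.sim))
        if config.randomize_subjects:
            sim.hardness = float(srng.uniform(*config.hardness_range))
            sim.metal_hu = float(srng.uniform(*config.metal_hu_range))
        for s in range(slices_per_subject):
            phantom_seed = int(srng.integers(0, 2**31 - 1))
            mask_seed = int(srng.integers(0, 2**31 - 1))
            applicator = APPLICATORS[int(srng.integers(0, len(APPLICATORS)))]
            free = generate_phantom(phantom_seed, config.size, config.complexity)
            mask = generate_metal_mask(mask_seed, config.size, applicator)
            noise_rng = np.random.default_rng(int(srng.integers(0, 2**31 - 1)))
            triplets.append(simulate_artifact_insert(free, mask, sim, rng=noise_rng))
            subject_of.append(subj)
            records.append(
                {
                    "subject": subj,
                    "slice": s,
                    "phantom_seed": phantom_seed,
                    "mask_seed": mask_seed,
                    "applicator": applicator,
                    "hardness": sim.hardness,
                    "metal_hu": sim.metal_hu,
                }
            )

    splits = {
        name: [i for i, subj in enumerate(subject_of) if subj in subs]
        for name, subs in sub_split.items()
    }
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "seed": seed,
        "n_subjects": n_subjects,
        "slices_per_subject": slices_per_subject,
        "config": json.loads(cfg_json),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "subject_splits": sub_split,
        "slice_splits": splits,
        "slices": records,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    return Dataset(triplets, subject_of, splits, manifest)
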