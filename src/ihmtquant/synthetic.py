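"""Synthetic MR phantoms and histology images with known ground truth.

No image data from the motivating ex vivo study is public, so every pipeline
stage is exercised against generated inputs whose truth is prescribed:

* an MR *phantom* — a 2D slice with three tissue compartments (a myocardium
  disc, a free-running fiber modelled as a thin tube arcing through the
  signal-free Fluorinert bath, and a junction zone where the tube meets the
  disc), each with a prescribed unsaturated amplitude ``m0``, single-sided
  residual fraction ``s_single = MT+/M0 = MT-/M0`` and ihMTR.  Repeated
  magnitude acquisitions carry independent Rician noise per repetition,
  applied *before* averaging, as in magnitude MRI;

* *polarized-light histology* — collagen pixels bright and saturated on a
  near-black background, with hues drawn strictly inside the Type I
  (red/orange/yellow) or Type III (green) bands;

* *brightfield histology* — collagen (saturated red), myocytes (yellow) and
  adipocytes (near-white) in configurable HSL boxes.

The ihMTR construction inverts the ratio definition: noiseless intensities
are ``MT+ = MT- = m0*s_single`` and ``MT± = MT∓ = m0*(s_single -
ihmtr_true/200)``, so the pipeline must return ``ihmtr_true`` exactly in the
noiseless case.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from PIL import Image

from .core import IMAGE_ROLES, MTWeightedSet, ProtocolParams, save_volume
from .errors import InvalidSpecError
from .histology import BAND_CLASSES, HueBandConfig, PixelClass, hls_to_rgb
from .roi import FREE_RUNNING, MYOCARDIUM, PMJ, RegionMask
from .studydata import DEFAULT_REGION_IHMTR, HISTOLOGY_PER_SAMPLE, SELECTED_PROTOCOLS

__all__ = [
    "CompartmentSpec", "PhantomSpec", "HistologyTruth",
    "three_compartment_masks", "default_phantom_spec", "generate_phantom",
    "SyntheticPolarizedImage", "generate_polarized_histology",
    "SyntheticBrightfieldImage", "generate_brightfield_histology",
    "write_phantom", "simulate_mri_study", "simulate_histology_study",
]


# ---------------------------------------------------------------------------
# MR phantom


@dataclass(frozen=True)
class CompartmentSpec:
    """One phantom compartment.

    ``s_single`` is the single-sided residual fraction MT+/M0 in (0, 1];
    ``ihmtr_true`` the prescribed ihMTR in %.  The implied dual-sided
    residual ``s_single - ihmtr_true/200`` must be non-negative, otherwise
    the compartment is physically impossible.  Background (label 0, the Fluorinert
    bath) must have ``m0 = 0``.
    """

    label: int
    geometry: object        # boolean mask array, or object with .mask(shape, voxel)
    m0: float
    s_single: float = 0.5
    ihmtr_true: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in (0, 1, 2, 3):
            raise InvalidSpecError(f"unknown compartment label {self.label}")
        if self.label == 0 and self.m0 != 0:
            raise InvalidSpecError("background (label 0) must have m0 = 0")
        if self.m0 < 0:
            raise InvalidSpecError("m0 must be non-negative")
        if not 0 < self.s_single <= 1:
            raise InvalidSpecError("s_single must be in (0, 1]")
        if self.ihmtr_true < 0 or self.s_single - self.ihmtr_true / 200.0 < 0:
            raise InvalidSpecError(
                f"ihmtr_true={self.ihmtr_true} implies a negative dual-sided "
                f"residual for s_single={self.s_single}")

    @property
    def dual_residual(self) -> float:
        return self.s_single - self.ihmtr_true / 200.0


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic acquisition.

    Defaults reproduce the study conditions of the protocol-application
    phase: 50 repetitions per MT-weighted image, 10 reference averages,
    0.25 x 0.25 mm in-plane voxels.  ``noise_sigma`` is the Rician scale in
    signal units (0 disables noise).
    """

    matrix_size: tuple[int, int]
    compartments: tuple[CompartmentSpec, ...]
    voxel_size_mm: tuple[float, float] = (0.25, 0.25)
    noise_sigma: float = 0.0
    n_mt_reps: int = 50
    n_m0_reps: int = 10
    seed: int = 0
    protocol: ProtocolParams | None = None
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        if self.n_mt_reps < 1 or self.n_m0_reps < 1:
            raise InvalidSpecError("repetition counts must be >= 1")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        if not self.compartments:
            raise InvalidSpecError("at least one compartment is required")


def _pixel_centers_mm(shape: tuple[int, int],
                      voxel_size_mm: tuple[float, float]):
    yy = (np.arange(shape[0]) + 0.5) * voxel_size_mm[0]
    xx = (np.arange(shape[1]) + 0.5) * voxel_size_mm[1]
    return np.meshgrid(yy, xx, indexing="ij")


def three_compartment_masks(matrix_size: int | tuple[int, int] = 96,
                            voxel_size_mm: tuple[float, float] = (0.25, 0.25),
                            disc_center_mm: tuple[float, float] | None = None,
                            disc_radius_mm: float = 6.0,
                            tube_center_mm: tuple[float, float] | None = None,
                            tube_radius_mm: float = 9.0,
                            fiber_diameter_mm: float = 1.0,
                            junction_halfwidth_mm: float = 1.5
                            ) -> dict[int, np.ndarray]:
    """Disjoint masks of the default phantom topology.

    Myocardium is a filled disc; the free-running fiber is a tube of the
    given diameter (default 1 mm, about 4 voxels at 0.25 mm) following a
    circular arc outside the disc; the PMJ is the zone, of half-width
    ``junction_halfwidth_mm`` around the disc boundary, where the tube meets
    the disc.  Tube pixels deeper inside the disc belong to the myocardium
    (the fiber terminates at the junction).
    """
    if isinstance(matrix_size, int):
        matrix_size = (matrix_size, matrix_size)
    fov = (matrix_size[0] * voxel_size_mm[0], matrix_size[1] * voxel_size_mm[1])
    if disc_center_mm is None:
        disc_center_mm = (fov[0] / 2.0, fov[1] / 3.0)
    if tube_center_mm is None:
        tube_center_mm = (fov[0] / 2.0, fov[1] / 3.0 + 2.0 * disc_radius_mm)
    yy, xx = _pixel_centers_mm(matrix_size, voxel_size_mm)
    d_disc = np.hypot(yy - disc_center_mm[0], xx - disc_center_mm[1])
    d_tube = np.hypot(yy - tube_center_mm[0], xx - tube_center_mm[1])

    tube = np.abs(d_tube - tube_radius_mm) <= fiber_diameter_mm / 2.0
    pmj = tube & (d_disc >= disc_radius_mm - junction_halfwidth_mm) \
               & (d_disc <= disc_radius_mm + junction_halfwidth_mm)
    fiber = tube & (d_disc > disc_radius_mm + junction_halfwidth_mm)
    myo = (d_disc <= disc_radius_mm) & ~pmj
    return {FREE_RUNNING: fiber, PMJ: pmj, MYOCARDIUM: myo}


def default_phantom_spec(region_ihmtr: Sequence[float] = DEFAULT_REGION_IHMTR,
                         s_single: float = 0.5,
                         m0: float = 1.0,
                         noise_sigma: float = 0.0,
                         n_mt_reps: int = 50,
                         n_m0_reps: int = 10,
                         matrix_size: int | tuple[int, int] = 96,
                         voxel_size_mm: tuple[float, float] = (0.25, 0.25),
                         seed: int = 0,
                         protocol: ProtocolParams | None = None,
                         temperature_c: float | None = None,
                         **geometry_kwargs) -> PhantomSpec:
    """Three-compartment phantom prescribing ihMTR for
    (free-running fiber, PMJ, myocardium)."""
    if isinstance(matrix_size, int):
        matrix_size = (matrix_size, matrix_size)
    masks = three_compartment_masks(matrix_size, voxel_size_mm, **geometry_kwargs)
    i_fr, i_pmj, i_myo = region_ihmtr
    comps = (
        CompartmentSpec(FREE_RUNNING, masks[FREE_RUNNING], m0, s_single, i_fr),
        CompartmentSpec(PMJ, masks[PMJ], m0, s_single, i_pmj),
        CompartmentSpec(MYOCARDIUM, masks[MYOCARDIUM], m0, s_single, i_myo),
    )
    return PhantomSpec(matrix_size=matrix_size, compartments=comps,
                       voxel_size_mm=voxel_size_mm, noise_sigma=noise_sigma,
                       n_mt_reps=n_mt_reps, n_m0_reps=n_m0_reps, seed=seed,
                       protocol=protocol, temperature_c=temperature_c)


def _resolve_mask(geometry, shape, voxel_size_mm) -> np.ndarray:
    if hasattr(geometry, "mask"):
        geometry = geometry.mask(shape, voxel_size_mm)
    mask = np.asarray(geometry, dtype=bool)
    if mask.shape != tuple(shape):
        raise InvalidSpecError(
            f"compartment mask shape {mask.shape} does not match grid {shape}")
    return mask


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float,
            n_reps: int) -> np.ndarray:
    """Independent Rician draws per repetition: magnitude of the noiseless
    signal plus complex Gaussian noise of scale ``sigma`` per channel."""
    if sigma == 0:
        return np.repeat(signal[..., None], n_reps, axis=-1)
    shape = signal.shape + (n_reps,)
    re = signal[..., None] + rng.normal(0.0, sigma, shape)
    im = rng.normal(0.0, sigma, shape)
    return np.hypot(re, im)


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[MTWeightedSet, RegionMask, np.ndarray]:
    """Generate one synthetic acquisition.

    Returns the repeated MT-weighted/reference volumes, the region label
    mask matching the compartment geometry exactly, and the per-voxel
    prescribed-ihMTR map (NaN in the signal-free background).
    """
    shape = tuple(spec.matrix_size)
    masks = [_resolve_mask(c.geometry, shape, spec.voxel_size_mm)
             for c in spec.compartments]
    cover = np.zeros(shape, dtype=int)
    for m in masks:
        cover += m
    if (cover > 1).any():
        raise InvalidSpecError("compartment geometries overlap")

    m0_img = np.zeros(shape)
    single = np.zeros(shape)
    dual = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.uint8)
    truth = np.full(shape, np.nan)
    for comp, mask in zip(spec.compartments, masks):
        m0_img[mask] = comp.m0
        single[mask] = comp.m0 * comp.s_single
        dual[mask] = comp.m0 * comp.dual_residual
        labels[mask] = comp.label
        if comp.label != 0:
            truth[mask] = comp.ihmtr_true

    rng = np.random.default_rng(spec.seed)
    groups = {
        "mt_plus": _rician(rng, single, spec.noise_sigma, spec.n_mt_reps),
        "mt_minus": _rician(rng, single, spec.noise_sigma, spec.n_mt_reps),
        "mt_pm": _rician(rng, dual, spec.noise_sigma, spec.n_mt_reps),
        "mt_mp": _rician(rng, dual, spec.noise_sigma, spec.n_mt_reps),
        "m0": _rician(rng, m0_img, spec.noise_sigma, spec.n_m0_reps),
    }
    mtset = MTWeightedSet(**groups, protocol=spec.protocol,
                          temperature_c=spec.temperature_c,
                          voxel_size_mm=spec.voxel_size_mm)
    return mtset, RegionMask(labels), truth


# ---------------------------------------------------------------------------
# Synthetic histology


@dataclass(frozen=True)
class HistologyTruth:
    """Prescribed composition of one synthetic histology field of view.

    ``frac_collagen``/``frac_adipocyte`` are percentages of tissue pixels;
    ``type1_frac``/``type3_frac`` are percentages *of collagen pixels* with
    Type I (red/orange/yellow) and Type III (green) hues; any remainder is
    drawn outside every band (classified "other").
    """

    region: str = "free_running"
    frac_collagen: float = 50.0
    frac_adipocyte: float = 0.0
    type1_frac: float = 70.0
    type3_frac: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("frac_collagen", "frac_adipocyte", "type1_frac", "type3_frac"):
            v = getattr(self, attr)
            if not 0 <= v <= 100:
                raise InvalidSpecError(f"{attr}={v} outside [0, 100]")
        if self.type1_frac + self.type3_frac > 100 + 1e-9:
            raise InvalidSpecError("type1_frac + type3_frac must be <= 100")
        if self.frac_collagen + self.frac_adipocyte > 100 + 1e-9:
            raise InvalidSpecError("frac_collagen + frac_adipocyte must be <= 100")


#: Hue margin (degrees) kept from band edges so that 8-bit quantisation of
#: the PNG cannot move a pixel across a band boundary.
HUE_MARGIN_DEG = 2.0

#: Hue interval used for collagen pixels belonging to no band ("other").
OTHER_HUE_INTERVAL = (160.0, 300.0)


def _sample_hues(rng: np.random.Generator, n: int,
                 intervals: Sequence[tuple[float, float]],
                 margin: float = HUE_MARGIN_DEG) -> np.ndarray:
    """Uniform hues over a union of intervals, shrunk by ``margin`` per side."""
    ivs = [(lo + margin, hi - margin) for lo, hi in intervals]
    lengths = np.array([hi - lo for lo, hi in ivs])
    if (lengths <= 0).any():
        raise ValueError("margin exceeds an interval width")
    which = rng.choice(len(ivs), size=n, p=lengths / lengths.sum())
    u = rng.random(n)
    los = np.array([iv[0] for iv in ivs])
    return los[which] + u * lengths[which]


def _rgb8(hue, lightness, saturation) -> np.ndarray:
    rgb = hls_to_rgb(hue, lightness, saturation)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


@dataclass
class SyntheticPolarizedImage:
    """A polarized-light field of view with per-pixel ground truth.

    ``labels`` uses the classifier's :class:`~ihmtquant.histology.PixelClass`
    codes; ``realized_counts`` records the exact number of pixels drawn in
    each class (the ground truth the classifier must recover).
    """

    image: np.ndarray
    labels: np.ndarray
    realized_counts: dict[str, int]
    truth: HistologyTruth

    @property
    def n_collagen_px(self) -> int:
        return int((self.labels != int(PixelClass.NON_COLLAGEN)).sum())


def generate_polarized_histology(truth: HistologyTruth,
                                 size: tuple[int, int] = (256, 256),
                                 config: HueBandConfig | None = None
                                 ) -> SyntheticPolarizedImage:
    """Generate a polarized-light Picrosirius-red appearance image.

    Collagen pixels are bright (lightness ~0.5) and saturated with hues drawn
    strictly inside the configured class bands; everything else is the
    near-black unsaturated background (lightness < 0.05), emulating the
    extinction of non-birefringent material between crossed polarizers.
    """
    if size[0] < 64 or size[1] < 64:
        raise InvalidSpecError("image size must be at least 64 x 64")
    config = config or HueBandConfig()
    rng = np.random.default_rng(truth.seed)
    n_px = size[0] * size[1]

    is_collagen = rng.random(n_px) < truth.frac_collagen / 100.0
    n_col = int(is_collagen.sum())
    labels = np.zeros(n_px, dtype=np.uint8)

    # class of each collagen pixel: Type I / Type III / out-of-band
    u = rng.random(n_col)
    p1 = truth.type1_frac / 100.0
    p3 = truth.type3_frac / 100.0
    is_t1 = u < p1
    is_t3 = (u >= p1) & (u < p1 + p3)
    is_other = ~is_t1 & ~is_t3

    hues = np.zeros(n_col)
    if is_t1.any():
        t1_bands = (*config.red, *config.orange, *config.yellow)
        hues[is_t1] = _sample_hues(rng, int(is_t1.sum()), t1_bands)
    if is_t3.any():
        hues[is_t3] = _sample_hues(rng, int(is_t3.sum()), config.green)
    if is_other.any():
        hues[is_other] = _sample_hues(rng, int(is_other.sum()),
                                      [OTHER_HUE_INTERVAL], margin=0.0)

    # ground-truth band label from the sampled hue
    col_labels = np.full(n_col, int(PixelClass.OTHER), dtype=np.uint8)
    for cls in BAND_CLASSES:
        in_band = np.zeros(n_col, dtype=bool)
        for lo, hi in config.bands[cls]:
            in_band |= (hues >= lo) & (hues < hi)
        col_labels[in_band] = int(cls)
    labels[is_collagen] = col_labels

    light = rng.uniform(0.45, 0.55, n_col)
    sat = rng.uniform(0.85, 1.0, n_col)

    image = np.zeros((n_px, 3), dtype=np.uint8)
    bg_gray = rng.integers(0, 9, size=n_px, dtype=np.uint8)  # lightness < 0.04
    image[:] = bg_gray[:, None]
    image[is_collagen] = _rgb8(hues, light, sat)

    counts = {"background": int(n_px - n_col)}
    for cls in (*BAND_CLASSES, PixelClass.OTHER):
        counts[cls.name.lower()] = int((col_labels == int(cls)).sum())
    counts["collagen"] = n_col
    return SyntheticPolarizedImage(image=image.reshape(*size, 3),
                                   labels=labels.reshape(size),
                                   realized_counts=counts, truth=truth)


@dataclass
class SyntheticBrightfieldImage:
    """A brightfield field of view with ground-truth class masks."""

    image: np.ndarray
    masks: dict[str, np.ndarray]
    truth: HistologyTruth

    def realized_fraction(self, name: str) -> float:
        mask = self.masks[name]
        return 100.0 * mask.sum() / mask.size


def generate_brightfield_histology(truth: HistologyTruth,
                                   size: tuple[int, int] = (256, 256)
                                   ) -> SyntheticBrightfieldImage:
    """Brightfield Picrosirius-red appearance: collagen saturated red,
    myocytes yellow, adipocytes near-white; the whole field is tissue."""
    if size[0] < 64 or size[1] < 64:
        raise InvalidSpecError("image size must be at least 64 x 64")
    rng = np.random.default_rng(truth.seed)
    n_px = size[0] * size[1]

    u = rng.random(n_px)
    p_col = truth.frac_collagen / 100.0
    p_adp = truth.frac_adipocyte / 100.0
    is_col = u < p_col
    is_adp = (u >= p_col) & (u < p_col + p_adp)
    is_myo = ~is_col & ~is_adp

    hue = np.zeros(n_px)
    light = np.zeros(n_px)
    sat = np.zeros(n_px)
    n_col, n_adp, n_myo = int(is_col.sum()), int(is_adp.sum()), int(is_myo.sum())
    if n_col:
        hue[is_col] = _sample_hues(rng, n_col, [(334.0, 360.0), (0.0, 16.0)],
                                   margin=0.0)
        sat[is_col] = rng.uniform(0.60, 0.95, n_col)
        light[is_col] = rng.uniform(0.35, 0.60, n_col)
    if n_adp:
        hue[is_adp] = rng.uniform(0.0, 360.0, n_adp)
        sat[is_adp] = rng.uniform(0.0, 0.05, n_adp)
        light[is_adp] = rng.uniform(0.90, 0.97, n_adp)
    if n_myo:
        hue[is_myo] = rng.uniform(45.0, 55.0, n_myo)
        sat[is_myo] = rng.uniform(0.60, 0.90, n_myo)
        light[is_myo] = rng.uniform(0.45, 0.60, n_myo)

    image = _rgb8(hue, light, sat).reshape(*size, 3)
    masks = {"collagen": is_col.reshape(size),
             "adipocyte": is_adp.reshape(size),
             "myocyte": is_myo.reshape(size)}
    return SyntheticBrightfieldImage(image=image, masks=masks, truth=truth)


# ---------------------------------------------------------------------------
# On-disk study simulation (NIfTI / PNG / YAML manifests)


def write_phantom(out_dir: str | Path, mtset: MTWeightedSet, mask: RegionMask,
                  truth_map: np.ndarray, as_4d: bool = True) -> Path:
    """Write one acquisition as NIfTI plus a YAML manifest and JSON truth.

    ``as_4d=False`` writes one file per repetition instead of a 4D stack;
    both layouts load back identically through the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vox = mtset.voxel_size_mm
    manifest: dict = {}
    for role in IMAGE_ROLES:
        stack = getattr(mtset, role)
        if as_4d:
            fname = f"{role}.nii.gz"
            save_volume(stack, out_dir / fname, vox)
            manifest[role] = fname
        else:
            names = []
            for r in range(stack.shape[-1]):
                fname = f"{role}_rep{r:03d}.nii.gz"
                save_volume(stack[..., r], out_dir / fname, vox)
                names.append(fname)
            manifest[role] = names
    save_volume(mask.labels, out_dir / "mask.nii.gz", vox, dtype=np.uint8)
    if mtset.protocol is not None:
        manifest["protocol"] = mtset.protocol.to_dict()
    if mtset.temperature_c is not None:
        manifest["temperature_c"] = mtset.temperature_c
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump({"region_ihmtr": {
            str(int(lab)): float(np.nanmean(np.where(mask.labels == lab,
                                                     truth_map, np.nan)))
            for lab in np.unique(mask.labels) if lab != 0}}, fh, indent=2)
    return out_dir / "manifest.yaml"


def simulate_mri_study(out_dir: str | Path,
                       n_samples: int = 5,
                       region_ihmtr: Sequence[float] = DEFAULT_REGION_IHMTR,
                       protocols: Sequence[ProtocolParams] = SELECTED_PROTOCOLS,
                       noise_sigma: float = 0.02,
                       n_mt_reps: int = 50,
                       n_m0_reps: int = 10,
                       matrix_size: int = 96,
                       seed: int = 0) -> Path:
    """Write a full samples x protocols phantom study and its manifest.

    Every sample/protocol acquisition gets an independent noise stream
    derived from ``seed``.  Returns the study manifest path, directly
    consumable by :func:`ihmtquant.reporting.run_mri_pipeline`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(seed).generate_state(n_samples * len(protocols))
    study: dict = {"samples": {}}
    truth: dict = {}
    i = 0
    for s in range(1, n_samples + 1):
        sample = f"S{s}"
        entry: dict = {"protocols": {}}
        for prot in protocols:
            spec = default_phantom_spec(region_ihmtr=region_ihmtr,
                                        noise_sigma=noise_sigma,
                                        n_mt_reps=n_mt_reps, n_m0_reps=n_m0_reps,
                                        matrix_size=matrix_size,
                                        seed=int(seeds[i] % 2**31), protocol=prot)
            i += 1
            mtset, mask, truth_map = generate_phantom(spec)
            acq_dir = out_dir / sample / (prot.name or f"protocol{i}")
            write_phantom(acq_dir, mtset, mask, truth_map)
            rel = acq_dir.relative_to(out_dir)
            entry["protocols"][prot.name] = str(rel / "manifest.yaml")
            entry["mask"] = str(rel / "mask.nii.gz")
        study["samples"][sample] = entry
        truth[sample] = {name: float(v) for name, v in
                         zip(("free_running", "pmj", "myocardium"), region_ihmtr)}
    manifest_path = out_dir / "study.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(study, fh)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return manifest_path


def default_histology_truths(seed: int = 0) -> list[dict[str, HistologyTruth]]:
    """Per-sample free-running/PMJ compositions emulating the study: the
    generator prescribes each sample's published composition values."""
    tbl = HISTOLOGY_PER_SAMPLE
    truths = []
    for s in range(5):
        truths.append({
            "free_running": HistologyTruth(
                region="free_running",
                frac_collagen=tbl["total_collagen"]["free_running"][s],
                frac_adipocyte=tbl["adipocyte"]["free_running"][s],
                type1_frac=tbl["type1"]["free_running"][s],
                type3_frac=tbl["type3"]["free_running"][s],
                seed=seed + 2 * s),
            "pmj": HistologyTruth(
                region="pmj",
                frac_collagen=tbl["total_collagen"]["pmj"][s],
                frac_adipocyte=tbl["adipocyte"]["pmj"][s],
                type1_frac=tbl["type1"]["pmj"][s],
                type3_frac=tbl["type3"]["pmj"][s],
                seed=seed + 2 * s + 1),
        })
    return truths


def simulate_histology_study(out_dir: str | Path,
                             truths: Sequence[dict[str, HistologyTruth]] | None = None,
                             images_per_region: int = 2,
                             size: tuple[int, int] = (192, 192),
                             seed: int = 0) -> Path:
    """Write a samples x regions histology study (polarized + brightfield
    PNGs) and its manifest for :func:`ihmtquant.reporting.run_histology_pipeline`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if truths is None:
        truths = default_histology_truths(seed)
    study: dict = {"samples": {}}
    for s, regions in enumerate(truths, start=1):
        sample = f"S{s}"
        entry: dict = {}
        for region, truth in regions.items():
            pol_paths, bf_paths = [], []
            for img_i in range(images_per_region):
                t = HistologyTruth(**{**truth.__dict__,
                                      "seed": truth.seed * 1000 + img_i})
                pol = generate_polarized_histology(t, size=size)
                bf = generate_brightfield_histology(t, size=size)
                base = out_dir / sample / region
                base.mkdir(parents=True, exist_ok=True)
                pol_name = base / f"polarized_{img_i}.png"
                bf_name = base / f"brightfield_{img_i}.png"
                Image.fromarray(pol.image, "RGB").save(pol_name)
                Image.fromarray(bf.image, "RGB").save(bf_name)
                with open(base / f"truth_{img_i}.json", "w") as fh:
                    json.dump({"prescribed": t.__dict__,
                               "realized_counts": pol.realized_counts}, fh, indent=2)
                pol_paths.append(str(pol_name.relative_to(out_dir)))
                bf_paths.append(str(bf_name.relative_to(out_dir)))
            entry[region] = {"polarized": pol_paths, "brightfield": bf_paths}
        study["samples"][sample] = entry
    manifest_path = out_dir / "study.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(study, fh)
    return manifest_path
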