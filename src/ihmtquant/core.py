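"""Computation of inhomogeneous magnetization transfer ratio (ihMTR) maps.

An ihMT experiment acquires four MT-weighted magnitude images under
positive/negative single-sided saturation (MT+, MT-) and the two
frequency-alternated dual-sided schemes (MT±, MT∓), plus an unsaturated
reference image (M0).  Each image is acquired repeatedly and the repetitions
are averaged.  The ihMT ratio, expressed in percent, is the voxel-wise

    ihMTR = 100 * ((<MT+> + <MT->) - (<MT±> + <MT∓>)) / <M0>

where ``< >`` denotes the repetition average.  Because dual-sided saturation
additionally saturates dipolar order, the single/dual difference isolates the
dipolar-order (inhomogeneous) contribution, which is strong in highly
organised macromolecular matrices such as the collagen sheath of free-running
cardiac Purkinje fibers.

Volumes are plain numpy arrays; repeated acquisitions are stacked along the
*last* axis.  NIfTI-1 input/output goes through :mod:`nibabel`, and a small
YAML manifest maps the five image roles to files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

from .errors import GridMismatchError, ManifestError

__all__ = [
    "ProtocolParams",
    "MTWeightedSet",
    "IhMTRMap",
    "as_repetition_stack",
    "average_repetitions",
    "compute_ihmtr",
    "load_volume",
    "save_volume",
    "load_mtset_manifest",
    "save_ihmtr_map",
]

#: Names of the five image roles of one ihMT acquisition.
IMAGE_ROLES = ("mt_plus", "mt_minus", "mt_pm", "mt_mp", "m0")


@dataclass(frozen=True)
class ProtocolParams:
    """One pulsed ihMT saturation configuration.

    Parameters mirror the fields of a saturation protocol table: Hann pulse
    width PW, pulse repetition delay Δt, burst structure, burst repetition
    time BTR, saturation offset ΔF and RMS saturation amplitude B1RMS.

    ``duty_cycle_pct`` and ``fa_deg`` are stored verbatim when tabulated and
    never derived from the timing fields (the tabulated duty-cycle convention
    is not re-derivable from PW, Δt and BTR alone).
    """

    pw_ms: float
    dt_ms: float
    pulses_per_burst: int
    n_bursts: int
    btr_ms: float
    df_khz: float
    b1rms_ut: float = 9.0
    duty_cycle_pct: float | None = None
    fa_deg: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        for attr in ("pw_ms", "dt_ms", "pulses_per_burst", "n_bursts",
                     "btr_ms", "df_khz", "b1rms_ut"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"ProtocolParams.{attr} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def as_repetition_stack(volumes: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Return repeated volumes as one array with the repetition axis last.

    Accepts either a sequence of equally-shaped volumes or an already-stacked
    array (repetition axis last, as in a 4D NIfTI of 2D/3D frames).
    """
    if isinstance(volumes, np.ndarray):
        stack = np.asarray(volumes, dtype=float)
        if stack.ndim < 2:
            raise GridMismatchError("a volume stack needs at least 2 dimensions")
        return stack
    vols = [np.asarray(v, dtype=float) for v in volumes]
    if not vols:
        raise GridMismatchError("empty repetition list")
    shape = vols[0].shape
    for i, v in enumerate(vols):
        if v.shape != shape:
            raise GridMismatchError(
                f"repetition {i} has shape {v.shape}, expected {shape}")
    return np.stack(vols, axis=-1)


def average_repetitions(volumes: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Voxel-wise arithmetic mean of repeated magnitude volumes."""
    return as_repetition_stack(volumes).mean(axis=-1)


@dataclass
class MTWeightedSet:
    """The five image groups of one ihMT acquisition.

    Each group holds the repeated magnitude volumes stacked along the last
    axis; all groups must share one spatial grid.
    """

    mt_plus: np.ndarray
    mt_minus: np.ndarray
    mt_pm: np.ndarray
    mt_mp: np.ndarray
    m0: np.ndarray
    protocol: ProtocolParams | None = None
    temperature_c: float | None = None
    voxel_size_mm: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for role in IMAGE_ROLES:
            setattr(self, role, as_repetition_stack(getattr(self, role)))
        grid = self.mt_plus.shape[:-1]
        for role in IMAGE_ROLES:
            arr = getattr(self, role)
            if arr.shape[-1] < 1:
                raise GridMismatchError(f"{role} has no repetitions")
            if arr.shape[:-1] != grid:
                raise GridMismatchError(
                    f"{role} grid {arr.shape[:-1]} differs from mt_plus grid {grid}")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.mt_plus.shape[:-1]

    def scaled(self, factor: float) -> "MTWeightedSet":
        """A copy with every image group multiplied by ``factor``."""
        return MTWeightedSet(
            *(getattr(self, role) * factor for role in IMAGE_ROLES),
            protocol=self.protocol, temperature_c=self.temperature_c,
            voxel_size_mm=self.voxel_size_mm)


@dataclass
class IhMTRMap:
    """Per-voxel ihMTR (%) with a validity mask.

    ``values`` is NaN outside ``valid``; ``valid`` excludes voxels whose
    averaged M0 falls at or below the background threshold.
    """

    values: np.ndarray
    valid: np.ndarray
    m0_mean: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def compute_ihmtr(mtset: MTWeightedSet,
                  m0_threshold_frac: float = 0.1,
                  per_repetition_ratio: bool = False) -> IhMTRMap:
    """Compute the ihMTR map (%) from one acquisition.

    Repetitions are averaged first and the ratio formed from the averaged
    images (default).  ``per_repetition_ratio=True`` instead forms one ratio
    per repetition index (against the averaged M0) and averages the ratios —
    exposed for sensitivity analyses of the averaging order.

    Voxels with ``<M0> <= m0_threshold_frac * max(<M0>)`` are flagged invalid
    (signal-free embedding medium produces only noise there) and set to NaN.
    """
    if not 0 <= m0_threshold_frac < 1:
        raise ValueError("m0_threshold_frac must be in [0, 1)")
    m0_mean = mtset.m0.mean(axis=-1)
    valid = m0_mean > m0_threshold_frac * m0_mean.max()
    if not valid.any():
        warnings.warn("ihMTR map has no valid voxels", stacklevel=2)

    if per_repetition_ratio:
        n_rep = min(getattr(mtset, r).shape[-1]
                    for r in ("mt_plus", "mt_minus", "mt_pm", "mt_mp"))
        num = (mtset.mt_plus[..., :n_rep] + mtset.mt_minus[..., :n_rep]
               - mtset.mt_pm[..., :n_rep] - mtset.mt_mp[..., :n_rep])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = 100.0 * num / m0_mean[..., None]
        values = ratios.mean(axis=-1)
    else:
        num = (mtset.mt_plus.mean(axis=-1) + mtset.mt_minus.mean(axis=-1)
               - mtset.mt_pm.mean(axis=-1) - mtset.mt_mp.mean(axis=-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            values = 100.0 * num / m0_mean

    values = np.where(valid, values, np.nan)
    meta = {"m0_threshold_frac": m0_threshold_frac,
            "per_repetition_ratio": per_repetition_ratio}
    if mtset.protocol is not None:
        meta["protocol"] = mtset.protocol.to_dict()
    if mtset.temperature_c is not None:
        meta["temperature_c"] = mtset.temperature_c
    return IhMTRMap(values=values, valid=valid, m0_mean=m0_mean, metadata=meta)


# ---------------------------------------------------------------------------
# NIfTI-1 and manifest I/O


def load_volume(path: str | Path) -> np.ndarray:
    """Load a NIfTI volume as a float array (any dimensionality)."""
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def save_volume(data: np.ndarray, path: str | Path,
                voxel_size_mm: Sequence[float] | None = None,
                dtype=np.float64) -> Path:
    """Save an array as NIfTI-1 with an optional voxel size in the affine."""
    path = Path(path)
    affine = np.eye(4)
    if voxel_size_mm is not None:
        for i, v in enumerate(voxel_size_mm[:3]):
            affine[i, i] = v
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    nib.save(img, str(path))
    return path


def _load_role(entry) -> np.ndarray:
    """One manifest role: a single path (4D stack or lone volume) or a list
    of per-repetition paths."""
    if isinstance(entry, (list, tuple)):
        return as_repetition_stack([load_volume(p) for p in entry])
    arr = load_volume(entry)
    if arr.ndim == 2:          # a single 2D repetition
        arr = arr[..., None]
    return arr


def load_mtset_manifest(path: str | Path) -> MTWeightedSet:
    """Build an :class:`MTWeightedSet` from a YAML manifest.

    The manifest maps each of the five roles (``mt_plus``, ``mt_minus``,
    ``mt_pm``, ``mt_mp``, ``m0``) to a NIfTI path (4D stack, repetition axis
    last) or to a list of per-repetition paths, and may carry a ``protocol``
    block (:class:`ProtocolParams` fields) and ``temperature_c``.
    """
    path = Path(path)
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict):
        raise ManifestError(f"manifest {path} is not a mapping")

    def resolve(p):
        q = Path(p)
        if not q.is_absolute():
            q = path.parent / q
        if not q.exists():
            raise ManifestError(f"manifest entry references missing file: {p}")
        return q

    groups = {}
    for role in IMAGE_ROLES:
        if role not in spec:
            raise ManifestError(f"manifest {path} lacks required role '{role}'")
        entry = spec[role]
        if isinstance(entry, (list, tuple)):
            entry = [resolve(p) for p in entry]
        else:
            entry = resolve(entry)
        groups[role] = _load_role(entry)

    protocol = None
    if "protocol" in spec and spec["protocol"] is not None:
        protocol = ProtocolParams(**spec["protocol"])
    return MTWeightedSet(**groups, protocol=protocol,
                         temperature_c=spec.get("temperature_c"))


def save_ihmtr_map(ihmtr: IhMTRMap, path: str | Path,
                   voxel_size_mm: Sequence[float] | None = None) -> Path:
    """Write the map (float NIfTI), validity mask (uint8 NIfTI) and a JSON
    sidecar echoing the acquisition metadata."""
    path = Path(path)
    save_volume(ihmtr.values, path, voxel_size_mm)
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[:-len(suf)]
            ext = suf
            break
    else:
        ext = ".nii.gz"
    save_volume(ihmtr.valid.astype(np.uint8), path.with_name(stem + "_valid" + ext),
                voxel_size_mm, dtype=np.uint8)
    with open(path.with_name(stem + ".json"), "w") as fh:
        json.dump(ihmtr.metadata, fh, indent=2, sort_keys=True)
    return path
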