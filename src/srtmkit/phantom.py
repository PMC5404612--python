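"""Digital striatum phantom: label volumes, dynamic-image rendering, ROI
extraction.

Stands in for the atlas-based ROI pipeline: bilateral ellipsoidal caudate,
putamen and ventral striatum plus a cerebellum reference region are placed
on a configurable grid, region TACs are painted into every member voxel
(plus independent per-voxel noise), and ROI TACs are recovered as unweighted
voxel means.  NIfTI I/O with a JSON sidecar carries the frame schedule,
which the NIfTI header cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .cohort import noise_sigma
from .kinetics import TimeActivityCurve
from .schedule import FrameSchedule

__all__ = [
    "LABELS",
    "LabelPhantom",
    "DynamicImage",
    "make_phantom",
    "render_dynamic_image",
    "extract_roi_tac",
    "save_nifti",
    "load_dynamic_image",
]

#: Canonical label map.
LABELS: dict[int, str] = {
    0: "background",
    1: "caudate_left",
    2: "caudate_right",
    3: "putamen_left",
    4: "putamen_right",
    5: "ventral_striatum_left",
    6: "ventral_striatum_right",
    7: "cerebellum",
}
NAME_TO_LABEL = {v: k for k, v in LABELS.items()}

#: Default per-region volume targets in ml (bilateral striatal sub-regions
#: split evenly from the reference ROI volumes; cerebellum generous).
DEFAULT_VOLUME_TARGETS_ML: dict[str, float] = {
    "caudate_left": 10.2,
    "caudate_right": 10.5,
    "putamen_left": 10.7,
    "putamen_right": 11.3,
    "ventral_striatum_left": 1.4,
    "ventral_striatum_right": 1.5,
    "cerebellum": 30.0,
}

STRIATUM_LABELS = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class LabelPhantom:
    labels: np.ndarray                    # 3-D int volume
    voxel_size_mm: tuple[float, float, float]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def region_mask(self, label: int | str | tuple) -> np.ndarray:
        """Boolean mask for a label, region name, or label-set (pooled)."""
        if isinstance(label, str):
            label = NAME_TO_LABEL[label]
        if isinstance(label, (tuple, list, set, frozenset, np.ndarray)):
            return np.isin(self.labels, list(label))
        return self.labels == int(label)

    def region_volume_ml(self, label: int | str | tuple) -> float:
        return float(self.region_mask(label).sum()) * self.voxel_volume_ml


@dataclass(frozen=True)
class DynamicImage:
    data: np.ndarray                      # (x, y, z, frame) kBq/ml
    schedule: FrameSchedule
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("dynamic image must be 4-D")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError("frame axis must match the schedule")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("dynamic image must be finite")


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    semi_axes_vox: tuple[float, float, float],
) -> np.ndarray:
    ix, iy, iz = np.indices(shape)
    a, b, c = semi_axes_vox
    cx, cy, cz = center
    return ((ix - cx) / a) ** 2 + ((iy - cy) / b) ** 2 + ((iz - cz) / c) ** 2 <= 1.0


def _solve_scale(target_vox: float, ratios: tuple[float, float, float]) -> tuple[float, float, float]:
    """Semi-axes (in voxels) of an ellipsoid with given axis ratios whose
    continuous volume matches target_vox voxels."""
    prod = ratios[0] * ratios[1] * ratios[2]
    s = (target_vox / (4.0 / 3.0 * np.pi * prod)) ** (1.0 / 3.0)
    return tuple(r * s for r in ratios)


def make_phantom(
    dims: tuple[int, int, int] = (64, 64, 32),
    voxel_size_mm: tuple[float, float, float] = (2.1, 2.1, 2.4),
    region_volume_targets_ml: dict[str, float] | None = None,
    volume_tolerance: float = 0.10,
) -> LabelPhantom:
    """Build the bilateral ellipsoidal striatum phantom.

    Region volumes (voxel count x voxel volume) land within
    ``volume_tolerance`` (default 10%) of the requested targets; left/right
    pairs are mirror-symmetric.  Raises if a target cannot be achieved
    inside ``dims`` without overlap.
    """
    targets = dict(DEFAULT_VOLUME_TARGETS_ML)
    if region_volume_targets_ml:
        targets.update(region_volume_targets_ml)
    dims = tuple(int(d) for d in dims)
    if any(d <= 0 for d in dims):
        raise ValueError("dims must be positive")
    vox_ml = float(np.prod(voxel_size_mm)) / 1000.0
    nx, ny, nz = dims
    # anatomically-inspired relative placements (fractions of the grid):
    # (x, y) center fractions and ellipsoid axis ratios
    placement = {
        "caudate_left": ((0.33, 0.60), (1.0, 1.8, 1.3)),
        "caudate_right": ((0.67, 0.60), (1.0, 1.8, 1.3)),
        "putamen_left": ((0.18, 0.44), (1.0, 1.6, 1.5)),
        "putamen_right": ((0.82, 0.44), (1.0, 1.6, 1.5)),
        "ventral_striatum_left": ((0.42, 0.30), (1.0, 1.2, 1.0)),
        "ventral_striatum_right": ((0.58, 0.30), (1.0, 1.2, 1.0)),
        "cerebellum": ((0.50, 0.80), (1.8, 1.4, 1.0)),
    }
    z_frac = {
        "caudate_left": 0.62, "caudate_right": 0.62,
        "putamen_left": 0.50, "putamen_right": 0.50,
        "ventral_striatum_left": 0.38, "ventral_striatum_right": 0.38,
        "cerebellum": 0.25,
    }
    labels = np.zeros(dims, dtype=np.int16)
    for name, (frac_xy, ratios) in placement.items():
        target_vox = targets[name] / vox_ml
        axes = _solve_scale(target_vox, ratios)
        center = (frac_xy[0] * (nx - 1), frac_xy[1] * (ny - 1), z_frac[name] * (nz - 1))
        mask = _ellipsoid_mask(dims, center, axes)
        if np.any(labels[mask] != 0):
            raise ValueError(f"region {name} overlaps a previously placed region")
        labels[mask] = NAME_TO_LABEL[name]
        achieved = mask.sum() * vox_ml
        if abs(achieved - targets[name]) > volume_tolerance * targets[name]:
            raise ValueError(
                f"cannot achieve volume target for {name}: "
                f"requested {targets[name]:.2f} ml, achieved {achieved:.2f} ml"
            )
    return LabelPhantom(labels=labels, voxel_size_mm=tuple(float(v) for v in voxel_size_mm))


def render_dynamic_image(
    phantom: LabelPhantom,
    region_tacs: dict[str, TimeActivityCurve],
    voxel_noise_scale: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> DynamicImage:
    """Paint region TACs into a 4-D dynamic image.

    Every voxel of a region follows that region's TAC plus independent
    zero-mean Gaussian noise under the same count-statistics law as the
    cohort generator; background voxels are zero.
    """
    present = [int(l) for l in np.unique(phantom.labels) if l != 0]
    missing = [LABELS[l] for l in present if LABELS[l] not in region_tacs]
    if missing:
        raise ValueError(f"missing TACs for phantom regions: {missing}")
    sched = next(iter(region_tacs.values())).schedule
    for t in region_tacs.values():
        if t.schedule.n_frames != sched.n_frames or not np.array_equal(
            t.schedule.frame_end, sched.frame_end
        ):
            raise ValueError("all region TACs must share one schedule")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    shape = phantom.labels.shape + (sched.n_frames,)
    data = np.zeros(shape)
    for lab in present:
        name = LABELS[lab]
        mask = phantom.labels == lab
        clean = region_tacs[name].activity
        nvox = int(mask.sum())
        block = np.broadcast_to(clean, (nvox, clean.size)).copy()
        if voxel_noise_scale > 0:
            sig = noise_sigma(clean, sched, voxel_noise_scale)
            block += gen.normal(0.0, 1.0, block.shape) * sig
        data[mask] = block
    return DynamicImage(data=data, schedule=sched, voxel_size_mm=phantom.voxel_size_mm)


def extract_roi_tac(
    image: DynamicImage,
    phantom: LabelPhantom,
    label: int | str | tuple,
    name: str = "",
) -> TimeActivityCurve:
    """Unweighted voxel-mean TAC over a label or pooled label-set.

    Label-sets (e.g. whole striatum, labels 1..6) are pooled voxelwise —
    one mean over all member voxels — not averaged region-wise.
    """
    if image.data.shape[:3] != phantom.labels.shape:
        raise ValueError("image and phantom must share the 3-D grid")
    mask = phantom.region_mask(label)
    if not mask.any():
        raise ValueError(f"empty label {label!r}")
    mean = image.data[mask].mean(axis=0)
    return TimeActivityCurve(image.schedule, mean, name or str(label))


# ---------------------------------------------------------------------------
# NIfTI I/O (JSON sidecar carries frame timing)

def save_nifti(
    data: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    path: str | Path,
    schedule: FrameSchedule | None = None,
    sidecar: dict | None = None,
) -> None:
    """Write a 3-D/4-D volume as NIfTI (.nii) with an optional JSON sidecar."""
    path = Path(path)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    meta = dict(sidecar or {})
    if schedule is not None:
        meta["frame_start_min"] = schedule.frame_start.tolist()
        meta["frame_end_min"] = schedule.frame_end.tolist()
    if meta:
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)


def load_dynamic_image(path: str | Path) -> DynamicImage:
    """Read a 4-D NIfTI plus its frame-timing sidecar."""
    path = Path(path)
    img = nib.load(str(path))
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    sched = FrameSchedule(
        frame_start=np.array(meta["frame_start_min"]),
        frame_end=np.array(meta["frame_end_min"]),
    )
    vox = tuple(float(v) for v in img.header.get_zooms()[:3])
    return DynamicImage(data=np.asarray(img.dataobj, dtype=float), schedule=sched,
                        voxel_size_mm=vox)
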