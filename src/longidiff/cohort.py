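"""Synthetic longitudinal brain phantoms with known regional atrophy.

Each subject is an ellipsoidal "brain" containing a few ellipsoidal regions
whose semi-axes shrink (or expand) across visits at a known rate, plus a
subject-fixed smooth texture field and per-visit Gaussian noise.  Images are
min-max normalized over brain voxels with exactly-zero background, visits
are nominally 6 months apart, and the two missingness patterns used for
past-conditioned and past+following-conditioned imputation can be applied.
Ground truth (label maps, analytic and rasterized region volumes) is stored
alongside every record, so metrics can be validated without any real data.

Region boundaries are rasterized with a one-voxel soft edge (linear partial
volume ramp on the signed ellipsoid distance), so sub-voxel shrinkage between
visits is visible in the intensities, as it is in real interpolated MRI.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .metrics import RegionVolumes, region_volumes

__all__ = ["RegionSpec", "CohortSpec", "Visit", "LongitudinalRecord",
           "generate_cohort", "apply_missingness", "default_regions",
           "write_nifti", "read_nifti", "imputation_targets"]


@dataclass(frozen=True)
class RegionSpec:
    """One ellipsoidal region with a volume trajectory across visits."""

    label: int
    center: tuple[float, float, float]     # fractional coordinates in [0, 1]
    semi_axes: tuple[float, float, float]  # voxels, at visit 0
    intensity: float
    rho: float = 1.0          # per-visit axis scale (geometric mode)
    mode: str = "geometric"   # "geometric" (constant ratio) or "linear" volume
    vol_rate: float = 0.0     # per-visit fractional volume loss (linear mode)

    def axis_scale(self, visit: int) -> float:
        if self.mode == "geometric":
            return self.rho ** visit
        if self.mode == "linear":
            v = 1.0 - self.vol_rate * visit
            if v <= 0:
                raise ValueError(
                    f"linear trajectory of region {self.label} reaches "
                    f"non-positive volume at visit {visit}")
            return v ** (1.0 / 3.0)
        raise ValueError(f"unknown atrophy mode {self.mode!r}")

    def analytic_volume(self, visit: int, voxel_volume: float = 1.0) -> float:
        s = self.axis_scale(visit)
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c * s ** 3 * voxel_volume


def default_regions(rho: float = 0.95, mode: str = "geometric",
                    vol_rate: float = 0.04,
                    ventricle_expansion: bool = False) -> tuple[RegionSpec, ...]:
    """Three stand-in regions: two bright shrinking gray-matter-like bodies
    and one dark ventricle-like body (optionally expanding)."""
    common = dict(mode=mode, vol_rate=vol_rate)
    vent_rho = (1.0 / rho if ventricle_expansion else rho)
    vent = dict(mode=mode,
                vol_rate=(-vol_rate if ventricle_expansion else vol_rate))
    return (
        RegionSpec(1, (0.40, 0.38, 0.40), (5.5, 4.5, 4.5), 0.75, rho, **common),
        RegionSpec(2, (0.63, 0.63, 0.40), (4.5, 3.5, 3.5), 0.90, rho, **common),
        RegionSpec(3, (0.50, 0.50, 0.68), (4.0, 3.0, 3.0), 0.12, vent_rho,
                   **vent),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for phantom generation."""

    n_subjects: int = 24
    n_visits: int = 5
    shape: tuple[int, int, int] = (32, 32, 32)
    regions: tuple[RegionSpec, ...] = field(default_factory=default_regions)
    brain_axes: tuple[float, float, float] = (13.5, 12.5, 12.5)
    tissue_intensity: float = 0.35
    background_texture: float = 0.05
    noise_sd: float = 0.02
    skull_shell: bool = False
    center_jitter: float = 0.5    # sd of per-subject region-center jitter, voxels
    axes_jitter: float = 0.03     # sd of per-subject relative semi-axis jitter
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    visit_interval_months: float = 6.0  # metadata only; no computation uses it
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_subjects < 1 or self.n_visits < 1:
            raise ValueError("n_subjects and n_visits must be positive")


@dataclass
class Visit:
    image: np.ndarray
    exists: bool = True


@dataclass
class LongitudinalRecord:
    """One subject's ordered visit trajectory plus ground truth."""

    subject_id: str
    visits: list[Visit]
    brain_mask: np.ndarray
    labelmaps: list[np.ndarray]
    volumes: list[RegionVolumes]          # analytic ellipsoid volumes
    raster_volumes: list[RegionVolumes]   # voxel-count volumes
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    visit_interval_months: float = 6.0

    @property
    def n_visits(self) -> int:
        return len(self.visits)


def _ellipsoid_fields(shape, center_vox, axes):
    """Signed, voxel-scaled distance-to-surface field of an ellipsoid."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_vox, axes))
    rho = np.sqrt(rho2)
    mean_axis = float(np.mean(axes))
    return (1.0 - rho) * mean_axis  # ~ voxels inside (+) / outside (-)


def _coverage(dist):
    return np.clip(dist + 0.5, 0.0, 1.0)


def _render_subject(spec: CohortSpec, rng: np.random.Generator):
    shape = spec.shape
    center = tuple((s - 1) / 2.0 for s in shape)
    brain_dist = _ellipsoid_fields(shape, center, spec.brain_axes)
    brain_cov = _coverage(brain_dist)
    brain_mask = brain_dist > 0
    texture = gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    texture /= max(texture.std(), 1e-12)
    # per-subject anatomical jitter, fixed across visits
    jitters = []
    for region in spec.regions:
        dc = rng.normal(0.0, spec.center_jitter, size=3)
        da = 1.0 + rng.normal(0.0, spec.axes_jitter, size=3)
        jitters.append((dc, da))
    return brain_cov, brain_mask, texture, jitters


def _render_visit(spec: CohortSpec, visit: int, brain_cov, brain_mask, texture,
                  jitters, rng: np.random.Generator):
    shape = spec.shape
    img = spec.tissue_intensity * brain_cov
    labelmap = np.zeros(shape, dtype=np.int32)
    raster = {}
    analytic = {}
    voxvol = float(np.prod(spec.spacing))
    for region, (dc, da) in zip(spec.regions, jitters):
        c = tuple(f * (s - 1) + d
                  for f, s, d in zip(region.center, shape, dc))
        scale = region.axis_scale(visit)
        axes = tuple(a * j * scale for a, j in zip(region.semi_axes, da))
        if any(ci - ai < 0 or ci + ai > si - 1
               for ci, ai, si in zip(c, axes, shape)):
            raise ValueError(
                f"region {region.label} extends outside the volume")
        dist = _ellipsoid_fields(shape, c, axes)
        cov = _coverage(dist)
        img += (region.intensity - spec.tissue_intensity) * cov
        inside = dist > 0
        labelmap[inside] = region.label
        raster[region.label] = float(inside.sum()) * voxvol
        analytic[region.label] = (4.0 / 3.0 * math.pi
                                  * float(np.prod(axes)) * voxvol)
    if spec.skull_shell:
        outer = _coverage(_ellipsoid_fields(
            shape, tuple((s - 1) / 2.0 for s in shape),
            tuple(a + 2.0 for a in spec.brain_axes)))
        img += 0.85 * np.clip(outer - brain_cov, 0.0, 1.0)
    img += spec.background_texture * texture * brain_cov
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal(shape) * brain_mask
    nz = brain_mask if not spec.skull_shell else (img != 0)
    img = np.clip(img, 0.0, None)
    img[~nz] = 0.0
    lo = img[nz].min()
    hi = img[nz].max()
    img[nz] = (img[nz] - lo) / (hi - lo)
    return img.astype(np.float64), labelmap, analytic, raster


def generate_cohort(spec: CohortSpec,
                    seed: int | None = None) -> list[LongitudinalRecord]:
    """Generate the full cohort; a pure function of (spec, seed)."""
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    records = []
    for s, child in enumerate(root.spawn(spec.n_subjects)):
        rng = np.random.default_rng(child)
        brain_cov, brain_mask, texture, jitters = _render_subject(spec, rng)
        visits, labelmaps, vols, rvols = [], [], [], []
        for r in range(spec.n_visits):
            img, lm, analytic, raster = _render_visit(
                spec, r, brain_cov, brain_mask, texture, jitters, rng)
            visits.append(Visit(image=img, exists=True))
            labelmaps.append(lm)
            vols.append(analytic)
            rvols.append(raster)
        records.append(LongitudinalRecord(
            subject_id=f"sub-{s:03d}", visits=visits, brain_mask=brain_mask,
            labelmaps=labelmaps, volumes=vols, raster_volumes=rvols,
            spacing=spec.spacing,
            visit_interval_months=spec.visit_interval_months))
    return records


def apply_missingness(records: list[LongitudinalRecord],
                      pattern: str) -> list[LongitudinalRecord]:
    """Flag visits as missing following the two study patterns.

    "P": every second visit is missing (flags 1,0,1,0,...), so each missing
    visit has an observed past neighbour.  "PF": the middle visit of every
    consecutive complete triple is missing (1,0,1 | 1,0,1 | ...), so each
    missing visit has observed past and following neighbours.  The true
    images are retained (flag only) as evaluation targets.
    """
    if pattern not in ("P", "PF"):
        raise ValueError(f"pattern must be 'P' or 'PF', got {pattern!r}")
    min_r = 2 if pattern == "P" else 3
    out = []
    for rec in records:
        R = rec.n_visits
        if R < min_r:
            raise ValueError(
                f"pattern {pattern} needs at least {min_r} visits, "
                f"record {rec.subject_id} has {R}")
        if pattern == "P":
            missing = set(range(1, R, 2))
        else:
            missing = {i for i in range(1, R, 3) if i + 1 < R}
        visits = [Visit(image=v.image, exists=(i not in missing))
                  for i, v in enumerate(rec.visits)]
        out.append(replace_visits(rec, visits))
    return out


def replace_visits(rec: LongitudinalRecord,
                   visits: list[Visit]) -> LongitudinalRecord:
    return LongitudinalRecord(
        subject_id=rec.subject_id, visits=visits, brain_mask=rec.brain_mask,
        labelmaps=rec.labelmaps, volumes=rec.volumes,
        raster_volumes=rec.raster_volumes, spacing=rec.spacing,
        visit_interval_months=rec.visit_interval_months)


def imputation_targets(records: list[LongitudinalRecord],
                       kind: str) -> list[tuple[int, int]]:
    """(record index, visit index) pairs imputable under condition kind.

    "P" needs an observed previous visit; "PF" additionally an observed
    following visit.
    """
    targets = []
    for i, rec in enumerate(records):
        for r, v in enumerate(rec.visits):
            if v.exists:
                continue
            if r == 0 or not rec.visits[r - 1].exists:
                continue
            if kind == "PF" and (r + 1 >= rec.n_visits
                                 or not rec.visits[r + 1].exists):
                continue
            targets.append((i, r))
    return targets


# -- NIfTI I/O ----------------------------------------------------------------

def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_nifti(record: LongitudinalRecord, out_dir):
    """Write one record as NIfTI volumes plus JSON flags and TSV truth tables."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(record.spacing)
    for r, v in enumerate(record.visits):
        nib.save(nib.Nifti1Image(v.image.astype(np.float64), aff),
                 out / f"visit_{r:02d}.nii")
        nib.save(nib.Nifti1Image(record.labelmaps[r].astype(np.int16), aff),
                 out / f"labelmap_{r:02d}.nii")
    nib.save(nib.Nifti1Image(record.brain_mask.astype(np.uint8), aff),
             out / "brain_mask.nii")
    meta = {"subject_id": record.subject_id,
            "existence": [int(v.exists) for v in record.visits],
            "spacing": list(record.spacing),
            "visit_interval_months": record.visit_interval_months}
    (out / "record.json").write_text(json.dumps(meta, indent=2))
    with open(out / "volumes.tsv", "w") as fh:
        fh.write("subject\tvisit\tregion\tvolume_mm3\traster_volume_mm3\n")
        for r in range(record.n_visits):
            for lab in sorted(record.volumes[r]):
                fh.write(f"{record.subject_id}\t{r}\t{lab}\t"
                         f"{record.volumes[r][lab]:.6f}\t"
                         f"{record.raster_volumes[r][lab]:.6f}\n")


def read_nifti(in_dir) -> LongitudinalRecord:
    """Round-trip counterpart of :func:`write_nifti`."""
    from pathlib import Path
    src = Path(in_dir)
    meta_path = src / "record.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no record.json under {src}")
    meta = json.loads(meta_path.read_text())
    existence = meta["existence"]
    visits, labelmaps, vols, rvols = [], [], [], []
    for r, e in enumerate(existence):
        img = np.asarray(nib.load(src / f"visit_{r:02d}.nii").dataobj,
                         dtype=np.float64)
        visits.append(Visit(image=img, exists=bool(e)))
        labelmaps.append(np.asarray(
            nib.load(src / f"labelmap_{r:02d}.nii").dataobj, dtype=np.int32))
    mask = np.asarray(nib.load(src / "brain_mask.nii").dataobj) > 0
    import pandas as pd
    table = pd.read_csv(src / "volumes.tsv", sep="\t")
    for r in range(len(existence)):
        sub = table[table["visit"] == r]
        vols.append({int(row.region): float(row.volume_mm3)
                     for row in sub.itertuples()})
        rvols.append({int(row.region): float(row.raster_volume_mm3)
                      for row in sub.itertuples()})
    return LongitudinalRecord(
        subject_id=meta["subject_id"], visits=visits, brain_mask=mask,
        labelmaps=labelmaps, volumes=vols, raster_volumes=rvols,
        spacing=tuple(meta["spacing"]),
        visit_interval_months=meta["visit_interval_months"])
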