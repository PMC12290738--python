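"""Evaluation statistics for imputed volumes.

Image-level: structural similarity (SSIM) and peak signal-to-noise ratio
(PSNR), both restricted to a brain mask.  Volume-level: per-region error
rate |vhat - v| / v against the observed visit, progression rate
|v_i - v_{i-1}| / v_{i-1} against the previous visit, and the annualized
atrophy-rate comparison across complete-data, doubled-six-month and
imputed-visit scenarios.

Masked metrics zero all voxels outside the mask in both inputs before any
windowed filtering, so values are invariant to arbitrary changes outside
the mask.  SSIM uses a Gaussian window (sigma 1.5, size min(11, dims),
K1 = 0.01, K2 = 0.03) and averages the SSIM map over mask voxels only;
data_range defaults to 1.0 for min-max normalized images.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = ["RegionVolumes", "MetricReport", "ssim", "psnr", "masked_mse",
           "region_volumes", "error_rate", "progression_rate",
           "progression_gap", "annualized_atrophy_comparison",
           "aggregate_report", "segment_by_intensity", "class_means_from",
           "read_volume_table", "write_volume_table"]

RegionVolumes = dict[int, float]


def _check_pair(x: np.ndarray, y: np.ndarray, mask: np.ndarray):
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    if mask.shape != x.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {x.shape}")
    if not mask.any():
        raise ValueError("mask is empty")


def ssim(x: np.ndarray, y: np.ndarray, mask: np.ndarray,
         window: int = 11, data_range: float = 1.0,
         sigma: float = 1.5) -> float:
    """Masked structural similarity index in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask).astype(bool)
    _check_pair(x, y, mask)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    win = min(window, *x.shape)
    if win % 2 == 0:
        win -= 1
    _, smap = structural_similarity(
        x * mask, y * mask, win_size=win, data_range=data_range,
        gaussian_weights=True, sigma=sigma, use_sample_covariance=False,
        full=True)
    return float(smap[mask].mean())


def masked_mse(x: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over mask voxels."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask).astype(bool)
    _check_pair(x, y, mask)
    d = (x - y)[mask]
    return float(np.mean(d * d))


def psnr(x: np.ndarray, y: np.ndarray, mask: np.ndarray,
         data_range: float = 1.0) -> float:
    """Masked peak signal-to-noise ratio in dB; +inf for identical images."""
    mse = masked_mse(x, y, mask)
    if mse == 0.0:
        return math.inf
    return 20.0 * math.log10(data_range) - 10.0 * math.log10(mse)


def region_volumes(labelmap: np.ndarray, voxel_volume: float = 1.0) -> RegionVolumes:
    """Per-label volume (voxel count x voxel volume); label 0 is background."""
    labelmap = np.asarray(labelmap)
    if labelmap.min() < 0:
        raise ValueError("labelmap must be nonnegative")
    labels, counts = np.unique(labelmap, return_counts=True)
    out = {int(l): float(c) * voxel_volume
           for l, c in zip(labels, counts) if l != 0}
    if not out:
        raise ValueError("labelmap contains no nonzero labels")
    return out


def _align(a: RegionVolumes, b: RegionVolumes):
    if set(a) != set(b):
        raise ValueError(
            f"region sets differ: {sorted(set(a) ^ set(b))} not shared")


def error_rate(imputed: RegionVolumes, observed: RegionVolumes) -> RegionVolumes:
    """|vhat - v| / v per region (observed volumes in the denominator)."""
    _align(imputed, observed)
    return {r: abs(imputed[r] - observed[r]) / observed[r] for r in observed}


def progression_rate(current: RegionVolumes,
                     previous: RegionVolumes) -> RegionVolumes:
    """|v_i - v_{i-1}| / v_{i-1} per region."""
    _align(current, previous)
    return {r: abs(current[r] - previous[r]) / previous[r] for r in previous}


def progression_gap(imputed: RegionVolumes, observed: RegionVolumes,
                    previous: RegionVolumes) -> RegionVolumes:
    """|progression(imputed) - progression(observed)| per region."""
    ri = progression_rate(imputed, previous)
    ro = progression_rate(observed, previous)
    return {r: abs(ri[r] - ro[r]) for r in ri}


def annualized_atrophy_comparison(
        baseline: RegionVolumes, six_month: RegionVolumes,
        twelve_month: RegionVolumes,
        imputed_twelve_month: RegionVolumes) -> pd.DataFrame:
    """One-year atrophy rates under three scenarios, anchored at baseline.

    Scenario 1 (complete): (V0 - V12) / V0 with the observed 12-month volume.
    Scenario 2 (doubled):  2 * (V0 - V6) / V0, the linear extrapolation of
    the six-month rate.  Scenario 3 (imputed): (V0 - V12_hat) / V0 with the
    volume from the imputed 12-month image.  Deviations are absolute
    differences from scenario 1.
    """
    for v in (six_month, twelve_month, imputed_twelve_month):
        _align(baseline, v)
    rows = []
    for r in sorted(baseline):
        v0 = baseline[r]
        r1 = (v0 - twelve_month[r]) / v0
        r2 = 2.0 * (v0 - six_month[r]) / v0
        r3 = (v0 - imputed_twelve_month[r]) / v0
        rows.append({"region": r, "rate_complete": r1, "rate_doubled": r2,
                     "rate_imputed": r3, "dev_doubled": abs(r2 - r1),
                     "dev_imputed": abs(r3 - r1)})
    return pd.DataFrame(rows).set_index("region")


@dataclass
class MetricReport:
    """Image- and volume-level metrics for one imputation experiment."""

    ssim: float
    psnr_db: float
    error_rate: RegionVolumes = field(default_factory=dict)
    progression_rate: RegionVolumes = field(default_factory=dict)
    progression_gap: RegionVolumes = field(default_factory=dict)

    @property
    def mean_error_rate(self) -> float:
        return float(np.mean(list(self.error_rate.values())))

    @property
    def mean_progression_rate(self) -> float:
        return float(np.mean(list(self.progression_rate.values())))

    @property
    def mean_progression_gap(self) -> float:
        return float(np.mean(list(self.progression_gap.values())))

    def to_dict(self) -> dict:
        return {"ssim": self.ssim, "psnr_db": self.psnr_db,
                "error_rate": {str(k): v for k, v in self.error_rate.items()},
                "progression_rate": {str(k): v
                                     for k, v in self.progression_rate.items()},
                "progression_gap": {str(k): v
                                    for k, v in self.progression_gap.items()},
                "mean_error_rate": self.mean_error_rate,
                "mean_progression_rate": self.mean_progression_rate,
                "mean_progression_gap": self.mean_progression_gap}

    def to_json(self) -> str:
        def enc(o):
            return "inf" if o == math.inf else o
        return json.dumps({k: (enc(v) if not isinstance(v, dict) else v)
                           for k, v in self.to_dict().items()}, indent=2)


def aggregate_report(reports: list[MetricReport],
                     groups: list | None = None) -> pd.DataFrame:
    """Mean and standard deviation of each summary metric across reports.

    Region means are taken within each report first, then mean +/- sd across
    reports (optionally stratified by ``groups``, one label per report).
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    rows = [{"ssim": r.ssim, "psnr_db": r.psnr_db,
             "error_rate": r.mean_error_rate if r.error_rate else np.nan,
             "progression_rate": (r.mean_progression_rate
                                  if r.progression_rate else np.nan),
             "progression_gap": (r.mean_progression_gap
                                 if r.progression_gap else np.nan)}
            for r in reports]
    df = pd.DataFrame(rows)
    if groups is not None:
        df["group"] = groups
        return df.groupby("group").agg(["mean", "std"])
    return df.agg(["mean", "std"])


# -- external volume tables ---------------------------------------------------

def write_volume_table(volumes: dict[tuple[str, int], RegionVolumes],
                       path) -> None:
    """Write {(subject, visit): RegionVolumes} as a tab-separated table with
    columns subject, visit, region, volume_mm3."""
    rows = [{"subject": s, "visit": v, "region": r, "volume_mm3": vol}
            for (s, v), rv in sorted(volumes.items())
            for r, vol in sorted(rv.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_volume_table(path) -> dict[tuple[str, int], RegionVolumes]:
    """Inverse of :func:`write_volume_table`; accepts tables produced by
    external volumetry pipelines with the same four columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "visit", "region", "volume_mm3"}
    if not required <= set(df.columns):
        raise ValueError(
            f"volume table must have columns {sorted(required)}, "
            f"got {list(df.columns)}")
    out: dict[tuple[str, int], RegionVolumes] = {}
    for row in df.itertuples():
        out.setdefault((str(row.subject), int(row.visit)), {})[
            int(row.region)] = float(row.volume_mm3)
    return out


# -- intensity-based volumetry for imputed images -----------------------------

def class_means_from(image: np.ndarray, labelmap: np.ndarray,
                     mask: np.ndarray) -> dict[int, float]:
    """Mean intensity of each label (0 = unlabeled tissue) within the mask."""
    image = np.asarray(image, dtype=float)
    labelmap = np.asarray(labelmap)
    mask = np.asarray(mask).astype(bool)
    means = {}
    for lab in np.unique(labelmap[mask]):
        means[int(lab)] = float(image[mask & (labelmap == lab)].mean())
    return means


def segment_by_intensity(volume: np.ndarray, mask: np.ndarray,
                         class_means: dict[int, float]) -> np.ndarray:
    """Nearest-class-mean labeling of mask voxels.

    A deliberately simple stand-in for a full segmentation pipeline: each
    voxel inside the mask is assigned the label whose calibrated mean
    intensity is closest.  Returns an integer label map (0 outside the mask
    and for the unlabeled-tissue class).
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    labels = np.array(sorted(class_means))
    means = np.array([class_means[int(l)] for l in labels])
    dist = np.abs(volume[mask][:, None] - means[None, :])
    choice = labels[np.argmin(dist, axis=1)]
    out = np.zeros(volume.shape, dtype=np.int32)
    out[mask] = choice
    return out
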