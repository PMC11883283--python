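"""Image-derived quantifications as generic array/mask operations.

Re-implements the study's ImageJ/MIPAR-style measurements: a channel is
thresholded, despeckled with a 3x3 median filter and decomposed into
8-connected particles above a minimum area; mean fluorescence over the
retained particles is the pooled total intensity divided by total area
(RawIntDen / SumArea); compartment ratios divide two such means;
cardiomyocyte proliferation is the per-section fraction of Mef2+ nuclei
that are also EdU+, averaged over sections within a heart; AFOG trichrome
composition is %red (fibrin), %blue (collagen) and the remainder as
orange (muscle).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

__all__ = [
    "ChannelImage",
    "ParticleMask",
    "SectionCellCounts",
    "threshold_particles",
    "mean_fluorescence",
    "colocalization_ratio",
    "proliferation_index",
    "afog_composition",
    "percent_area",
]

CHANNEL_ROLES = (
    "GFP", "red_reporter", "MHC", "Mef2", "EdU", "AFOG_red", "AFOG_blue",
)


@dataclass(frozen=True)
class ChannelImage:
    """One 2-D intensity channel (arbitrary density units, ADU)."""

    data: np.ndarray
    role: str = "GFP"
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("channel image must be 2-D")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")
        object.__setattr__(self, "data", arr)


@dataclass(frozen=True)
class ParticleMask:
    """Labeled particles surviving the area filter."""

    labels: np.ndarray  # int array, 0 = background
    min_area: int
    empty_after_filter: bool = False

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def total_area(self) -> int:
        return int(np.count_nonzero(self.labels))

    @property
    def particle_areas(self) -> np.ndarray:
        if self.total_area == 0:
            return np.array([], dtype=int)
        return np.bincount(self.labels.ravel())[1:]

    @property
    def n_particles(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class SectionCellCounts:
    """Nuclei counts for one section: total Mef2+ and Mef2+EdU+ doubles."""

    section_id: str
    heart_id: str
    mef2_count: int
    double_positive_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.double_positive_count <= self.mef2_count):
            raise ValueError(
                f"section {self.section_id}: doubles must lie in [0, mef2]"
            )


def threshold_particles(
    img: ChannelImage, threshold: float, min_area: int = 50
) -> ParticleMask:
    """Threshold, despeckle and keep particles larger than ``min_area``.

    Pixels >= threshold form the binary mask; a 3x3 median filter removes
    speckle; 8-connected components with area <= min_area are dropped.
    An all-background result is valid and flagged, not an error.
    """
    data = img.data
    if threshold > data.max() and data.size and data.max() > 0:
        _warnings.warn("threshold above image maximum; mask will be empty")
    binary = data >= threshold
    despeckled = ndimage.median_filter(binary.astype(np.uint8), size=3) > 0
    labels = measure.label(despeckled, connectivity=2)
    if labels.max() > 0:
        areas = np.bincount(labels.ravel())
        kill = np.flatnonzero(areas <= min_area)
        relabel = np.zeros(areas.size, dtype=labels.dtype)
        keep = [i for i in range(1, areas.size) if i not in set(kill)]
        for new, old in enumerate(keep, start=1):
            relabel[old] = new
        labels = relabel[labels]
    empty = labels.max() == 0
    return ParticleMask(labels=labels, min_area=min_area, empty_after_filter=bool(empty))


def mean_fluorescence(measure_img: ChannelImage, roi: ParticleMask) -> float:
    """Pooled mean intensity over the retained-particle pixels.

    Total intensity over all particle pixels divided by total particle
    area (area-weighted; NOT the mean of per-particle means). Reported in
    ADU per pixel; with a known pixel size this converts to ADU/um^2 by
    dividing by pixel_size_um**2.
    """
    if measure_img.data.shape != roi.labels.shape:
        raise ValueError("image and mask dimensions differ")
    area = roi.total_area
    if area == 0:
        raise ValueError("empty_roi: no retained particles to measure")
    total = float(measure_img.data[roi.mask].sum())
    mean = total / area
    if measure_img.pixel_size_um:
        mean = mean / measure_img.pixel_size_um**2
    return mean


def colocalization_ratio(
    gfp: ChannelImage, roi_a: ParticleMask, roi_b: ParticleMask
) -> float:
    """Ratio of mean reporter fluorescence between two compartment ROIs.

    E.g. mean GFP within the epicardium mask over mean GFP within the
    muscle mask; 7.36 means 7.36-fold brighter in compartment A.
    """
    return mean_fluorescence(gfp, roi_a) / mean_fluorescence(gfp, roi_b)


def proliferation_index(
    sections: list[SectionCellCounts], per_heart: bool = True
) -> pd.DataFrame:
    """Cardiomyocyte proliferation index per section and per heart.

    Per section: Mef2+EdU+ doubles / total Mef2+ nuclei. Per heart: the
    arithmetic mean of its section indices (sections are averaged, not
    pooled, so a small section counts as much as a large one). Sections
    with zero Mef2+ nuclei are excluded with a warning; hearts outside
    the expected 2-4 sections are flagged with a warning too.
    """
    rows = []
    for s in sections:
        if s.mef2_count == 0:
            _warnings.warn(f"section {s.section_id}: no Mef2+ nuclei; excluded")
            continue
        rows.append(
            {
                "heart_id": s.heart_id,
                "section_id": s.section_id,
                "index": s.double_positive_count / s.mef2_count,
            }
        )
    per_section = pd.DataFrame(rows, columns=["heart_id", "section_id", "index"])
    if not per_heart:
        return per_section
    counts = per_section.groupby("heart_id")["index"].agg(["mean", "size"])
    outside = counts.index[(counts["size"] < 2) | (counts["size"] > 4)]
    for h in outside:
        _warnings.warn(f"heart {h}: {counts.loc[h, 'size']} usable sections (expected 2-4)")
    return counts.rename(columns={"mean": "index", "size": "n_sections"}).reset_index()


def afog_composition(red_pct: float, blue_pct: float) -> tuple[float, float, float]:
    """Trichrome composition (%red fibrin, %blue collagen, %orange muscle).

    Orange is defined by subtraction: 100 - %red - %blue. Red and blue
    percentages exceeding 100 together indicate inconsistent thresholding
    and raise.
    """
    if red_pct < 0 or blue_pct < 0:
        raise ValueError("percent areas must be >= 0")
    if red_pct + blue_pct > 100.0 + 1e-9:
        raise ValueError(
            f"red ({red_pct}) + blue ({blue_pct}) exceed 100%; "
            "inconsistent thresholding"
        )
    orange = 100.0 - red_pct - blue_pct
    return (red_pct, blue_pct, orange)


def percent_area(roi: ParticleMask) -> float:
    """Retained-particle area as a percentage of the image area."""
    return 100.0 * roi.total_area / roi.labels.size


def read_section_counts(path) -> list[SectionCellCounts]:
    """Read a CSV with columns section_id, heart_id, mef2, double_positive."""
    df = pd.read_csv(path)
    required = {"section_id", "heart_id", "mef2", "double_positive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"section table missing column(s): {sorted(missing)}")
    return [
        SectionCellCounts(str(r.section_id), str(r.heart_id), int(r.mef2), int(r.double_positive))
        for r in df.itertuples()
    ]
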