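"""Coronary artery calcium scoring: Agatston and volume scores.

A calcified lesion is a connected component of voxels with HU >= 130
inside one artery label, spanning at least three contiguous pixels.
Connectivity is in-plane 8-connected by default (the Agatston score is a
per-slice planimetric measure); a 3-D 26-connected mode is available for
sensitivity studies.  Each lesion scores its area (mm^2) times a density
weight from its peak HU (1: 130-199, 2: 200-299, 3: 300-399, 4: > 399),
and the volume score is voxel volume times the number of calcified
voxels.  Per-artery scores over RCA, LAD, LCX and LM sum to the totals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from .volume import ARTERY_LABELS, ARTERY_NAMES, ArteryMask, CTVolume, voxel_geometry

__all__ = [
    "Lesion",
    "CACReport",
    "detect_lesions",
    "agatston_weight",
    "score_scan",
    "DEFAULT_THRESHOLD_HU",
    "MIN_LESION_PIXELS",
]

DEFAULT_THRESHOLD_HU = 130.0
MIN_LESION_PIXELS = 3

#: Agatston slice thickness (mm) at which the score is defined.
AGATSTON_SLICE_THICKNESS_MM = 3.0


def agatston_weight(max_hu: float) -> int:
    """Density weight from a lesion's peak HU.

    Bins are half-open — [130, 200) -> 1, [200, 300) -> 2, [300, 400) -> 3,
    [400, inf) -> 4 — so integer HU reproduce the conventional
    130-199 / 200-299 / 300-399 / >399 bins exactly.
    """
    if max_hu < DEFAULT_THRESHOLD_HU:
        raise ValueError(f"peak HU {max_hu} below the 130 HU calcium threshold")
    if max_hu < 200:
        return 1
    if max_hu < 300:
        return 2
    if max_hu < 400:
        return 3
    return 4


@dataclass(frozen=True)
class Lesion:
    """One detected calcification component (per slice per artery)."""

    artery: str  # RCA | LAD | LCX | LM
    slice_index: int
    pixel_count: int
    area_mm2: float
    max_hu: float
    weight: int

    def __post_init__(self) -> None:
        if self.pixel_count < MIN_LESION_PIXELS:
            raise ValueError("lesion below the three contiguous pixel minimum")
        if self.max_hu < DEFAULT_THRESHOLD_HU:
            raise ValueError("lesion peak below the 130 HU threshold")
        if self.weight != agatston_weight(self.max_hu):
            raise ValueError("weight inconsistent with peak HU bin")

    @property
    def agatston(self) -> float:
        return self.area_mm2 * self.weight


@dataclass
class CACReport:
    """Per-artery and total Agatston/volume scores for one scan."""

    protocol: str
    agatston: dict[str, float]  # per artery
    volume_mm3: dict[str, float]
    lesions: list[Lesion] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def total_agatston(self) -> float:
        return sum(self.agatston[a] for a in ARTERY_NAMES)

    @property
    def total_volume_mm3(self) -> float:
        return sum(self.volume_mm3[a] for a in ARTERY_NAMES)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "per_artery": {
                a: {"agatston": self.agatston[a], "volume_mm3": self.volume_mm3[a]}
                for a in ARTERY_NAMES
            },
            "total_agatston": self.total_agatston,
            "total_volume_mm3": self.total_volume_mm3,
            "n_lesions": len(self.lesions),
            "meta": self.meta,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def lesion_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (l.artery, l.slice_index, l.pixel_count, l.area_mm2, l.max_hu, l.weight)
                for l in self.lesions
            ],
            columns=["artery", "slice", "pixels", "area_mm2", "max_hu", "weight"],
        )


def detect_lesions(
    volume: CTVolume,
    mask: ArteryMask,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    min_pixels: int = MIN_LESION_PIXELS,
    three_d: bool = False,
) -> list[Lesion]:
    """Find calcified lesions per artery label.

    Per slice and per artery, connected components (in-plane 8-connected)
    of voxels with ``HU >= threshold_hu`` within the artery label are
    extracted; components smaller than ``min_pixels`` are discarded.  With
    ``three_d=True`` components are 26-connected across slices instead and
    a lesion's ``slice_index`` is its first slice.
    """
    mask.check_congruent(volume)
    lesions: list[Lesion] = []
    pixel_area, _ = voxel_geometry(volume)
    hot = volume.voxels >= threshold_hu

    for label_value, artery in sorted(ARTERY_LABELS.items()):
        candidate = hot & (mask.labels == label_value)
        if not candidate.any():
            continue
        if three_d:
            comp = measure.label(candidate, connectivity=3)
            lesions.extend(
                _components_to_lesions(
                    comp, volume.voxels, artery, pixel_area, min_pixels, three_d=True
                )
            )
        else:
            for s in np.flatnonzero(candidate.any(axis=(1, 2))):
                comp = measure.label(candidate[s], connectivity=2)
                lesions.extend(
                    _components_to_lesions(
                        comp, volume.voxels[s], artery, pixel_area, min_pixels,
                        slice_index=int(s),
                    )
                )
    return lesions


def _components_to_lesions(
    comp: np.ndarray,
    hu: np.ndarray,
    artery: str,
    pixel_area: float,
    min_pixels: int,
    slice_index: int | None = None,
    three_d: bool = False,
) -> list[Lesion]:
    out: list[Lesion] = []
    n = comp.max()
    if n == 0:
        return out
    flat = comp.ravel()
    counts = np.bincount(flat, minlength=n + 1)
    max_hu = np.full(n + 1, -np.inf)
    np.maximum.at(max_hu, flat, hu.ravel())
    for cid in range(1, n + 1):
        if counts[cid] < min_pixels:
            continue
        if three_d:
            first_slice = int(np.flatnonzero((comp == cid).any(axis=(1, 2)))[0])
        else:
            first_slice = int(slice_index)  # type: ignore[arg-type]
        peak = float(max_hu[cid])
        out.append(
            Lesion(
                artery=artery,
                slice_index=first_slice,
                pixel_count=int(counts[cid]),
                area_mm2=float(counts[cid] * pixel_area),
                max_hu=peak,
                weight=agatston_weight(peak),
            )
        )
    return out


def score_scan(
    volume: CTVolume,
    mask: ArteryMask,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    min_pixels: int = MIN_LESION_PIXELS,
    three_d: bool = False,
) -> CACReport:
    """Compute per-artery and total Agatston and volume scores.

    Per artery: Agatston = sum over lesions of area_mm2 x weight; volume
    score = voxel volume x total calcified pixel count.  Totals are exact
    sums over the four arteries.
    """
    if not np.isclose(volume.slice_thickness, AGATSTON_SLICE_THICKNESS_MM):
        warnings.warn(
            f"Agatston scoring is defined at {AGATSTON_SLICE_THICKNESS_MM} mm "
            f"slices; volume has {volume.slice_thickness} mm",
            stacklevel=2,
        )
    lesions = detect_lesions(volume, mask, threshold_hu, min_pixels, three_d)
    _, voxel_volume = voxel_geometry(volume)
    agatston = {a: 0.0 for a in ARTERY_NAMES}
    volume_score = {a: 0.0 for a in ARTERY_NAMES}
    for les in lesions:
        agatston[les.artery] += les.agatston
        volume_score[les.artery] += les.pixel_count * voxel_volume
    return CACReport(
        protocol=volume.protocol.value,
        agatston=agatston,
        volume_mm3=volume_score,
        lesions=lesions,
        meta={"threshold_hu": threshold_hu, "min_pixels": min_pixels,
              "three_d": three_d},
    )
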