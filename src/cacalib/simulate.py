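"""Synthetic phantom and patient-cohort generation.

This module produces the digital stand-ins for the physical study objects:

* rasterized electron-density phantom volumes at either protocol, with the
  spectral HU shift applied through the inverse of a known monotone
  transfer function and i.i.d. Gaussian protocol noise added, and
* paired patient-like volumes (noiseless ground truth, a noisy CSCT
  realization, and a spectrally shifted noisy LDCT realization) containing
  spheroidal calcified lesions inside four disjoint tubular coronary-artery
  regions, with an optional per-slice motion jitter acting as a heart-rate
  surrogate.

Because the generating transfer function is known, every downstream stage
(ROI measurement, curve fitting, calibration, scoring, agreement
statistics) can be validated end to end without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantoms import PhantomSpec, TransferModel
from .volume import (
    ARTERY_LABELS,
    ArteryMask,
    CTVolume,
    Protocol,
    save_mask,
    save_volume,
)

__all__ = [
    "CohortParams",
    "make_phantom_volume",
    "make_patient",
    "make_cohort",
    "GenerationError",
    "PATIENT_GRID",
]

logger = logging.getLogger(__name__)

AIR_HU = -1000.0

#: Patient-volume grid: (n_slices, n_rows, n_cols), in-plane spacing (mm),
#: slice thickness (mm).  3-mm slices match the Agatston convention; the
#: in-plane grid covers an 110-mm cardiac field of view.
PATIENT_GRID = {
    "shape": (30, 128, 128),
    "pixel_spacing": (0.86, 0.86),
    "slice_thickness": 3.0,
}

#: Tubular artery regions: label -> (base x_mm, base y_mm, drift amp mm,
#: slice range).  Centerlines drift sinusoidally along the scan axis.
_ARTERY_GEOMETRY = {
    1: ((-30.0, 5.0), 4.0, (0, None)),    # RCA
    2: ((18.0, -22.0), 4.0, (0, None)),   # LAD
    3: ((26.0, 12.0), 4.0, (0, None)),    # LCX
    4: ((2.0, -8.0), 1.0, (10, 17)),      # LM (short segment)
}
ARTERY_TUBE_RADIUS_MM = 5.0
BODY_HU = 40.0


class GenerationError(RuntimeError):
    """Raised when synthetic geometry cannot be placed after retries."""


@dataclass
class CohortParams:
    """Parameters of a synthetic patient cohort.

    ``lesions_per_artery`` is the mean of a Poisson count per artery;
    lesion peak HU and radius are drawn uniformly from their ranges.
    ``motion_sigma_mm`` is the SD of the per-slice in-plane translation
    applied to lesion-bearing LDCT slices (0 = perfectly gated); it doubles
    as a heart-rate surrogate for subgroup stratification.
    """

    n_patients: int = 40
    lesions_per_artery: float = 1.5
    lesion_peak_hu_range: tuple[float, float] = (160.0, 800.0)
    lesion_radius_range: tuple[float, float] = (1.0, 2.5)
    motion_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_peak_hu_range
        if lo < 130:
            raise ValueError("lesion peak HU must be >= the 130 HU threshold")
        if hi <= lo or self.lesion_radius_range[1] <= self.lesion_radius_range[0]:
            raise ValueError("lesion parameter ranges must be non-degenerate")
        if self.lesions_per_artery < 0 or self.motion_sigma_mm < 0:
            raise ValueError("rates and magnitudes must be non-negative")

    @property
    def hr_bpm(self) -> float:
        """Heart-rate surrogate: gated-quality at 0 motion, higher with jitter."""
        return 55.0 + 12.0 * self.motion_sigma_mm


# ---------------------------------------------------------------------------
# Phantom rasterization
# ---------------------------------------------------------------------------

def make_phantom_volume(
    spec: PhantomSpec,
    protocol: Protocol | str,
    transfer: TransferModel,
    seed: int | None = 0,
    matrix: int = 512,
    fov_mm: float | None = None,
    n_slices: int = 5,
) -> CTVolume:
    """Rasterize an ED phantom as scanned with one protocol.

    Body and insert voxels take their nominal CSCT-energy HU for protocol
    CSCT, or the transfer inverse of it for protocol LDCT (the simulated
    spectral shift); the surrounding air stays at -1000 HU.  Gaussian noise
    with the protocol's SD is then added.  The default in-plane grid
    mimics a 512-matrix reconstruction with protocol FOV 320 mm (CSCT) or
    500 mm (LDCT).
    """
    protocol = Protocol(protocol)
    if protocol not in (Protocol.CSCT, Protocol.LDCT):
        raise ValueError("phantoms are scanned with protocol CSCT or LDCT")
    if fov_mm is None:
        fov_mm = 320.0 if protocol is Protocol.CSCT else 500.0
    spacing = fov_mm / matrix

    vol = CTVolume(
        voxels=np.full((n_slices, matrix, matrix), AIR_HU),
        pixel_spacing=(spacing, spacing),
        slice_thickness=3.0,
        protocol=protocol,
        meta={"phantom": spec.variant, "fov_mm": fov_mm},
    )
    ymm, xmm = vol.inplane_coords_mm()

    def to_protocol(csct_hu: float) -> float:
        if protocol is Protocol.CSCT:
            return csct_hu
        return float(transfer.inverse(csct_hu))

    a, b = spec.body_axes[0] / 2.0, spec.body_axes[1] / 2.0
    body = (xmm / a) ** 2 + (ymm / b) ** 2 <= 1.0
    plane = np.full((matrix, matrix), AIR_HU)
    plane[body] = to_protocol(spec.body_hu)
    for ins in spec.inserts:
        disc = (xmm - ins.center[0]) ** 2 + (ymm - ins.center[1]) ** 2 <= ins.radius ** 2
        plane[disc] = to_protocol(ins.csct_hu)
    vol.voxels[:] = plane

    sd = transfer.noise_sd_csct if protocol is Protocol.CSCT else transfer.noise_sd_ldct
    if sd > 0:
        rng = np.random.default_rng(seed)
        vol.voxels += rng.normal(0.0, sd, size=vol.voxels.shape)
    return vol


# ---------------------------------------------------------------------------
# Patient generation
# ---------------------------------------------------------------------------

def _artery_centerline(label: int, n_slices: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (slice indices, x_mm, y_mm) of one artery's centerline."""
    (bx, by), amp, (s0, s1) = _ARTERY_GEOMETRY[label]
    s1 = n_slices if s1 is None else min(s1, n_slices)
    s = np.arange(s0, s1)
    phase = 2 * np.pi * s / max(n_slices, 1)
    return s, bx + amp * np.sin(phase + label), by + amp * np.cos(phase + label)


def _build_anatomy(n_slices: int, ymm: np.ndarray, xmm: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Soft-tissue thorax background and artery label volume."""
    shape = (n_slices,) + ymm.shape
    truth = np.full(shape, AIR_HU)
    half_x, half_y = np.abs(xmm).max(), np.abs(ymm).max()
    body = (xmm / (0.95 * half_x)) ** 2 + (ymm / (0.90 * half_y)) ** 2 <= 1.0
    truth[:, body] = BODY_HU

    labels = np.zeros(shape, dtype=np.int16)
    for lab in sorted(_ARTERY_GEOMETRY):
        s_idx, cx, cy = _artery_centerline(lab, n_slices)
        for s, x0, y0 in zip(s_idx, cx, cy):
            tube = (xmm - x0) ** 2 + (ymm - y0) ** 2 <= ARTERY_TUBE_RADIUS_MM ** 2
            labels[s][tube] = lab
    return truth, labels


def _place_lesions(
    truth: np.ndarray,
    params: CohortParams,
    rng: np.random.Generator,
    ymm: np.ndarray,
    xmm: np.ndarray,
    slice_thickness: float,
    max_retries: int = 50,
) -> list[dict]:
    """Add spheroidal lesions inside the artery tubes; returns ground truth.

    Each lesion is a sphere at its peak HU with a linear falloff to the
    background over one in-plane voxel shell, centered exactly on a voxel
    center so that even the smallest lesion contributes at least one
    supra-threshold voxel.  Lesions are kept mutually separated so truth
    connected components correspond one-to-one to generated lesions.
    """
    n_slices = truth.shape[0]
    shell = max(abs(xmm[0, 1] - xmm[0, 0]), abs(ymm[1, 0] - ymm[0, 0]))
    placed: list[dict] = []

    for lab in sorted(_ARTERY_GEOMETRY):
        n_lesions = rng.poisson(params.lesions_per_artery)
        s_idx, cx, cy = _artery_centerline(lab, n_slices)
        for _ in range(n_lesions):
            radius = rng.uniform(*params.lesion_radius_range)
            peak = rng.uniform(*params.lesion_peak_hu_range)
            for attempt in range(max_retries):
                s = int(rng.choice(s_idx))
                k = int(np.flatnonzero(s_idx == s)[0])
                max_off = max(ARTERY_TUBE_RADIUS_MM - radius - shell, 0.0)
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, max_off)
                x0 = cx[k] + rad * np.cos(ang)
                y0 = cy[k] + rad * np.sin(ang)
                # snap the lesion center onto the nearest voxel center
                j = int(np.argmin(np.abs(xmm[0] - x0)))
                i = int(np.argmin(np.abs(ymm[:, 0] - y0)))
                x0, y0 = float(xmm[0, j]), float(ymm[i, 0])
                z0 = s * slice_thickness
                min_sep = radius + shell + 1.0
                if all(
                    np.sqrt((p["x_mm"] - x0) ** 2 + (p["y_mm"] - y0) ** 2
                            + (p["z_mm"] - z0) ** 2)
                    > min_sep + p["radius_mm"] + shell
                    for p in placed
                ):
                    break
            else:
                # The artery segment is saturated; drop the lesion so the
                # recorded ground truth stays exact for what was placed.
                logger.info(
                    "dropping unplaceable lesion in %s after %d attempts",
                    ARTERY_LABELS[lab], max_retries,
                )
                continue

            zs = (np.arange(n_slices) - s) * slice_thickness
            reach = radius + shell
            s_lo = max(0, s - int(np.ceil(reach / slice_thickness)))
            s_hi = min(n_slices, s + int(np.ceil(reach / slice_thickness)) + 1)
            d_inplane = np.sqrt((xmm - x0) ** 2 + (ymm - y0) ** 2)
            n_vox = 0
            for sz in range(s_lo, s_hi):
                d = np.sqrt(d_inplane ** 2 + zs[sz] ** 2)
                profile = np.where(
                    d <= radius,
                    peak,
                    peak + (BODY_HU - peak) * (d - radius) / shell,
                )
                lesion_px = d <= reach
                truth[sz][lesion_px] = np.maximum(truth[sz][lesion_px],
                                                  profile[lesion_px])
                n_vox += int((profile[lesion_px] >= 130.0).sum())

            placed.append({
                "artery": ARTERY_LABELS[lab],
                "slice": s,
                "x_mm": x0, "y_mm": y0, "z_mm": z0,
                "radius_mm": radius,
                "peak_hu": peak,
                "n_voxels_ge_130": n_vox,
            })
    return placed


def make_patient(
    params: CohortParams,
    transfer: TransferModel,
    patient_seed: int,
) -> tuple[CTVolume, CTVolume, CTVolume, ArteryMask, dict]:
    """Generate one synthetic patient: (truth, csct, ldct, mask, meta).

    ``truth`` is the noiseless object at CSCT energy; ``csct`` adds the
    CSCT protocol noise; ``ldct`` is the voxel-wise transfer inverse of
    truth plus LDCT noise, with optional per-slice motion jitter applied
    to lesion-bearing slices.  ``meta`` records seeds, the lesion ground
    truth and the heart-rate subgroup surrogate.
    """
    shape = PATIENT_GRID["shape"]
    spacing = PATIENT_GRID["pixel_spacing"]
    thickness = PATIENT_GRID["slice_thickness"]

    ss = np.random.SeedSequence(patient_seed)
    geom_rng, csct_rng, ldct_rng, motion_rng = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    template = CTVolume(
        voxels=np.zeros(shape), pixel_spacing=spacing,
        slice_thickness=thickness, protocol=Protocol.TRUTH,
    )
    ymm, xmm = template.inplane_coords_mm()
    truth_arr, labels = _build_anatomy(shape[0], ymm, xmm)
    lesions = _place_lesions(truth_arr, params, geom_rng, ymm, xmm, thickness)

    _, voxel_volume = (spacing[0] * spacing[1],
                       spacing[0] * spacing[1] * thickness)
    meta = {
        "patient_seed": int(patient_seed),
        "hr_bpm": params.hr_bpm,
        "phase": "diastole",
        "motion_sigma_mm": params.motion_sigma_mm,
        "truth_lesion_count": len(lesions),
        "truth_total_volume_mm3": float(
            sum(l["n_voxels_ge_130"] for l in lesions) * voxel_volume
        ),
        "lesions": lesions,
    }

    truth = template.copy_with(voxels=truth_arr.copy(), protocol=Protocol.TRUTH,
                               extra_meta={"role": "truth"})

    csct_arr = truth_arr.copy()
    if transfer.noise_sd_csct > 0:
        csct_arr = csct_arr + csct_rng.normal(
            0.0, transfer.noise_sd_csct, size=shape
        )
    csct = template.copy_with(voxels=csct_arr, protocol=Protocol.CSCT)

    ldct_arr = np.asarray(transfer.inverse(truth_arr), dtype=float)
    if transfer.noise_sd_ldct > 0:
        ldct_arr = ldct_arr + ldct_rng.normal(
            0.0, transfer.noise_sd_ldct, size=shape
        )
    if params.motion_sigma_mm > 0:
        lesion_slices = np.flatnonzero((truth_arr >= 130.0).any(axis=(1, 2)))
        for s in lesion_slices:
            dy, dx = motion_rng.normal(0.0, params.motion_sigma_mm, size=2)
            ldct_arr[s] = ndimage.shift(
                ldct_arr[s], (dy / spacing[0], dx / spacing[1]),
                order=1, mode="nearest",
            )
    ldct = template.copy_with(voxels=ldct_arr, protocol=Protocol.LDCT)

    mask = ArteryMask(labels=labels)
    return truth, csct, ldct, mask, meta


def assign_subgroup(meta: dict) -> str:
    """Four-subgroup heart-rate stratification from patient metadata."""
    if meta.get("phase") == "systole":
        return "systole"
    hr = float(meta["hr_bpm"])
    if hr < 60:
        return "diastole_hr_lt60"
    if hr <= 65:
        return "diastole_hr_60_65"
    return "diastole_hr_gt65"


MANIFEST_COLUMNS = [
    "patient_id", "subgroup", "csct_path", "ldct_path", "mask_path",
    "truth_path", "truth_lesion_count", "truth_total_volume_mm3",
]


def patient_seed_for(master_seed: int, index: int) -> int:
    """Deterministic per-patient seed derived from (master seed, index)."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0]
               % (2 ** 31))


def make_cohort(
    params: CohortParams,
    transfer: TransferModel,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Generate a cohort on disk and return its manifest.

    Writes per-patient truth/CSCT/LDCT volumes and the artery mask as
    NIfTI, plus ``manifest.csv``.  Per-patient seeds derive
    deterministically from ``params.seed``, so identical parameters yield
    identical cohorts regardless of generation order.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / ".write_test").write_text("")
        (out_dir / ".write_test").unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    rows = []
    for i in range(params.n_patients):
        pid = f"P{i:03d}"
        truth, csct, ldct, mask, meta = make_patient(
            params, transfer, patient_seed_for(params.seed, i)
        )
        paths = {
            "truth_path": out_dir / f"{pid}_truth.nii.gz",
            "csct_path": out_dir / f"{pid}_csct.nii.gz",
            "ldct_path": out_dir / f"{pid}_ldct.nii.gz",
            "mask_path": out_dir / f"{pid}_mask.nii.gz",
        }
        save_volume(truth, paths["truth_path"])
        save_volume(csct, paths["csct_path"])
        save_volume(ldct, paths["ldct_path"])
        save_mask(mask, paths["mask_path"],
                  pixel_spacing=truth.pixel_spacing,
                  slice_thickness=truth.slice_thickness)
        rows.append({
            "patient_id": pid,
            "subgroup": assign_subgroup(meta),
            **{k: str(v) for k, v in paths.items()},
            "truth_lesion_count": meta["truth_lesion_count"],
            "truth_total_volume_mm3": meta["truth_total_volume_mm3"],
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
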