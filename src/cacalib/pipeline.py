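"""End-to-end orchestration: simulate -> calibrate -> score -> compare.

Mirrors the study workflow: scan the ED phantoms with both protocols,
measure paired insert HU, fit the calibration polynomial, generate a
patient cohort, score CSCT/LDCT/cLDCT for every patient, and tabulate
agreement.  Every run is deterministic given its seed and writes a
provenance record beside its outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CalibrationCurve,
    apply_calibration,
    build_pair_table,
    fit_calibration,
    measure_insert_hu,
)
from .phantoms import TransferModel, default_phantom_spec, default_transfer_model
from .scoring import score_scan
from .simulate import CohortParams, make_cohort, make_phantom_volume
from .stats import SubgroupSpec, cohort_compare
from .volume import Protocol, load_mask, load_volume

__all__ = ["RunConfig", "run_end_to_end", "StageError", "score_cohort"]

logger = logging.getLogger(__name__)

PHANTOM_VARIANTS = ("ED1", "ED2", "ED3", "ED4")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: str = "cacalib_run"
    seed: int = 0
    n_patients: int = 40
    lesions_per_artery: float = 1.5
    lesion_peak_hu_range: tuple[float, float] = (160.0, 800.0)
    lesion_radius_range: tuple[float, float] = (1.0, 2.5)
    motion_sigma_mm: float = 0.0
    noise_sd_csct: float = 30.0
    noise_sd_ldct: float = 15.0
    phantom_matrix: int = 512
    phantom_noise: bool = True
    candidate_orders: tuple[int, ...] = (1, 2, 3)

    def cohort_params(self) -> CohortParams:
        return CohortParams(
            n_patients=self.n_patients,
            lesions_per_artery=self.lesions_per_artery,
            lesion_peak_hu_range=tuple(self.lesion_peak_hu_range),
            lesion_radius_range=tuple(self.lesion_radius_range),
            motion_sigma_mm=self.motion_sigma_mm,
            seed=self.seed,
        )

    def transfer_model(self, noiseless: bool = False) -> TransferModel:
        return default_transfer_model(
            noise_sd_csct=0.0 if noiseless else self.noise_sd_csct,
            noise_sd_ldct=0.0 if noiseless else self.noise_sd_ldct,
        )


def calibrate_from_phantoms(
    transfer: TransferModel,
    seed: int = 0,
    matrix: int = 512,
    candidate_orders=(1, 2, 3),
    out_dir: Path | None = None,
) -> tuple[CalibrationCurve, pd.DataFrame]:
    """Scan all four phantom variants with both protocols and fit the curve.

    Returns the selected curve and the pooled pair table (all variants'
    insert ROI means, as a DataFrame).
    """
    ss = np.random.SeedSequence([seed, 0xED])
    seeds = ss.generate_state(2 * len(PHANTOM_VARIANTS)) % (2 ** 31)
    ldct_rows, csct_rows = [], []
    for i, variant in enumerate(PHANTOM_VARIANTS):
        spec = default_phantom_spec(variant)
        csct_vol = make_phantom_volume(
            spec, Protocol.CSCT, transfer, seed=int(seeds[2 * i]), matrix=matrix
        )
        ldct_vol = make_phantom_volume(
            spec, Protocol.LDCT, transfer, seed=int(seeds[2 * i + 1]), matrix=matrix
        )
        csct_rows.append(measure_insert_hu(csct_vol, spec))
        ldct_rows.append(measure_insert_hu(ldct_vol, spec))
    pairs = build_pair_table(
        pd.concat(ldct_rows, ignore_index=True),
        pd.concat(csct_rows, ignore_index=True),
    )
    curve, diagnostics = fit_calibration(pairs, candidate_orders=candidate_orders)
    if out_dir is not None:
        pairs.to_csv(out_dir / "hu_pairs.csv")
        curve.to_json(out_dir / "calibration_curve.json")
        diagnostics.to_csv(out_dir / "fit_diagnostics.csv", index=False)
    return curve, pairs.rows


def score_cohort(
    manifest: pd.DataFrame, curve: CalibrationCurve
) -> dict[str, dict[str, "object"]]:
    """Score CSCT, LDCT and calibrated LDCT for every cohort patient."""
    reports: dict[str, dict[str, object]] = {}
    for _, row in manifest.iterrows():
        mask = load_mask(row["mask_path"])
        csct = load_volume(row["csct_path"])
        ldct = load_volume(row["ldct_path"])
        cldct = apply_calibration(ldct, curve)
        reports[row["patient_id"]] = {
            "CSCT": score_scan(csct, mask),
            "LDCT": score_scan(ldct, mask),
            "cLDCT": score_scan(cldct, mask),
        }
    return reports


def run_end_to_end(config: RunConfig) -> Path:
    """Run the full workflow; returns the output directory.

    Outputs: ``hu_pairs.csv``, ``calibration_curve.json``,
    ``fit_diagnostics.csv``, the cohort NIfTI files and ``manifest.csv``,
    per-patient score reports (``scores.csv``), agreement and per-artery
    tables, and ``provenance.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        transfer = config.transfer_model()
        phantom_transfer = config.transfer_model(noiseless=not config.phantom_noise)
        curve, _ = calibrate_from_phantoms(
            phantom_transfer,
            seed=config.seed,
            matrix=config.phantom_matrix,
            candidate_orders=config.candidate_orders,
            out_dir=out_dir,
        )
    except Exception as exc:
        raise StageError("calibration", exc) from exc

    try:
        cohort_dir = out_dir / "cohort"
        manifest = make_cohort(config.cohort_params(), transfer, cohort_dir)
    except Exception as exc:
        raise StageError("simulate-cohort", exc) from exc

    try:
        reports = score_cohort(manifest, curve)
        score_rows = []
        for pid, by_prot in reports.items():
            for prot, rep in by_prot.items():
                row = {"patient_id": pid, "protocol": prot,
                       "total_agatston": rep.total_agatston,
                       "total_volume_mm3": rep.total_volume_mm3}
                row.update({f"agatston_{a}": rep.agatston[a]
                            for a in rep.agatston})
                score_rows.append(row)
        pd.DataFrame(score_rows).to_csv(out_dir / "scores.csv", index=False)
    except Exception as exc:
        raise StageError("scoring", exc) from exc

    try:
        tables = cohort_compare(manifest, reports, SubgroupSpec())
        tables["agreement"].to_csv(out_dir / "agreement.csv", index=False)
        tables["per_artery"].to_csv(out_dir / "per_artery.csv", index=False)
    except Exception as exc:
        raise StageError("compare", exc) from exc

    provenance = {
        "cacalib_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": asdict(config),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out_dir
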