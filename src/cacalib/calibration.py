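"""Polynomial HU calibration between CT protocols.

Spectral shaping (e.g. a silver beam-shaping filter on a low-dose chest
protocol versus a copper filter on a dedicated calcium-scoring protocol)
raises the effective beam energy and shifts measured Hounsfield units.
This module recovers the protocol-to-protocol HU relationship from paired
phantom insert measurements and applies it voxel-wise.

The estimator :class:`HUCalibrator` follows the scikit-learn protocol:
``fit(ldct_hu, csct_hu)`` least-squares fits polynomials of each candidate
order on a centered/scaled abscissa, discards badly conditioned orders,
selects the minimum-SSE fit (ties broken toward lower order), and exposes
the selected polynomial through ``predict`` and through
:meth:`HUCalibrator.transform_volume` for whole CT volumes.  Module-level
functions (:func:`fit_calibration`, :func:`apply_calibration`, ...) are
thin wrappers over it.
"""

from __future__ import annotations

import datetime
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .phantoms import PhantomSpec, TransferModelError, bisect_monotone_inverse
from .volume import CTVolume, GeometryError, Protocol

__all__ = [
    "HUPairTable",
    "CalibrationCurve",
    "HUCalibrator",
    "measure_insert_hu",
    "fit_calibration",
    "apply_calibration",
    "invert_curve",
    "CalibrationError",
]

logger = logging.getLogger(__name__)

#: Condition number of the scaled Vandermonde matrix above which a
#: candidate order is flagged badly conditioned and excluded.
CONDITION_LIMIT = 1e8

#: SSE slack (relative to SStot) within which candidate orders are treated
#: as tied; ties resolve toward the lower order.
_SSE_TIE_RTOL = 1e-10


class CalibrationError(ValueError):
    """Raised for unusable pair tables or ill-conditioned fits."""


# ---------------------------------------------------------------------------
# Pair table
# ---------------------------------------------------------------------------

@dataclass
class HUPairTable:
    """Paired mean insert HU measurements (one row per phantom x insert)."""

    rows: pd.DataFrame  # columns: variant, insert, ldct_hu, csct_hu

    COLUMNS = ("variant", "insert", "ldct_hu", "csct_hu")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise CalibrationError(f"pair table missing columns {sorted(missing)}")
        if df.duplicated(subset=["variant", "insert"]).any():
            raise CalibrationError("duplicate (variant, insert) rows in pair table")
        self.rows = df.reset_index(drop=True)

    @property
    def ldct_hu(self) -> np.ndarray:
        return self.rows["ldct_hu"].to_numpy(dtype=float)

    @property
    def csct_hu(self) -> np.ndarray:
        return self.rows["csct_hu"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "HUPairTable":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))

    @classmethod
    def read_csv(cls, path: str | Path) -> "HUPairTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.rows.to_csv(path, index=False)
        return path


# ---------------------------------------------------------------------------
# Fitted curve
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """A fitted calibration polynomial with fit diagnostics.

    ``coeffs`` are in the raw-HU basis, highest degree first (so an order-3
    curve stores (c3, c2, c1, c0)).  ``sse`` is the sum of squared
    residuals and ``r2 = 1 - sse / SStot`` with SStot about the mean of the
    reference HU values.  ``condition_ok`` is False when the scaled design
    matrix was rank deficient or had condition number above 1e8.
    """

    order: int
    coeffs: tuple[float, ...]
    domain: tuple[float, float]
    sse: float
    r2: float
    condition_ok: bool = True
    condition_number: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coeffs) != self.order + 1:
            raise CalibrationError(
                f"order {self.order} curve needs {self.order + 1} coefficients"
            )
        self.coeffs = tuple(float(c) for c in self.coeffs)
        if self.sse < 0:
            raise CalibrationError("sse must be non-negative")
        if not self.is_increasing_on_domain():
            warnings.warn(
                "calibration curve is not strictly increasing on its fitted "
                "domain; inverse mapping may be ambiguous",
                stacklevel=2,
            )

    def __call__(self, hu):
        """Evaluate the polynomial at HU value(s)."""
        return np.polyval(self.coeffs, hu)

    def is_increasing_on_domain(self, step: float = 1.0) -> bool:
        lo, hi = self.domain
        if not np.isfinite([lo, hi]).all() or hi <= lo:
            return True
        grid = np.arange(lo, hi + step, step)
        return bool(np.all(np.diff(self(grid)) > 0))

    # -- JSON serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "order": self.order,
            "coeffs_highest_first": list(self.coeffs),
            "domain": list(self.domain),
            "sse": self.sse,
            "r2": self.r2,
            "condition_ok": self.condition_ok,
            "condition_number": self.condition_number,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationCurve":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            order=int(payload["order"]),
            coeffs=tuple(payload["coeffs_highest_first"]),
            domain=tuple(payload["domain"]),
            sse=float(payload["sse"]),
            r2=float(payload["r2"]),
            condition_ok=bool(payload.get("condition_ok", True)),
            condition_number=float(payload.get("condition_number", float("nan"))),
            meta=payload.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class HUCalibrator(BaseEstimator, RegressorMixin):
    """Least-squares polynomial calibration with SSE-based order selection.

    Parameters
    ----------
    candidate_orders : sequence of int, default (1, 2, 3)
        Polynomial orders to try.
    max_order : int, default 3
        Upper bound applied to ``candidate_orders``.
    order : int, optional
        Explicit order override; skips selection (the order must still be
        well conditioned on the data).
    condition_limit : float, default 1e8
        Condition-number threshold for excluding an order.

    Attributes
    ----------
    curve_ : CalibrationCurve
        The selected fit, coefficients in the raw-HU basis.
    order_ : int
        Selected polynomial order.
    coeffs_ : ndarray
        Selected coefficients, highest degree first.
    diagnostics_ : pandas.DataFrame
        Per-candidate-order ``(order, sse, r2, condition_ok,
        condition_number, selected)`` table.

    Notes
    -----
    Fitting uses a centered/scaled abscissa (the data domain mapped onto
    [-1, 1]) for numerical stability; reported coefficients are mapped back
    to the raw-HU basis and evaluate identically within rounding.
    """

    def __init__(
        self,
        candidate_orders: Sequence[int] = (1, 2, 3),
        max_order: int = 3,
        order: int | None = None,
        condition_limit: float = CONDITION_LIMIT,
    ):
        self.candidate_orders = candidate_orders
        self.max_order = max_order
        self.order = order
        self.condition_limit = condition_limit

    # -- core fit -----------------------------------------------------------

    def fit(self, X, y):
        """Fit candidate polynomials to paired HU values and select one.

        Parameters
        ----------
        X : array-like, shape (n,) or (n, 1)
            Source-protocol (e.g. LDCT) mean HU values.
        y : array-like, shape (n,)
            Reference-protocol (e.g. CSCT) mean HU values.
        """
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise CalibrationError("X must be 1-D (or a single-column 2-D array)")
        yv = np.asarray(y, dtype=float)
        if yv.shape != x.shape:
            raise CalibrationError("X and y must have equal length")
        if not (np.isfinite(x).all() and np.isfinite(yv).all()):
            raise CalibrationError("non-finite HU values in pair data")

        orders = sorted({int(k) for k in (
            [self.order] if self.order is not None else self.candidate_orders
        ) if int(k) <= self.max_order})
        if not orders:
            raise CalibrationError("no candidate orders <= max_order")
        n_distinct = np.unique(x).size
        if n_distinct < min(orders) + 1:
            raise CalibrationError(
                f"need at least {min(orders) + 1} distinct abscissa values, "
                f"got {n_distinct}"
            )

        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise CalibrationError("degenerate abscissa (zero span)")
        mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
        xs = (x - mid) / half
        sstot = float(np.sum((yv - yv.mean()) ** 2))

        rows = []
        fits: dict[int, np.ndarray] = {}
        for k in orders:
            if n_distinct < k + 1:
                rows.append((k, np.inf, -np.inf, False, np.inf))
                continue
            V = np.vander(xs, k + 1)  # columns highest degree first
            cond = float(np.linalg.cond(V))
            coef_s, _, rank, _ = np.linalg.lstsq(V, yv, rcond=None)
            cond_ok = cond <= self.condition_limit and rank == k + 1
            resid = yv - V @ coef_s
            sse = float(resid @ resid)
            r2 = 1.0 - sse / sstot if sstot > 0 else 1.0
            rows.append((k, sse, r2, cond_ok, cond))
            if cond_ok:
                fits[k] = coef_s

        diag = pd.DataFrame(
            rows, columns=["order", "sse", "r2", "condition_ok", "condition_number"]
        )
        if not fits:
            raise CalibrationError(
                "all candidate orders are rank deficient or badly conditioned"
            )

        ok = diag[diag["condition_ok"]]
        sse_min = float(ok["sse"].min())
        tie_tol = _SSE_TIE_RTOL * max(sstot, 1.0)
        tied = ok[ok["sse"] <= sse_min + tie_tol]
        selected = int(tied["order"].min())
        diag["selected"] = diag["order"] == selected

        # Map scaled-basis coefficients back to the raw-HU basis by
        # composing with (x - mid) / half.
        poly_scaled = np.polynomial.Polynomial(fits[selected][::-1])
        shift = np.polynomial.Polynomial([-mid / half, 1.0 / half])
        poly_raw = poly_scaled(shift)
        coeffs = np.zeros(selected + 1)
        coeffs[selected - len(poly_raw.coef) + 1:] = poly_raw.coef[::-1]

        row = diag.loc[diag["order"] == selected].iloc[0]
        self.order_ = selected
        self.coeffs_ = coeffs
        self.diagnostics_ = diag
        self.curve_ = CalibrationCurve(
            order=selected,
            coeffs=tuple(coeffs),
            domain=(lo, hi),
            sse=float(row["sse"]),
            r2=float(row["r2"]),
            condition_ok=bool(row["condition_ok"]),
            condition_number=float(row["condition_number"]),
            meta={
                "n_pairs": int(x.size),
                "candidate_orders": orders,
                "fitted_at": datetime.datetime.now().isoformat(timespec="seconds"),
            },
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Evaluate the selected calibration polynomial at HU value(s)."""
        check_is_fitted(self, "curve_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        lo, hi = self.curve_.domain
        if x.size and (x.min() < lo or x.max() > hi):
            logger.info(
                "evaluating calibration outside fitted domain [%.1f, %.1f]", lo, hi
            )
        return np.polyval(self.coeffs_, x)

    def transform_volume(self, volume: CTVolume, force: bool = False) -> CTVolume:
        """Apply the calibration voxel-wise to an LDCT volume.

        Returns a new volume with protocol ``cLDCT``; geometry and any mask
        association are untouched.  Refuses a badly conditioned curve
        unless ``force`` is set.
        """
        check_is_fitted(self, "curve_")
        return apply_calibration(volume, self.curve_, force=force)


# ---------------------------------------------------------------------------
# ROI measurement on phantom volumes
# ---------------------------------------------------------------------------

def measure_insert_hu(
    volume: CTVolume,
    spec: PhantomSpec,
    roi_diameter_mm: float = 20.0,
    n_central_slices: int = 3,
) -> pd.DataFrame:
    """Mean HU in a circular ROI at the center of each rod insert.

    A disc of the requested diameter (default 2 cm) is placed at each
    insert center; voxels whose in-plane centers fall inside the disc are
    averaged over the central slice span of the phantom (default: middle 3
    slices).  If the ROI does not fit inside an insert it is shrunk to the
    insert radius with a logged warning.

    Returns a DataFrame with columns ``variant, insert, mean_hu, n_voxels``.
    """
    n_slices = volume.shape[0]
    k = min(n_central_slices, n_slices)
    s0 = (n_slices - k) // 2
    central = volume.voxels[s0:s0 + k]

    ymm, xmm = volume.inplane_coords_mm()
    half_extent_y = np.abs(ymm).max()
    half_extent_x = np.abs(xmm).max()

    records = []
    for ins in spec.inserts:
        cx, cy = ins.center
        if abs(cx) > half_extent_x or abs(cy) > half_extent_y:
            raise GeometryError(
                f"insert {ins.name} center {ins.center} outside the volume"
            )
        roi_r = roi_diameter_mm / 2.0
        if roi_r > ins.radius:
            logger.warning(
                "ROI radius %.1f mm exceeds insert %s radius %.1f mm; shrinking",
                roi_r, ins.name, ins.radius,
            )
            roi_r = ins.radius
        disc = (xmm - cx) ** 2 + (ymm - cy) ** 2 <= roi_r ** 2
        n_vox = int(disc.sum()) * k
        if n_vox == 0:
            raise GeometryError(
                f"ROI for insert {ins.name} contains no voxel centers"
            )
        records.append((spec.variant, ins.name, float(central[:, disc].mean()), n_vox))
    return pd.DataFrame(records, columns=["variant", "insert", "mean_hu", "n_voxels"])


def build_pair_table(
    ldct_measurements: pd.DataFrame, csct_measurements: pd.DataFrame
) -> HUPairTable:
    """Join per-insert ROI means from the two protocols into a pair table."""
    merged = pd.merge(
        ldct_measurements.rename(columns={"mean_hu": "ldct_hu"}),
        csct_measurements.rename(columns={"mean_hu": "csct_hu"}),
        on=["variant", "insert"],
        validate="one_to_one",
    )
    return HUPairTable(merged[["variant", "insert", "ldct_hu", "csct_hu"]])


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def fit_calibration(
    pairs: HUPairTable | pd.DataFrame,
    candidate_orders: Sequence[int] = (1, 2, 3),
    max_order: int = 3,
    order: int | None = None,
) -> tuple[CalibrationCurve, pd.DataFrame]:
    """Fit the calibration curve from a pair table.

    Returns ``(curve, diagnostics)`` where diagnostics is the per-order
    (sse, r2, condition) table from :class:`HUCalibrator`.
    """
    table = pairs if isinstance(pairs, HUPairTable) else HUPairTable(pairs)
    est = HUCalibrator(
        candidate_orders=candidate_orders, max_order=max_order, order=order
    )
    est.fit(table.ldct_hu, table.csct_hu)
    return est.curve_, est.diagnostics_


def apply_calibration(
    volume: CTVolume, curve: CalibrationCurve, force: bool = False
) -> CTVolume:
    """Map every voxel of an LDCT volume through the calibration polynomial.

    The result carries protocol ``cLDCT`` and records curve provenance in
    its metadata.  Only LDCT volumes may be calibrated (a CSCT volume is
    already on the reference scale).
    """
    if volume.protocol is not Protocol.LDCT:
        raise ValueError(
            f"apply_calibration requires an LDCT volume, got {volume.protocol.value}"
        )
    if not curve.condition_ok and not force:
        raise CalibrationError(
            "refusing badly conditioned calibration curve (pass force=True)"
        )
    lo, hi = curve.domain
    vmin, vmax = float(volume.voxels.min()), float(volume.voxels.max())
    if vmin < lo or vmax > hi:
        logger.info(
            "volume HU range [%.0f, %.0f] extends beyond fitted domain "
            "[%.0f, %.0f]; extrapolating", vmin, vmax, lo, hi,
        )
    return volume.copy_with(
        voxels=np.polyval(curve.coeffs, volume.voxels),
        protocol=Protocol.CLDCT,
        extra_meta={
            "calibration": {
                "order": curve.order,
                "coeffs_highest_first": list(curve.coeffs),
                "r2": curve.r2,
            }
        },
    )


def invert_curve(
    curve: CalibrationCurve,
    csct_hu,
    bracket: tuple[float, float] = (-3000.0, 5000.0),
    tol: float = 1e-6,
) -> float | np.ndarray:
    """Solve ``curve(x) = csct_hu`` by bisection on a monotone bracket."""
    try:
        return bisect_monotone_inverse(curve.__call__, csct_hu, bracket, tol)
    except TransferModelError as exc:
        raise CalibrationError(str(exc)) from exc
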