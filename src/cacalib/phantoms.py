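"""Electron-density phantom specifications and the spectral transfer model.

The digital phantoms emulate a four-variant electron-density (ED)
calibration phantom family: a core cylinder with nine tissue/bone
equivalent rod inserts (ED1, 18 cm diameter), the same core wrapped in one
or two soft-tissue bolus layers (ED2, 23 cm; ED3, 28 cm), and the core
surrounded by an elliptical annulus carrying eight further rod inserts
(ED4, 32 x 27 cm).  Nominal insert HU values at the calcium-scoring
protocol's effective energy are configuration defaults loaded from
``data/ed_phantoms.json``.

The :class:`TransferModel` captures the spectral HU shift between the
silver-filtered low-dose chest protocol (LDCT) and the copper-filtered
calcium-scoring protocol (CSCT) as a strictly increasing forward mapping
LDCT-HU -> CSCT-HU.  The simulator evaluates its numeric inverse to place
known CSCT-energy materials on the LDCT scale; the calibration module's
job is to recover the forward mapping from phantom measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable

import numpy as np

__all__ = [
    "EQ1_COEFFS",
    "eq1_forward",
    "InsertSpec",
    "PhantomSpec",
    "TransferModel",
    "default_phantom_spec",
    "default_transfer_model",
    "identity_transfer_model",
    "PhantomSpecError",
    "TransferModelError",
]

#: Cubic LDCT->CSCT mapping coefficients, highest degree first.  This is the
#: calibration polynomial for the silver-filter LDCT / copper-filter CSCT
#: protocol pair; its derivative has negative discriminant, so the cubic is
#: strictly increasing on the whole HU axis.
EQ1_COEFFS: tuple[float, float, float, float] = (3.871e-7, -8.504e-4, 1.453, -12.97)

#: Default per-protocol image noise (HU SD), matching the tube-current
#: modulation noise targets of the two protocols.
DEFAULT_NOISE_SD = {"CSCT": 30.0, "LDCT": 15.0}


def eq1_forward(ldct_hu):
    """Evaluate the default cubic spectral mapping LDCT-HU -> CSCT-HU."""
    return np.polyval(EQ1_COEFFS, ldct_hu)


class PhantomSpecError(ValueError):
    """Raised for geometrically invalid phantom specifications."""


class TransferModelError(ValueError):
    """Raised when a transfer function is not strictly increasing."""


@dataclass(frozen=True)
class InsertSpec:
    """One cylindrical rod insert: material, in-plane center, radius, HU."""

    name: str
    center: tuple[float, float]  # (x_mm, y_mm), origin at phantom center
    radius: float  # mm
    csct_hu: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise PhantomSpecError(f"insert {self.name}: radius must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """One ED phantom variant: elliptical body plus rod inserts."""

    variant: str  # ED1..ED4
    body_axes: tuple[float, float]  # full (long_mm, short_mm) diameters
    body_hu: float
    inserts: tuple[InsertSpec, ...]

    def __post_init__(self) -> None:
        a, b = self.body_axes[0] / 2.0, self.body_axes[1] / 2.0
        for ins in self.inserts:
            x, y = ins.center
            # Insert must sit fully inside the elliptical body boundary.
            scale = (x / a) ** 2 + (y / b) ** 2
            margin = ins.radius / min(a, b)
            if np.sqrt(scale) + margin > 1.0 + 1e-9:
                raise PhantomSpecError(
                    f"{self.variant}: insert {ins.name} at {ins.center} "
                    f"extends outside the body"
                )
        for i, p in enumerate(self.inserts):
            for q in self.inserts[i + 1:]:
                d = np.hypot(p.center[0] - q.center[0], p.center[1] - q.center[1])
                if d < p.radius + q.radius - 1e-9:
                    raise PhantomSpecError(
                        f"{self.variant}: inserts {p.name} and {q.name} overlap"
                    )


def _load_config() -> dict:
    with resources.files("cacalib.data").joinpath("ed_phantoms.json").open() as fh:
        return json.load(fh)


def default_phantom_spec(variant: str, config: dict | None = None) -> PhantomSpec:
    """Build the default spec for a phantom variant (ED1, ED2, ED3 or ED4).

    ED1-ED3 share the nine-insert core layout (one central rod plus eight on
    a ring); ED2/ED3 differ only in body diameter (bolus layers are uniform
    soft tissue).  ED4 adds eight rods on an outer elliptical ring.
    """
    cfg = config or _load_config()
    if variant not in cfg["variants"]:
        raise PhantomSpecError(f"unknown phantom variant {variant!r}")
    hu = cfg["insert_hu_csct"]
    r = float(cfg["insert_radius_mm"])

    inserts: list[InsertSpec] = []
    core = cfg["core_inserts"]
    ring_r = float(cfg["core_ring_radius_mm"])
    inserts.append(InsertSpec(core[0], (0.0, 0.0), r, hu[core[0]]))
    for k, name in enumerate(core[1:]):
        theta = 2 * np.pi * k / (len(core) - 1)
        inserts.append(
            InsertSpec(name, (ring_r * np.cos(theta), ring_r * np.sin(theta)),
                       r, hu[name])
        )
    if variant == "ED4":
        ax, ay = cfg["outer_ring_axes_mm"]
        outer = cfg["outer_inserts"]
        for k, name in enumerate(outer):
            # Offset half a step so outer rods interleave with the core ring;
            # annulus rods get an "_outer" suffix so (variant, insert) names
            # stay unique even for materials repeated from the core.
            theta = 2 * np.pi * (k + 0.5) / len(outer)
            inserts.append(
                InsertSpec(f"{name}_outer",
                           (ax * np.cos(theta), ay * np.sin(theta)),
                           r, hu[name])
            )

    axes = tuple(cfg["variants"][variant]["body_axes_mm"])
    return PhantomSpec(
        variant=variant,
        body_axes=(float(axes[0]), float(axes[1])),
        body_hu=float(cfg["body_hu"]),
        inserts=tuple(inserts),
    )


@dataclass
class TransferModel:
    """Ground-truth spectral relation between the two protocols.

    ``forward`` maps LDCT HU to CSCT HU and must be strictly increasing on
    [-1024, 3000] (checked on a 1-HU grid at construction).  The inverse is
    evaluated numerically by vectorized bisection, so any monotone callable
    can be substituted for the default cubic.
    """

    forward: Callable[[np.ndarray], np.ndarray] = eq1_forward
    noise_sd_csct: float = DEFAULT_NOISE_SD["CSCT"]
    noise_sd_ldct: float = DEFAULT_NOISE_SD["LDCT"]
    check_domain: tuple[float, float] = (-1024.0, 3000.0)

    def __post_init__(self) -> None:
        self.validate_monotone()

    def validate_monotone(self) -> None:
        lo, hi = self.check_domain
        grid = np.arange(lo, hi + 1.0, 1.0)
        vals = np.asarray(self.forward(grid), dtype=float)
        if not np.all(np.diff(vals) > 0):
            raise TransferModelError(
                "transfer forward mapping is not strictly increasing on "
                f"[{lo}, {hi}]"
            )

    def inverse(
        self,
        csct_hu,
        bracket: tuple[float, float] = (-3000.0, 5000.0),
        tol: float = 1e-6,
    ) -> np.ndarray:
        """Invert the forward mapping by bisection, elementwise."""
        return bisect_monotone_inverse(self.forward, csct_hu, bracket, tol)


def bisect_monotone_inverse(
    forward: Callable[[np.ndarray], np.ndarray],
    y,
    bracket: tuple[float, float] = (-3000.0, 5000.0),
    tol: float = 1e-6,
):
    """Elementwise bisection inverse of an increasing function.

    Bisection runs until the bracket width falls below ``tol`` (HU), which
    for mappings with slope of order 1 also bounds ``|forward(x) - y|``.
    Raises :class:`TransferModelError` when a target lies outside the
    forward image of the bracket (no sign change).
    """
    yv = np.asarray(y, dtype=float)
    lo = np.full(yv.shape, float(bracket[0]))
    hi = np.full(yv.shape, float(bracket[1]))
    flo = np.asarray(forward(lo), dtype=float)
    fhi = np.asarray(forward(hi), dtype=float)
    if np.any(flo > yv) or np.any(fhi < yv):
        raise TransferModelError(
            f"target HU outside the forward range of the bracket {bracket}"
        )
    n_iter = int(np.ceil(np.log2((bracket[1] - bracket[0]) / tol)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        fmid = np.asarray(forward(mid), dtype=float)
        take_hi = fmid < yv
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    out = 0.5 * (lo + hi)
    return out if out.shape else float(out)


def default_transfer_model(**kwargs) -> TransferModel:
    """Transfer model with the default cubic forward and protocol noise."""
    return TransferModel(forward=eq1_forward, **kwargs)


def identity_transfer_model(noise_sd_csct: float = 0.0,
                            noise_sd_ldct: float = 0.0) -> TransferModel:
    """Transfer model with no spectral shift (useful for null tests)."""
    return TransferModel(
        forward=lambda x: np.asarray(x, dtype=float) + 0.0,
        noise_sd_csct=noise_sd_csct,
        noise_sd_ldct=noise_sd_ldct,
    )
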