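"""Agreement statistics for paired calcium-score comparisons.

Implements the comparison machinery used to judge whether calibrated
low-dose scores agree with the gated reference: ordinary least-squares
regression with r^2, Bland-Altman bias and 95% limits of agreement, and
two-sample t-tests (Welch by default, pooled optionally), plus cohort-level
tables stratified by heart-rate subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import CACReport
from .volume import ARTERY_NAMES

__all__ = [
    "AgreementResult",
    "TTestResult",
    "SubgroupSpec",
    "regress_and_correlate",
    "bland_altman",
    "two_sample_ttest",
    "cohort_compare",
]


@dataclass(frozen=True)
class AgreementResult:
    """Regression + Bland-Altman summary for one score pairing (B vs A)."""

    n: int
    slope: float
    intercept: float
    r2: float
    bias: float          # mean(B - A)
    loa_low: float       # bias - z_(1-alpha/2) * SD(B - A)
    loa_high: float
    alpha: float = 0.05

    @property
    def loa_half_width(self) -> float:
        """Half-width of the limits of agreement (the '± LoA' figure)."""
        return (self.loa_high - self.loa_low) / 2.0


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    variant: str  # "welch" | "pooled"


def _as_pair(a, b, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if av.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {av.size}")
    if not (np.isfinite(av).all() and np.isfinite(bv).all()):
        raise ValueError("non-finite values in score lists")
    return av, bv


def regress_and_correlate(a, b) -> tuple[float, float, float]:
    """OLS of b on a; returns (slope, intercept, r2 = squared Pearson r)."""
    av, bv = _as_pair(a, b, min_n=3)
    if np.var(av) == 0:
        raise ValueError("zero variance in the predictor scores")
    res = sps.linregress(av, bv)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def bland_altman(a, b, alpha: float = 0.05) -> AgreementResult:
    """Bland-Altman agreement of b against a.

    Differences d = b - a; bias = mean(d); limits of agreement are
    bias +/- z_(1-alpha/2) * SD(d) with the n-1 SD denominator
    (z = 1.959964 at alpha = 0.05).  The regression fields come from OLS
    of b on a when n >= 3 and the predictor is non-constant, else NaN.
    """
    av, bv = _as_pair(a, b, min_n=2)
    d = bv - av
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    z = float(sps.norm.ppf(1 - alpha / 2))
    try:
        slope, intercept, r2 = regress_and_correlate(av, bv)
    except ValueError:
        slope = intercept = r2 = float("nan")
    return AgreementResult(
        n=int(av.size),
        slope=slope,
        intercept=intercept,
        r2=r2,
        bias=bias,
        loa_low=bias - z * sd,
        loa_high=bias + z * sd,
        alpha=alpha,
    )


def two_sample_ttest(a, b, variant: str = "welch") -> TTestResult:
    """Two-sided two-sample t-test of a vs b.

    ``welch`` (default) uses unequal variances with Satterthwaite degrees
    of freedom; ``pooled`` assumes equal variances with df = n1 + n2 - 2.
    Identical constant samples have no within-group variance and raise.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size < 2 or bv.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(av, ddof=1) == 0 and np.var(bv, ddof=1) == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    if variant == "welch":
        res = sps.ttest_ind(av, bv, equal_var=False)
        df = float(res.df)
    elif variant == "pooled":
        res = sps.ttest_ind(av, bv, equal_var=True)
        df = float(av.size + bv.size - 2)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    return TTestResult(float(res.statistic), df, float(res.pvalue), variant)


@dataclass
class SubgroupSpec:
    """Rule mapping per-patient metadata to a subgroup label.

    The default emulates four-way heart-rate stratification: diastolic
    reconstructions split at < 60, 60-65 and > 65 bpm, plus a systolic
    group.  Any callable ``meta_row -> label`` may be substituted.
    """

    rule: Callable[[Mapping], str] | None = None

    def __call__(self, meta_row: Mapping) -> str:
        if self.rule is not None:
            return self.rule(meta_row)
        if "subgroup" in meta_row and isinstance(meta_row["subgroup"], str):
            return meta_row["subgroup"]
        if meta_row.get("phase") == "systole":
            return "systole"
        hr = float(meta_row["hr_bpm"])
        if hr < 60:
            return "diastole_hr_lt60"
        if hr <= 65:
            return "diastole_hr_60_65"
        return "diastole_hr_gt65"


_PAIRINGS = (("CSCT", "LDCT"), ("CSCT", "cLDCT"))
_SCORE_GETTERS = {
    "total_agatston": lambda r: r.total_agatston,
    "total_volume_mm3": lambda r: r.total_volume_mm3,
}


def cohort_compare(
    manifest: pd.DataFrame,
    reports: Mapping[str, Mapping[str, CACReport]],
    subgroups: SubgroupSpec | None = None,
    alpha: float = 0.05,
    ttest_variant: str = "welch",
) -> dict[str, pd.DataFrame]:
    """Protocol agreement and per-artery comparison tables for a cohort.

    Parameters
    ----------
    manifest : DataFrame
        One row per patient with at least ``patient_id`` and whatever the
        subgroup rule needs (a ``subgroup`` column is used directly).
    reports : mapping patient_id -> {protocol -> CACReport}
        Per-patient reports for protocols CSCT, LDCT and cLDCT.  Patients
        missing any report are excluded with a warning entry.
    subgroups : SubgroupSpec, optional

    Returns
    -------
    dict with
      ``agreement``: one row per (pairing, score type, subgroup incl. "all")
      with n, slope, intercept, r2, bias, loa_low, loa_high, loa_half_width;
      ``per_artery``: per (pairing, artery) mean/SD of each protocol's
      Agatston score and the t-test p-value;
      ``excluded``: patients dropped for missing reports.
    """
    spec = subgroups or SubgroupSpec()
    rows, excluded = [], []
    for _, row in manifest.iterrows():
        pid = row["patient_id"]
        prot_reports = reports.get(pid, {})
        missing = [p for p in ("CSCT", "LDCT", "cLDCT") if p not in prot_reports]
        if missing:
            excluded.append({"patient_id": pid, "missing": ",".join(missing)})
            continue
        entry = {"patient_id": pid, "subgroup": spec(row)}
        for prot in ("CSCT", "LDCT", "cLDCT"):
            rep = prot_reports[prot]
            for score_name, getter in _SCORE_GETTERS.items():
                entry[f"{prot}_{score_name}"] = getter(rep)
            for artery in ARTERY_NAMES:
                entry[f"{prot}_agatston_{artery}"] = rep.agatston[artery]
        rows.append(entry)
    if excluded:
        import warnings

        warnings.warn(
            f"excluding {len(excluded)} patient(s) with missing reports",
            stacklevel=2,
        )
    scores = pd.DataFrame(rows)
    if scores.empty:
        raise ValueError("no patient has a complete set of reports")

    agreement_rows = []
    group_frames = [("all", scores)] + [
        (name, g) for name, g in scores.groupby("subgroup", sort=True)
    ]
    for ref, other in _PAIRINGS:
        for score_name in _SCORE_GETTERS:
            for group_name, g in group_frames:
                if len(g) < 2:
                    continue
                res = bland_altman(
                    g[f"{ref}_{score_name}"], g[f"{other}_{score_name}"],
                    alpha=alpha,
                )
                agreement_rows.append({
                    "pairing": f"{ref}_vs_{other}",
                    "score": score_name,
                    "subgroup": group_name,
                    "n": res.n,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r2": res.r2,
                    "bias": res.bias,
                    "loa_low": res.loa_low,
                    "loa_high": res.loa_high,
                    "loa_half_width": res.loa_half_width,
                })
    agreement = pd.DataFrame(agreement_rows)

    artery_rows = []
    for ref, other in _PAIRINGS:
        for artery in ARTERY_NAMES:
            x = scores[f"{ref}_agatston_{artery}"].to_numpy()
            y = scores[f"{other}_agatston_{artery}"].to_numpy()
            try:
                tt = two_sample_ttest(x, y, variant=ttest_variant)
                p, t = tt.p_value, tt.statistic
            except ValueError:
                p = t = float("nan")
            artery_rows.append({
                "pairing": f"{ref}_vs_{other}",
                "artery": artery,
                f"mean_{ref}": float(x.mean()),
                f"sd_{ref}": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
                f"mean_{other}": float(y.mean()),
                f"sd_{other}": float(y.std(ddof=1)) if y.size > 1 else float("nan"),
                "t_statistic": t,
                "p_value": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            })
    per_artery = pd.DataFrame(artery_rows)

    return {
        "agreement": agreement,
        "per_artery": per_artery,
        "excluded": pd.DataFrame(excluded, columns=["patient_id", "missing"]),
        "scores": scores,
    }


def plot_bland_altman(a, b, ax=None, alpha: float = 0.05):
    """Scatter of differences vs means with bias and LoA lines (optional)."""
    import matplotlib.pyplot as plt

    av, bv = _as_pair(a, b, min_n=2)
    res = bland_altman(av, bv, alpha=alpha)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((av + bv) / 2.0, bv - av, s=12)
    for y, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=0.8)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (B - A)")
    return ax
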