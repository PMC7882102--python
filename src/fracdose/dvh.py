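"""Cumulative dose-volume histograms and the Dq% / Dmean summary metrics.

Dq% — the minimum dose received by the hottest q% of an ROI's volume — is
computed from exact voxel ranks, not from a binned curve.  With N in-ROI
voxel doses sorted in descending order ``d_(1) >= ... >= d_(N)``, the target
rank is ``k = q/100 * N`` and Dq% is the linear interpolation of the order
statistics at fractional rank k (clamped to [1, N]).  For q -> 100 this
recovers the in-ROI minimum.  The binned cumulative curve exists for plotting
and export only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateROIError, ParameterError
from .grids import DoseGrid, StructureMask, same_grid


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of ROI volume receiving at least each bin dose."""

    bin_edges: np.ndarray
    cum_volume_fraction: np.ndarray
    roi: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_Gy": self.bin_edges, "volume_fraction": self.cum_volume_fraction}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class DVHMetrics:
    """Near-minimum (D98%), near-maximum (D2%) and mean dose of one ROI."""

    roi: str
    d98: float
    d2: float
    dmean: float
    prescription: float = 0.0

    def as_dict(self) -> dict:
        return {"roi": self.roi, "d98": self.d98, "d2": self.d2, "dmean": self.dmean}


def roi_doses(dose: DoseGrid, roi: StructureMask) -> np.ndarray:
    """In-ROI voxel doses; the substrate for every metric below."""
    if not same_grid(dose, roi):
        raise ParameterError("dose and ROI must be on the same grid (resample the ROI first)")
    if not roi.mask.any():
        raise DegenerateROIError(f"ROI {roi.name!r} is empty")
    return dose.dose[roi.mask]


def compute_dvh(dose: DoseGrid, roi: StructureMask, bin_width: float = 0.05) -> DVHCurve:
    """Cumulative DVH from a differential histogram of in-ROI voxel doses.

    Bin edges run from 0 to just above the ROI maximum in uniform steps of
    ``bin_width`` Gy; ``cum_volume_fraction[i]`` is the fraction of ROI volume
    with dose >= ``bin_edges[i]``.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    voxels = roi_doses(dose, roi)
    n_bins = int(np.ceil((voxels.max() + bin_width) / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(voxels, bins=edges)
    cum = np.concatenate([np.cumsum(hist[::-1])[::-1], [0]]) / voxels.size
    return DVHCurve(bin_edges=edges, cum_volume_fraction=cum, roi=roi.name)


def dose_at_volume(voxels_or_curve, q_percent: float) -> float:
    """Dq%: minimum dose received by the hottest ``q_percent`` of ROI volume.

    Accepts either the raw in-ROI voxel doses (exact rank interpolation,
    preferred) or a :class:`DVHCurve` (inverse-reads the binned curve).
    """
    if not 0 < q_percent < 100:
        raise ParameterError("q_percent must lie strictly between 0 and 100")
    if isinstance(voxels_or_curve, DVHCurve):
        curve = voxels_or_curve
        frac = q_percent / 100.0
        # cum_volume_fraction is non-increasing in dose; invert by interpolation
        cv = curve.cum_volume_fraction[::-1]
        dv = curve.bin_edges[::-1]
        return float(np.interp(frac, cv, dv))
    voxels = np.asarray(voxels_or_curve, dtype=float).reshape(-1)
    if voxels.size == 0:
        raise DegenerateROIError("no voxel doses supplied")
    d_desc = np.sort(voxels)[::-1]
    n = d_desc.size
    k = q_percent / 100.0 * n
    if k <= 1:
        return float(d_desc[0])
    if k >= n:
        return float(d_desc[-1])
    return float(np.interp(k, np.arange(1, n + 1), d_desc))


def mean_dose(dose: DoseGrid, roi: StructureMask) -> float:
    """Arithmetic mean of in-ROI voxel doses (Gy)."""
    return float(roi_doses(dose, roi).mean())


def dvh_metrics(dose: DoseGrid, roi: StructureMask, prescription: float = 0.0) -> DVHMetrics:
    """D98%, D2% and Dmean of one ROI in a single pass."""
    voxels = roi_doses(dose, roi)
    return DVHMetrics(
        roi=roi.name,
        d98=dose_at_volume(voxels, 98.0),
        d2=dose_at_volume(voxels, 2.0),
        dmean=float(voxels.mean()),
        prescription=prescription,
    )


def relative_difference(planned: DVHMetrics, delivered: DVHMetrics) -> dict:
    """Signed relative differences, 100 * (planned - delivered) / planned, per metric.

    Positive values mean the delivered dose is lower than planned (underdose).
    Normalization is by the planned metric value; normalizing by prescription
    instead is a caller-side choice.
    """
    if planned.roi != delivered.roi:
        raise ParameterError(
            f"metrics compare different ROIs: {planned.roi!r} vs {delivered.roi!r}"
        )
    out = {}
    for key in ("d98", "d2", "dmean"):
        p = getattr(planned, key)
        d = getattr(delivered, key)
        if p == 0:
            raise ParameterError(f"planned {key} is zero; relative difference undefined")
        out[key] = 100.0 * (p - d) / p
    return out


@dataclass
class PlanGoal:
    """One coverage goal: volume fraction receiving >= threshold compared to a bound."""

    description: str
    threshold_gy: float
    required_fraction: float
    comparison: str  # "ge" or "eq"
    achieved_fraction: float
    passed: bool


def evaluate_plan_goals(
    dose: DoseGrid, ptv: StructureMask, prescription: float
) -> list[PlanGoal]:
    """Check the three PTV coverage goals of the treatment protocol.

    For prescription Rx: V(Rx) >= 50%, V(0.98 Rx) >= 95%, V(1.10 Rx) = 0%.
    At the 50.4 Gy prescription the thresholds are 50.4, 49.392 and 55.44 Gy.
    """
    if prescription <= 0:
        raise ParameterError("prescription must be positive")
    voxels = roi_doses(dose, ptv)
    n = voxels.size

    def vol_frac(threshold: float) -> float:
        return float(np.count_nonzero(voxels >= threshold)) / n

    specs = [
        ("V(Rx) >= 50%", prescription, 0.50, "ge"),
        ("V(0.98 Rx) >= 95%", 0.98 * prescription, 0.95, "ge"),
        ("V(1.10 Rx) = 0%", 1.10 * prescription, 0.0, "eq"),
    ]
    goals = []
    for desc, thr, req, cmp in specs:
        achieved = vol_frac(thr)
        passed = achieved >= req if cmp == "ge" else achieved == req
        goals.append(PlanGoal(desc, thr, req, cmp, achieved, passed))
    return goals


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-ROI difference rows into the standard report layout."""
    return pd.DataFrame(rows, columns=["roi", "dd98_pct", "dd2_pct", "ddmean_pct"])
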