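"""Trajectory-log parsing and machine-control error statistics.

A trajectory log holds time-sampled expected ("planned") and actual
("recorded") machine axis values — per-leaf MLC positions for both banks,
cumulative monitor units, gantry angle and jaw positions — at a fixed
sampling interval (20 ms on the modeled machine).  The reference dialect is a
plain-text record schema (one sample per line, documented column order) so
logs are portable and diffable; vendor binaries can be added as extra
dialects.

MLC leaf positions are tip coordinates along the leaf-travel axis (x, mm):
bank A approaches from negative x, bank B from positive x, so a pair's gap is
``bank_b - bank_a >= 0`` when open.  MLC error statistics pool signed
per-leaf differences (actual - expected) over all leaves and samples by
default; MU error statistics default to the mean +/- SD of absolute
cumulative-MU differences, with a signed variant behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FormatError,
    IntegrityError,
    ParameterError,
)

#: Millennium-120 leaf-pair widths (mm): 10 outer 10 mm, 40 central 5 mm, 10 outer 10 mm.
MILLENNIUM_120_WIDTHS = np.concatenate([np.full(10, 10.0), np.full(40, 5.0), np.full(10, 10.0)])

#: Maximum leaf speed of the modeled machine (mm/s).
MAX_LEAF_SPEED_MM_S = 25.0

_LOG_MAGIC = "fracdose-trajectory-log 1"


def _pair_edges(leaf_widths: np.ndarray) -> np.ndarray:
    """Leaf-pair boundary coordinates (mm) on the perpendicular axis, centered on 0."""
    edges = np.concatenate([[0.0], np.cumsum(leaf_widths)])
    return edges - edges[-1] / 2.0


@dataclass
class TrajectoryLog:
    """Time-sampled expected/actual machine axis values for one beam."""

    sampling_interval_ms: float
    beam_id: str
    mu_expected: np.ndarray  # (n,) cumulative MU
    mu_actual: np.ndarray
    gantry_expected: np.ndarray  # (n,) deg
    gantry_actual: np.ndarray
    jaw_expected: np.ndarray  # (n, 4): x1 x2 y1 y2 mm
    jaw_actual: np.ndarray
    bank_a_expected: np.ndarray  # (n, n_pairs) mm
    bank_a_actual: np.ndarray
    bank_b_expected: np.ndarray
    bank_b_actual: np.ndarray

    def __post_init__(self):
        for name in (
            "mu_expected", "mu_actual", "gantry_expected", "gantry_actual",
            "jaw_expected", "jaw_actual", "bank_a_expected", "bank_a_actual",
            "bank_b_expected", "bank_b_actual",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.sampling_interval_ms <= 0:
            raise ParameterError("sampling_interval_ms must be positive")
        n = self.mu_expected.size
        shapes_ok = (
            self.mu_actual.size == n
            and self.gantry_expected.size == n
            and self.gantry_actual.size == n
            and self.jaw_expected.shape == (n, 4)
            and self.jaw_actual.shape == (n, 4)
            and self.bank_a_expected.shape == self.bank_a_actual.shape
            and self.bank_a_expected.shape == self.bank_b_expected.shape
            and self.bank_b_expected.shape == self.bank_b_actual.shape
            and self.bank_a_expected.shape[0] == n
        )
        if not shapes_ok:
            raise IntegrityError("log streams have inconsistent shapes")
        for label, mu in (("expected", self.mu_expected), ("actual", self.mu_actual)):
            if np.any(np.diff(mu) < 0):
                idx = int(np.argmax(np.diff(mu) < 0)) + 1
                raise IntegrityError(f"{label} cumulative MU decreases at sample {idx}")

    @property
    def n_samples(self) -> int:
        return self.mu_expected.size

    @property
    def n_leaf_pairs(self) -> int:
        return self.bank_a_expected.shape[1]

    def mlc_differences(self, moving_only: bool = False) -> np.ndarray:
        """Signed per-leaf per-sample position differences (actual - expected), pooled.

        With ``moving_only`` a leaf contributes only at samples where its
        expected position changes from the previous sample.
        """
        diff_a = self.bank_a_actual - self.bank_a_expected
        diff_b = self.bank_b_actual - self.bank_b_expected
        if not moving_only:
            return np.concatenate([diff_a.ravel(), diff_b.ravel()])
        out = []
        for exp, diff in ((self.bank_a_expected, diff_a), (self.bank_b_expected, diff_b)):
            moving = np.zeros(exp.shape, dtype=bool)
            moving[1:] = np.abs(np.diff(exp, axis=0)) > 0
            out.append(diff[moving])
        return np.concatenate(out)

    def mu_differences(self) -> np.ndarray:
        """Signed per-sample cumulative-MU differences (actual - expected)."""
        return self.mu_actual - self.mu_expected


@dataclass
class ControlPointSequence:
    """Per-control-point MLC aperture description of one DMLC beam."""

    bank_a: np.ndarray  # (n_cp, n_pairs) mm
    bank_b: np.ndarray
    mu_fraction: np.ndarray  # (n_cp,) in [0, 1], non-decreasing
    leaf_widths: np.ndarray = field(default_factory=lambda: MILLENNIUM_120_WIDTHS.copy())
    jaw: np.ndarray = field(default_factory=lambda: np.array([-60.0, 60.0, -60.0, 60.0]))
    total_mu: float = 0.0
    closed_gap_mm: float = 0.5

    def __post_init__(self):
        self.bank_a = np.atleast_2d(np.asarray(self.bank_a, dtype=float))
        self.bank_b = np.atleast_2d(np.asarray(self.bank_b, dtype=float))
        self.mu_fraction = np.asarray(self.mu_fraction, dtype=float).reshape(-1)
        self.leaf_widths = np.asarray(self.leaf_widths, dtype=float).reshape(-1)
        self.jaw = np.asarray(self.jaw, dtype=float).reshape(-1)
        if self.bank_a.shape != self.bank_b.shape:
            raise ParameterError("bank arrays must have equal shapes")
        if self.bank_a.shape[1] != self.leaf_widths.size:
            raise ParameterError("leaf_widths length must match the number of leaf pairs")
        if self.jaw.size != 4:
            raise ParameterError("jaw must be (x1, x2, y1, y2)")
        if self.mu_fraction.size != self.bank_a.shape[0]:
            raise ParameterError("mu_fraction length must match the number of control points")
        if np.any(self.mu_fraction < 0) or np.any(self.mu_fraction > 1):
            raise ParameterError("mu_fraction must lie in [0, 1]")
        if np.any(np.diff(self.mu_fraction) < 0):
            raise ParameterError("mu_fraction must be non-decreasing")
        open_pairs = (self.bank_b - self.bank_a) > self.closed_gap_mm
        if np.any((self.bank_b - self.bank_a)[open_pairs] < 0):  # pragma: no cover
            raise ParameterError("bank B must not cross bank A on open pairs")

    @property
    def n_control_points(self) -> int:
        return self.bank_a.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.bank_a.shape[1]


@dataclass
class LogErrorStats:
    """Pooled MLC-position and MU-delivery error statistics of one or more logs."""

    mlc_mean: float = np.nan  # mm
    mlc_sd: float = np.nan
    mu_mean: float = np.nan  # MU
    mu_sd: float = np.nan
    n_samples: int = 0
    max_abs_mlc: float = np.nan  # mm

    def as_dict(self) -> dict:
        return {
            "mlc_mean_mm": self.mlc_mean,
            "mlc_sd_mm": self.mlc_sd,
            "mu_mean_mu": self.mu_mean,
            "mu_sd_mu": self.mu_sd,
            "max_abs_mlc_mm": self.max_abs_mlc,
            "n_samples": self.n_samples,
        }


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def mlc_error_stats(log: TrajectoryLog, moving_only: bool = False) -> LogErrorStats:
    """Mean, SD and max |error| of signed MLC position differences (mm)."""
    if log.n_samples < 1:
        raise ParameterError("log has no samples")
    diffs = log.mlc_differences(moving_only=moving_only)
    mean, sd = _mean_sd(diffs)
    return LogErrorStats(
        mlc_mean=mean, mlc_sd=sd, n_samples=log.n_samples,
        max_abs_mlc=float(np.abs(diffs).max()),
    )

def mu_error_stats(log: TrajectoryLog, signed: bool = False) -> LogErrorStats:
    """Mean and SD of cumulative-MU delivery differences.

    The default statistic is taken on absolute differences — a delivery-lag
    magnitude; pass ``signed=True`` for the signed variant.
    """
    if log.n_samples < 1:
        raise ParameterError("log has no samples")
    diffs = log.mu_differences()
    if not signed:
        diffs = np.abs(diffs)
    mean, sd = _mean_sd(diffs)
    return LogErrorStats(mu_mean=mean, mu_sd=sd, n_samples=log.n_samples)


def pooled_error_stats(logs, moving_only: bool = False, signed_mu: bool = False) -> LogErrorStats:
    """Error statistics over the concatenated samples of several logs.

    Equivalent to computing the statistics on one log holding all samples, so
    per-beam logs of a fraction can be pooled exactly.
    """
    logs = list(logs)
    if not logs:
        raise ParameterError("no logs supplied")
    mlc = np.concatenate([lg.mlc_differences(moving_only=moving_only) for lg in logs])
    mu = np.concatenate([lg.mu_differences() for lg in logs])
    if not signed_mu:
        mu = np.abs(mu)
    mlc_mean, mlc_sd = _mean_sd(mlc)
    mu_mean, mu_sd = _mean_sd(mu)
    return LogErrorStats(
        mlc_mean=mlc_mean, mlc_sd=mlc_sd, mu_mean=mu_mean, mu_sd=mu_sd,
        n_samples=sum(lg.n_samples for lg in logs), max_abs_mlc=float(np.abs(mlc).max()),
    )


@dataclass
class ApertureStats:
    """Plan aperture parameters averaged over control points."""

    mean_aperture_cm2: float
    mean_gap_mm: float
    total_mu: float
    degenerate: bool = False


def aperture_stats(cps: ControlPointSequence) -> ApertureStats:
    """Mean aperture area, mean open-pair MLC gap and total MU of a plan beam.

    Per control point the aperture area sums, over open leaf pairs inside the
    jaw window, the x-gap clipped to the jaws times the leaf width clipped to
    the jaws.  A pair is open iff its gap exceeds the closed-gap threshold
    (default 0.5 mm); closed pairs parked under the jaws contribute nothing.
    Gap width is the unclipped mean gap of open pairs.  Results are averaged
    over control points.
    """
    if cps.n_control_points < 1:
        raise ParameterError("control point sequence is empty")
    x1, x2, y1, y2 = cps.jaw
    edges = _pair_edges(cps.leaf_widths)
    y_lo, y_hi = edges[:-1], edges[1:]
    width_in_jaw = np.clip(np.minimum(y_hi, y2) - np.maximum(y_lo, y1), 0.0, None)  # (p,)
    gaps = cps.bank_b - cps.bank_a  # (n_cp, p)
    in_jaw = width_in_jaw > 0
    open_pairs = (gaps > cps.closed_gap_mm) & in_jaw[None, :]
    x_open = np.clip(
        np.minimum(cps.bank_b, x2) - np.maximum(cps.bank_a, x1), 0.0, None
    )
    areas_mm2 = np.sum(np.where(open_pairs, x_open * width_in_jaw[None, :], 0.0), axis=1)
    n_open = open_pairs.sum(axis=1)
    degenerate = bool(np.all(n_open == 0))
    if degenerate:
        import warnings

        warnings.warn("no open leaf pairs in any control point; aperture area is 0")
        mean_gap = 0.0
    else:
        with np.errstate(invalid="ignore"):
            per_cp_gap = np.where(
                n_open > 0, np.sum(np.where(open_pairs, gaps, 0.0), axis=1) / np.maximum(n_open, 1), np.nan
            )
        mean_gap = float(np.nanmean(per_cp_gap))
    return ApertureStats(
        mean_aperture_cm2=float(areas_mm2.mean()) / 100.0,
        mean_gap_mm=mean_gap,
        total_mu=float(cps.total_mu),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Tolerance checks
# ---------------------------------------------------------------------------

#: Statistics that a tolerance table may bound (all compared as |value| <= tol).
TOLERANCE_KEYS = ("mlc_mean_mm", "mlc_sd_mm", "max_abs_mlc_mm", "mu_mean_mu", "mu_sd_mu")


def tolerance_check(stats: LogErrorStats, tolerances: dict) -> pd.DataFrame:
    """Flag statistics exceeding configured tolerances.

    ``tolerances`` maps statistic names (subset of :data:`TOLERANCE_KEYS`) to
    bounds; tolerance values come from the user's QA program configuration,
    never from this package.  An empty or unknown-keyed table is rejected.
    """
    if not tolerances:
        raise ConfigurationError("tolerance table is empty")
    unknown = set(tolerances) - set(TOLERANCE_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown tolerance entries: {sorted(unknown)}")
    values = stats.as_dict()
    rows = []
    for key, tol in tolerances.items():
        val = values[key]
        rows.append(
            {"statistic": key, "value": val, "tolerance": tol, "passed": bool(abs(val) <= tol)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Portable text dialect
# ---------------------------------------------------------------------------


def write_log(log: TrajectoryLog, path) -> None:
    """Write the portable plain-text dialect.

    Header comments carry beam metadata; each data line holds, in order:
    ``t_ms  mu_exp mu_act  gantry_exp gantry_act  jaw_exp(4) jaw_act(4)
    bankA_exp(p) bankA_act(p) bankB_exp(p) bankB_act(p)``.
    """
    p = log.n_leaf_pairs
    with open(path, "w") as fh:
        fh.write(f"# {_LOG_MAGIC}\n")
        fh.write(f"# beam_id: {log.beam_id}\n")
        fh.write(f"# sampling_interval_ms: {log.sampling_interval_ms:.17g}\n")
        fh.write(f"# n_leaf_pairs: {p}\n")
        for i in range(log.n_samples):
            row = np.concatenate(
                [
                    [i * log.sampling_interval_ms],
                    [log.mu_expected[i], log.mu_actual[i]],
                    [log.gantry_expected[i], log.gantry_actual[i]],
                    log.jaw_expected[i], log.jaw_actual[i],
                    log.bank_a_expected[i], log.bank_a_actual[i],
                    log.bank_b_expected[i], log.bank_b_actual[i],
                ]
            )
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_log(path, dialect: str = "text") -> TrajectoryLog:
    """Parse a trajectory log; only the portable text dialect is built in.

    Truncated or corrupted records raise an integrity error naming the record
    index rather than being silently clipped.
    """
    if dialect != "text":
        raise FormatError(f"unsupported trajectory-log dialect {dialect!r}")
    meta = {}
    rows = []
    with open(path) as fh:
        first = fh.readline().strip()
        if first != f"# {_LOG_MAGIC}":
            raise FormatError(f"{path}: not a {_LOG_MAGIC} file")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                continue
            rows.append(line)
    try:
        n_pairs = int(meta["n_leaf_pairs"])
        interval = float(meta["sampling_interval_ms"])
        beam_id = meta.get("beam_id", "")
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: missing or malformed header fields") from exc
    n_cols = 1 + 2 + 2 + 8 + 4 * n_pairs
    data = np.empty((len(rows), n_cols))
    for i, line in enumerate(rows):
        parts = line.split()
        if len(parts) != n_cols:
            raise IntegrityError(
                f"{path}: record {i} has {len(parts)} fields, expected {n_cols}"
            )
        try:
            data[i] = [float(v) for v in parts]
        except ValueError as exc:
            raise IntegrityError(f"{path}: record {i} contains a non-numeric field") from exc
    if data.shape[0] == 0:
        raise IntegrityError(f"{path}: log contains no samples")
    c = 1
    mu = data[:, c : c + 2]; c += 2
    gantry = data[:, c : c + 2]; c += 2
    jaw_exp = data[:, c : c + 4]; c += 4
    jaw_act = data[:, c : c + 4]; c += 4
    ba_exp = data[:, c : c + n_pairs]; c += n_pairs
    ba_act = data[:, c : c + n_pairs]; c += n_pairs
    bb_exp = data[:, c : c + n_pairs]; c += n_pairs
    bb_act = data[:, c : c + n_pairs]; c += n_pairs
    return TrajectoryLog(
        sampling_interval_ms=interval,
        beam_id=beam_id,
        mu_expected=mu[:, 0], mu_actual=mu[:, 1],
        gantry_expected=gantry[:, 0], gantry_actual=gantry[:, 1],
        jaw_expected=jaw_exp, jaw_actual=jaw_act,
        bank_a_expected=ba_exp, bank_a_actual=ba_act,
        bank_b_expected=bb_exp, bank_b_actual=bb_act,
    )


def log_qa_report(stats_by_beam: dict, aperture_by_beam: dict | None = None) -> pd.DataFrame:
    """One row per beam: MLC/MU error statistics plus optional aperture parameters."""
    rows = []
    for beam, stats in stats_by_beam.items():
        row = {"beam": beam}
        row.update(stats.as_dict())
        if aperture_by_beam and beam in aperture_by_beam:
            ap = aperture_by_beam[beam]
            row.update(
                {
                    "mean_aperture_cm2": ap.mean_aperture_cm2,
                    "mean_gap_mm": ap.mean_gap_mm,
                    "total_mu": ap.total_mu,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
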