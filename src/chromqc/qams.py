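"""External-standard calibration and single-marker (QAMS) quantitation.

QAMS (quantitative analysis of multi-components by single marker)
quantifies several analytes from one calibrated internal reference.  A
relative correction factor per analyte x,

    f_x = (W_is * A_x) / (W_x * A_is),

is measured on mixed reference solutions (W concentrations, A peak
areas; "is" the internal standard — here forsythoside A).  A sample's
analyte content then follows from the internal standard's content and
the two sample peak areas:

    C_x = (A_x * C_is) / (f_x * A_is),

so only the internal standard needs a calibration curve at assay time.
The external standard method (ESM) — one fitted line per analyte —
serves as the ground truth against which QAMS is validated via relative
errors (RE%), and spike-recovery experiments validate accuracy:

    recovery% = (detected - original) / spiked * 100.

Contents are mg per g of powder: the sample prep dissolves
``sample_mass_g`` in ``extract_volume_mL`` and injects
``injection_volume_uL``, so an on-column amount of m µg corresponds to
m * (V_extract/V_inject) / mass / 1000 mg/g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._report import round_half_up

__all__ = [
    "CalibrationCurve",
    "RCFMeasurement",
    "RCFSet",
    "SamplePrep",
    "RecoveryExperiment",
    "ContentReport",
    "fit_calibration",
    "esm_content",
    "rcf",
    "aggregate_rcf",
    "check_rcf_reproducibility",
    "qams_content",
    "recovery_rate",
    "relative_error",
    "re_summary",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted line area = slope * amount(µg) + intercept with its linear range."""

    analyte: str
    wavelength_nm: float
    slope: float
    intercept: float
    r: float
    linear_range_ug: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"{self.analyte}: slope must be > 0, got {self.slope}")
        lo, hi = self.linear_range_ug
        if not lo < hi:
            raise ValueError(f"{self.analyte}: linear range low must be < high")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"{self.analyte}: |r| must be <= 1, got {self.r}")

    def predict_area(self, amount_ug: float) -> float:
        return self.slope * amount_ug + self.intercept

    def invert(self, area: float) -> float:
        """Amount (µg) producing ``area``; warns outside the linear range."""
        amount = (area - self.intercept) / self.slope
        lo, hi = self.linear_range_ug
        if not lo <= amount <= hi:
            warnings.warn(
                f"{self.analyte} @ {self.wavelength_nm} nm: inverted amount "
                f"{amount:.4g} µg outside linear range [{lo}, {hi}]",
                stacklevel=2,
            )
        return amount


@dataclass(frozen=True)
class RCFMeasurement:
    """One replicate measurement of analyte and internal standard on a mixed solution."""

    analyte: str
    wavelength_nm: float
    W_is: float  # internal standard concentration, µg/mL
    A_is: float  # internal standard peak area
    W_x: float  # analyte concentration, µg/mL
    A_x: float  # analyte peak area

    def __post_init__(self) -> None:
        for name in ("W_is", "A_is", "W_x", "A_x"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class RCFSet:
    analyte: str
    wavelength_nm: float
    replicates: tuple[float, ...]
    mean_f: float
    rsd_pct: float


@dataclass(frozen=True)
class SamplePrep:
    """Extraction constants: mass dissolved, flask volume, injection volume."""

    sample_mass_g: float = 0.5
    extract_volume_mL: float = 25.0
    injection_volume_uL: float = 5.0

    def __post_init__(self) -> None:
        for name in ("sample_mass_g", "extract_volume_mL", "injection_volume_uL"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ug_on_column_to_mg_per_g(self) -> float:
        """mg/g of powder per µg injected on column."""
        return (self.extract_volume_mL * 1000.0 / self.injection_volume_uL) / (
            self.sample_mass_g * 1000.0
        )


@dataclass(frozen=True)
class RecoveryExperiment:
    detected: float
    original: float
    spiked: float

    def __post_init__(self) -> None:
        if self.spiked <= 0:
            raise ValueError("spiked amount must be positive")


@dataclass(frozen=True)
class ContentReport:
    batch_id: str
    analyte: str
    wavelength_nm: float
    esm_content: float
    qams_content: float
    re_pct: float


def fit_calibration(
    points: Sequence[tuple[float, float]],
    analyte: str,
    wavelength_nm: float,
) -> CalibrationCurve:
    """Ordinary least squares of area on amount (µg) over a calibration series.

    Requires >= 3 points spanning a positive amount range; the fitted
    linear range is simply (min, max) of the amounts used.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("calibration needs at least 3 (amount, area) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) <= 0:
        raise ValueError("calibration amounts are degenerate (zero variance)")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        analyte=analyte,
        wavelength_nm=wavelength_nm,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        linear_range_ug=(float(x.min()), float(x.max())),
    )


def esm_content(area: float, curve: CalibrationCurve, prep: SamplePrep) -> float:
    """External-standard content (mg/g) from a sample peak area."""
    amount_ug = curve.invert(area)
    if amount_ug < 0:
        raise ValueError(
            f"{curve.analyte}: area {area} below intercept {curve.intercept}"
        )
    return amount_ug * prep.ug_on_column_to_mg_per_g


def rcf(m: RCFMeasurement) -> float:
    """Relative correction factor f_x = (W_is * A_x) / (W_x * A_is)."""
    return (m.W_is * m.A_x) / (m.W_x * m.A_is)


def _rsd_pct(values: np.ndarray) -> float:
    return 100.0 * float(np.std(values, ddof=1)) / float(np.mean(values))


def aggregate_rcf(
    replicates: Iterable[float], analyte: str, wavelength_nm: float
) -> RCFSet:
    """Mean and RSD over replicate correction factors (mean reported to 3 decimals)."""
    f = np.asarray(list(replicates), dtype=float)
    if f.size < 2:
        raise ValueError("need at least 2 replicate correction factors")
    if np.any(f <= 0):
        raise ValueError("correction factors must be positive")
    return RCFSet(
        analyte=analyte,
        wavelength_nm=wavelength_nm,
        replicates=tuple(f),
        mean_f=round_half_up(float(np.mean(f)), 3),
        rsd_pct=_rsd_pct(f),
    )


def check_rcf_reproducibility(
    sets: Sequence[RCFSet], max_rsd_pct: float = 3.0
) -> pd.DataFrame:
    """Pooled RSD of mean correction factors across instruments/columns.

    Groups by (analyte, wavelength); groups with fewer than 2 sets are
    skipped with a warning.  Returns one row per analyte/wavelength with
    the cross-condition RSD and a pass flag (RSD <= ``max_rsd_pct``).
    """
    rows = []
    keyed: dict[tuple[str, float], list[float]] = {}
    for s in sets:
        keyed.setdefault((s.analyte, s.wavelength_nm), []).append(s.mean_f)
    for (analyte, wl), means in sorted(keyed.items()):
        if len(means) < 2:
            warnings.warn(
                f"{analyte} @ {wl} nm: only {len(means)} condition(s), skipped",
                stacklevel=2,
            )
            continue
        r = _rsd_pct(np.asarray(means))
        rows.append(
            {
                "analyte": analyte,
                "wavelength_nm": wl,
                "n_conditions": len(means),
                "rsd_pct": r,
                "passed": r <= max_rsd_pct,
            }
        )
    return pd.DataFrame(rows)


def qams_content(A_x: float, f_x: float, A_is: float, is_content: float) -> float:
    """Single-marker content: C_x = (A_x * C_is) / (f_x * A_is), mg/g."""
    if f_x <= 0:
        raise ValueError(f"correction factor must be > 0, got {f_x}")
    if A_is <= 0 or is_content <= 0 or A_x < 0:
        raise ValueError("areas and internal-standard content must be positive")
    return (A_x * is_content) / (f_x * A_is)


def recovery_rate(e: RecoveryExperiment) -> float:
    """Spike recovery, percent: (detected - original) / spiked * 100."""
    return 100.0 * (e.detected - e.original) / e.spiked


def relative_error(qams: float, esm: float) -> float:
    """Method-agreement RE%, 100 * (qams - esm) / esm, reported to 2 decimals."""
    if esm <= 0:
        raise ValueError(f"ESM content must be > 0, got {esm}")
    return round_half_up(100.0 * (qams - esm) / esm, 2)


def re_summary(reports: Sequence[ContentReport]) -> tuple[float, float, pd.DataFrame]:
    """Extrema and per-analyte summary of relative errors over content reports."""
    if not reports:
        raise ValueError("need at least one content report")
    df = pd.DataFrame(
        {
            "batch_id": [r.batch_id for r in reports],
            "analyte": [r.analyte for r in reports],
            "wavelength_nm": [r.wavelength_nm for r in reports],
            "esm_content": [r.esm_content for r in reports],
            "qams_content": [r.qams_content for r in reports],
            "re_pct": [r.re_pct for r in reports],
        }
    )
    grouped = (
        df.groupby(["analyte", "wavelength_nm"])["re_pct"]
        .agg(["min", "max", "mean", "count"])
        .reset_index()
    )
    return float(df["re_pct"].min()), float(df["re_pct"].max()), grouped
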