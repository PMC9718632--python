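"""Domain types and CSV I/O for chromatographic peak data.

The currency of the whole pipeline is the *peak table*: one sample's list
of detected peaks (retention time in minutes, baseline-corrected area in
arbitrary detector units) at a single detection wavelength.  Batches of
peak tables are matched across samples into a *common-peak matrix*, the
batches-by-peaks area matrix on which fingerprint similarity and the
multivariate screens operate.

All interchange is plain CSV (UTF-8, comma separated, mandatory header);
retention times are minutes and areas are detector-arbitrary units
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakTable",
    "Trace",
    "BatchPanel",
    "CommonPeakMatrix",
    "FormatError",
    "ValidationError",
    "read_peak_table",
    "write_peak_table",
    "read_trace",
    "write_trace",
]

#: tolerance below which two retention times count as duplicates (minutes)
RT_DUPLICATE_TOL = 1e-6

PEAK_TABLE_COLUMNS = ("sample_id", "wavelength_nm", "rt_min", "area", "height", "label")
TRACE_COLUMNS = ("time_min", "signal", "wavelength_nm")


class FormatError(ValueError):
    """A file does not conform to the expected CSV layout."""


class ValidationError(ValueError):
    """Data violate a domain invariant (negative area, unordered times, ...)."""


@dataclass(frozen=True)
class Peak:
    """One chromatographic peak.

    Parameters
    ----------
    rt_min:
        Retention time of the apex, minutes.
    area:
        Baseline-corrected peak area, signal·min in arbitrary detector units.
    height:
        Optional apex signal above baseline.
    wavelength_nm:
        Detection wavelength, nm.
    label:
        Optional analyte name ("forsythoside A", ...) or None for unknowns.
    """

    rt_min: float
    area: float
    height: float | None = None
    wavelength_nm: float = 237.0
    label: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.rt_min) or self.rt_min < 0:
            raise ValidationError(f"rt_min must be finite and >= 0, got {self.rt_min}")
        if not np.isfinite(self.area) or self.area < 0:
            raise ValidationError(f"area must be finite and >= 0, got {self.area}")
        if self.wavelength_nm <= 0:
            raise ValidationError(f"wavelength_nm must be > 0, got {self.wavelength_nm}")


@dataclass
class PeakTable:
    """One sample's peaks at one wavelength, sorted by retention time.

    Construction sorts peaks and collapses duplicates (retention times
    closer than ``RT_DUPLICATE_TOL``): the larger-area member is kept and a
    warning is emitted, so a table is always strictly increasing in rt.
    """

    sample_id: str
    wavelength_nm: float
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValidationError("wavelength_nm must be > 0")
        for p in self.peaks:
            if abs(p.wavelength_nm - self.wavelength_nm) > 1e-9:
                raise ValidationError(
                    f"peak at rt {p.rt_min} has wavelength {p.wavelength_nm}, "
                    f"table is {self.wavelength_nm}"
                )
        self.peaks = self._sorted_dedup(self.peaks)

    @staticmethod
    def _sorted_dedup(peaks: Sequence[Peak]) -> list[Peak]:
        ordered = sorted(peaks, key=lambda p: p.rt_min)
        out: list[Peak] = []
        for p in ordered:
            if out and p.rt_min - out[-1].rt_min < RT_DUPLICATE_TOL:
                keep = p if p.area > out[-1].area else out[-1]
                warnings.warn(
                    f"duplicate rt {p.rt_min:.6f} min in sample "
                    f"{'?'}: keeping larger area {keep.area}",
                    stacklevel=3,
                )
                out[-1] = keep
            else:
                out.append(p)
        return out

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def rts(self) -> np.ndarray:
        return np.array([p.rt_min for p in self.peaks], dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "wavelength_nm": self.wavelength_nm,
                "rt_min": [p.rt_min for p in self.peaks],
                "area": [p.area for p in self.peaks],
                "height": [p.height for p in self.peaks],
                "label": [p.label for p in self.peaks],
            },
            columns=list(PEAK_TABLE_COLUMNS),
        )


@dataclass
class Trace:
    """A raw chromatogram: detector signal on a strictly increasing time grid."""

    time_min: np.ndarray
    signal: np.ndarray
    wavelength_nm: float

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_min.shape != self.signal.shape or self.time_min.ndim != 1:
            raise ValidationError("time_min and signal must be equal-length 1-D arrays")
        if self.time_min.size >= 2 and not np.all(np.diff(self.time_min) > 0):
            raise ValidationError("time_min must be strictly increasing")
        if self.wavelength_nm <= 0:
            raise ValidationError("wavelength_nm must be > 0")

    def __len__(self) -> int:
        return self.time_min.size


@dataclass
class BatchPanel:
    """Peak tables for >= 2 batches sharing one detection wavelength."""

    batches: list[PeakTable]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.batches) < 2:
            raise ValidationError("a panel needs at least 2 batches")
        ids = [t.sample_id for t in self.batches]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate sample ids in panel: {ids}")
        wls = {t.wavelength_nm for t in self.batches}
        if len(wls) != 1:
            raise ValidationError(f"panel mixes wavelengths: {sorted(wls)}")

    @property
    def wavelength_nm(self) -> float:
        return self.batches[0].wavelength_nm

    @property
    def batch_ids(self) -> list[str]:
        return [t.sample_id for t in self.batches]

    def __len__(self) -> int:
        return len(self.batches)


@dataclass
class CommonPeakMatrix:
    """Batches x matched-common-peaks area matrix.

    ``peak_ids`` number the matched peaks 1..K in elution order;
    ``consensus_rt_min`` is the per-peak median retention time over batches.
    Entries may be NaN only when matching was run without requiring a peak
    in every batch.
    """

    batch_ids: list[str]
    consensus_rt_min: np.ndarray
    areas: np.ndarray
    peak_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.consensus_rt_min = np.asarray(self.consensus_rt_min, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 2:
            raise ValidationError("areas must be 2-D (batches x peaks)")
        if self.areas.shape[0] != len(self.batch_ids):
            raise ValidationError("row count must equal number of batch ids")
        if self.areas.shape[1] != self.consensus_rt_min.size:
            raise ValidationError("column count must equal number of consensus rts")
        if not self.peak_ids:
            self.peak_ids = list(range(1, self.areas.shape[1] + 1))
        if len(self.peak_ids) != self.areas.shape[1]:
            raise ValidationError("peak_ids length mismatch")
        if self.consensus_rt_min.size >= 2 and not np.all(
            np.diff(self.consensus_rt_min) > 0
        ):
            raise ValidationError("consensus rts must be strictly increasing")

    @property
    def n_batches(self) -> int:
        return self.areas.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.areas.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"peak_{k}" for k in self.peak_ids]
        return pd.DataFrame(self.areas, index=pd.Index(self.batch_ids, name="batch_id"), columns=cols)

    def consensus_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"peak_id": self.peak_ids, "consensus_rt_min": self.consensus_rt_min}
        )


# ---------------------------------------------------------------------------
# CSV I/O


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_peak_table(path, **read_csv_kwargs) -> PeakTable:
    """Read one peak table from CSV.

    Required columns: ``sample_id``, ``wavelength_nm``, ``rt_min``, ``area``;
    optional ``height`` and ``label``.  Rows violating domain invariants
    raise :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    _require_columns(df, ("sample_id", "wavelength_nm", "rt_min", "area"), path)
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    sample_ids = df["sample_id"].unique()
    if len(sample_ids) != 1:
        raise FormatError(f"{path}: expected a single sample_id, got {list(sample_ids)}")
    wls = df["wavelength_nm"].unique()
    if len(wls) != 1:
        raise FormatError(f"{path}: expected a single wavelength, got {list(wls)}")
    peaks = []
    for i, row in df.iterrows():
        try:
            peaks.append(
                Peak(
                    rt_min=float(row["rt_min"]),
                    area=float(row["area"]),
                    height=None if pd.isna(row.get("height")) else float(row["height"]),
                    wavelength_nm=float(row["wavelength_nm"]),
                    label=None if pd.isna(row.get("label")) else str(row["label"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from exc
    return PeakTable(str(sample_ids[0]), float(wls[0]), peaks)


def write_peak_table(table: PeakTable, path) -> None:
    """Write a peak table as CSV with the canonical column order."""
    table.to_dataframe().to_csv(path, index=False, float_format="%.9g")


def read_trace(path, **read_csv_kwargs) -> Trace:
    """Read a raw chromatogram (columns ``time_min``, ``signal``, ``wavelength_nm``)."""
    df = pd.read_csv(path, **read_csv_kwargs)
    _require_columns(df, TRACE_COLUMNS, path)
    wls = df["wavelength_nm"].unique()
    if len(wls) != 1:
        raise FormatError(f"{path}: expected a single wavelength, got {list(wls)}")
    return Trace(df["time_min"].to_numpy(), df["signal"].to_numpy(), float(wls[0]))


def write_trace(trace: Trace, path) -> None:
    pd.DataFrame(
        {
            "time_min": trace.time_min,
            "signal": trace.signal,
            "wavelength_nm": trace.wavelength_nm,
        }
    ).to_csv(path, index=False, float_format="%.9g")
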