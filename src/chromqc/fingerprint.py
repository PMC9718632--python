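"""Reference fingerprints and batch similarity.

The reference fingerprint of a batch panel is built by the median method:
per common peak, the median area over batches (even counts take the
midpoint of the two central order statistics).  Each batch is then scored
against the reference by the included-angle cosine on common-peak area
vectors — the congruence coefficient used by chromatographic fingerprint
similarity software; values above 0.95 conventionally indicate consistent
batch quality.  Precision / stability / repeatability are summarized as
RSDs (sample standard deviation over mean, in percent) of retention times
and of peak quantities relative to a designated reference peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CommonPeakMatrix, PeakTable, ValidationError

__all__ = [
    "Fingerprint",
    "median_reference",
    "cosine_similarity",
    "correlation_similarity",
    "panel_similarities",
    "rsd",
    "relative_to_reference_peak",
    "validation_report",
]


@dataclass(frozen=True)
class Fingerprint:
    """Per-peak reference areas (median method) with consensus retention times."""

    peak_ids: tuple[int, ...]
    reference_areas: np.ndarray
    reference_rts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_areas", np.asarray(self.reference_areas, float))
        object.__setattr__(self, "reference_rts", np.asarray(self.reference_rts, float))
        if not (
            len(self.peak_ids) == self.reference_areas.size == self.reference_rts.size
        ):
            raise ValidationError("fingerprint fields must have equal length")
        if np.any(self.reference_areas <= 0):
            raise ValidationError("reference areas must be positive")


def median_reference(matrix: CommonPeakMatrix) -> Fingerprint:
    """Median-method reference fingerprint of a common-peak matrix."""
    if matrix.n_batches < 1:
        raise ValidationError("need at least one batch")
    medians = np.nanmedian(matrix.areas, axis=0)
    return Fingerprint(
        peak_ids=tuple(matrix.peak_ids),
        reference_areas=medians,
        reference_rts=matrix.consensus_rt_min,
    )


def cosine_similarity(a, b) -> float:
    """Included-angle cosine of two area vectors, in [-1, 1]."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValidationError("vectors must be equal-length and 1-D")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def correlation_similarity(a, b) -> float:
    """Pearson correlation of two area vectors (alternative similarity metric)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("correlation needs equal-length vectors of size >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(a, b)[0, 1])


_METRICS = {"cosine": cosine_similarity, "correlation": correlation_similarity}


def panel_similarities(
    matrix: CommonPeakMatrix, fp: Fingerprint, metric: str = "cosine"
) -> pd.Series:
    """Similarity of every batch's area vector to the reference fingerprint."""
    if tuple(matrix.peak_ids) != tuple(fp.peak_ids):
        raise ValidationError(
            "matrix and fingerprint peak ids differ: "
            f"{matrix.peak_ids} vs {fp.peak_ids}"
        )
    try:
        sim = _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    scores = [sim(row, fp.reference_areas) for row in matrix.areas]
    return pd.Series(scores, index=matrix.batch_ids, name=f"{metric}_similarity")


def rsd(values) -> float:
    """Relative standard deviation in percent (sample SD / mean * 100)."""
    v = np.asarray(list(values), float)
    if v.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = float(np.mean(v))
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * float(np.std(v, ddof=1)) / mean


def relative_to_reference_peak(table: PeakTable, ref_index: int) -> pd.DataFrame:
    """Retention times and areas of a table relative to one of its peaks.

    ``ref_index`` is a 0-based position in the rt-sorted table. Relative
    rt and relative area of the reference peak itself are exactly 1.
    """
    if not 0 <= ref_index < len(table):
        raise KeyError(
            f"reference peak index {ref_index} out of range for a "
            f"{len(table)}-peak table"
        )
    ref = table.peaks[ref_index]
    if ref.rt_min <= 0 or ref.area <= 0:
        raise ValueError("reference peak must have positive rt and area")
    return pd.DataFrame(
        {
            "rt_min": table.rts,
            "area": table.areas,
            "relative_rt": table.rts / ref.rt_min,
            "relative_area": table.areas / ref.area,
        }
    )


def validation_report(matrices: list[CommonPeakMatrix], ref_peak_index: int = 0) -> pd.DataFrame:
    """Per-peak RSDs of retention time and relative area over replicate runs.

    ``matrices`` holds one aligned common-peak matrix per condition
    (e.g. six repeat injections); rows of each matrix are averaged first.
    Used for precision / stability / repeatability summaries.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    k = matrices[0].n_peaks
    rts = np.array([m.consensus_rt_min for m in matrices])
    areas = np.array([np.nanmean(m.areas, axis=0) for m in matrices])
    rel_areas = areas / areas[:, [ref_peak_index]]
    return pd.DataFrame(
        {
            "peak_id": matrices[0].peak_ids,
            "rt_rsd_pct": [rsd(rts[:, j]) for j in range(k)],
            "rel_area_rsd_pct": [
                rsd(rel_areas[:, j]) if j != ref_peak_index else 0.0 for j in range(k)
            ],
        }
    )
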