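"""Peak detection, screening filters, cross-batch matching and localization.

Mirrors the screening cascade used when establishing an HPLC fingerprint:
detect peaks in each trace, shear the solvent-front region (everything
eluting before 5 min), match peaks across batches within a retention-time
tolerance, and keep as *common peaks* only those matched in every batch
whose area exceeds the screening threshold (strictly greater than 0.4
area units) in every batch.  Analyte peaks are afterwards located
relative to the internal-standard peak either by relative retention value
(rt ratio) or by retention time difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .core import BatchPanel, CommonPeakMatrix, Peak, PeakTable, Trace, ValidationError

__all__ = [
    "MatchConfig",
    "PeakNotFoundError",
    "detect_peaks",
    "shear_solvent_region",
    "filter_min_area",
    "match_common_peaks",
    "locate_by_relative_retention",
    "locate_by_rt_difference",
]


class PeakNotFoundError(LookupError):
    """No peak satisfies a localization query."""


@dataclass(frozen=True)
class MatchConfig:
    """Constants of the common-peak screening cascade.

    rt_tolerance_min:
        absolute retention-time window for cross-batch matching (minutes).
    min_area:
        screening threshold; a common peak must exceed it (strictly) in
        every batch.
    solvent_cut_min:
        solvent-front boundary; peaks with rt strictly below are sheared.
    require_all_batches:
        if True (default) a matched peak must appear in every batch;
        otherwise missing entries are reported as NaN.
    reference_batch:
        index of the batch whose peaks seed the matching clusters.
    """

    rt_tolerance_min: float = 0.5
    min_area: float = 0.4
    solvent_cut_min: float = 5.0
    require_all_batches: bool = True
    reference_batch: int = 0

    def __post_init__(self) -> None:
        if self.rt_tolerance_min <= 0:
            raise ValidationError("rt_tolerance_min must be > 0")
        if self.min_area < 0:
            raise ValidationError("min_area must be >= 0")
        if self.solvent_cut_min < 0:
            raise ValidationError("solvent_cut_min must be >= 0")


def detect_peaks(
    trace: Trace, min_height: float = 0.0, min_prominence: float = 0.0
) -> PeakTable:
    """Detect peaks in a raw chromatogram.

    Local maxima above ``min_height`` and ``min_prominence`` are apexes.
    Each peak is integrated by the trapezoid rule between bounds placed at
    apex +/- 4 sigma (sigma from the full width at half maximum), clipped
    at the signal minimum between adjacent apexes, after subtracting the
    linear baseline chord joining the bounds.  The apex grid time is the
    retention time.
    """
    if min_height < 0 or min_prominence < 0:
        raise ValidationError("detection thresholds must be >= 0")
    if len(trace) < 3:
        raise ValidationError("trace must have at least 3 points")
    t, y = trace.time_min, trace.signal
    idx, _ = _sig.find_peaks(
        y,
        height=min_height if min_height > 0 else None,
        prominence=min_prominence if min_prominence > 0 else None,
    )
    if idx.size == 0:
        return PeakTable(sample_id="trace", wavelength_nm=trace.wavelength_nm, peaks=[])

    widths_pts = _sig.peak_widths(y, idx, rel_height=0.5)[0]
    dt = float(np.median(np.diff(t)))
    sigmas = widths_pts * dt / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    peaks: list[Peak] = []
    for k, apex in enumerate(idx):
        half_window = 4.0 * sigmas[k]
        lo_t = t[apex] - half_window
        hi_t = t[apex] + half_window
        lo = int(np.searchsorted(t, lo_t, side="left"))
        hi = int(np.searchsorted(t, hi_t, side="right")) - 1
        # clip the window at the valley shared with a neighbouring apex
        if k > 0 and idx[k - 1] >= lo:
            valley = idx[k - 1] + int(np.argmin(y[idx[k - 1] : apex + 1]))
            lo = max(lo, valley)
        if k + 1 < idx.size and idx[k + 1] <= hi:
            valley = apex + int(np.argmin(y[apex : idx[k + 1] + 1]))
            hi = min(hi, valley)
        lo = max(lo, 0)
        hi = min(hi, len(t) - 1)
        if hi - lo < 2:
            continue
        seg_t = t[lo : hi + 1]
        seg_y = y[lo : hi + 1]
        baseline = np.interp(seg_t, [seg_t[0], seg_t[-1]], [seg_y[0], seg_y[-1]])
        area = float(np.trapezoid(seg_y - baseline, seg_t))
        if area <= 0:
            continue
        apex_baseline = float(np.interp(t[apex], seg_t, baseline))
        peaks.append(
            Peak(
                rt_min=float(t[apex]),
                area=area,
                height=float(y[apex] - apex_baseline),
                wavelength_nm=trace.wavelength_nm,
            )
        )
    return PeakTable(sample_id="trace", wavelength_nm=trace.wavelength_nm, peaks=peaks)


def shear_solvent_region(table: PeakTable, cut_min: float = 5.0) -> PeakTable:
    """Remove solvent-front peaks: every peak with rt strictly below ``cut_min``."""
    if cut_min < 0:
        raise ValidationError("cut_min must be >= 0")
    kept = [p for p in table.peaks if p.rt_min >= cut_min]
    return PeakTable(table.sample_id, table.wavelength_nm, kept)


def filter_min_area(obj, min_area: float):
    """Area screen with strict inequality (area must be *greater than* the threshold).

    On a :class:`PeakTable`, drops individual peaks; on a
    :class:`CommonPeakMatrix`, drops columns unless the area exceeds the
    threshold in every batch (NaN entries from partial matches fail).
    """
    if min_area < 0:
        raise ValidationError("min_area must be >= 0")
    if isinstance(obj, PeakTable):
        kept = [p for p in obj.peaks if p.area > min_area]
        return PeakTable(obj.sample_id, obj.wavelength_nm, kept)
    if isinstance(obj, CommonPeakMatrix):
        with np.errstate(invalid="ignore"):
            keep = np.all(obj.areas > min_area, axis=0)
        return CommonPeakMatrix(
            batch_ids=list(obj.batch_ids),
            consensus_rt_min=obj.consensus_rt_min[keep],
            areas=obj.areas[:, keep],
            peak_ids=list(range(1, int(keep.sum()) + 1)),
        )
    raise TypeError(f"cannot area-filter {type(obj).__name__}")


def match_common_peaks(panel: BatchPanel, cfg: MatchConfig | None = None) -> CommonPeakMatrix:
    """Match peaks across batches into a common-peak matrix.

    Clusters are seeded from the reference batch's peaks (greedy, in
    elution order): each other batch contributes its nearest unassigned
    peak within ``rt_tolerance_min`` of the seed.  A refinement pass then
    re-assigns members against the cluster's median retention time, which
    centers the matching window when the seed itself jittered.  A cluster
    is a common peak iff it has exactly one member from every batch
    (unless ``require_all_batches`` is off) and every member's area
    exceeds ``min_area``.  Columns are numbered 1..K in elution order.
    """
    cfg = cfg or MatchConfig()
    for table in panel.batches:
        if len(table) == 0:
            raise ValidationError(f"batch {table.sample_id} has no peaks")
    n = len(panel)
    ref_idx = cfg.reference_batch
    if not 0 <= ref_idx < n:
        raise ValidationError(f"reference batch index {ref_idx} out of range")

    rts = [t.rts for t in panel.batches]
    areas = [t.areas for t in panel.batches]

    def assign(centers: np.ndarray) -> list[dict[int, int]]:
        """For each cluster center, nearest unassigned peak per batch within tolerance."""
        clusters: list[dict[int, int]] = [dict() for _ in centers]
        for b in range(n):
            taken = np.zeros(rts[b].size, dtype=bool)
            # visit clusters nearest-first per batch to keep assignment greedy but stable
            for ci in np.argsort(centers):
                diffs = np.abs(rts[b] - centers[ci])
                diffs[taken] = np.inf
                j = int(np.argmin(diffs))
                if diffs[j] <= cfg.rt_tolerance_min:
                    clusters[ci][b] = j
                    taken[j] = True
        return clusters

    seed_centers = rts[ref_idx]
    clusters = assign(seed_centers)
    # refinement: recenter on the cluster median rt and re-assign
    refined_centers = np.array(
        [
            np.median([rts[b][j] for b, j in c.items()]) if c else seed_centers[ci]
            for ci, c in enumerate(clusters)
        ]
    )
    clusters = assign(refined_centers)

    cols = []
    for ci, members in enumerate(clusters):
        if cfg.require_all_batches and len(members) != n:
            continue
        if not members:
            continue
        member_rts = [rts[b][j] for b, j in members.items()]
        member_areas = np.full(n, np.nan)
        for b, j in members.items():
            member_areas[b] = areas[b][j]
        with np.errstate(invalid="ignore"):
            ok = np.all(member_areas[list(members)] > cfg.min_area)
        if not ok:
            continue
        cols.append((float(np.median(member_rts)), member_areas))

    cols.sort(key=lambda c: c[0])
    if cols:
        consensus = np.array([c[0] for c in cols])
        mat = np.column_stack([c[1] for c in cols])
    else:
        consensus = np.empty(0)
        mat = np.empty((n, 0))
    return CommonPeakMatrix(
        batch_ids=panel.batch_ids,
        consensus_rt_min=consensus,
        areas=mat,
        peak_ids=list(range(1, len(cols) + 1)),
    )


def _pick(table: PeakTable, deviations: np.ndarray, tol: float, what: str) -> Peak:
    if len(table) == 0:
        raise PeakNotFoundError(f"empty peak table while locating by {what}")
    best = float(np.min(deviations))
    if best > tol:
        nearest = table.peaks[int(np.argmin(deviations))]
        raise PeakNotFoundError(
            f"no peak within {what} tolerance {tol}; nearest candidate at "
            f"rt {nearest.rt_min:.3f} min deviates by {best:.4g}"
        )
    tied = np.flatnonzero(np.isclose(deviations, best))
    winner = max(tied, key=lambda i: table.peaks[int(i)].area)
    return table.peaks[int(winner)]


def locate_by_relative_retention(
    table: PeakTable, is_rt: float, expected_rrv: float, tol: float = 0.05
) -> Peak:
    """Locate an analyte peak by relative retention value rt / is_rt.

    Returns the peak whose rrv deviates least (relatively) from
    ``expected_rrv``, provided the relative deviation is <= ``tol``;
    ties go to the larger area.
    """
    if is_rt <= 0:
        raise ValidationError("internal standard rt must be > 0")
    rrv = table.rts / is_rt
    deviations = np.abs(rrv - expected_rrv) / expected_rrv
    return _pick(table, deviations, tol, "relative retention")


def locate_by_rt_difference(
    table: PeakTable, is_rt: float, expected_delta: float, tol: float = 0.5
) -> Peak:
    """Locate an analyte peak by retention-time difference rt - is_rt (minutes)."""
    if is_rt <= 0:
        raise ValidationError("internal standard rt must be > 0")
    deltas = table.rts - is_rt
    deviations = np.abs(deltas - expected_delta)
    return _pick(table, deviations, tol, "rt difference")


def warn_if_unresolved(specs_rts: np.ndarray, sigma: float, min_sep_sigmas: float = 4.0) -> None:
    """Warn when planted peaks sit closer than ``min_sep_sigmas`` sigmas apart."""
    d = np.diff(np.sort(np.asarray(specs_rts, float)))
    if np.any(d < min_sep_sigmas * sigma):
        warnings.warn(
            f"peaks closer than {min_sep_sigmas} sigma: minimum separation "
            f"{d.min():.3f} min at sigma {sigma}",
            stacklevel=2,
        )
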