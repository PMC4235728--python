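"""ARISA electropherogram processing.

Turns a size-called peak table into a relative-intensity OTU table where
the OTUs are fragment-length bins. The supported processing order is fixed:

1. intensity filter — peaks at or below ``min_rfu`` (default 10 RFU) are
   excluded (strict: exactly 10 RFU is excluded);
2. window clip — peaks outside the detectable fragment-length window
   (default 200–1150 bp, both endpoints included) are excluded;
3. binning — each surviving peak is assigned to exactly one fragment-length
   bin; bin width depends on fragment size (3 bp below 700 bp, 5 bp from
   700 to 1000 bp, 10 bp above 1000 bp) and intensities are summed per bin;
4. relative-intensity filter — bins holding less than ``min_relative_intensity``
   (default 0.1%) of the sample's total summed intensity are dropped in a
   single pass against the pre-filter total, and the survivors re-normalized;
5. technical-replicate QC — duplicate profiles of a sample are compared by
   Bray-Curtis similarity and merged (mean relative intensity) when they
   agree, flagged otherwise.

Bins are laid on a fixed grid anchored at the window's lower edge with
half-open intervals; the upper window endpoint closes the last bin. A fixed
grid (rather than peak-centered bins) keeps the binning deterministic and
independent of peak order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ValidationError
from .io import OTUTable, PeakRecord, PeakTable, RELATIVE_INTENSITY

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Intensity filters for peak processing.

    ``min_rfu`` is an exclusive lower bound: a peak is kept only if its
    intensity is strictly greater. ``min_relative_intensity`` is the
    fraction of a sample's total binned intensity below which a bin is
    discarded (0.001 = 0.1%).
    """

    min_rfu: float = 10.0
    min_relative_intensity: float = 0.001

    def __post_init__(self) -> None:
        if self.min_rfu < 0:
            raise ValidationError("min_rfu must be >= 0")
        if not (0 <= self.min_relative_intensity < 1):
            raise ValidationError("min_relative_intensity must be in [0, 1)")


@dataclass(frozen=True)
class BinningScheme:
    """Piecewise-constant binning grid over a detection window.

    ``regimes`` is an ordered list of ``(start_bp, end_bp, width_bp)``
    intervals that tile ``[min_bp, max_bp]`` without overlap. Within each
    regime, bins are ``[start + k*w, start + (k+1)*w)`` with the last bin
    truncated at the regime end; the final bin of the window is closed so
    that a peak at exactly ``max_bp`` is binned. A peak at a regime
    boundary belongs to the higher regime's first bin.
    """

    regimes: tuple[tuple[float, float, float], ...] = (
        (200.0, 700.0, 3.0),
        (700.0, 1000.0, 5.0),
        (1000.0, 1150.0, 10.0),
    )

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, width in self.regimes:
            if width <= 0:
                raise ValidationError("bin width must be positive")
            if end <= start:
                raise ValidationError("regime end must exceed start")
            if prev_end is not None and not math.isclose(start, prev_end):
                raise ValidationError("regimes must tile the window without gaps")
            prev_end = end

    @property
    def min_bp(self) -> float:
        return self.regimes[0][0]

    @property
    def max_bp(self) -> float:
        return self.regimes[-1][1]

    def bin_edges(self) -> list[tuple[float, float]]:
        """All (lo, hi) bin intervals in ascending order."""
        edges: list[tuple[float, float]] = []
        for start, end, width in self.regimes:
            lo = start
            while lo < end and not math.isclose(lo, end):
                hi = min(lo + width, end)
                edges.append((lo, hi))
                lo = hi
        return edges

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges())

    def bin_of(self, size_bp: float) -> tuple[float, float]:
        """Return the (lo, hi) interval of the bin holding ``size_bp``.

        Raises ``ValueError`` for sizes outside the window (the clip step
        must run first).
        """
        if size_bp < self.min_bp or size_bp > self.max_bp:
            raise ValueError(f"fragment size {size_bp} outside window "
                             f"[{self.min_bp}, {self.max_bp}]")
        if size_bp == self.max_bp:  # closed last bin of the window
            return self.bin_edges()[-1]
        for start, end, width in self.regimes:
            if start <= size_bp < end:
                k = int((size_bp - start) // width)
                lo = start + k * width
                return (lo, min(lo + width, end))
        raise ValueError(f"fragment size {size_bp} not covered by any regime")

    @staticmethod
    def bin_label(lo: float, hi: float) -> str:
        return f"bin_{lo:07.2f}_{hi:07.2f}"


DEFAULT_SCHEME = BinningScheme()


@dataclass
class BinnedProfile:
    """Per sample x replicate binned fingerprint.

    ``intensity`` maps bin label -> summed RFU; ``relative`` maps bin
    label -> relative intensity. After the relative-intensity filter the
    retained relative intensities sum to 1.
    """

    sample_id: str
    replicate_id: str
    intensity: dict[str, float] = field(default_factory=dict)
    relative: dict[str, float] = field(default_factory=dict)

    @property
    def total_intensity(self) -> float:
        return float(sum(self.intensity.values()))

    @property
    def n_bins(self) -> int:
        return len(self.intensity)


@dataclass
class ReplicateQCResult:
    """Outcome of comparing the two technical replicates of one sample."""

    sample_id: str
    similarity: float
    passed: bool
    merged_profile: BinnedProfile | None = None


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def filter_min_rfu(peaks: PeakTable, params: FilterParams) -> PeakTable:
    """Drop peaks with intensity at or below the RFU floor (strict >)."""
    kept = [r for r in peaks.records if r.intensity_rfu > params.min_rfu]
    removed = len(peaks.records) - len(kept)
    logger.info("RFU filter: removed %d of %d peaks (<= %g RFU)",
                removed, len(peaks.records), params.min_rfu)
    if not kept:
        logger.warning("RFU filter removed every peak")
    return PeakTable(kept, peaks.provenance)


def clip_to_window(peaks: PeakTable, scheme: BinningScheme = DEFAULT_SCHEME) -> PeakTable:
    """Drop peaks outside the detectable size window (closed endpoints)."""
    lo, hi = scheme.min_bp, scheme.max_bp
    kept = [r for r in peaks.records if lo <= r.size_bp <= hi]
    logger.info("window clip: removed %d of %d peaks outside [%g, %g] bp",
                len(peaks.records) - len(kept), len(peaks.records), lo, hi)
    return PeakTable(kept, peaks.provenance)


def assign_bins(
    peaks: PeakTable, scheme: BinningScheme = DEFAULT_SCHEME
) -> list[BinnedProfile]:
    """Bin peaks and sum intensities, one profile per (sample, replicate).

    Peaks must already be RFU-filtered and clipped; a peak outside the
    window indicates a pipeline-order bug and raises ``ValueError``.
    Profiles are returned in first-appearance order of (sample, replicate).
    """
    profiles: dict[tuple[str, str], BinnedProfile] = {}
    for rec in peaks.records:
        lo, hi = scheme.bin_of(rec.size_bp)
        label = scheme.bin_label(lo, hi)
        key = (rec.sample_id, rec.replicate_id)
        prof = profiles.get(key)
        if prof is None:
            prof = profiles[key] = BinnedProfile(rec.sample_id, rec.replicate_id)
        prof.intensity[label] = prof.intensity.get(label, 0.0) + rec.intensity_rfu
    for prof in profiles.values():
        total = prof.total_intensity
        prof.relative = {b: v / total for b, v in prof.intensity.items()}
    return list(profiles.values())


def relative_intensity_filter(
    profile: BinnedProfile, params: FilterParams
) -> BinnedProfile:
    """Drop bins below the relative-intensity floor; re-normalize survivors.

    Relative intensities are computed once against the pre-filter sample
    total (single pass, no iteration to a fixed point), then the surviving
    bins are re-normalized to sum to 1 for downstream Bray-Curtis work.
    """
    total = profile.total_intensity
    if total <= 0:
        raise EmptyInputError(
            f"sample {profile.sample_id!r} rep {profile.replicate_id!r}: "
            "zero total intensity"
        )
    kept = {
        b: v for b, v in profile.intensity.items()
        if v / total >= params.min_relative_intensity
    }
    if not kept:
        raise EmptyInputError(
            f"sample {profile.sample_id!r}: no bin passes the "
            f"{params.min_relative_intensity:.4%} relative-intensity filter"
        )
    kept_total = sum(kept.values())
    return BinnedProfile(
        profile.sample_id,
        profile.replicate_id,
        intensity=dict(kept),
        relative={b: v / kept_total for b, v in kept.items()},
    )


def _bray_curtis_similarity(a: dict[str, float], b: dict[str, float]) -> float:
    keys = set(a) | set(b)
    num = sum(min(a.get(k, 0.0), b.get(k, 0.0)) for k in keys)
    den = sum(a.values()) + sum(b.values())
    if den == 0:
        raise ValidationError("both profiles are empty")
    return 2.0 * num / den


def merge_technical_replicates(
    p1: BinnedProfile, p2: BinnedProfile, min_similarity: float = 0.8
) -> ReplicateQCResult:
    """Compare two technical replicates and merge them when they agree.

    Similarity is Bray-Curtis on the union of bins of the two relative-
    intensity profiles. Replicates at or above ``min_similarity`` are merged
    by averaging relative intensities per bin and re-normalizing; a failure
    is reported as a QC state, never raised.
    """
    if p1.sample_id != p2.sample_id:
        raise ValidationError(
            f"replicates belong to different samples: {p1.sample_id!r} vs {p2.sample_id!r}"
        )
    sim = _bray_curtis_similarity(p1.relative, p2.relative)
    if sim < min_similarity:
        return ReplicateQCResult(p1.sample_id, sim, passed=False)
    keys = sorted(set(p1.relative) | set(p2.relative))
    mean = {k: 0.5 * (p1.relative.get(k, 0.0) + p2.relative.get(k, 0.0)) for k in keys}
    total = sum(mean.values())
    merged = BinnedProfile(
        p1.sample_id,
        "merged",
        intensity=dict(mean),
        relative={k: v / total for k, v in mean.items()},
    )
    return ReplicateQCResult(p1.sample_id, sim, passed=True, merged_profile=merged)


def profiles_to_otu_table(profiles: list[BinnedProfile]) -> OTUTable:
    """Assemble per-sample profiles into a relative-intensity OTU table.

    Bin labels become OTU ids (union over samples, ascending); bins absent
    from a sample get abundance 0.
    """
    if not profiles:
        raise EmptyInputError("no profiles to assemble")
    seen: set[str] = set()
    for p in profiles:
        if p.sample_id in seen:
            raise ValidationError(f"duplicate sample {p.sample_id!r} in profile set")
        seen.add(p.sample_id)
    bins = sorted(set().union(*(p.relative.keys() for p in profiles)))
    data = pd.DataFrame(
        [[p.relative.get(b, 0.0) for b in bins] for p in profiles],
        index=[p.sample_id for p in profiles],
        columns=bins,
    )
    return OTUTable(data, RELATIVE_INTENSITY)


def process_peak_table(
    peaks: PeakTable,
    params: FilterParams = FilterParams(),
    scheme: BinningScheme = DEFAULT_SCHEME,
    replicate_threshold: float = 0.8,
) -> tuple[OTUTable, pd.DataFrame]:
    """Run the full fingerprint-processing pipeline on a peak table.

    Returns the merged relative-intensity OTU table (QC-passing samples
    only) and a QC report with one row per sample (replicate similarity,
    pass flag, per-stage peak attrition is logged).

    Samples with a single replicate pass QC trivially (similarity 1.0).
    """
    filtered = filter_min_rfu(peaks, params)
    clipped = clip_to_window(filtered, scheme)
    profiles = assign_bins(clipped, scheme)
    profiles = [relative_intensity_filter(p, params) for p in profiles]

    by_sample: dict[str, list[BinnedProfile]] = {}
    for p in profiles:
        by_sample.setdefault(p.sample_id, []).append(p)

    merged: list[BinnedProfile] = []
    qc_rows = []
    for sid, reps in by_sample.items():
        if len(reps) == 1:
            merged.append(reps[0])
            qc_rows.append((sid, 1.0, True, 1))
            continue
        if len(reps) > 2:
            raise ValidationError(f"sample {sid!r} has {len(reps)} replicates; expected <= 2")
        qc = merge_technical_replicates(reps[0], reps[1], replicate_threshold)
        qc_rows.append((sid, qc.similarity, qc.passed, 2))
        if qc.passed:
            merged.append(qc.merged_profile)
        else:
            logger.warning("sample %s failed replicate QC (similarity %.3f < %.3f)",
                           sid, qc.similarity, replicate_threshold)
    qc_report = pd.DataFrame(
        qc_rows, columns=["sample_id", "replicate_similarity", "qc_passed", "n_replicates"]
    )
    table = profiles_to_otu_table(merged)
    return table, qc_report
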