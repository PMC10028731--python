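"""Coverage normalization, interval exclusion, dual-threshold peak calling,
triangularity screening and summit-window extraction.

The peak rule is deliberately simple: after dividing each track by its median
per-base coverage (the median is robust to the long right tail that enriched
bases create), a base qualifies when the IP track exceeds ``ip_threshold``
(default 4) while every control track stays below ``control_threshold``
(default 3). Maximal runs of qualifying bases become peaks; each peak gets a
summit (leftmost maximum of IP coverage) and a triangularity score — the
Pearson correlation of the coverage around the summit with an ideal symmetric
triangle — standing in for a by-eye check of peak shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Per-base coverage over one chromosome. ``excluded`` marks bases that
    are ignored by the median and the peak predicate (set via
    apply_exclusions); their values are zeroed."""

    chrom: str
    values: np.ndarray
    normalized: bool = False
    excluded: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("coverage must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be >= 0")
        if self.excluded is not None:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != self.values.shape:
                raise ValueError("exclusion mask length mismatch")

    def __len__(self) -> int:
        return self.values.size

    @property
    def exclusion_mask(self) -> np.ndarray:
        if self.excluded is None:
            return np.zeros(self.values.size, dtype=bool)
        return self.excluded


@dataclass
class PeakCallerParams:
    ip_threshold: float = 4.0
    control_threshold: float = 3.0
    min_width: int = 1
    merge_gap: int = 0
    exclusions: list[tuple[str, int, int]] = field(default_factory=list)
    window_width: int = 60
    triangularity_min: float = 0.8

    def __post_init__(self):
        if not self.ip_threshold > self.control_threshold >= 0:
            raise ValueError("require ip_threshold > control_threshold >= 0")
        if self.min_width < 1 or self.merge_gap < 0 or self.window_width < 1:
            raise ValueError("invalid width/gap parameters")


@dataclass
class Peak:
    chrom: str
    start: int
    end: int  # half-open
    summit: int
    max_coverage: float
    triangularity: float = float("nan")
    passed_shape: bool = False

    def __post_init__(self):
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie inside the peak")


def apply_exclusions(
    track: CoverageTrack, exclusions: list[tuple[str, int, int]]
) -> CoverageTrack:
    """Zero out excluded intervals and mark them so the median and the peak
    predicate ignore them. Intervals for other chromosomes are skipped."""
    values = track.values.copy()
    mask = track.exclusion_mask.copy()
    for chrom, start, end in exclusions:
        if chrom != track.chrom:
            continue
        if start < 0 or end > values.size or start > end:
            raise ValueError(f"exclusion [{start}, {end}) out of bounds")
        values[start:end] = 0.0
        mask[start:end] = True
    return CoverageTrack(track.chrom, values, track.normalized, mask)


def normalize_coverage(track: CoverageTrack) -> CoverageTrack:
    """Divide by the median per-base coverage over non-excluded bases."""
    if track.normalized:
        raise ValueError("track is already median-normalized")
    keep = ~track.exclusion_mask
    if not keep.any():
        raise ValueError("all bases excluded; median undefined")
    med = float(np.median(track.values[keep]))
    if med <= 0:
        raise ValueError("median per-base coverage is zero; cannot normalize")
    values = track.values / med
    if track.excluded is not None:
        values[track.excluded] = 0.0
    return CoverageTrack(track.chrom, values, True, track.excluded)


def _runs_from_mask(qualifies: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    idx = np.flatnonzero(qualifies)
    if idx.size == 0:
        return []
    runs = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 <= merge_gap:
            prev = i
        else:
            runs.append((start, prev + 1))
            start = prev = i
    runs.append((start, prev + 1))
    return runs


def triangularity_score(
    ip: CoverageTrack, summit: int, flank: int
) -> float:
    """Pearson correlation between coverage on [summit-flank, summit+flank]
    and an ideal symmetric triangle apexed at the summit. The window is
    clipped at chromosome ends; a zero-variance window scores 0."""
    lo = max(0, summit - flank)
    hi = min(len(ip), summit + flank + 1)
    obs = ip.values[lo:hi]
    ideal = -np.abs(np.arange(lo, hi) - summit).astype(np.float64)
    if obs.size < 3 or np.ptp(obs) == 0:
        return 0.0
    obs_c = obs - obs.mean()
    tri_c = ideal - ideal.mean()
    denom = np.sqrt((obs_c**2).sum() * (tri_c**2).sum())
    return float((obs_c * tri_c).sum() / denom)


def call_peaks(
    ip: CoverageTrack,
    controls: list[CoverageTrack],
    params: PeakCallerParams,
) -> list[Peak]:
    """Dual-threshold peak calling: a base qualifies iff normalized IP
    coverage > ip_threshold and coverage in *every* control <
    control_threshold. Qualifying runs (gaps <= merge_gap bridged, width >=
    min_width) become peaks, with summit = leftmost argmax of IP coverage."""
    if not ip.normalized or any(not c.normalized for c in controls):
        raise ValueError("call_peaks requires median-normalized tracks")
    for c in controls:
        if c.chrom != ip.chrom or len(c) != len(ip):
            raise ValueError("control track chromosome/length mismatch")

    qualifies = ip.values > params.ip_threshold
    for c in controls:
        qualifies &= c.values < params.control_threshold
    qualifies &= ~ip.exclusion_mask

    peaks = []
    for start, end in _runs_from_mask(qualifies, params.merge_gap):
        if end - start < params.min_width:
            continue
        seg = ip.values[start:end]
        summit = start + int(np.argmax(seg))
        # score the shape over the peak's full extent plus flanking
        # background, so plateau-topped but localized pileups still read
        # as triangular while threshold-edge slivers do not
        flank = params.window_width + (end - start) // 2
        tri = triangularity_score(ip, summit, flank)
        peaks.append(
            Peak(
                chrom=ip.chrom,
                start=start,
                end=end,
                summit=summit,
                max_coverage=float(seg.max()),
                triangularity=tri,
                passed_shape=tri >= params.triangularity_min,
            )
        )
    return peaks


def extract_site_windows(
    genome: str, peaks: list[Peak], window_width: int
) -> list[str]:
    """The window_width bases centered on each summit: [summit - w//2,
    summit - w//2 + w). Windows overrunning a chromosome end are dropped
    with a warning; output order follows peak order."""
    windows = []
    L = len(genome)
    for i, pk in enumerate(peaks):
        lo = pk.summit - window_width // 2
        hi = lo + window_width
        if lo < 0 or hi > L:
            logger.warning(
                "dropping window for peak %d at summit %d: [%d, %d) overruns "
                "the chromosome", i, pk.summit, lo, hi,
            )
            continue
        windows.append(genome[lo:hi])
    return windows


# ---------------------------------------------------------------------------
# peak table output

def peaks_to_bed6(peaks: list[Peak]) -> str:
    """6-column BED: name=peakNNN, score=max_coverage*100 rounded, strand '.'."""
    lines = []
    for i, pk in enumerate(peaks):
        lines.append(
            f"{pk.chrom}\t{pk.start}\t{pk.end}\tpeak{i:03d}\t"
            f"{int(round(pk.max_coverage * 100))}\t."
        )
    return "\n".join(lines) + ("\n" if lines else "")


def peaks_to_tsv(peaks: list[Peak]) -> str:
    lines = ["chrom\tstart\tend\tsummit\tmax_coverage\ttriangularity\tpassed_shape"]
    for pk in peaks:
        lines.append(
            f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.summit}\t"
            f"{pk.max_coverage:.6g}\t{pk.triangularity:.4f}\t{int(pk.passed_shape)}"
        )
    return "\n".join(lines) + "\n"
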