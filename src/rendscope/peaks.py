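"""End-count peak calling and shadow correction.

A peak is a position whose normalized end count stands at least
``z_threshold``-fold over the local background (mean count in a +/-50 nt
window excluding the immediate +/-2 nt) and above an absolute floor.  Reads
originating at a strong peak deposit a spurious opposite-end signal one
fragment length away — the "shadow"; it is removed by down-weighting the
opposite-end contributions of peak-originating reads by the peak's enrichment
factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .synthetic import AnnotatedGenome
from .tracks import EndTrack, LengthFilter, TrackSet, retained_alignments

__all__ = ["PeakParams", "Peak", "call_peaks", "call_all_peaks", "remove_shadows", "write_peaks_bed"]


@dataclass(frozen=True)
class PeakParams:
    half_window: int = 50
    gap: int = 2
    z_threshold: float = 10.0
    min_count: float = 5.0
    background_floor: float = 0.25

    def __post_init__(self) -> None:
        if not self.half_window > self.gap >= 0:
            raise ValueError("require half_window > gap >= 0")
        if self.z_threshold <= 1:
            raise ValueError("z_threshold must be > 1")
        if self.min_count <= 0:
            raise ValueError("min_count must be > 0")


@dataclass(frozen=True)
class Peak:
    ref_id: str
    strand: str
    end_type: str
    position: int  # 1-based
    count: float  # normalized units
    background: float  # local mean, normalized units
    enrichment_factor: float  # count / max(background, background_floor)


def _local_background(arr: np.ndarray, half_window: int, gap: int) -> np.ndarray:
    """Mean of counts in [i-hw, i+hw] excluding [i-gap, i+gap], truncated at
    the reference ends; zero-count positions participate in the mean."""
    n = len(arr)
    cs = np.concatenate([[0.0], np.cumsum(arr)])

    def window_sum(h: int) -> tuple[np.ndarray, np.ndarray]:
        i = np.arange(n)
        lo = np.maximum(i - h, 0)
        hi = np.minimum(i + h, n - 1)
        return cs[hi + 1] - cs[lo], (hi - lo + 1).astype(float)

    s_out, n_out = window_sum(half_window)
    s_in, n_in = window_sum(gap)
    denom = n_out - n_in
    with np.errstate(invalid="ignore", divide="ignore"):
        bg = np.where(denom > 0, (s_out - s_in) / np.maximum(denom, 1), 0.0)
    return bg


def call_peaks(track: EndTrack, params: PeakParams | None = None) -> list[Peak]:
    """Call peaks on one normalized end track, sorted by position."""
    params = params or PeakParams()
    if not track.normalized:
        raise ValueError("call_peaks requires a normalized track")
    arr = track.to_array()
    if not track.counts:
        return []
    bg = _local_background(arr, params.half_window, params.gap)
    is_peak = (arr >= params.min_count) & (arr >= params.z_threshold * bg)
    peaks = []
    for i in np.nonzero(is_peak)[0]:
        b = float(bg[i])
        peaks.append(
            Peak(
                ref_id=track.ref_id,
                strand=track.strand,
                end_type=track.end_type,
                position=int(i) + 1,
                count=float(arr[i]),
                background=b,
                enrichment_factor=float(arr[i]) / max(b, params.background_floor),
            )
        )
    return peaks


def call_all_peaks(tracks: TrackSet, params: PeakParams | None = None) -> list[Peak]:
    peaks: list[Peak] = []
    for t in sorted(tracks, key=lambda t: (t.ref_id, t.strand, t.end_type)):
        peaks.extend(call_peaks(t, params))
    return peaks


def remove_shadows(
    tracks: TrackSet,
    peaks: Sequence[Peak],
    alignments: Sequence[AlignmentRecord] | None = None,
    genome: AnnotatedGenome | None = None,
    length_filter: LengthFilter | None = None,
) -> TrackSet:
    """Down-weight the opposite-end contributions of peak-originating reads.

    For each 5' peak at p, every retained alignment whose (reassigned) 5' end
    is p contributes 1/enrichment_factor of its weight to the 3' track, and
    symmetrically for 3' peaks shadowing the 5' track.  All factors are taken
    from the pre-correction tracks (5' peaks first, 3' second, but frozen
    factors make the order immaterial).

    When ``alignments`` is None a wig-only fallback divides opposite-end
    counts within one fragment-length window of each peak by its enrichment
    factor; this equals read attribution only when peak reads share uniform
    opposite ends.
    """
    if tracks.corrected:
        raise ValueError("tracks already shadow-corrected")
    if not tracks.normalized:
        raise ValueError("remove_shadows requires normalized tracks")
    lf = length_filter or LengthFilter()

    factor: dict[tuple[str, str, str], dict[int, float]] = {}
    for pk in peaks:
        track = tracks.get(pk.ref_id, pk.strand, pk.end_type)
        if pk.position not in track.counts:
            raise ValueError(
                f"peak position {pk.ref_id}:{pk.position} absent from "
                f"{pk.end_type}/{pk.strand} track"
            )
        factor.setdefault((pk.ref_id, pk.strand, pk.end_type), {})[
            pk.position
        ] = pk.enrichment_factor

    out = tracks.copy()

    if alignments is not None:
        if genome is None:
            raise ValueError("read-attributed correction needs the genome for masking")
        for a in retained_alignments(alignments, genome, lf):
            w = tracks.get(a.ref_id, a.strand, "5p").scale_factor or 0.0
            ef5 = factor.get((a.ref_id, a.strand, "5p"), {}).get(a.five_prime)
            if ef5 is not None:
                t3 = out.get(a.ref_id, a.strand, "3p")
                t3.counts[a.three_prime] = max(
                    t3.counts.get(a.three_prime, 0.0) - w * (1 - 1 / ef5), 0.0
                )
            ef3 = factor.get((a.ref_id, a.strand, "3p"), {}).get(a.three_prime)
            if ef3 is not None:
                t5 = out.get(a.ref_id, a.strand, "5p")
                t5.counts[a.five_prime] = max(
                    t5.counts.get(a.five_prime, 0.0) - w * (1 - 1 / ef3), 0.0
                )
    else:
        for pk in peaks:
            opp = "3p" if pk.end_type == "5p" else "5p"
            t = out.get(pk.ref_id, pk.strand, opp)
            p = pk.position
            sign = 1 if pk.strand == "+" else -1
            if pk.end_type == "5p":
                lo, hi = p + sign * lf.min_len, p + sign * lf.max_len
            else:
                lo, hi = p - sign * lf.max_len, p - sign * lf.min_len
            lo, hi = min(lo, hi), max(lo, hi)
            for q in list(t.counts):
                if lo <= q <= hi:
                    t.counts[q] /= pk.enrichment_factor

    for t in out:
        t.corrected = True
    return out


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """BED6; score = enrichment factor capped at 1000."""
    rows = [
        (
            pk.ref_id,
            pk.position - 1,
            pk.position,
            pk.end_type,
            min(int(round(pk.enrichment_factor)), 1000),
            pk.strand,
        )
        for pk in peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
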