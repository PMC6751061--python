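"""Condition-induced promoter calling and operon assignment.

A promoter is called at each induced-condition 5'-end peak whose windowed
fold change (induced/control, both normalized and shadow-corrected, with a
pseudocount) is at least 10-fold — the criterion used to collect a
sigma-factor regulon after artificial induction.  For each call the -40..+1
window (41 nt, transcription orientation) is extracted for motif analysis,
and the operon is read off as the same-strand genes lying between the TSS and
the nearest downstream 3'-end peak.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._seq import revcomp
from .peaks import Peak
from .synthetic import AnnotatedGenome, Gene
from .tracks import EndTrack

__all__ = [
    "RegulonParams",
    "PromoterCall",
    "fold_change_track",
    "merge_nearby_peaks",
    "call_induced_promoters",
    "upstream_window",
    "infer_operon",
    "complete_call",
    "build_regulon_table",
    "write_upstream_fasta",
    "write_tss_bed",
]


@dataclass(frozen=True)
class RegulonParams:
    fc_threshold: float = 10.0
    fc_window: int = 2  # +/- nt summed on both tracks before the ratio
    pseudocount: float = 0.5  # normalized units
    upstream_len: int = 40  # -40..+1 inclusive = 41 nt
    max_operon_scan: int = 15_000
    min_gene_overlap: float = 0.5
    merge_within: int = 5  # nearby 5' peaks merged to the higher one

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.upstream_len < 1:
            raise ValueError("upstream_len must be >= 1")


@dataclass
class PromoterCall:
    name: str
    ref_id: str
    strand: str
    tss: int
    fold_change: float
    upstream41: str = ""
    operon_genes: tuple[str, ...] = ()
    transcript_end3: int | None = None
    source: str = "rendseq"


def fold_change_track(
    track_induced: EndTrack,
    track_control: EndTrack,
    params: RegulonParams | None = None,
) -> dict[int, float]:
    """FC(i) = (A(i)+c) / (B(i)+c), A/B = windowed sums of normalized 5' counts.

    Positions where both windowed sums are zero are omitted.
    """
    params = params or RegulonParams()
    for t in (track_induced, track_control):
        if not t.normalized:
            raise ValueError("fold_change_track requires normalized tracks")
    key = (track_induced.ref_id, track_induced.strand, track_induced.end_type)
    if key != (track_control.ref_id, track_control.strand, track_control.end_type):
        raise ValueError("mismatched ref/strand/end-type between conditions")
    if track_induced.end_type != "5p":
        raise ValueError("fold changes are defined on 5' tracks")

    w, c = params.fc_window, params.pseudocount
    candidates: set[int] = set()
    for t in (track_induced, track_control):
        for p in t.counts:
            candidates.update(range(p - w, p + w + 1))
    out: dict[int, float] = {}
    for i in sorted(candidates):
        a = sum(track_induced.counts.get(j, 0.0) for j in range(i - w, i + w + 1))
        b = sum(track_control.counts.get(j, 0.0) for j in range(i - w, i + w + 1))
        if a == 0.0 and b == 0.0:
            continue
        out[i] = (a + c) / (b + c)
    return out


def merge_nearby_peaks(peaks: Sequence[Peak], within: int = 5) -> list[Peak]:
    """Collapse peaks closer than ``within`` nt (same ref/strand/end-type) to
    the highest-count one; ties keep the leftmost."""
    out: list[Peak] = []
    by_group: dict[tuple[str, str, str], list[Peak]] = {}
    for pk in peaks:
        by_group.setdefault((pk.ref_id, pk.strand, pk.end_type), []).append(pk)
    for group in by_group.values():
        group = sorted(group, key=lambda p: p.position)
        cluster: list[Peak] = []
        for pk in group:
            if cluster and pk.position - cluster[-1].position <= within:
                cluster.append(pk)
            else:
                if cluster:
                    out.append(max(cluster, key=lambda p: (p.count, -p.position)))
                cluster = [pk]
        if cluster:
            out.append(max(cluster, key=lambda p: (p.count, -p.position)))
    return sorted(out, key=lambda p: (p.ref_id, p.position))


def call_induced_promoters(
    fc_map: Mapping[int, float],
    peaks_induced: Sequence[Peak],
    params: RegulonParams | None = None,
) -> list[PromoterCall]:
    """One (partial) promoter call per induced 5' peak with FC >= threshold.

    ``fc_map`` must come from the same ref/strand the peaks were called on.
    The peak position is taken as the +1 site.
    """
    params = params or RegulonParams()
    five = [p for p in peaks_induced if p.end_type == "5p"]
    five = merge_nearby_peaks(five, params.merge_within)
    calls = []
    for pk in five:
        fc = fc_map.get(pk.position)
        if fc is not None and fc >= params.fc_threshold:
            calls.append(
                PromoterCall(
                    name=f"orphan:{pk.position}",
                    ref_id=pk.ref_id,
                    strand=pk.strand,
                    tss=pk.position,
                    fold_change=fc,
                )
            )
    return calls


def upstream_window(
    genome: AnnotatedGenome,
    ref_id: str,
    tss: int,
    strand: str,
    params: RegulonParams | None = None,
) -> str:
    """The -40..+1 window in transcription orientation (41 nt; +1 base last)."""
    params = params or RegulonParams()
    u = params.upstream_len
    if strand == "+":
        return genome.fetch(ref_id, tss - u, tss)
    return revcomp(genome.fetch(ref_id, tss, tss + u))


def infer_operon(
    call: PromoterCall,
    peaks_3prime: Sequence[Peak],
    genes: Sequence[Gene],
    params: RegulonParams | None = None,
) -> PromoterCall:
    """Complete a call with the transcript 3' end and the operon gene list.

    The transcript end is the nearest same-strand 3' peak downstream of the
    TSS within ``max_operon_scan``; operon genes are same-strand genes with at
    least ``min_gene_overlap`` of their length inside [tss, end3], in
    transcription order, and the call is renamed for the first of them.
    """
    params = params or RegulonParams()
    sign = 1 if call.strand == "+" else -1
    downstream = [
        pk.position
        for pk in peaks_3prime
        if pk.end_type == "3p"
        and pk.ref_id == call.ref_id
        and pk.strand == call.strand
        and 0 < sign * (pk.position - call.tss) <= params.max_operon_scan
    ]
    end3 = min(downstream, key=lambda p: sign * (p - call.tss)) if downstream else None

    operon: list[Gene] = []
    if end3 is not None:
        lo, hi = min(call.tss, end3), max(call.tss, end3)
        for g in genes:
            if g.ref_id != call.ref_id or g.strand != call.strand:
                continue
            overlap = max(0, min(hi, g.end) - max(lo, g.start) + 1)
            if overlap / (g.end - g.start + 1) >= params.min_gene_overlap:
                operon.append(g)
        operon.sort(key=lambda g: sign * g.start)

    name = operon[0].name if operon else f"orphan:{call.tss}"
    return dataclasses.replace(
        call,
        name=name,
        transcript_end3=end3,
        operon_genes=tuple(g.name for g in operon),
    )


def complete_call(
    call: PromoterCall,
    genome: AnnotatedGenome,
    peaks_3prime: Sequence[Peak],
    params: RegulonParams | None = None,
) -> PromoterCall:
    call = infer_operon(call, peaks_3prime, genome.genes, params)
    call.upstream41 = upstream_window(genome, call.ref_id, call.tss, call.strand, params)
    return call


def _fmt_fc(fc: float) -> str:
    if fc != fc:  # NaN: promoter predicted by scan, no measured fold change
        return ""
    s = f"{fc:.1f}"
    return s[:-2] if s.endswith(".0") else s


def build_regulon_table(calls: Sequence[PromoterCall]) -> pd.DataFrame:
    """Tab-separable regulon table: one row per called promoter, sorted by
    reference then position; fold changes printed to one decimal place with a
    trailing .0 dropped (101.0 -> "101")."""
    rows = [
        {
            "promoter": c.name,
            "sequence": c.upstream41,
            "operon": " ".join(c.operon_genes) if c.operon_genes else "",
            "fold_change": _fmt_fc(c.fold_change),
            "source": c.source,
            "ref_id": c.ref_id,
            "tss": c.tss,
            "strand": c.strand,
        }
        for c in sorted(calls, key=lambda c: (c.ref_id, c.tss))
    ]
    return pd.DataFrame(
        rows,
        columns=["promoter", "sequence", "operon", "fold_change", "source", "ref_id", "tss", "strand"],
    )


def write_upstream_fasta(calls: Sequence[PromoterCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.ref_id, c.tss)):
            fh.write(f">{c.name}\n{c.upstream41}\n")


def write_tss_bed(calls: Sequence[PromoterCall], path: str | Path) -> None:
    rows = [
        (c.ref_id, c.tss - 1, c.tss, c.name, min(int(round(c.fold_change)), 1000), c.strand)
        for c in sorted(calls, key=lambda c: (c.ref_id, c.tss))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
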