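"""Per-position 5'/3' end counting, normalization, and wig track IO.

Each (reference, strand, end-type) gets its own sparse track of counts at
1-based genomic positions.  Alignments overlapping an rRNA/tRNA mask feature
by at least one nucleotide are excluded from both the tracks and the
normalization denominator; the length filter (15-45 nt by default, applied
after 5' reassignment) gates which ends are counted.  Normalization is per
million non-rRNA/tRNA aligned reads, matching the convention for comparing
end-enriched libraries of different depth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .synthetic import AnnotatedGenome

__all__ = [
    "LengthFilter",
    "EndTrack",
    "TrackSet",
    "count_ends",
    "retained_alignments",
    "count_nonribo",
    "normalize_tracks",
    "write_wig",
    "read_wig",
    "read_gff3_masks",
]

END_TYPES = ("5p", "3p")
STRANDS = ("+", "-")


@dataclass(frozen=True)
class LengthFilter:
    min_len: int = 15
    max_len: int = 45

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")

    def accepts(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


@dataclass
class EndTrack:
    ref_id: str
    strand: str
    end_type: str  # '5p' | '3p'
    ref_len: int
    counts: dict[int, float] = field(default_factory=dict)
    normalized: bool = False
    scale_factor: float | None = None
    corrected: bool = False

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.ref_len, dtype=float)
        if self.counts:
            pos = np.fromiter(self.counts.keys(), dtype=int)
            val = np.fromiter(self.counts.values(), dtype=float)
            arr[pos - 1] = val
        return arr

    def copy(self) -> "EndTrack":
        return copy.deepcopy(self)


class TrackSet:
    """The four tracks per reference: {5',3'} x {+,-}."""

    def __init__(self, tracks: Iterable[EndTrack] = ()):
        self._tracks: dict[tuple[str, str, str], EndTrack] = {}
        for t in tracks:
            self.add(t)

    def add(self, track: EndTrack) -> None:
        self._tracks[(track.ref_id, track.strand, track.end_type)] = track

    def get(self, ref_id: str, strand: str, end_type: str) -> EndTrack:
        return self._tracks[(ref_id, strand, end_type)]

    def __iter__(self) -> Iterator[EndTrack]:
        return iter(self._tracks.values())

    def __len__(self) -> int:
        return len(self._tracks)

    def copy(self) -> "TrackSet":
        return TrackSet(t.copy() for t in self._tracks.values())

    @property
    def normalized(self) -> bool:
        return all(t.normalized for t in self._tracks.values())

    @property
    def corrected(self) -> bool:
        return any(t.corrected for t in self._tracks.values())


def _mask_arrays(genome: AnnotatedGenome) -> dict[str, np.ndarray]:
    masks = {rid: np.zeros(len(seq), dtype=bool) for rid, seq in genome.sequences.items()}
    for rid, s, e in genome.mask_features:
        masks[rid][s - 1 : e] = True
    return masks


def retained_alignments(
    alignments: Sequence[AlignmentRecord],
    genome: AnnotatedGenome,
    length_filter: LengthFilter | None = None,
) -> list[AlignmentRecord]:
    """Alignments that survive the mask-overlap exclusion and length filter —
    exactly the reads whose ends enter the tracks."""
    lf = length_filter or LengthFilter()
    masks = _mask_arrays(genome)
    out = []
    for a in alignments:
        n = genome.length(a.ref_id)
        if a.start < 1 or a.end > n:
            raise ValueError(f"alignment of read {a.read_id} beyond reference bounds")
        if masks[a.ref_id][a.start - 1 : a.end].any():
            continue
        if lf.accepts(a.length):
            out.append(a)
    return out


def count_nonribo(alignments: Sequence[AlignmentRecord], genome: AnnotatedGenome) -> int:
    """Normalization denominator: aligned reads with no mask overlap,
    counted before the length filter."""
    masks = _mask_arrays(genome)
    return sum(
        1 for a in alignments if not masks[a.ref_id][a.start - 1 : a.end].any()
    )


def count_ends(
    alignments: Sequence[AlignmentRecord],
    genome: AnnotatedGenome,
    length_filter: LengthFilter | None = None,
) -> TrackSet:
    """Count read 5' and 3' ends per position/strand into raw tracks.

    Expects alignments that have already been 5'-reassigned.  Each retained
    alignment increments exactly one position in the 5' track and one in the
    3' track of its strand.
    """
    tracks = TrackSet(
        EndTrack(rid, strand, end, len(seq))
        for rid, seq in genome.sequences.items()
        for strand in STRANDS
        for end in END_TYPES
    )
    for a in retained_alignments(alignments, genome, length_filter):
        t5 = tracks.get(a.ref_id, a.strand, "5p")
        t3 = tracks.get(a.ref_id, a.strand, "3p")
        t5.counts[a.five_prime] = t5.counts.get(a.five_prime, 0) + 1
        t3.counts[a.three_prime] = t3.counts.get(a.three_prime, 0) + 1
    return tracks


def normalize_tracks(tracks: TrackSet, n_nonribo_reads: int) -> TrackSet:
    """Scale every count by 1e6 / n_nonribo_reads (reads per million)."""
    if n_nonribo_reads <= 0:
        raise ValueError("n_nonribo_reads must be > 0")
    out = TrackSet()
    scale = 1e6 / n_nonribo_reads
    for t in tracks:
        if t.normalized:
            raise ValueError(f"track {t.ref_id}/{t.strand}/{t.end_type} already normalized")
        nt = t.copy()
        nt.counts = {p: c * scale for p, c in t.counts.items()}
        nt.normalized = True
        nt.scale_factor = scale
        out.add(nt)
    return out


# ---------------------------------------------------------------------------
# wig IO (variableStep, 1-based positions)


def _track_name(t: EndTrack) -> str:
    strand = "fwd" if t.strand == "+" else "rev"
    return f"{t.ref_id}_{t.end_type}_{strand}"


def write_wig(tracks: TrackSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sorted(tracks, key=_track_name):
            flags = []
            if t.normalized:
                flags.append("normalized")
            if t.corrected:
                flags.append("shadow-corrected")
            desc = f" ({', '.join(flags)})" if flags else ""
            fh.write(
                f'track type=wiggle_0 name="{_track_name(t)}" '
                f'description="{t.end_type} ends {t.strand} strand{desc}" '
                f"reflen={t.ref_len} normalized={int(t.normalized)} "
                f"corrected={int(t.corrected)} scale={t.scale_factor or 0:.10g}\n"
            )
            fh.write(f"variableStep chrom={t.ref_id}\n")
            for p in sorted(t.counts):
                fh.write(f"{p}\t{t.counts[p]:.6f}\n")


def read_wig(path: str | Path) -> TrackSet:
    tracks = TrackSet()
    cur: EndTrack | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("track"):
                kv = dict(
                    part.split("=", 1)
                    for part in line.split()
                    if "=" in part and not part.startswith("description")
                )
                name = kv["name"].strip('"')
                ref_id, end_type, strand_word = name.rsplit("_", 2)[0], *name.rsplit("_", 2)[1:]
                cur = EndTrack(
                    ref_id=ref_id,
                    strand="+" if strand_word == "fwd" else "-",
                    end_type=end_type,
                    ref_len=int(kv["reflen"]),
                    normalized=bool(int(kv.get("normalized", "0"))),
                    corrected=bool(int(kv.get("corrected", "0"))),
                    scale_factor=float(kv.get("scale", "0")) or None,
                )
                tracks.add(cur)
            elif line.startswith("variableStep") or not line:
                continue
            else:
                pos, val = line.split("\t")
                assert cur is not None, "wig data before track header"
                cur.counts[int(pos)] = float(val)
    return tracks


def _read_gff3(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
    )


def read_gff3_masks(path: str | Path) -> list[tuple[str, int, int]]:
    """Read rRNA/tRNA mask intervals from a GFF3 file."""
    df = _read_gff3(path)
    keep = df["type"].isin(["rRNA", "tRNA"])
    return [
        (str(r.seqid), int(r.start), int(r.end))
        for r in df[keep].itertuples(index=False)
    ]


def read_gff3_genes(path: str | Path) -> list:
    """Read gene features from a GFF3 file into Gene records."""
    from .synthetic import Gene

    df = _read_gff3(path)
    genes = []
    for r in df[df["type"] == "gene"].itertuples(index=False):
        attrs = dict(
            kv.split("=", 1) for kv in str(r.attrs).split(";") if "=" in kv
        )
        name = attrs.get("Name") or attrs.get("ID") or f"{r.seqid}:{r.start}"
        genes.append(Gene(name, str(r.seqid), int(r.start), int(r.end), str(r.strand)))
    return genes
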