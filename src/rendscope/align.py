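"""One-mismatch, single-reported-hit read alignment with 5'-mismatch reassignment.

The mapping policy mirrors the classic short-read setting used for end-enriched
libraries: report one best locus per read, allowing at most one substitution
(``-v 1 -k 1`` semantics).  Because the read 5' end carries the positional
signal, reads whose 5'-most base mismatches the reference — the signature of a
non-templated base added during reverse transcription — have their 5' end
reassigned one position downstream before end counting.

The aligner is exact for ``max_mismatches <= 1``: a pigeonhole seed index over
7-mers guarantees that every locus with at most one substitution is examined
for reads of length >= 14; shorter reads fall back to a full scan.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from ._seq import encode, revcomp
from .synthetic import AnnotatedGenome, SimRead

__all__ = [
    "AlignParams",
    "AlignmentRecord",
    "GenomeIndex",
    "align_reads",
    "reassign_5prime",
    "reassign_all",
    "write_sam",
    "read_sam",
]

logger = logging.getLogger(__name__)

_SEED_K = 7


@dataclass(frozen=True)
class AlignParams:
    max_mismatches: int = 1
    max_hits: int = 1

    def __post_init__(self) -> None:
        if self.max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        if self.max_hits != 1:
            raise ValueError("only max_hits=1 is supported")


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    ref_id: str
    start: int  # 1-based leftmost aligned base on the reference
    strand: str
    length: int
    mismatch_offsets: tuple[int, ...] = ()  # 0-based, read orientation
    ambiguous: bool = False

    @property
    def end(self) -> int:
        """1-based rightmost aligned base."""
        return self.start + self.length - 1

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


class GenomeIndex:
    """Seed index over both strands of every reference.

    Minus-strand text is the reverse complement of the reference, so a read
    aligned to it runs left-to-right in read orientation; position ``p`` in the
    reverse-complement text of a reference of length ``n`` corresponds to the
    genomic leftmost coordinate ``n - p - L`` (0-based) for an ``L``-long read.
    """

    def __init__(self, genome: AnnotatedGenome):
        if not genome.sequences:
            raise ValueError("empty reference")
        self.ref_ids = sorted(genome.sequences)
        self.texts: dict[tuple[str, str], str] = {}
        for rid in self.ref_ids:
            seq = genome.sequences[rid]
            if not seq:
                raise ValueError(f"empty reference {rid}")
            self.texts[(rid, "+")] = seq
            self.texts[(rid, "-")] = revcomp(seq)
        self.seeds: dict[str, list[tuple[str, str, int]]] = {}
        for key, text in self.texts.items():
            for p in range(len(text) - _SEED_K + 1):
                self.seeds.setdefault(text[p : p + _SEED_K], []).append((*key, p))

    def ref_len(self, rid: str) -> int:
        return len(self.texts[(rid, "+")])


def _count_mismatches(read: str, text: str, pos: int, cap: int) -> tuple[int, tuple[int, ...]]:
    mm = 0
    offs: list[int] = []
    for j in range(len(read)):
        a = read[j]
        if a != text[pos + j] or a == "N":
            mm += 1
            if mm > cap:
                return mm, ()
            offs.append(j)
    return mm, tuple(offs)


def _candidates_seeded(index: GenomeIndex, read: str) -> set[tuple[str, str, int]]:
    cands: set[tuple[str, str, int]] = set()
    L = len(read)
    for seed_off in (0, _SEED_K):
        seed = read[seed_off : seed_off + _SEED_K]
        for rid, strand, p in index.seeds.get(seed, ()):
            left = p - seed_off
            if 0 <= left and left + L <= len(index.texts[(rid, strand)]):
                cands.add((rid, strand, left))
    return cands


def _candidates_full(index: GenomeIndex, read: str) -> Iterable[tuple[str, str, int]]:
    enc = encode(read)
    enc = np.where(enc == 4, 5, enc)  # read N (4->5) never equals any text value
    L = len(read)
    for (rid, strand), text in index.texts.items():
        t = encode(text)
        if len(t) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(t, L)
        mm = (win != enc).sum(axis=1)
        for p in np.nonzero(mm <= 1)[0]:
            yield rid, strand, int(p)


def align_reads(
    reads: Sequence[SimRead],
    genome: AnnotatedGenome,
    params: AlignParams | None = None,
    index: GenomeIndex | None = None,
) -> list[AlignmentRecord]:
    """Align each read to its minimal-mismatch locus, if that minimum is
    within ``params.max_mismatches``; ties set the ``ambiguous`` flag and are
    broken deterministically (ref id, then coordinate, then + before -)."""
    params = params or AlignParams()
    index = index or GenomeIndex(genome)
    out: list[AlignmentRecord] = []
    for read in reads:
        seq = read.seq.upper()
        if not seq:
            logger.warning("skipping empty read %s", read.read_id)
            continue
        L = len(seq)
        if L >= 2 * _SEED_K:
            cands = _candidates_seeded(index, seq)
        else:
            cands = set(_candidates_full(index, seq))
        best_mm = params.max_mismatches + 1
        hits: list[tuple[str, str, int, tuple[int, ...]]] = []
        for rid, strand, left in cands:
            text = index.texts[(rid, strand)]
            if text[left : left + L] == seq and "N" not in seq:
                mm, offs = 0, ()
            else:
                mm, offs = _count_mismatches(seq, text, left, params.max_mismatches)
            if mm > params.max_mismatches:
                continue
            if mm < best_mm:
                best_mm = mm
                hits = [(rid, strand, left, offs)]
            elif mm == best_mm:
                hits.append((rid, strand, left, offs))
        if not hits:
            continue

        def genomic_start(h: tuple[str, str, int, tuple[int, ...]]) -> int:
            rid, strand, left, _ = h
            n = index.ref_len(rid)
            return left if strand == "+" else n - left - L

        hits.sort(key=lambda h: (h[0], genomic_start(h), 0 if h[1] == "+" else 1))
        rid, strand, left, offs = hits[0]
        out.append(
            AlignmentRecord(
                read_id=read.read_id,
                ref_id=rid,
                start=genomic_start(hits[0]) + 1,
                strand=strand,
                length=L,
                mismatch_offsets=offs,
                ambiguous=len(hits) > 1,
            )
        )
    return out


def reassign_5prime(alignment: AlignmentRecord) -> AlignmentRecord | None:
    """If the 5'-most read base mismatches, move the alignment's 5' terminus one
    base downstream (toward the read 3' end); otherwise return unchanged.

    Returns None (with a warning) if trimming would leave an empty alignment.
    """
    if 0 not in alignment.mismatch_offsets:
        return alignment
    if alignment.length <= 1:
        logger.warning("dropping read %s: 5' reassignment leaves no bases", alignment.read_id)
        return None
    new_offs = tuple(o - 1 for o in alignment.mismatch_offsets if o != 0)
    start = alignment.start + 1 if alignment.strand == "+" else alignment.start
    return dataclasses.replace(
        alignment, start=start, length=alignment.length - 1, mismatch_offsets=new_offs
    )


def reassign_all(alignments: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    out = []
    for a in alignments:
        r = reassign_5prime(a)
        if r is not None:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# SAM interoperability (text SAM, single reference block per record)


def _sam_header(genome: AnnotatedGenome) -> pysam.AlignmentHeader:
    rids = sorted(genome.sequences)
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": rid, "LN": len(genome.sequences[rid])} for rid in rids],
        }
    )


def write_sam(
    alignments: Sequence[AlignmentRecord],
    genome: AnnotatedGenome,
    path: str | Path,
    reads: Sequence[SimRead] | None = None,
) -> None:
    header = _sam_header(genome)
    seq_by_id = {r.read_id: r.seq for r in reads} if reads else {}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_id
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_name = a.ref_id
            seg.reference_start = a.start - 1
            seg.mapping_quality = 255
            seg.cigarstring = f"{a.length}M"
            seq = seq_by_id.get(a.read_id)
            if seq is not None:
                seg.query_sequence = seq if a.strand == "+" else revcomp(seq)
            seg.set_tag("NM", len(a.mismatch_offsets))
            fh.write(seg)


def read_sam(path: str | Path, genome: AnnotatedGenome | None = None) -> list[AlignmentRecord]:
    """Read a (text) SAM of simple single-block records back into AlignmentRecords.

    Mismatch offsets are recomputed against ``genome`` when provided, else left
    empty (the NM tag count alone cannot localize the mismatch).
    """
    out = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            strand = "-" if seg.is_reverse else "+"
            length = seg.query_length or seg.infer_query_length()
            offs: tuple[int, ...] = ()
            if genome is not None and seg.query_sequence:
                ref = genome.sequences[seg.reference_name]
                refseq = ref[seg.reference_start : seg.reference_start + length]
                # SAM stores SEQ in reference orientation; compare in read orientation
                if strand == "+":
                    readseq, text = seg.query_sequence, refseq
                else:
                    readseq, text = revcomp(seg.query_sequence), revcomp(refseq)
                offs = tuple(j for j in range(length) if readseq[j] != text[j])
            out.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    ref_id=seg.reference_name,
                    start=seg.reference_start + 1,
                    strand=strand,
                    length=int(length),
                    mismatch_offsets=offs,
                )
            )
    return out
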