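"""Synthetic annotated genomes and end-enriched read simulation.

End-enriched RNA-seq (Rend-seq) sparsely fragments transcripts so that a
disproportionate share of sequenced fragments retain an original transcript
5' or 3' end; counting read ends then marks transcription start sites and
terminators as sharp single-nucleotide spikes.  This module builds toy
annotated genomes with planted transcription units (TUs) and simulates reads
with that statistical structure, recording per-read ground truth so the
downstream analysis can be validated end to end.

Coordinates are 1-based inclusive in every public field; internal arithmetic
uses 0-based half-open slices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import BASES, revcomp

__all__ = [
    "TranscriptionUnit",
    "Gene",
    "AnnotatedGenome",
    "SimulatorParams",
    "SimRead",
    "GroundTruthRecord",
    "GroundTruth",
    "make_genome",
    "simulate_reads",
    "standard_fixture",
    "STANDARD_FIXTURE_CONDITIONS",
    "write_fasta",
    "write_fastq",
    "write_gff3",
    "write_truth_bed",
    "write_truth_table",
]


class PlacementError(ValueError):
    """Raised when requested transcription units cannot be placed on a reference."""


@dataclass(frozen=True)
class Gene:
    name: str
    ref_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str


@dataclass(frozen=True)
class TranscriptionUnit:
    """A planted transcript: +1 site, last transcribed base, and abundances.

    ``abundance`` maps condition label -> expected transcript copy number
    (arbitrary non-negative units; only ratios matter to the simulator).
    """

    name: str
    ref_id: str
    tss: int
    end3: int
    strand: str
    abundance: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.strand == "+" and self.tss > self.end3:
            raise ValueError(f"TU {self.name}: + strand requires tss <= end3")
        if self.strand == "-" and self.tss < self.end3:
            raise ValueError(f"TU {self.name}: - strand requires tss >= end3")
        if any(v < 0 for v in self.abundance.values()):
            raise ValueError(f"TU {self.name}: negative abundance")

    @property
    def length(self) -> int:
        return abs(self.end3 - self.tss) + 1

    @property
    def span(self) -> tuple[int, int]:
        """(leftmost, rightmost) genomic coordinates, 1-based inclusive."""
        return (min(self.tss, self.end3), max(self.tss, self.end3))


@dataclass
class AnnotatedGenome:
    """Reference sequences plus gene/mask annotation and any planted TUs."""

    sequences: dict[str, str]
    circular: dict[str, bool] = field(default_factory=dict)
    genes: list[Gene] = field(default_factory=list)
    mask_features: list[tuple[str, int, int]] = field(default_factory=list)
    planted_tus: list[TranscriptionUnit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences or any(len(s) == 0 for s in self.sequences.values()):
            raise ValueError("sequences must be non-empty")
        for rid in self.sequences:
            self.circular.setdefault(rid, False)
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            raise ValueError("gene names must be unique")
        for g in self.genes:
            if not (1 <= g.start <= g.end <= len(self.sequences[g.ref_id])):
                raise ValueError(f"gene {g.name} out of bounds")
        for rid, s, e in self.mask_features:
            if not (1 <= s <= e <= len(self.sequences[rid])):
                raise ValueError(f"mask feature {rid}:{s}-{e} out of bounds")

    def length(self, ref_id: str) -> int:
        return len(self.sequences[ref_id])

    def fetch(self, ref_id: str, start: int, end: int) -> str:
        """1-based inclusive slice of the forward strand, wrapping on circular refs."""
        seq = self.sequences[ref_id]
        n = len(seq)
        if 1 <= start <= end <= n:
            return seq[start - 1 : end]
        if self.circular.get(ref_id, False):
            return "".join(seq[(i - 1) % n] for i in range(start, end + 1))
        raise ValueError(f"window {ref_id}:{start}-{end} out of bounds on linear ref")


@dataclass(frozen=True)
class SimulatorParams:
    """Fragmentation and library parameters for the read simulator.

    ``p_true5``/``p_true3`` are the probabilities that a fragment retains the
    transcript's true 5' or 3' end; the remainder are internal fragments.  The
    protocol isolates 20-40 nt fragments, which the defaults mirror.  ``p_nta``
    models the single untemplated base reverse transcription can prepend to a
    read 5' end.
    """

    frag_len_min: int = 20
    frag_len_max: int = 40
    p_true5: float = 0.25
    p_true3: float = 0.25
    p_nta: float = 0.05
    err_rate: float = 0.001
    ribo_fraction: float = 0.10
    depth: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_true5", "p_true3", "p_nta", "err_rate", "ribo_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_true5 + self.p_true3 > 1.0:
            raise ValueError("p_true5 + p_true3 must be <= 1")
        if not 1 <= self.frag_len_min <= self.frag_len_max:
            raise ValueError("require 1 <= frag_len_min <= frag_len_max")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass(frozen=True)
class SimRead:
    read_id: str
    seq: str

    @property
    def qual(self) -> str:
        return "I" * len(self.seq)


@dataclass(frozen=True)
class GroundTruthRecord:
    read_id: str
    source: str  # TU name or mask feature label
    end_class: str  # '5p' | '3p' | 'internal' | 'ribo'
    ref_id: str
    strand: str
    genome5: int  # true genomic coordinate of the fragment 5' end (1-based)
    genome3: int
    nta: bool


@dataclass
class GroundTruth:
    records: list[GroundTruthRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])

    def expected_fold_changes(
        self, genome: AnnotatedGenome, induced: str, control: str
    ) -> dict[str, float]:
        """Planted abundance ratios (induced/control) per TU; inf if control is 0."""
        out = {}
        for tu in genome.planted_tus:
            a, b = tu.abundance.get(induced, 0.0), tu.abundance.get(control, 0.0)
            out[tu.name] = float("inf") if b == 0 else a / b
        return out


# ---------------------------------------------------------------------------
# Genome construction


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def _place_intervals(
    rng: np.random.Generator,
    ref_len: int,
    lengths: Sequence[int],
    forbidden: list[tuple[int, int]],
    margin: int = 60,
    max_tries: int = 2000,
) -> list[tuple[int, int]]:
    """Place non-overlapping 1-based intervals avoiding `forbidden`, with a
    `margin` clearance on both sides (room for upstream promoter windows)."""
    placed: list[tuple[int, int]] = []
    occupied = list(forbidden)
    for L in lengths:
        ok = None
        if ref_len - L - margin + 1 <= margin + 1:
            raise PlacementError(
                f"could not place a {L} bp transcription unit on a {ref_len} bp reference"
            )
        for _ in range(max_tries):
            start = int(rng.integers(margin + 1, ref_len - L - margin + 1))
            end = start + L - 1
            if all(end + margin < s or start - margin > e for s, e in occupied):
                ok = (start, end)
                break
        if ok is None:
            raise PlacementError(
                f"could not place a {L} bp transcription unit on a {ref_len} bp reference"
            )
        placed.append(ok)
        occupied.append(ok)
    return placed


def make_genome(
    n_refs: int = 1,
    ref_lengths: int | Sequence[int] = 60_000,
    n_tus: int = 0,
    tu_spec: Sequence[Mapping] | Mapping | None = None,
    seed: int = 0,
    mask_len: int = 2_000,
) -> AnnotatedGenome:
    """Build a random annotated genome with planted transcription units.

    Each reference carries one rRNA-like mask locus.  ``tu_spec`` is either a
    single template dict applied to every TU or a list of ``n_tus`` dicts with
    optional keys ``length`` (default 2000), ``strand`` ('+'), ``abundance``
    ({'control': 1.0, 'induced': 1.0}), ``n_genes`` (1), ``tss`` (fixed +1
    coordinate instead of random placement) and ``embed`` (a 41-mer written
    into the sequence so its final base is the +1 base).
    """
    rng = np.random.default_rng(seed)
    if isinstance(ref_lengths, int):
        ref_lengths = [ref_lengths] * n_refs
    if len(ref_lengths) != n_refs:
        raise ValueError("ref_lengths must match n_refs")
    if any(rl < 1000 for rl in ref_lengths):
        raise ValueError("ref_lengths must be >= 1 kb")

    if tu_spec is None:
        specs = [dict() for _ in range(n_tus)]
    elif isinstance(tu_spec, Mapping):
        specs = [dict(tu_spec) for _ in range(n_tus)]
    else:
        specs = [dict(s) for s in tu_spec]
        if len(specs) != n_tus:
            raise ValueError("tu_spec list length must equal n_tus")

    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    masks: list[tuple[str, int, int]] = []
    tus: list[TranscriptionUnit] = []

    # round-robin TUs over refs
    per_ref: list[list[tuple[int, dict]]] = [[] for _ in range(n_refs)]
    for i, spec in enumerate(specs):
        per_ref[i % n_refs].append((i, spec))

    for r in range(n_refs):
        ref_id = f"ref{r + 1}"
        ref_len = int(ref_lengths[r])
        seq = list(_random_dna(rng, ref_len))

        # one rRNA mask locus per ref, in the first third
        m_start = int(rng.integers(200, max(201, ref_len // 3)))
        m_end = min(m_start + mask_len - 1, ref_len - 200)
        masks.append((ref_id, m_start, m_end))

        fixed = [(i, s) for i, s in per_ref[r] if s.get("tss") is not None]
        free = [(i, s) for i, s in per_ref[r] if s.get("tss") is None]

        forbidden = [(m_start, m_end)]
        spans: dict[int, tuple[int, int]] = {}
        for i, s in fixed:
            L = int(s.get("length", 2000))
            strand = s.get("strand", "+")
            tss = int(s["tss"])
            span = (tss, tss + L - 1) if strand == "+" else (tss - L + 1, tss)
            if not (1 <= span[0] <= span[1] <= ref_len):
                raise PlacementError(f"fixed TU at tss={tss} exceeds {ref_id}")
            spans[i] = span
            forbidden.append(span)
        lengths = [int(s.get("length", 2000)) for _, s in free]
        for (i, _), span in zip(free, _place_intervals(rng, ref_len, lengths, forbidden)):
            spans[i] = span

        for i, s in per_ref[r]:
            strand = s.get("strand", "+")
            left, right = spans[i]
            tss, end3 = (left, right) if strand == "+" else (right, left)
            name = s.get("name", f"tu{i + 1:02d}")
            abundance = dict(s.get("abundance", {"control": 1.0, "induced": 1.0}))
            embed = s.get("embed")
            if embed is not None:
                if strand == "+":
                    a = tss - len(embed)  # 0-based start of window ending at tss
                    if a < 0:
                        raise PlacementError(f"embed window for {name} exceeds {ref_id}")
                    seq[a:tss] = list(embed)
                else:
                    b = tss - 1  # 0-based
                    if b + len(embed) > ref_len:
                        raise PlacementError(f"embed window for {name} exceeds {ref_id}")
                    seq[b : b + len(embed)] = list(revcomp(embed))
            n_genes = int(s.get("n_genes", 1))
            tu_len = abs(end3 - tss) + 1
            cds_len = max(tu_len - 40, n_genes)  # leave a short 5' UTR
            bounds = np.linspace(0, cds_len, n_genes + 1).astype(int)
            for k in range(n_genes):
                if strand == "+":
                    g_start = tss + 20 + int(bounds[k])
                    g_end = tss + 20 + int(bounds[k + 1]) - 1
                else:
                    g_start = tss - 20 - int(bounds[k + 1]) + 1
                    g_end = tss - 20 - int(bounds[k])
                    g_start, g_end = min(g_start, g_end), max(g_start, g_end)
                genes.append(Gene(f"{name}_g{k + 1}", ref_id, g_start, g_end, strand))
            tus.append(TranscriptionUnit(name, ref_id, tss, end3, strand, abundance))

        # genes for the mask locus are not annotated as genes: mask only
        sequences[ref_id] = "".join(seq)

    return AnnotatedGenome(
        sequences=sequences,
        circular={rid: False for rid in sequences},
        genes=genes,
        mask_features=masks,
        planted_tus=tus,
    )


#: condition labels of the standard synthetic benchmark, mirroring the
#: uninduced / sigma-factor-overexpression design the analysis targets.
STANDARD_FIXTURE_CONDITIONS = ("WT", "induced")


def standard_fixture(
    seed: int = 7,
    ref_length: int = 60_000,
    n_tus: int = 12,
    n_induced: int = 8,
    induction_fold: float = 100.0,
    n_genes_cycle: Sequence[int] = (1, 2, 3),
) -> AnnotatedGenome:
    """The standard benchmark genome: a plasmid-sized reference with
    ``n_induced`` TUs induced ``induction_fold``-fold and the rest constitutive.

    Induced TUs are rare in the uninduced condition (abundance 0.05 vs 5.0 for
    constitutive TUs) and rise to 5.0 on induction, emulating a regulon that is
    nearly silent until its sigma factor appears.
    """
    control, induced = STANDARD_FIXTURE_CONDITIONS
    specs = []
    for i in range(n_tus):
        if i < n_induced:
            abundance = {control: 5.0 / induction_fold, induced: 5.0}
        else:
            abundance = {control: 5.0, induced: 5.0}
        specs.append(
            {
                "length": 1500 + 250 * (i % 4),
                "strand": "+" if i % 2 == 0 else "-",
                "abundance": abundance,
                "n_genes": n_genes_cycle[i % len(n_genes_cycle)],
            }
        )
    return make_genome(
        n_refs=1, ref_lengths=ref_length, n_tus=n_tus, tu_spec=specs, seed=seed
    )


# ---------------------------------------------------------------------------
# Read simulation


def _apply_errors(rng: np.random.Generator, seq: str, err_rate: float) -> str:
    if err_rate <= 0.0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < err_rate)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alt = [b for b in BASES if b != chars[i]]
        chars[i] = alt[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_reads(
    genome: AnnotatedGenome,
    params: SimulatorParams,
    condition: str,
) -> tuple[list[SimRead], GroundTruth]:
    """Simulate ``params.depth`` end-enriched reads for one condition.

    Reads are drawn from planted TUs proportionally to their abundance in
    ``condition``; a ``ribo_fraction`` share comes from mask (rRNA-like) loci
    instead.  Each TU read keeps the transcript's true 5' end with probability
    ``p_true5``, the true 3' end with ``p_true3``, and is otherwise an internal
    fragment placed uniformly.  Minus-strand transcripts emit reverse-
    complemented reads.  With probability ``p_nta`` one random base differing
    from the templated upstream base is prepended (non-template addition).
    """
    rng = np.random.default_rng(params.seed)
    tus = genome.planted_tus
    weights = np.array([tu.abundance.get(condition, None) for tu in tus], dtype=object)
    if any(w is None for w in weights):
        raise KeyError(f"condition {condition!r} missing from a TU abundance map")
    weights = weights.astype(float)

    reads: list[SimRead] = []
    truth = GroundTruth()
    if params.depth == 0:
        return reads, truth

    total_w = weights.sum()
    use_ribo = params.ribo_fraction > 0 and genome.mask_features
    if total_w == 0 and not use_ribo:
        raise ValueError(
            "degenerate input: depth > 0 but all abundances are 0 and no rRNA source"
        )
    probs = weights / total_w if total_w > 0 else None

    for i in range(params.depth):
        rid = f"r{i:06d}"
        if use_ribo and (probs is None or rng.random() < params.ribo_fraction):
            mref, ms, me = genome.mask_features[
                int(rng.integers(0, len(genome.mask_features)))
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            L = int(rng.integers(params.frag_len_min, params.frag_len_max + 1))
            L = min(L, me - ms + 1)
            left = int(rng.integers(ms, me - L + 2))
            right = left + L - 1
            g5, g3 = (left, right) if strand == "+" else (right, left)
            frag = genome.fetch(mref, left, right)
            if strand == "-":
                frag = revcomp(frag)
            frag = _apply_errors(rng, frag, params.err_rate)
            reads.append(SimRead(rid, frag))
            truth.records.append(
                GroundTruthRecord(rid, f"mask:{mref}:{ms}-{me}", "ribo", mref, strand, g5, g3, False)
            )
            continue

        tu = tus[int(rng.choice(len(tus), p=probs))]
        T = tu.length
        u = rng.random()
        if u < params.p_true5:
            cls = "5p"
        elif u < params.p_true5 + params.p_true3:
            cls = "3p"
        else:
            cls = "internal"
        L = int(rng.integers(params.frag_len_min, params.frag_len_max + 1))
        L = min(L, T)
        if cls == "5p":
            s = 0
        elif cls == "3p":
            s = T - L
        else:
            s = int(rng.integers(0, T - L + 1))
        # transcript coord s (0-based from +1 site) -> genomic fragment ends
        if tu.strand == "+":
            g5 = tu.tss + s
            g3 = g5 + L - 1
            frag = genome.fetch(tu.ref_id, g5, g3)
        else:
            g5 = tu.tss - s
            g3 = g5 - L + 1
            frag = revcomp(genome.fetch(tu.ref_id, g3, g5))

        nta = False
        if params.p_nta > 0 and rng.random() < params.p_nta:
            # templated base immediately upstream of the fragment 5' end
            n = genome.length(tu.ref_id)
            if tu.strand == "+" and g5 >= 2:
                templ = genome.fetch(tu.ref_id, g5 - 1, g5 - 1)
            elif tu.strand == "-" and g5 <= n - 1:
                templ = revcomp(genome.fetch(tu.ref_id, g5 + 1, g5 + 1))
            else:
                templ = None
            if templ is not None:
                alt = [b for b in BASES if b != templ]
                frag = alt[int(rng.integers(0, 3))] + frag
                nta = True

        frag = _apply_errors(rng, frag, params.err_rate)
        reads.append(SimRead(rid, frag))
        truth.records.append(
            GroundTruthRecord(rid, tu.name, cls, tu.ref_id, tu.strand, g5, g3, nta)
        )

    return reads, truth


# ---------------------------------------------------------------------------
# Writers


def write_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=rid, description="")
        for rid, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable[SimRead], path: str | Path) -> None:
    def _records():
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(r.seq)
            yield rec

    SeqIO.write(_records(), str(path), "fastq")


def write_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, seq in genome.sequences.items():
            fh.write(f"##sequence-region {rid} 1 {len(seq)}\n")
        for g in genome.genes:
            fh.write(
                f"{g.ref_id}\trendscope\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.name};Name={g.name}\n"
            )
        for i, (rid, s, e) in enumerate(genome.mask_features, 1):
            fh.write(
                f"{rid}\trendscope\trRNA\t{s}\t{e}\t.\t+\t.\tID=mask{i};Name=mask{i}\n"
            )


def write_truth_bed(genome: AnnotatedGenome, path: str | Path) -> None:
    """BED6 of planted TSS and 3' ends (0-based half-open, per BED)."""
    rows = []
    for tu in genome.planted_tus:
        rows.append((tu.ref_id, tu.tss - 1, tu.tss, f"{tu.name}_tss", 0, tu.strand))
        rows.append((tu.ref_id, tu.end3 - 1, tu.end3, f"{tu.name}_end3", 0, tu.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_truth_table(truth: GroundTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
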