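"""Ungapped motif discovery, consensus calling, genome scanning, and
inverted-repeat search.

The promoter consensus is learned from the called -40..+1 windows by a
deterministic one-occurrence-per-sequence (OOPS) expectation-maximization:
every window of every input sequence seeds a soft position weight matrix
(0.7 on the seed base, 0.1 elsewhere), each EM round assigns every sequence
its best-scoring offset (ties to the leftmost) and rebuilds the PWM, and the
converged model with the highest total information content wins.  Log-odds
scores are in bits against the input-composition background.

The degenerate inverted-repeat search covers operator motifs of the
SOS-repressor kind: an IUPAC half-site, a bounded spacer, then the reverse
complement of the half-site, each half tolerating a bounded mismatch count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seq import BASES, IUPAC, encode, revcomp, revcomp_iupac
from .synthetic import AnnotatedGenome, Gene

__all__ = [
    "PWM",
    "MotifModel",
    "IUPACPattern",
    "PromoterPrediction",
    "InvertedRepeatMatch",
    "build_pwm",
    "discover_motif",
    "consensus_string",
    "scan_genome",
    "predict_promoters",
    "find_inverted_repeat",
    "write_meme_minimal",
]

_UNIFORM = np.full(4, 0.25)


@dataclass
class PWM:
    probs: np.ndarray  # (width, 4), columns over A,C,G,T
    background: np.ndarray = field(default_factory=lambda: _UNIFORM.copy())
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(width, 4) log2(p/background); zero-probability cells -> -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)

    def information_content(self) -> np.ndarray:
        """Bits per column: 2 - H(column); in [0, 2]."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        return 2.0 - h

    def score(self, seq: str, offset: int = 0) -> float:
        lo = self.log_odds()
        enc = encode(seq[offset : offset + self.width])
        if len(enc) < self.width or (enc == 4).any():
            raise ValueError("window too short or contains non-ACGT bases")
        return float(lo[np.arange(self.width), enc].sum())


@dataclass
class MotifModel:
    pwm: PWM
    offsets: tuple[int, ...]  # per-sequence 0-based motif start
    train_scores: tuple[float, ...]  # log-odds at each assigned offset
    n_iterations: int
    ic_trajectory: tuple[float, ...]  # total IC after each EM iteration

    @property
    def information_content(self) -> np.ndarray:
        return self.pwm.information_content()

    @property
    def total_ic(self) -> float:
        return float(self.pwm.information_content().sum())

    @property
    def min_train_score(self) -> float:
        """Default genome-scan threshold: worst training-occurrence score."""
        return min(self.train_scores)


@dataclass(frozen=True)
class IUPACPattern:
    half_site: str
    spacer_min: int
    spacer_max: int
    max_mismatches_per_half: int = 0

    def __post_init__(self) -> None:
        if not self.half_site:
            raise ValueError("half_site must be non-empty")
        if any(c not in IUPAC for c in self.half_site):
            raise ValueError("half_site must be IUPAC nucleotide codes")
        if self.spacer_min > self.spacer_max or self.spacer_min < 0:
            raise ValueError("require 0 <= spacer_min <= spacer_max")


@dataclass(frozen=True)
class InvertedRepeatMatch:
    start: int  # 1-based first base of the left half-site
    end: int  # 1-based last base of the right half-site
    spacer: int
    mismatches_left: int
    mismatches_right: int
    site: str


@dataclass(frozen=True)
class PromoterPrediction:
    ref_id: str
    strand: str
    motif_start: int  # 1-based leftmost genomic coordinate of the window
    score: float  # log-odds bits
    nearest_downstream_gene: str | None
    gene_distance: int | None = None  # nt from the motif's downstream edge to that gene

    def is_promoter_proximal(self, max_gap: int = 150) -> bool:
        """Whether the hit sits in the promoter region of a coding gene —
        the criterion for calling it a predicted target."""
        return self.gene_distance is not None and self.gene_distance <= max_gap


def _background_from(sequences: Sequence[str], floor: float = 1e-3) -> np.ndarray:
    counts = np.zeros(4)
    for s in sequences:
        enc = encode(s)
        counts += np.bincount(enc[enc < 4], minlength=4)
    bg = counts / counts.sum() if counts.sum() else _UNIFORM.copy()
    bg = np.maximum(bg, floor)
    return bg / bg.sum()


def build_pwm(
    sequences: Sequence[str],
    width: int | None = None,
    offsets: Sequence[int] | None = None,
    pseudocount: float = 0.0,
    background: np.ndarray | None = None,
) -> PWM:
    """Anchored counting: probs[j][b] = (count_b + pseudocount*bg_b) / (n + pseudocount)."""
    if not sequences:
        raise ValueError("empty sequence set")
    n = len(sequences)
    if width is None:
        width = min(len(s) for s in sequences)
    if offsets is None:
        offsets = [0] * n
    bg = _background_from(sequences) if background is None else np.asarray(background, float)
    counts = np.zeros((width, 4))
    for s, o in zip(sequences, offsets):
        if o < 0 or o + width > len(s):
            raise ValueError(f"offset {o} invalid for sequence of length {len(s)}")
        enc = encode(s[o : o + width])
        if (enc == 4).any():
            raise ValueError("sequences must be over A/C/G/T")
        counts[np.arange(width), enc] += 1
    probs = (counts + pseudocount * bg) / (n + pseudocount)
    return PWM(probs=probs, background=bg, pseudocount=pseudocount)


def _window_matrix(enc_seqs: list[np.ndarray], width: int) -> list[np.ndarray]:
    """Per sequence, the (n_offsets, width) matrix of encoded windows."""
    return [np.lib.stride_tricks.sliding_window_view(e, width) for e in enc_seqs]


def _best_offsets(windows: list[np.ndarray], lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.empty(len(windows), dtype=int)
    scores = np.empty(len(windows))
    cols = np.arange(lo.shape[0])
    for i, win in enumerate(windows):
        s = lo[cols, win].sum(axis=1)
        offsets[i] = int(np.argmax(s))  # ties -> leftmost
        scores[i] = s[offsets[i]]
    return offsets, scores


def discover_motif(
    sequences: Sequence[str],
    width: int = 30,
    pseudocount: float = 0.5,
    max_iter: int = 100,
) -> MotifModel:
    """Deterministic all-seed OOPS EM motif discovery.

    Every window of every sequence is tried as a seed; each seed is iterated
    to convergence (stable offsets) or ``max_iter``; the converged model with
    the highest total information content is returned (ties: first seed in
    scan order).
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    if width > min(len(s) for s in sequences):
        raise ValueError("width exceeds the shortest sequence")
    bg = _background_from(sequences)
    enc_seqs = [encode(s) for s in sequences]
    if any((e == 4).any() for e in enc_seqs):
        raise ValueError("sequences must be over A/C/G/T")
    windows = _window_matrix(enc_seqs, width)

    best: MotifModel | None = None
    for si, enc in enumerate(enc_seqs):
        for so in range(len(enc) - width + 1):
            seed = enc[so : so + width]
            probs = np.full((width, 4), 0.1)
            probs[np.arange(width), seed] = 0.7
            pwm = PWM(probs=probs, background=bg, pseudocount=pseudocount)
            prev = None
            traj: list[float] = []
            it = 0
            for it in range(1, max_iter + 1):
                offsets, scores = _best_offsets(windows, pwm.log_odds())
                pwm = build_pwm(
                    sequences, width, offsets, pseudocount=pseudocount, background=bg
                )
                traj.append(float(pwm.information_content().sum()))
                if prev is not None and np.array_equal(offsets, prev):
                    break
                prev = offsets
            offsets, scores = _best_offsets(windows, pwm.log_odds())
            model = MotifModel(
                pwm=pwm,
                offsets=tuple(int(o) for o in offsets),
                train_scores=tuple(float(s) for s in scores),
                n_iterations=it,
                ic_trajectory=tuple(traj),
            )
            # ties (to float noise) keep the first seed in scan order
            if best is None or model.total_ic > best.total_ic + 1e-9:
                best = model
    assert best is not None
    return best


def consensus_string(pwm: PWM, majority: float = 0.5) -> str:
    """Uppercase base where the top probability >= majority, lowercase where
    >= 0.25, else 'n'."""
    out = []
    for col in pwm.probs:
        b = int(np.argmax(col))
        p = col[b]
        if p >= majority:
            out.append(BASES[b])
        elif p > 0.25:  # strictly above uniform, else no base is informative
            out.append(BASES[b].lower())
        else:
            out.append("n")
    return "".join(out)


def _nearest_downstream_gene(
    genes: Sequence[Gene], ref_id: str, strand: str, win_left: int, win_right: int
) -> tuple[str | None, int | None]:
    """(gene name, gap in nt from the motif's downstream edge to the gene)."""
    cands = [g for g in genes if g.ref_id == ref_id and g.strand == strand]
    if strand == "+":
        ahead = [g for g in cands if g.start >= win_right]
        if not ahead:
            return None, None
        g = min(ahead, key=lambda g: g.start)
        return g.name, g.start - win_right
    ahead = [g for g in cands if g.end <= win_left]
    if not ahead:
        return None, None
    g = max(ahead, key=lambda g: g.end)
    return g.name, win_left - g.end


def scan_genome(
    pwm: PWM,
    genome: AnnotatedGenome,
    threshold: float,
    genes: Sequence[Gene] | None = None,
) -> list[PromoterPrediction]:
    """Log-odds scan of both strands; hits >= threshold, with overlapping
    same-strand hits within width/2 collapsed to the best-scoring one."""
    if not np.isfinite(threshold) and threshold < 0:
        raise ValueError("threshold must be finite or +inf")
    w = pwm.width
    if all(len(s) < w for s in genome.sequences.values()):
        raise ValueError("PWM wider than every reference")
    lo = pwm.log_odds()
    cols = np.arange(w)
    genes = genome.genes if genes is None else genes
    hits: list[PromoterPrediction] = []
    for rid in sorted(genome.sequences):
        seq = genome.sequences[rid]
        n = len(seq)
        if n < w:
            continue
        for strand, text in (("+", seq), ("-", revcomp(seq))):
            enc = encode(text)
            win = np.lib.stride_tricks.sliding_window_view(enc, w)
            scores = lo[cols, win].sum(axis=1)
            for p in np.nonzero(scores >= threshold)[0]:
                left = int(p) + 1 if strand == "+" else n - int(p) - w + 1
                gene, gap = _nearest_downstream_gene(
                    genes, rid, strand, left, left + w - 1
                )
                hits.append(
                    PromoterPrediction(
                        ref_id=rid,
                        strand=strand,
                        motif_start=left,
                        score=float(scores[p]),
                        nearest_downstream_gene=gene,
                        gene_distance=gap,
                    )
                )
    # collapse same-strand hits closer than width/2, best score wins
    hits.sort(key=lambda h: (-h.score, h.ref_id, h.motif_start))
    kept: list[PromoterPrediction] = []
    for h in hits:
        if any(
            k.ref_id == h.ref_id
            and k.strand == h.strand
            and abs(k.motif_start - h.motif_start) < w / 2
            for k in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.ref_id, h.motif_start, h.strand))
    return kept


def predict_promoters(
    model: MotifModel,
    genome: AnnotatedGenome,
    genes: Sequence[Gene] | None = None,
    threshold_offset: float = 2.0,
    max_gene_gap: int = 150,
) -> list[PromoterPrediction]:
    """Predicted promoters: scan hits in the promoter region of a coding gene.

    The scan threshold is the minimum training-occurrence score plus
    ``threshold_offset`` (default +2 bits, which keeps chance sites scoring
    near the weakest training promoter out of the call set).  Only hits whose
    downstream edge lies within ``max_gene_gap`` nt of a same-strand gene
    start qualify, and multiple qualifying hits upstream of the same gene
    collapse to the best-scoring one — predictions are per target gene, as a
    promoter table lists them.
    """
    hits = scan_genome(
        model.pwm, genome, model.min_train_score + threshold_offset, genes
    )
    best: dict[tuple, PromoterPrediction] = {}
    for h in hits:
        if not h.is_promoter_proximal(max_gene_gap):
            continue
        k = (h.ref_id, h.strand, h.nearest_downstream_gene)
        if k not in best or h.score > best[k].score:
            best[k] = h
    return sorted(best.values(), key=lambda h: (h.ref_id, h.motif_start))


def _iupac_mismatches(seq: str, pattern: str, cap: int) -> int:
    mm = 0
    for a, c in zip(seq, pattern):
        if a not in IUPAC[c]:
            mm += 1
            if mm > cap:
                return mm
    return mm


def find_inverted_repeat(sequence: str, pattern: IUPACPattern) -> list[InvertedRepeatMatch]:
    """All loci matching half-site + spacer + reverse-complemented half-site.

    Each half tolerates up to ``max_mismatches_per_half`` mismatches under
    IUPAC semantics; every (position, spacer) combination is reported.
    """
    sequence = sequence.upper()
    h = len(pattern.half_site)
    rc_pat = revcomp_iupac(pattern.half_site)
    cap = pattern.max_mismatches_per_half
    n = len(sequence)
    out: list[InvertedRepeatMatch] = []
    for i in range(n - h + 1):
        left = sequence[i : i + h]
        mml = _iupac_mismatches(left, pattern.half_site, cap)
        if mml > cap:
            continue
        for sp in range(pattern.spacer_min, pattern.spacer_max + 1):
            j = i + h + sp
            if j + h > n:
                break
            right = sequence[j : j + h]
            mmr = _iupac_mismatches(right, rc_pat, cap)
            if mmr > cap:
                continue
            out.append(
                InvertedRepeatMatch(
                    start=i + 1,
                    end=j + h,
                    spacer=sp,
                    mismatches_left=mml,
                    mismatches_right=mmr,
                    site=sequence[i : j + h],
                )
            )
    return out


def write_meme_minimal(
    pwm: PWM, path: str | Path, name: str = "motif_1", nsites: int | None = None
) -> None:
    """Serialize the PWM as a MEME-minimal-format text block."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.5f}" for b, f in zip(BASES, pwm.background)) + "\n\n"
        )
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {nsites or 20} E= 0\n"
        )
        for col in pwm.probs:
            fh.write(" " + " ".join(f"{p:9.6f}" for p in col) + "\n")
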