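"""Independent oracles used to cross-check the package implementations.

Each oracle recomputes a result by a different route (exhaustive scan,
per-read tally, full enumeration) and must stay independent of the code
paths it checks.
"""

from __future__ import annotations

import numpy as np

_ORACLE_COMP = str.maketrans("ACGT", "TGCA")


def oracle_revcomp(seq: str) -> str:
    return seq.translate(_ORACLE_COMP)[::-1]


def oracle_align(read: str, sequences: dict[str, str], max_mm: int = 1):
    """Score every offset of every strand of every reference; return all
    minimal-mismatch loci as (ref_id, strand, start_1based, mm) if the
    minimum is within max_mm, else []."""
    best = max_mm + 1
    hits = []
    enc_read = np.frombuffer(read.encode(), dtype=np.uint8)
    for rid in sorted(sequences):
        seq = sequences[rid]
        n, L = len(seq), len(read)
        if L > n:
            continue
        for strand in "+-":
            text = seq if strand == "+" else oracle_revcomp(seq)
            enc = np.frombuffer(text.encode(), dtype=np.uint8)
            win = np.lib.stride_tricks.sliding_window_view(enc, L)
            mm = (win != enc_read).sum(axis=1)
            for p in range(len(mm)):
                m = int(mm[p])
                if m > max_mm or m > best:
                    continue
                start0 = p if strand == "+" else n - p - L
                if m < best:
                    best = m
                    hits = []
                hits.append((rid, strand, start0 + 1, m))
    return [h for h in hits if h[3] == best] if best <= max_mm else []


def oracle_end_tally(alignments, genome, min_len=15, max_len=45):
    """Per-read tally of 5'/3' end counts, with mask and length filtering,
    as plain dictionaries keyed (ref, strand, end_type) -> {pos: count}."""
    masked = {}
    for rid, s, e in genome.mask_features:
        masked.setdefault(rid, set()).update(range(s, e + 1))
    tally: dict[tuple, dict[int, int]] = {}
    for a in alignments:
        if not (min_len <= a.length <= max_len):
            continue
        span = set(range(a.start, a.start + a.length))
        if span & masked.get(a.ref_id, set()):
            continue
        right = a.start + a.length - 1
        p5, p3 = (a.start, right) if a.strand == "+" else (right, a.start)
        for end, pos in (("5p", p5), ("3p", p3)):
            d = tally.setdefault((a.ref_id, a.strand, end), {})
            d[pos] = d.get(pos, 0) + 1
    return tally


_ORACLE_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_ORACLE_IUPAC_COMP = dict(zip("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"))


def oracle_inverted_repeats(sequence: str, half: str, sp_min: int, sp_max: int, max_mm: int):
    """Enumerate every (position, spacer) pair; return (start_1based, spacer)
    for all inverted-repeat matches."""
    rc_half = "".join(_ORACLE_IUPAC_COMP[c] for c in reversed(half))
    h, n = len(half), len(sequence)
    out = []
    for i in range(n):
        for sp in range(sp_min, sp_max + 1):
            if i + 2 * h + sp > n:
                continue
            left = sequence[i : i + h]
            right = sequence[i + h + sp : i + 2 * h + sp]
            mml = sum(1 for a, c in zip(left, half) if a not in _ORACLE_IUPAC[c])
            mmr = sum(1 for a, c in zip(right, rc_half) if a not in _ORACLE_IUPAC[c])
            if mml <= max_mm and mmr <= max_mm:
                out.append((i + 1, sp))
    return out
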