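"""Published SigN promoter windows from B. subtilis plasmid pBS32.

Each entry is the -40..+1 window (41 nt, transcription orientation, +1 base
last) of a SigN-dependent promoter, with its operon assignment and, where the
promoter was detected by Rend-seq after artificial SigN induction, the
reported induction fold change.  The two entries with ``fold_change=None``
were not Rend-seq-detected but predicted by consensus scanning; they serve as
the positive controls for :func:`rendscope.motif.scan_genome`.

The set doubles as the reference training input for motif discovery: the
SigN consensus blocks (a -35-like TTTACG element and a -10-like GATA element)
must emerge from these sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PromoterEntry",
    "PBS32_PROMOTERS",
    "rendseq_detected",
    "predicted_only",
    "all_windows",
    "embedded_promoter_genome",
]


@dataclass(frozen=True)
class PromoterEntry:
    name: str
    window41: str  # -40..+1, transcription orientation
    operon: str
    function: str
    fold_change: float | None  # None: predicted by consensus scan, not Rend-seq


PBS32_PROMOTERS: tuple[PromoterEntry, ...] = (
    PromoterEntry("sigN", "TTTTCGTTTACGTTTCTATTTCTCTAGATAAAATCATTAAG", "sigN", "Sigma factor", 101.0),
    PromoterEntry("zpaB", "TTCTCATTTACGTTTTAGAAAGACTAGATATAAAGATTACG", "zpaB", "DNA gyrase", 152.5),
    PromoterEntry("zpaD", "TCTTATTTACATAACTGGTTATGCCGGATAAAAGAAGATAG", "zpaDE", "Unknown", 38.0),
    PromoterEntry("zpbP", "CTACCAATTTACGTTTCACCATTCTCAGATATAAATATATT", "zpbP", "Unknown", 158.4),
    PromoterEntry("zpbS", "TTTTGATTTACGAATTCATATTCATAGATATAAGTATAAAA", "zpbS", "PG interaction", 333.2),
    PromoterEntry("zpbW", "TCCATTAATTTACATATGGAAAATTACGGATATAATCGTTA", "zpbW", "Regulator", 178.0),
    PromoterEntry("zpbY", "GAAAATCAATTTACGTTTTCAAAGGCACAGATATAATAACA", "zpbYZ zpcABCD", "Unknown", 226.0),
    PromoterEntry("zpcE", "TTTTTGATTTACGTTTCTAAAACCCAAGATATAAAAGATAT", "zpcEFGH", "Nucleotide synth.", 339.6),
    PromoterEntry("zpcJ", "AATTAATTTACGTTTTCCAAGAACCAGATATAAATAAAAAG", "zpcJK", "Nucleotide synth.", 245.9),
    PromoterEntry("zpcL", "TTTTGATTTACGTTTTTAATACTCCAGATATAAATATTAAG", "zpcLM", "Nucleotide synth.", 202.5),
    PromoterEntry("zpcN", "TTATGATTTACGTTTTTGTTTACCCAGATAAAATAACAAAG", "zpcNOP", "Unknown", 356.7),
    PromoterEntry("zpcU", "GCTTGATTTACGTTTTAAAAACCCCAGATATAATAACGAAG", "zpcUV", "Exonuclease", 263.0),
    PromoterEntry("zpcX", "CATTAATTTACGTTTTCGAATCACCAGATATAAATAAAGAG", "zpcXYZ", "Nucleotide synth.", 309.2),
    PromoterEntry("zpdB", "TTTCAATTTACGTTTTCGAATCACCAGATATAAATACAAAG", "zpdBCDEF", "Nucleotide synth.", 176.3),
    PromoterEntry("zpdG", "ATCCAATTTACGTTTTTGCCGGTCCAGATATAAATACTTTG", "zpdG", "DNA Pol III", 401.0),
    PromoterEntry("zpdH1", "TCATAATTTACATTTCTGTTATAACCGATATAATACCCTCA", "zpdHIJKLM", "Nucleotide synth.", 85.0),
    PromoterEntry("zpdH2", "AAATGATTTACGTTTTTCAATAACCAGATATAAATATAAAG", "zpdHIJKLM", "Nucleotide synth.", 297.7),
    PromoterEntry("zpbQ", "TGTGGTTTACGTTTTAATAGAGCCAGATATAATCATACCAA", "zpbQR", "Unknown", None),
    PromoterEntry("zpcR", "AATTTACGTTTCAGGTGATCCAGATATAATAACAAAAAATA", "zpcJKLMNOPQRSTUV", "Unknown", None),
)


def rendseq_detected() -> list[PromoterEntry]:
    return [p for p in PBS32_PROMOTERS if p.fold_change is not None]


def predicted_only() -> list[PromoterEntry]:
    return [p for p in PBS32_PROMOTERS if p.fold_change is None]


def all_windows() -> list[str]:
    return [p.window41 for p in PBS32_PROMOTERS]


def embedded_promoter_genome(seed: int = 0, spacing: int = 3000, pad: int = 1000):
    """A synthetic plasmid-sized genome carrying every published promoter window.

    The real pBS32 sequence is not bundled; this stand-in embeds each -40..+1
    window (final base = +1 site) in random background whose base composition
    matches the windows themselves, with a downstream ORF annotated per
    promoter.  It validates consensus scanning: a motif trained on the
    Rend-seq-detected windows must rediscover every embedded site and flag the
    predicted-only ones as new targets.

    Returns ``(genome, tss_by_name)`` with 1-based +1 coordinates.
    """
    import numpy as np

    from ._seq import BASES, encode
    from .synthetic import AnnotatedGenome, Gene

    rng = np.random.default_rng(seed)
    windows = all_windows()
    counts = np.zeros(4)
    for w in windows:
        enc = encode(w)
        counts += np.bincount(enc, minlength=4)[:4]
    comp = counts / counts.sum()

    n = 2 * pad + spacing * len(windows)
    seq = list("".join(np.array(list(BASES))[rng.choice(4, size=n, p=comp)]))
    genes: list[Gene] = []
    tss_by_name: dict[str, int] = {}
    for i, entry in enumerate(PBS32_PROMOTERS):
        tss = pad + i * spacing  # 1-based; window occupies [tss-40, tss]
        seq[tss - 41 : tss] = list(entry.window41)
        tss_by_name[entry.name] = tss
        genes.append(Gene(f"{entry.name}_orf", "pBS32like", tss + 20, tss + 920, "+"))
    genome = AnnotatedGenome(sequences={"pBS32like": "".join(seq)}, genes=genes)
    return genome, tss_by_name
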