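# rendscope

Regulon discovery from end-enriched RNA sequencing (Rend-seq), built for the
setting where an alternative sigma factor is artificially induced and the
transcription units it activates must be read directly off the transcriptome:
transcription start sites (TSSs) from 5′-end count spikes, operon extents
from 3′-end spikes, induced promoters from a ≥10-fold change rule, and the
promoter consensus from the called −40..+1 windows. The motivating system is
the plasmid-encoded sigma factor SigN of *Bacillus subtilis* plasmid pBS32,
whose regulon drives DNA-damage-triggered cell death, but every stage is
generic for bacterial end-enriched libraries.

## Method

Rend-seq sparsely fragments transcripts, so reads disproportionately retain
an original transcript 5′ or 3′ end. The pipeline:

1. **Align** 15–45 nt reads with one-mismatch, single-best-hit semantics. A
   read whose 5′-most base mismatches the reference (the signature of a
   non-templated addition during reverse transcription) has its 5′ end
   reassigned one position downstream.
2. **Count ends** per genomic position and strand into 5′/3′ tracks,
   excluding reads that touch rRNA/tRNA mask features, and **normalize** per
   million non-rRNA/tRNA aligned reads.
3. **Call peaks**: position *i* is a peak when
   `c(i) ≥ 5` (normalized units) and `c(i) ≥ 10 · bg(i)`, with `bg(i)` the
   mean count in ±50 nt excluding ±2 nt. The enrichment factor is
   `E(i) = c(i) / max(bg(i), 0.25)`.
4. **Remove shadows**: reads originating at a strong peak deposit a spurious
   opposite-end spike one fragment-length away; each such read's opposite-end
   contribution is divided by the peak's enrichment factor.
5. **Call promoters**: for each induced-condition 5′ peak, the fold change
   `FC(i) = (A(i)+c)/(B(i)+c)` (windowed ±2 nt sums of induced *A* and
   control *B*, pseudocount `c = 0.5`) must be **≥ 10**. The peak position is
   the +1 site; the −40..+1 window (41 nt) feeds motif discovery, and the
   operon is the run of same-strand genes up to the nearest downstream 3′
   peak.
6. **Discover the consensus** with a deterministic one-occurrence-per-sequence
   EM over all seed windows (PWM width 30, log-odds in bits), then **scan**
   the genome for additional promoter-proximal matches — predicted regulon
   members the differential analysis missed.

Also included: a degenerate inverted-repeat search (SOS-box/LexA-operator
style: IUPAC half-site, bounded spacer, reverse-complement half-site), Miller
unit arithmetic `OD420/(t · OD600) · dilution · 1000` for reporter assays,
and a ground-truthed simulator of end-enriched reads (true-end fractions,
20–40 nt fragments, 5′ non-template additions, rRNA contamination,
condition-specific induction) so the entire pipeline is testable without any
sequencing data.

## Worked example

Learn the SigN promoter consensus from the nineteen published pBS32 −40..+1
windows and print it:

```python
from rendscope.motif import consensus_string, discover_motif
from rendscope.promoters_pbs32 import all_windows

model = discover_motif(all_windows(), width=30)
print(consensus_string(model.pwm))
print(f"{model.total_ic:.1f} bits in {model.n_iterations} EM iterations")
```

```
aATTTACGTTTTtaAAtaaCCAGATATAAA
35.2 bits in 2 EM iterations
```

The uppercase blocks are the −35-like (`TTTACG`) and −10-like (`GATATAA`)
promoter elements; lowercase marks weaker preference. Or run the whole
pipeline on the standard synthetic benchmark (60 kb reference, 12
transcription units, 8 induced 100-fold, 50,000 reads per condition):

```sh
rendscope run-all --config cfg.yaml     # cfg.yaml: "mode: simulate\nseed: 7"
```

```
called 8 promoters -> rendscope_out/regulon.tsv
```

The regulon table lists each promoter by its first operon gene with its
41-nt window, operon, and fold change — on this benchmark, exactly the eight
planted induced TSSs at their exact coordinates, with measured fold changes
of roughly 50–140 (compositional renormalization compresses the planted
100-fold induction; see `docs/methods.md`).

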