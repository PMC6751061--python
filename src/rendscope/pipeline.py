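"""End-to-end orchestration: simulate/load -> align -> tracks -> peaks ->
shadow correction -> promoter calling -> motif -> genome scan.

One flat YAML config drives the run; every stage writes its intermediate
(FASTA/FASTQ, wig, BED, TSV, MEME-minimal motif text) plus a manifest
recording parameters, the seed, input checksums, and record counts at every
filter.  A rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

from . import align as _align
from . import motif as _motif
from . import peaks as _peaks
from . import regulon as _regulon
from . import synthetic as _syn
from . import tracks as _tracks

__all__ = [
    "PipelineConfig",
    "SimulateSpec",
    "MotifConfig",
    "ConfigError",
    "StageError",
    "validate_config",
    "config_from_dict",
    "run_pipeline",
    "RunResult",
]

logger = logging.getLogger("rendscope")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass(frozen=True)
class SimulateSpec:
    ref_length: int = 60_000
    n_tus: int = 12
    n_induced: int = 8
    induction_fold: float = 100.0


@dataclass(frozen=True)
class MotifConfig:
    width: int = 30
    pseudocount: float = 0.5
    max_iter: int = 100
    #: added to the minimum training-occurrence score to form the scan threshold
    scan_threshold_offset: float = 2.0
    #: a predicted target must start a gene within this many nt downstream
    max_gene_gap: int = 150


@dataclass(frozen=True)
class InputPaths:
    reference: str = ""
    annotation: str = ""
    reads: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "simulate"  # 'simulate' | 'fastq'
    seed: int = 7
    log_level: str = "INFO"
    output_dir: str = "rendscope_out"
    control: str = "WT"
    induced: tuple[str, ...] = ("induced",)
    simulate: SimulateSpec = SimulateSpec()
    inputs: InputPaths = InputPaths()
    simulator: _syn.SimulatorParams = _syn.SimulatorParams()
    align: _align.AlignParams = _align.AlignParams()
    length_filter: _tracks.LengthFilter = _tracks.LengthFilter()
    peaks: _peaks.PeakParams = _peaks.PeakParams()
    regulon: _regulon.RegulonParams = _regulon.RegulonParams()
    motif: MotifConfig = MotifConfig()

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "fastq"):
            raise ConfigError(f"mode must be 'simulate' or 'fastq', got {self.mode!r}")
        if not self.induced:
            raise ConfigError("need at least one induced condition")
        if self.control in self.induced:
            raise ConfigError("control condition cannot also be induced")
        if self.mode == "fastq":
            for p in (self.inputs.reference, self.inputs.annotation, *self.inputs.reads.values()):
                if not p or not Path(p).exists():
                    raise ConfigError(f"input path missing or absent: {p!r}")
            for cond in (self.control, *self.induced):
                if cond not in self.inputs.reads:
                    raise ConfigError(f"no reads given for condition {cond!r}")


_SECTION_TYPES = {
    "simulate": SimulateSpec,
    "simulator": _syn.SimulatorParams,
    "align": _align.AlignParams,
    "length_filter": _tracks.LengthFilter,
    "peaks": _peaks.PeakParams,
    "regulon": _regulon.RegulonParams,
    "motif": MotifConfig,
}
_TOP_KEYS = {
    "mode", "seed", "log_level", "output_dir", "conditions", "inputs",
    *_SECTION_TYPES,
}


def _check_keys(given: Mapping, allowed: set[str], context: str) -> None:
    for k in given:
        if k not in allowed:
            hint = difflib.get_close_matches(str(k), allowed, n=1)
            extra = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ConfigError(f"unknown key {k!r} in {context}{extra}")


def _build_section(cls, data: Mapping, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(data, fields, context)
    try:
        return cls(**data)
    except (ValueError, TypeError) as e:
        raise ConfigError(f"{context}: {e}") from e


def config_from_dict(raw: Mapping) -> PipelineConfig:
    _check_keys(raw, _TOP_KEYS, "config")
    cond = raw.get("conditions", {})
    _check_keys(cond, {"control", "induced"}, "conditions")
    induced = cond.get("induced", ["induced"])
    if isinstance(induced, str):
        induced = [induced]
    inputs_raw = raw.get("inputs", {})
    _check_keys(inputs_raw, {"reference", "annotation", "reads"}, "inputs")
    kwargs = dict(
        mode=raw.get("mode", "simulate"),
        seed=int(raw.get("seed", 7)),
        log_level=str(raw.get("log_level", "INFO")),
        output_dir=str(raw.get("output_dir", "rendscope_out")),
        control=str(cond.get("control", "WT")),
        induced=tuple(induced),
        inputs=InputPaths(
            reference=str(inputs_raw.get("reference", "")),
            annotation=str(inputs_raw.get("annotation", "")),
            reads=dict(inputs_raw.get("reads", {})),
        ),
    )
    for key, cls in _SECTION_TYPES.items():
        if key in raw:
            kwargs[key] = _build_section(cls, raw[key] or {}, key)
    try:
        return PipelineConfig(**kwargs)
    except (ValueError, TypeError) as e:
        raise ConfigError(str(e)) from e


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default, and invariant-check a YAML config file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config must be a YAML mapping")
    return config_from_dict(raw)


# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    genome: _syn.AnnotatedGenome
    tracks: dict[str, _tracks.TrackSet]  # corrected, normalized, per condition
    peaks: dict[str, list[_peaks.Peak]]  # on corrected tracks, per condition
    calls: list[_regulon.PromoterCall]
    motif_model: _motif.MotifModel | None
    consensus: str
    predictions: list[_motif.PromoterPrediction]
    table: "object"  # pandas DataFrame
    manifest: dict
    output_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _condition_seed(base: int, i: int) -> int:
    return (base * 1000 + i) % (2**31 - 1)


def _load_fastq(path: str) -> list[_syn.SimRead]:
    return [
        _syn.SimRead(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fastq")
    ]


def _load_reference(cfg: PipelineConfig) -> _syn.AnnotatedGenome:
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(cfg.inputs.reference, "fasta")
    }
    genes = _tracks.read_gff3_genes(cfg.inputs.annotation)
    masks = _tracks.read_gff3_masks(cfg.inputs.annotation)
    return _syn.AnnotatedGenome(
        sequences=seqs, genes=genes, mask_features=masks
    )


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute every stage for each condition pair and write all artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "checksums": {},
        "counts": {},
    }

    def _write(path: Path):
        written.append(path)
        return path

    conditions = (config.control, *config.induced)
    try:
        stage = "inputs"
        reads: dict[str, list[_syn.SimRead]] = {}
        if config.mode == "simulate":
            genome = _syn.standard_fixture(
                seed=config.seed,
                ref_length=config.simulate.ref_length,
                n_tus=config.simulate.n_tus,
                n_induced=config.simulate.n_induced,
                induction_fold=config.simulate.induction_fold,
            )
            # the fixture's condition labels follow the config
            label_map = dict(zip(_syn.STANDARD_FIXTURE_CONDITIONS, (config.control, config.induced[0])))
            genome.planted_tus = [
                dataclasses.replace(
                    tu,
                    abundance={label_map.get(k, k): v for k, v in tu.abundance.items()},
                )
                for tu in genome.planted_tus
            ]
            _syn.write_fasta(genome, _write(outdir / "genome.fasta"))
            _syn.write_gff3(genome, _write(outdir / "annotation.gff3"))
            _syn.write_truth_bed(genome, _write(outdir / "truth_ends.bed"))
            for i, cond in enumerate(conditions):
                params = dataclasses.replace(
                    config.simulator, seed=_condition_seed(config.seed, i)
                )
                rds, truth = _syn.simulate_reads(genome, params, cond)
                reads[cond] = rds
                _syn.write_fastq(rds, _write(outdir / f"reads_{cond}.fastq"))
                _syn.write_truth_table(truth, _write(outdir / f"truth_{cond}.tsv"))
                logger.info("simulated %d reads for condition %s", len(rds), cond)
        else:
            genome = _load_reference(config)
            for cond in conditions:
                reads[cond] = _load_fastq(config.inputs.reads[cond])
                manifest["checksums"][f"reads_{cond}"] = _sha256(
                    Path(config.inputs.reads[cond])
                )
                logger.info("loaded %d reads for condition %s", len(reads[cond]), cond)
            manifest["checksums"]["reference"] = _sha256(Path(config.inputs.reference))
            if not any(reads.values()):
                logger.warning("no reads in any condition; emitting empty outputs")

        stage = "align"
        index = _align.GenomeIndex(genome)
        aligned: dict[str, list[_align.AlignmentRecord]] = {}
        for cond in conditions:
            recs = _align.align_reads(reads[cond], genome, config.align, index)
            recs = _align.reassign_all(recs)
            aligned[cond] = recs
            n_mask_excl = len(recs) - _tracks.count_nonribo(recs, genome)
            n_retained = len(
                _tracks.retained_alignments(recs, genome, config.length_filter)
            )
            manifest["counts"][cond] = {
                "reads": len(reads[cond]),
                "aligned": len(recs),
                "unaligned": len(reads[cond]) - len(recs),
                "mask_excluded": n_mask_excl,
                "length_filtered": len(recs) - n_mask_excl - n_retained,
                "retained": n_retained,
            }
            logger.info("condition %s: %s", cond, manifest["counts"][cond])
            _align.write_sam(recs, genome, _write(outdir / f"aligned_{cond}.sam"), reads[cond])

        stage = "tracks"
        corrected: dict[str, _tracks.TrackSet] = {}
        peaks_post: dict[str, list[_peaks.Peak]] = {}
        for cond in conditions:
            raw = _tracks.count_ends(aligned[cond], genome, config.length_filter)
            _tracks.write_wig(raw, _write(outdir / f"ends_raw_{cond}.wig"))
            denom = _tracks.count_nonribo(aligned[cond], genome)
            if denom == 0:
                logger.warning("condition %s has no non-rRNA/tRNA reads; tracks left raw", cond)
                corrected[cond] = raw
                peaks_post[cond] = []
                continue
            norm = _tracks.normalize_tracks(raw, denom)
            _tracks.write_wig(norm, _write(outdir / f"ends_norm_{cond}.wig"))

            stage = "peaks"
            pre = _peaks.call_all_peaks(norm, config.peaks)
            corr = _peaks.remove_shadows(
                norm, pre, aligned[cond], genome, config.length_filter
            )
            _tracks.write_wig(corr, _write(outdir / f"ends_corrected_{cond}.wig"))
            post = _peaks.call_all_peaks(corr, config.peaks)
            # a genuine end must be a peak both on the observed track and after
            # shadow removal: shadow spikes vanish on correction, while noise in
            # a correction-emptied neighborhood was never a peak to begin with
            pre_keys = {(p.ref_id, p.strand, p.end_type, p.position) for p in pre}
            confirmed = [
                p for p in post
                if (p.ref_id, p.strand, p.end_type, p.position) in pre_keys
            ]
            _peaks.write_peaks_bed(confirmed, _write(outdir / f"peaks_{cond}.bed"))
            corrected[cond] = corr
            peaks_post[cond] = confirmed
            manifest["counts"][cond]["peaks_precorrection"] = len(pre)
            manifest["counts"][cond]["peaks_postcorrection"] = len(post)
            manifest["counts"][cond]["peaks"] = len(confirmed)
            logger.info(
                "condition %s: %d confirmed peaks (%d observed, %d after shadow removal)",
                cond, len(confirmed), len(pre), len(post),
            )

        stage = "regulon"
        calls: list[_regulon.PromoterCall] = []
        control = config.control
        for cond in config.induced:
            if not corrected[cond].normalized or not corrected[control].normalized:
                continue
            for rid in sorted(genome.sequences):
                for strand in "+-":
                    fc = _regulon.fold_change_track(
                        corrected[cond].get(rid, strand, "5p"),
                        corrected[control].get(rid, strand, "5p"),
                        config.regulon,
                    )
                    pk_here = [
                        p for p in peaks_post[cond]
                        if p.ref_id == rid and p.strand == strand
                    ]
                    for call in _regulon.call_induced_promoters(fc, pk_here, config.regulon):
                        calls.append(
                            _regulon.complete_call(
                                call, genome, peaks_post[cond], config.regulon
                            )
                        )
        calls.sort(key=lambda c: (c.ref_id, c.tss))
        logger.info("called %d induced promoters", len(calls))
        manifest["counts"]["promoter_calls"] = len(calls)
        _regulon.write_tss_bed(calls, _write(outdir / "promoters.bed"))
        _regulon.write_upstream_fasta(calls, _write(outdir / "promoters_upstream41.fasta"))

        stage = "motif"
        model: _motif.MotifModel | None = None
        consensus = ""
        predictions: list[_motif.PromoterPrediction] = []
        if len(calls) >= 2:
            windows = [c.upstream41 for c in calls]
            model = _motif.discover_motif(
                windows,
                width=config.motif.width,
                pseudocount=config.motif.pseudocount,
                max_iter=config.motif.max_iter,
            )
            consensus = _motif.consensus_string(model.pwm)
            _motif.write_meme_minimal(
                model.pwm, _write(outdir / "motif_meme.txt"), nsites=len(windows)
            )
            logger.info("motif IC %.1f bits, consensus %s", model.total_ic, consensus)

            stage = "scan"
            hits = _motif.predict_promoters(
                model,
                genome,
                threshold_offset=config.motif.scan_threshold_offset,
                max_gene_gap=config.motif.max_gene_gap,
            )
            # drop hits explaining a promoter we already called by Rend-seq
            called_windows = {
                (c.ref_id, c.strand, c.tss) for c in calls
            }
            w = model.pwm.width

            def _is_known(h: _motif.PromoterPrediction) -> bool:
                for rid, strand, tss in called_windows:
                    if h.ref_id != rid or h.strand != strand:
                        continue
                    lo = tss - config.regulon.upstream_len if strand == "+" else tss
                    hi = tss if strand == "+" else tss + config.regulon.upstream_len
                    if lo <= h.motif_start <= hi or lo <= h.motif_start + w - 1 <= hi:
                        return True
                return False

            predictions = [h for h in hits if not _is_known(h)]
            manifest["counts"]["scan_hits"] = len(hits)
            manifest["counts"]["predicted_new_targets"] = len(predictions)
            logger.info(
                "scan at %.2f bits: %d promoter-proximal hits, %d beyond the called set",
                model.min_train_score + config.motif.scan_threshold_offset,
                len(hits), len(predictions),
            )
            import pandas as pd

            pd.DataFrame(
                [dataclasses.asdict(p) for p in predictions],
                columns=[
                    "ref_id", "strand", "motif_start", "score",
                    "nearest_downstream_gene", "gene_distance",
                ],
            ).to_csv(_write(outdir / "predictions.tsv"), sep="\t", index=False)

        stage = "table"
        table_calls = list(calls)
        for p in predictions:
            tss = (
                p.motif_start + (model.pwm.width - 1) if p.strand == "+" else p.motif_start
            )
            table_calls.append(
                _regulon.PromoterCall(
                    name=p.nearest_downstream_gene or f"orphan:{tss}",
                    ref_id=p.ref_id,
                    strand=p.strand,
                    tss=tss,
                    fold_change=math.nan,
                    upstream41="",
                    source="predicted",
                )
            )
        table = _regulon.build_regulon_table(table_calls)
        table.to_csv(_write(outdir / "regulon.tsv"), sep="\t", index=False)

        stage = "manifest"
        for p in written:
            manifest["checksums"][p.name] = _sha256(p)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except (ConfigError, StageError):
        raise
    except Exception as e:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, str(e)) from e
    finally:
        logger.removeHandler(handler)
        handler.close()

    return RunResult(
        genome=genome,
        tracks=corrected,
        peaks=peaks_post,
        calls=calls,
        motif_model=model,
        consensus=consensus,
        predictions=predictions,
        table=table,
        manifest=manifest,
        output_dir=outdir,
    )
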