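"""Format adapters (FASTA, BED, SAM, VCF, TSV, JSON) and end-to-end pipeline
orchestration with a reproducibility manifest.

Conventions: internal coordinates are 0-based half-open; BED is written
0-based half-open; SAM and VCF are written 1-based per their standards.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from . import __version__
from .calling import FilterThresholds, ScreenResult, screen_sample
from .classify import annotate, build_databases, classify, frequency_filter
from .cnv import CnvThresholds, call_cnv, compute_rpkm, default_k_svd, standardize_zrpkm
from .coverage import compute_coverage, gap_report, summarize_coverage
from .simulate import (AlignedRead, GeneModel, SampleTruth,
                       SimulationConfig, TruthVariant, build_catalog,
                       build_reference, design_panel, sample_cohort,
                       simulate_amplicon_counts, simulate_reads)
from .tgt import genotype_sample
from .validation import build_confusion, validation_report

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_sam",
    "read_sam",
    "write_truth_vcf",
    "write_calls_vcf",
    "read_vcf_records",
]


class FormatError(ValueError):
    """Malformed record, with file/line context."""


# ---------------------------------------------------------------------------
# Format adapters
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    import pyfaidx
    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(path: str | Path, rows: list[tuple], chrom: str) -> None:
    """Rows: (start, end[, name[, score/pool]]) 0-based half-open."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in (chrom, *row)) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, list[str]]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer interval") from exc
            if end < start:
                raise FormatError(f"{path}:{ln}: end < start")
            out.append((parts[0], start, end, parts[3:]))
    return out


def _sam_header(model: GeneModel) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": model.name, "LN": model.sequence_length}],
        "PG": [{"ID": "cftrscreen", "PN": "cftrscreen", "VN": __version__}],
    })


_CIGAR_OPS = {"M": 0, "I": 1, "D": 2}
_CIGAR_OPS_INV = {0: "M", 1: "I", 2: "D"}


def write_sam(path: str | Path, reads: list[AlignedRead], model: GeneModel) -> None:
    header = _sam_header(model)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.name
            a.query_sequence = r.seq
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigartuples = [(_CIGAR_OPS[op], n) for op, n in r.cigar]
            out.write(a)


def read_sam(path: str | Path, sample_id: str = "sample") -> list[AlignedRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            cigar = tuple((_CIGAR_OPS_INV[op], n) for op, n in a.cigartuples)
            reads.append(AlignedRead(
                name=a.query_name, sample_id=sample_id,
                start=a.reference_start, strand="-" if a.is_reverse else "+",
                cigar=cigar, seq=a.query_sequence))
    return reads


def _vcf_header(model: GeneModel, fmt: bool = True) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line(f"##contig=<ID={model.name},length={model.sequence_length}>")
    h.add_line('##INFO=<ID=VID,Number=1,Type=String,Description="Variant id">')
    h.add_line('##INFO=<ID=TIER,Number=1,Type=String,Description="Pathogenicity tier">')
    h.add_line('##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Consequence">')
    h.add_line('##INFO=<ID=FREQ,Number=1,Type=Float,Description="Population frequency">')
    h.add_line('##INFO=<ID=DB,Number=0,Type=Flag,Description="In mutation database">')
    for status in ("low_fraction", "single_strand", "low_depth",
                   "no_call_region", "excess_alleles", "common_polymorphism"):
        h.add_line(f'##FILTER=<ID={status},Description="{status}">')
    if fmt:
        h.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        h.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
        h.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
        h.add_line('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alt fraction">')
    return h


def write_truth_vcf(path: str | Path, truth: SampleTruth,
                    catalog: list[TruthVariant], model: GeneModel, seq: str,
                    seed: int | None = None) -> int:
    """Per-sample truth VCF; one record per non-reference genotype entry
    (the large deletion as a symbolic <DEL>). Returns record count."""
    by_id = {v.id: v for v in catalog}
    h = _vcf_header(model)
    if seed is not None:
        h.add_line(f"##cftrscreen_seed={seed}")
    h.add_sample(truth.sample_id)
    n = 0
    with pysam.VariantFile(str(path), "w", header=h) as out:
        for vid, geno in sorted(truth.genotypes.items(),
                                key=lambda kv: by_id[kv[0]].pos):
            v = by_id[vid]
            if v.vtype == "large_deletion":
                rec = out.new_record(contig=model.name, start=v.pos,
                                     alleles=(seq[v.pos], "<DEL>"),
                                     stop=v.locus[1])
            else:
                rec = out.new_record(contig=model.name, start=v.pos,
                                     alleles=(v.ref_allele, v.alt_allele))
            rec.info["VID"] = vid
            rec.info["TIER"] = v.tier
            gt = (1, 1) if geno == "hom" else (0, 1)
            rec.samples[truth.sample_id]["GT"] = gt
            out.write(rec)
            n += 1
    return n


def write_calls_vcf(path: str | Path, screen: ScreenResult, model: GeneModel,
                    seed: int | None = None) -> None:
    h = _vcf_header(model)
    if seed is not None:
        h.add_line(f"##cftrscreen_seed={seed}")
    h.add_sample(screen.sample_id)
    with pysam.VariantFile(str(path), "w", header=h) as out:
        for c in sorted(screen.calls, key=lambda c: c.pos):
            rec = out.new_record(contig=model.name, start=c.pos,
                                 alleles=(c.ref, c.alt))
            rec.filter.add("PASS" if c.filter_status == "PASS" else c.filter_status)
            s = rec.samples[screen.sample_id]
            if c.genotype is not None:
                s["GT"] = (1, 1) if c.genotype == "hom" else (0, 1)
            else:
                s["GT"] = (None, None)
            s["DP"] = c.depth
            s["AD"] = (c.depth - sum(c.strand_counts), sum(c.strand_counts))
            s["AF"] = c.alt_fraction
            out.write(rec)


def read_vcf_records(path: str | Path) -> list[dict]:
    out = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            sample = next(iter(rec.samples), None)
            gt = rec.samples[sample]["GT"] if sample else None
            out.append({
                "pos0": rec.start, "ref": rec.ref, "alt": rec.alts[0],
                "filter": list(rec.filter), "info": dict(rec.info), "gt": gt,
            })
    return out


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    cnv_thresholds: CnvThresholds = field(default_factory=CnvThresholds)
    k_svd: int | None = None            # None: auto by cohort size
    outdir: str = "cftrscreen_out"
    emit_sam: bool = False              # SAM per sample is bulky; opt in
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            simulation=SimulationConfig(**raw.get("simulation", {})),
            thresholds=FilterThresholds(**raw.get("thresholds", {})),
            cnv_thresholds=CnvThresholds(**raw.get("cnv", {})),
            k_svd=raw.get("k_svd"),
            outdir=raw.get("outdir", "cftrscreen_out"),
            emit_sam=raw.get("emit_sam", False),
        )


@dataclass
class RunManifest:
    version: str
    config: dict
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    started: float = 0.0
    finished: float = 0.0
    failed_stage: str | None = None


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute simulate -> qc -> call -> classify -> cnv -> tgt -> validate,
    writing per-stage outputs and a digest manifest to ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__,
                           config=dataclasses.asdict(config),
                           seed=config.simulation.seed, started=time.time())
    ctx: dict = {}
    stages = [
        ("simulate", _stage_simulate), ("qc", _stage_qc), ("call", _stage_call),
        ("classify", _stage_classify), ("cnv", _stage_cnv), ("tgt", _stage_tgt),
        ("validate", _stage_validate),
    ]
    try:
        for name, fn in stages:
            info = fn(config, ctx, out)
            manifest.stages[name] = info
    except Exception as exc:
        manifest.failed_stage = name
        _finalize(manifest, out)
        raise StageError(name, exc) from exc
    _finalize(manifest, out)
    return manifest


def _finalize(manifest: RunManifest, out: Path) -> None:
    manifest.finished = time.time()
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest.outputs[str(p.relative_to(out))] = _digest(p)
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, default=str))


def _stage_simulate(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    sim = config.simulation
    model, seq = build_reference(sim)
    panel = design_panel(model)
    catalog = build_catalog(model, seq, panel)
    cohort = sample_cohort(catalog, sim)
    ctx.update(model=model, seq=seq, panel=panel, catalog=catalog, cohort=cohort)
    write_fasta(out / "reference.fa", model.name, seq)
    write_bed(out / "amplicons.bed",
              [(a.insert[0], a.insert[1], a.id, a.pool) for a in panel.amplicons],
              model.name)
    write_bed(out / "targets.bed",
              [(s, e, f"target_{i+1}") for i, (s, e) in enumerate(panel.target_regions)],
              model.name)
    vcf_dir = out / "truth"
    vcf_dir.mkdir(exist_ok=True)
    n_records = 0
    reads = {}
    for truth in cohort:
        n_records += write_truth_vcf(vcf_dir / f"{truth.sample_id}.vcf", truth,
                                     catalog, model, seq, seed=sim.seed)
        reads[truth.sample_id] = simulate_reads(truth, panel, sim, model, seq, catalog)
        if config.emit_sam:
            sam_dir = out / "sam"
            sam_dir.mkdir(exist_ok=True)
            write_sam(sam_dir / f"{truth.sample_id}.sam", reads[truth.sample_id], model)
    ctx["reads"] = reads
    return {"samples": len(cohort), "truth_records": n_records,
            "amplicons": panel.n_amplicons}


def _stage_qc(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    reports = {}
    gapfile_rows = []
    for sid, reads in ctx["reads"].items():
        profile = compute_coverage(reads, ctx["panel"], ctx["model"].sequence_length)
        report = summarize_coverage(profile, ctx["panel"])
        reports[sid] = report
        for row in gap_report(report, ctx["panel"], ctx["model"], ctx["catalog"]):
            gapfile_rows.append({"sample": sid, **row})
    ctx["qc"] = reports
    (out / "coverage_qc.json").write_text(json.dumps({
        sid: {"mean_depth": r.mean_depth, "uniformity": r.uniformity,
              "pct_ge_100x": r.pct_ge_100x, "pct_lt_50x": r.pct_lt_50x,
              "on_target_fraction": r.on_target_fraction,
              "n_gaps": len(r.gaps)}
        for sid, r in reports.items()}, indent=2))
    (out / "gap_worklist.json").write_text(json.dumps(gapfile_rows, indent=2))
    ctx["gap_worklist"] = gapfile_rows
    return {"samples": len(reports),
            "total_gaps": sum(len(r.gaps) for r in reports.values())}


def _stage_call(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    screens = {}
    calls_dir = out / "calls"
    calls_dir.mkdir(exist_ok=True)
    for sid, reads in ctx["reads"].items():
        screen = screen_sample(reads, ctx["panel"], config.thresholds,
                               ctx["seq"], sample_id=sid)
        screens[sid] = screen
        write_calls_vcf(calls_dir / f"{sid}.vcf", screen, ctx["model"],
                        seed=config.simulation.seed)
        write_bed(calls_dir / f"{sid}.nocall.bed",
                  [(s, e, "no_call") for s, e in screen.no_call_regions],
                  ctx["model"].name)
    ctx["screens"] = screens
    n_pass = sum(sum(c.filter_status == "PASS" for c in s.calls)
                 for s in screens.values())
    return {"samples": len(screens), "pass_calls": n_pass}


def _stage_classify(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    popdb, mutdb, predictors = build_databases(ctx["catalog"])
    rows = []
    for sid, screen in ctx["screens"].items():
        for c in screen.calls:
            if c.filter_status != "PASS":
                continue
            ann = annotate(c, ctx["model"], ctx["seq"], popdb, mutdb, predictors)
            kept = frequency_filter(ann)
            cls = classify(ann)
            rows.append({
                "sample": sid, "pos0": c.pos, "ref": c.ref, "alt": c.alt,
                "cdna": ann.cdna_name, "consequence": ann.consequence,
                "genotype": c.genotype, "tier": cls.tier,
                "evidence": ";".join(cls.evidence),
                "population_freq": ann.population_freq,
                "kept_after_frequency_filter": kept,
            })
    import pandas as pd
    pd.DataFrame(rows).to_csv(out / "classified_variants.tsv", sep="\t", index=False)
    ctx["classified"] = rows
    return {"classified": len(rows),
            "discarded_common": sum(not r["kept_after_frequency_filter"] for r in rows)}


def _stage_cnv(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    import pandas as pd
    counts = {t.sample_id: simulate_amplicon_counts(t, ctx["panel"],
                                                    config.simulation, ctx["model"])
              for t in ctx["cohort"]}
    # cross-sample standardization is meaningless on a handful of samples;
    # depth-based CNV calling needs a real cohort behind it
    if len(counts) < 8:
        ctx["cnv_calls"] = []
        return {"skipped": "cohort too small for depth-normalized CNV calling"}
    m = compute_rpkm(counts, ctx["panel"])
    k = config.k_svd if config.k_svd is not None else default_k_svd(len(m.sample_ids))
    standardize_zrpkm(m, k_svd=k)
    calls = call_cnv(m, ctx["panel"], ctx["model"], config.cnv_thresholds)
    ctx["cnv_calls"] = calls
    pd.DataFrame([{
        "sample": c.sample_id, "amplicon_start": c.amplicon_run[0],
        "amplicon_end": c.amplicon_run[1], "exon_first": c.exon_span[0],
        "exon_last": c.exon_span[1], "state": c.state, "mean_zrpkm": c.mean_zrpkm,
    } for c in calls]).to_csv(out / "cnv_calls.tsv", sep="\t", index=False)
    pd.DataFrame(m.zrpkm, index=m.amplicon_ids, columns=m.sample_ids) \
        .to_csv(out / "zrpkm.tsv", sep="\t")
    return {"cnv_calls": len(calls), "k_svd": k}


def _stage_tgt(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    import pandas as pd
    tract = ctx["model"].tgt_tract
    rows = []
    diplos = {}
    for sid, reads in ctx["reads"].items():
        d = genotype_sample(reads, tract, sample_id=sid, refseq=ctx["seq"])
        diplos[sid] = d
        rows.append({
            "sample": sid, "status": d.status,
            "alleles": ",".join(f"{a.label}:{n}" for a, n in d.alleles),
            "spanning_reads": d.spanning_reads, "parse_failures": d.parse_failures,
            "risk_flags": ",".join(sorted(d.risk_flags)),
        })
    ctx["tgt"] = diplos
    pd.DataFrame(rows).to_csv(out / "tgt_diplotypes.tsv", sep="\t", index=False)
    return {"samples": len(rows),
            "no_calls": sum(d.status == "no_call" for d in diplos.values())}


def _stage_validate(config: PipelineConfig, ctx: dict, out: Path) -> dict:
    confusion = build_confusion(ctx["cohort"], ctx["screens"], ctx["catalog"],
                                cnv_calls=ctx.get("cnv_calls"))
    report = validation_report(confusion)
    gap_loci = {(row["sample"], vid) for row in ctx["gap_worklist"]
                for vid in row["known_variants"]}
    report["fn_in_gap_worklist"] = {
        vid: [s in {g[0] for g in gap_loci if g[1] == vid} for s in b["samples"]]
        for vid, b in report["fn_breakdown"].items()}
    (out / "validation_report.json").write_text(json.dumps(report, indent=2))
    ctx["validation"] = report
    return {"tp": confusion.tp_variants, "fn": confusion.fn_variants,
            "fp": confusion.fp_variants}
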