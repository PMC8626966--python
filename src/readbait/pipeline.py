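"""One-invocation pipeline: screen → fitlaw → extend, with a manifest.

The config is a plain mapping (usually read from TOML). Each stage runs
only if its section is present; every referenced input file is checked
before any stage starts. All JSON outputs are timestamp-free so a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import tomllib
from importlib import metadata
from pathlib import Path
from typing import Any, Mapping, Union

from Bio import SeqIO

from . import extension as ext
from . import powerlaw as pl
from . import screen as sc
from .intervals import parse_point, parse_region

log = logging.getLogger("readbait")

_FILE_KEYS = {
    "screen": (
        "r1",
        "r2",
        "contaminant_ids",
        "annotation_ids",
        "annotation_ids2",
        "new_annotation_ids",
        "psl",
        "alignments",
    ),
    "fitlaw": ("gtf",),
    "extend": ("alignments", "genome", "fit"),
}


class PipelineError(RuntimeError):
    pass


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    have = {type(h) for h in log.handlers}
    if logging.StreamHandler not in have:
        log.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def _check_inputs(config: Mapping[str, Any]) -> None:
    missing = []
    for stage, keys in _FILE_KEYS.items():
        section = config.get(stage, {})
        for key in keys:
            path = section.get(key)
            if path is not None and not Path(path).exists():
                missing.append(f"{stage}.{key} = {path}")
    if missing:
        raise PipelineError("missing input file(s): " + "; ".join(missing))


def _run_screen(section: Mapping[str, Any], outdir: Path) -> dict:
    cfg = sc.ScreenConfig(
        minscore=int(section.get("minscore", 130)),
        min_mean_phred=float(section.get("min_mean_phred", 15.0)),
        min_length=int(section.get("min_length", 36)),
    )
    reads = sc.read_fastq(section["r1"], mate_flag="1")
    paired = None
    if "r2" in section:
        mates = {r.read_id for r in sc.read_fastq(section["r2"], mate_flag="2")}
        paired = {r.read_id for r in reads} & mates
    annot = set()
    for key in ("annotation_ids", "annotation_ids2"):
        if key in section:
            annot |= sc.read_id_set(section[key])  # union over mappers
    report = sc.classify_reads(
        reads,
        paired_ids=paired,
        contaminant_hits=(
            sc.read_id_set(section["contaminant_ids"])
            if "contaminant_ids" in section
            else ()
        ),
        annotation_hits=annot,
        score_table=sc.psl_scores(section["psl"]) if "psl" in section else None,
        new_annotation_hits=(
            sc.read_id_set(section["new_annotation_ids"])
            if "new_annotation_ids" in section
            else ()
        ),
        config=cfg,
    )
    report.to_json(outdir / "screen_report.json")
    report.to_tsv(outdir / "screen_report.tsv")
    candidates = set(report.candidate_ids)
    with open(outdir / "candidates.fastq", "w") as fh:
        for r in reads:
            if r.read_id in candidates:
                qual = "".join(chr(q + 33) for q in r.qualities)
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
    result = {"report": outdir / "screen_report.json", "counts": report.counts}
    if "alignments" in section:
        gaps = sc.gap_candidates(
            section["alignments"], min_gap=int(section.get("min_gap", 21))
        )
        sc.gap_features_to_tsv(gaps, outdir / "gap_features.tsv")
        sc.gap_features_to_bed(gaps, outdir / "gap_features.bed")
        result["n_gap_candidates"] = len({g.read_id for g in gaps})
    log.info("screen: %d reads, %d candidates", report.total, report.counts["candidate"])
    return result


def _run_fitlaw(section: Mapping[str, Any], outdir: Path) -> pl.PowerLawFit:
    table = pl.extract_transcript_lengths(section["gtf"])
    table.to_tsv(outdir / "transcript_lengths.tsv")
    fit = pl.fit_length_distribution(
        table,
        bin_width=int(section.get("bin_width", 100)),
        drop_overlong=bool(section.get("drop_overlong", True)),
        x_min=float(section.get("x_min", 1.0)),
        tie=section.get("median_tie", "lower"),
    )
    if "x_max" in section:
        fit.x_max = float(section["x_max"])
    fit.to_json(outdir / "fit.json")
    (outdir / "fit.txt").write_text(fit.to_report())
    log.info("fitlaw: alpha=%.4g adjusted_r2=%.4g", fit.alpha, fit.adjusted_r2)
    return fit


def _run_extend(
    section: Mapping[str, Any], fit: pl.PowerLawFit | None, outdir: Path
) -> dict:
    if fit is None:
        if "fit" not in section:
            raise PipelineError("extend stage needs a fitlaw stage or extend.fit path")
        fit = pl.PowerLawFit.from_json(section["fit"])
    model = pl.MembershipModel(
        fit,
        mode=section.get("mode", "truncated"),
        threshold=float(section.get("threshold", 0.3)),
    )
    chrom, center = parse_point(section["anchor"])
    span = parse_region(section["model_span"])
    if span.chrom != chrom:
        raise PipelineError("anchor and model span name different chromosomes")
    anchor = ext.AnchorPoint(
        chrom=chrom,
        center=center,
        model_span=(span.start, span.end),
        strand=section.get("strand", "unknown"),
    )
    window = float(section.get("window", fit.x_max))
    frags = ext.collect_fragments(section["alignments"], anchor, window)
    scored = ext.score_fragments(frags, model)
    estimate = ext.estimate_extension(anchor, scored)
    ext.fragments_to_tsv(scored, outdir / "fragments.tsv")
    estimate.to_json(outdir / "extension.json")
    (outdir / "span.bed").write_text(estimate.to_bed_line() + "\n")
    if "genome" in section:
        record = ext.extract_span_sequence(section["genome"], estimate)
        SeqIO.write([record], str(outdir / "span.fa"), "fasta")
    log.info(
        "extend: %d fragments, %d retained, full length %d bp",
        len(scored),
        len(estimate.retained),
        estimate.full_length,
    )
    return estimate.to_dict()


def run_pipeline(
    config: Mapping[str, Any], outdir: Union[str, Path]
) -> dict:
    """Run the configured stages; returns (and writes) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    _check_inputs(config)

    try:
        version = metadata.version("readbait")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest: dict[str, Any] = {
        "package": "readbait",
        "version": version,
        "seed": config.get("seed"),
        "config": {k: v for k, v in config.items()},
        "stages": [],
    }

    fit: pl.PowerLawFit | None = None
    if "screen" in config:
        _run_screen(config["screen"], outdir)
        manifest["stages"].append("screen")
    if "fitlaw" in config:
        fit = _run_fitlaw(config["fitlaw"], outdir)
        manifest["stages"].append("fitlaw")
    if "extend" in config:
        _run_extend(config["extend"], fit, outdir)
        manifest["stages"].append("extend")

    manifest["outputs"] = sorted(
        p.name for p in outdir.iterdir() if p.name not in ("run.log", "manifest.json")
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def run_pipeline_toml(config_path: Union[str, Path], outdir: Union[str, Path]) -> dict:
    with open(config_path, "rb") as fh:
        config = tomllib.load(fh)
    return run_pipeline(config, outdir)
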