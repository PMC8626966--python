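"""Synthetic fixtures for every stage of the salvage/extension pipeline.

Three generators, all deterministic under a fixed seed:

* :func:`sample_truncated_powerlaw` — heavy-tailed transcript-length
  samples from a truncated power law via inverse-CDF sampling, the
  generative assumption the log-log fitter must invert.
* :func:`make_planted_locus` — a single-chromosome genome with one
  planted transcript, a gap-bearing model read anchored inside it and
  sequencing fragments of the transcript around it, emitted as
  FASTA/GTF/SAM/BED/FASTQ plus a truth JSON.
* :func:`make_screen_fixture` — FASTQ pairs plus the evidence files
  (id lists, PSL scores) that force the screening cascade to reproduce
  a planted per-category truth table.

Default parameters mirror the published study conditions: length-law
exponent 0.594 on support [1, 6932] bp, a 149 bp model read carrying a
23 bp alignment gap inside a 1556 bp transcript, ~200 bp sonication-
sized fragments, and screening category proportions of
32.4 / 3.2 / 0.2 / 46.4 / 16.7 / 0.46 / 0.58 percent.

Fragments are drawn uniformly over the positions a real cDNA fragment
can occupy: fully inside the planted transcript and with its center at
most x_max from the model-read center. Nucleotide composition is
uniform and no sequencing-error model is applied.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np
import pysam
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .extension import AnchorPoint
from .powerlaw import TranscriptLengthTable

__all__ = [
    "SimulationConfig",
    "PlantedLocus",
    "ScreenFixture",
    "sample_truncated_powerlaw",
    "make_planted_locus",
    "make_screen_fixture",
]

_DEFAULT_CATEGORY_COUNTS = {
    "unpaired": 3240,
    "contaminant": 320,
    "low_quality": 20,
    "annotated": 4640,
    "low_score": 1670,
    "new_annotated": 46,
    "candidate": 58,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    alpha: float = 0.594
    x_min: int = 1
    x_max: int = 6932
    n_transcripts: int = 100_000
    planted_length: int = 1556
    model_read_length: int = 149
    gap_length: int = 23
    model_read_offset: int | None = None  # bp from transcript start; None = centered
    fragment_count: int = 100
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 30.0
    mate_read_length: int = 76
    chrom_name: str = "chrS"
    margin: int = 1000  # flanking sequence on each side of the transcript
    category_counts: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORY_COUNTS)
    )

    def __post_init__(self) -> None:
        if self.x_min < 1 or self.x_min >= self.x_max:
            raise ValueError("need 1 <= x_min < x_max")
        if self.gap_length < 1:
            raise ValueError("gap_length must be >= 1")
        if min(self.category_counts.values(), default=0) < 0:
            raise ValueError("category counts must be >= 0")

    @classmethod
    def from_toml(cls, path: Union[str, Path]) -> "SimulationConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


# ---------------------------------------------------------------------------
# truncated power-law sampling


def _sample_continuous(
    alpha: float, x_min: float, x_max: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    u = rng.random(n)
    if alpha == 1.0:
        return x_min * (x_max / x_min) ** u  # log-uniform branch
    a1 = 1.0 - alpha
    return (x_min**a1 + u * (x_max**a1 - x_min**a1)) ** (1.0 / a1)


def sample_truncated_powerlaw(config: SimulationConfig) -> TranscriptLengthTable:
    """Integer lengths from the truncated power law by inverse-CDF.

    Continuous draws are rounded to the nearest integer and clipped to
    the support, so the discrete law is P(k) ≈ F(k+½) − F(k−½).
    """
    rng = np.random.default_rng(config.seed)
    x = _sample_continuous(
        config.alpha, config.x_min, config.x_max, config.n_transcripts, rng
    )
    lengths = np.clip(np.rint(x), config.x_min, config.x_max).astype(np.int64)
    return TranscriptLengthTable(
        lengths,
        source_label=(
            f"simulated truncated power law alpha={config.alpha} "
            f"support=[{config.x_min},{config.x_max}] seed={config.seed}"
        ),
    )


# ---------------------------------------------------------------------------
# planted locus

_SAM_QUAL = 40  # constant base quality for simulated reads


@dataclass
class PlantedLocus:
    outdir: Path
    genome_fasta: Path
    annotation_gtf: Path
    model_read_sam: Path
    fragments_sam: Path
    fragments_bed: Path
    model_read_fastq: Path
    fragments_r1_fastq: Path
    fragments_r2_fastq: Path
    truth_json: Path
    truth: dict

    @property
    def anchor(self) -> AnchorPoint:
        m = self.truth["model_read"]
        return AnchorPoint(
            chrom=self.truth["chrom"],
            center=m["center"],
            model_span=(m["start"], m["end"]),
            strand="+",
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _write_fasta(path: Path, name: str, seq: str) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], str(path), "fasta")


def _sam_header(chrom: str, length: int) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": chrom, "LN": length}],
        }
    )


def make_planted_locus(
    config: SimulationConfig, outdir: Union[str, Path]
) -> PlantedLocus:
    """Build the planted-transcript locus fixture under ``outdir``.

    The model read is aligned with one N gap of ``gap_length`` bp in its
    CIGAR; its aligned span covers ``model_read_length + gap_length``
    reference bases. Fragment lengths are Normal(mean, sd) clipped at
    20 bp; mates of each fragment are emitted as a proper SAM pair and
    the fragment itself as a BED line. The truth JSON records the
    planted span and every fragment's center distance from the anchor.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    ref_span = config.model_read_length + config.gap_length
    if config.planted_length < ref_span:
        raise ValueError("planted transcript shorter than the model read's span")
    chrom_len = config.planted_length + 2 * config.margin
    tx_start = config.margin + 1
    tx_end = config.margin + config.planted_length

    genome = _random_seq(rng, chrom_len)
    genome_fasta = outdir / "genome.fa"
    _write_fasta(genome_fasta, config.chrom_name, genome)

    # annotation: one gene / transcript / exon over the planted span
    annotation_gtf = outdir / "annotation.gtf"
    attrs = 'gene_id "PLANTEDG"; transcript_id "PLANTED.1";'
    with open(annotation_gtf, "w") as fh:
        for ftype in ("gene", "transcript", "exon"):
            fh.write(
                f"{config.chrom_name}\treadbait_sim\t{ftype}\t{tx_start}\t{tx_end}"
                f"\t.\t+\t.\t{attrs}\n"
            )

    # model read with an internal N gap
    offset = config.model_read_offset
    if offset is None:
        offset = (config.planted_length - ref_span) // 2
    if not 0 <= offset <= config.planted_length - ref_span:
        raise ValueError("model_read_offset places the read outside the transcript")
    model_start = tx_start + offset
    model_end = model_start + ref_span - 1
    model_center = (model_start + model_end) // 2
    left_match = (config.model_read_length + 1) // 2
    right_match = config.model_read_length - left_match
    gap_start = model_start + left_match  # 1-based first gapped base
    gap_end = gap_start + config.gap_length - 1
    model_seq = (
        genome[model_start - 1 : model_start - 1 + left_match]
        + genome[gap_end : gap_end + right_match]
    )
    cigar = f"{left_match}M{config.gap_length}N{right_match}M"

    header = _sam_header(config.chrom_name, chrom_len)
    model_read_sam = outdir / "model_read.sam"
    with pysam.AlignmentFile(str(model_read_sam), "wh", header=header) as sam:
        a = pysam.AlignedSegment(header)
        a.query_name = "model_read"
        a.flag = 0
        a.reference_id = 0
        a.reference_start = model_start - 1
        a.mapping_quality = 60
        a.cigarstring = cigar
        a.query_sequence = model_seq
        a.query_qualities = pysam.qualitystring_to_array(
            chr(_SAM_QUAL + 33) * len(model_seq)
        )
        sam.write(a)

    model_read_fastq = outdir / "model_read.fastq"
    with open(model_read_fastq, "w") as fh:
        fh.write(f"@model_read\n{model_seq}\n+\n{chr(_SAM_QUAL + 33) * len(model_seq)}\n")

    # fragments of the planted transcript around the anchor
    fragments = []
    for i in range(config.fragment_count):
        length = int(
            np.clip(
                np.rint(rng.normal(config.fragment_length_mean, config.fragment_length_sd)),
                20,
                config.planted_length,
            )
        )
        c_lo = tx_start + (length - 1) // 2
        c_hi = tx_end - (length - 1 - (length - 1) // 2)
        c_lo = max(c_lo, model_center - config.x_max)
        c_hi = min(c_hi, model_center + config.x_max)
        center = int(rng.integers(c_lo, c_hi + 1))
        start = center - (length - 1) // 2
        end = start + length - 1
        fragments.append(
            {
                "name": f"frag{i:04d}",
                "start": start,
                "end": end,
                "center": center,
                "distance": abs(center - model_center),
            }
        )

    fragments_bed = outdir / "fragments.bed"
    with open(fragments_bed, "w") as fh:
        for f in fragments:
            fh.write(f"{config.chrom_name}\t{f['start'] - 1}\t{f['end']}\t{f['name']}\n")

    # paired SAM: mate1 left-anchored, mate2 right-anchored on each fragment
    records = []
    r1_lines, r2_lines = [], []
    for f in fragments:
        flen = f["end"] - f["start"] + 1
        rlen = min(config.mate_read_length, flen)
        m1_start, m2_start = f["start"], f["end"] - rlen + 1
        seq1 = genome[m1_start - 1 : m1_start - 1 + rlen]
        seq2 = genome[m2_start - 1 : m2_start - 1 + rlen]
        qual = chr(_SAM_QUAL + 33) * rlen
        for flag, pos, mpos, tlen, seq in (
            (99, m1_start, m2_start, flen, seq1),
            (147, m2_start, m1_start, -flen, seq2),
        ):
            a = pysam.AlignedSegment(header)
            a.query_name = f["name"]
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos - 1
            a.mapping_quality = 60
            a.cigarstring = f"{rlen}M"
            a.next_reference_id = 0
            a.next_reference_start = mpos - 1
            a.template_length = tlen
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(qual)
            records.append(a)
        r1_lines.append(f"@{f['name']}\n{seq1}\n+\n{qual}\n")
        r2_lines.append(
            f"@{f['name']}\n{str(Seq(seq2).reverse_complement())}\n+\n{qual}\n"
        )
    records.sort(key=lambda a: a.reference_start)
    fragments_sam = outdir / "fragments.sam"
    with pysam.AlignmentFile(str(fragments_sam), "wh", header=header) as sam:
        for a in records:
            sam.write(a)
    fragments_r1 = outdir / "fragments_R1.fastq"
    fragments_r2 = outdir / "fragments_R2.fastq"
    fragments_r1.write_text("".join(r1_lines))
    fragments_r2.write_text("".join(r2_lines))

    truth = {
        "seed": config.seed,
        "chrom": config.chrom_name,
        "chrom_length": chrom_len,
        "planted": {"start": tx_start, "end": tx_end, "length": config.planted_length},
        "model_read": {
            "start": model_start,
            "end": model_end,
            "center": model_center,
            "read_length": config.model_read_length,
            "cigar": cigar,
            "gap": {
                "start": gap_start,
                "end": gap_end,
                "length": config.gap_length,
            },
        },
        "fragments": fragments,
        "config": {
            k: v for k, v in asdict(config).items() if k != "category_counts"
        },
    }
    truth_json = outdir / "truth.json"
    truth_json.write_text(json.dumps(truth, indent=2) + "\n")

    return PlantedLocus(
        outdir=outdir,
        genome_fasta=genome_fasta,
        annotation_gtf=annotation_gtf,
        model_read_sam=model_read_sam,
        fragments_sam=fragments_sam,
        fragments_bed=fragments_bed,
        model_read_fastq=model_read_fastq,
        fragments_r1_fastq=fragments_r1,
        fragments_r2_fastq=fragments_r2,
        truth_json=truth_json,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# screening-cascade fixture


@dataclass
class ScreenFixture:
    outdir: Path
    r1_fastq: Path
    r2_fastq: Path
    contaminant_ids: Path
    annotation_ids: Path
    new_annotation_ids: Path
    psl: Path
    truth_json: Path
    truth: dict


def _psl_line(qname: str, matches: int, mismatches: int) -> str:
    qsize = matches + mismatches
    fields = [
        matches, mismatches, 0, 0, 0, 0, 0, 0, "+", qname, qsize, 0, qsize,
        "chrS", 10_000, 0, qsize, 1, f"{qsize},", "0,", "0,",
    ]
    return "\t".join(str(f) for f in fields)


def make_screen_fixture(
    config: SimulationConfig, outdir: Union[str, Path]
) -> ScreenFixture:
    """Reads plus evidence files realising ``config.category_counts``.

    Each category's evidence is planted so the cascade must land every
    read in its intended bucket: unpaired reads lack a mate in R2,
    contaminant/annotated/new-annotated ids appear in the respective id
    lists, low-quality reads carry Q2 bases, low-score reads get a PSL
    score of 90 (< minscore 130) and survivors score 150.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    read_len = 100
    r1_lines, r2_lines = [], []
    id_lists: dict[str, list[str]] = {cat: [] for cat in _DEFAULT_CATEGORY_COUNTS}
    psl_lines = ["psLayout version 3", "", "match\tmis-", "-" * 20]
    category_by_read: dict[str, str] = {}

    for cat, count in config.category_counts.items():
        if cat not in id_lists:
            raise ValueError(f"unknown screening category {cat!r}")
        for i in range(count):
            rid = f"{cat}_{i:05d}"
            category_by_read[rid] = cat
            id_lists[cat].append(rid)
            seq = _random_seq(rng, read_len)
            qual = ("#" if cat == "low_quality" else "I") * read_len  # Q2 / Q40
            r1_lines.append(f"@{rid}\n{seq}\n+\n{qual}\n")
            if cat != "unpaired":
                mate = _random_seq(rng, read_len)
                r2_lines.append(f"@{rid}\n{mate}\n+\n{'I' * read_len}\n")
            if cat == "low_score":
                psl_lines.append(_psl_line(rid, 95, 5))  # score 90
            elif cat in ("new_annotated", "candidate"):
                psl_lines.append(_psl_line(rid, 150, 0))  # score 150

    r1 = outdir / "reads_R1.fastq"
    r2 = outdir / "reads_R2.fastq"
    r1.write_text("".join(r1_lines))
    r2.write_text("".join(r2_lines))

    contaminant = outdir / "contaminant_ids.txt"
    annotation = outdir / "annotation_ids.txt"
    new_annotation = outdir / "new_annotation_ids.txt"
    contaminant.write_text("".join(i + "\n" for i in id_lists["contaminant"]))
    annotation.write_text("".join(i + "\n" for i in id_lists["annotated"]))
    new_annotation.write_text("".join(i + "\n" for i in id_lists["new_annotated"]))
    psl = outdir / "scores.psl"
    psl.write_text("".join(line + "\n" for line in psl_lines))

    truth = {
        "seed": config.seed,
        "counts": dict(config.category_counts),
        "total": sum(config.category_counts.values()),
        "category_by_read": category_by_read,
    }
    truth_json = outdir / "truth.json"
    truth_json.write_text(json.dumps(truth, indent=2) + "\n")

    return ScreenFixture(
        outdir=outdir,
        r1_fastq=r1,
        r2_fastq=r2,
        contaminant_ids=contaminant,
        annotation_ids=annotation,
        new_annotation_ids=new_annotation,
        psl=psl,
        truth_json=truth_json,
        truth=truth,
    )
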