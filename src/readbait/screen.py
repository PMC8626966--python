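"""The unmapped-read salvage cascade.

Reads that an aligner failed to place are not rescued by realigning
here; the external tools (rRNA/contaminant screens, annotation mappers,
BLAT, BLAST) have already been run and their outputs are consumed as id
sets and score tables. What this module implements is the decision
logic: the fixed-order cascade that partitions the unmapped fraction
into categories, the explicit quality rule, and the gap rule that marks
a read as a novel-transcript candidate when its alignment contains a
reference gap strictly longer than 20 bp (long gaps are likely introns,
so such reads are the interesting ones an annotation-naive aligner
throws away).

Cascade order (first match wins):
unpaired -> contaminant -> low_quality -> annotated -> low_score ->
new_annotated -> candidate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pysam
from Bio import SeqIO

from .intervals import GenomicInterval

__all__ = [
    "CATEGORIES",
    "ReadRecord",
    "GapFeature",
    "ScreenReport",
    "ScreenConfig",
    "classify_reads",
    "quality_filter",
    "gap_candidates",
    "read_fastq",
    "read_id_set",
    "psl_scores",
]

CATEGORIES = (
    "unpaired",
    "contaminant",
    "low_quality",
    "annotated",
    "low_score",
    "new_annotated",
    "candidate",
)

# CIGAR ops that consume the reference; gaps are N (skip) and D (deletion)
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X
_GAP_OPS = {2: "D", 3: "N"}


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: list[int]
    mate_flag: str = "1"  # "1", "2" or "unpaired"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence and quality lengths differ"
            )


def phred_from_string(qual: str) -> list[int]:
    """Decode a Phred-33 quality string; non-Phred-33 characters error."""
    scores = []
    for ch in qual:
        code = ord(ch)
        if code < 33 or code > 126:
            raise ValueError(f"non-Phred-33 quality character {ch!r}")
        scores.append(code - 33)
    return scores


def read_fastq(path: Union[str, Path], mate_flag: str = "1") -> list[ReadRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(
            ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities=list(rec.letter_annotations["phred_quality"]),
                mate_flag=mate_flag,
            )
        )
    return records


def read_id_set(path: Union[str, Path]) -> frozenset[str]:
    """One read id per line; blanks and '#' comments ignored."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split()[0])
    return frozenset(ids)


def psl_scores(path: Union[str, Path]) -> dict[str, int]:
    """Best BLAT score per query from a PSL file.

    Score = matches + repMatches - misMatches - qNumInsert - tNumInsert
    (the UCSC web-BLAT convention). Header block lines are skipped.
    """
    scores: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 21 or not fields[0].isdigit():
                continue  # psLayout header / separator lines
            matches, mismatches, repmatches = (int(fields[i]) for i in (0, 1, 2))
            q_ins, t_ins = int(fields[4]), int(fields[6])
            qname = fields[9]
            score = matches + repmatches - mismatches - q_ins - t_ins
            if score > scores.get(qname, -(10**9)):
                scores[qname] = score
    return scores


# ---------------------------------------------------------------------------
# quality rule


@dataclass(frozen=True)
class ScreenConfig:
    minscore: int = 130
    min_mean_phred: float = 15.0
    min_length: int = 36


def quality_filter(
    read: ReadRecord,
    min_mean_phred: float = 15.0,
    min_length: int = 36,
) -> bool:
    """True when the read passes: mean Phred >= threshold and length >= min.

    Both comparisons are inclusive — a read exactly at a threshold passes.
    Replaces tool-version-dependent "default arguments" with an explicit,
    configurable rule.
    """
    if len(read.sequence) < min_length:
        return False
    if not read.qualities:
        return False
    mean_q = sum(read.qualities) / len(read.qualities)
    return mean_q >= min_mean_phred


# ---------------------------------------------------------------------------
# cascade


@dataclass
class ScreenReport:
    total: int
    counts: dict[str, int]
    fractions: dict[str, float]
    candidate_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "counts": self.counts,
            "fractions": self.fractions,
            "candidate_ids": self.candidate_ids,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\tfraction\n")
            for cat in CATEGORIES:
                fh.write(f"{cat}\t{self.counts[cat]}\t{self.fractions[cat]:.6g}\n")
            fh.write(f"total\t{self.total}\t1\n")


def classify_reads(
    reads: Sequence[ReadRecord],
    paired_ids: Iterable[str] | None = None,
    contaminant_hits: Iterable[str] = (),
    annotation_hits: Iterable[str] = (),
    score_table: Mapping[str, int] | None = None,
    new_annotation_hits: Iterable[str] = (),
    config: ScreenConfig = ScreenConfig(),
) -> ScreenReport:
    """Assign every read to the first matching cascade category.

    ``paired_ids`` is the set of read ids whose mate is present; a read
    outside it (or flagged unpaired) is "unpaired". ``annotation_hits``
    should already be the union over annotation mappers. A read missing
    from the BLAT ``score_table`` scores 0 and is therefore "low_score"
    (only scored survivors can proceed). Survivors of every filter are
    the candidates. Hit ids that refer to no input read draw a warning,
    never an error.
    """
    contaminant = frozenset(contaminant_hits)
    annotated = frozenset(annotation_hits)
    new_annotated = frozenset(new_annotation_hits)
    scores = dict(score_table or {})
    paired = frozenset(paired_ids) if paired_ids is not None else None

    input_ids = {r.read_id for r in reads}
    for label, hits in (
        ("contaminant", contaminant),
        ("annotation", annotated),
        ("new-annotation", new_annotated),
        ("score-table", frozenset(scores)),
    ):
        orphans = hits - input_ids
        if orphans:
            warnings.warn(
                f"{len(orphans)} {label} hit id(s) not present in the input reads",
                RuntimeWarning,
                stacklevel=2,
            )

    counts = {cat: 0 for cat in CATEGORIES}
    candidate_ids: list[str] = []
    for read in reads:
        rid = read.read_id
        if read.mate_flag == "unpaired" or (paired is not None and rid not in paired):
            cat = "unpaired"
        elif rid in contaminant:
            cat = "contaminant"
        elif not quality_filter(read, config.min_mean_phred, config.min_length):
            cat = "low_quality"
        elif rid in annotated:
            cat = "annotated"
        elif scores.get(rid, 0) < config.minscore:
            cat = "low_score"
        elif rid in new_annotated:
            cat = "new_annotated"
        else:
            cat = "candidate"
            candidate_ids.append(rid)
        counts[cat] += 1

    total = len(reads)
    fractions = {
        cat: (counts[cat] / total if total else 0.0) for cat in CATEGORIES
    }
    return ScreenReport(
        total=total, counts=counts, fractions=fractions, candidate_ids=candidate_ids
    )


# ---------------------------------------------------------------------------
# gap rule


@dataclass(frozen=True)
class GapFeature:
    """A reference gap (N or D CIGAR op) inside one read's alignment."""

    read_id: str
    chrom: str
    gap_start: int  # 1-based inclusive
    gap_end: int
    gap_length: int
    cigar_op: str

    def __post_init__(self) -> None:
        if self.gap_length != self.gap_end - self.gap_start + 1 or self.gap_length < 1:
            raise ValueError("inconsistent gap coordinates")

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.gap_start, self.gap_end)

    def to_bed_line(self) -> str:
        chrom, bstart, bend = self.interval().to_bed()
        return f"{chrom}\t{bstart}\t{bend}\t{self.read_id}\t{self.gap_length}\t."


def gap_candidates(
    alignments: Union[str, Path], min_gap: int = 21
) -> list[GapFeature]:
    """Reads whose CIGAR contains an N or D gap of at least ``min_gap`` bp.

    The published rule is "gap higher than 20 bp", i.e. strictly greater
    than 20 — the default ``min_gap=21`` encodes it. Gap coordinates are
    obtained by walking the CIGAR over the reference; a read with several
    qualifying gaps yields several features. Records without a CIGAR are
    skipped with a warning.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    features: list[GapFeature] = []
    mode = "rb" if str(alignments).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignments), mode) as sam:
        for aln in sam:
            cig = aln.cigartuples
            if cig is None:
                # placed records without a CIGAR ('*') are worth flagging;
                # genuinely unplaced reads are skipped silently
                if aln.reference_id >= 0:
                    warnings.warn(
                        f"{aln.query_name}: no CIGAR, skipped",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                continue
            if aln.is_unmapped:
                continue
            ref_pos = aln.reference_start  # 0-based
            for op, length in cig:
                if op in _GAP_OPS and length >= min_gap:
                    features.append(
                        GapFeature(
                            read_id=aln.query_name,
                            chrom=aln.reference_name,
                            gap_start=ref_pos + 1,
                            gap_end=ref_pos + length,
                            gap_length=length,
                            cigar_op=_GAP_OPS[op],
                        )
                    )
                if op in _REF_CONSUMING:
                    ref_pos += length
    return features


def gap_features_to_bed(features: Sequence[GapFeature], path: Union[str, Path]) -> None:
    Path(path).write_text("".join(f.to_bed_line() + "\n" for f in features))


def gap_features_to_tsv(features: Sequence[GapFeature], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tgap_start\tgap_end\tgap_length\tcigar_op\n")
        for f in features:
            fh.write(
                f"{f.read_id}\t{f.chrom}\t{f.gap_start}\t{f.gap_end}\t"
                f"{f.gap_length}\t{f.cigar_op}\n"
            )
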