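"""Full-length span estimation around an anchor ("model") read.

Given an anchor read of a putative novel transcript and the mapped
fragments in its neighbourhood, each fragment is scored by the fitted
length law's tail probability at its center-to-center distance from the
anchor. Fragments scoring above the threshold are retained as
co-members; the union of their spans with the anchor's own span is the
estimated full-length locus, reported together with the left/right (and
strand-resolved 5'/3') extensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import pysam
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval
from .powerlaw import MembershipModel, membership_probability

__all__ = [
    "AnchorPoint",
    "FragmentCandidate",
    "ExtensionEstimate",
    "collect_fragments",
    "score_fragments",
    "estimate_extension",
    "extract_span_sequence",
]


@dataclass(frozen=True)
class AnchorPoint:
    """The model read's location: chrom, center and aligned span (1-based)."""

    chrom: str
    center: int
    model_span: tuple[int, int]
    strand: str = "unknown"

    def __post_init__(self) -> None:
        start, end = self.model_span
        if not start <= self.center <= end:
            raise ValueError(
                f"anchor center {self.center} outside model span [{start}, {end}]"
            )
        if self.strand not in ("+", "-", "unknown", "."):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class FragmentCandidate:
    """A mapped fragment near the anchor, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    name: str = ""
    distance_x: int = 0
    probability: float | None = None
    retained: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"fragment start {self.start} > end {self.end}")

    @property
    def center(self) -> int:
        """Floor midpoint (biases < 1 bp for even-length fragments)."""
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ExtensionEstimate:
    """The estimated full-length span and its per-side extensions."""

    anchor: AnchorPoint
    retained: list[FragmentCandidate]
    span: tuple[int, int]
    ext_left: int
    ext_right: int
    ext_5p: int
    ext_3p: int
    total_extension: int
    full_length: int
    strand_resolved: bool

    def to_dict(self) -> dict:
        return {
            "chrom": self.anchor.chrom,
            "anchor_center": self.anchor.center,
            "model_span": list(self.anchor.model_span),
            "strand": self.anchor.strand,
            "span": list(self.span),
            "ext_left": self.ext_left,
            "ext_right": self.ext_right,
            "ext_5p": self.ext_5p,
            "ext_3p": self.ext_3p,
            "total_extension": self.total_extension,
            "full_length": self.full_length,
            "strand_resolved": self.strand_resolved,
            "n_retained": len(self.retained),
            "retained": [
                {
                    "name": f.name,
                    "start": f.start,
                    "end": f.end,
                    "center": f.center,
                    "distance": f.distance_x,
                    "probability": f.probability,
                }
                for f in self.retained
            ],
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def span_interval(self) -> GenomicInterval:
        strand = self.anchor.strand if self.anchor.strand in ("+", "-") else "."
        return GenomicInterval(self.anchor.chrom, *self.span, strand=strand)

    def to_bed_line(self, name: str = "estimated_span") -> str:
        chrom, bstart, bend = self.span_interval().to_bed()
        strand = self.span_interval().strand
        return f"{chrom}\t{bstart}\t{bend}\t{name}\t0\t{strand}"


# ---------------------------------------------------------------------------
# fragment collection


def _fragments_from_bed(path: Union[str, Path], chrom: str) -> list[FragmentCandidate]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: not a BED line")
            if fields[0] != chrom:
                continue
            iv = GenomicInterval.from_bed(fields[0], int(fields[1]), int(fields[2]))
            name = fields[3] if len(fields) > 3 else f"bed{lineno}"
            out.append(FragmentCandidate(iv.chrom, iv.start, iv.end, name=name))
    return out


def _fragments_from_sam(path: Union[str, Path], chrom: str) -> list[FragmentCandidate]:
    """Merge mates mapped to ``chrom`` into one template fragment per name."""
    spans: dict[str, tuple[int, int]] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as sam:
        if chrom not in sam.references:
            raise ValueError(f"{chrom!r} absent from alignment header")
        for aln in sam:
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.reference_name != chrom
            ):
                continue
            start = aln.reference_start + 1
            end = aln.reference_end  # pysam end is exclusive 0-based == inclusive 1-based
            prev = spans.get(aln.query_name)
            if prev is None:
                spans[aln.query_name] = (start, end)
            else:
                spans[aln.query_name] = (min(prev[0], start), max(prev[1], end))
    return [
        FragmentCandidate(chrom, s, e, name=name) for name, (s, e) in spans.items()
    ]


def collect_fragments(
    alignments: Union[str, Path],
    anchor: AnchorPoint,
    window: float,
    fmt: str | None = None,
) -> list[FragmentCandidate]:
    """Fragments on the anchor's chromosome with centers within ±window.

    SAM/BAM input: secondary/supplementary records are dropped and the
    two mates of a pair are merged into one template fragment spanning
    their outermost coordinates (a lone mapped mate stands alone). BED
    input is taken fragment-per-line. Format is inferred from the file
    suffix unless ``fmt`` is given ("sam" or "bed").
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if fmt is None:
        suffix = Path(str(alignments)).suffix.lower()
        fmt = "bed" if suffix == ".bed" else "sam"
    if fmt == "bed":
        frags = _fragments_from_bed(alignments, anchor.chrom)
    elif fmt == "sam":
        frags = _fragments_from_sam(alignments, anchor.chrom)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    for f in frags:
        f.distance_x = abs(f.center - anchor.center)
    frags = [f for f in frags if f.distance_x <= window]
    frags.sort(key=lambda f: (f.start, f.end, f.name))
    return frags


def score_fragments(
    fragments: Sequence[FragmentCandidate], model: MembershipModel
) -> list[FragmentCandidate]:
    """Attach a membership probability and the strict retention verdict.

    A distance of 0 (fragment center on the anchor center) is clamped to
    the law's x_min, where the tail is 1. Retention is strict:
    probability > threshold.
    """
    scored = []
    for f in fragments:
        x = max(float(f.distance_x), model.fit.x_min)
        p = membership_probability(model, x)
        scored.append(
            FragmentCandidate(
                f.chrom,
                f.start,
                f.end,
                name=f.name,
                distance_x=f.distance_x,
                probability=p,
                retained=p > model.threshold,
            )
        )
    return scored


def estimate_extension(
    anchor: AnchorPoint, scored: Sequence[FragmentCandidate]
) -> ExtensionEstimate:
    """Merge retained fragments with the anchor span into one estimate.

    No chaining or coverage continuity is required: every retained
    fragment extends the span directly, so isolated low-coverage
    fragments contribute. An empty retained set returns the anchor span
    itself with zero extensions.
    """
    retained = [f for f in scored if f.retained]
    mstart, mend = anchor.model_span
    span_start = min([mstart] + [f.start for f in retained])
    span_end = max([mend] + [f.end for f in retained])
    ext_left = mstart - span_start
    ext_right = span_end - mend
    if anchor.strand == "+":
        ext_5p, ext_3p, resolved = ext_left, ext_right, True
    elif anchor.strand == "-":
        ext_5p, ext_3p, resolved = ext_right, ext_left, True
    else:
        ext_5p, ext_3p, resolved = ext_left, ext_right, False
    return ExtensionEstimate(
        anchor=anchor,
        retained=sorted(retained, key=lambda f: (f.start, f.end, f.name)),
        span=(span_start, span_end),
        ext_left=ext_left,
        ext_right=ext_right,
        ext_5p=ext_5p,
        ext_3p=ext_3p,
        total_extension=ext_left + ext_right,
        full_length=span_end - span_start + 1,
        strand_resolved=resolved,
    )


def fragments_to_tsv(
    fragments: Sequence[FragmentCandidate], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tcenter\tdistance\tprobability\tretained\n")
        for f in fragments:
            prob = "" if f.probability is None else f"{f.probability:.6g}"
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t{f.center}\t"
                f"{f.distance_x}\t{prob}\t{int(f.retained)}\n"
            )


def extract_span_sequence(
    genome: Union[str, Path], estimate: ExtensionEstimate
) -> SeqRecord:
    """Fetch the estimated span's genomic sequence (FASTA must be indexable).

    Minus-strand estimates are reverse-complemented. The record id is
    ``chrom:start-end(strand)`` in 1-based inclusive coordinates.
    """
    chrom = estimate.anchor.chrom
    start, end = estimate.span
    with pysam.FastaFile(str(genome)) as fa:
        if chrom not in fa.references:
            raise ValueError(f"{chrom!r} absent from genome FASTA")
        chrom_len = fa.get_reference_length(chrom)
        if end > chrom_len or start < 1:
            raise ValueError(
                f"span [{start}, {end}] outside {chrom} (length {chrom_len})"
            )
        seq = Seq(fa.fetch(chrom, start - 1, end))
    strand = estimate.anchor.strand
    if strand == "-":
        seq = seq.reverse_complement()
    strand_char = strand if strand in ("+", "-") else "."
    return SeqRecord(seq, id=f"{chrom}:{start}-{end}({strand_char})", description="")
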