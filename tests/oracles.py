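"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: tail
probabilities come from numerical integration, critical distances from
bisection, exponents from an exact discrete maximum-likelihood fit, and
gap coordinates from a string-level CIGAR walker.
"""

from __future__ import annotations

import re

import numpy as np
import pysam
from scipy.integrate import quad
from scipy.optimize import minimize_scalar


def quad_tail(alpha: float, lo: float, hi: float, x: float) -> float:
    """P(X >= x) for density ∝ t^-alpha on [lo, hi], by quadrature."""
    if x <= lo:
        return 1.0
    if x >= hi:
        return 0.0
    dens = lambda t: t**-alpha  # noqa: E731
    num, _ = quad(dens, x, hi)
    den, _ = quad(dens, lo, hi)
    return num / den


def bisect_critical(
    alpha: float, lo: float, hi: float, threshold: float, tol: float = 1e-9
) -> float:
    """Distance where the truncated tail crosses ``threshold``."""
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if quad_tail(alpha, lo, hi, mid) > threshold:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def mle_discrete(lengths: np.ndarray, x_min: float, x_max: float) -> float:
    """Exact ML exponent for integer samples rounded from the continuous law."""
    ks, cnt = np.unique(np.asarray(lengths, dtype=float), return_counts=True)
    lo = np.maximum(ks - 0.5, x_min)
    hi = np.minimum(ks + 0.5, x_max)

    def nll(a: float) -> float:
        if abs(a - 1.0) < 1e-9:
            a += 1e-9
        a1 = 1.0 - a
        z = x_max**a1 - x_min**a1
        pk = (hi**a1 - lo**a1) / z
        return -float(np.sum(cnt * np.log(pk)))

    res = minimize_scalar(nll, bounds=(0.05, 8.0), method="bounded")
    return float(res.x)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_OPS = set("MDN=X")


def cigar_gaps_bruteforce(
    pos: int, cigar: str, min_gap: int
) -> list[tuple[int, int, int, str]]:
    """(gap_start, gap_end, length, op) per qualifying N/D op; pos is 1-based."""
    out = []
    ref = pos
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op in "ND" and n >= min_gap:
            out.append((ref, ref + n - 1, n, op))
        if op in _REF_OPS:
            ref += n
    return out


def random_cigar(rng: np.random.Generator) -> str:
    """A structurally valid CIGAR: M blocks interleaved with I/D/N/S ops."""
    parts = []
    if rng.random() < 0.3:
        parts.append(f"{rng.integers(1, 20)}S")
    parts.append(f"{rng.integers(1, 80)}M")
    for _ in range(rng.integers(0, 4)):
        op = rng.choice(["I", "D", "N"])
        parts.append(f"{rng.integers(1, 60)}{op}")
        parts.append(f"{rng.integers(1, 80)}M")
    if rng.random() < 0.3:
        parts.append(f"{rng.integers(1, 20)}S")
    return "".join(parts)


def query_length(cigar: str) -> int:
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op in "MIS=X")


def write_sam(path, chrom: str, chrom_len: int, records: list[dict]) -> None:
    """Write a minimal SAM; each record dict uses 1-based ``pos``/``mpos``."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": chrom_len}]}
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec["qname"]
            a.flag = rec.get("flag", 0)
            a.reference_id = 0
            a.reference_start = rec["pos"] - 1
            a.mapping_quality = rec.get("mapq", 60)
            a.cigarstring = rec["cigar"]
            if "mpos" in rec:
                a.next_reference_id = 0
                a.next_reference_start = rec["mpos"] - 1
                a.template_length = rec.get("tlen", 0)
            qlen = query_length(rec["cigar"])
            a.query_sequence = rec.get("seq", "A" * qlen)
            a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            sam.write(a)


def lengths_to_gtf(lengths, path, chrom: str = "chrT") -> None:
    """One single-exon transcript per length, laid end to end on one chrom."""
    pos = 1
    with open(path, "w") as fh:
        for i, length in enumerate(lengths):
            end = pos + int(length) - 1
            attrs = f'gene_id "G{i:06d}"; transcript_id "T{i:06d}";'
            fh.write(f"{chrom}\ttest\ttranscript\t{pos}\t{end}\t.\t+\t.\t{attrs}\n")
            fh.write(f"{chrom}\ttest\texon\t{pos}\t{end}\t.\t+\t.\t{attrs}\n")
            pos = end + 101
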