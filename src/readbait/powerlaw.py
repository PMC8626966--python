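"""Power-law model of transcript lengths and fragment co-membership.

The model: transcript lengths are heavy-tailed and well described, after
discarding overlong outliers, by a power law ``p(x) ∝ x^-alpha`` on a
finite support ``[x_min, x_max]``. The exponent is estimated exactly as
in the published procedure — bin the lengths with a fixed width (100 bp),
take the ordinal bin rank k as the regression x, and run ordinary least
squares of ``ln(count)`` on ``ln(k)``; ``alpha = -slope`` and
``C = exp(intercept)``.

The fitted law is then re-used as a spatial prior: a sequencing fragment
whose center lies a distance ``x`` from the center of an anchor read is
scored by the upper-tail probability ``P(X >= x)`` of the fitted law —
the probability that a transcript is long enough to span both. Fragments
scoring above a threshold (default 0.3) are deemed co-members of the
same transcript.

Two probability modes exist:

* ``truncated`` (default) — the proper tail of the power law restricted
  to ``[x_min, x_max]``; the normalization constant cancels, the tail is
  1 at ``x_min`` and 0 at ``x_max``.
* ``literal`` — the printed closed form ``1 - F(x)`` with
  ``F(x) = 1 - C/(alpha-1) * x^-(alpha-1)``, using the stored C. This is
  improper whenever ``alpha < 1`` (the tail integral diverges); values
  are clamped into [0, 1] with a warning. Kept for auditing published
  parameter sets only.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterator, Union

import numpy as np
import statsmodels.api as sm
from gffutils.feature import feature_from_line

__all__ = [
    "TranscriptLengthTable",
    "BinnedFrequency",
    "PowerLawFit",
    "MembershipModel",
    "GtfParseError",
    "EmptyAnnotationError",
    "DegenerateRegressionError",
    "extract_transcript_lengths",
    "filter_overlong",
    "bin_lengths",
    "fit_loglog",
    "fit_length_distribution",
    "membership_probability",
    "critical_distance",
]


class GtfParseError(ValueError):
    """A GTF line that cannot be interpreted; the message names the line."""


class EmptyAnnotationError(ValueError):
    """No transcript records found in the annotation."""


class DegenerateRegressionError(ValueError):
    """Too few usable bins (or no x-spread) for the log-log regression."""


# ---------------------------------------------------------------------------
# length table


@dataclass
class TranscriptLengthTable:
    """Transcript lengths (bp), one per transcript, plus optional ids."""

    lengths: np.ndarray
    source_label: str = ""
    transcript_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if self.lengths.ndim != 1:
            raise ValueError("lengths must be one-dimensional")
        if self.lengths.size and self.lengths.min() < 1:
            raise ValueError("all transcript lengths must be >= 1 bp")
        if self.transcript_ids is not None and len(self.transcript_ids) != self.lengths.size:
            raise ValueError("transcript_ids and lengths disagree in size")

    def __len__(self) -> int:
        return int(self.lengths.size)

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Two-column TSV: transcript_id, length."""
        ids = self.transcript_ids or [f"tx{i}" for i in range(len(self))]
        with open(path, "w") as fh:
            for tid, length in zip(ids, self.lengths):
                fh.write(f"{tid}\t{int(length)}\n")


def _gtf_lines(source: Union[str, Path, IO[str]]) -> Iterator[tuple[int, str]]:
    if hasattr(source, "read"):
        handle = source
        close = False
    else:
        handle = open(source)
        close = True
    try:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line
    finally:
        if close:
            handle.close()


def extract_transcript_lengths(
    annotation: Union[str, Path, IO[str]],
    source_label: str = "",
) -> TranscriptLengthTable:
    """Extract one length per transcript from a GTF (2.2 dialect).

    The length of a transcript is the sum of its exon lengths when exon
    features are present, else the span of its ``transcript`` feature.
    Results are ordered by transcript id, so the table is deterministic
    regardless of input record order.
    """
    exon_sum: dict[str, int] = {}
    tx_span: dict[str, int] = {}
    for lineno, line in _gtf_lines(annotation):
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        ftype = fields[2]
        if ftype not in ("exon", "transcript"):
            continue
        try:
            feat = feature_from_line(line)
            start, end = int(feat.start), int(feat.end)
        except Exception as exc:  # noqa: BLE001 - rewrap with line number
            raise GtfParseError(f"line {lineno}: {exc}") from exc
        if start > end or start < 1:
            raise GtfParseError(f"line {lineno}: invalid span [{start}, {end}]")
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise GtfParseError(f"line {lineno}: missing transcript_id attribute")
        tid = tids[0]
        span = end - start + 1
        if ftype == "exon":
            exon_sum[tid] = exon_sum.get(tid, 0) + span
        else:
            tx_span[tid] = span
    ids = sorted(set(exon_sum) | set(tx_span))
    if not ids:
        raise EmptyAnnotationError("annotation contains no transcript records")
    lengths = [exon_sum.get(t, tx_span.get(t, 0)) for t in ids]
    return TranscriptLengthTable(
        np.array(lengths, dtype=np.int64),
        source_label=source_label or getattr(annotation, "name", str(annotation)),
        transcript_ids=ids,
    )


def filter_overlong(
    table: TranscriptLengthTable, tie: str = "lower"
) -> tuple[TranscriptLengthTable, int]:
    """Drop transcripts strictly longer than the sample median.

    Longer transcripts yield disproportionately many reads, so the upper
    half of the length distribution is discarded before fitting. For
    even-sized samples the median is the lower of the two central values
    (``tie="lower"``, the default) or their mean (``tie="mean"``).
    """
    if len(table) == 0:
        raise ValueError("cannot take the median of an empty length table")
    ordered = np.sort(table.lengths)
    n = ordered.size
    if tie == "lower":
        median = float(ordered[(n - 1) // 2])
    elif tie == "mean":
        median = float(np.median(ordered))
    else:
        raise ValueError("tie must be 'lower' or 'mean'")
    keep = table.lengths <= median
    ids = (
        [t for t, k in zip(table.transcript_ids, keep) if k]
        if table.transcript_ids is not None
        else None
    )
    retained = TranscriptLengthTable(
        table.lengths[keep], source_label=table.source_label, transcript_ids=ids
    )
    return retained, int(median) if float(median).is_integer() else median


# ---------------------------------------------------------------------------
# binning and the log-log fit


@dataclass
class BinnedFrequency:
    """Occupied length bins: bin k covers ``((k-1)*w, k*w]`` for width w."""

    bin_width: int
    ranks: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if self.ranks.size != self.counts.size:
            raise ValueError("ranks and counts disagree in size")
        if self.ranks.size and (np.diff(self.ranks) <= 0).any():
            raise ValueError("rank indices must be strictly increasing")
        if self.ranks.size and self.ranks.min() < 1:
            raise ValueError("rank indices start at 1")

    @property
    def bins(self) -> list[tuple[int, float]]:
        return [(int(k), float(c)) for k, c in zip(self.ranks, self.counts)]

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def bin_lengths(table: TranscriptLengthTable, bin_width: int = 100) -> BinnedFrequency:
    """Histogram lengths into fixed-width bins indexed by rank.

    A length L falls in the bin of rank ``ceil(L / bin_width)``, i.e. a
    length exactly at a bin boundary belongs to the lower bin. Only
    occupied bins are emitted; the counts always sum to ``len(table)``.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    ranks = (table.lengths + bin_width - 1) // bin_width
    uniq, counts = np.unique(ranks, return_counts=True)
    return BinnedFrequency(bin_width, uniq, counts)


@dataclass
class PowerLawFit:
    """Fitted parameters of the binned log-log regression.

    ``alpha`` is minus the OLS slope of ln(count) on ln(rank);
    ``C = exp(intercept)``. ``x_min``/``x_max`` are the support bounds
    used by the membership tail (by convention x_max is the overlong
    cutoff, i.e. the sample median).
    """

    alpha: float
    C: float
    x_min: float
    x_max: float
    r2: float
    adjusted_r2: float
    slope_pvalue: float
    n_bins_used: int
    bin_width: int | None = None
    median_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if not self.x_min < self.x_max:
            raise ValueError("x_min must be < x_max")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "C": self.C,
            "x_min": self.x_min,
            "x_max": self.x_max,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "slope_pvalue": self.slope_pvalue,
            "n_bins_used": self.n_bins_used,
            "bin_width": self.bin_width,
            "median_cutoff": self.median_cutoff,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PowerLawFit":
        return cls(**json.loads(Path(path).read_text()))

    def to_report(self) -> str:
        """Flat key/value text report."""
        buf = io.StringIO()
        for key, value in self.to_dict().items():
            buf.write(f"{key}\t{value}\n")
        return buf.getvalue()


def fit_loglog(
    binned: BinnedFrequency,
    x_min: float = 1.0,
    x_max: float | None = None,
) -> PowerLawFit:
    """OLS of ln(count) on ln(rank index) over bins with count > 0.

    Returns alpha = -slope, C = exp(intercept), R², adjusted R²
    (``1 - (1 - R²)(n-1)/(n-2)`` for the single predictor) and the
    two-sided p-value of the slope. ``x_max`` defaults to the upper edge
    of the last occupied bin when not supplied (pass the overlong median
    cutoff to reproduce the published pipeline).
    """
    mask = np.asarray(binned.counts) > 0
    ranks = binned.ranks[mask]
    counts = np.asarray(binned.counts, dtype=float)[mask]
    if ranks.size < 3:
        raise DegenerateRegressionError(
            f"need >= 3 non-empty bins for the log-log fit, got {ranks.size}"
        )
    lnx = np.log(ranks.astype(float))
    lny = np.log(counts)
    if np.ptp(lnx) == 0:
        raise DegenerateRegressionError("all counts fall in a single bin")
    model = sm.OLS(lny, sm.add_constant(lnx)).fit()
    intercept, slope = model.params
    if x_max is None:
        x_max = float(ranks.max() * binned.bin_width)
    return PowerLawFit(
        alpha=float(-slope),
        C=float(np.exp(intercept)),
        x_min=float(x_min),
        x_max=float(x_max),
        r2=float(model.rsquared),
        adjusted_r2=float(model.rsquared_adj),
        slope_pvalue=float(model.pvalues[1]),
        n_bins_used=int(ranks.size),
        bin_width=binned.bin_width,
    )


def fit_length_distribution(
    table: TranscriptLengthTable,
    bin_width: int = 100,
    drop_overlong: bool = True,
    x_min: float = 1.0,
    tie: str = "lower",
) -> PowerLawFit:
    """Full fitting pipeline: overlong filter → bin → log-log OLS.

    When ``drop_overlong`` is set (default), lengths above the sample
    median are removed first and the median becomes the tail's x_max.
    """
    median: float | None = None
    if drop_overlong:
        table, median = filter_overlong(table, tie=tie)
    binned = bin_lengths(table, bin_width=bin_width)
    fit = fit_loglog(binned, x_min=x_min, x_max=median)
    fit.median_cutoff = median
    return fit


# ---------------------------------------------------------------------------
# membership probability


@dataclass
class MembershipModel:
    """A fitted length law re-used to score fragment co-membership."""

    fit: PowerLawFit
    mode: str = "truncated"
    threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in ("truncated", "literal"):
            raise ValueError("mode must be 'truncated' or 'literal'")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in the open interval (0, 1)")

    def probability(self, x):
        return membership_probability(self, x)

    def critical_distance(self) -> float:
        return critical_distance(self)


def _truncated_tail(x: np.ndarray, alpha: float, lo: float, hi: float) -> np.ndarray:
    if alpha == 1.0:
        p = np.log(hi / x) / np.log(hi / lo)
    else:
        a1 = 1.0 - alpha
        p = (hi**a1 - np.power(x, a1)) / (hi**a1 - lo**a1)
    return p


def membership_probability(model: MembershipModel, x):
    """P(same transcript) for a fragment whose center is ``x`` bp away.

    Truncated mode: the upper tail ``P(X >= x)`` of the power law on
    ``[x_min, x_max]`` — 1 at/below x_min, 0 at/beyond x_max, strictly
    decreasing in between; the normalization constant C cancels.

    Literal mode: ``1 - F(x)`` with the printed closed form, clamped to
    [0, 1] (a warning is emitted when clamping fires).

    Accepts a scalar or an array; x must be strictly positive.
    """
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if (arr <= 0).any():
        raise ValueError("distance x must be > 0")
    fit = model.fit
    if model.mode == "truncated":
        inside = np.clip(arr, fit.x_min, fit.x_max)
        p = _truncated_tail(inside, fit.alpha, fit.x_min, fit.x_max)
        p = np.where(arr < fit.x_min, 1.0, np.where(arr > fit.x_max, 0.0, p))
        p = np.clip(p, 0.0, 1.0)  # guard fp wobble at the support edges
    else:
        if fit.alpha == 1.0:
            raise ZeroDivisionError("literal mode is undefined at alpha = 1")
        tail = fit.C / (fit.alpha - 1.0) * np.power(arr, -(fit.alpha - 1.0))
        p = np.clip(tail, 0.0, 1.0)
        if (tail < 0).any() or (tail > 1).any():
            warnings.warn(
                "literal-mode tail fell outside [0, 1] and was clamped; "
                "the printed formula is improper for these parameters",
                RuntimeWarning,
                stacklevel=2,
            )
    return float(p[0]) if scalar else p


def critical_distance(model: MembershipModel) -> float:
    """The distance at which the truncated tail equals the threshold.

    Fragments strictly closer than this are always retained. Closed
    form: invert ``P(X >= x) = t`` on ``[x_min, x_max]``.
    """
    if model.mode != "truncated":
        raise ValueError("critical_distance is defined for truncated mode only")
    t = model.threshold
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    fit = model.fit
    lo, hi, a = fit.x_min, fit.x_max, fit.alpha
    if a == 1.0:
        return float(hi ** (1.0 - t) * lo**t)
    a1 = 1.0 - a
    return float((hi**a1 - t * (hi**a1 - lo**a1)) ** (1.0 / a1))


def with_scaled_C(model: MembershipModel, factor: float) -> MembershipModel:
    """Same model with C scaled — truncated probabilities are unchanged."""
    return replace(model, fit=replace(model.fit, C=model.fit.C * factor))
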