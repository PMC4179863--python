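"""Simultaneous demultiplexing and multi-criterion quality filtering.

Every input read is sorted into one of three bins: *high* quality (used
for OTU clustering, additionally emitted truncated to a fixed length),
*mid* quality (used only for abundance counting, so that noisy reads add
to counts without inflating diversity), or *rejected*.  The high band is
defined by an average-quality floor and an expected-error ceiling; the
mid band relaxes both (a multiplicative factor on expected error, a
subtractive Phred slack on average quality).  Structural filters
(length, ambiguous bases, homopolymer runs) apply to both bands.

The expected (accumulated) error of a read is the sum of per-base error
probabilities, ``sum_i 10**(-Q_i/10)`` — a length-aware quality measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

from .seqio import MappingTable, SequenceRead

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

REJECT_REASONS = (
    "too_short", "too_long", "ambiguous", "homopolymer",
    "avg_qual", "expected_error", "window_qual", "no_barcode", "no_primer",
)


@dataclass
class FilterSpec:
    """All filtering thresholds.

    Defaults target 454/MiSeq-scale amplicon data: reads are truncated to
    ``truncation_len`` (250 bp) for clustering input, the high band
    requires expected error <= 1.0 and mean quality >= Q27, and the mid
    band relaxes expected error 4x and mean quality by 5 Phred.
    ``max_len`` 0 means unlimited.
    """

    min_len: int = 250
    max_len: int = 0
    min_avg_qual: float = 27.0
    max_expected_error: float = 1.0
    window_width: int = 50
    window_min_qual: float = 25.0
    max_ambiguous: int = 0
    max_homopolymer: int = 8
    barcode_mismatch_max: int = 0
    primer_mismatch_max: int = 1
    adapter: Optional[str] = None
    truncation_len: int = 250
    mid_relax: float = 4.0
    avg_qual_slack: float = 5.0
    trim_from: str = "3p"  # which end the sliding-window trim removes

    def __post_init__(self) -> None:
        if self.mid_relax < 1:
            raise ValueError("mid_relax must be >= 1")
        if self.max_len and not (self.min_len <= self.truncation_len <= self.max_len):
            raise ValueError("require min_len <= truncation_len <= max_len")

    _OPTION_KEYS = (
        ("MinReadLength", "min_len", int),
        ("MaxReadLength", "max_len", int),
        ("MinAvgQuality", "min_avg_qual", float),
        ("MaxAccumulatedError", "max_expected_error", float),
        ("QualWindowWidth", "window_width", int),
        ("QualWindowThreshold", "window_min_qual", float),
        ("MaxAmbiguousNT", "max_ambiguous", int),
        ("MaxHomopolymer", "max_homopolymer", int),
        ("BarcodeErrors", "barcode_mismatch_max", int),
        ("PrimerErrors", "primer_mismatch_max", int),
        ("TruncateLength", "truncation_len", int),
        ("MidQualRelax", "mid_relax", float),
        ("AvgQualSlack", "avg_qual_slack", float),
    )

    @classmethod
    def from_options(cls, options: dict[str, str]) -> "FilterSpec":
        """Build a spec from option-file key/value pairs; unknown keys are
        preserved-with-warning by the caller (they do not raise here)."""
        known = {k: (attr, conv) for k, attr, conv in cls._OPTION_KEYS}
        kwargs = {}
        for key, value in options.items():
            if key in known:
                attr, conv = known[key]
                kwargs[attr] = conv(value)
            elif key == "Adapter":
                kwargs["adapter"] = value.upper() or None
        return cls(**kwargs)

    def to_options(self) -> dict[str, str]:
        opts = {}
        for key, attr, conv in self._OPTION_KEYS:
            value = getattr(self, attr)
            opts[key] = str(int(value)) if conv is int else repr(float(value))
        if self.adapter:
            opts["Adapter"] = self.adapter
        return opts


@dataclass(frozen=True)
class FilterOutcome:
    verdict: str  # high | mid | rejected
    reject_reason: Optional[str] = None
    processed_read: Optional[SequenceRead] = None

    def __post_init__(self) -> None:
        if (self.verdict == "rejected") != (self.reject_reason is not None):
            raise ValueError("reject_reason present iff verdict is rejected")


@dataclass
class DemuxReport:
    """Per-sample read counts by verdict plus rejection bookkeeping.

    Count conservation holds by construction: high + mid over samples,
    plus rejected and unassigned, equals the number of input reads.
    """

    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)
    reject_reasons: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0
    total_input: int = 0

    def record(self, sample: Optional[str], verdict: str,
               reason: Optional[str] = None) -> None:
        self.total_input += 1
        if sample is None:
            self.unassigned += 1
            return
        counts = self.per_sample.setdefault(
            sample, {"high": 0, "mid": 0, "rejected": 0})
        counts[verdict] += 1
        if reason is not None:
            self.reject_reasons[reason] = self.reject_reasons.get(reason, 0) + 1

    @property
    def total_accounted(self) -> int:
        return self.unassigned + sum(
            sum(v.values()) for v in self.per_sample.values())

    def to_rows(self) -> list[dict]:
        rows = []
        for sample in sorted(self.per_sample):
            rows.append({"sample": sample, **self.per_sample[sample]})
        return rows


def expected_error(quals: Sequence[int]) -> float:
    """Sum of per-base error probabilities, ``sum 10**(-Q/10)``."""
    total = 0.0
    for q in quals:
        if q < 0:
            raise ValueError(f"negative Phred quality {q}")
        total += 10.0 ** (-q / 10.0)
    return total


def mean_quality(quals: Sequence[int]) -> float:
    return sum(quals) / len(quals) if quals else 0.0


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def match_barcode(
    read: SequenceRead, mapping: MappingTable, mismatch_max: int
) -> tuple[Optional[str], SequenceRead]:
    """Match 5'-anchored sample barcodes within a Hamming-distance budget.

    The unique sample at minimal distance <= ``mismatch_max`` wins and its
    barcode is clipped off; a tie at the minimal distance leaves the read
    unassigned (safety against cross-sample bleed).
    """
    best_dist = mismatch_max + 1
    best_row = None
    tie = False
    for row in mapping:
        bc = row.barcode
        if len(read.bases) < len(bc):
            continue
        d = hamming(read.bases[:len(bc)], bc)
        if d < best_dist:
            best_dist, best_row, tie = d, row, False
        elif d == best_dist and best_row is not None:
            tie = True
    if best_row is None or tie or best_dist > mismatch_max:
        return None, read
    return best_row.sample_id, read.slice(len(best_row.barcode))


def match_primer(
    read: SequenceRead, primer_iupac: str, mismatch_max: int
) -> tuple[bool, SequenceRead]:
    """Match a degenerate primer at the current 5' start of the read.

    A degenerate IUPAC position matches any base in its set at zero cost;
    on success the primer is clipped off.
    """
    primer = primer_iupac.upper()
    if len(read.bases) < len(primer):
        return False, read
    mismatches = 0
    for base, code in zip(read.bases, primer):
        if base not in IUPAC.get(code, code):
            mismatches += 1
            if mismatches > mismatch_max:
                return False, read
    return True, read.slice(len(primer))


def trim_low_quality_tail(read: SequenceRead, window_width: int,
                          window_min_qual: float,
                          trim_from: str = "3p") -> SequenceRead:
    """Sliding-window quality trim.

    A window slides inward from the read end being preserved; at the
    first window whose mean quality falls below the threshold the read is
    cut at that window's start.  Default removes the low-quality 3' tail,
    preserving the 5' region; ``trim_from='5p'`` mirrors the scan.
    Reads shorter than the window are returned unchanged.
    """
    if read.quals is None or window_width <= 0 or len(read) < window_width:
        return read
    quals = read.quals
    if trim_from == "5p":
        quals = quals[::-1]
    window_sum = sum(quals[:window_width])
    cut = None
    for start in range(len(quals) - window_width + 1):
        if start > 0:
            window_sum += quals[start + window_width - 1] - quals[start - 1]
        if window_sum / window_width < window_min_qual:
            cut = start
            break
    if cut is None:
        return read
    if trim_from == "5p":
        return read.slice(len(read) - cut)
    return read.slice(0, cut)


def longest_homopolymer(bases: str) -> int:
    best = run = 0
    prev = ""
    for b in bases:
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best


def classify_read(read: SequenceRead, spec: FilterSpec) -> FilterOutcome:
    """Apply the full filter cascade to one (barcode/primer-clipped) read.

    Order: adapter clip, window tail-trim, structural filters, then the
    quality bands.  Rejection reports the first failing criterion in a
    fixed precedence so reports are deterministic.
    """
    if spec.adapter:
        pos = read.bases.find(spec.adapter)
        if pos >= 0:
            read = read.slice(0, pos)
    quality_filters_on = (
        spec.min_avg_qual > 0 or spec.max_expected_error > 0
        or spec.window_width > 0)
    if read.quals is None and quality_filters_on:
        raise ValueError(
            f"read {read.read_id!r} has no qualities; disable quality "
            "criteria (MinAvgQuality/MaxAccumulatedError/QualWindowWidth 0) "
            "for quality-less input")
    if read.quals is not None:
        read = trim_low_quality_tail(
            read, spec.window_width, spec.window_min_qual, spec.trim_from)

    def rejected(reason: str) -> FilterOutcome:
        return FilterOutcome("rejected", reason)

    if len(read) < spec.min_len:
        return rejected("too_short")
    if spec.max_len and len(read) > spec.max_len:
        return rejected("too_long")
    if read.bases.count("N") > spec.max_ambiguous:
        return rejected("ambiguous")
    if longest_homopolymer(read.bases) > spec.max_homopolymer:
        return rejected("homopolymer")

    if read.quals is None:
        return FilterOutcome("high", processed_read=read)
    avg = mean_quality(read.quals)
    ee = expected_error(read.quals)
    if avg >= spec.min_avg_qual and ee <= spec.max_expected_error:
        return FilterOutcome("high", processed_read=read)
    if (avg >= spec.min_avg_qual - spec.avg_qual_slack
            and ee <= spec.max_expected_error * spec.mid_relax):
        return FilterOutcome("mid", processed_read=read)
    if avg < spec.min_avg_qual - spec.avg_qual_slack:
        return rejected("avg_qual")
    return rejected("expected_error")


@dataclass
class DemuxResult:
    """Output bins of a demultiplexing run.

    ``high``/``mid`` hold full-length (trimmed, untruncated) reads with
    sample labels; ``high_truncated`` are copies of the high bin cut to
    the clustering input length.
    """

    high: list[SequenceRead]
    mid: list[SequenceRead]
    high_truncated: list[SequenceRead]
    report: DemuxReport


def _demux_one(read: SequenceRead, mapping: MappingTable, spec: FilterSpec,
               demultiplex: bool) -> tuple[Optional[str], FilterOutcome]:
    sample: Optional[str] = None
    if demultiplex:
        sample, read = match_barcode(read, mapping, spec.barcode_mismatch_max)
        if sample is None:
            return None, FilterOutcome("rejected", "no_barcode")
        row = next(r for r in mapping if r.sample_id == sample)
        if row.fwd_primer:
            found, read = match_primer(read, row.fwd_primer,
                                       spec.primer_mismatch_max)
            if not found:
                return sample, FilterOutcome("rejected", "no_primer")
    return sample, classify_read(read, spec)


def demultiplex_run(
    reads: Iterable[Union[SequenceRead, tuple[SequenceRead, SequenceRead]]],
    mapping: MappingTable,
    spec: FilterSpec,
    demultiplex: bool = True,
) -> DemuxResult:
    """Sort every input read into high / mid / rejected, assigning samples.

    For read pairs the barcode and primer are matched on the forward
    mate and the pair verdict is the worse of the two mates; both mates
    are retained in the winning bin.
    """
    result = DemuxResult([], [], [], DemuxReport())
    order = {"high": 0, "mid": 1, "rejected": 2}
    for item in reads:
        if isinstance(item, tuple):
            fwd, rev = item
            sample, fwd_out = _demux_one(fwd, mapping, spec, demultiplex)
            if sample is None:
                result.report.record(None, "rejected")
                continue
            rev_out = classify_read(rev, spec)
            out = max(fwd_out, rev_out, key=lambda o: order[o.verdict])
            processed = (fwd_out.processed_read, rev_out.processed_read)
        else:
            sample, out = _demux_one(item, mapping, spec, demultiplex)
            if sample is None and demultiplex:
                result.report.record(None, "rejected")
                continue
            processed = (out.processed_read, None)
        sample_label = sample if demultiplex else (item.sample or "all")
        result.report.record(sample_label, out.verdict, out.reject_reason)
        if out.verdict == "rejected":
            continue
        emitted = [r.with_sample(sample_label) for r in processed if r is not None]
        if out.verdict == "high":
            result.high.extend(emitted)
            for r in emitted:
                if len(r) >= spec.truncation_len:
                    result.high_truncated.append(r.slice(0, spec.truncation_len))
        else:
            result.mid.extend(emitted)
    return result
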