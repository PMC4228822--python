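"""Domain types shared by all analysis stages.

Coordinate convention: all internal intervals are 0-based half-open on the
forward strand. Per-cytosine positions are 1-based on the cytosine's own
strand, matching the CGmap dialect that is the toolkit's pileup entry point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGTN")
CONTEXTS = ("CG", "CHG", "CHH")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: upper-case sequence over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"contig {self.contig_id}: illegal characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


@dataclass
class FeatureRecord:
    """A genomic interval (gene, TE, exon set or repeat), 0-based half-open."""

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    feature_class: str = "gene"
    exon_intervals: list[tuple[int, int]] | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.feature_id}: invalid interval "
                f"[{self.start},{self.end})"
            )
        if self.exon_intervals:
            for s, e in self.exon_intervals:
                if s < self.start or e > self.end or s >= e:
                    raise FormatError(
                        f"feature {self.feature_id}: exon [{s},{e}) outside "
                        f"feature span [{self.start},{self.end})"
                    )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def union_exon_length(self) -> int:
        """Union length of all exons; the feature span when no exons given."""
        if not self.exon_intervals:
            return self.end - self.start
        return union_length(self.exon_intervals)


@dataclass
class CytosineRecord:
    """One strand-resolved cytosine with methylated/unmethylated read counts.

    ``mc_count`` is the number of reads supporting methylation (read as C),
    ``t_count`` the number supporting no methylation (converted, read as T).
    """

    contig_id: str
    position: int  # 1-based, on the cytosine's own strand
    strand: str
    context: str  # CG, CHG, CHH or "unknown"
    dinucleotide_context: str
    mc_count: int
    t_count: int

    def __post_init__(self):
        if self.mc_count < 0 or self.t_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def coverage(self) -> int:
        return self.mc_count + self.t_count

    @property
    def level(self) -> float:
        """Methylation level #C/(#C+#T); NaN when the site has no coverage."""
        cov = self.coverage
        if cov == 0:
            return math.nan
        return self.mc_count / cov


@dataclass
class TranscriptRecord:
    """An assembled transcript with an assembly-comparison class code and an
    FPKM point estimate plus 95% confidence bounds."""

    transcript_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "."
    class_code: str = "u"
    fpkm: float | None = None
    fpkm_conf_lo: float | None = None
    fpkm_conf_hi: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"transcript {self.transcript_id}: invalid interval"
            )
        if self.fpkm is not None and self.has_confidence_interval and not (
            self.fpkm_conf_lo <= self.fpkm <= self.fpkm_conf_hi
        ):
            raise FormatError(
                f"transcript {self.transcript_id}: FPKM {self.fpkm} outside "
                f"its confidence interval "
                f"[{self.fpkm_conf_lo}, {self.fpkm_conf_hi}]"
            )

    @property
    def has_confidence_interval(self) -> bool:
        return self.fpkm_conf_lo is not None and self.fpkm_conf_hi is not None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LibraryStats:
    """Per-library sequencing summary: raw vs uniquely mapped reads."""

    library_id: str
    raw_reads: int
    unique_reads: int
    read_length: int
    mapability: float | None = None  # percent
    coverage_per_strand: float | None = None  # X

    def __post_init__(self):
        if not (0 <= self.unique_reads <= self.raw_reads):
            raise ValueError("need 0 <= unique_reads <= raw_reads")


@dataclass
class ReadPlacement:
    """A uniquely aligned read span, 0-based half-open."""

    read_id: str
    contig_id: str
    start: int
    end: int
    unique: bool = True

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"read {self.read_id}: empty span")


@dataclass
class CoverageWindow:
    """One fixed-width genomic window with mean per-bp depth in two libraries."""

    contig_id: str
    start: int
    end: int
    depth_a: float
    depth_b: float
    norm_ratio: float | None = None
    log_ratio: float | None = None

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class CNVCall:
    window: CoverageWindow
    direction: str  # gain_in_a | loss_in_a
    passed_threshold: bool
    confirmed: bool | None = None


@dataclass
class NovelGeneCall:
    """A cluster of overlapping novel transcripts collapsed to its spanning
    interval, with the downstream homology flag."""

    cluster_id: str
    contig_id: str
    start: int
    end: int
    member_transcript_ids: list[str] = field(default_factory=list)
    homologous: bool | None = None
    source_samples: list[str] = field(default_factory=list)

    @property
    def span_length(self) -> int:
        return self.end - self.start
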