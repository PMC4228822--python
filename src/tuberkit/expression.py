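"""Feature-level read counting, RPKM and library statistics.

A uniquely aligned read counts for a gene or TE only when its full aligned
span lies within that feature and within no other feature; reads touching
zero features or the overlap of two are tallied as unassigned with a
reason. Expression is reported as RPKM (reads per kilobase of exon model
per million reads counted), with gene length taken as the union length of
all exons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import FeatureRecord, LibraryStats, ReadPlacement


@dataclass
class ExpressionRecord:
    feature_id: str
    count: int
    union_exon_length: int
    rpkm: float


def assign_reads(placements: Sequence[ReadPlacement],
                 features: Sequence[FeatureRecord]
                 ) -> tuple[dict[str, int], dict[str, int]]:
    """Count reads mapped entirely to a single gene or TE.

    Returns (counts, unassigned) where counts maps feature_id -> reads and
    unassigned tallies the reasons: "no_feature" (touches none),
    "not_contained" (overlaps a feature but crosses its edge), "ambiguous"
    (contained in or touching two or more features). Non-unique placements
    never enter counting ("non_unique").
    """
    trees: dict[str, IntervalTree] = {}
    for i, f in enumerate(features):
        trees.setdefault(f.contig_id, IntervalTree()).addi(f.start, f.end, i)
    counts = {f.feature_id: 0 for f in features}
    unassigned = {"no_feature": 0, "not_contained": 0, "ambiguous": 0,
                  "non_unique": 0}
    for read in placements:
        if not read.unique:
            unassigned["non_unique"] += 1
            continue
        tree = trees.get(read.contig_id)
        hits = sorted(tree.overlap(read.start, read.end)) if tree else []
        if not hits:
            unassigned["no_feature"] += 1
        elif len(hits) > 1:
            unassigned["ambiguous"] += 1
        else:
            f = features[hits[0].data]
            if f.start <= read.start and read.end <= f.end:
                counts[f.feature_id] += 1
            else:
                unassigned["not_contained"] += 1
    return counts, unassigned


def compute_rpkm(counts: Mapping[str, int],
                 features: Sequence[FeatureRecord],
                 total_counted: int) -> list[ExpressionRecord]:
    """RPKM = count / (union_exon_length/1000) / (total_counted/1e6)."""
    if total_counted <= 0:
        raise ValueError("total_counted must be > 0")
    out = []
    for f in features:
        count = int(counts.get(f.feature_id, 0))
        length = f.union_exon_length
        if length <= 0:
            if count > 0:
                raise ValueError(
                    f"feature {f.feature_id} has zero exon length but "
                    f"{count} reads")
            rpkm = 0.0
        else:
            rpkm = count / (length / 1000.0) / (total_counted / 1e6)
        out.append(ExpressionRecord(f.feature_id, count, length, rpkm))
    return out


def expression_table(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature_id, r.count, r.union_exon_length, r.rpkm)
         for r in records],
        columns=["feature_id", "count", "union_exon_length", "rpkm"])


def coverage_classes(count_table_a: Mapping[str, int],
                     count_table_b: Mapping[str, int],
                     min_reads: int = 10) -> tuple[pd.DataFrame, dict]:
    """Classify features by >=min_reads coverage in two libraries.

    Returns (per_feature, venn): per_feature has one row per feature with
    its counts and class in {both, a_only, b_only, neither}; venn maps each
    class to its feature count plus "percent_covered_a"/"percent_covered_b"
    — the kind of histogram/Venn summary used to judge library completeness.
    """
    if set(count_table_a) != set(count_table_b):
        diff = sorted(set(count_table_a) ^ set(count_table_b))
        raise ValueError(f"feature sets differ between libraries: {diff}")
    rows = []
    for fid in sorted(count_table_a):
        ca, cb = count_table_a[fid], count_table_b[fid]
        in_a, in_b = ca >= min_reads, cb >= min_reads
        cls = ("both" if in_a and in_b else
               "a_only" if in_a else "b_only" if in_b else "neither")
        rows.append((fid, ca, cb, cls))
    per_feature = pd.DataFrame(
        rows, columns=["feature_id", "count_a", "count_b", "klass"])
    n = len(per_feature)
    venn = {cls: int((per_feature["klass"] == cls).sum())
            for cls in ("both", "a_only", "b_only", "neither")}
    venn["percent_covered_a"] = (
        100.0 * (venn["both"] + venn["a_only"]) / n if n else math.nan)
    venn["percent_covered_b"] = (
        100.0 * (venn["both"] + venn["b_only"]) / n if n else math.nan)
    return per_feature, venn


def fold_change(rpkm_treated: float, rpkm_untreated: float) -> float | None:
    """Expression ratio, treated over untreated; None when undefined.

    Matches the orientation of a treated-vs-control table: values above 1
    mean induction by the treatment. Returns None when the untreated RPKM
    is zero (and the treated is not).
    """
    if rpkm_treated < 0 or rpkm_untreated < 0:
        raise ValueError("RPKM values must be >= 0")
    if rpkm_untreated == 0:
        return None
    return rpkm_treated / rpkm_untreated


def fold_change_table(rpkm_untreated: Mapping[str, float],
                      rpkm_treated: Mapping[str, float]) -> pd.DataFrame:
    """Per-feature fold changes, rounded to 2 decimals at serialization
    (round-half-even), mirroring a treated/untreated comparison table."""
    rows = []
    for fid in sorted(set(rpkm_untreated) & set(rpkm_treated)):
        fc = fold_change(rpkm_treated[fid], rpkm_untreated[fid])
        rows.append((fid, rpkm_untreated[fid], rpkm_treated[fid],
                     math.nan if fc is None else round(fc, 2)))
    return pd.DataFrame(rows, columns=[
        "feature_id", "rpkm_untreated", "rpkm_treated", "fold_change"])


def library_stats(library_id: str, raw_reads: int, unique_reads: int,
                  read_length: int,
                  genome_size: int | None = None) -> LibraryStats:
    """Mapping summary for one library.

    Mapability = 100 * unique/raw, rounded to 2 decimals; per-strand
    coverage = unique * read_length / (2 * genome_size) when a genome size
    is supplied (each strand of a bisulfite library is sequenced
    separately, hence the factor 2).
    """
    stats = LibraryStats(library_id=library_id, raw_reads=raw_reads,
                         unique_reads=unique_reads, read_length=read_length)
    if raw_reads > 0:
        stats.mapability = round(100.0 * unique_reads / raw_reads, 2)
    if genome_size:
        stats.coverage_per_strand = (
            unique_reads * read_length / (2.0 * genome_size))
    return stats
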