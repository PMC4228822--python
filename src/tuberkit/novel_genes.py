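"""Novel-gene prediction from assembly-comparison transcript records.

The cascade mirrors a reference-guided assembly workflow downstream of
transcript assembly and comparison: keep intergenic transcripts (class
code "u") that overlap no known annotation and whose FPKM is at least 4
throughout its 95% confidence interval; cluster surviving transcripts that
overlap into one spanning interval each; drop clusters at or above the
longest-known-gene length cutoff (36,573 bp); and accept the remainder as
novel genes only when flagged homologous to a known protein (the homology
flag is produced upstream by protein-database search and consumed here).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import FeatureRecord, NovelGeneCall, TranscriptRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_FPKM = 4.0
DEFAULT_LENGTH_CUTOFF = 36_573


def filter_novel_transcripts(transcripts: Sequence[TranscriptRecord],
                             known_features: Sequence[FeatureRecord],
                             min_fpkm: float = DEFAULT_MIN_FPKM,
                             use_point_estimate: bool = False,
                             strand_aware: bool = False
                             ) -> list[TranscriptRecord]:
    """Class-code, overlap and FPKM-confidence filters.

    A transcript survives iff its class code is "u", it shares no position
    with any known feature (>=1 bp overlap disqualifies; strand-blind by
    default because "u" transcripts may be unstranded — ``strand_aware``
    restricts the check to same-strand features, with unstranded
    transcripts still compared against both), and its FPKM
    confidence-interval lower bound is at least ``min_fpkm`` (boundary
    inclusive). With ``use_point_estimate`` the FPKM point estimate is
    tested instead of the lower bound. Transcripts without a confidence
    interval are excluded and logged.
    """
    trees: dict[str, IntervalTree] = {}
    for f in known_features:
        trees.setdefault(f.contig_id, IntervalTree()).addi(
            f.start, f.end, f.strand)
    out = []
    for t in transcripts:
        if t.class_code != "u":
            continue
        if use_point_estimate:
            if t.fpkm is None:
                logger.warning("transcript %s has no FPKM, excluded",
                               t.transcript_id)
                continue
            if t.fpkm < min_fpkm:
                continue
        else:
            if not t.has_confidence_interval:
                logger.warning("transcript %s has no FPKM confidence "
                               "interval, excluded", t.transcript_id)
                continue
            if t.fpkm_conf_lo < min_fpkm:
                continue
        tree = trees.get(t.contig_id)
        hits = tree.overlap(t.start, t.end) if tree is not None else set()
        if strand_aware and t.strand in "+-":
            hits = {h for h in hits if h.data == t.strand}
        if hits:
            continue
        out.append(t)
    return out


def cluster_overlapping(transcripts: Sequence[TranscriptRecord],
                        spanning_interval: bool = True
                        ) -> list[NovelGeneCall]:
    """Merge overlapping transcripts into one call per connected component.

    Overlap (same contig, >=1 shared bp, strand-blind) is transitive
    through chains: a sweep over start-sorted intervals closes a cluster
    only when the next transcript starts past the running maximum end, so
    the partition equals the connected components of the overlap graph. The
    call's interval is the union span of its members (or, with
    ``spanning_interval=False``, the span of the single longest member).
    Output is ordered by (contig, start) and independent of input order.
    """
    by_contig: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        by_contig.setdefault(t.contig_id, []).append(t)
    calls = []
    for contig in sorted(by_contig):
        members: list[TranscriptRecord] = []
        span_end = None
        ordered = sorted(by_contig[contig],
                         key=lambda t: (t.start, t.end, t.transcript_id))

        def close():
            if not members:
                return
            start = min(t.start for t in members)
            end = max(t.end for t in members)
            if not spanning_interval:
                longest = max(members,
                              key=lambda t: (t.length, t.transcript_id))
                start, end = longest.start, longest.end
            calls.append(NovelGeneCall(
                cluster_id="",
                contig_id=contig, start=start, end=end,
                member_transcript_ids=sorted(
                    t.transcript_id for t in members)))

        for t in ordered:
            if span_end is not None and t.start >= span_end:
                close()
                members, span_end = [], None
            members.append(t)
            span_end = t.end if span_end is None else max(span_end, t.end)
        close()
    calls.sort(key=lambda c: (c.contig_id, c.start))
    for i, c in enumerate(calls, 1):
        c.cluster_id = f"novel{str(i).zfill(4)}"
    return calls


def finalize_novel_genes(clusters: Sequence[NovelGeneCall],
                         homology_table: Mapping[str, bool],
                         length_cutoff: int = DEFAULT_LENGTH_CUTOFF
                         ) -> list[NovelGeneCall]:
    """Length filter then homology requirement.

    Clusters whose span is at or above ``length_cutoff`` (the longest known
    gene) are removed; the rest are novel genes only if their homology flag
    is true. A cluster absent from the table counts as not homologous.
    """
    out = []
    for c in clusters:
        if c.span_length >= length_cutoff:
            continue
        c.homologous = bool(homology_table.get(c.cluster_id, False))
        if c.homologous:
            out.append(c)
    return out


def novel_gene_cascade(transcripts: Sequence[TranscriptRecord],
                       known_features: Sequence[FeatureRecord],
                       homology_table: Mapping[str, bool],
                       min_fpkm: float = DEFAULT_MIN_FPKM,
                       length_cutoff: int = DEFAULT_LENGTH_CUTOFF
                       ) -> list[NovelGeneCall]:
    """The full filter cascade in one call."""
    survivors = filter_novel_transcripts(transcripts, known_features,
                                         min_fpkm=min_fpkm)
    clusters = cluster_overlapping(survivors)
    return finalize_novel_genes(clusters, homology_table,
                                length_cutoff=length_cutoff)


def per_sample_summary(per_sample_calls: Mapping[str, Sequence[NovelGeneCall]],
                       merged_calls: Sequence[NovelGeneCall] | None = None
                       ) -> pd.DataFrame:
    """Per-sample and merged novel-gene counts (prediction summary table)."""
    rows = [(sample, len(calls))
            for sample, calls in per_sample_calls.items()]
    if merged_calls is not None:
        rows.append(("merged", len(merged_calls)))
    return pd.DataFrame(rows, columns=["sample", "n_novel_genes"])
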