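"""Readers and writers for the standard formats the toolkit touches.

FASTA, GFF3/BED annotations, CGmap/ATCGmap cytosine pileups, GTF transcript
records carrying assembly-comparison attributes, and wiggle/BED track output.

Parsers validate strictly: malformed lines abort with their line number
rather than being skipped, so a truncated or corrupt input never produces a
silently wrong analysis.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from gffutils.feature import feature_from_line

from .core import (
    CNVCall,
    CytosineRecord,
    FeatureRecord,
    FormatError,
    GenomeSequence,
    TranscriptRecord,
)

logger = logging.getLogger(__name__)

CGMAP_CONTEXTS = {"CG", "CHG", "CHH"}


# ---------------------------------------------------------------------------
# FASTA

def parse_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records.

    Sequences are upper-cased; characters outside {A,C,G,T,N} and duplicate
    contig ids are format errors, as is an empty file.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(genomes: Sequence[GenomeSequence], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.contig_id}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / BED features

def _parse_gff3_features(path: str | Path) -> list[FeatureRecord]:
    """GFF3 (1-based closed) -> internal 0-based half-open records.

    Exon lines are grouped under their Parent feature; every non-exon line
    with an ID becomes a feature. The feature class is the GFF3 type column,
    with transposable-element types normalized to "TE".
    """
    parents: dict[str, FeatureRecord] = {}
    order: list[str] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(f"unparseable GFF3 line: {exc}", lineno)
            start = feat.start - 1  # to 0-based half-open
            end = feat.end
            if end <= start:
                raise FormatError(
                    f"feature end {feat.end} <= start after normalization",
                    lineno,
                )
            ftype = feat.featuretype
            if ftype == "exon":
                parent_ids = feat.attributes.get("Parent", [])
                if not parent_ids:
                    raise FormatError("exon without Parent attribute", lineno)
                exons.setdefault(parent_ids[0], []).append((start, end))
                continue
            fid = (feat.attributes.get("ID") or [f"{ftype}:{lineno}"])[0]
            fclass = {
                "transposable_element": "TE",
                "TE": "TE",
                "repeat_region": "repeat",
                "repeat": "repeat",
            }.get(ftype, ftype)
            if fid in parents:
                raise FormatError(f"duplicate feature ID {fid!r}", lineno)
            parents[fid] = FeatureRecord(
                feature_id=fid,
                contig_id=feat.seqid,
                start=start,
                end=end,
                strand=feat.strand if feat.strand in "+-" else "+",
                feature_class=fclass,
            )
            order.append(fid)
    for fid, ivals in exons.items():
        if fid in parents:
            parents[fid].exon_intervals = sorted(ivals)
    return [parents[fid] for fid in order]


def _parse_bed_features(path: str | Path) -> list[FeatureRecord]:
    """BED4/BED6 (already 0-based half-open) -> records, coordinates kept."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError("BED line has fewer than 3 columns", lineno)
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise FormatError("non-integer BED coordinates", lineno)
            if end <= start:
                raise FormatError(f"BED end {end} <= start {start}", lineno)
            name = cols[3] if len(cols) > 3 else f"{cols[0]}:{start}-{end}"
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            out.append(FeatureRecord(
                feature_id=name, contig_id=cols[0], start=start, end=end,
                strand=strand, feature_class="repeat",
            ))
    return out


def parse_features(path: str | Path, dialect: str = "GFF3") -> list[FeatureRecord]:
    """Read gene/TE/repeat annotations from GFF3 or BED.

    Coordinates are normalized to the internal 0-based half-open convention;
    GFF3 exon lines are grouped under their parent so union-exon lengths are
    available downstream.
    """
    if dialect.upper() == "GFF3":
        return _parse_gff3_features(path)
    if dialect.upper() == "BED":
        return _parse_bed_features(path)
    raise ValueError(f"unknown feature dialect {dialect!r}")


def write_gff3(features: Sequence[FeatureRecord], path: str | Path) -> None:
    """Write features (and their exons) back out as GFF3, 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            ftype = {"TE": "transposable_element"}.get(
                f.feature_class, f.feature_class)
            fh.write(
                f"{f.contig_id}\ttuberkit\t{ftype}\t{f.start + 1}\t{f.end}"
                f"\t.\t{f.strand}\t.\tID={f.feature_id}\n"
            )
            for i, (s, e) in enumerate(f.exon_intervals or [], 1):
                fh.write(
                    f"{f.contig_id}\ttuberkit\texon\t{s + 1}\t{e}\t.\t"
                    f"{f.strand}\t.\tID={f.feature_id}.exon{i};"
                    f"Parent={f.feature_id}\n"
                )


# ---------------------------------------------------------------------------
# CGmap / ATCGmap pileups

def parse_cgmap(path: str | Path) -> list[CytosineRecord]:
    """Read an 8-column CGmap pileup into CytosineRecords.

    Columns: contig, nucleotide {C,G}, 1-based position, context
    {CG,CHG,CHH}, dinucleotide context, methylation level, methylated read
    count, total coverage. A C in column 2 is a plus-strand cytosine, a G a
    minus-strand one. The stored level is recomputed from the counts; the
    file's level column is only checked for consistency (within 0.01).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 8:
                raise FormatError(
                    f"expected 8 CGmap columns, got {len(cols)}", lineno)
            contig, nuc, pos_s, context, dinuc, level_s, mc_s, total_s = cols
            if nuc not in ("C", "G"):
                raise FormatError(f"nucleotide column must be C or G, got "
                                  f"{nuc!r}", lineno)
            if context not in CGMAP_CONTEXTS:
                raise FormatError(f"unknown context token {context!r}", lineno)
            try:
                pos, mc, total = int(pos_s), int(mc_s), int(total_s)
                file_level = float(level_s)
            except ValueError:
                raise FormatError("non-numeric CGmap field", lineno)
            if mc > total:
                raise FormatError(
                    f"methylated count {mc} exceeds coverage {total}", lineno)
            if total > 0 and abs(file_level - mc / total) > 0.01:
                raise FormatError(
                    f"level {file_level} inconsistent with counts "
                    f"{mc}/{total}", lineno)
            out.append(CytosineRecord(
                contig_id=contig,
                position=pos,
                strand="+" if nuc == "C" else "-",
                context=context,
                dinucleotide_context=dinuc,
                mc_count=mc,
                t_count=total - mc,
            ))
    return out


def serialize_cgmap(records: Iterable[CytosineRecord], path: str | Path) -> None:
    """Write CytosineRecords as 8-column CGmap.

    Records with an unknown context cannot be represented in the dialect and
    are skipped with a logged warning. parse_cgmap(serialize_cgmap(x))
    reproduces x for representable records.
    """
    n_skipped = 0
    with open(path, "w") as fh:
        for r in records:
            if r.context not in CGMAP_CONTEXTS:
                n_skipped += 1
                continue
            level = r.level
            level_s = "0.0" if math.isnan(level) else f"{level:.6g}"
            nuc = "C" if r.strand == "+" else "G"
            fh.write(
                f"{r.contig_id}\t{nuc}\t{r.position}\t{r.context}\t"
                f"{r.dinucleotide_context}\t{level_s}\t{r.mc_count}\t"
                f"{r.coverage}\n"
            )
    if n_skipped:
        logger.warning("serialize_cgmap: skipped %d records with unknown "
                       "context", n_skipped)


def parse_atcgmap(path: str | Path) -> list[CytosineRecord]:
    """Read a BS-Seeker2-style ATCGmap pileup.

    Columns: contig, nucleotide {C,G}, position, context, dinucleotide,
    then per-base Watson counts A,T,C,G and Crick counts A,T,C,G. On the
    cytosine's own strand an unconverted C supports methylation and a
    converted T supports none: for a plus-strand cytosine these are the
    Watson C and T counts, for a minus-strand one the Crick G-column is the
    unconverted base and the Crick A-column the converted one (reads on the
    Crick strand are reported in Watson orientation).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 13:
                raise FormatError(
                    f"expected >=13 ATCGmap columns, got {len(cols)}", lineno)
            contig, nuc, pos_s, context, dinuc = cols[:5]
            if nuc not in ("C", "G"):
                raise FormatError("nucleotide column must be C or G", lineno)
            if context not in CGMAP_CONTEXTS:
                raise FormatError(f"unknown context token {context!r}", lineno)
            try:
                pos = int(pos_s)
                wa, wt, wc, wg = (int(x) for x in cols[5:9])
                ca, ct, cc, cg = (int(x) for x in cols[9:13])
            except ValueError:
                raise FormatError("non-numeric ATCGmap field", lineno)
            if nuc == "C":
                mc, t = wc, wt
                strand = "+"
            else:
                mc, t = cg, ca
                strand = "-"
            out.append(CytosineRecord(
                contig_id=contig, position=pos, strand=strand,
                context=context, dinucleotide_context=dinuc,
                mc_count=mc, t_count=t,
            ))
    return out


# ---------------------------------------------------------------------------
# GTF transcript records (assembly-comparison output)

def _gtf_attr(feat, key: str) -> str | None:
    vals = feat.attributes.get(key)
    return vals[0] if vals else None


def parse_transcript_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Read assembled transcripts from GTF.

    Transcript lines carry ``class_code``, ``FPKM``, ``conf_lo`` and
    ``conf_hi`` attributes. A transcript missing FPKM attributes is kept but
    flagged (confidence bounds None) so downstream FPKM filters can exclude
    and log it. conf_lo > FPKM violates the confidence-interval invariant and
    is a format error.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:
                raise FormatError(f"unparseable GTF line: {exc}", lineno)
            if feat.featuretype != "transcript":
                continue
            tid = _gtf_attr(feat, "transcript_id")
            if tid is None:
                raise FormatError("transcript line without transcript_id",
                                  lineno)
            fpkm_s = _gtf_attr(feat, "FPKM")
            lo_s = _gtf_attr(feat, "conf_lo")
            hi_s = _gtf_attr(feat, "conf_hi")
            try:
                fpkm = float(fpkm_s) if fpkm_s is not None else None
                lo = float(lo_s) if lo_s is not None else None
                hi = float(hi_s) if hi_s is not None else None
            except ValueError:
                raise FormatError("non-numeric FPKM attribute", lineno)
            if fpkm is None:
                logger.warning("transcript %s has no FPKM attribute; it will "
                               "be excluded from FPKM filters", tid)
            try:
                rec = TranscriptRecord(
                    transcript_id=tid,
                    contig_id=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else ".",
                    class_code=_gtf_attr(feat, "class_code") or ".",
                    fpkm=fpkm,
                    fpkm_conf_lo=lo,
                    fpkm_conf_hi=hi,
                )
            except FormatError as exc:
                raise FormatError(str(exc), lineno)
            out.append(rec)
    return out


def write_transcript_gtf(transcripts: Sequence[TranscriptRecord],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (f'gene_id "{t.transcript_id}"; '
                     f'transcript_id "{t.transcript_id}"; '
                     f'class_code "{t.class_code}";')
            if t.fpkm is not None:
                attrs += f' FPKM "{t.fpkm:.6g}";'
            if t.has_confidence_interval:
                attrs += (f' conf_lo "{t.fpkm_conf_lo:.6g}";'
                          f' conf_hi "{t.fpkm_conf_hi:.6g}";')
            fh.write(
                f"{t.contig_id}\ttuberkit\ttranscript\t{t.start + 1}\t"
                f"{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Track output (wiggle / BED)

def serialize_tracks(records: Sequence, path: str | Path,
                     dialect: str = "wiggle") -> None:
    """Write methylation levels (wiggle variableStep, 1-based) or CNV calls
    (BED, 0-based half-open) for genome-browser display.

    Input must be sorted by contig then position; the first offending record
    is named otherwise.
    """
    dialect = dialect.lower()
    if dialect == "wiggle":
        _write_wiggle(records, path)
    elif dialect == "bed":
        _write_bed(records, path)
    else:
        raise ValueError(f"unknown track dialect {dialect!r}")


def _check_sorted(keys, what):
    prev = None
    for i, key in enumerate(keys):
        if prev is not None and key < prev:
            raise ValueError(
                f"records not sorted by contig and position: {what} index "
                f"{i} ({key}) follows {prev}")
        prev = key


def _write_wiggle(records: Sequence[CytosineRecord], path) -> None:
    _check_sorted([(r.contig_id, r.position) for r in records], "cytosine")
    with open(path, "w") as fh:
        fh.write('track type=wiggle_0 name="methylation_level"\n')
        current = None
        for r in records:
            if math.isnan(r.level):
                continue
            if r.contig_id != current:
                fh.write(f"variableStep chrom={r.contig_id}\n")
                current = r.contig_id
            fh.write(f"{r.position}\t{r.level:.6g}\n")


def _write_bed(records: Sequence, path) -> None:
    rows = []
    for r in records:
        if isinstance(r, CNVCall):
            w = r.window
            score = 0.0 if w.log_ratio is None else w.log_ratio
            rows.append((w.contig_id, w.start, w.end,
                         r.direction, f"{score:.4f}"))
        else:  # FeatureRecord-like interval
            rows.append((r.contig_id, r.start, r.end,
                         getattr(r, "feature_id", "."), "0"))
    _check_sorted([(c, s) for c, s, *_ in rows], "interval")
    with open(path, "w") as fh:
        fh.write('track name="tuberkit_calls"\n')
        for contig, start, end, name, score in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\n")
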