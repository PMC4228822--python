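"""Per-cytosine methylation calling, filtering and summaries.

The methylation level of one cytosine is estimated as #C/(#C+#T) over the
bisulfite reads covering it and serves as an estimate of the fraction of
cells methylated at that site. Sites covered by fewer than four reads are
excluded by default before any summary. Feature-level and genome-level
means are unweighted means of per-site levels (site-weighted, not
read-pooled), computed per sequence context (CG, CHG, CHH; H = A, C or T).

Functions accept either a pileup DataFrame (columns contig_id, position,
strand, context, mc_count, t_count) or a list of CytosineRecord.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CytosineRecord, FeatureRecord, GenomeSequence

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
DEFAULT_MIN_COVERAGE = 4


@dataclass
class MethylationSummary:
    """Mean-methylation summary for one (scope, context) cell."""

    scope: str
    context: str
    n_sites_retained: int
    fraction_retained: float | None  # percent of classifiable sites in scope
    mean_level: float | None


@dataclass
class MetageneProfile:
    """Mean methylation across length-normalized gene bodies plus flanks.

    ``table`` has one row per (region, bin, context) with the pooled mean
    level and the number of contributing sites; bin 0 of the upstream
    region is always the 5' end regardless of gene strand.
    """

    n_bins_body: int
    flank_bp: int
    n_bins_flank: int
    table: pd.DataFrame


# ---------------------------------------------------------------------------

def classify_context(genome: GenomeSequence, position: int,
                     strand: str) -> str:
    """Sequence context of the cytosine at a 1-based position.

    Reads the two bases downstream on the cytosine's own strand: CG if the
    next base is G, CHG if H then G, CHH if both H; "unknown" when the
    needed bases run off the contig or any is N. The base at the position
    must be C (plus strand) or G (minus strand).
    """
    seq = genome.sequence
    i = position - 1
    if not 0 <= i < len(seq):
        raise ValueError(f"position {position} outside contig "
                         f"{genome.contig_id}")
    if strand == "+":
        if seq[i] != "C":
            raise ValueError(
                f"{genome.contig_id}:{position}+ is {seq[i]!r}, not C")
        n1 = seq[i + 1] if i + 1 < len(seq) else "N"
        n2 = seq[i + 2] if i + 2 < len(seq) else "N"
    elif strand == "-":
        if seq[i] != "G":
            raise ValueError(
                f"{genome.contig_id}:{position}- is {seq[i]!r}, not G "
                "(minus-strand cytosines appear as G on the plus strand)")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        n1 = comp[seq[i - 1]] if i - 1 >= 0 else "N"
        n2 = comp[seq[i - 2]] if i - 2 >= 0 else "N"
    else:
        raise ValueError(f"invalid strand {strand!r}")
    h = {"A", "C", "T"}
    if n1 == "G":
        return "CG"
    if n1 in h and n2 == "G":
        return "CHG"
    if n1 in h and n2 in h:
        return "CHH"
    return "unknown"


def call_methylation(mc_count: int, t_count: int) -> float:
    """Methylation level #C/(#C+#T); NaN when the site has no coverage."""
    if mc_count < 0 or t_count < 0:
        raise ValueError("read counts must be non-negative")
    cov = mc_count + t_count
    if cov == 0:
        return math.nan
    return mc_count / cov


# ---------------------------------------------------------------------------

def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
        if "level" not in df.columns:
            df = df.copy()
            cov = df["mc_count"] + df["t_count"]
            with np.errstate(invalid="ignore", divide="ignore"):
                df["level"] = np.where(
                    cov > 0, df["mc_count"] / cov.replace(0, 1), np.nan)
        return df
    rows = [(r.contig_id, r.position, r.strand, r.context,
             r.mc_count, r.t_count, r.level) for r in records]
    return pd.DataFrame(rows, columns=[
        "contig_id", "position", "strand", "context",
        "mc_count", "t_count", "level"])


def records_from_frame(df: pd.DataFrame) -> list[CytosineRecord]:
    return [
        CytosineRecord(
            contig_id=row.contig_id, position=int(row.position),
            strand=row.strand, context=row.context,
            dinucleotide_context=getattr(row, "dinucleotide_context", "NN"),
            mc_count=int(row.mc_count), t_count=int(row.t_count))
        for row in df.itertuples()
    ]


def filter_by_coverage(records, min_cov: int = DEFAULT_MIN_COVERAGE
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep sites covered by at least ``min_cov`` reads.

    Returns (retained, report); the report gives per-context totals,
    retained counts and the retained percentage — the site-retention table
    a methylome QC section prints.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    df = _as_frame(records)
    cov = df["mc_count"] + df["t_count"]
    retained = df[cov >= min_cov].reset_index(drop=True)
    rows = []
    for ctx in CONTEXTS:
        mask = df["context"] == ctx
        total = int(mask.sum())
        kept = int((mask & (cov >= min_cov)).sum())
        rows.append((ctx, total, kept,
                     100.0 * kept / total if total else math.nan))
    report = pd.DataFrame(
        rows, columns=["context", "n_total", "n_retained",
                       "percent_retained"])
    return retained, report


def _merged_intervals(features: Sequence[FeatureRecord],
                      feature_class: str) -> dict[str, np.ndarray]:
    """Union of intervals of one class per contig (set semantics: a site in
    two overlapping features still counts once)."""
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        if f.feature_class == feature_class:
            per_contig.setdefault(f.contig_id, []).append((f.start, f.end))
    out = {}
    for contig, ivals in per_contig.items():
        merged = []
        for s, e in sorted(ivals):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out[contig] = np.array(merged).reshape(-1, 2)
    return out


def _in_scope_mask(df: pd.DataFrame, features, scope: str) -> np.ndarray:
    if scope == "genome":
        return np.ones(len(df), dtype=bool)
    intervals = _merged_intervals(features, scope)
    mask = np.zeros(len(df), dtype=bool)
    pos0 = df["position"].to_numpy() - 1
    contigs = df["contig_id"].to_numpy()
    for contig, arr in intervals.items():
        cmask = contigs == contig
        if not cmask.any():
            continue
        idx = np.searchsorted(arr[:, 0], pos0[cmask], side="right") - 1
        inside = (idx >= 0) & (pos0[cmask] < arr[np.clip(idx, 0, None), 1])
        mask[np.flatnonzero(cmask)[inside]] = True
    return mask


def summarize_methylation(records, features: Sequence[FeatureRecord],
                          scope: str, context: str) -> MethylationSummary:
    """Unweighted mean of per-site levels for one (scope, context) cell.

    ``scope`` is "genome" (all retained sites), "gene" or "TE" (sites inside
    the union of that class's intervals). Records are expected to be
    coverage-filtered already. Zero qualifying sites yield an undefined
    mean, not an error.
    """
    if scope not in ("genome", "gene", "TE"):
        raise ValueError(f"unknown scope {scope!r}")
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    df = _as_frame(records)
    sel = df[(df["context"] == context)
             & _in_scope_mask(df, features, scope)]
    n = len(sel)
    n_classifiable = int((_as_frame(records)["context"] == context).sum())
    return MethylationSummary(
        scope=scope,
        context=context,
        n_sites_retained=n,
        fraction_retained=(100.0 * n / n_classifiable
                           if n_classifiable else None),
        mean_level=float(sel["level"].mean()) if n else None,
    )


def summary_table(records, features) -> pd.DataFrame:
    """All nine (scope x context) summaries as one tidy table."""
    rows = []
    for scope in ("genome", "gene", "TE"):
        for ctx in CONTEXTS:
            s = summarize_methylation(records, features, scope, ctx)
            rows.append((scope, ctx, s.n_sites_retained,
                         math.nan if s.mean_level is None else s.mean_level))
    return pd.DataFrame(rows, columns=["scope", "context",
                                       "n_sites", "mean_level"])


# ---------------------------------------------------------------------------

def metagene_profile(records, genes: Sequence[FeatureRecord],
                     n_bins_body: int = 20, flank_bp: int = 500,
                     n_bins_flank: int = 10) -> MetageneProfile:
    """Average methylation across length-normalized gene bodies and flanks.

    Each gene body is rescaled to ``n_bins_body`` equal bins; flanks of
    ``flank_bp`` are cut into ``n_bins_flank`` fixed-width bins. Minus-strand
    genes are reversed so bin 0 is always 5'. Bin values pool sites across
    genes; empty bins are NaN with n_sites 0. Genes shorter than
    ``n_bins_body`` bp are skipped with a warning.
    """
    if n_bins_body < 1 or n_bins_flank < 1 or flank_bp < 1:
        raise ValueError("bin and flank parameters must be positive")
    df = _as_frame(records)
    by_contig = {c: sub.sort_values("position")
                 for c, sub in df.groupby("contig_id")}

    sums: dict[tuple[str, int, str], float] = {}
    counts: dict[tuple[str, int, str], int] = {}
    for gene in genes:
        glen = gene.end - gene.start
        if glen < n_bins_body:
            logger.warning("metagene_profile: gene %s (%d bp) shorter than "
                           "%d bins, skipped", gene.feature_id, glen,
                           n_bins_body)
            continue
        sub = by_contig.get(gene.contig_id)
        if sub is None:
            continue
        pos = sub["position"].to_numpy() - 1  # 0-based
        lo = np.searchsorted(pos, gene.start - flank_bp)
        hi = np.searchsorted(pos, gene.end + flank_bp)
        window = sub.iloc[lo:hi]
        for p0, ctx, level in zip(window["position"].to_numpy() - 1,
                                  window["context"], window["level"]):
            if ctx not in CONTEXTS or math.isnan(level):
                continue
            if p0 < gene.start:  # left flank on the plus strand
                off = p0 - (gene.start - flank_bp)
                b = int(off * n_bins_flank // flank_bp)
                region, b5 = ("upstream", b) if gene.strand == "+" else \
                    ("downstream", n_bins_flank - 1 - b)
            elif p0 >= gene.end:
                off = p0 - gene.end
                b = int(off * n_bins_flank // flank_bp)
                region, b5 = ("downstream", b) if gene.strand == "+" else \
                    ("upstream", n_bins_flank - 1 - b)
            else:
                rel = (p0 - gene.start) / glen
                b = min(int(rel * n_bins_body), n_bins_body - 1)
                region = "body"
                b5 = b if gene.strand == "+" else n_bins_body - 1 - b
            key = (region, b5, ctx)
            sums[key] = sums.get(key, 0.0) + level
            counts[key] = counts.get(key, 0) + 1

    rows = []
    for region, nbins in (("upstream", n_bins_flank),
                          ("body", n_bins_body),
                          ("downstream", n_bins_flank)):
        for b in range(nbins):
            for ctx in CONTEXTS:
                n = counts.get((region, b, ctx), 0)
                rows.append((region, b, ctx,
                             sums[(region, b, ctx)] / n if n else math.nan,
                             n))
    return MetageneProfile(
        n_bins_body=n_bins_body, flank_bp=flank_bp, n_bins_flank=n_bins_flank,
        table=pd.DataFrame(rows, columns=["region", "bin", "context",
                                          "mean_level", "n_sites"]))


# ---------------------------------------------------------------------------

def rank_te_by_expression(te_methylation: Mapping[str, float],
                          te_expression: Mapping[str, float],
                          silenced_threshold: float = 0.0) -> pd.DataFrame:
    """Partition TEs into silenced vs expressed and rank by expression.

    Silenced means expression <= ``silenced_threshold`` (default: exactly
    zero); expressed TEs are sorted ascending by expression with ties broken
    by feature id. TEs missing either value are excluded and logged.
    """
    rows = []
    for te in set(te_methylation) | set(te_expression):
        if te not in te_methylation or te not in te_expression:
            logger.warning("rank_te_by_expression: TE %s missing a value, "
                           "excluded", te)
            continue
        expr = te_expression[te]
        rows.append((te, te_methylation[te], expr,
                     "silenced" if expr <= silenced_threshold
                     else "expressed"))
    df = pd.DataFrame(rows, columns=["feature_id", "mean_level",
                                     "expression", "partition"])
    silenced = df[df["partition"] == "silenced"].sort_values(
        "feature_id", kind="stable")
    expressed = df[df["partition"] == "expressed"].sort_values(
        ["expression", "feature_id"], kind="stable")
    out = pd.concat([silenced, expressed], ignore_index=True)
    out["rank"] = range(len(out))
    return out
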