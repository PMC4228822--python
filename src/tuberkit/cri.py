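"""Composite RIP Index (CRI) from overlapping dinucleotide frequencies.

Repeat-induced point mutation (RIP) is a fungal genome-defense process that
converts CpA dinucleotides to TpA within repeated sequence. Its footprint is
therefore an excess of the mutation product and a depletion of its substrate:

* RIP product index  = TpA / ApT
* RIP substrate index = (CpA + TpG) / (ApC + GpT)
* CRI = product − substrate

Positive CRI indicates RIP-like mutation. Both component indices are ratios
of overlapping dinucleotide counts on one strand; because TpA and ApT are
each self-reverse-complementary and CpA↔TpG, ApC↔GpT swap within their sums,
the CRI of a sequence equals the CRI of its reverse complement exactly, so
the choice of strand is irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product as _iterproduct
from typing import Sequence

import pandas as pd

from .core import FeatureRecord, GenomeSequence, VALID_BASES

DINUCLEOTIDES = ["".join(p) for p in _iterproduct("ACGT", repeat=2)]

#: features with fewer counted pairs than this are flagged low-confidence
DEFAULT_MIN_PAIRS = 20


@dataclass
class DinucleotideCounts:
    """Overlapping dinucleotide tallies for one sequence.

    ``n_pairs`` counts every overlapping pair not containing N; the 16
    entries of ``counts`` sum to it.
    """

    counts: dict[str, int]
    n_pairs: int


@dataclass
class CRIResult:
    product_index: float | None
    substrate_index: float | None
    cri: float | None
    defined: bool
    n_pairs: int = 0
    low_confidence: bool = False


def count_dinucleotides(sequence: str) -> DinucleotideCounts:
    """Count overlapping dinucleotides left to right; pairs with N skipped."""
    bad = set(sequence) - VALID_BASES
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    n_pairs = 0
    for i in range(len(sequence) - 1):
        pair = sequence[i:i + 2]
        if "N" in pair:
            continue
        counts[pair] += 1
        n_pairs += 1
    return DinucleotideCounts(counts=counts, n_pairs=n_pairs)


def rip_product_index(counts: DinucleotideCounts) -> float | None:
    """TpA/ApT; None (undefined) when ApT = 0."""
    apt = counts.counts["AT"]
    if apt == 0:
        return None
    return counts.counts["TA"] / apt


def rip_substrate_index(counts: DinucleotideCounts) -> float | None:
    """(CpA+TpG)/(ApC+GpT); None (undefined) when the denominator is 0."""
    denom = counts.counts["AC"] + counts.counts["GT"]
    if denom == 0:
        return None
    return (counts.counts["CA"] + counts.counts["TG"]) / denom


def composite_rip_index(sequence: str,
                        min_pairs: int = DEFAULT_MIN_PAIRS) -> CRIResult:
    """CRI of one sequence from a single counting pass.

    Undefined component indices (zero denominators) propagate: the CRI is
    defined iff both components are. Results from fewer than ``min_pairs``
    counted pairs are flagged low-confidence, not dropped.
    """
    counts = count_dinucleotides(sequence)
    product = rip_product_index(counts)
    substrate = rip_substrate_index(counts)
    defined = product is not None and substrate is not None
    return CRIResult(
        product_index=product,
        substrate_index=substrate,
        cri=(product - substrate) if defined else None,
        defined=defined,
        n_pairs=counts.n_pairs,
        low_confidence=counts.n_pairs < min_pairs,
    )


def _result_row(name: str, contig: str, start: int, end: int,
                res: CRIResult, counts: DinucleotideCounts) -> dict:
    c = counts.counts
    return {
        "name": name, "contig_id": contig, "start": start, "end": end,
        "TpA": c["TA"], "ApT": c["AT"], "CpA": c["CA"], "TpG": c["TG"],
        "ApC": c["AC"], "GpT": c["GT"],
        "product_index": math.nan if res.product_index is None
        else res.product_index,
        "substrate_index": math.nan if res.substrate_index is None
        else res.substrate_index,
        "cri": math.nan if res.cri is None else res.cri,
        "defined": res.defined,
        "low_confidence": res.low_confidence,
    }


def cri_over_features(genome: Sequence[GenomeSequence],
                      features: Sequence[FeatureRecord] | None = None,
                      mode: str = "per_feature",
                      window_bp: int = 500,
                      step_bp: int = 100,
                      min_pairs: int = DEFAULT_MIN_PAIRS) -> pd.DataFrame:
    """Score annotated features or sliding windows across a genome.

    ``per_feature`` mode scores each feature's plus-strand genomic sequence
    (strand symmetry makes the strand choice irrelevant); ``window`` mode
    scores sliding windows of ``window_bp`` advancing by ``step_bp``.
    Undefined results appear as NaN with ``defined`` False rather than being
    dropped.
    """
    contigs = {g.contig_id: g for g in genome}
    rows = []
    if mode == "per_feature":
        if features is None:
            raise ValueError("per_feature mode requires features")
        for f in features:
            if f.contig_id not in contigs:
                raise ValueError(
                    f"feature {f.feature_id} on unknown contig "
                    f"{f.contig_id}")
            contig = contigs[f.contig_id]
            if f.end > contig.length:
                raise ValueError(
                    f"feature {f.feature_id} extends past the end of "
                    f"{f.contig_id}")
            seq = contig.sequence[f.start:f.end]
            counts = count_dinucleotides(seq)
            res = composite_rip_index(seq, min_pairs=min_pairs)
            rows.append(_result_row(f.feature_id, f.contig_id, f.start,
                                    f.end, res, counts))
    elif mode == "window":
        if window_bp <= 1 or step_bp <= 0:
            raise ValueError("need window_bp > 1 and step_bp > 0")
        for g in genome:
            start = 0
            while start < g.length:
                end = min(start + window_bp, g.length)
                seq = g.sequence[start:end]
                counts = count_dinucleotides(seq)
                res = composite_rip_index(seq, min_pairs=min_pairs)
                rows.append(_result_row(
                    f"{g.contig_id}:{start}-{end}", g.contig_id, start, end,
                    res, counts))
                if end == g.length:
                    break
                start += step_bp
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)
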