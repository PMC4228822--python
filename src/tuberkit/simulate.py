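"""Synthetic fungal genome, methylome, coverage and expression generator.

Emulates the statistical structure of a TE-rich fungal multi-omics study at
toy scale: a small multi-contig genome with non-overlapping gene and
transposable-element annotations; per-cytosine methylation with context- and
feature-specific means; binomial bisulfite pileups at configurable depth;
RIP-style CpA→TpA mutation of repeats; two-library window coverage tracks
with planted copy-number changes; and two-condition expression counts with
planted fold changes.

Every simulator is deterministic under its seed and emits the ground truth
alongside the data, so downstream callers can be scored for recovery without
re-reading the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FeatureRecord, GenomeSequence

_BASES = np.array(list("ACGT"), dtype="S1")

#: default per-(feature class, context) mean methylation levels of the
#: free-living mycelium methylome the generator emulates
DEFAULT_METH_MEANS: dict[str, dict[str, float]] = {
    "genome": {"CG": 0.303, "CHG": 0.081, "CHH": 0.101},
    "gene": {"CG": 0.0064, "CHG": 0.0036, "CHH": 0.0039},
    "TE": {"CG": 0.7051, "CHG": 0.1485, "CHH": 0.1727},
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset.

    Defaults describe the emulated study at toy scale: two 500 kb contigs,
    a repeat fraction above half the genome, heavily methylated TEs against
    near-unmethylated genes, 30x per-strand coverage and a small residual
    bisulfite non-conversion rate.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 500_000
    n_genes: int = 40
    n_tes: int = 60
    te_fraction: float = 0.58
    gene_length_mean: int = 1_500
    meth_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_METH_MEANS.items()})
    beta_concentration: float = 10.0
    depth: float = 30.0
    conversion_failure: float = 0.005
    window_bp: int = 100_000
    cnv_regions: list[tuple[str, int, int, float]] = field(
        default_factory=list)
    expression_baseline_mean: float = 100.0
    expression_fold_changes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for p in (self.te_fraction, self.conversion_failure):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        for cls, ctxs in self.meth_means.items():
            for ctx, m in ctxs.items():
                if not 0.0 <= m <= 1.0:
                    raise ValueError(
                        f"meth_means[{cls}][{ctx}] = {m} outside [0,1]")
        for region in self.cnv_regions:
            if region[3] <= 0:
                raise ValueError("cnv fold_change must be > 0")


# ---------------------------------------------------------------------------
# Genome and annotation

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _place_on_contig(rng: np.random.Generator, contig_id: str,
                     lengths: list[tuple[str, int, str]],
                     contig_length: int) -> list[FeatureRecord]:
    """Place features of given lengths non-overlappingly, uniformly.

    The free space left over after stacking all features is split into
    random gaps (uniform spacings), which makes every admissible
    non-overlapping arrangement equally likely up to feature order.
    """
    total = sum(l for _, l, _ in lengths)
    free = contig_length - total
    if free < 0:
        raise ValueError(
            f"cannot pack {total} bp of features into {contig_length} bp "
            f"contig {contig_id}; reduce n_genes/n_tes or lengths")
    order = rng.permutation(len(lengths))
    cuts = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    gaps = np.diff(np.concatenate([[0], cuts]))
    out = []
    pos = 0
    for gap, idx in zip(gaps, order):
        fid, flen, fclass = lengths[idx]
        pos += int(gap)
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(FeatureRecord(
            feature_id=fid, contig_id=contig_id, start=pos, end=pos + flen,
            strand=strand, feature_class=fclass))
        pos += flen
    return out


def simulate_genome(config: SimulationConfig
                    ) -> tuple[list[GenomeSequence], list[FeatureRecord]]:
    """Uniform-background genome with non-overlapping gene/TE annotations.

    TE lengths are drawn around ``te_fraction * genome / n_tes`` and then
    rescaled so the realized repeat fraction matches the target closely;
    gene lengths are drawn around ``gene_length_mean``.
    """
    rng = np.random.default_rng(config.seed)
    genome_bp = config.n_contigs * config.contig_length

    gene_lengths = rng.integers(
        max(200, config.gene_length_mean // 2),
        config.gene_length_mean * 3 // 2 + 1,
        size=config.n_genes,
    ) if config.n_genes else np.array([], dtype=int)

    if config.n_tes:
        te_target = config.te_fraction * genome_bp
        te_mean = te_target / config.n_tes
        raw = rng.uniform(0.5 * te_mean, 1.5 * te_mean, size=config.n_tes)
        te_lengths = np.maximum(
            50, np.round(raw * te_target / raw.sum()).astype(int))
    else:
        te_lengths = np.array([], dtype=int)

    feats = ([(f"gene{str(i + 1).zfill(4)}", int(l), "gene")
              for i, l in enumerate(gene_lengths)]
             + [(f"te{str(i + 1).zfill(4)}", int(l), "TE")
                for i, l in enumerate(te_lengths)])
    if sum(l for _, l, _ in feats) > 0.98 * genome_bp:
        raise ValueError(
            "requested features occupy more than 98% of the genome; "
            "reduce n_genes/n_tes or increase contig_length")

    # round-robin by running load keeps per-contig packing feasible
    per_contig: list[list[tuple[str, int, str]]] = [
        [] for _ in range(config.n_contigs)]
    loads = np.zeros(config.n_contigs)
    for item in sorted(feats, key=lambda t: -t[1]):
        c = int(np.argmin(loads))
        per_contig[c].append(item)
        loads[c] += item[1]

    genomes, features = [], []
    for ci in range(config.n_contigs):
        contig_id = f"contig{ci + 1}"
        genomes.append(GenomeSequence(
            contig_id, _random_sequence(rng, config.contig_length)))
        features.extend(_place_on_contig(
            rng, contig_id, per_contig[ci], config.contig_length))
    features.sort(key=lambda f: (f.contig_id, f.start))
    return genomes, features


# ---------------------------------------------------------------------------
# Methylome truth and bisulfite pileup

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")


def _context_arrays(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized cytosine context classification for one contig.

    Returns (positions0, strand_is_plus, context_code) for every C (plus
    strand) and G (minus strand); context codes 0=CG 1=CHG 2=CHH 3=unknown.
    Contexts are read 5'->3' on the cytosine's own strand; H = A, C or T.
    """
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = a.size
    is_h = (a == _A) | (a == _C) | (a == _T)

    def classify(pos, nxt, nxt2):
        code = np.full(pos.size, 3, dtype=np.int8)
        valid1 = nxt >= 0
        n1 = np.where(valid1, a[np.clip(nxt, 0, n - 1)], _N)
        code[valid1 & (n1 == _G)] = 0
        valid2 = valid1 & (nxt2 >= 0)
        n2 = np.where(valid2, a[np.clip(nxt2, 0, n - 1)], _N)
        h1 = valid1 & np.where(valid1, is_h[np.clip(nxt, 0, n - 1)], False)
        h2 = valid2 & np.where(valid2, is_h[np.clip(nxt2, 0, n - 1)], False)
        code[h1 & valid2 & (n2 == _G)] = 1
        code[h1 & h2] = 2
        return code

    plus = np.flatnonzero(a == _C)
    nxt = np.where(plus + 1 < n, plus + 1, -1)
    nxt2 = np.where(plus + 2 < n, plus + 2, -1)
    code_plus = classify(plus, nxt, nxt2)

    minus = np.flatnonzero(a == _G)
    # downstream on the minus strand = upstream on the plus strand,
    # complemented: a plus-strand C upstream reads as G on the minus strand
    comp = a.copy()
    for x, y in ((_A, _T), (_C, _G), (_G, _C), (_T, _A)):
        comp[a == x] = y
    is_h_minus = (comp == _A) | (comp == _C) | (comp == _T)

    def classify_minus(pos):
        code = np.full(pos.size, 3, dtype=np.int8)
        valid1 = pos - 1 >= 0
        n1 = np.where(valid1, comp[np.clip(pos - 1, 0, n - 1)], _N)
        code[valid1 & (n1 == _G)] = 0
        valid2 = pos - 2 >= 0
        n2 = np.where(valid2, comp[np.clip(pos - 2, 0, n - 1)], _N)
        h1 = valid1 & np.where(valid1,
                               is_h_minus[np.clip(pos - 1, 0, n - 1)], False)
        h2 = valid2 & np.where(valid2,
                               is_h_minus[np.clip(pos - 2, 0, n - 1)], False)
        code[h1 & valid2 & (n2 == _G)] = 1
        code[h1 & h2] = 2
        return code

    code_minus = classify_minus(minus)

    positions = np.concatenate([plus, minus])
    strands = np.concatenate([
        np.ones(plus.size, dtype=bool), np.zeros(minus.size, dtype=bool)])
    codes = np.concatenate([code_plus, code_minus])
    order = np.argsort(positions, kind="stable")
    return positions[order], strands[order], codes[order]


_CONTEXT_NAMES = np.array(["CG", "CHG", "CHH", "unknown"])


def simulate_methylome(genome: Sequence[GenomeSequence],
                       features: Sequence[FeatureRecord],
                       config: SimulationConfig) -> pd.DataFrame:
    """Draw a true methylation level for every classifiable cytosine.

    Levels are Beta-distributed around ``meth_means[class][context]`` with
    the configured concentration (a mean of exactly 0 or 1 yields that
    constant); intergenic sites use the genome-background means. Returns the
    truth table with columns contig_id, position (1-based, cytosine's own
    strand), strand, context, dinucleotide_context, feature_class,
    true_level.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        config.seed).spawn(2)[0])
    frames = []
    for g in genome:
        pos0, is_plus, codes = _context_arrays(g.sequence)
        keep = codes != 3
        pos0, is_plus, codes = pos0[keep], is_plus[keep], codes[keep]

        fclass = np.zeros(g.length, dtype=np.int8)  # 0 intergenic
        for f in features:
            if f.contig_id != g.contig_id:
                continue
            fclass[f.start:f.end] = 1 if f.feature_class == "gene" else 2
        site_class = fclass[pos0]

        class_names = np.array(["genome", "gene", "TE"])
        means = np.empty((3, 3))
        for i, cls in enumerate(class_names):
            for j, ctx in enumerate(("CG", "CHG", "CHH")):
                try:
                    means[i, j] = config.meth_means[cls][ctx]
                except KeyError:
                    raise ValueError(
                        f"meth_means missing mean for ({cls}, {ctx})")
        m = means[site_class, codes]

        conc = config.beta_concentration
        level = np.empty(m.size)
        interior = (m > 0) & (m < 1)
        level[~interior] = m[~interior]
        if interior.any():
            level[interior] = rng.beta(
                m[interior] * conc, (1 - m[interior]) * conc)

        seq = g.sequence
        dinuc = np.array([
            (seq[p:p + 2] if plus else
             seq[max(p - 1, 0):p + 1].translate(
                 _COMP_TABLE)[::-1]) if 0 <= p < g.length else "N"
            for p, plus in zip(pos0, is_plus)])
        frames.append(pd.DataFrame({
            "contig_id": g.contig_id,
            "position": pos0 + 1,
            "strand": np.where(is_plus, "+", "-"),
            "context": _CONTEXT_NAMES[codes],
            "dinucleotide_context": dinuc,
            "feature_class": class_names[site_class],
            "true_level": level,
        }))
    return pd.concat(frames, ignore_index=True)


_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")


def simulate_bisulfite_pileup(truth: pd.DataFrame, depth: float,
                              conversion_failure: float,
                              seed: int) -> pd.DataFrame:
    """Observe each true level through the bisulfite sequencing model.

    Bisulfite conversion followed by PCR reads unmethylated cytosines as
    thymines, so at a site with true level p and residual non-conversion
    rate e, a read reports C with probability p + (1-p)e. Coverage is
    Poisson(depth) per site; mc_count is Binomial(coverage, p'). Sites with
    zero coverage are emitted with NaN level.

    Returns a pileup table with the truth's site columns plus mc_count,
    t_count and level.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    cov = rng.poisson(depth, size=len(truth))
    p = truth["true_level"].to_numpy()
    p_obs = p + (1.0 - p) * conversion_failure
    mc = rng.binomial(cov, p_obs)
    out = truth.drop(columns=["true_level", "feature_class"],
                     errors="ignore").copy()
    out["mc_count"] = mc
    out["t_count"] = cov - mc
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(cov > 0, mc / np.maximum(cov, 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# RIP mutation

def apply_rip(sequence: str, fraction: float,
              seed: int = 0) -> tuple[str, list[int]]:
    """Mutate a Bernoulli(fraction) subset of RIP-eligible sites.

    Eligible sites, marked on the *original* sequence in a single pass, are
    the C of every CpA (mutated C->T) and the G of every TpG (the
    minus-strand CpA; mutated G->A). Marking before mutating makes the
    operation order-independent: a mutation never creates or destroys
    another site's eligibility.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    a = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    eligible_c = np.flatnonzero((a[:-1] == _C) & (a[1:] == _A))
    eligible_g = np.flatnonzero((a[1:] == _G) & (a[:-1] == _T)) + 1
    eligible = np.union1d(eligible_c, eligible_g)
    if eligible.size == 0:
        return sequence, []
    hit = eligible[rng.random(eligible.size) < fraction]
    is_c = a[hit] == _C
    a[hit[is_c]] = _T
    a[hit[~is_c]] = _A
    return a.tobytes().decode(), sorted(int(i) for i in hit)


# ---------------------------------------------------------------------------
# Coverage tracks with planted CNV

def _contig_lengths(genome) -> dict[str, int]:
    if isinstance(genome, Mapping):
        return dict(genome)
    return {g.contig_id: g.length for g in genome}


def simulate_coverage_tracks(genome, cnv_regions, depth: float, seed: int,
                             window_bp: int = 100_000
                             ) -> tuple[pd.DataFrame, pd.DataFrame,
                                        pd.DataFrame]:
    """Two per-window depth tables with copy-number changes planted in B.

    ``genome`` is a list of GenomeSequence or a {contig: length} mapping;
    ``cnv_regions`` is a list of (contig, start, end, fold_change). Window
    read totals are Poisson(depth * width); in library B, windows
    overlapping a CNV region have their expected depth scaled by the
    region's fold change (prorated by the overlapped fraction for windows
    that straddle a region edge). Returns (table_a, table_b, truth), where
    truth carries the true per-window expected ratio B/A.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    lengths = _contig_lengths(genome)
    by_contig: dict[str, list[tuple[int, int, float]]] = {}
    for contig, start, end, fold in cnv_regions:
        if contig not in lengths:
            raise ValueError(f"cnv region on unknown contig {contig}")
        if not (0 <= start < end <= lengths[contig]):
            raise ValueError(f"cnv region [{start},{end}) outside {contig}")
        for s, e, _ in by_contig.get(contig, []):
            if start < e and s < end:
                raise ValueError("overlapping cnv_regions")
        by_contig.setdefault(contig, []).append((start, end, fold))

    rng = np.random.default_rng(seed)
    rows_a, rows_b, rows_t = [], [], []
    for contig in sorted(lengths):
        clen = lengths[contig]
        for start in range(0, clen, window_bp):
            end = min(start + window_bp, clen)
            width = end - start
            scale = 1.0
            for s, e, fold in by_contig.get(contig, []):
                overlap = max(0, min(end, e) - max(start, s))
                if overlap:
                    scale += (fold - 1.0) * overlap / width
            reads_a = rng.poisson(depth * width)
            reads_b = rng.poisson(depth * width * scale)
            rows_a.append((contig, start, end, reads_a / width))
            rows_b.append((contig, start, end, reads_b / width))
            rows_t.append((contig, start, end, scale))
    cols = ["contig_id", "start", "end", "depth"]
    return (pd.DataFrame(rows_a, columns=cols),
            pd.DataFrame(rows_b, columns=cols),
            pd.DataFrame(rows_t, columns=["contig_id", "start", "end",
                                          "true_ratio_b_over_a"]))


# ---------------------------------------------------------------------------
# Assembly-comparison transcript records (novel-gene stage demo input)

def simulate_transcripts(genome, features: Sequence[FeatureRecord],
                         seed: int, n_candidates: int = 12,
                         ) -> tuple[list, dict[str, bool]]:
    """Toy assembled-transcript set for exercising the novel-gene cascade.

    Plants intergenic candidate transcripts with class code "u" and FPKM
    confidence intervals straddling the conventional threshold of 4, some
    overlapping each other (to exercise clustering), plus a few transcripts
    matching known features (class code "="). Returns (transcripts,
    homology_by_transcript_id); cluster-level homology must be derived by
    the caller after clustering (a cluster is homologous when any member
    is).
    """
    from .core import TranscriptRecord

    rng = np.random.default_rng(seed)
    lengths = _contig_lengths(genome)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        occupied.setdefault(f.contig_id, []).append((f.start, f.end))
    gaps: list[tuple[str, int, int]] = []
    for contig, clen in lengths.items():
        prev = 0
        for s, e in sorted(occupied.get(contig, [])) + [(clen, clen)]:
            if s - prev >= 2_000:
                gaps.append((contig, prev, s))
            prev = max(prev, e)
    transcripts, homology = [], {}
    for i in range(n_candidates):
        contig, gs, ge = gaps[int(rng.integers(0, len(gaps)))]
        tlen = int(rng.integers(300, 1_500))
        start = int(rng.integers(gs, max(gs + 1, ge - tlen)))
        lo = float(rng.uniform(1.0, 9.0))
        tid = f"tcons{str(i + 1).zfill(4)}"
        transcripts.append(TranscriptRecord(
            transcript_id=tid, contig_id=contig, start=start,
            end=min(start + tlen, ge), strand=".", class_code="u",
            fpkm=lo * 1.3, fpkm_conf_lo=lo, fpkm_conf_hi=lo * 1.8))
        homology[tid] = bool(rng.random() < 0.7)
    for i, f in enumerate(list(features)[:3]):
        tid = f"tcons_known{i + 1}"
        transcripts.append(TranscriptRecord(
            transcript_id=tid, contig_id=f.contig_id, start=f.start,
            end=f.end, strand=f.strand, class_code="=", fpkm=20.0,
            fpkm_conf_lo=15.0, fpkm_conf_hi=25.0))
        homology[tid] = True
    return transcripts, homology


# ---------------------------------------------------------------------------
# Two-condition expression counts

def simulate_expression_counts(features: Sequence[FeatureRecord],
                               baseline_mean: float | Mapping[str, float],
                               fold_changes: Mapping[str, float] | float,
                               seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson counts for two conditions with planted fold changes.

    Condition A counts are Poisson(mean), condition B counts
    Poisson(mean * fold_change). Returns (counts, truth): counts has columns
    feature_id, count_a, count_b; truth has the per-feature baseline mean
    and true fold change.
    """
    rng = np.random.default_rng(seed)
    rows, truths = [], []
    for f in features:
        mean = (baseline_mean.get(f.feature_id, 100.0)
                if isinstance(baseline_mean, Mapping) else baseline_mean)
        if mean <= 0:
            raise ValueError(f"baseline mean for {f.feature_id} must be > 0")
        fold = (fold_changes.get(f.feature_id, 1.0)
                if isinstance(fold_changes, Mapping) else float(fold_changes))
        ca = int(rng.poisson(mean))
        cb = int(rng.poisson(mean * fold))
        rows.append((f.feature_id, ca, cb))
        truths.append((f.feature_id, mean, fold))
    counts = pd.DataFrame(rows, columns=["feature_id", "count_a", "count_b"])
    truth = pd.DataFrame(
        truths, columns=["feature_id", "baseline_mean", "true_fold_change"])
    return counts, truth
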