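"""End-to-end orchestration: simulate, analyse, report.

A run takes a flat key-value config and an output directory, simulates a
dataset (or consumes provided inputs), and executes the analysis stages in
dependency order: methylome -> CNV -> CRI -> expression -> novel genes.
Every run writes a JSON manifest recording the config snapshot, seed,
checksums of every output, and the toolkit version; reruns with unchanged
config and inputs skip stages whose recorded checksums still match and are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from . import cnv as cnv_mod
from . import cri as cri_mod
from . import expression as expr_mod
from . import methylome as meth_mod
from . import novel_genes as novel_mod
from . import simulate as sim_mod
from .core import GenomeSequence
from .io import (serialize_cgmap, serialize_tracks, write_fasta, write_gff3,
                 write_transcript_gtf)
from .methylome import records_from_frame

logger = logging.getLogger(__name__)

#: analysis thresholds; one namespace, echoed into every manifest
DEFAULT_THRESHOLDS = {
    "min_cov": 4,
    "window_bp": 100_000,
    "log_ratio_threshold": 0.3,
    "min_reads": 10,
    "min_fpkm": 4.0,
    "length_cutoff": 36_573,
    "rip_fraction": 0.3,
}

_INT_KEYS = {"seed", "n_contigs", "contig_length", "n_genes", "n_tes",
             "gene_length_mean", "window_bp", "min_cov", "min_reads",
             "length_cutoff"}
_FLOAT_KEYS = {"te_fraction", "beta_concentration", "depth",
               "conversion_failure", "expression_baseline_mean",
               "log_ratio_threshold", "min_fpkm", "rip_fraction"}


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Flat ``key = value`` config file -> dict, defaults filled in."""
    cfg: dict[str, Any] = dict(DEFAULT_THRESHOLDS)
    cfg.update(seed=0, n_contigs=2, contig_length=500_000, n_genes=40,
               n_tes=60, te_fraction=0.58, gene_length_mean=1_500,
               beta_concentration=10.0, depth=30.0,
               conversion_failure=0.005, expression_baseline_mean=100.0)
    if path is not None:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"config line {lineno}: expected "
                                     f"'key = value', got {line!r}")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                try:
                    if key in _INT_KEYS:
                        cfg[key] = int(value)
                    elif key in _FLOAT_KEYS:
                        cfg[key] = float(value)
                    else:
                        raise KeyError
                except KeyError:
                    raise ValueError(f"config line {lineno}: unknown key "
                                     f"{key!r}")
                except ValueError:
                    raise ValueError(f"config line {lineno}: bad value "
                                     f"{value!r} for {key!r}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_hash(cfg: dict, keys: list[str], inputs: list[Path]) -> str:
    h = hashlib.sha256()
    for k in sorted(keys):
        h.update(f"{k}={cfg[k]};".encode())
    for p in sorted(inputs):
        h.update(_sha256(p).encode())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, cfg: dict, command: str):
        self.path = out_dir / "manifest.json"
        self.previous = {}
        if self.path.exists():
            try:
                self.previous = json.loads(self.path.read_text())
            except json.JSONDecodeError:
                pass
        self.data = {
            "command": command,
            "tool_version": __version__,
            "config": {k: v for k, v in sorted(cfg.items())},
            "seed": cfg.get("seed"),
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": {},
            "outputs": {},
        }

    def stage_unchanged(self, name: str, stage_hash: str,
                        out_dir: Path) -> bool:
        prev = self.previous.get("stages", {}).get(name)
        if not prev or prev["hash"] != stage_hash:
            return False
        for rel, digest in prev["outputs"].items():
            p = out_dir / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record_stage(self, name: str, stage_hash: str, out_dir: Path,
                     outputs: list[Path], skipped: bool = False) -> None:
        digests = {str(p.relative_to(out_dir)): _sha256(p) for p in outputs}
        self.data["stages"][name] = {
            "hash": stage_hash, "outputs": digests, "skipped": skipped}
        self.data["outputs"].update(digests)

    def write(self, status: str = "ok", failing_stage: str | None = None):
        self.data["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.data["status"] = status
        if failing_stage:
            self.data["failing_stage"] = failing_stage
        self.path.write_text(json.dumps(self.data, indent=2) + "\n")


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config_path: str | Path | None, out_dir: str | Path,
                 command: str = "tuberkit run") -> dict[str, Any]:
    """Simulate a dataset and run every analysis stage over it.

    Returns a dict of the in-memory stage results; all tables and tracks
    are written under ``out_dir`` together with ``manifest.json``. Stages
    whose config and inputs are unchanged since the previous run (verified
    by checksum) are skipped.
    """
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, cfg, command)
    results: dict[str, Any] = {"config": cfg}
    current = "simulate"
    try:
        results.update(_run_stages(cfg, out, manifest, results))
    except Exception:
        current = next(
            (s for s in ("simulate", "methylome", "cnv", "cri", "expression",
                         "novel_genes", "report")
             if s not in manifest.data["stages"]), current)
        manifest.write(status="failed", failing_stage=current)
        raise
    manifest.write()
    return results


def _run_stages(cfg, out: Path, manifest: _Manifest, results):
    sim_keys = ["seed", "n_contigs", "contig_length", "n_genes", "n_tes",
                "te_fraction", "gene_length_mean", "beta_concentration",
                "depth", "conversion_failure", "rip_fraction",
                "expression_baseline_mean", "window_bp"]

    # -- simulate ----------------------------------------------------------
    sc = sim_mod.SimulationConfig(
        seed=cfg["seed"], n_contigs=cfg["n_contigs"],
        contig_length=cfg["contig_length"], n_genes=cfg["n_genes"],
        n_tes=cfg["n_tes"], te_fraction=cfg["te_fraction"],
        gene_length_mean=cfg["gene_length_mean"],
        beta_concentration=cfg["beta_concentration"], depth=cfg["depth"],
        conversion_failure=cfg["conversion_failure"],
        window_bp=cfg["window_bp"],
        expression_baseline_mean=cfg["expression_baseline_mean"])
    genome, features = sim_mod.simulate_genome(sc)

    # RIP-mutate the repeats so the CRI stage has signal to find
    ripped, rip_positions = [], {}
    for g in genome:
        seq = g.sequence
        tes = [f for f in features
               if f.contig_id == g.contig_id and f.feature_class == "TE"]
        positions = []
        for i, f in enumerate(tes):
            mut, pos = sim_mod.apply_rip(
                seq[f.start:f.end], cfg["rip_fraction"],
                seed=(cfg["seed"] * 100_003 + f.start * 7 + i) % 2**31)
            seq = seq[:f.start] + mut + seq[f.end:]
            positions.extend(p + f.start for p in pos)
        ripped.append(GenomeSequence(g.contig_id, seq))
        rip_positions[g.contig_id] = sorted(positions)
    genome = ripped

    truth = sim_mod.simulate_methylome(genome, features, sc)
    pileup = sim_mod.simulate_bisulfite_pileup(
        truth, sc.depth, sc.conversion_failure,
        seed=(cfg["seed"] + 1) % 2**31)

    n_windows = cfg["n_contigs"] * (cfg["contig_length"] // cfg["window_bp"])
    cnv_regions = []
    if n_windows >= 8:  # plant one 2.5x window; keep the planted fraction
        # small so library-size normalization barely moves the ratio
        cnv_regions = [("contig1", cfg["window_bp"], 2 * cfg["window_bp"],
                        2.5)]
    cov_a, cov_b, cov_truth = sim_mod.simulate_coverage_tracks(
        genome, cnv_regions, sc.depth, seed=(cfg["seed"] + 2) % 2**31,
        window_bp=cfg["window_bp"])

    fold_changes = {f.feature_id: (8.0 if i % 7 == 0 else 1.0)
                    for i, f in enumerate(features)}
    counts, expr_truth = sim_mod.simulate_expression_counts(
        features, cfg["expression_baseline_mean"], fold_changes,
        seed=(cfg["seed"] + 3) % 2**31)

    transcripts, homology_by_tid = sim_mod.simulate_transcripts(
        genome, features, seed=(cfg["seed"] + 4) % 2**31)

    sim_outputs = [out / n for n in (
        "genome.fa", "features.gff3", "pileup.cgmap", "methylome_truth.tsv",
        "coverage_a.tsv", "coverage_b.tsv", "coverage_truth.tsv",
        "expression_counts.tsv", "expression_truth.tsv",
        "transcripts.gtf", "homology.tsv", "rip_positions.tsv")]
    shash = _stage_hash(cfg, sim_keys, [])
    if not manifest.stage_unchanged("simulate", shash, out):
        write_fasta(genome, out / "genome.fa")
        write_gff3(features, out / "features.gff3")
        serialize_cgmap(records_from_frame(pileup), out / "pileup.cgmap")
        _tsv(truth, out / "methylome_truth.tsv")
        _tsv(cov_a, out / "coverage_a.tsv")
        _tsv(cov_b, out / "coverage_b.tsv")
        _tsv(cov_truth, out / "coverage_truth.tsv")
        _tsv(counts, out / "expression_counts.tsv")
        _tsv(expr_truth, out / "expression_truth.tsv")
        write_transcript_gtf(transcripts, out / "transcripts.gtf")
        _tsv(pd.DataFrame(sorted(homology_by_tid.items()),
                          columns=["transcript_id", "homologous"]),
             out / "homology.tsv")
        _tsv(pd.DataFrame(
            [(c, p) for c, ps in rip_positions.items() for p in ps],
            columns=["contig_id", "position0"]), out / "rip_positions.tsv")
        manifest.record_stage("simulate", shash, out, sim_outputs)
    else:
        logger.info("simulate stage unchanged, skipped")
        manifest.record_stage("simulate", shash, out, sim_outputs,
                              skipped=True)

    # -- methylome ---------------------------------------------------------
    retained, retention = meth_mod.filter_by_coverage(pileup, cfg["min_cov"])
    meth_summary = meth_mod.summary_table(retained, features)
    profile = meth_mod.metagene_profile(
        retained, [f for f in features if f.feature_class == "gene"])
    meth_outputs = [out / n for n in (
        "retention_report.tsv", "methylation_summary.tsv",
        "metagene_profile.tsv", "methylation.wig")]
    shash = _stage_hash(cfg, sim_keys + ["min_cov"], [out / "pileup.cgmap"])
    if not manifest.stage_unchanged("methylome", shash, out):
        _tsv(retention, out / "retention_report.tsv")
        _tsv(meth_summary, out / "methylation_summary.tsv")
        _tsv(profile.table, out / "metagene_profile.tsv")
        wig_records = records_from_frame(
            retained.sort_values(["contig_id", "position"]))
        serialize_tracks(wig_records, out / "methylation.wig", "wiggle")
        manifest.record_stage("methylome", shash, out, meth_outputs)
    else:
        manifest.record_stage("methylome", shash, out, meth_outputs,
                              skipped=True)

    # -- cnv ---------------------------------------------------------------
    calls = cnv_mod.call_cnv(cov_a, cov_b, cfg["log_ratio_threshold"])
    genome_bp = cfg["n_contigs"] * cfg["contig_length"]
    cnv_outputs = [out / "cnv_calls.tsv", out / "cnv_calls.bed"]
    shash = _stage_hash(cfg, sim_keys + ["log_ratio_threshold"],
                        [out / "coverage_a.tsv", out / "coverage_b.tsv"])
    if not manifest.stage_unchanged("cnv", shash, out):
        _tsv(cnv_mod.calls_table(calls), out / "cnv_calls.tsv")
        serialize_tracks(cnv_mod.called(calls), out / "cnv_calls.bed", "BED")
        manifest.record_stage("cnv", shash, out, cnv_outputs)
    else:
        manifest.record_stage("cnv", shash, out, cnv_outputs, skipped=True)

    # -- cri ---------------------------------------------------------------
    cri_table = cri_mod.cri_over_features(genome, features)
    cri_outputs = [out / "cri_per_feature.tsv"]
    shash = _stage_hash(cfg, sim_keys, [out / "genome.fa",
                                        out / "features.gff3"])
    if not manifest.stage_unchanged("cri", shash, out):
        _tsv(cri_table, out / "cri_per_feature.tsv")
        manifest.record_stage("cri", shash, out, cri_outputs)
    else:
        manifest.record_stage("cri", shash, out, cri_outputs, skipped=True)

    # -- expression --------------------------------------------------------
    counts_a = dict(zip(counts["feature_id"], counts["count_a"]))
    counts_b = dict(zip(counts["feature_id"], counts["count_b"]))
    rpkm_a = expr_mod.compute_rpkm(counts_a, features,
                                   max(1, sum(counts_a.values())))
    rpkm_b = expr_mod.compute_rpkm(counts_b, features,
                                   max(1, sum(counts_b.values())))
    fc_table = expr_mod.fold_change_table(
        {r.feature_id: r.rpkm for r in rpkm_a},
        {r.feature_id: r.rpkm for r in rpkm_b})
    _, venn = expr_mod.coverage_classes(counts_a, counts_b,
                                        cfg["min_reads"])
    expr_outputs = [out / "rpkm_a.tsv", out / "rpkm_b.tsv",
                    out / "fold_changes.tsv", out / "coverage_classes.tsv"]
    shash = _stage_hash(cfg, sim_keys + ["min_reads"],
                        [out / "expression_counts.tsv"])
    if not manifest.stage_unchanged("expression", shash, out):
        _tsv(expr_mod.expression_table(rpkm_a), out / "rpkm_a.tsv")
        _tsv(expr_mod.expression_table(rpkm_b), out / "rpkm_b.tsv")
        _tsv(fc_table, out / "fold_changes.tsv")
        _tsv(pd.DataFrame([venn]), out / "coverage_classes.tsv")
        manifest.record_stage("expression", shash, out, expr_outputs)
    else:
        manifest.record_stage("expression", shash, out, expr_outputs,
                              skipped=True)

    # -- novel genes -------------------------------------------------------
    survivors = novel_mod.filter_novel_transcripts(
        transcripts, features, min_fpkm=cfg["min_fpkm"])
    clusters = novel_mod.cluster_overlapping(survivors)
    cluster_homology = {
        c.cluster_id: any(homology_by_tid.get(t, False)
                          for t in c.member_transcript_ids)
        for c in clusters}
    novel_calls = novel_mod.finalize_novel_genes(
        clusters, cluster_homology, length_cutoff=cfg["length_cutoff"])
    novel_outputs = [out / "novel_genes.tsv"]
    shash = _stage_hash(cfg, sim_keys + ["min_fpkm", "length_cutoff"],
                        [out / "transcripts.gtf", out / "homology.tsv"])
    if not manifest.stage_unchanged("novel_genes", shash, out):
        _tsv(pd.DataFrame(
            [(c.cluster_id, c.contig_id, c.start, c.end, c.span_length,
              ",".join(c.member_transcript_ids)) for c in novel_calls],
            columns=["cluster_id", "contig_id", "start", "end",
                     "span_length", "members"]),
            out / "novel_genes.tsv")
        manifest.record_stage("novel_genes", shash, out, novel_outputs)
    else:
        manifest.record_stage("novel_genes", shash, out, novel_outputs,
                              skipped=True)

    return {
        "genome": genome, "features": features, "pileup": pileup,
        "truth": truth, "retention": retention,
        "methylation_summary": meth_summary, "cnv_calls": calls,
        "cnv_truth": cov_truth, "cri_table": cri_table,
        "fold_changes": fc_table, "expression_truth": expr_truth,
        "venn": venn, "novel_calls": novel_calls,
        "genome_bp": genome_bp,
    }


# ---------------------------------------------------------------------------

def report(out_dir: str | Path) -> str:
    """Human-readable markdown report over a completed run's tables."""
    out = Path(out_dir)
    parts = ["# tuberkit run report\n"]

    def section(title: str, filename: str, fmt=None):
        parts.append(f"\n## {title}\n")
        p = out / filename
        if not p.exists():
            parts.append("_not run_\n")
            return
        df = pd.read_csv(p, sep="\t")
        parts.append((fmt(df) if fmt else df.to_string(index=False)) + "\n")

    section("Cytosine retention (coverage filter)", "retention_report.tsv")
    section("Methylation levels by scope and context",
            "methylation_summary.tsv",
            lambda df: df.assign(
                mean_percent=(100 * df["mean_level"]).round(2)
            ).to_string(index=False))
    p = out / "cnv_calls.tsv"
    parts.append("\n## Copy-number variation\n")
    if p.exists():
        calls = pd.read_csv(p, sep="\t")
        n = int(calls["passed_threshold"].sum())
        bp = int((calls["end"] - calls["start"])[calls["passed_threshold"]]
                 .sum())
        total = int((calls["end"] - calls["start"]).sum())
        parts.append(f"{n} called windows covering {bp} bp "
                     f"({100.0 * bp / total:.2f}% of the genome)\n")
    else:
        parts.append("_not run_\n")
    section("Composite RIP index per feature (head)", "cri_per_feature.tsv",
            lambda df: df.head(10).to_string(index=False))
    section("Expression fold changes (head)", "fold_changes.tsv",
            lambda df: df.head(10).to_string(index=False))
    section("Novel gene calls", "novel_genes.tsv")
    text = "".join(parts)
    (out / "report.md").write_text(text)
    return text
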