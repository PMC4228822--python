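"""Read-depth copy-number variation between two sequencing libraries.

The genome is tiled into fixed-width windows (100 kb by default); each
library's mean per-bp window depth is divided by that library's genome-wide
mean depth (library-size normalization), and a window is called a CNV when
the absolute log10 of the normalized depth ratio reaches the threshold
(0.3 by default, about a two-fold change). Calls from one library pair can
be confirmed against calls from an independent pair on the same tiling.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CNVCall, CoverageWindow

DEFAULT_WINDOW_BP = 100_000
DEFAULT_THRESHOLD = 0.3


def window_coverage(depth_table: pd.DataFrame,
                    window_bp: int = DEFAULT_WINDOW_BP,
                    contig_lengths: Mapping[str, int] | None = None
                    ) -> pd.DataFrame:
    """Mean per-bp depth in tiling windows from position 0.

    ``depth_table`` holds per-interval depths (columns contig_id, start,
    end, depth; per-bp input is the one-bp-interval special case). Intervals
    may span window boundaries; their depth contributes to each overlapped
    window in proportion to the overlap. The last window of a contig may be
    short. Returns a window table (contig_id, start, end, depth).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if (depth_table["depth"] < 0).any():
        raise ValueError("negative depths")
    lengths = dict(contig_lengths) if contig_lengths else {}
    for contig, sub in depth_table.groupby("contig_id"):
        lengths.setdefault(contig, int(sub["end"].max()))
    rows = []
    for contig in sorted(lengths):
        clen = lengths[contig]
        n_windows = (clen + window_bp - 1) // window_bp
        acc = np.zeros(n_windows)
        sub = depth_table[depth_table["contig_id"] == contig]
        for s, e, d in zip(sub["start"], sub["end"], sub["depth"]):
            w0, w1 = s // window_bp, (e - 1) // window_bp
            for w in range(w0, w1 + 1):
                overlap = min(e, (w + 1) * window_bp) - max(s, w * window_bp)
                acc[w] += d * overlap
        for w in range(n_windows):
            ws, we = w * window_bp, min((w + 1) * window_bp, clen)
            rows.append((contig, ws, we, acc[w] / (we - ws)))
    return pd.DataFrame(rows, columns=["contig_id", "start", "end", "depth"])


def _check_same_tiling(a: pd.DataFrame, b: pd.DataFrame) -> None:
    ka = list(zip(a["contig_id"], a["start"], a["end"]))
    kb = list(zip(b["contig_id"], b["start"], b["end"]))
    if ka != kb:
        raise ValueError("window tables do not tile identical coordinates")


def call_cnv(windows_a: pd.DataFrame, windows_b: pd.DataFrame,
             threshold: float = DEFAULT_THRESHOLD,
             log_base: float = 10.0) -> list[CNVCall]:
    """Call CNV windows from two window-depth tables on one tiling.

    Each library's window depths are divided by that library's genome-wide
    mean depth; a window is called iff |log(norm_a/norm_b)| >= threshold
    (boundary inclusive). Windows with zero depth in either library have an
    undefined ratio and are skipped (returned with passed_threshold False
    and log_ratio None).
    """
    _check_same_tiling(windows_a, windows_b)
    widths = (windows_a["end"] - windows_a["start"]).to_numpy(float)
    da = windows_a["depth"].to_numpy(float)
    db = windows_b["depth"].to_numpy(float)
    mean_a = (da * widths).sum() / widths.sum()
    mean_b = (db * widths).sum() / widths.sum()
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("a library has zero genome-wide depth")
    calls = []
    for i in range(len(windows_a)):
        win = CoverageWindow(
            contig_id=windows_a["contig_id"].iloc[i],
            start=int(windows_a["start"].iloc[i]),
            end=int(windows_a["end"].iloc[i]),
            depth_a=float(da[i]), depth_b=float(db[i]))
        na, nb = da[i] / mean_a, db[i] / mean_b
        if na > 0 and nb > 0:
            win.norm_ratio = na / nb
            win.log_ratio = math.log(win.norm_ratio, log_base)
            passed = abs(win.log_ratio) >= threshold
            direction = "gain_in_a" if win.log_ratio > 0 else "loss_in_a"
        else:
            passed = False
            direction = "gain_in_a" if na > nb else "loss_in_a"
        calls.append(CNVCall(window=win, direction=direction,
                             passed_threshold=passed))
    return calls


def called(calls: Sequence[CNVCall]) -> list[CNVCall]:
    return [c for c in calls if c.passed_threshold]


def merge_adjacent_calls(calls: Sequence[CNVCall]) -> list[CNVCall]:
    """Merge directly adjacent called windows with the same direction.

    Off the default path: each called window is its own region unless a
    caller opts into merging. Merged regions carry the width-weighted mean
    depths and the recomputed log ratio of their members.
    """
    merged: list[CNVCall] = []
    for c in sorted(called(calls),
                    key=lambda c: (c.window.contig_id, c.window.start)):
        if merged:
            prev = merged[-1]
            if (prev.window.contig_id == c.window.contig_id
                    and prev.window.end == c.window.start
                    and prev.direction == c.direction):
                pw, cw = prev.window, c.window
                w1, w2 = pw.width, cw.width
                prev.window = CoverageWindow(
                    contig_id=pw.contig_id, start=pw.start, end=cw.end,
                    depth_a=(pw.depth_a * w1 + cw.depth_a * w2) / (w1 + w2),
                    depth_b=(pw.depth_b * w1 + cw.depth_b * w2) / (w1 + w2))
                if pw.norm_ratio and cw.norm_ratio:
                    prev.window.norm_ratio = (
                        pw.norm_ratio * w1 + cw.norm_ratio * w2) / (w1 + w2)
                    prev.window.log_ratio = math.log10(
                        prev.window.norm_ratio)
                continue
        merged.append(CNVCall(window=CoverageWindow(
            contig_id=c.window.contig_id, start=c.window.start,
            end=c.window.end, depth_a=c.window.depth_a,
            depth_b=c.window.depth_b, norm_ratio=c.window.norm_ratio,
            log_ratio=c.window.log_ratio),
            direction=c.direction, passed_threshold=True,
            confirmed=c.confirmed))
    return merged


def genome_fraction(calls: Sequence[CNVCall], genome_size: int) -> float:
    """Percent of the genome covered by called windows."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    bp = sum(c.window.width for c in calls if c.passed_threshold)
    return 100.0 * bp / genome_size


def confirmation_concordance(calls_primary: Sequence[CNVCall],
                             calls_confirm: Sequence[CNVCall]
                             ) -> tuple[int, float | None]:
    """How many primary calls an independent library pair confirms.

    A primary call is confirmed iff the identical window is called in the
    confirming set with the same direction. Returns (n_confirmed, percent);
    percent is None when there are no primary calls. Marks each primary
    call's ``confirmed`` flag in place.
    """
    confirm_index = {
        (c.window.contig_id, c.window.start, c.window.end): c.direction
        for c in calls_confirm if c.passed_threshold}
    primary = called(calls_primary)
    n_confirmed = 0
    for c in primary:
        key = (c.window.contig_id, c.window.start, c.window.end)
        c.confirmed = confirm_index.get(key) == c.direction
        n_confirmed += c.confirmed
    if not primary:
        return 0, None
    return n_confirmed, 100.0 * n_confirmed / len(primary)


def calls_table(calls: Sequence[CNVCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        w = c.window
        rows.append((w.contig_id, w.start, w.end, w.depth_a, w.depth_b,
                     math.nan if w.log_ratio is None else w.log_ratio,
                     c.direction, c.passed_threshold, c.confirmed))
    return pd.DataFrame(rows, columns=[
        "contig_id", "start", "end", "depth_a", "depth_b", "log_ratio",
        "direction", "passed_threshold", "confirmed"])
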