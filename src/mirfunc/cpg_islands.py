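"""Sliding-window CpG-island statistics and island calling on promoters.

A 200-bp window slides at 1-bp steps. Per window, GC% is 100*(#C+#G)/N and the
CpG observed/expected ratio is #CpG * N / (#C * #G) with N the window length
and #CpG the overlapping count of "CG" dimers (0 by convention when a window
has no C or no G). A window qualifies for an island when GC% > 50 and
Obs/Exp > 0.6 (strict); overlapping or adjacent qualifying windows are merged
into maximal island ranges, so every island spans at least one window length.
Windows containing N are emitted flagged and excluded from islands and
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import DnaSequence

GC_THRESHOLD = 50.0
OBS_EXP_THRESHOLD = 0.6


@dataclass(frozen=True)
class CpgWindowStats:
    """Per-window GC% and CpG Obs/Exp (0-based half-open coordinates)."""

    start: int
    end: int
    gc_percent: float
    obs_exp: float
    skipped: bool = False  # window contained N

    @property
    def qualifies(self) -> bool:
        return (
            not self.skipped
            and self.gc_percent > GC_THRESHOLD
            and self.obs_exp > OBS_EXP_THRESHOLD
        )


@dataclass(frozen=True)
class CpgIsland:
    """A maximal merged run of qualifying windows."""

    start: int
    end: int
    mean_gc: float
    mean_obs_exp: float


@dataclass(frozen=True)
class CpgSummary:
    """Per-sequence min/max of the window statistics plus island count."""

    gene_id: str
    min_gc: float
    max_gc: float
    min_obs_exp: float
    max_obs_exp: float
    n_islands: int


def window_stats(
    seq: DnaSequence, window: int = 200, step: int = 1
) -> list[CpgWindowStats]:
    """Sliding-window GC% and CpG Obs/Exp over a promoter sequence.

    One record per start position 0, step, 2*step, ... while the window fits.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    n = seq.length
    if n < window:
        raise ValueError(
            f"{seq.id}: sequence length {n} below minimum window length {window}"
        )
    a = np.frombuffer(seq.seq.encode(), dtype=np.uint8)
    is_c = (a == ord("C")).astype(np.int64)
    is_g = (a == ord("G")).astype(np.int64)
    is_n = (a == ord("N")).astype(np.int64)
    is_cpg = np.zeros(n, dtype=np.int64)
    is_cpg[: n - 1] = is_c[: n - 1] & is_g[1:]
    # prefix sums for O(1) window counts
    cum = lambda x: np.concatenate(([0], np.cumsum(x)))
    cc, cg_, cn, ccpg = cum(is_c), cum(is_g), cum(is_n), cum(is_cpg)
    out: list[CpgWindowStats] = []
    for start in range(0, n - window + 1, step):
        end = start + window
        n_c = int(cc[end] - cc[start])
        n_g = int(cg_[end] - cg_[start])
        n_cpg = int(ccpg[end - 1] - ccpg[start])  # dimers fully inside window
        has_n = (cn[end] - cn[start]) > 0
        gc = 100.0 * (n_c + n_g) / window
        obs_exp = n_cpg * window / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
        out.append(
            CpgWindowStats(
                start=start, end=end, gc_percent=gc, obs_exp=obs_exp, skipped=bool(has_n)
            )
        )
    return out


def call_islands(stats: Sequence[CpgWindowStats]) -> list[CpgIsland]:
    """Merge qualifying windows into maximal island ranges.

    Windows pass with GC% > 50 and Obs/Exp > 0.6 (both strict); overlapping or
    book-ended qualifying windows merge, and island statistics are means over
    the constituent windows.
    """
    islands: list[CpgIsland] = []
    run: list[CpgWindowStats] = []

    def flush() -> None:
        if run:
            islands.append(
                CpgIsland(
                    start=run[0].start,
                    end=run[-1].end,
                    mean_gc=float(np.mean([w.gc_percent for w in run])),
                    mean_obs_exp=float(np.mean([w.obs_exp for w in run])),
                )
            )
            run.clear()

    for w in stats:
        if not w.qualifies:
            continue
        if run and w.start > run[-1].end:  # disjoint (not even book-ended)
            flush()
        run.append(w)
    flush()
    return islands


def summarize(
    gene_id: str, stats: Sequence[CpgWindowStats], islands: Sequence[CpgIsland]
) -> CpgSummary:
    """Min/max GC% and Obs/Exp over non-skipped windows, plus island count."""
    usable = [w for w in stats if not w.skipped]
    if not usable:
        raise ValueError(f"{gene_id}: no usable (N-free) windows")
    gcs = [w.gc_percent for w in usable]
    oes = [w.obs_exp for w in usable]
    return CpgSummary(
        gene_id=gene_id,
        min_gc=min(gcs),
        max_gc=max(gcs),
        min_obs_exp=min(oes),
        max_obs_exp=max(oes),
        n_islands=len(islands),
    )


def write_window_table(stats: Sequence[CpgWindowStats], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tgc_percent\tobs_exp\tskipped\n")
        for w in stats:
            fh.write(
                f"{w.start}\t{w.end}\t{w.gc_percent:.2f}\t{w.obs_exp:.4f}\t"
                f"{int(w.skipped)}\n"
            )


def write_island_bed(
    islands: Sequence[CpgIsland], chrom: str, path: str | Path
) -> None:
    """BED6 of called islands (score = mean Obs/Exp x 100, capped at 1000)."""
    with open(path, "w") as fh:
        for k, isl in enumerate(islands):
            score = min(1000, int(round(isl.mean_obs_exp * 100)))
            fh.write(f"{chrom}\t{isl.start}\t{isl.end}\tCpG_island_{k + 1}\t{score}\t+\n")


def write_summary_table(summaries: Sequence[CpgSummary], path: str | Path) -> None:
    """TSV summary: per-gene min/max GC% and Obs/Exp (2 decimals) + islands."""
    with open(path, "w") as fh:
        fh.write("gene_id\tmin_gc\tmax_gc\tmin_obs_exp\tmax_obs_exp\tn_islands\n")
        for s in summaries:
            fh.write(
                f"{s.gene_id}\t{s.min_gc:.2f}\t{s.max_gc:.2f}\t{s.min_obs_exp:.2f}\t"
                f"{s.max_obs_exp:.2f}\t{s.n_islands}\n"
            )
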