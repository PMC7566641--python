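"""Contiguous hypo-/hypermethylated region identification.

Windows are scored by how many significant CpGs of each direction they
contain. Seed windows exceed the 95th percentile of those counts (computed
separately for each direction, over all windows including zero-count ones)
and have at least 75% of their significant CpGs in one direction. Adjacent
seed windows of the same direction, or seeds separated by a single
sub-threshold window, merge into one region. Region boundaries snap to the
outermost endpoints of DMRs overlapping the merged window span; a region
with no overlapping DMR keeps its window edges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import WindowGrid

__all__ = ["window_sig_counts", "call_regions"]


def window_sig_counts(results: pd.DataFrame, grid: WindowGrid) -> pd.DataFrame:
    """Per-window counts of significant hypo- and hypermethylated CpGs."""
    sig = results.loc[results["significant"].to_numpy(dtype=bool)]
    widx = grid.assign(sig["pos"].to_numpy())
    n = len(grid)
    n_hypo = np.zeros(n, dtype=int)
    n_hyper = np.zeros(n, dtype=int)
    inside = widx >= 0
    for w, d in zip(widx[inside], sig["direction"].to_numpy()[inside]):
        if d == "hypo":
            n_hypo[w] += 1
        else:
            n_hyper[w] += 1
    out = grid.windows.copy()
    out["n_hypo"] = n_hypo
    out["n_hyper"] = n_hyper
    return out


def call_regions(counts: pd.DataFrame, dmrs: pd.DataFrame, grid: WindowGrid,
                 pct: float = 95.0, purity: float = 0.75,
                 max_gap: int = 1) -> pd.DataFrame:
    """Call hypo/hyper regions from window counts and DMR coordinates.

    Returns a frame with chrom, start, end, direction, window_ids, n_hypo,
    n_hyper and purity (the max-direction fraction over the supporting
    windows). No seed windows yields an empty frame, not an error.
    """
    n_hypo = counts["n_hypo"].to_numpy()
    n_hyper = counts["n_hyper"].to_numpy()
    thr_hypo = float(np.percentile(n_hypo, pct))
    thr_hyper = float(np.percentile(n_hyper, pct))
    total = n_hypo + n_hyper
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, np.maximum(n_hypo, n_hyper) / np.maximum(total, 1), 0.0)

    seed_dir = np.full(len(counts), "", dtype=object)
    for w in range(len(counts)):
        if total[w] == 0 or frac[w] < purity:
            continue
        if n_hypo[w] > thr_hypo and n_hypo[w] >= n_hyper[w]:
            seed_dir[w] = "hypo"
        elif n_hyper[w] > thr_hyper and n_hyper[w] > n_hypo[w]:
            seed_dir[w] = "hyper"

    regions = []
    for direction in ("hypo", "hyper"):
        seeds = np.flatnonzero(seed_dir == direction)
        if len(seeds) == 0:
            continue
        runs = [[seeds[0]]]
        for w in seeds[1:]:
            if w - runs[-1][-1] <= max_gap + 1:
                runs[-1].append(w)
            else:
                runs.append([w])
        for run in runs:
            w_start = int(counts["start"].iloc[run[0]])
            w_end = int(counts["end"].iloc[run[-1]])
            start, end = w_start, w_end
            if len(dmrs):
                hit = dmrs[(dmrs["start"] < w_end) & (dmrs["end"] > w_start)
                           & (dmrs["direction"] == direction)]
                if len(hit):
                    start = int(hit["start"].min())
                    end = int(hit["end"].max())
            regions.append(
                {
                    "chrom": grid.region.chrom,
                    "start": start,
                    "end": end,
                    "direction": direction,
                    "window_ids": list(run),
                    "n_hypo": int(n_hypo[run].sum()),
                    "n_hyper": int(n_hyper[run].sum()),
                }
            )

    if not regions:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "direction", "window_ids",
                     "n_hypo", "n_hyper", "purity"],
        )
    out = pd.DataFrame(regions)
    out["purity"] = np.maximum(out["n_hypo"], out["n_hyper"]) / (
        out["n_hypo"] + out["n_hyper"]
    )
    # DMR snapping can make same-direction regions coincide; merge overlaps
    out = out.sort_values(["direction", "start"]).reset_index(drop=True)
    merged = []
    for _, row in out.iterrows():
        if merged and row["direction"] == merged[-1]["direction"] and \
                row["start"] < merged[-1]["end"]:
            prev = merged[-1]
            prev["end"] = max(prev["end"], row["end"])
            prev["window_ids"] = sorted(set(prev["window_ids"]) | set(row["window_ids"]))
            prev["n_hypo"] += row["n_hypo"]
            prev["n_hyper"] += row["n_hyper"]
            prev["purity"] = max(prev["n_hypo"], prev["n_hyper"]) / (
                prev["n_hypo"] + prev["n_hyper"]
            )
        else:
            merged.append(dict(row))
    out = pd.DataFrame(merged).sort_values("start").reset_index(drop=True)
    return out
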