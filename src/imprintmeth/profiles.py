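"""Windowed methylation profiles, ATAC overlay and profile correlations.

The target region is tiled into fixed-width windows (10 kbp for the
full-size region, giving 135 windows over 1.35 Mbp). Per window and
cohort, the point estimate of percent methylation pools every covered
(sample, site) cell; the 95% confidence interval is t-based across
per-sample window means. ATAC peak scores are normalized per sample to
that sample's total signal over the region, the per-window maximum of the
normalized scores is taken for each sample, and window scores are averaged
across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotationSet, Interval, MethCallTable

__all__ = ["WindowGrid", "make_windows", "window_methylation", "window_atac",
           "profile_correlation"]


@dataclass
class WindowGrid:
    """A gap-free tiling of a region by fixed-width windows."""

    region: Interval
    width: int
    windows: pd.DataFrame  # window (index), start, end

    def __len__(self) -> int:
        return len(self.windows)

    def assign(self, pos: np.ndarray) -> np.ndarray:
        """Window index for each position (half-open rule); -1 outside region."""
        pos = np.asarray(pos)
        idx = (pos - self.region.start) // self.width
        idx = np.where((pos >= self.region.start) & (pos < self.region.end), idx, -1)
        return idx.astype(int)


def make_windows(region: Interval, width: int = 10_000) -> WindowGrid:
    """Tile ``region`` into ceil(length / width) windows; the final window is
    truncated when the region length is not divisible by ``width``."""
    if width <= 0:
        raise ValueError("window width must be positive")
    if width > region.length:
        warnings.warn(
            f"window width {width} exceeds region length {region.length}; "
            "using a single window", stacklevel=2,
        )
    starts = np.arange(region.start, region.end, width)
    ends = np.minimum(starts + width, region.end)
    df = pd.DataFrame({"start": starts, "end": ends})
    df.index.name = "window"
    return WindowGrid(region=region, width=width, windows=df)


def window_methylation(table: MethCallTable, grid: WindowGrid,
                       cohort: str) -> pd.DataFrame:
    """Per-window mean percent methylation with a 95% CI for one cohort.

    The mean pools all covered (sample, site) cells of the window; the CI is
    computed from across-sample window means (t distribution). Windows with
    no measurable CpG are missing (NaN), not zero.
    """
    rows = table.cohort_mask(cohort)
    if rows.sum() == 0:
        raise ValueError(f"no samples in cohort {cohort!r}")
    beta = table.beta[rows]
    widx = grid.assign(table.sites["pos"].to_numpy())

    n_windows = len(grid)
    mean = np.full(n_windows, np.nan)
    ci_lo = np.full(n_windows, np.nan)
    ci_hi = np.full(n_windows, np.nan)
    for w in range(n_windows):
        cols = widx == w
        if not cols.any():
            continue
        cells = beta[:, cols]
        if np.isnan(cells).all():
            continue
        mean[w] = np.nanmean(cells) * 100.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_sample = np.nanmean(cells, axis=1) * 100.0
        per_sample = per_sample[~np.isnan(per_sample)]
        if len(per_sample) >= 2 and np.ptp(per_sample) > 0:
            sem = np.std(per_sample, ddof=1) / np.sqrt(len(per_sample))
            tcrit = stats.t.ppf(0.975, df=len(per_sample) - 1)
            center = per_sample.mean()
            ci_lo[w] = center - tcrit * sem
            ci_hi[w] = center + tcrit * sem
        else:
            ci_lo[w] = ci_hi[w] = mean[w]
    out = grid.windows.copy()
    out["mean"] = mean
    out["ci_lo"] = np.minimum(ci_lo, mean)
    out["ci_hi"] = np.maximum(ci_hi, mean)
    return out


def window_atac(peaks: AnnotationSet, grid: WindowGrid) -> pd.DataFrame:
    """Per-window normalized ATAC score averaged across samples.

    For each sample (the ``sample`` attribute of the peak set), peak scores
    are divided by the sample's total score inside the region; the window
    score for a sample is the maximum normalized peak score in the window
    (0 when the sample has no peak there), and window scores are averaged
    across samples.
    """
    df, _ = peaks.clip_to_region(grid.region)
    if "sample" not in df.df.columns:
        raise ValueError("ATAC peak set needs a 'sample' attribute")
    n_windows = len(grid)
    per_sample_scores = []
    for sample, chunk in df.df.groupby("sample"):
        total = chunk["score"].sum()
        if total <= 0:
            raise ValueError(f"ATAC sample {sample!r} has zero total signal in region")
        norm = chunk["score"].to_numpy() / total
        # a peak contributes to every window it overlaps
        scores = np.zeros(n_windows)
        for (s, e, v) in zip(chunk["start"], chunk["end"], norm):
            w_first = max(int((s - grid.region.start) // grid.width), 0)
            w_last = min(int((e - 1 - grid.region.start) // grid.width), n_windows - 1)
            for w in range(w_first, w_last + 1):
                scores[w] = max(scores[w], v)
        per_sample_scores.append(scores)
    out = grid.windows.copy()
    out["atac"] = np.mean(per_sample_scores, axis=0)
    return out


def profile_correlation(x: np.ndarray | pd.Series,
                        y: np.ndarray | pd.Series) -> tuple[float, float, int]:
    """Pearson correlation of two per-window profiles.

    Missing windows are removed pairwise. Returns (r, two-sided p, n).
    Raises on fewer than three complete pairs or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least three paired non-missing windows")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance profile; correlation undefined")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n
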