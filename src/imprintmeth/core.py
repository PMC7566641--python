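"""Coordinate conventions, interval algebra, CpG maps and tabular/track I/O.

All internal coordinates are 0-based and half-open (BED convention).
Genome-browser style spans, where both endpoints are printed 1-based and
inclusive, are converted on ingest with :meth:`Interval.from_one_based`
and recovered losslessly with :meth:`Interval.to_one_based`.

A CpG dinucleotide occupies exactly two base pairs, ``[pos, pos + 2)``,
where ``pos`` is the position of the cytosine on the plus strand.
Methylation calls are assumed to be strand-collapsed by the upstream
caller, so sites are defined on the plus strand only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Interval",
    "AnnotationSet",
    "MethCallTable",
    "read_meth_calls",
    "coverage_filter",
    "cpg_map_from_sequence",
    "intersect",
    "write_track",
    "read_track",
    "read_bed",
]

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based, half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_one_based(cls, chrom: str, first: int, last: int, **kw) -> "Interval":
        """Build from a 1-based, inclusive coordinate pair."""
        return cls(chrom, first - 1, last, **kw)

    def to_one_based(self) -> tuple[int, int]:
        """Return the (first, last) 1-based inclusive pair; lossless round trip."""
        return self.start + 1, self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def clip(self, region: "Interval") -> "Interval":
        if not self.overlaps(region):
            raise ValueError(f"{self} does not overlap clipping region {region}")
        return replace(
            self, start=max(self.start, region.start), end=min(self.end, region.end)
        )


_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

ANNOTATION_KINDS = {
    "gene_isoform",
    "enhancer",
    "tr_site",
    "atac_peak",
    "chromatin_signature",
    "loop_score",
}


@dataclass
class AnnotationSet:
    """Labeled genomic intervals of one kind, held as a DataFrame.

    The frame always carries BED6 columns (chrom, start, end, name, score,
    strand); kind-specific attributes (gene, isoform, source, sample,
    signature class ...) live in additional columns.
    """

    kind: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        for col in ("chrom", "start", "end"):
            if col not in self.df.columns:
                raise ValueError(f"annotation frame lacks column {col!r}")
        df = self.df.copy()
        if "name" not in df.columns:
            df["name"] = "."
        if "score" not in df.columns:
            df["score"] = 0.0
        if "strand" not in df.columns:
            df["strand"] = "."
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self) -> list[Interval]:
        return [
            Interval(r.chrom, int(r.start), int(r.end),
                     r.strand if r.strand in _VALID_STRANDS else ".",
                     str(r.name_) if hasattr(r, "name_") else str(r.name))
            for r in self.df.rename(columns={"name": "name_"}).itertuples(index=False)
        ]

    def clip_to_region(self, region: Interval) -> tuple["AnnotationSet", int]:
        """Drop intervals outside ``region``; returns (clipped set, n dropped)."""
        df = self.df
        keep = (
            (df["chrom"] == region.chrom)
            & (df["start"] < region.end)
            & (df["end"] > region.start)
        )
        n_dropped = int((~keep).sum())
        return AnnotationSet(self.kind, df[keep].reset_index(drop=True)), n_dropped

    def write_bed(self, path) -> None:
        df = self.df.copy()
        extra = [c for c in df.columns if c not in _BED_COLUMNS]
        out = df[_BED_COLUMNS].copy()
        if extra:
            out["attrs"] = [
                ";".join(f"{k}={df.at[i, k]}" for k in extra) for i in df.index
            ]
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_bed(cls, path, kind: str) -> "AnnotationSet":
        return read_bed(path, kind)


def read_bed(path, kind: str) -> AnnotationSet:
    """Read BED4/BED6 (+ optional trailing key=value attribute column)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    ncol = df.shape[1]
    names = _BED_COLUMNS[: min(ncol, 6)]
    if ncol > 6:
        names = names + ["attrs"]
        df = df.iloc[:, :7]
    df.columns = names
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(0.0)
    if "attrs" in df.columns:
        parsed = df["attrs"].fillna("").map(
            lambda s: dict(kv.split("=", 1) for kv in s.split(";") if "=" in kv)
        )
        keys = sorted({k for d in parsed for k in d})
        for k in keys:
            df[k] = [d.get(k) for d in parsed]
        df = df.drop(columns=["attrs"])
    return AnnotationSet(kind, df)


# ---------------------------------------------------------------------------
# Methylation call table


@dataclass
class MethCallTable:
    """Per-sample, per-CpG methylated/total bisulfite read counts.

    ``sites`` is a frame with columns chrom and pos (0-based position of the
    plus-strand C), indexed by a stable ordinal site id. ``samples`` is a
    frame indexed by sample id with a ``cohort`` column and an optional
    ``group`` column. ``meth`` and ``total`` are (n_samples, n_sites) integer
    arrays; a cell with ``total == 0`` is missing (not zero methylation).
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        n_samp, n_site = self.meth.shape
        if self.total.shape != (n_samp, n_site):
            raise ValueError("meth and total shapes differ")
        if len(self.samples) != n_samp or len(self.sites) != n_site:
            raise ValueError("sites/samples do not match count matrix shape")
        if (self.meth < 0).any() or (self.total < 0).any():
            raise ValueError("negative read counts")
        bad = self.meth > self.total
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"methylated reads exceed total reads at sample "
                f"{self.samples.index[i]!r}, site {self.sites.index[j]}"
            )
        pos = self.sites["pos"].to_numpy()
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise ValueError("CpG sites must be strictly increasing in position")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def beta(self) -> np.ndarray:
        """Methylation fraction; NaN where the cell is missing."""
        with np.errstate(divide="ignore", invalid="ignore"):
            b = self.meth / self.total
        b[self.total == 0] = np.nan
        return b

    def cohort_mask(self, cohort: str) -> np.ndarray:
        return (self.samples["cohort"] == cohort).to_numpy()

    def not_measurable(self, cohort: str) -> np.ndarray:
        """Sites with no covered cell in any sample of ``cohort``."""
        rows = self.cohort_mask(cohort)
        return (self.total[rows] == 0).all(axis=0)

    def subset_sites(self, mask: np.ndarray) -> "MethCallTable":
        return MethCallTable(
            self.sites.loc[mask].copy(),
            self.samples.copy(),
            self.meth[:, mask],
            self.total[:, mask],
        )

    def write_tsv(self, path) -> None:
        """Write the count-format TSV read back by :func:`read_meth_calls`."""
        out = pd.DataFrame(
            {"chrom": self.sites["chrom"], "pos": self.sites["pos"] + 1}
        )
        for i, sample in enumerate(self.samples.index):
            out[f"{sample}.meth"] = self.meth[i]
            out[f"{sample}.total"] = self.total[i]
        out.to_csv(path, sep="\t", index=False)


def read_meth_calls(path, sample_sheet: pd.DataFrame) -> MethCallTable:
    """Read a per-CpG call table (TSV) with a sample sheet.

    The TSV must have ``chrom`` and ``pos`` (1-based) columns followed by
    per-sample ``<id>.meth``/``<id>.total`` count columns; the alternative
    percent format ``<id>.pct``/``<id>.total`` is also accepted.
    ``sample_sheet`` needs a ``sample`` column mapping every sample in the
    file to a ``cohort`` (and optionally a ``group``).
    """
    df = pd.read_csv(path, sep="\t")
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise ValueError("call table must have 'chrom' and 'pos' columns")
    sheet = sample_sheet.set_index("sample") if "sample" in sample_sheet.columns else sample_sheet
    sample_ids = []
    for col in df.columns:
        if col.endswith(".total"):
            sample_ids.append(col[: -len(".total")])
    if not sample_ids:
        raise ValueError("no '<sample>.total' columns found")
    missing = [s for s in sample_ids if s not in sheet.index]
    if missing:
        raise ValueError(f"samples missing from sample sheet: {missing}")

    bad_rows = df.index[df["pos"] < 1].tolist()
    if bad_rows:
        raise ValueError(f"non-positive 1-based positions at rows {bad_rows}")

    n_sites = len(df)
    meth = np.zeros((len(sample_ids), n_sites), dtype=np.int64)
    total = np.zeros_like(meth)
    for i, s in enumerate(sample_ids):
        tot = pd.to_numeric(df[f"{s}.total"], errors="coerce")
        if tot.isna().any():
            rows = df.index[tot.isna()].tolist()
            raise ValueError(f"malformed total counts for sample {s!r} at rows {rows}")
        total[i] = tot.to_numpy(dtype=np.int64)
        if f"{s}.meth" in df.columns:
            m = pd.to_numeric(df[f"{s}.meth"], errors="coerce")
            if m.isna().any():
                rows = df.index[m.isna()].tolist()
                raise ValueError(f"malformed meth counts for sample {s!r} at rows {rows}")
            meth[i] = m.to_numpy(dtype=np.int64)
        elif f"{s}.pct" in df.columns:
            pct = pd.to_numeric(df[f"{s}.pct"], errors="coerce").to_numpy()
            meth[i] = np.where(
                total[i] > 0, np.rint(pct / 100.0 * total[i]), 0
            ).astype(np.int64)
        else:
            raise ValueError(f"sample {s!r} has neither .meth nor .pct column")
        # a cell with zero total reads is missing; its meth field is moot
        meth[i] = np.where(total[i] > 0, meth[i], 0)
        over = meth[i] > total[i]
        if over.any():
            j = int(np.argmax(over))
            raise ValueError(
                f"meth > total for sample {s!r} at {df['chrom'].iat[j]}:{df['pos'].iat[j]}"
            )

    sites = pd.DataFrame({"chrom": df["chrom"], "pos": df["pos"].astype(int) - 1})
    sites.index.name = "site"
    samples = sheet.loc[sample_ids, [c for c in ("cohort", "group") if c in sheet.columns]].copy()
    if "cohort" not in samples.columns:
        raise ValueError("sample sheet lacks a 'cohort' column")
    return MethCallTable(sites, samples, meth, total)


def coverage_filter(table: MethCallTable, min_depth: int = 5) -> MethCallTable:
    """Mask cells below ``min_depth`` total reads as missing.

    The retained cells all satisfy ``total >= min_depth``; masked cells get
    total = meth = 0, which downstream code treats as "no data", never as
    zero methylation.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    keep = table.total >= min_depth
    return MethCallTable(
        table.sites.copy(),
        table.samples.copy(),
        np.where(keep, table.meth, 0),
        np.where(keep, table.total, 0),
    )


# ---------------------------------------------------------------------------
# CpG maps

_IUPAC = set("ACGTNRYSWKMBDHV")


def cpg_map_from_sequence(seq: str, offset: Interval | int = 0) -> pd.DataFrame:
    """Census of plus-strand CG dinucleotides in a sequence.

    Returns a sites frame (chrom, pos) with positions offset into genome
    coordinates when ``offset`` is an :class:`Interval` (its chrom and start
    are used) or shifted by an integer otherwise.
    """
    s = seq.upper()
    bad = set(s) - _IUPAC
    if bad:
        pos = min(i for i, c in enumerate(s) if c in bad)
        raise ValueError(f"non-IUPAC character {s[pos]!r} at position {pos}")
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    hits = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    if isinstance(offset, Interval):
        chrom, shift = offset.chrom, offset.start
    else:
        chrom, shift = "seq", int(offset)
    sites = pd.DataFrame({"chrom": chrom, "pos": hits + shift})
    sites.index.name = "site"
    return sites


# ---------------------------------------------------------------------------
# Interval intersection


def intersect(a: list[Interval], b: list[Interval]) -> pd.DataFrame:
    """All overlapping pairs between two interval collections.

    Returns a frame with columns a_index, b_index, chrom, start, end,
    overlap (bp), using half-open overlap semantics; touching intervals
    ([0,10) vs [10,20)) do not overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(b):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    records = []
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(iv.start, iv.end), key=lambda h: (h.begin, h.data)):
            start = max(iv.start, hit.begin)
            end = min(iv.end, hit.end)
            records.append((i, hit.data, iv.chrom, start, end, end - start))
    return pd.DataFrame(
        records, columns=["a_index", "b_index", "chrom", "start", "end", "overlap"]
    )


def union_length(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by a union of (start, end) half-open spans."""
    if not intervals:
        return 0
    spans = sorted(intervals)
    total = 0
    cur_s, cur_e = spans[0]
    for s, e in spans[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def merge_spans(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open spans into a sorted disjoint list."""
    if not intervals:
        return []
    spans = sorted(intervals)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# Track export


def write_track(values: pd.DataFrame, path, name: str = "track") -> int:
    """Write per-window or per-position scores as bedGraph.

    ``values`` needs columns chrom, start, end, value. Rows with NaN scores
    are skipped with a warning; returns the number skipped. Output rows are
    deterministically ordered by (chrom, start).
    """
    df = values[["chrom", "start", "end", "value"]].copy()
    nan = df["value"].isna()
    n_skipped = int(nan.sum())
    if n_skipped:
        warnings.warn(f"write_track: skipped {n_skipped} NaN scores", stacklevel=2)
    df = df[~nan]
    if not np.isfinite(df["value"]).all():
        raise ValueError("write_track requires finite scores")
    df = df.sort_values(["chrom", "start"], kind="stable")
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for r in df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{r.value:.6g}\n")
    return n_skipped


def read_track(path) -> pd.DataFrame:
    """Read a bedGraph written by :func:`write_track`."""
    df = pd.read_csv(
        path, sep="\t", skiprows=1, header=None,
        names=["chrom", "start", "end", "value"],
    )
    return df
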