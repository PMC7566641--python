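"""Genomic-element catalogs and per-element attribution of significant CpGs.

Promoters are strand-aware 2,000 bp intervals (1,500 bp upstream plus
500 bp downstream of each isoform TSS). Gene bodies are the maximum
footprint per gene (the isoforms extending farthest in both directions).
Element classes are non-exclusive — a CpG inside both a promoter and a
gene body counts once in each — except the non-mapping class, which holds
CpGs overlapping none of promoters, gene bodies or either enhancer class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import percentileofscore

from .core import AnnotationSet, Interval, merge_spans, union_length
from .profiles import WindowGrid

__all__ = [
    "ElementCatalog",
    "build_promoters",
    "gene_footprints",
    "build_catalog",
    "count_sig_cpgs_by_element",
    "site_density_by_element",
    "label_sites",
    "signature_coverage_rank",
]

CLASS_NAMES = ["promoters", "gene_bodies", "islet_enhancers", "generic_enhancers"]


@dataclass
class ElementCatalog:
    """Per-class interval collections over one analysis region."""

    region: Interval
    promoters: pd.DataFrame          # chrom,start,end,gene,isoform,strand
    gene_bodies: pd.DataFrame        # chrom,start,end,gene
    islet_enhancers: pd.DataFrame    # chrom,start,end
    generic_enhancers: pd.DataFrame  # chrom,start,end

    def class_spans(self, name: str) -> list[tuple[int, int]]:
        df = getattr(self, name)
        return merge_spans([(int(s), int(e)) for s, e in zip(df["start"], df["end"])])

    def mapped_spans(self) -> list[tuple[int, int]]:
        spans = []
        for name in CLASS_NAMES:
            spans.extend(self.class_spans(name))
        return merge_spans(spans)

    def non_mapping_spans(self) -> list[tuple[int, int]]:
        """Region minus the union of all four element classes."""
        gaps = []
        cursor = self.region.start
        for s, e in self.mapped_spans():
            s = max(s, self.region.start)
            e = min(e, self.region.end)
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < self.region.end:
            gaps.append((cursor, self.region.end))
        return gaps


def build_promoters(isoforms: AnnotationSet, up: int = 1500, down: int = 500,
                    region: Interval | None = None) -> pd.DataFrame:
    """Strand-aware promoter intervals, one per isoform.

    Plus-strand TSS t maps to [t - up, t + down); minus-strand TSS t (the
    isoform end) maps to [t - down, t + up). Promoters poking out of the
    region are clipped with a warning.
    """
    df = isoforms.df
    if (~df["strand"].isin(["+", "-"])).any():
        raise ValueError("every isoform needs a '+' or '-' strand")
    rows = []
    n_clipped = 0
    for r in df.itertuples(index=False):
        if r.strand == "+":
            tss = int(r.start)
            s, e = tss - up, tss + down
        else:
            tss = int(r.end)
            s, e = tss - down, tss + up
        if region is not None:
            cs, ce = max(s, region.start), min(e, region.end)
            if (cs, ce) != (s, e):
                n_clipped += 1
            s, e = cs, ce
        if e <= s:
            continue
        rows.append((r.chrom, s, e, getattr(r, "gene", r.name),
                     getattr(r, "isoform", r.name), r.strand))
    if n_clipped:
        warnings.warn(f"build_promoters: clipped {n_clipped} promoters at region "
                      "bounds", stacklevel=2)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "isoform",
                                       "strand"])


def gene_footprints(isoforms: AnnotationSet) -> pd.DataFrame:
    """Per-gene maximum footprint: min start to max end over its isoforms."""
    df = isoforms.df
    key = "gene" if "gene" in df.columns else "name"
    grouped = df.groupby(key).agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
    )
    out = grouped.reset_index().rename(columns={key: "gene"})
    return out[["chrom", "start", "end", "gene"]]


def build_catalog(isoforms: AnnotationSet, enhancers: AnnotationSet,
                  region: Interval, up: int = 1500, down: int = 500) -> ElementCatalog:
    enh = enhancers.df
    if "source" not in enh.columns:
        raise ValueError("enhancer set needs a 'source' attribute (islet/generic)")
    return ElementCatalog(
        region=region,
        promoters=build_promoters(isoforms, up=up, down=down, region=region),
        gene_bodies=gene_footprints(isoforms),
        islet_enhancers=enh[enh["source"] == "islet"].reset_index(drop=True),
        generic_enhancers=enh[enh["source"] == "generic"].reset_index(drop=True),
    )


def _overlaps_any(pos: np.ndarray, spans: list[tuple[int, int]]) -> np.ndarray:
    """True where the 2 bp CpG footprint [pos, pos+2) overlaps any span."""
    mask = np.zeros(len(pos), dtype=bool)
    for s, e in spans:
        mask |= (pos + 2 > s) & (pos < e)
    return mask


def count_sig_cpgs_by_element(results: pd.DataFrame,
                              catalog: ElementCatalog) -> pd.DataFrame:
    """Hypo/hyper counts of significant CpGs per element class.

    Classes are non-exclusive; the ``whole_region`` row counts every
    significant CpG exactly once and the ``non_mapping`` row those CpGs
    overlapping none of the four classes.
    """
    sig = results.loc[results["significant"].to_numpy(dtype=bool)]
    pos = sig["pos"].to_numpy()
    is_hypo = (sig["direction"] == "hypo").to_numpy()
    rows = []

    def _add(name: str, mask: np.ndarray) -> None:
        nh = int((mask & is_hypo).sum())
        ny = int((mask & ~is_hypo).sum())
        tot = nh + ny
        rows.append((name, nh, ny,
                     100.0 * nh / tot if tot else np.nan,
                     100.0 * ny / tot if tot else np.nan))

    mapped = np.zeros(len(pos), dtype=bool)
    for name in CLASS_NAMES:
        m = _overlaps_any(pos, catalog.class_spans(name))
        mapped |= m
        _add(name, m)
    _add("non_mapping", ~mapped)
    _add("whole_region", np.ones(len(pos), dtype=bool))
    return pd.DataFrame(rows, columns=["element", "n_hypo", "n_hyper",
                                       "pct_hypo", "pct_hyper"])


def label_sites(tr_sites: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    """Label each binding site hypo/hyper by majority of its significant CpGs.

    Ties are labeled ``mixed``; sites with no significant constituent get an
    empty label. Returns the site frame with n_sig_hypo, n_sig_hyper and
    ``meth_label`` columns.
    """
    sig = results.loc[results["significant"].to_numpy(dtype=bool)]
    pos = sig["pos"].to_numpy()
    hypo = (sig["direction"] == "hypo").to_numpy()
    out = tr_sites.copy().reset_index(drop=True)
    n_hypo, n_hyper = [], []
    for s, e in zip(out["start"], out["end"]):
        inside = (pos + 2 > s) & (pos < e)
        n_hypo.append(int((inside & hypo).sum()))
        n_hyper.append(int((inside & ~hypo).sum()))
    out["n_sig_hypo"] = n_hypo
    out["n_sig_hyper"] = n_hyper
    out["meth_label"] = np.select(
        [out["n_sig_hypo"] > out["n_sig_hyper"],
         out["n_sig_hyper"] > out["n_sig_hypo"],
         (out["n_sig_hypo"] == out["n_sig_hyper"]) & (out["n_sig_hypo"] > 0)],
        ["hypo", "hyper", "mixed"],
        default="",
    )
    return out


def site_density_by_element(tr_sites: pd.DataFrame, catalog: ElementCatalog,
                            results: pd.DataFrame | None = None) -> pd.DataFrame:
    """Binding-site density per element class.

    Density is the summed site length clipped to the class span union,
    divided by the class union length (so splitting a class interval into
    adjacent pieces cannot change the ratio). When differential results are
    supplied, per-class hypo/hyper site counts (majority label) are added.
    """
    labeled = label_sites(tr_sites, results) if results is not None else tr_sites.copy()
    rows = []
    class_spans = {name: catalog.class_spans(name) for name in CLASS_NAMES}
    class_spans["non_mapping"] = catalog.non_mapping_spans()
    for name, spans in class_spans.items():
        total_len = union_length(spans)
        if total_len == 0:
            rows.append((name, np.nan, 0, 0, 0))
            continue
        covered = 0
        n_hypo = n_hyper = 0
        for i, (s, e) in enumerate(zip(labeled["start"], labeled["end"])):
            clip = sum(max(0, min(e, ce) - max(s, cs)) for cs, ce in spans)
            covered += clip
            if clip > 0 and results is not None:
                lab = labeled["meth_label"].iloc[i]
                if lab == "hypo":
                    n_hypo += 1
                elif lab == "hyper":
                    n_hyper += 1
        rows.append((name, covered / total_len, total_len, n_hypo, n_hyper))
    return pd.DataFrame(rows, columns=["element", "density", "element_bp",
                                       "n_hypo_sites", "n_hyper_sites"])


def signature_coverage_rank(class_intervals: dict[str, pd.DataFrame],
                            grid: WindowGrid,
                            background: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-window chromatin-signature coverage and background rank.

    For every signature class, each window's percent coverage by class
    intervals is ranked against a supplied background distribution of
    window coverages (genome-wide quantiles or a synthetic stand-in);
    windows with zero coverage are not scored. Returns a per-class summary
    with mean rank and the number of scored windows, plus the per-window
    table in the ``per_window`` attribute of the result.
    """
    missing = [k for k in class_intervals if k not in background]
    if missing:
        raise ValueError(f"no background distribution for classes: {missing}")
    per_window_rows = []
    summary_rows = []
    for cls, df in class_intervals.items():
        spans = merge_spans([(int(s), int(e)) for s, e in zip(df["start"], df["end"])])
        ranks = []
        for w, (ws, we) in enumerate(zip(grid.windows["start"], grid.windows["end"])):
            cov_bp = sum(max(0, min(we, e) - max(ws, s)) for s, e in spans)
            cov = 100.0 * cov_bp / (we - ws)
            if cov == 0:
                continue
            rank = float(percentileofscore(background[cls], cov, kind="mean"))
            ranks.append(rank)
            per_window_rows.append((cls, w, cov, rank))
        summary_rows.append((cls, float(np.mean(ranks)) if ranks else np.nan,
                             len(ranks)))
    summary = pd.DataFrame(summary_rows, columns=["class", "mean_rank",
                                                  "scored_windows"])
    summary.attrs["per_window"] = pd.DataFrame(
        per_window_rows, columns=["class", "window", "coverage_pct", "rank"]
    )
    return summary
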