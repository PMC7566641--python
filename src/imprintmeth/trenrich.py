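"""Transcriptional-regulator binding-site enrichment and classification.

Each binding site is scored by the fraction of its nucleotides covered by
CpG dinucleotides (each CpG covering [pos, pos + 2), unioned and clipped
to the site). Per regulator, site coverages are summed and regulators are
ranked (descending, average-rank ties, zero-score regulators excluded).
The analysis is run twice — against all CpGs (baseline) and against only
the significant differentially methylated CpGs — and the normalized rank
change dR = rank0/N0 - rank1/N1 measures over-enrichment (positive dR:
the regulator rose in the significant-set ranking). Per regulator, the
cumulative differential methylation dM is the mean over binding sites of
each site's mean delta over its significant constituent CpGs. Regulators
beyond the 5th/95th percentile in both dR and dM are classified
(over/under-enriched x hypo/hypermethylated).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import union_length
from .profiles import WindowGrid

__all__ = [
    "site_cpg_coverage",
    "tr_scores",
    "rank_change",
    "tr_cumulative_methylation",
    "classify_trs",
    "tr_enrichment_table",
    "map_tr_sites",
    "overlay_loop_scores",
]


def site_cpg_coverage(start: int, end: int, cpg_pos: np.ndarray) -> float:
    """Fraction of a site's nucleotides covered by CpG dinucleotides.

    CpG footprints [pos, pos+2) are unioned and clipped at the site's
    boundaries, so adjacent CpGs never double-count and a CpG straddling a
    boundary contributes only its inside base.
    """
    if end <= start:
        raise ValueError("site must have positive length")
    pos = np.asarray(cpg_pos)
    near = pos[(pos + 2 > start) & (pos < end)]
    if len(near) == 0:
        return 0.0
    spans = [(max(int(p), start), min(int(p) + 2, end)) for p in near]
    return union_length(spans) / (end - start)


def tr_scores(sites: pd.DataFrame, cpg_pos: np.ndarray,
              expressed: set[str] | None = None) -> pd.DataFrame:
    """Per-regulator summed CpG-coverage score and descending rank.

    ``sites`` needs chrom/start/end/name columns with the regulator name in
    ``name``. When an ``expressed`` set is given, regulators outside it are
    excluded before scoring. Regulators whose score is zero against the
    given CpG subset are excluded from the ranked list; the list size N is
    recorded on every row.
    """
    df = sites
    if expressed is not None:
        df = df[df["name"].isin(expressed)]
    if len(df) == 0:
        raise ValueError("empty regulator site set")
    pos = np.asarray(cpg_pos)
    cov = [
        site_cpg_coverage(int(s), int(e), pos)
        for s, e in zip(df["start"], df["end"])
    ]
    per_tr = pd.DataFrame({"tr": df["name"].to_numpy(), "coverage": cov}) \
        .groupby("tr")["coverage"].sum()
    scored = per_tr[per_tr > 0]
    ranks = rankdata(-scored.to_numpy(), method="average")
    out = pd.DataFrame({"tr": scored.index, "score": scored.to_numpy(),
                        "rank": ranks})
    out["n_ranked"] = len(out)
    return out.sort_values("rank").reset_index(drop=True)


def rank_change(baseline: pd.DataFrame, significant: pd.DataFrame) -> pd.DataFrame:
    """Normalized rank change per regulator between the two rankings.

    dR = rank_baseline/N0 - rank_significant/N1, positive when the
    regulator rose (over-enrichment). Regulators absent from the
    significant-set ranking get dR = NaN and dropped_out = True; they can
    only be under-enrichment candidates and are never classified as
    over-enriched.
    """
    b = baseline.set_index("tr")
    s = significant.set_index("tr")
    n0 = float(b["n_ranked"].iloc[0])
    n1 = float(s["n_ranked"].iloc[0])
    out = pd.DataFrame(index=b.index)
    out["rank0"] = b["rank"]
    out["score0"] = b["score"]
    out["rank1"] = s["rank"].reindex(b.index)
    out["score1"] = s["score"].reindex(b.index)
    out["delta_r"] = out["rank0"] / n0 - out["rank1"] / n1
    out["dropped_out"] = out["rank1"].isna()
    return out.reset_index()


def tr_cumulative_methylation(sites: pd.DataFrame,
                              results: pd.DataFrame) -> pd.DataFrame:
    """Per-regulator mean of per-site mean differential methylation.

    A site's mean delta averages the deltas of its significant constituent
    CpGs; sites with no significant constituent are excluded, and a
    regulator with no qualifying site gets dM = NaN (unclassifiable).
    """
    sig = results.loc[results["significant"].to_numpy(dtype=bool)]
    pos = sig["pos"].to_numpy()
    delta = sig["delta"].to_numpy()
    site_means = []
    for s, e in zip(sites["start"], sites["end"]):
        inside = (pos + 2 > s) & (pos < e)
        site_means.append(float(delta[inside].mean()) if inside.any() else np.nan)
    per_site = pd.DataFrame({"tr": sites["name"].to_numpy(),
                             "site_mean_delta": site_means})
    agg = per_site.groupby("tr")["site_mean_delta"].agg(
        delta_m="mean", n_sig_sites=lambda x: int(x.notna().sum())
    )
    return agg.reset_index()


def tr_enrichment_table(sites: pd.DataFrame, all_cpg_pos: np.ndarray,
                        results: pd.DataFrame,
                        expressed: set[str] | None = None) -> pd.DataFrame:
    """Full per-regulator record: scores, ranks, dR and dM."""
    sig_pos = results.loc[results["significant"], "pos"].to_numpy()
    baseline = tr_scores(sites, all_cpg_pos, expressed)
    sig_ranking = tr_scores(sites, sig_pos, expressed)
    rec = rank_change(baseline, sig_ranking)
    meth = tr_cumulative_methylation(
        sites if expressed is None else sites[sites["name"].isin(expressed)],
        results,
    )
    return rec.merge(meth, on="tr", how="left")


def classify_trs(records: pd.DataFrame, pct_lo: float = 5.0,
                 pct_hi: float = 95.0) -> pd.DataFrame:
    """Classify regulators by joint extremity of dR and dM.

    Cutoffs are the ``pct_lo``/``pct_hi`` percentiles of dR and of dM over
    the classifiable records. A class (e.g. ``over-enriched+hyper``) is
    assigned only when both dimensions pass a cutoff; single-dimension
    exceedances are flagged in ``enrich_extreme``/``meth_extreme`` so that
    partially extreme regulators remain identifiable.
    """
    if len(records) < 20:
        raise ValueError("need at least 20 regulator records for percentile cutoffs")
    out = records.copy()
    dr = out["delta_r"].to_numpy(dtype=float)
    dm = out["delta_m"].to_numpy(dtype=float)
    dr_ok, dm_ok = ~np.isnan(dr), ~np.isnan(dm)
    dr_lo, dr_hi = np.percentile(dr[dr_ok], [pct_lo, pct_hi])
    dm_lo, dm_hi = np.percentile(dm[dm_ok], [pct_lo, pct_hi])

    over = dr_ok & (dr > dr_hi)
    under = dr_ok & (dr < dr_lo)
    hyper = dm_ok & (dm > dm_hi)
    hypo = dm_ok & (dm < dm_lo)
    out["enrich_extreme"] = np.select([over, under], ["over", "under"], default="")
    out["meth_extreme"] = np.select([hyper, hypo], ["hyper", "hypo"], default="")
    out["tr_class"] = np.select(
        [over & hyper, over & hypo, under & hyper, under & hypo],
        ["over-enriched+hyper", "over-enriched+hypo",
         "under-enriched+hyper", "under-enriched+hypo"],
        default="unclassified",
    )
    return out


def map_tr_sites(labeled_sites: pd.DataFrame,
                 targets: pd.DataFrame) -> pd.DataFrame:
    """Per-regulator site placements over called regions or elements.

    ``labeled_sites`` is the output of
    :func:`imprintmeth.elements.label_sites`; ``targets`` needs start/end
    and a ``direction`` or ``element`` naming column. Returns per (tr,
    target): total sites, differentially methylated sites split hypo/hyper,
    and the regulator-wide fraction of differentially methylated sites.
    """
    name_col = "direction" if "direction" in targets.columns else "element"
    rows = []
    for tr, chunk in labeled_sites.groupby("name"):
        n_total = len(chunk)
        n_dm = int((chunk["meth_label"] != "").sum())
        for t_idx, t in targets.reset_index(drop=True).iterrows():
            inside = chunk[(chunk["start"] < t["end"]) & (chunk["end"] > t["start"])]
            rows.append(
                {
                    "tr": tr,
                    "target": f"{t[name_col]}_{t_idx}",
                    "n_sites": len(inside),
                    "n_dm_hypo": int((inside["meth_label"] == "hypo").sum()),
                    "n_dm_hyper": int((inside["meth_label"] == "hyper").sum()),
                    "frac_dm_overall": n_dm / n_total if n_total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def overlay_loop_scores(track: pd.DataFrame, window_counts: pd.DataFrame,
                        grid: WindowGrid) -> tuple[pd.DataFrame, int]:
    """Join raw chromatin-loop scores onto per-window site counts.

    Loop scores stay at their native coordinates (never window-averaged or
    normalized); each in-region score row gains the id and counts of the
    window it falls in. Returns (joined table, number of out-of-region
    scores dropped).
    """
    if (track["score"] < 0).any():
        raise ValueError("loop scores must be non-negative")
    pos = track["pos"].to_numpy()
    widx = grid.assign(pos)
    keep = widx >= 0
    n_dropped = int((~keep).sum())
    joined = track[keep].copy()
    joined["window"] = widx[keep]
    for col in window_counts.columns:
        if col.startswith("n_"):
            joined[col] = window_counts[col].to_numpy()[widx[keep]]
    return joined.reset_index(drop=True), n_dropped
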