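"""Per-CpG differential methylation testing and derived structures.

The test is a beta-binomial likelihood-ratio test of a shared versus a
cohort-specific methylation proportion at each CpG. Counts m ~ BB(n, p, rho)
with a per-site dispersion rho estimated by method of moments and shrunk
50/50 toward the across-site median; the likelihood ratio is referred to a
chi-squared distribution with one degree of freedom and p-values are
corrected by Benjamini-Hochberg FDR across all tested sites. Sites where
either cohort has fewer than two covered samples are reported as untested,
never as p = 1.

DMRs are runs of significant CpGs chained when consecutive significant
sites lie within a bandwidth of each other (default 1000 bp), kept when
they have at least ``min_cpgs`` constituents; since every constituent is
itself significant, the maximum constituent FDR of a DMR is below the
site-level threshold by construction (and is still recorded and enforced).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import betaln
from statsmodels.stats.multitest import multipletests

from .core import MethCallTable

__all__ = [
    "test_cpgs",
    "call_dmrs",
    "group_signature",
    "SignatureSet",
    "direction_signature_association",
    "sample_distance_cluster",
]

_RHO_FLOOR = 1e-6
_RHO_CAP = 0.5


def _bb_loglik(p: np.ndarray, meth: np.ndarray, total: np.ndarray,
               rho: np.ndarray) -> np.ndarray:
    """Beta-binomial log-likelihood per site, summed over samples.

    ``p`` and ``rho`` broadcast over sites; cells with total == 0 contribute
    exactly zero. Binomial-coefficient terms are omitted (they cancel in
    likelihood ratios).
    """
    conc = (1.0 - rho) / rho
    a = p * conc
    b = (1.0 - p) * conc
    ll = betaln(meth + a[None, :], total - meth + b[None, :]) - betaln(a, b)[None, :]
    return ll.sum(axis=0)


def _bb_mle_p(meth: np.ndarray, total: np.ndarray, rho: np.ndarray,
              iters: int = 80) -> np.ndarray:
    """Vectorized golden-section maximization of the BB likelihood over p."""
    lo = np.full(rho.shape, 1e-4)
    hi = np.full(rho.shape, 1.0 - 1e-4)
    inv_phi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - inv_phi * (hi - lo)
    x2 = lo + inv_phi * (hi - lo)
    f1 = _bb_loglik(x1, meth, total, rho)
    f2 = _bb_loglik(x2, meth, total, rho)
    for _ in range(iters):
        left = f1 >= f2  # maximum lies in [lo, x2]
        hi = np.where(left, x2, hi)
        lo = np.where(left, lo, x1)
        new_x1 = np.where(left, hi - inv_phi * (hi - lo), x2)
        new_x2 = np.where(left, x1, lo + inv_phi * (hi - lo))
        probe = np.where(left, new_x1, new_x2)
        fp = _bb_loglik(probe, meth, total, rho)
        new_f1 = np.where(left, fp, f2)
        new_f2 = np.where(left, f1, fp)
        x1, x2, f1, f2 = new_x1, new_x2, new_f1, new_f2
    return (lo + hi) / 2.0


def _mom_dispersion(meth: np.ndarray, total: np.ndarray,
                    cohort_masks: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments dispersion per site, pooled across cohorts."""
    n_sites = meth.shape[1]
    x2 = np.zeros(n_sites)
    df_resid = np.zeros(n_sites)
    denom = np.zeros(n_sites)
    for mask in cohort_masks:
        m = meth[mask]
        n = total[mask]
        covered = n > 0
        n_tot = n.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_tot > 0, m.sum(axis=0) / np.maximum(n_tot, 1), np.nan)
        pq = p * (1.0 - p)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = (m - n * p[None, :]) ** 2 / (n * pq[None, :])
        contrib = np.where(covered & np.isfinite(contrib), contrib, 0.0)
        x2 += contrib.sum(axis=0)
        k = covered.sum(axis=0)
        df_resid += np.maximum(k - 1, 0)
        denom += np.where(covered, n - 1, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (x2 - df_resid) / denom
    rho = np.where(np.isfinite(rho), rho, 0.0)
    return np.clip(rho, _RHO_FLOOR, _RHO_CAP)


def test_cpgs(table: MethCallTable, case: str = "insulinoma",
              control: str = "beta", fdr_threshold: float = 0.005,
              shrink: float = 0.5) -> pd.DataFrame:
    """Beta-binomial LRT of cohort-specific methylation at every CpG.

    Returns one row per site: per-cohort mean beta, ``delta`` (case minus
    control, fraction units), the LRT ``statistic``, ``p``, BH ``fdr``,
    a ``significant`` flag at ``fdr_threshold`` and a ``direction`` in
    {hypo, hyper} for significant sites. ``tested`` is False where either
    cohort had fewer than two covered samples.
    """
    case_mask = table.cohort_mask(case)
    ctrl_mask = table.cohort_mask(control)
    if case_mask.sum() == 0 or ctrl_mask.sum() == 0:
        raise ValueError(f"cohorts {case!r}/{control!r} not found in table")

    meth, total = table.meth, table.total
    beta = table.beta
    with np.errstate(invalid="ignore"):
        mean_case = np.nanmean(np.where(case_mask[:, None], beta, np.nan), axis=0)
        mean_ctrl = np.nanmean(np.where(ctrl_mask[:, None], beta, np.nan), axis=0)
    delta = mean_case - mean_ctrl

    informative_case = (total[case_mask] > 0).sum(axis=0)
    informative_ctrl = (total[ctrl_mask] > 0).sum(axis=0)
    tested = (informative_case >= 2) & (informative_ctrl >= 2)

    rho_raw = _mom_dispersion(meth, total, [case_mask, ctrl_mask])
    rho_med = float(np.median(rho_raw[tested])) if tested.any() else _RHO_FLOOR
    rho = np.clip((1.0 - shrink) * rho_raw + shrink * rho_med, _RHO_FLOOR, _RHO_CAP)

    p0 = _bb_mle_p(meth, total, rho)
    ll0 = _bb_loglik(p0, meth, total, rho)
    p_case = _bb_mle_p(meth[case_mask], total[case_mask], rho)
    ll_case = _bb_loglik(p_case, meth[case_mask], total[case_mask], rho)
    p_ctrl = _bb_mle_p(meth[ctrl_mask], total[ctrl_mask], rho)
    ll_ctrl = _bb_loglik(p_ctrl, meth[ctrl_mask], total[ctrl_mask], rho)

    statistic = np.maximum(2.0 * (ll_case + ll_ctrl - ll0), 0.0)
    pvals = stats.chi2.sf(statistic, df=1)

    fdr = np.full(len(pvals), np.nan)
    significant = np.zeros(len(pvals), dtype=bool)
    if tested.any():
        _, q, _, _ = multipletests(pvals[tested], method="fdr_bh")
        fdr[tested] = q
        significant[tested] = q < fdr_threshold
    direction = np.where(significant, np.where(delta < 0, "hypo", "hyper"), "")

    out = pd.DataFrame(
        {
            "chrom": table.sites["chrom"].to_numpy(),
            "pos": table.sites["pos"].to_numpy(),
            "mean_beta_case": mean_case,
            "mean_beta_control": mean_ctrl,
            "delta": delta,
            "dispersion": rho,
            "statistic": np.where(tested, statistic, np.nan),
            "p": np.where(tested, pvals, np.nan),
            "fdr": fdr,
            "tested": tested,
            "significant": significant,
            "direction": direction,
        },
        index=table.sites.index,
    )
    return out


def call_dmrs(results: pd.DataFrame, bandwidth: int = 1000, min_cpgs: int = 3,
              max_fdr: float = 0.005) -> pd.DataFrame:
    """Chain significant CpGs within ``bandwidth`` into DMRs.

    Chaining is direction-aware: a run of hypomethylated CpGs and a run of
    hypermethylated CpGs are distinct DMRs even when interleaved within the
    bandwidth, so each DMR is pure in direction. Each DMR spans
    first-to-last constituent plus one base (half-open) and records its
    constituent site ids, maximum constituent FDR and mean delta. Chains
    shorter than ``min_cpgs`` or with a maximum constituent FDR at or above
    ``max_fdr`` are dropped.
    """
    sig = results.loc[results["significant"].to_numpy(dtype=bool)].sort_values("pos")
    rows = []
    for (chrom, _direction), chunk in sig.groupby(["chrom", "direction"], sort=True):
        pos = chunk["pos"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > bandwidth)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            members = chunk.iloc[s:e]
            if len(members) < min_cpgs:
                continue
            worst = float(members["fdr"].max())
            if worst >= max_fdr:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(members["pos"].iloc[0]),
                    "end": int(members["pos"].iloc[-1]) + 1,
                    "n_cpgs": len(members),
                    "site_ids": list(members.index),
                    "max_fdr": worst,
                    "mean_delta": float(members["delta"].mean()),
                    "direction": _direction,
                }
            )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_cpgs", "site_ids", "max_fdr",
                       "mean_delta", "direction"],
    )
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class SignatureSet:
    """Intermediate and final products of the five-step signature procedure."""

    retained: dict[str, np.ndarray]        # step 1: per-group surviving site ids
    measurable: np.ndarray                 # step 2: measurable in all groups
    group_mean_delta: pd.DataFrame         # step 3: per-group mean differential
    cross_group_sd: pd.Series              # step 4: SD of group means
    signature_ids: np.ndarray              # step 5: above the percentile cutoff
    sd_threshold: float


def group_signature(table: MethCallTable, control: str = "beta",
                    pct: float = 95.0) -> SignatureSet:
    """Five-step extraction of sub-group signature CpGs.

    (1) within each tumor sub-group, drop CpGs whose per-sample differential
    methylation (sample beta minus the mean reference beta) has a standard
    deviation above the group's ``pct`` percentile; (2) keep CpGs measurable
    in all three groups; (3) per group, average the differential; (4) take
    the standard deviation of the three group means; (5) call CpGs above the
    ``pct`` percentile of that SD the signature. Percentiles use the
    linear-interpolation convention throughout.
    """
    beta = table.beta
    ctrl = table.cohort_mask(control)
    ref = np.nanmean(np.where(ctrl[:, None], beta, np.nan), axis=0)

    groups = sorted(
        g for g in table.samples.loc[~ctrl, "group"].unique() if g not in ("", None)
    )
    if len(groups) < 2:
        raise ValueError("need at least two tumor sub-groups")

    retained: dict[str, np.ndarray] = {}
    group_means: dict[str, np.ndarray] = {}
    for g in groups:
        mask = (table.samples["group"] == g).to_numpy() & ~ctrl
        if mask.sum() < 2:
            raise ValueError(f"sub-group {g!r} has fewer than two samples")
        diff = beta[mask] - ref[None, :]
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(diff, axis=0, ddof=1)
            mean = np.nanmean(diff, axis=0)
        measurable_g = ~np.isnan(sd)
        cutoff = float(np.percentile(sd[measurable_g], pct)) if measurable_g.any() else np.inf
        keep = measurable_g & (sd <= cutoff)
        retained[g] = np.flatnonzero(keep)
        mean[~keep] = np.nan
        group_means[g] = mean

    mat = pd.DataFrame(group_means, index=table.sites.index)
    measurable = np.flatnonzero(mat.notna().all(axis=1).to_numpy())
    with np.errstate(invalid="ignore"):
        sd_across = mat.std(axis=1, ddof=1)
    eligible_sd = sd_across.iloc[measurable]
    threshold = float(np.percentile(eligible_sd.to_numpy(), pct))
    signature = eligible_sd.index[eligible_sd.to_numpy() > threshold].to_numpy()
    return SignatureSet(
        retained=retained,
        measurable=measurable,
        group_mean_delta=mat,
        cross_group_sd=sd_across,
        signature_ids=np.sort(signature),
        sd_threshold=threshold,
    )


def direction_signature_association(results: pd.DataFrame,
                                    signature_ids: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared (no continuity correction) of direction vs signature.

    Builds the 2x2 table {hypo, hyper} x {in signature, not} over significant
    CpGs and returns (chi2, df, p).
    """
    sig = results.loc[results["significant"].to_numpy(dtype=bool)]
    if len(sig) == 0:
        raise ValueError("no significant CpGs")
    in_sig = sig.index.isin(signature_ids)
    is_hypo = (sig["direction"] == "hypo").to_numpy()
    tab = np.array(
        [
            [int((is_hypo & in_sig).sum()), int((is_hypo & ~in_sig).sum())],
            [int((~is_hypo & in_sig).sum()), int((~is_hypo & ~in_sig).sum())],
        ]
    )
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table (empty margin)")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(df), float(p)


def sample_distance_cluster(table: MethCallTable, k: int | None = None):
    """Ward clustering of samples on 1 - Pearson correlation distance.

    Correlations are pairwise complete over covered cells. Returns the
    linkage matrix and, when ``k`` is given, flat cluster labels indexed by
    sample (ties broken deterministically by sample order in the table).
    """
    if table.n_samples < 3:
        raise ValueError("need at least three samples to cluster")
    beta = pd.DataFrame(table.beta.T, columns=table.samples.index)
    corr = beta.corr(method="pearson", min_periods=2)
    dist = (1.0 - corr).to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="ward")
    if k is None:
        return z, None
    labels = pd.Series(fcluster(z, t=k, criterion="maxclust"),
                       index=table.samples.index, name="cluster")
    return z, labels
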