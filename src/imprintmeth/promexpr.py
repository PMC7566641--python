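"""Promoter methylation index versus gene expression.

Methylation fractions are moved to the M-value (logit) scale,
M = log2(beta / (1 - beta)), which is directly comparable with log2
expression fold changes. Per gene, one promoter isoform is selected —
the one whose methylation/expression log-fold-change ratio is closest
to 1 — and genes are classified by the concordance of their promoter
methylation and expression changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Interval, MethCallTable

__all__ = [
    "methylation_index",
    "promoter_m_lfc",
    "select_isoform",
    "classify_gene",
    "gene_classification_table",
]

CATEGORIES = [
    "significant-opposite",
    "opposite-nonsignificant",
    "concordant",
    "expression-only",
    "methylation-only",
]


def methylation_index(beta, eps: float = 0.01):
    """M-value of a methylation fraction: log2(b / (1 - b)).

    ``beta`` must lie in [0, 1]; values are clamped to [eps, 1 - eps] before
    the logit so that fully (un)methylated sites stay finite.
    """
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    return float(m) if np.isscalar(beta) else m


def promoter_m_lfc(table: MethCallTable, promoter: Interval,
                   case: str = "insulinoma", control: str = "beta",
                   eps: float = 0.01) -> float | None:
    """Methylation-index log-fold change of a promoter between cohorts.

    The promoter beta per cohort is the unweighted mean of the cohort-mean
    betas of its constituent CpGs; the M-LFC is M(case) - M(control).
    Returns None when the promoter has no CpG measurable in both cohorts.
    """
    pos = table.sites["pos"].to_numpy()
    inside = (table.sites["chrom"].to_numpy() == promoter.chrom) & \
        (pos + 2 > promoter.start) & (pos < promoter.end)
    if not inside.any():
        return None
    beta = table.beta[:, inside]
    case_rows = table.cohort_mask(case)
    ctrl_rows = table.cohort_mask(control)
    with np.errstate(invalid="ignore"):
        mean_case = np.nanmean(beta[case_rows], axis=0)
        mean_ctrl = np.nanmean(beta[ctrl_rows], axis=0)
    ok = ~np.isnan(mean_case) & ~np.isnan(mean_ctrl)
    if not ok.any():
        return None
    b_case = float(mean_case[ok].mean())
    b_ctrl = float(mean_ctrl[ok].mean())
    return methylation_index(b_case, eps) - methylation_index(b_ctrl, eps)


def select_isoform(m_lfcs: pd.Series, expr_lfc: float) -> str:
    """Pick the promoter isoform whose M-LFC / expression-LFC ratio is
    closest to 1 (deterministic tie-break: first isoform in order).

    With a zero expression fold change the ratio is undefined; the isoform
    with the largest absolute M-LFC is returned instead.
    """
    m_lfcs = m_lfcs.dropna()
    if len(m_lfcs) == 0:
        raise ValueError("no isoform with a methylation log-fold change")
    if expr_lfc == 0:
        score = -m_lfcs.abs()
    else:
        score = (m_lfcs / expr_lfc - 1.0).abs()
    # idxmin on ties returns the first occurrence, our stated tie-break
    return score.idxmin()


def classify_gene(m_lfc: float | None, expr_lfc: float | None,
                  expr_significant: bool) -> str:
    """Concordance category of one gene's methylation and expression changes."""
    has_m = m_lfc is not None and np.isfinite(m_lfc)
    has_e = expr_lfc is not None and expr_lfc == expr_lfc
    if has_m and not has_e:
        return "methylation-only"
    if has_e and not has_m:
        return "expression-only"
    if not has_m and not has_e:
        raise ValueError("gene has neither methylation nor expression data")
    opposite = np.sign(m_lfc) != np.sign(expr_lfc) and m_lfc != 0 and expr_lfc != 0
    if opposite:
        return "significant-opposite" if expr_significant else "opposite-nonsignificant"
    return "concordant"


def gene_classification_table(table: MethCallTable, promoters: pd.DataFrame,
                              expression: pd.DataFrame,
                              case: str = "insulinoma", control: str = "beta",
                              eps: float = 0.01) -> pd.DataFrame:
    """Per-gene promoter-methylation vs expression summary (scatter-ready).

    ``promoters`` is the per-isoform frame from
    :func:`imprintmeth.elements.build_promoters`; ``expression`` carries
    gene, log2fc and significant columns. Output rows: gene, the selected
    isoform, M-LFC, expression log2fc, significance flag, and category.
    """
    expr = expression.set_index("gene")
    rows = []
    genes = sorted(set(promoters["gene"]) | set(expr.index))
    for gene in genes:
        iso_rows = promoters[promoters["gene"] == gene]
        m_by_iso = pd.Series(
            {
                r.isoform: promoter_m_lfc(
                    table,
                    Interval(r.chrom, int(r.start), int(r.end)),
                    case=case, control=control, eps=eps,
                )
                for r in iso_rows.itertuples(index=False)
            },
            dtype=float,
        )
        has_m = m_by_iso.notna().any()
        has_e = gene in expr.index
        e_lfc = float(expr.at[gene, "log2fc"]) if has_e else None
        e_sig = bool(expr.at[gene, "significant"]) if has_e else False
        if has_m:
            if has_e:
                iso = select_isoform(m_by_iso, e_lfc)
            else:
                iso = m_by_iso.abs().idxmax()
            m_lfc = float(m_by_iso[iso])
        else:
            iso, m_lfc = "", None
        if not has_m and not has_e:
            continue
        rows.append(
            {
                "gene": gene,
                "isoform": iso,
                "m_lfc": m_lfc if m_lfc is not None else np.nan,
                "expr_log2fc": e_lfc if e_lfc is not None else np.nan,
                "expr_significant": e_sig,
                "category": classify_gene(m_lfc, e_lfc, e_sig),
            }
        )
    return pd.DataFrame(rows)
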