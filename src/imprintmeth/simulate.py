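"""Synthetic bisulfite-count cohorts with planted differential methylation.

The generator emulates a targeted deep-bisulfite study of a 1.35 Mbp
imprinted region: ~30,000 CpGs, beta-binomial read counts at ~22x mean
depth, a small reference cohort of purified beta cells (n=5) against a
larger tumor cohort (n=19), broad tumor hypomethylation punctuated by
focal hypermethylated blocks that carry islet-specific enhancers and the
binding sites of an islet master regulator, plus three tumor sub-groups
with planted signature CpGs. ATAC open-chromatin peak scores are generated
inversely proportional to local reference methylation, and a differential
expression table is emitted that is deliberately decoupled from promoter
methylation for most genes.

Every planted parameter is recorded in a :class:`SyntheticTruth` bundle so
downstream recovery can be measured against ground truth.

The default configuration is paper-shaped (1.35 Mb / ~30k CpGs); the
:meth:`SimConfig.scaled` configuration shrinks the region tenfold (135 kb,
~3,000 CpGs, 1 kb windows) so the whole pipeline runs in seconds while
keeping per-site depth, cohort sizes and effect sizes unchanged — per-CpG
statistical behavior is therefore identical to the full-size configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnnotationSet, Interval, MethCallTable

__all__ = ["SimConfig", "SyntheticTruth", "simulate_region", "simulate_counts",
           "simulate_expression", "simulate_bundle"]

# (relative start, relative end) block layouts, as fractions of region length;
# blocks are aligned to window boundaries by construction below.
_HYPER_BLOCK_FRACS = [(0.20, 0.222), (0.44, 0.462), (0.72, 0.742)]
_HYPO_BLOCK_FRACS = [(0.09, 0.127), (0.57, 0.607)]


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Deltas are in methylation-fraction units and are applied to the tumor
    cohort relative to the reference (beta-cell) landscape; expected betas
    are clamped to [0.02, 0.98] after all shifts.
    """

    chrom: str = "chr11"
    region_start: int = 1_850_000
    region_length: int = 1_350_000
    cpg_density_per_kb: float = 22.7      # ~30.6k CpGs over 1.35 Mb
    window_width: int = 10_000

    n_beta: int = 5
    n_insulinoma: int = 19
    group_sizes: tuple[int, int, int] = (8, 6, 5)

    mean_depth: float = 22.0              # negative-binomial mean
    depth_size: float = 5.0               # negative-binomial size (dispersion)
    bio_dispersion: float = 0.015         # beta-binomial intra-class correlation

    # levels chosen so the tumor-side binomial variance p(1-p) is nearly
    # uniform across gene loci and background (0.30 vs 0.77), keeping the
    # within-group spread of the signature procedure homogeneous
    bg_high: float = 0.80                 # methylated background
    bg_low: float = 0.35                  # low-methylation gene loci
    hyper_block_base: float = 0.45        # reference level inside hyper blocks
    broad_hypo_delta: float = -0.03       # region-wide tumor hypomethylation
    gene_hypo_delta: float = -0.05        # extra tumor hypomethylation at gene loci
    hyper_block_delta: float = 0.30       # focal tumor hypermethylation
    hypo_block_delta: float = -0.70       # focal near-total tumor methylation loss
    # At each sub-group's signature CpGs the OTHER sub-groups lose
    # methylation by this amount while the group itself retains the normal
    # level: the group is distinguished by escaping the shared loss. This
    # yields a large across-group spread, keeps every group's within-group
    # variance typical, and still shifts the whole-cohort mean (so
    # signature CpGs and overall differential methylation stay associated).
    signature_deltas: tuple[float, float, float] = (-0.60, -0.60, -0.60)
    n_signature_per_group: int = 40
    signature_block_guard: int = 2_000    # min distance from any planted block
    # CpG-poor shores flanking each planted block, emulating the sparse
    # background around CpG-dense islands/enhancer clusters; wider than the
    # default DMR chaining bandwidth so block DMRs end at block edges
    block_flank_gap: int = 1_200

    n_genes: int = 14
    gene_width: int = 50_000
    max_isoforms: int = 3

    # The planted regulators get few sites (low summed-coverage score, so
    # they sit at the bottom of the baseline ranking) that lie entirely in
    # planted blocks (full significant-set coverage, so they rise to the
    # top of the significant-set ranking); background regulators get more
    # sites, scattered outside the blocks.
    n_background_trs: int = 40
    planted_tr_sites: int = 10
    planted_tr_site_len: int = 400
    background_tr_sites: tuple[int, int] = (20, 50)
    background_tr_site_len: int = 200
    n_islet_enhancers_per_block: int = 2
    n_generic_enhancers: int = 12
    enhancer_width: int = 600
    n_atac_samples: int = 4

    nfat_like_lfc: float = 3.0            # overexpressed alternate driver
    pdx_like_lfc: float = -1.5            # downregulated canonical driver
    expr_lfc_mean: float = -1.0           # broad tumor downregulation of region genes
    expr_lfc_sd: float = 1.2
    expr_sig_cutoff: float = 1.0

    @classmethod
    def scaled(cls, **overrides) -> "SimConfig":
        """Tenfold-reduced desk-scale configuration (135 kb, 1 kb windows)."""
        base = dict(
            region_length=135_000,
            window_width=1_000,
            gene_width=5_000,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """Scaled configuration with every planted effect set to zero."""
        base = dict(
            broad_hypo_delta=0.0,
            gene_hypo_delta=0.0,
            hyper_block_delta=0.0,
            hypo_block_delta=0.0,
            signature_deltas=(0.0, 0.0, 0.0),
        )
        base.update(overrides)
        return cls.scaled(**base)

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_insulinoma:
            raise ValueError("sub-group sizes must sum to n_insulinoma")
        if self.region_length <= 0 or self.window_width <= 0:
            raise ValueError("region_length and window_width must be positive")
        for delta, base in [
            (self.hyper_block_delta, self.hyper_block_base),
            (self.broad_hypo_delta, self.bg_high),
            (self.hypo_block_delta, self.bg_high),
        ]:
            if not 0.0 <= base + delta <= 1.0:
                raise ValueError("planted delta drives expected beta outside [0, 1]")

    @property
    def region(self) -> Interval:
        return Interval(self.chrom, self.region_start,
                        self.region_start + self.region_length)

    @property
    def beta_samples(self) -> list[str]:
        return [f"Beta_{i + 1}" for i in range(self.n_beta)]

    @property
    def insulinoma_samples(self) -> list[str]:
        return [f"Ins_{i + 1}" for i in range(self.n_insulinoma)]

    def sample_sheet(self) -> pd.DataFrame:
        groups = []
        for g, size in enumerate(self.group_sizes, start=1):
            groups.extend([f"G{g}"] * size)
        sheet = pd.DataFrame(
            {
                "sample": self.beta_samples + self.insulinoma_samples,
                "cohort": ["beta"] * self.n_beta + ["insulinoma"] * self.n_insulinoma,
                "group": [""] * self.n_beta + groups,
            }
        )
        return sheet


@dataclass
class SyntheticTruth:
    """The planted parameters, for downstream recovery tests."""

    hyper_blocks: list[Interval]
    hypo_blocks: list[Interval]
    signature_sites: dict[str, list[int]]     # group -> site ids
    tr_classes: dict[str, str]                # TR name -> planted class
    expression_lfc: dict[str, float]

    def to_json(self) -> str:
        payload = {
            "hyper_blocks": [[iv.chrom, iv.start, iv.end] for iv in self.hyper_blocks],
            "hypo_blocks": [[iv.chrom, iv.start, iv.end] for iv in self.hypo_blocks],
            "signature_sites": self.signature_sites,
            "tr_classes": self.tr_classes,
            "expression_lfc": self.expression_lfc,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            hyper_blocks=[Interval(c, s, e) for c, s, e in d["hyper_blocks"]],
            hypo_blocks=[Interval(c, s, e) for c, s, e in d["hypo_blocks"]],
            signature_sites={k: list(v) for k, v in d["signature_sites"].items()},
            tr_classes=d["tr_classes"],
            expression_lfc=d["expression_lfc"],
        )


def _snap(x: float, width: int) -> int:
    return int(round(x / width)) * width


def _block_intervals(config: SimConfig, fracs) -> list[Interval]:
    region = config.region
    out = []
    for lo, hi in fracs:
        start = region.start + _snap(lo * config.region_length, config.window_width)
        end = region.start + _snap(hi * config.region_length, config.window_width)
        if end <= start or end > region.end:
            raise ValueError("planted block does not fit inside the region")
        out.append(Interval(config.chrom, start, end))
    return out


def _in_any(pos: np.ndarray, blocks: list[Interval]) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for iv in blocks:
        mask |= (pos >= iv.start) & (pos < iv.end)
    return mask


def _draw_positions(rng: np.random.Generator, region: Interval, n: int) -> np.ndarray:
    """Distinct CpG positions at least 2 bp apart, sorted."""
    pos = np.sort(rng.choice(region.length - 2, size=min(n * 2, region.length // 3),
                             replace=False))
    keep = np.concatenate([[True], np.diff(pos) >= 2])
    pos = pos[keep]
    if len(pos) > n:  # thin evenly so density stays uniform across the region
        pos = pos[np.sort(rng.choice(len(pos), size=n, replace=False))]
    return pos + region.start


def simulate_region(config: SimConfig, seed: int):
    """Generate CpG sites, the annotation stack, and the planted truth.

    Returns ``(sites, annotations, truth)`` where ``annotations`` is a dict
    of :class:`AnnotationSet` keyed by gene_isoform, enhancer, tr_site and
    atac_peak. ATAC peaks are produced per pseudo-sample, with scores
    inversely tied to the reference methylation landscape of each window.
    """
    rng = np.random.default_rng(seed)
    region = config.region

    hyper_blocks = _block_intervals(config, _HYPER_BLOCK_FRACS)
    hypo_blocks = _block_intervals(config, _HYPO_BLOCK_FRACS)
    blocks = hyper_blocks + hypo_blocks

    n_cpgs = int(round(config.region_length / 1000 * config.cpg_density_per_kb))
    pos = _draw_positions(rng, region, n_cpgs)
    # carve CpG-poor shores around every planted block
    flank = config.block_flank_gap
    shores = []
    for b in blocks:
        shores.append(Interval(b.chrom, max(b.start - flank, region.start), b.start))
        shores.append(Interval(b.chrom, b.end, min(b.end + flank, region.end)))
    pos = pos[~_in_any(pos, shores)]
    sites = pd.DataFrame({"chrom": config.chrom, "pos": pos})
    sites.index.name = "site"

    # --- genes: footprints in the gaps between planted blocks, isoforms with
    # shared and distinct TSSs on alternating strands
    gene_rows = []
    slots = np.linspace(region.start + config.gene_width,
                        region.end - 2 * config.gene_width, config.n_genes)
    gene_names = [f"GENE{g + 1:02d}" for g in range(config.n_genes)]
    # genes (and hence their 1.5 kb-upstream promoters) must keep clear of
    # planted blocks so element classes stay directionally pure
    promoter_reach = 1_600
    avoid = [
        Interval(b.chrom, max(b.start - promoter_reach, region.start),
                 min(b.end + promoter_reach, region.end))
        for b in blocks
    ]
    for g, left in enumerate(slots):
        start = int(left)
        gene_iv = Interval(config.chrom, start, start + config.gene_width)
        while any(gene_iv.overlaps(b) for b in avoid):
            start += config.window_width
            gene_iv = Interval(config.chrom, start, start + config.gene_width)
        strand = "+" if g % 2 == 0 else "-"
        n_iso = int(rng.integers(1, config.max_isoforms + 1))
        for k in range(n_iso):
            jitter = int(rng.integers(0, max(config.gene_width // 4, 1)))
            if strand == "+":
                s = gene_iv.start + jitter
                e = gene_iv.end
            else:
                s = gene_iv.start
                e = gene_iv.end - jitter
            gene_rows.append((config.chrom, s, e, gene_names[g], 0.0, strand,
                              gene_names[g], f"{gene_names[g]}.{k + 1}"))
    isoforms = AnnotationSet(
        "gene_isoform",
        pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name", "score",
                                         "strand", "gene", "isoform"]),
    )
    gene_footprints = {
        name: Interval(config.chrom,
                       int(isoforms.df.loc[isoforms.df["gene"] == name, "start"].min()),
                       int(isoforms.df.loc[isoforms.df["gene"] == name, "end"].max()))
        for name in gene_names
    }

    # --- enhancers: islet-specific inside hyper blocks, generic elsewhere
    enh_rows = []
    for block in hyper_blocks:
        for _ in range(config.n_islet_enhancers_per_block):
            s = int(rng.integers(block.start, block.end - config.enhancer_width))
            enh_rows.append((config.chrom, s, s + config.enhancer_width,
                             "islet_enh", 0.0, ".", "islet"))
    placed = 0
    while placed < config.n_generic_enhancers:
        s = int(rng.integers(region.start, region.end - config.enhancer_width))
        iv = Interval(config.chrom, s, s + config.enhancer_width)
        if any(iv.overlaps(b) for b in blocks):
            continue
        enh_rows.append((config.chrom, s, s + config.enhancer_width,
                         "generic_enh", 0.0, ".", "generic"))
        placed += 1
    enhancers = AnnotationSet(
        "enhancer",
        pd.DataFrame(enh_rows, columns=["chrom", "start", "end", "name", "score",
                                        "strand", "source"]),
    )

    # --- transcriptional regulator binding sites. The PDX1-like regulator is
    # confined to hyper blocks and the NFATC1-like regulator to hypo blocks;
    # background regulators are scattered outside all planted blocks. Planted
    # sites are longer (hence lower baseline CpG-coverage rank) so that their
    # rise in the significant-set ranking is the planted signal.
    tr_rows = []

    def _place_in(block_list, name, n_sites, length):
        lens = np.array([b.length for b in block_list], dtype=float)
        for _ in range(n_sites):
            b = block_list[rng.choice(len(block_list), p=lens / lens.sum())]
            s = int(rng.integers(b.start, b.end - length))
            tr_rows.append((config.chrom, s, s + length, name, 0.0, "."))

    _place_in(hyper_blocks, "PDX1L", config.planted_tr_sites, config.planted_tr_site_len)
    _place_in(hypo_blocks, "NFATC1L", config.planted_tr_sites, config.planted_tr_site_len)
    lo, hi = config.background_tr_sites
    for t in range(config.n_background_trs):
        name = f"TR{t + 3:03d}"
        n_sites = int(rng.integers(lo, hi + 1))
        placed = 0
        while placed < n_sites:
            s = int(rng.integers(region.start, region.end - config.background_tr_site_len))
            iv = Interval(config.chrom, s, s + config.background_tr_site_len)
            if any(iv.overlaps(b) for b in blocks):
                continue
            tr_rows.append((config.chrom, s, s + config.background_tr_site_len,
                            name, 0.0, "."))
            placed += 1
    tr_sites = AnnotationSet(
        "tr_site",
        pd.DataFrame(tr_rows, columns=["chrom", "start", "end", "name", "score",
                                       "strand"]),
    )

    # --- ATAC peaks, one pseudo-sample at a time; peak score decreases with
    # the local reference methylation level of the window it sits in
    p_beta = _reference_landscape(config, pos, hyper_blocks, list(gene_footprints.values()))
    n_windows = -(-config.region_length // config.window_width)
    atac_rows = []
    for a in range(config.n_atac_samples):
        sample = f"ATAC_{a + 1}"
        for w in range(n_windows):
            w_start = region.start + w * config.window_width
            w_end = min(w_start + config.window_width, region.end)
            in_w = (pos >= w_start) & (pos < w_end)
            level = float(p_beta[in_w].mean()) if in_w.any() else config.bg_high
            score = (1.05 - level) * float(rng.uniform(0.9, 1.1))
            peak_len = config.window_width // 4
            s = w_start + (w_end - w_start - peak_len) // 2
            atac_rows.append((config.chrom, s, s + peak_len, sample, score, ".",
                              sample))
    atac = AnnotationSet(
        "atac_peak",
        pd.DataFrame(atac_rows, columns=["chrom", "start", "end", "name", "score",
                                         "strand", "sample"]),
    )

    # --- signature CpG sets per tumor sub-group. Drawn from the methylated
    # background outside planted blocks (plus a guard margin, so signature
    # CpGs cannot chain into block DMRs) and outside gene loci, so the
    # shifts survive the [0, 1] clamp intact.
    guard = config.signature_block_guard
    guarded = [
        Interval(b.chrom, max(b.start - guard, region.start),
                 min(b.end + guard, region.end))
        for b in blocks
    ]
    outside = np.flatnonzero(
        ~_in_any(pos, guarded) & ~_in_any(pos, list(gene_footprints.values()))
    )
    n_sig = config.n_signature_per_group
    chosen = rng.choice(outside, size=3 * n_sig, replace=False)
    signature_sites = {
        f"G{g + 1}": sorted(int(i) for i in chosen[g * n_sig:(g + 1) * n_sig])
        for g in range(3)
    }

    expr = simulate_expression(gene_names, config, seed)
    truth = SyntheticTruth(
        hyper_blocks=hyper_blocks,
        hypo_blocks=hypo_blocks,
        signature_sites=signature_sites,
        tr_classes={"PDX1L": "over-enriched+hyper", "NFATC1L": "over-enriched+hypo"},
        expression_lfc=dict(zip(expr["gene"], expr["log2fc"])),
    )
    annotations = {
        "gene_isoform": isoforms,
        "enhancer": enhancers,
        "tr_site": tr_sites,
        "atac_peak": atac,
    }
    return sites, annotations, truth


def _reference_landscape(config: SimConfig, pos: np.ndarray,
                         hyper_blocks: list[Interval],
                         gene_footprints: list[Interval]) -> np.ndarray:
    """Reference (beta-cell) expected methylation per CpG."""
    p = np.full(len(pos), config.bg_high)
    p[_in_any(pos, gene_footprints)] = config.bg_low
    p[_in_any(pos, hyper_blocks)] = config.hyper_block_base
    return p


def expected_betas(config: SimConfig, sites: pd.DataFrame, truth: SyntheticTruth,
                   annotations: dict) -> tuple[np.ndarray, np.ndarray]:
    """Expected per-CpG beta for the reference and tumor cohorts (no noise)."""
    pos = sites["pos"].to_numpy()
    genes = annotations["gene_isoform"].df
    footprints = [
        Interval(config.chrom, int(g["start"].min()), int(g["end"].max()))
        for _, g in genes.groupby("gene")
    ]
    p_beta = _reference_landscape(config, pos, truth.hyper_blocks, footprints)
    p_ins = p_beta + config.broad_hypo_delta
    in_gene = _in_any(pos, footprints)
    p_ins[in_gene] = p_beta[in_gene] + config.gene_hypo_delta
    hyper = _in_any(pos, truth.hyper_blocks)
    hypo = _in_any(pos, truth.hypo_blocks)
    p_ins[hyper] = p_beta[hyper] + config.hyper_block_delta
    p_ins[hypo] = p_beta[hypo] + config.hypo_block_delta
    return np.clip(p_beta, 0.02, 0.98), np.clip(p_ins, 0.02, 0.98)


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray,
                   rho: float) -> np.ndarray:
    """Beta-binomial draws with mean p and intra-class correlation rho."""
    if rho <= 0:
        return rng.binomial(n, p)
    conc = (1.0 - rho) / rho
    q = rng.beta(np.maximum(p * conc, 1e-9), np.maximum((1.0 - p) * conc, 1e-9))
    return rng.binomial(n, q)


def simulate_counts(sites: pd.DataFrame, config: SimConfig, truth: SyntheticTruth,
                    annotations: dict, seed: int) -> MethCallTable:
    """Draw per-cell read depths and methylated counts for both cohorts.

    Depth is negative-binomial around ``mean_depth``; methylated counts are
    beta-binomial with biological dispersion ``bio_dispersion``. At the
    signature CpGs of sub-group g, every tumor sample NOT in g is shifted
    by ``config.signature_deltas[g]`` while samples of g keep the ordinary
    tumor level — each group is distinguished by escaping a methylation
    loss the other tumors share.
    """
    rng = np.random.default_rng(seed + 1)
    p_beta, p_ins = expected_betas(config, sites, truth, annotations)
    sheet = config.sample_sheet().set_index("sample")

    n_sites = len(sites)
    samples = list(sheet.index)
    p_cells = np.zeros((len(samples), n_sites))
    sig_shift = {f"G{g + 1}": config.signature_deltas[g] for g in range(3)}
    for i, s in enumerate(samples):
        if sheet.at[s, "cohort"] == "beta":
            p = p_beta.copy()
        else:
            p = p_ins.copy()
            own = sheet.at[s, "group"]
            for g, ids in truth.signature_sites.items():
                if g != own:
                    idx = np.asarray(ids, dtype=int)
                    p[idx] = p[idx] + sig_shift[g]
        p_cells[i] = np.clip(p, 0.02, 0.98)

    size = config.depth_size
    prob = size / (size + config.mean_depth)
    total = rng.negative_binomial(size, prob, size=p_cells.shape)
    meth = _beta_binomial(rng, total, p_cells, config.bio_dispersion)
    return MethCallTable(sites.copy(), sheet, meth, total)


def simulate_expression(genes: list[str], config: SimConfig, seed: int) -> pd.DataFrame:
    """Differential expression table for region genes and regulators.

    Log2 fold changes for region genes are drawn independently of their
    promoter methylation (the decoupling the analysis is meant to expose),
    around a mildly negative mean (broad tumor downregulation; combined
    with region-wide promoter hypomethylation this populates the
    "discordant" same-sign quadrants). The NFATC1-like regulator is
    emitted at its planted log2 fold change of 3 (significant) and the
    PDX1-like regulator as downregulated.
    """
    if not genes:
        raise ValueError("gene list is empty")
    rng = np.random.default_rng(seed + 2)
    rows = []
    for g in genes:
        lfc = float(rng.normal(config.expr_lfc_mean, config.expr_lfc_sd))
        rows.append((g, lfc, abs(lfc) > config.expr_sig_cutoff))
    rows.append(("PDX1L", config.pdx_like_lfc, config.pdx_like_lfc != 0.0))
    rows.append(("NFATC1L", config.nfat_like_lfc, config.nfat_like_lfc != 0.0))
    for t in range(config.n_background_trs):
        lfc = float(rng.normal(0.0, config.expr_lfc_sd))
        rows.append((f"TR{t + 3:03d}", lfc, abs(lfc) > config.expr_sig_cutoff))
    return pd.DataFrame(rows, columns=["gene", "log2fc", "significant"])


def simulate_bundle(config: SimConfig, seed: int) -> dict:
    """One call producing the full synthetic study: region, counts, expression."""
    sites, annotations, truth = simulate_region(config, seed)
    table = simulate_counts(sites, config, truth, annotations, seed)
    genes = sorted(annotations["gene_isoform"].df["gene"].unique())
    expression = simulate_expression(genes, config, seed)
    return {
        "config": config,
        "sites": sites,
        "annotations": annotations,
        "truth": truth,
        "table": table,
        "expression": expression,
    }
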