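"""Methylome x transcriptome integration.

Four association layers, run in order on the upstream tables:

1. global Pearson correlation between region methylation and
   expression (absolute levels, or condition differences vs
   log-fold-change);
2. metagene methylation profiles of differentially expressed genes
   (all / up / down), per condition;
3. expression association of DMR-related genes (genes whose body or
   promoter overlaps a DMR), per context and direction;
4. the DMR x DEG cross-classification (hyper/hypo x up/down counts and
   Venn sets) and the TE layer tying DMR-bearing TEs to the DEGs whose
   extended domain (body +- 2 kb) they sit in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import (
    FLANK_BP,
    FeatureIndex,
    GeneModel,
    MetageneProfile,
    metagene_profile,
)
from .methylation import CONTEXTS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# level 1: correlation
# ---------------------------------------------------------------------------

def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with the exact two-sided t-transform p-value (n-2 df).

    NaN pairs are dropped; a constant vector (or n < 3) gives (nan,
    nan, n) — undefined, reported as missing rather than 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def gene_region_levels(
    sites: pd.DataFrame,
    levels_by_sample: Mapping[str, np.ndarray],
    genes: Sequence[GeneModel],
    index: FeatureIndex,
    regions: Sequence[str] = ("promoter", "body", "down2k"),
) -> pd.DataFrame:
    """Depth-independent gene-level methylation: mean site level per
    gene x region x context x sample (weighting sites equally within
    the region; NaN when no covered site).

    Tidy output: gene_id, region, context, sample, mean_level, n_sites.
    """
    rows = []
    by_chrom = {}
    for chrom in sites["chrom"].unique():
        sel = sites["chrom"].to_numpy() == chrom
        by_chrom[chrom] = (np.flatnonzero(sel), sites.loc[sel, "pos"].to_numpy() - 1,
                           sites.loc[sel, "context"].to_numpy())
    for g in genes:
        if g.chrom not in by_chrom:
            continue
        gidx, pos0, ctx = by_chrom[g.chrom]
        clen = index.chrom_lengths.get(g.chrom)
        for region in regions:
            if region == "body":
                lo, hi = g.start, g.end
            elif region in ("promoter", "up2k"):
                lo, hi, _ = g.promoter(clen)
            elif region == "down2k":
                lo, hi, _ = g.downstream(clen)
            else:
                raise ValueError(region)
            sel = (pos0 >= lo) & (pos0 < hi)
            for context in CONTEXTS:
                csel = sel & (ctx == context)
                sub_idx = gidx[csel]
                for sample, lv in levels_by_sample.items():
                    vals = np.asarray(lv)[sub_idx]
                    vals = vals[~np.isnan(vals)]
                    rows.append(
                        {
                            "gene_id": g.gene_id,
                            "region": region,
                            "context": context,
                            "sample": sample,
                            "mean_level": float(vals.mean()) if len(vals) else np.nan,
                            "n_sites": int(len(vals)),
                        }
                    )
    return pd.DataFrame(rows)


def correlate_meth_expr(
    gene_meth: pd.DataFrame,
    expression: pd.Series,
    value_col: str = "mean_level",
) -> pd.DataFrame:
    """Pearson correlation per (region, context) stratum between
    gene-level methylation and an expression quantity (FPKM,
    log-fold-change, or a methylation/expression difference).

    ``gene_meth`` is tidy (gene_id, region, context, value_col) already
    reduced to one row per gene per stratum; ``expression`` is indexed
    by gene_id.
    """
    rows = []
    for (region, context), sub in gene_meth.groupby(["region", "context"]):
        merged = sub.set_index("gene_id")[value_col].to_frame("meth").join(
            expression.rename("expr"), how="inner"
        )
        r, p, n = pearson_with_p(merged["meth"].to_numpy(), merged["expr"].to_numpy())
        rows.append({"region": region, "context": context, "pearson_r": r, "p_value": p, "n": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# level 2: DEG methylation profiles
# ---------------------------------------------------------------------------

def deg_methylation_profiles(
    deg_table: pd.DataFrame,
    sites: pd.DataFrame,
    levels: np.ndarray,
    genes: Sequence[GeneModel],
) -> list[MetageneProfile]:
    """Metagene profiles for DEG classes: "all" (union of up and down),
    "up" and "down".  Empty classes are skipped with a log entry."""
    status = deg_table["status"]
    groups: dict[str, str] = {}
    for gid in status.index[status == "up"]:
        groups[gid] = "up"
    for gid in status.index[status == "down"]:
        groups[gid] = "down"
    if not groups:
        logger.info("no DEGs; skipping DEG methylation profiles")
        return []
    profiles = metagene_profile(sites, levels, genes, groups)
    all_groups = {g: "all" for g in groups}
    profiles += metagene_profile(sites, levels, genes, all_groups)
    return profiles


# ---------------------------------------------------------------------------
# level 3: DMR-related gene expression association
# ---------------------------------------------------------------------------

def dmr_gene_expression_association(
    dmr_genes: pd.DataFrame,
    deg_table: pd.DataFrame,
) -> pd.DataFrame:
    """Join DMR-related genes to expression: one row per (gene, region,
    context, direction) with its methylation difference and LFC.

    A gene hit by both hyper- and hypomethylated DMRs in the same
    region/context appears once per direction (counted in both
    classes).  ``mean_diff`` averages the gene's DMRs of that class.
    """
    if dmr_genes.empty:
        return pd.DataFrame(
            columns=["gene_id", "region", "context", "direction", "mean_diff",
                     "log2_fold_change", "status"]
        )
    agg = (
        dmr_genes.groupby(["gene_id", "region", "context", "direction"])["mean_diff"]
        .mean()
        .reset_index()
    )
    out = agg.join(
        deg_table[["log2_fold_change", "status"]], on="gene_id", how="left"
    )
    return out


def association_summary(assoc: pd.DataFrame) -> pd.DataFrame:
    """Median LFC of DMR-related genes per context x region x direction
    (the box-plot view of the association)."""
    if assoc.empty:
        return pd.DataFrame(columns=["context", "region", "direction", "median_lfc", "n_genes"])
    rows = []
    for (context, region, direction), sub in assoc.groupby(["context", "region", "direction"]):
        rows.append(
            {
                "context": context,
                "region": region,
                "direction": direction,
                "median_lfc": float(sub["log2_fold_change"].median()),
                "n_genes": int(sub["gene_id"].nunique()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# level 4: cross-classification and TE layer
# ---------------------------------------------------------------------------

@dataclass
class CrossClassification:
    """hyper/hypo x up/down gene counts per context for one region,
    with the underlying gene sets for Venn rendering."""

    region: str
    counts: pd.DataFrame  # context, direction, status, n_genes
    sets: dict[tuple[str, str, str], set[str]]  # (context, direction, status) -> genes
    dual_class: dict[str, set[str]]  # context -> genes hit by both directions


def cross_classify(
    dmr_genes: pd.DataFrame, deg_table: pd.DataFrame, region: str = "body"
) -> CrossClassification:
    """Count DMR-related genes per (context, hyper/hypo, up/down) cell.

    Cells are intersections by gene id between the DMR-related genes of
    the region and the DEGs; a dual-direction gene contributes to both
    of its direction rows.
    """
    sub = dmr_genes[dmr_genes["region"] == region]
    degs_up = set(deg_table.index[deg_table["status"] == "up"])
    degs_down = set(deg_table.index[deg_table["status"] == "down"])
    rows = []
    sets: dict[tuple[str, str, str], set[str]] = {}
    dual: dict[str, set[str]] = {}
    for context in CONTEXTS:
        csub = sub[sub["context"] == context]
        hyper = set(csub.loc[csub["direction"] == "hyper", "gene_id"])
        hypo = set(csub.loc[csub["direction"] == "hypo", "gene_id"])
        dual[context] = hyper & hypo
        for direction, meth_set in (("hyper", hyper), ("hypo", hypo)):
            for status, deg_set in (("up", degs_up), ("down", degs_down)):
                cell = meth_set & deg_set
                sets[(context, direction, status)] = cell
                rows.append(
                    {
                        "context": context,
                        "direction": direction,
                        "status": status,
                        "n_genes": len(cell),
                    }
                )
    return CrossClassification(
        region=region, counts=pd.DataFrame(rows), sets=sets, dual_class=dual
    )


def te_dmr_deg_association(
    annotated_dmrs: pd.DataFrame,
    index: FeatureIndex,
    deg_table: pd.DataFrame,
    genes: Sequence[GeneModel],
    flank: int = FLANK_BP,
) -> pd.DataFrame:
    """Triples (DEG, TE, DMR): DMRs lying in TEs that sit inside the
    extended domain (body +- 2 kb) of a DEG that is also DMR-related.

    One row per (gene, TE, DMR) combination — a DMR spanning two TEs
    yields two rows.  ``te_region`` locates the TE relative to the gene
    (body / up2k / down2k, body taking precedence).
    """
    deg_ids = set(deg_table.index[deg_table["status"].isin(["up", "down"])])
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for i, row in annotated_dmrs.iterrows():
        tes = index.tes_overlapping(row["chrom"], row["start"], row["end"])
        if not len(tes):
            continue
        related = [g for g in
                   (str(row.get("gene_body_hits", "")) + "," + str(row.get("promoter_hits", ""))).split(",")
                   if g]
        for te in tes.itertuples():
            for gid in sorted(set(related) & deg_ids):
                g = gene_by_id[gid]
                dom_lo, dom_hi = g.start - flank, g.end + flank
                if not (te.start < dom_hi and te.end > dom_lo):
                    continue
                if te.start < g.end and te.end > g.start:
                    te_region = "body"
                else:
                    upstream = (te.end <= g.start) if g.strand == "+" else (te.start >= g.end)
                    te_region = "up2k" if upstream else "down2k"
                rows.append(
                    {
                        "gene_id": gid,
                        "te_id": te.te_id,
                        "te_class": te.te_class,
                        "family": te.family,
                        "te_region": te_region,
                        "dmr_index": i,
                        "context": row["context"],
                        "direction": row["direction"],
                        "deg_status": deg_table.loc[gid, "status"],
                    }
                )
    cols = ["gene_id", "te_id", "te_class", "family", "te_region",
            "dmr_index", "context", "direction", "deg_status"]
    return pd.DataFrame(rows, columns=cols)
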