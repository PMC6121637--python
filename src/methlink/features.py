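"""Genomic feature model and region-level methylation summaries.

Genes are intervals with strand, exon structure and derived
sub-regions: the promoter (2 kb upstream of the TSS, identical in
extent to the upstream flank), the body (TSS to TES), introns (body
minus exons) and the 2-kb downstream flank.  Every analysis in this
package that talks about "regions" resolves them through
:class:`FeatureIndex`, so promoter/exon/intron/flank/TE/intergenic mean
the same thing everywhere.

Metagene profiles average site methylation over 50 fixed 40-bp bins in
each flank and 50 length-normalised bins in the body, gene-weighted
(within-gene means first, then across genes) so long genes do not
dominate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .methylation import CONTEXTS

logger = logging.getLogger(__name__)

FLANK_BP = 2000
REGION_LABELS = (
    "promoter",
    "up2k",
    "body",
    "exon",
    "intron",
    "down2k",
    "TE",
    "intergenic",
)


class AnnotationError(ValueError):
    pass


@dataclass
class GeneModel:
    """A gene as an oriented interval with exons; 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.end <= self.start:
            raise AnnotationError(
                f"{self.gene_id}: TES must follow TSS ({self.start}..{self.end})"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if s < self.start or e > self.end or e <= s:
                raise AnnotationError(f"{self.gene_id}: exon ({s},{e}) outside body")

    @property
    def tss(self) -> int:
        """Transcription start as a half-open boundary coordinate."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def promoter(self, chrom_length: int | None = None, flank: int = FLANK_BP):
        """2-kb region upstream of the TSS; truncated (and flagged) at edges."""
        if self.strand == "+":
            lo, hi = self.start - flank, self.start
        else:
            lo, hi = self.end, self.end + flank
        truncated = lo < 0 or (chrom_length is not None and hi > chrom_length)
        lo = max(lo, 0)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        return (lo, hi, truncated)

    def downstream(self, chrom_length: int | None = None, flank: int = FLANK_BP):
        if self.strand == "+":
            lo, hi = self.end, self.end + flank
        else:
            lo, hi = self.start - flank, self.start
        truncated = lo < 0 or (chrom_length is not None and hi > chrom_length)
        lo = max(lo, 0)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        return (lo, hi, truncated)

    def introns(self) -> list[tuple[int, int]]:
        if not self.exons:
            return []
        out = []
        exs = sorted(self.exons)
        cur = self.start
        for s, e in exs:
            if s > cur:
                out.append((cur, s))
            cur = max(cur, e)
        if cur < self.end:
            out.append((cur, self.end))
        return out


# ---------------------------------------------------------------------------
# interval index
# ---------------------------------------------------------------------------

@dataclass
class FeatureIndex:
    """Label lookup over the genome: position -> region labels, plus
    gene / TE overlap queries.  Overlapping labels are all reported; a
    promoter lying in a neighbouring gene's body contributes to both.
    """

    genes: list[GeneModel]
    tes: pd.DataFrame  # chrom, start, end, te_id, te_class, family, strand
    chrom_lengths: dict[str, int]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _gene_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _te_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for g in self.genes:
            clen = self.chrom_lengths.get(g.chrom)
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            gtree = self._gene_trees.setdefault(g.chrom, IntervalTree())
            gtree[g.start:g.end] = g
            tree[g.start:g.end] = ("body", g.gene_id)
            for s, e in g.exons:
                tree[s:e] = ("exon", g.gene_id)
            for s, e in g.introns():
                tree[s:e] = ("intron", g.gene_id)
            plo, phi, trunc = g.promoter(clen)
            if trunc:
                logger.warning("%s: promoter truncated at contig edge", g.gene_id)
            if phi > plo:
                tree[plo:phi] = ("promoter", g.gene_id)
                tree[plo:phi] = ("up2k", g.gene_id)
            dlo, dhi, _ = g.downstream(clen)
            if dhi > dlo:
                tree[dlo:dhi] = ("down2k", g.gene_id)
        if len(self.tes):
            for row in self.tes.itertuples():
                tree = self._trees.setdefault(row.chrom, IntervalTree())
                tree[row.start:row.end] = ("TE", row.te_id)
                ttree = self._te_trees.setdefault(row.chrom, IntervalTree())
                ttree[row.start:row.end] = row

    def labels_at(self, chrom: str, pos0: int) -> set[str]:
        """Region labels covering a 0-based position; ``intergenic`` when
        no gene-derived label or TE covers it."""
        tree = self._trees.get(chrom)
        hits = {lab for (lab, _x) in (iv.data for iv in tree[pos0])} if tree else set()
        if not hits:
            hits = {"intergenic"}
        return hits

    def genes_overlapping(
        self, chrom: str, start: int, end: int, region: str = "body"
    ) -> list[str]:
        """Gene ids whose body or promoter overlaps [start, end) by >= 1 bp."""
        out = []
        for g in (iv.data for iv in self._gene_trees.get(chrom, IntervalTree())[start - FLANK_BP:end + FLANK_BP]):
            if region == "body":
                lo, hi = g.start, g.end
            elif region == "promoter":
                lo, hi, _ = g.promoter(self.chrom_lengths.get(chrom))
            else:
                raise ValueError(region)
            if lo < end and start < hi:
                out.append(g.gene_id)
        return sorted(set(out))

    def tes_overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        tree = self._te_trees.get(chrom)
        rows = [iv.data for iv in tree[start:end]] if tree else []
        if not rows:
            return self.tes.iloc[0:0]
        return pd.DataFrame(rows).drop(columns=["Index"], errors="ignore")

    def te_intragenic(self) -> pd.Series:
        """True for TEs overlapping any gene body (TSS-TES)."""
        flags = []
        for row in self.tes.itertuples():
            gtree = self._gene_trees.get(row.chrom)
            flags.append(bool(gtree and gtree.overlaps(row.start, row.end)))
        return pd.Series(flags, index=self.tes.index, name="intragenic")

    def label_intervals(self, label: str) -> dict[str, np.ndarray]:
        """All intervals of one label, per chrom, as (n, 2) arrays."""
        out: dict[str, list] = {}
        for chrom, tree in self._trees.items():
            ivs = [(iv.begin, iv.end) for iv in tree if iv.data[0] == label]
            if ivs:
                out[chrom] = np.array(sorted(ivs))
        return {c: np.asarray(v) for c, v in out.items()}


def positions_in_intervals(pos0: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask: which 0-based positions fall in any [start, end)?

    Vectorised stabbing query against a (possibly overlapping) interval
    set; used for bulk region masking instead of per-site tree lookups.
    """
    mask = np.zeros(len(pos0), dtype=bool)
    for s, e in np.asarray(intervals).reshape(-1, 2):
        lo = np.searchsorted(pos0, s, side="left")
        hi = np.searchsorted(pos0, e, side="left")
        mask[lo:hi] = True
    return mask


# ---------------------------------------------------------------------------
# region-level methylation
# ---------------------------------------------------------------------------

def region_methylation(
    sites: pd.DataFrame,
    levels: Mapping[str, np.ndarray],
    index: FeatureIndex,
    labels: Sequence[str] = ("promoter", "exon", "intron", "body", "up2k", "down2k", "TE"),
) -> pd.DataFrame:
    """Mean site methylation per region label x context x sample.

    ``sites`` must be position-sorted within chromosome with columns
    chrom, pos (1-based), context; ``levels`` maps sample name to an
    aligned level array (NaN = uncovered).  Regions with no covered
    site of a context are reported as NaN (missing, not zero).
    """
    records = []
    ctx_arr = sites["context"].to_numpy()
    for label in labels:
        per_chrom = index.label_intervals(label)
        mask = np.zeros(len(sites), dtype=bool)
        for chrom, ivs in per_chrom.items():
            sel = sites["chrom"].to_numpy() == chrom
            pos0 = sites.loc[sel, "pos"].to_numpy() - 1
            mask[np.flatnonzero(sel)[positions_in_intervals(pos0, ivs)]] = True
        for context in CONTEXTS:
            cmask = mask & (ctx_arr == context)
            for sample, lv in levels.items():
                vals = np.asarray(lv)[cmask]
                vals = vals[~np.isnan(vals)]
                records.append(
                    {
                        "label": label,
                        "context": context,
                        "sample": sample,
                        "mean_level": float(vals.mean()) if len(vals) else np.nan,
                        "n_sites": int(len(vals)),
                    }
                )
    return pd.DataFrame.from_records(records)


def windowed_levels(
    sites: pd.DataFrame,
    levels: np.ndarray,
    chrom_lengths: Mapping[str, int],
    window: int = 50_000,
) -> pd.DataFrame:
    """Fixed-width window track of mean methylation per context (density
    view along chromosomes)."""
    records = []
    lv = np.asarray(levels, dtype=float)
    for chrom, clen in chrom_lengths.items():
        sel = sites["chrom"].to_numpy() == chrom
        pos0 = sites.loc[sel, "pos"].to_numpy() - 1
        ctx = sites.loc[sel, "context"].to_numpy()
        sub = lv[sel]
        edges = np.arange(0, clen + window, window)
        which = np.clip(np.digitize(pos0, edges) - 1, 0, len(edges) - 2)
        for context in CONTEXTS:
            csel = (ctx == context) & ~np.isnan(sub)
            sums = np.bincount(which[csel], weights=sub[csel], minlength=len(edges) - 1)
            cnts = np.bincount(which[csel], minlength=len(edges) - 1)
            with np.errstate(invalid="ignore"):
                means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
            for i, (lo, m, n) in enumerate(zip(edges[:-1], means, cnts)):
                records.append(
                    {
                        "chrom": chrom,
                        "start": int(lo),
                        "end": int(min(lo + window, clen)),
                        "context": context,
                        "mean_level": m,
                        "n_sites": int(n),
                    }
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Mean methylation across 50+50+50 bins (upstream / body / downstream),
    averaged gene-weighted within a gene group."""

    group: str
    context: str
    bin_means: np.ndarray  # (3 * n_bins,)
    bin_counts: np.ndarray  # genes contributing per bin
    n_genes: int
    n_bins: int = 50


def _gene_bin_means(
    pos0: np.ndarray, lv: np.ndarray, gene: GeneModel, n_bins: int, flank: int
) -> np.ndarray:
    """Per-gene mean level in each of the 3*n_bins strand-oriented bins."""
    out = np.full(3 * n_bins, np.nan)
    body_len = gene.length
    if body_len < n_bins:
        logger.info("%s shorter than %d bp; fractional binning", gene.gene_id, n_bins)
    bin_w = flank / n_bins

    segments = []  # (offset, positions-in-bin-units, levels)
    if gene.strand == "+":
        sel = (pos0 >= gene.start - flank) & (pos0 < gene.start)
        segments.append((0, (pos0[sel] - (gene.start - flank)) / bin_w, lv[sel]))
        sel = (pos0 >= gene.start) & (pos0 < gene.end)
        segments.append((n_bins, (pos0[sel] - gene.start) / body_len * n_bins, lv[sel]))
        sel = (pos0 >= gene.end) & (pos0 < gene.end + flank)
        segments.append((2 * n_bins, (pos0[sel] - gene.end) / bin_w, lv[sel]))
    else:
        sel = (pos0 >= gene.end) & (pos0 < gene.end + flank)
        segments.append((0, (gene.end + flank - 1 - pos0[sel]) / bin_w, lv[sel]))
        sel = (pos0 >= gene.start) & (pos0 < gene.end)
        segments.append(
            (n_bins, (gene.end - 1 - pos0[sel]) / body_len * n_bins, lv[sel])
        )
        sel = (pos0 >= gene.start - flank) & (pos0 < gene.start)
        segments.append((2 * n_bins, (gene.start - 1 - pos0[sel]) / bin_w, lv[sel]))

    for offset, frac_bins, vals in segments:
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        b = np.clip(frac_bins[ok].astype(int), 0, n_bins - 1) + offset
        sums = np.bincount(b, weights=vals[ok], minlength=3 * n_bins)
        cnts = np.bincount(b, minlength=3 * n_bins)
        nz = cnts > 0
        out[nz] = sums[nz] / cnts[nz]
    return out


def metagene_profile(
    sites: pd.DataFrame,
    levels: np.ndarray,
    genes: Sequence[GeneModel],
    groups: Mapping[str, str] | None = None,
    n_bins: int = 50,
    flank: int = FLANK_BP,
) -> list[MetageneProfile]:
    """Metagene profiles per gene group x context.

    Bin 1 sits at the far upstream edge, bin ``n_bins+1`` at the TSS and
    the last bin at the far downstream edge, for both strands.  Within
    each gene, site levels are averaged per bin; group curves average
    the per-gene bins so every gene carries equal weight.
    """
    if groups is None:
        groups = {g.gene_id: "all" for g in genes}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    lv_all = np.asarray(levels, dtype=float)
    for chrom in sites["chrom"].unique():
        sel = sites["chrom"].to_numpy() == chrom
        by_chrom[chrom] = (
            sites.loc[sel, "pos"].to_numpy() - 1,
            sites.loc[sel, "context"].to_numpy(),
            lv_all[sel],
        )
    acc: dict[tuple[str, str], list[np.ndarray]] = {}
    for g in genes:
        grp = groups.get(g.gene_id)
        if grp is None or g.chrom not in by_chrom:
            continue
        pos0, ctx, lv = by_chrom[g.chrom]
        for context in CONTEXTS:
            csel = ctx == context
            means = _gene_bin_means(pos0[csel], lv[csel], g, n_bins, flank)
            acc.setdefault((grp, context), []).append(means)
    profiles = []
    for (grp, context), rows in sorted(acc.items()):
        mat = np.vstack(rows)
        counts = (~np.isnan(mat)).sum(axis=0)
        sums = np.nansum(mat, axis=0)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        profiles.append(
            MetageneProfile(
                group=grp,
                context=context,
                bin_means=means,
                bin_counts=counts,
                n_genes=len(rows),
                n_bins=n_bins,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# expression / methylation grouping
# ---------------------------------------------------------------------------

EXPRESSION_GROUPS = ("no", "low", "medium", "high")


class GroupingError(ValueError):
    pass


@dataclass
class ExpressionGroups:
    """Four-way expression grouping: no (< 1 FPKM), then low / medium /
    high split at the 25th and 75th FPKM percentiles of expressed genes."""

    fpkm_25: float
    fpkm_75: float
    assignment: pd.Series  # gene_id -> group label

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().reindex(EXPRESSION_GROUPS, fill_value=0)


def expression_groups(
    fpkm: pd.Series,
    expressed_threshold: float = 1.0,
    include_unexpressed_in_percentiles: bool = False,
) -> ExpressionGroups:
    """Partition genes by replicate-averaged FPKM.

    Percentile thresholds are computed over expressed genes only
    (FPKM >= 1) by default, with linear interpolation; boundaries are
    inclusive on the upper group (FPKM exactly at the 75th percentile is
    "high").
    """
    fpkm = fpkm.astype(float)
    expressed = fpkm[fpkm >= expressed_threshold]
    pool = fpkm if include_unexpressed_in_percentiles else expressed
    if len(expressed) < 4:
        raise GroupingError(
            f"need >= 4 expressed genes to form quartile groups, have {len(expressed)}"
        )
    q25, q75 = np.percentile(pool.to_numpy(), [25, 75])
    labels = pd.Series("no", index=fpkm.index, dtype=object)
    labels[(fpkm >= expressed_threshold) & (fpkm < q25)] = "low"
    labels[(fpkm >= q25) & (fpkm < q75)] = "medium"
    labels[fpkm >= q75] = "high"
    labels[fpkm < expressed_threshold] = "no"
    return ExpressionGroups(fpkm_25=float(q25), fpkm_75=float(q75), assignment=labels)


@dataclass
class MethylationGroups:
    """Quintile grouping of genes by region methylation level (1 = least
    methylated, 5 = most)."""

    boundaries: np.ndarray  # the 20/40/60/80th percentiles
    assignment: pd.Series  # gene_id -> 1..5
    n_excluded: int  # genes with no measurable site in the region/context


def methylation_groups(gene_levels: pd.Series, n_groups: int = 5) -> MethylationGroups:
    """Assign genes to methylation-level quantile groups.

    Genes without a level (NaN: no covered site of the context in the
    region) are excluded and counted.  A degenerate distribution
    collapses to a single group with a warning.
    """
    vals = gene_levels.dropna().astype(float)
    n_excluded = int(gene_levels.isna().sum())
    if vals.empty:
        raise GroupingError("no genes with measurable methylation level")
    qs = np.percentile(vals.to_numpy(), np.linspace(0, 100, n_groups + 1)[1:-1])
    if np.allclose(vals.min(), vals.max()):
        logger.warning("degenerate methylation distribution; single group")
        assignment = pd.Series(1, index=vals.index)
        return MethylationGroups(boundaries=qs, assignment=assignment, n_excluded=n_excluded)
    assignment = pd.Series(
        np.searchsorted(qs, vals.to_numpy(), side="right") + 1, index=vals.index
    )
    return MethylationGroups(boundaries=qs, assignment=assignment, n_excluded=n_excluded)


def group_expression_table(
    meth_groups: MethylationGroups,
    expression: pd.Series,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gene-frequency histogram of expression per methylation group
    (expression on x, gene frequency on y)."""
    expr = np.log10(expression.astype(float) + 1.0)
    if bins is None:
        bins = np.linspace(0, max(float(expr.max()), 1.0), 21)
    rows = []
    for grp in sorted(meth_groups.assignment.unique()):
        ids = meth_groups.assignment.index[meth_groups.assignment == grp]
        vals = expr.reindex(ids).dropna().to_numpy()
        counts, _ = np.histogram(vals, bins=bins)
        for lo, hi, n in zip(bins[:-1], bins[1:], counts):
            rows.append(
                {"group": int(grp), "log10_fpkm_low": lo, "log10_fpkm_high": hi, "n_genes": int(n)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TE density profile
# ---------------------------------------------------------------------------

def te_density_profile(
    tes: pd.DataFrame,
    genes: Sequence[GeneModel],
    n_bins: int = 50,
    flank: int = FLANK_BP,
    by: str = "family",
) -> pd.DataFrame:
    """TE coverage fraction per metagene bin, per TE family (or class).

    For every gene, each of the 150 strand-oriented bins reports the
    fraction of its length covered by TEs of the family; the profile
    averages over genes.
    """
    keys = sorted(tes[by].unique()) if len(tes) else []
    te_by_chrom: dict[str, pd.DataFrame] = {
        c: sub.sort_values("start") for c, sub in tes.groupby("chrom")
    } if len(tes) else {}
    total = np.zeros((max(len(keys), 1), 3 * n_bins))
    n_genes = 0
    key_idx = {k: i for i, k in enumerate(keys)}
    for g in genes:
        n_genes += 1
        sub = te_by_chrom.get(g.chrom)
        if sub is None:
            continue
        # bin edges in genome coordinates, strand-oriented
        if g.strand == "+":
            edges = np.concatenate(
                [
                    np.linspace(g.start - flank, g.start, n_bins + 1)[:-1],
                    np.linspace(g.start, g.end, n_bins + 1)[:-1],
                    np.linspace(g.end, g.end + flank, n_bins + 1),
                ]
            )
        else:
            edges = np.concatenate(
                [
                    np.linspace(g.end + flank, g.end, n_bins + 1)[:-1],
                    np.linspace(g.end, g.start, n_bins + 1)[:-1],
                    np.linspace(g.start, g.start - flank, n_bins + 1),
                ]
            )
        lo = np.minimum(edges[:-1], edges[1:])
        hi = np.maximum(edges[:-1], edges[1:])
        width = np.maximum(hi - lo, 1e-9)
        dom_lo, dom_hi = lo.min(), hi.max()
        near = sub[(sub["end"] > dom_lo) & (sub["start"] < dom_hi)]
        for row in near.itertuples():
            ki = key_idx[getattr(row, by)]
            ov = np.minimum(hi, row.end) - np.maximum(lo, row.start)
            total[ki] += np.clip(ov, 0, None) / width
    frac = total / max(n_genes, 1)
    rows = []
    for k in keys:
        for b in range(3 * n_bins):
            region = ("up2k", "body", "down2k")[b // n_bins]
            rows.append(
                {
                    by: k,
                    "bin": b,
                    "region": region,
                    "coverage_fraction": frac[key_idx[k], b],
                }
            )
    if not keys:
        for b in range(3 * n_bins):
            rows.append(
                {by: None, "bin": b, "region": ("up2k", "body", "down2k")[b // n_bins], "coverage_fraction": 0.0}
            )
    return pd.DataFrame(rows)
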