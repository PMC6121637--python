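"""Differential methylation between two replicated conditions.

The model: at a cytosine site the methylated-read count of replicate r
is beta-binomial — binomial in the read depth n_r with a success
probability that varies between biological replicates around the
condition mean mu with dispersion phi, so that

    Var(m_r / n_r) = mu (1 - mu) (1 + (n_r - 1) phi) / n_r.

Calling proceeds in four steps, each exposed as a function:

1. :func:`smooth_levels` pools counts over a sliding window so that
   spatially correlated neighbouring sites inform each site's level
   estimate (replicate by replicate).
2. :func:`estimate_dispersion` computes a method-of-moments dispersion
   per site and condition from the replicate proportions and shrinks it
   toward the context-wide trend (empirical-Bayes style), flooring at
   1e-4.
3. :func:`dml_test` forms a Wald statistic
   (mu1 - mu2) / sqrt(var1 + var2) with the beta-binomial variance of
   each condition mean, and a two-sided normal p-value.
4. :func:`call_dmrs` merges runs of significant, same-direction,
   same-context sites into regions subject to length / site-count /
   significant-fraction filters, and labels each region hyper- or
   hypomethylated in the first condition relative to the second.

Because the mean and its variance are both computed from the same
window-pooled replicate counts, the test stays calibrated when
smoothing is on: the window is treated as a single beta-binomial locus
whose effective dispersion is estimated from the pooled replicate
proportions themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylation import CONTEXTS, Methylome
from .features import FeatureIndex

logger = logging.getLogger(__name__)

PHI_FLOOR = 1e-4
PHI_CEIL = 0.99


@dataclass(frozen=True)
class DmrParams:
    """DMR-calling thresholds.

    The smoothing window (200 bp) trades spatial pooling against
    boundary resolution: called region edges can overshoot true edges
    by about half a window, so the window is kept at the scale of the
    shortest regions worth reporting.
    """

    smooth_window: int = 200
    p_threshold: float = 1e-5
    min_len: int = 50
    min_sites: int = 3
    max_gap: int = 100
    pct_sig: float = 0.5
    prior_df: float = 4.0  # shrinkage weight: w = (R-1) / (R-1 + prior_df)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_counts(
    pos: np.ndarray, meth: np.ndarray, depth: np.ndarray, window_bp: int
) -> tuple[np.ndarray, np.ndarray]:
    """Window-pooled counts per site: sums of meth and depth over sites
    within +- window_bp/2 of each position (inclusive of the site).

    ``pos`` must be sorted.  window_bp <= 0 disables pooling (identity).
    Returns (pooled_meth, pooled_depth) aligned with ``pos``.
    """
    if window_bp <= 0:
        return meth.astype(float), depth.astype(float)
    half = window_bp / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    cm = np.concatenate([[0.0], np.cumsum(meth, dtype=float)])
    cd = np.concatenate([[0.0], np.cumsum(depth, dtype=float)])
    return cm[hi] - cm[lo], cd[hi] - cd[lo]


def smooth_levels(
    pos: np.ndarray, meth: np.ndarray, depth: np.ndarray, window_bp: int
) -> np.ndarray:
    """Depth-weighted moving-average level over +- window_bp/2.

    Equivalent to the pooled-count ratio; isolated sites keep their raw
    level, and window_bp <= 0 returns raw levels.
    """
    pm, pd_ = smooth_counts(np.asarray(pos), np.asarray(meth), np.asarray(depth), window_bp)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(pd_ > 0, pm / np.where(pd_ > 0, pd_, 1), np.nan)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def mom_dispersion(meth: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """Raw method-of-moments beta-binomial dispersion per site.

    ``meth``/``depth`` are (n_sites, R) replicate count matrices.  With
    pooled proportion p = sum(m)/sum(n), replicate-proportion variance
    s2 (ddof 1 over replicates with coverage) and harmonic-mean depth
    nbar, the estimate inverts Var(p_r) = p(1-p)(1 + (nbar-1) phi)/nbar:

        phi = (nbar * s2 - p(1-p)) / (p(1-p) (nbar - 1)).

    Sites with < 2 covered replicates or with p in {0, 1} return NaN
    (no information about phi).  Estimates may be negative; shrinkage
    and flooring happen in :func:`shrink_dispersion`.
    """
    m = np.asarray(meth, dtype=float)
    n = np.asarray(depth, dtype=float)
    covered = n > 0
    r_eff = covered.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_rep = np.where(covered, m / np.where(covered, n, 1), np.nan)
        p_hat = m.sum(axis=1) / np.maximum(n.sum(axis=1), 1e-12)
        resid2 = np.where(covered, (p_rep - p_hat[:, None]) ** 2, 0.0)
        s2 = resid2.sum(axis=1) / np.maximum(r_eff - 1, 1)
        nbar = r_eff / np.where(covered, 1.0 / np.where(covered, n, 1), 0.0).sum(axis=1)
        pq = p_hat * (1 - p_hat)
        phi = (nbar * s2 - pq) / (pq * np.maximum(nbar - 1, 1e-12))
    phi = np.where((r_eff >= 2) & (pq > 0), phi, np.nan)
    return phi


def shrink_dispersion(
    phi_raw: np.ndarray, n_replicates: int, prior_df: float = 4.0
) -> tuple[np.ndarray, float]:
    """Shrink per-site dispersions toward the context-wide mean.

    The trend is the mean of the finite raw estimates (unbiased, unlike
    a median of the heavily right-skewed per-site distribution), and
    each site gets weight w = (R-1)/(R-1+prior_df) on its own estimate.
    Returns (shrunk dispersions floored to [1e-4, 0.99], trend).
    """
    finite = np.isfinite(phi_raw)
    trend = float(np.clip(np.nanmean(phi_raw[finite]), PHI_FLOOR, PHI_CEIL)) if finite.any() else PHI_FLOOR
    w = (n_replicates - 1) / (n_replicates - 1 + prior_df)
    shrunk = np.where(finite, w * phi_raw + (1 - w) * trend, trend)
    return np.clip(shrunk, PHI_FLOOR, PHI_CEIL), trend


def estimate_dispersion(
    meth: np.ndarray, depth: np.ndarray, prior_df: float = 4.0
) -> np.ndarray:
    """Per-site shrunk beta-binomial dispersion for one condition.

    Falls back to the context-wide trend alone for single-replicate
    input (with a warning).
    """
    m = np.atleast_2d(np.asarray(meth, dtype=float))
    n = np.atleast_2d(np.asarray(depth, dtype=float))
    n_rep = m.shape[1]
    if n_rep < 2:
        logger.warning("single replicate: using context-wide dispersion only")
        return np.full(m.shape[0], PHI_FLOOR)
    raw = mom_dispersion(m, n)
    shrunk, _ = shrink_dispersion(raw, n_rep, prior_df)
    return shrunk


# ---------------------------------------------------------------------------
# per-site test
# ---------------------------------------------------------------------------

def _condition_mean_var(
    meth: np.ndarray, depth: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled mean and variance of the condition mean level.

    mu = sum(m)/sum(n); var = sum_r mu(1-mu)(1+(n_r-1)phi)/n_r / R^2
    over covered replicates.  The mu(1-mu) factor uses a continuity-
    clamped mu so boundary sites (all reads methylated/unmethylated)
    keep a positive variance.
    """
    m = np.asarray(meth, dtype=float)
    n = np.asarray(depth, dtype=float)
    covered = n > 0
    r_eff = covered.sum(axis=1)
    tot_n = n.sum(axis=1)
    mu = m.sum(axis=1) / np.maximum(tot_n, 1e-12)
    mu_c = (m.sum(axis=1) + 0.5) / (tot_n + 1.0)  # clamped for the variance
    pq = mu_c * (1 - mu_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(
            covered, (1 + (n - 1) * phi[:, None]) / np.where(covered, n, 1), 0.0
        )
        var = pq * terms.sum(axis=1) / np.maximum(r_eff, 1) ** 2
    mu = np.where(r_eff > 0, mu, np.nan)
    var = np.where(r_eff > 0, var, np.nan)
    return mu, var


def dml_test(
    meth1: np.ndarray,
    depth1: np.ndarray,
    meth2: np.ndarray,
    depth2: np.ndarray,
    phi1: np.ndarray,
    phi2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Wald test of equal mean level per site between two conditions.

    Count matrices are (n_sites, R) per condition (already
    window-pooled when smoothing is on).  Returns (mu1, mu2, stat, p);
    sites uncovered in a condition yield NaN and are skipped by the
    caller.  Identical data in both conditions gives stat 0, p 1.
    """
    mu1, var1 = _condition_mean_var(meth1, depth1, phi1)
    mu2, var2 = _condition_mean_var(meth2, depth2, phi2)
    diff = mu1 - mu2
    se = np.sqrt(var1 + var2)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(diff == 0, 0.0, diff / np.where(se > 0, se, np.nan))
    p = 2 * stats.norm.sf(np.abs(stat))
    p = np.where(np.isnan(stat), np.nan, p)
    return mu1, mu2, stat, p


def dml_scan(
    methylome: Methylome,
    condition1: str = "WT",
    condition2: str = "RT",
    params: DmrParams = DmrParams(),
) -> pd.DataFrame:
    """Run the full per-site differential-methylation scan.

    Smoothing, dispersion shrinkage (per context and condition) and the
    Wald test, chromosome by chromosome.  Returns the DML table sorted
    by (chrom, pos): chrom, pos, strand, context, mu1, mu2, diff, phi1,
    phi2, stat, p, p_adj (BH within context), plus raw pooled counts.
    Sites with zero depth in either condition are dropped (recorded in
    the log).
    """
    samples1 = methylome.conditions[condition1]
    samples2 = methylome.conditions[condition2]
    frames = []
    sites = methylome.sites
    for chrom, sub in sites.groupby("chrom", sort=True):
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy()
        for context in CONTEXTS:
            csel = (sub["context"] == context).to_numpy()
            if not csel.any():
                continue
            cpos = pos[csel]
            pooled = {}
            raw_m, raw_d = {}, {}
            for cond, group in ((condition1, samples1), (condition2, samples2)):
                pm, pdep = [], []
                rm, rd = [], []
                for s in group:
                    m = sub[f"meth_{s}"].to_numpy()[csel].astype(float)
                    d = m + sub[f"unmeth_{s}"].to_numpy()[csel].astype(float)
                    sm, sd = smooth_counts(cpos, m, d, params.smooth_window)
                    pm.append(sm)
                    pdep.append(sd)
                    rm.append(m)
                    rd.append(d)
                pooled[cond] = (np.column_stack(pm), np.column_stack(pdep))
                raw_m[cond] = np.column_stack(rm)
                raw_d[cond] = np.column_stack(rd)
            m1, d1 = pooled[condition1]
            m2, d2 = pooled[condition2]
            phi1 = estimate_dispersion(m1, d1, params.prior_df)
            phi2 = estimate_dispersion(m2, d2, params.prior_df)
            mu1, mu2, stat, p = dml_test(m1, d1, m2, d2, phi1, phi2)
            keep = (raw_d[condition1].sum(axis=1) > 0) & (
                raw_d[condition2].sum(axis=1) > 0
            )
            n_dropped = int((~keep).sum())
            if n_dropped:
                logger.info(
                    "%s/%s: %d sites uncovered in one condition skipped",
                    chrom, context, n_dropped,
                )
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": cpos[keep],
                        "strand": sub["strand"].to_numpy()[csel][keep],
                        "context": context,
                        "mu1": mu1[keep],
                        "mu2": mu2[keep],
                        "diff": (mu1 - mu2)[keep],
                        "phi1": phi1[keep],
                        "phi2": phi2[keep],
                        "stat": stat[keep],
                        "p": p[keep],
                        "raw_meth1": raw_m[condition1].sum(axis=1)[keep],
                        "raw_depth1": raw_d[condition1].sum(axis=1)[keep],
                        "raw_meth2": raw_m[condition2].sum(axis=1)[keep],
                        "raw_depth2": raw_d[condition2].sum(axis=1)[keep],
                    }
                )
            )
    dml = pd.concat(frames, ignore_index=True)
    dml["p_adj"] = np.nan
    for context in CONTEXTS:
        sel = (dml["context"] == context) & dml["p"].notna()
        if sel.any():
            dml.loc[sel, "p_adj"] = multipletests(
                dml.loc[sel, "p"], method="fdr_bh"
            )[1]
    return dml.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# DMR merging
# ---------------------------------------------------------------------------

def call_dmrs(dml: pd.DataFrame, params: DmrParams = DmrParams()) -> pd.DataFrame:
    """Merge significant same-direction sites into DMRs.

    Significant sites (p < p_threshold) of one context and sign,
    separated by <= max_gap bp, form a candidate region spanning the
    first to last such site.  The region is kept when it is at least
    min_len bp long, holds at least min_sites significant sites, and at
    least pct_sig of all tested sites inside it are significant.

    Direction is recomputed from the raw pooled counts inside the
    region: "hyper" means condition 1 (WT by convention) is the more
    methylated.  Columns: chrom, start, end (0-based half-open),
    context, direction, n_sites, n_sites_total, mean_diff,
    area_stat, mean_mu1, mean_mu2.
    """
    records = []
    for (chrom, context), sub in dml.groupby(["chrom", "context"], sort=True):
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy()
        p = sub["p"].to_numpy()
        sign = np.sign(sub["diff"].to_numpy())
        sig = (p < params.p_threshold) & (sign != 0)
        idx = np.flatnonzero(sig)
        if idx.size == 0:
            continue
        runs: list[list[int]] = [[idx[0]]]
        for i in idx[1:]:
            prev = runs[-1][-1]
            if pos[i] - pos[prev] <= params.max_gap and sign[i] == sign[prev]:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            first, last = run[0], run[-1]
            start0 = int(pos[first]) - 1
            end0 = int(pos[last])  # half-open, includes last site
            length = end0 - start0
            n_sig = len(run)
            in_region = (pos >= pos[first]) & (pos <= pos[last])
            n_total = int(in_region.sum())
            if (
                length < params.min_len
                or n_sig < params.min_sites
                or n_sig / n_total < params.pct_sig
            ):
                continue
            reg = sub[in_region]
            raw1 = reg["raw_meth1"].sum() / max(reg["raw_depth1"].sum(), 1e-12)
            raw2 = reg["raw_meth2"].sum() / max(reg["raw_depth2"].sum(), 1e-12)
            mean_diff = float(raw1 - raw2)
            records.append(
                {
                    "chrom": chrom,
                    "start": start0,
                    "end": end0,
                    "context": context,
                    "direction": "hyper" if mean_diff > 0 else "hypo",
                    "n_sites": n_sig,
                    "n_sites_total": n_total,
                    "mean_diff": mean_diff,
                    "area_stat": float(reg.loc[reg["p"] < params.p_threshold, "stat"].sum()),
                    "mean_mu1": float(reg["mu1"].mean()),
                    "mean_mu2": float(reg["mu2"].mean()),
                }
            )
    cols = [
        "chrom", "start", "end", "context", "direction", "n_sites",
        "n_sites_total", "mean_diff", "area_stat", "mean_mu1", "mean_mu2",
    ]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame.from_records(records)[cols]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_dmrs(dmrs: pd.DataFrame, index: FeatureIndex) -> pd.DataFrame:
    """Attach feature overlaps to each DMR (>= 1 bp overlap rule).

    Adds gene_body_hits / promoter_hits (comma-joined gene ids) and
    te_hits (te ids); a DMR spanning the TSS lists the gene under both
    body and promoter.
    """
    out = dmrs.copy()
    body_hits, prom_hits, te_hits = [], [], []
    for row in out.itertuples():
        body_hits.append(",".join(index.genes_overlapping(row.chrom, row.start, row.end, "body")))
        prom_hits.append(",".join(index.genes_overlapping(row.chrom, row.start, row.end, "promoter")))
        tes = index.tes_overlapping(row.chrom, row.start, row.end)
        te_hits.append(",".join(sorted(tes["te_id"])) if len(tes) else "")
    out["gene_body_hits"] = body_hits
    out["promoter_hits"] = prom_hits
    out["te_hits"] = te_hits
    return out


def dmr_gene_table(annotated: pd.DataFrame) -> pd.DataFrame:
    """Long-format DMR-related gene table: one row per
    (gene, region in {body, promoter}, DMR)."""
    rows = []
    for i, row in annotated.iterrows():
        for region, col in (("body", "gene_body_hits"), ("promoter", "promoter_hits")):
            hits = [g for g in str(row[col]).split(",") if g]
            for g in hits:
                rows.append(
                    {
                        "gene_id": g,
                        "region": region,
                        "dmr_index": i,
                        "chrom": row["chrom"],
                        "start": row["start"],
                        "end": row["end"],
                        "context": row["context"],
                        "direction": row["direction"],
                        "mean_diff": row["mean_diff"],
                    }
                )
    cols = ["gene_id", "region", "dmr_index", "chrom", "start", "end",
            "context", "direction", "mean_diff"]
    return pd.DataFrame(rows, columns=cols)


def dmr_region_distribution(
    annotated: pd.DataFrame, index: FeatureIndex,
    labels: Sequence[str] = ("promoter", "exon", "intron", "up2k", "down2k", "TE", "intergenic"),
) -> pd.DataFrame:
    """Fraction of total DMR length overlapping each region label,
    per context and direction (a DMR can count toward several labels)."""
    rows = []
    label_ivs = {lab: index.label_intervals(lab) for lab in labels if lab != "intergenic"}
    for (context, direction), sub in annotated.groupby(["context", "direction"]):
        total = float((sub["end"] - sub["start"]).sum())
        for lab in labels:
            ov = 0.0
            for row in sub.itertuples():
                if lab == "intergenic":
                    continue
                ivs = label_ivs[lab].get(row.chrom)
                if ivs is None:
                    continue
                # merged overlap of the DMR with this label's intervals
                clipped = np.clip(ivs, row.start, row.end)
                merged = _merge_length(clipped[clipped[:, 1] > clipped[:, 0]])
                ov += merged
            if lab == "intergenic":
                continue
            rows.append(
                {
                    "context": context,
                    "direction": direction,
                    "label": lab,
                    "length_fraction": ov / total if total else np.nan,
                    "total_dmr_bp": total,
                }
            )
    return pd.DataFrame(rows)


def _merge_length(intervals: np.ndarray) -> float:
    if len(intervals) == 0:
        return 0.0
    ivs = intervals[np.argsort(intervals[:, 0])]
    total, cur_lo, cur_hi = 0.0, ivs[0, 0], ivs[0, 1]
    for lo, hi in ivs[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    return float(total + (cur_hi - cur_lo))
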