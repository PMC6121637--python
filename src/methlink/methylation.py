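"""Per-site methylation levels, sequence-context classification, and
genome-wide context summaries for whole-genome bisulfite data.

A cytosine site is observed as a pair of read counts: ``meth`` reads
supporting methylation (unconverted C) and ``unmeth`` reads supporting
no methylation (converted to T).  The methylation level of a covered
site is

    ML = meth / (meth + unmeth)

and, when an unmethylated spike-in control is available, the level is
corrected for incomplete bisulfite conversion with rate ``r``:

    ML_corrected = (ML - r) / (1 - r)

Cytosines are classified by their downstream dinucleotide into the
three plant contexts CG, CHG and CHH (H = A, T or C), reading the
minus strand as its reverse complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
AMBIGUOUS = "ambiguous"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NonconversionRate:
    """Bisulfite non-conversion rate estimated from an unmethylated control.

    ``r`` is the fraction of reads over control cytosines that appear
    methylated; on a fully unmethylated spike-in every such read is a
    conversion failure.
    """

    r: float
    n_control_reads: int
    n_apparent_methylated: int

    def __post_init__(self):
        if not (0.0 <= self.r < 1.0):
            raise ValueError(f"non-conversion rate must be in [0, 1), got {self.r}")


class MissingControlError(ValueError):
    """Raised when a non-conversion estimate is requested without control data."""


@dataclass
class Methylome:
    """Per-cytosine counts for a multi-sample experiment, wide layout.

    ``sites`` has one row per (chrom, pos, strand) with columns
    ``chrom, pos, strand, context`` plus ``meth_<sample>`` and
    ``unmeth_<sample>`` for every sample.  ``pos`` is 1-based, matching
    the cytosine-report convention; interval arithmetic elsewhere in the
    package is 0-based half-open.
    """

    sites: pd.DataFrame
    samples: list[str]
    conditions: dict[str, list[str]] = field(default_factory=dict)

    def counts(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.sites[f"meth_{sample}"].to_numpy(),
            self.sites[f"unmeth_{sample}"].to_numpy(),
        )

    def depth(self, sample: str) -> np.ndarray:
        m, u = self.counts(sample)
        return m + u

    def levels(self, sample: str) -> np.ndarray:
        m, u = self.counts(sample)
        return methylation_level(m, u)

    def condition_of(self, sample: str) -> str:
        for cond, members in self.conditions.items():
            if sample in members:
                return cond
        raise KeyError(sample)


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def classify_context(seq: str, pos: int, strand: str) -> str | None:
    """Classify the cytosine at 1-based ``pos`` on ``strand`` of ``seq``.

    Returns "CG", "CHG" or "CHH"; ``None`` if the strand-oriented base at
    ``pos`` is not a cytosine; or :data:`AMBIGUOUS` when the contig ends
    before the context can be resolved (a truncated context is never
    guessed to be CHH).
    """
    i = pos - 1
    if i < 0 or i >= len(seq):
        raise IndexError(f"position {pos} outside sequence of length {len(seq)}")
    if strand == "+":
        b0 = seq[i].upper()
        nxt = seq[i + 1].upper() if i + 1 < len(seq) else None
        nxt2 = seq[i + 2].upper() if i + 2 < len(seq) else None
    elif strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        b0 = comp.get(seq[i].upper(), "N")
        nxt = comp.get(seq[i - 1].upper(), "N") if i - 1 >= 0 else None
        nxt2 = comp.get(seq[i - 2].upper(), "N") if i - 2 >= 0 else None
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if b0 != "C":
        return None
    if nxt is None:
        return AMBIGUOUS
    if nxt == "G":
        return "CG"
    if nxt2 is None:
        return AMBIGUOUS
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def context_table(seq: str) -> pd.DataFrame:
    """Vectorised context scan of one contig, both strands.

    Returns a DataFrame with 1-based ``pos``, ``strand`` and ``context``
    for every cytosine whose context is resolvable (edge cytosines with
    truncated context are dropped).  Sorted by position then strand.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    n = len(arr)
    is_c = arr == b"C"
    is_g = arr == b"G"

    rows = []
    # plus strand: C at i, look at i+1, i+2
    idx = np.flatnonzero(is_c)
    idx = idx[idx + 1 < n]
    nxt_g = is_g[idx + 1]
    ctx = np.full(idx.shape, "", dtype="U3")
    ctx[nxt_g] = "CG"
    rest = ~nxt_g
    ok2 = idx + 2 < n
    chg = rest & ok2 & np.where(ok2, is_g[np.minimum(idx + 2, n - 1)], False)
    chh = rest & ok2 & ~chg
    ctx[chg] = "CHG"
    ctx[chh] = "CHH"
    keep = ctx != ""
    rows.append(pd.DataFrame({"pos": idx[keep] + 1, "strand": "+", "context": ctx[keep]}))

    # minus strand: G at i in reference reads as C; context at i-1, i-2
    idx = np.flatnonzero(is_g)
    idx = idx[idx - 1 >= 0]
    nxt_c = is_c[idx - 1]  # complement of C is G -> next base (3' on minus) is G
    ctx = np.full(idx.shape, "", dtype="U3")
    ctx[nxt_c] = "CG"
    rest = ~nxt_c
    ok2 = idx - 2 >= 0
    chg = rest & ok2 & np.where(ok2, is_c[np.maximum(idx - 2, 0)], False)
    chh = rest & ok2 & ~chg
    ctx[chg] = "CHG"
    ctx[chh] = "CHH"
    keep = ctx != ""
    rows.append(pd.DataFrame({"pos": idx[keep] + 1, "strand": "-", "context": ctx[keep]}))

    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# levels
# ---------------------------------------------------------------------------

def methylation_level(meth, unmeth):
    """ML = meth / (meth + unmeth); NaN where the site has zero coverage.

    Zero-coverage sites are undefined, not zero — callers drop NaN.
    Accepts scalars or arrays.
    """
    m = np.asarray(meth, dtype=float)
    u = np.asarray(unmeth, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("read counts must be non-negative")
    depth = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(depth > 0, m / np.where(depth > 0, depth, 1), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def correct_level(ml, r: float):
    """Invert the non-conversion mixture: (ML - r) / (1 - r), clipped to [0, 1].

    A truly unmethylated site observed at level r maps back to 0.
    """
    if not (0.0 <= r < 1.0):
        raise ValueError(f"non-conversion rate must be in [0, 1), got {r}")
    ml_arr = np.asarray(ml, dtype=float)
    out = np.clip((ml_arr - r) / (1.0 - r), 0.0, 1.0)
    out = np.where(np.isnan(ml_arr), np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def estimate_nonconversion(meth, unmeth) -> NonconversionRate:
    """Estimate r from an unmethylated control: apparent-methylated reads
    over all reads at control cytosines."""
    m = np.asarray(meth, dtype=float)
    u = np.asarray(unmeth, dtype=float)
    total = float(m.sum() + u.sum())
    if m.size == 0 or total <= 0:
        raise MissingControlError(
            "no covered control cytosines; supply r manually"
        )
    n_meth = float(m.sum())
    return NonconversionRate(
        r=n_meth / total,
        n_control_reads=int(round(total)),
        n_apparent_methylated=int(round(n_meth)),
    )


# ---------------------------------------------------------------------------
# methylated-site calling and context summaries
# ---------------------------------------------------------------------------

def call_methylated(
    meth: np.ndarray,
    unmeth: np.ndarray,
    context: np.ndarray,
    r: float = 0.0,
    q: float = 0.01,
) -> np.ndarray:
    """Binary methylated/unmethylated call per covered site.

    A site is methylated when its methylated-read count is inconsistent
    with pure non-conversion noise: one-sided binomial test of
    meth >= observed against rate ``r``, BH-adjusted within each context
    at ``q``.  With r = 0 this reduces to meth >= 1.  Uncovered sites
    are False.
    """
    m = np.asarray(meth)
    depth = m + np.asarray(unmeth)
    covered = depth > 0
    called = np.zeros(m.shape, dtype=bool)
    if r <= 0:
        called[covered] = m[covered] >= 1
        return called
    pvals = stats.binom.sf(m - 1, depth, r)  # P(X >= m | depth, r)
    ctx = np.asarray(context)
    for c in np.unique(ctx[covered]):
        sel = covered & (ctx == c) & (m >= 1)
        if not sel.any():
            continue
        reject = multipletests(pvals[sel], alpha=q, method="fdr_bh")[0]
        called[np.flatnonzero(sel)] = reject
    return called


@dataclass
class ContextSummary:
    """Per-sample and averaged methylated-site tallies by context.

    ``per_sample``: rows = samples, tidy columns (context, n_sites,
    n_methylated, ratio) including a ``total`` pseudo-context.
    ``averages``: one row per condition plus ``all``; counts are
    arithmetic means of the constituent samples, ratios recomputed from
    the mean counts.  ``relative_proportions``: each sample's share of
    its methylated sites per context, plus the across-sample mean.
    """

    per_sample: pd.DataFrame
    averages: pd.DataFrame
    relative_proportions: pd.DataFrame


def summarize_context_counts(
    counts: pd.DataFrame, condition_of: Mapping[str, str]
) -> ContextSummary:
    """Summary arithmetic from pre-tabulated per-sample, per-context counts.

    ``counts`` columns: sample, context (CG/CHG/CHH), n_sites,
    n_methylated.  Totals over contexts are derived, ratios are
    n_methylated / n_sites, condition and grand averages are means of
    the replicate counts, and relative proportions are each context's
    share of a sample's methylated sites.
    """
    required = {"sample", "context", "n_sites", "n_methylated"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    df = counts.copy()
    totals = (
        df.groupby("sample", sort=False)[["n_sites", "n_methylated"]]
        .sum()
        .reset_index()
        .assign(context="total")
    )
    per_sample = pd.concat([df, totals], ignore_index=True)
    per_sample["ratio"] = per_sample["n_methylated"] / per_sample["n_sites"]

    samples = list(dict.fromkeys(df["sample"]))
    rows = []
    groups: dict[str, list[str]] = {}
    for s in samples:
        groups.setdefault(condition_of[s], []).append(s)
    for label, members in list(groups.items()) + [("all", samples)]:
        sub = per_sample[per_sample["sample"].isin(members)]
        agg = sub.groupby("context", sort=False)[["n_sites", "n_methylated"]].mean()
        agg["ratio"] = agg["n_methylated"] / agg["n_sites"]
        agg = agg.reset_index().assign(group=label)
        rows.append(agg)
    averages = pd.concat(rows, ignore_index=True)[
        ["group", "context", "n_sites", "n_methylated", "ratio"]
    ]

    share = df.pivot(index="sample", columns="context", values="n_methylated")
    share = share.div(share.sum(axis=1), axis=0)[list(CONTEXTS)]
    share.loc["mean"] = share.loc[samples].mean(axis=0)
    return ContextSummary(
        per_sample=per_sample, averages=averages, relative_proportions=share
    )


def summarize_contexts(
    methylome: Methylome, r: float = 0.0, q: float = 0.01
) -> ContextSummary:
    """Tabulate methylated sites per sample and context from raw counts.

    Site universes are each sample's covered sites; a warning is logged
    when samples cover unequal site sets.  Site calls use
    :func:`call_methylated`.
    """
    ctx = methylome.sites["context"].to_numpy()
    cov_counts = []
    records = []
    for s in methylome.samples:
        m, u = methylome.counts(s)
        covered = (m + u) > 0
        cov_counts.append(int(covered.sum()))
        called = call_methylated(m, u, ctx, r=r, q=q)
        for c in CONTEXTS:
            sel = covered & (ctx == c)
            records.append(
                {
                    "sample": s,
                    "context": c,
                    "n_sites": int(sel.sum()),
                    "n_methylated": int((called & sel).sum()),
                }
            )
    if len(set(cov_counts)) > 1:
        logger.warning(
            "samples cover unequal site universes (%s); summaries use each "
            "sample's own covered sites",
            dict(zip(methylome.samples, cov_counts)),
        )
    condition_of = {
        s: methylome.condition_of(s) if methylome.conditions else "all"
        for s in methylome.samples
    }
    return summarize_context_counts(pd.DataFrame.from_records(records), condition_of)


def level_histogram(
    levels: np.ndarray, context: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Counts of covered sites per methylation-level bin, per context.

    Bins partition [0, 1] into ``n_bins`` equal intervals, the last one
    closed, so fully methylated sites land in the top bin.  NaN levels
    (uncovered sites) are excluded.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = {}
    lv = np.asarray(levels, dtype=float)
    ctx = np.asarray(context)
    for c in CONTEXTS:
        vals = lv[(ctx == c) & ~np.isnan(lv)]
        out[c], _ = np.histogram(vals, bins=edges)
    df = pd.DataFrame(out)
    df.insert(0, "bin_low", edges[:-1])
    df.insert(1, "bin_high", edges[1:])
    return df
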