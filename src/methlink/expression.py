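"""Gene-expression quantification and a minimal negative-binomial
two-group differential-expression test.

Counts K_gs for gene g in sample s are modelled as negative binomial,
Var(K) = mu + alpha mu^2, with a per-gene dispersion alpha moderated
toward a mean-dispersion trend alpha(mu) = a0 + a1/mu fitted across
genes.  Libraries are normalised by median-of-ratios size factors and
differential expression between two replicated conditions is assessed
with a Wald test on the log of the normalised condition means, BH
adjusted.  This is a deliberately small re-derivation of the classic
NB workflow, not a re-implementation of any particular tool.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    The reference is the per-gene geometric mean over samples (genes
    with a zero anywhere are excluded); each sample's factor is the
    median ratio of its counts to the reference.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    logmat = np.log(mat[positive])
    ref = logmat.mean(axis=1)
    sf = np.exp(np.median(logmat - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = counts * 1e9 / (length_bp * library_size).

    Library sizes default to column sums of the count matrix.
    """
    lengths = gene_lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any() or lengths.isna().any():
        bad = lengths.index[(lengths <= 0) | lengths.isna()].tolist()[:5]
        raise ValueError(f"non-positive or missing gene lengths, e.g. {bad}")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lib = library_sizes.reindex(counts.columns).astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.astype(float).div(lengths, axis=0).div(lib, axis=1) * 1e9


def condition_means(table: pd.DataFrame, condition_of: dict[str, str]) -> pd.DataFrame:
    """Replicate-averaged columns, one per condition."""
    groups: dict[str, list[str]] = {}
    for s in table.columns:
        groups.setdefault(condition_of[s], []).append(s)
    return pd.DataFrame({c: table[cols].mean(axis=1) for c, cols in groups.items()})


def classify_expressed(
    fpkm: pd.DataFrame,
    condition_of: dict[str, str],
    threshold: float = 1.0,
) -> pd.Series:
    """Label each gene by where it is expressed (condition-mean FPKM >=
    threshold): one condition name, "both", or "neither"."""
    means = condition_means(fpkm, condition_of)
    conds = list(means.columns)
    if len(conds) != 2:
        raise ValueError(f"expected two conditions, got {conds}")
    a, b = conds
    in_a = means[a] >= threshold
    in_b = means[b] >= threshold
    out = pd.Series("neither", index=fpkm.index, dtype=object)
    out[in_a & in_b] = "both"
    out[in_a & ~in_b] = a
    out[~in_a & in_b] = b
    return out


# ---------------------------------------------------------------------------
# NB differential expression
# ---------------------------------------------------------------------------

def _dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by non-negative least squares over
    genes with a usable method-of-moments estimate."""
    ok = np.isfinite(alpha) & (mu > 0) & (alpha > 0)
    if ok.sum() < 10:
        return (float(np.nanmedian(alpha[np.isfinite(alpha)])) if np.isfinite(alpha).any() else 0.1, 0.0)
    design = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, _ = optimize.nnls(design, alpha[ok])
    return float(coef[0]), float(coef[1])


def detect_degs(
    counts: pd.DataFrame,
    condition_of: dict[str, str],
    condition1: str = "WT",
    condition2: str = "RT",
    alpha: float = 0.05,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """Two-group NB Wald test with moderated dispersion.

    Per gene: size-factor-normalised condition means m1, m2; pooled
    within-condition method-of-moments dispersion, squeezed toward the
    fitted trend with prior weight ``prior_df`` (residual df of the
    design contributes the per-gene weight); Wald statistic

        z = (log(m1 + 0.5) - log(m2 + 0.5)) / se,
        se^2 = (1/(m1+0.5) + a)/R1 + (1/(m2+0.5) + a)/R2,

    two-sided normal p, BH adjustment.  status is "up" when condition 1
    is the higher (padj < alpha), "down" when lower, else "ns"; all-zero
    genes get p = 1.  Swapping the condition labels flips every LFC sign
    and leaves p-values unchanged.
    """
    s1 = [s for s in counts.columns if condition_of[s] == condition1]
    s2 = [s for s in counts.columns if condition_of[s] == condition2]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("need >= 2 replicates per condition")
    sf = size_factors(counts[s1 + s2])
    norm = counts[s1 + s2].div(sf, axis=1)
    n1 = norm[s1].to_numpy(dtype=float)
    n2 = norm[s2].to_numpy(dtype=float)
    R1, R2 = n1.shape[1], n2.shape[1]
    m1 = n1.mean(axis=1)
    m2 = n2.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()

    # pooled within-condition variance -> MoM dispersion
    v_within = (n1.var(axis=1, ddof=1) * (R1 - 1) + n2.var(axis=1, ddof=1) * (R2 - 1)) / (
        R1 + R2 - 2
    )
    mu_bar = (m1 + m2) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mom = (v_within - mu_bar) / np.maximum(mu_bar, 1e-12) ** 2
    a0, a1 = _dispersion_trend(mu_bar, alpha_mom)
    trend = a0 + a1 / np.maximum(mu_bar, 1e-12)
    df_res = R1 + R2 - 2
    w = df_res / (df_res + prior_df)
    alpha_use = np.clip(
        np.where(np.isfinite(alpha_mom), w * np.clip(alpha_mom, 0, None) + (1 - w) * trend, trend),
        1e-8,
        10.0,
    )

    lfc_nat = np.log(m1 + 0.5) - np.log(m2 + 0.5)
    se = np.sqrt(
        (1.0 / (m1 + 0.5) + alpha_use) / R1 + (1.0 / (m2 + 0.5) + alpha_use) / R2
    )
    z = lfc_nat / se
    p = 2 * stats.norm.sf(np.abs(z))
    allzero = (m1 == 0) & (m2 == 0)
    p = np.where(allzero, 1.0, p)
    z = np.where(allzero, 0.0, z)
    padj = multipletests(p, method="fdr_bh")[1]
    lfc2 = lfc_nat / np.log(2)
    status = np.where(
        (padj < alpha) & (lfc2 > 0), "up", np.where((padj < alpha) & (lfc2 < 0), "down", "ns")
    )
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "mean_1": m1,
            "mean_2": m2,
            "log2_fold_change": lfc2,
            "dispersion": alpha_use,
            "stat": z,
            "p_value": p,
            "p_adjusted": padj,
            "status": status,
        },
        index=counts.index,
    )
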