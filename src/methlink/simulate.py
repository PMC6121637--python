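"""Self-contained synthetic fixtures for the full pipeline.

The generator emits everything the analysis consumes — a small
multi-chromosome genome, gene and TE annotations, per-cytosine
methylation counts for a two-condition, three-replicate design, a
gene-level count matrix, and an unmethylated spike-in contig — with
the statistical structure the downstream methods assume:

* per-site methylated counts are beta-binomial around context-specific
  baseline levels (CG high, CHG intermediate, CHH low), with Poisson
  read depth;
* planted differentially methylated regions shift the mean level of
  one sequence context in the first condition, in promoters, gene
  bodies, TEs or intergenic space;
* bisulfite non-conversion is applied as the mixture
  mu_obs = mu + (1 - mu) * r, whose exact inverse is the level
  correction formula, and the spike-in contig ("lambda_control") is
  truly unmethylated so its apparent level estimates r;
* expression counts are negative binomial with the condition mean
  coupled to the planted promoter methylation difference through
  exp(coupling_slope * delta_meth), emulating the negative
  methylation-expression relationship the integration layer looks for.

Everything is deterministic given the seed, including the emitted
files (byte-identical re-runs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FLANK_BP, GeneModel
from .methylation import CONTEXTS, Methylome, context_table

logger = logging.getLogger(__name__)

SPIKEIN_CHROM = "lambda_control"

TE_FAMILIES = {
    "classI": ("Copia", "Gypsy", "LINE-L1"),
    "classII": ("Helitron", "hAT", "MuDR"),
}


class SizingError(ValueError):
    """Requested annotation counts cannot fit in the requested genome."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic fixture.

    Defaults emulate a two-condition (WT vs RT), three-replicate WGBS +
    RNA-seq petal experiment at ~30x depth: context baselines follow
    genome-wide plant petal averages (CG 0.380, CHG 0.204, CHH 0.092),
    replicate dispersion 0.05 per context, and 150 planted DMRs of
    |effect| 0.4 spread over promoters, bodies, TEs and intergenic
    space, with promoter methylation coupled to expression at slope -2
    (natural-log fold change per unit methylation difference).
    """

    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    n_genes: int = 300
    n_tes: int = 300
    te_class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"classI": 0.6, "classII": 0.4}
    )
    conditions: tuple[str, str] = ("WT", "RT")
    replicates_per_condition: int = 3
    baseline_levels: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.380, "CHG": 0.204, "CHH": 0.092}
    )
    dispersion: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.05, "CHG": 0.05, "CHH": 0.05}
    )
    depth_mean: float = 30.0
    n_dmrs: int = 150
    dmr_effect: float = 0.4
    dmr_placement: Mapping[str, float] = field(
        default_factory=lambda: {
            "promoter": 0.4,
            "body": 0.3,
            "te": 0.2,
            "intergenic": 0.1,
        }
    )
    coupling_slope: float = -2.0
    nonconversion_rate: float = 0.008
    seed: int = 0

    # secondary knobs (kept out of the headline signature)
    gc_content: float = 0.38
    gene_length_range: tuple[int, int] = (1000, 3000)
    max_exons: int = 4
    te_length_range: tuple[int, int] = (200, 2000)
    dmr_length_range: tuple[int, int] = (200, 1000)
    min_dmr_sites: int = 5
    hyper_fraction: float = 0.5
    expr_log_mean: float = np.log(150.0)
    expr_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    spikein_length: int = 20_000

    def validate(self) -> None:
        def _check_fractions(name, d):
            vals = np.array(list(d.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"{name} proportions must lie in [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1, got {vals.sum()}")

        _check_fractions("te_class_fractions", self.te_class_fractions)
        _check_fractions("dmr_placement", self.dmr_placement)
        for name, d in (("baseline_levels", self.baseline_levels),
                        ("dispersion", self.dispersion)):
            for c in CONTEXTS:
                v = d[c]
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{name}[{c}] must be in [0, 1], got {v}")
        if self.replicates_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not (0.0 <= self.nonconversion_rate <= 0.05):
            raise ValueError("nonconversion_rate must be in [0, 0.05]")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are supported")

    @property
    def samples(self) -> list[str]:
        return [
            f"{cond}_{i + 1}"
            for cond in self.conditions
            for i in range(self.replicates_per_condition)
        ]

    @property
    def condition_map(self) -> dict[str, list[str]]:
        return {
            cond: [f"{cond}_{i + 1}" for i in range(self.replicates_per_condition)]
            for cond in self.conditions
        }


@dataclass
class Fixture:
    """In-memory synthetic dataset; file serialisation lives in io."""

    config: SimConfig
    genome: dict[str, str]  # chrom -> sequence (includes the spike-in contig)
    genes: list[GeneModel]
    tes: pd.DataFrame  # chrom, start, end, te_id, te_class, family, strand
    methylome: Methylome
    spikein: Methylome
    truth_dmrs: pd.DataFrame
    truth_genes: pd.DataFrame
    counts: pd.DataFrame  # genes x samples
    gene_lengths: pd.Series

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {
            c: len(s) for c, s in self.genome.items() if c != SPIKEIN_CHROM
        }


# ---------------------------------------------------------------------------
# genome and annotations
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)
    return bases.tobytes().decode("ascii")


def generate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame]:
    """Random genome with non-overlapping genes and scattered TEs.

    Gene bodies never overlap each other and keep a 2-kb margin from
    chromosome ends so promoters and flanks always exist.  TEs may fall
    inside or between genes.  Raises :class:`SizingError` when the
    requested gene count cannot fit.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom_len = config.genome_length // config.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {c: _random_sequence(rng, chrom_len, config.gc_content) for c in chroms}
    genome[SPIKEIN_CHROM] = _random_sequence(rng, config.spikein_length, config.gc_content)

    lmin, lmax = config.gene_length_range
    margin = FLANK_BP
    usable = chrom_len - 2 * margin
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    # feasibility: bodies plus a 1-bp gap each must fit the usable span
    if any(n * (lmax + 1) > usable for n in per_chrom):
        raise SizingError(
            f"{config.n_genes} genes of up to {lmax} bp cannot fit "
            f"{config.n_chromosomes} x {chrom_len} bp with {margin} bp margins"
        )
    genes: list[GeneModel] = []
    gi = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        lengths = rng.integers(lmin, lmax + 1, size=n)
        slack = usable - int(lengths.sum())
        if slack < n:
            raise SizingError(f"gene bodies do not fit on {chrom}")
        # distribute the slack as inter-gene gaps (ordered uniform split)
        cuts = np.sort(rng.choice(slack, size=n, replace=False))
        starts = margin + cuts + np.concatenate([[0], np.cumsum(lengths[:-1])])
        for start, length in zip(starts, lengths):
            start, end = int(start), int(start + length)
            n_ex = int(rng.integers(1, config.max_exons + 1))
            if n_ex == 1:
                exons = [(start, end)]
            else:
                inner = np.sort(
                    rng.choice(np.arange(start + 1, end), size=2 * n_ex - 2, replace=False)
                )
                bounds = np.concatenate([[start], inner, [end]])
                exons = [
                    (int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_ex)
                ]
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:04d}",
                    chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    start=start,
                    end=end,
                    exons=exons,
                )
            )
            gi += 1

    te_rows = []
    tmin, tmax = config.te_length_range
    classes = list(config.te_class_fractions)
    class_p = np.array([config.te_class_fractions[c] for c in classes])
    for ti in range(config.n_tes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(tmin, tmax + 1))
        start = int(rng.integers(0, chrom_len - length))
        te_class = classes[int(rng.choice(len(classes), p=class_p))]
        family = TE_FAMILIES[te_class][int(rng.integers(len(TE_FAMILIES[te_class])))]
        te_rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "te_id": f"te{ti + 1:04d}",
                "te_class": te_class,
                "family": family,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    tes = pd.DataFrame(
        te_rows,
        columns=["chrom", "start", "end", "te_id", "te_class", "family", "strand"],
    )
    return genome, genes, tes


# ---------------------------------------------------------------------------
# DMR planting
# ---------------------------------------------------------------------------

def _context_positions(ctx_tables: Mapping[str, pd.DataFrame], chrom: str, context: str) -> np.ndarray:
    t = ctx_tables[chrom]
    return t.loc[t["context"] == context, "pos"].to_numpy() - 1  # 0-based


def plant_dmrs(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    tes: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    ctx_tables: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Choose the planted differentially methylated regions.

    Each DMR gets a placement (promoter / body / te / intergenic by the
    configured proportions), a target context (CG 0.4, CHG 0.3,
    CHH 0.3), a signed effect (+|effect| = hyper in the first
    condition, hyper_fraction of the time) and an interval holding at
    least ``min_dmr_sites`` cytosines of the context.  Planted regions
    never overlap one another.  The truth table records the nominal and
    the clip-realised effect.
    """
    chroms = [c for c in genome if c != SPIKEIN_CHROM]
    if ctx_tables is None:
        ctx_tables = {c: context_table(genome[c]) for c in chroms}
    placements = list(config.dmr_placement)
    place_p = np.array([config.dmr_placement[k] for k in placements])
    ctx_choices, ctx_p = list(CONTEXTS), np.array([0.4, 0.3, 0.3])
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    lmin, lmax = config.dmr_length_range
    base = config.baseline_levels
    n_placed = 0
    for di in range(config.n_dmrs):
        placed = False
        for _attempt in range(200):
            placement = placements[int(rng.choice(len(placements), p=place_p))]
            context = ctx_choices[int(rng.choice(len(ctx_choices), p=ctx_p))]
            length = int(rng.integers(lmin, lmax + 1))
            gene_id, te_id = "", ""
            if placement == "promoter" and genes:
                g = genes[int(rng.integers(len(genes)))]
                lo, hi, _ = g.promoter(len(genome[g.chrom]))
                chrom, gene_id = g.chrom, g.gene_id
            elif placement == "body" and genes:
                g = genes[int(rng.integers(len(genes)))]
                lo, hi = g.start, g.end
                chrom, gene_id = g.chrom, g.gene_id
            elif placement == "te" and len(tes):
                te = tes.iloc[int(rng.integers(len(tes)))]
                lo, hi, chrom, te_id = int(te["start"]), int(te["end"]), te["chrom"], te["te_id"]
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                lo, hi = FLANK_BP, len(genome[chrom]) - FLANK_BP
                placement = "intergenic"
            length = min(length, hi - lo)
            if length < lmin // 2:
                continue
            start = int(rng.integers(lo, hi - length + 1))
            end = start + length
            if placement == "intergenic":
                # keep clear of gene domains and TEs
                clash = any(
                    g.start - FLANK_BP < end and start < g.end + FLANK_BP
                    for g in genes_by_chrom.get(chrom, [])
                )
                tsub = tes[tes["chrom"] == chrom]
                clash = clash or bool(
                    ((tsub["start"] < end) & (start < tsub["end"])).any()
                )
                if clash:
                    continue
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            cpos = _context_positions(ctx_tables, chrom, context)
            n_sites = int(((cpos >= start) & (cpos < end)).sum())
            if n_sites < config.min_dmr_sites:
                continue
            sign = 1.0 if rng.random() < config.hyper_fraction else -1.0
            effect = sign * config.dmr_effect
            mu_shift = base[context] + effect
            realized = float(np.clip(mu_shift, 0.0, 1.0) - base[context])
            if realized != effect:
                logger.warning(
                    "dmr%04d: effect %.2f clipped to %.3f at baseline %.3f",
                    di + 1, effect, realized, base[context],
                )
            occupied[chrom].append((start, end))
            rows.append(
                {
                    "dmr_id": f"dmr{di + 1:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "context": context,
                    "placement": placement,
                    "gene_id": gene_id,
                    "te_id": te_id,
                    "effect": effect,
                    "realized_effect": realized,
                    "direction": "hyper" if effect > 0 else "hypo",
                    "n_target_sites": n_sites,
                }
            )
            placed = True
            n_placed += 1
            break
        if not placed:
            logger.warning("could not place DMR %d after 200 attempts", di + 1)
    return pd.DataFrame(
        rows,
        columns=[
            "dmr_id", "chrom", "start", "end", "context", "placement",
            "gene_id", "te_id", "effect", "realized_effect", "direction",
            "n_target_sites",
        ],
    )


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

def _beta_binomial(
    rng: np.random.Generator, depth: np.ndarray, mu: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Beta-binomial draw; phi = 0 degenerates to plain binomial."""
    p = np.array(mu, dtype=float, copy=True)
    disp = phi > 0
    interior = disp & (mu > 0) & (mu < 1)
    if interior.any():
        conc = (1.0 - phi[interior]) / phi[interior]
        p[interior] = rng.beta(mu[interior] * conc, (1 - mu[interior]) * conc)
    return rng.binomial(depth, np.clip(p, 0.0, 1.0))


def simulate_methylome(
    genome: Mapping[str, str],
    truth_dmrs: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    ctx_tables: Mapping[str, pd.DataFrame] | None = None,
) -> tuple[Methylome, Methylome]:
    """Draw per-site counts for every cytosine of every sample.

    Site means are the context baselines, shifted by each planted
    DMR's effect for the first condition only, clipped to [0, 1], then
    mixed with the non-conversion floor.  Depth is Poisson per site and
    sample; replicate variation is beta-binomial with the context
    dispersion.  Returns (methylome, spike-in methylome); the spike-in
    contig is simulated with true level 0 everywhere.
    """
    config.validate()
    chroms = [c for c in genome if c != SPIKEIN_CHROM]
    if ctx_tables is None:
        ctx_tables = {c: context_table(genome[c]) for c in chroms}
    cond1 = config.conditions[0]
    r = config.nonconversion_rate
    frames = []
    for chrom in chroms:
        t = ctx_tables[chrom]
        pos0 = t["pos"].to_numpy() - 1
        ctx = t["context"].to_numpy()
        mu_base = np.array([config.baseline_levels[c] for c in ctx])
        phi = np.array([config.dispersion[c] for c in ctx])
        mu = {cond: mu_base.copy() for cond in config.conditions}
        tsub = truth_dmrs[truth_dmrs["chrom"] == chrom] if len(truth_dmrs) else truth_dmrs
        for row in tsub.itertuples():
            sel = (pos0 >= row.start) & (pos0 < row.end) & (ctx == row.context)
            mu[cond1][sel] = np.clip(mu[cond1][sel] + row.effect, 0.0, 1.0)
        frame = t.copy()
        frame.insert(0, "chrom", chrom)
        for cond in config.conditions:
            mu_obs = mu[cond] + (1.0 - mu[cond]) * r
            for s in config.condition_map[cond]:
                depth = rng.poisson(config.depth_mean, size=len(pos0))
                meth = _beta_binomial(rng, depth, mu_obs, phi)
                frame[f"meth_{s}"] = meth
                frame[f"unmeth_{s}"] = depth - meth
        frames.append(frame)
    sites = pd.concat(frames, ignore_index=True)
    methylome = Methylome(
        sites=sites, samples=config.samples, conditions=config.condition_map
    )

    spike_t = context_table(genome[SPIKEIN_CHROM])
    spike = spike_t.copy()
    spike.insert(0, "chrom", SPIKEIN_CHROM)
    mu_obs = np.full(len(spike_t), r)
    phi = np.array([config.dispersion[c] for c in spike_t["context"]])
    for s in config.samples:
        depth = rng.poisson(config.depth_mean, size=len(spike_t))
        meth = _beta_binomial(rng, depth, mu_obs, phi)
        spike[f"meth_{s}"] = meth
        spike[f"unmeth_{s}"] = depth - meth
    spikein = Methylome(
        sites=spike, samples=config.samples, conditions=config.condition_map
    )
    return methylome, spikein


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def promoter_meth_difference(
    genes: Sequence[GeneModel], truth_dmrs: pd.DataFrame, flank: int = FLANK_BP
) -> pd.Series:
    """True per-gene promoter methylation shift (condition 1 minus
    condition 2): the summed realised effects of planted DMRs that
    overlap the promoter.  The shift is the regional effect itself, not
    a promoter-wide average — expression responds to the differentially
    methylated element, however much of the 2-kb promoter it spans."""
    delta = pd.Series(0.0, index=[g.gene_id for g in genes])
    if not len(truth_dmrs):
        return delta
    for g in genes:
        lo, hi, _ = g.promoter(None)
        sub = truth_dmrs[truth_dmrs["chrom"] == g.chrom]
        for row in sub.itertuples():
            ov = min(hi, row.end) - max(lo, row.start)
            if ov > 0:
                delta[g.gene_id] += row.realized_effect
    return delta


def simulate_expression(
    genes: Sequence[GeneModel],
    truth_dmrs: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Negative-binomial count matrix with methylation-coupled means.

    Baseline gene means are log-normal; the first condition's mean is
    scaled by exp(coupling_slope * delta_promoter_methylation).
    Returns (counts genes x samples, per-gene truth table, gene
    lengths = summed exon length).
    """
    config.validate()
    gene_ids = [g.gene_id for g in genes]
    delta = promoter_meth_difference(genes, truth_dmrs)
    mu_g = rng.lognormal(config.expr_log_mean, config.expr_log_sd, size=len(genes))
    lfc_nat = config.coupling_slope * delta.to_numpy()
    alpha = config.nb_dispersion
    n_param = 1.0 / alpha if alpha > 0 else np.inf
    cond1 = config.conditions[0]
    data = {}
    for cond in config.conditions:
        mean = mu_g * np.exp(lfc_nat) if cond == cond1 else mu_g
        for s in config.condition_map[cond]:
            if alpha > 0:
                lam = rng.gamma(shape=n_param, scale=mean / n_param)
                data[s] = rng.poisson(lam)
            else:
                data[s] = rng.poisson(mean)
    counts = pd.DataFrame(data, index=gene_ids)
    lengths = pd.Series(
        [sum(e - s for s, e in g.exons) for g in genes], index=gene_ids, name="length_bp"
    )
    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseline_mean": mu_g,
            "delta_meth_promoter": delta.to_numpy(),
            "true_lfc_nat": lfc_nat,
            "true_log2fc": lfc_nat / np.log(2),
        }
    )
    return counts, truth_genes, lengths


# ---------------------------------------------------------------------------
# one-call fixture
# ---------------------------------------------------------------------------

def generate_fixture(config: SimConfig | None = None) -> Fixture:
    """Generate the complete synthetic dataset for one configuration."""
    if config is None:
        config = SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome, genes, tes = generate_genome(config, rng)
    chroms = [c for c in genome if c != SPIKEIN_CHROM]
    ctx_tables = {c: context_table(genome[c]) for c in chroms}
    truth_dmrs = plant_dmrs(genome, genes, tes, config, rng, ctx_tables)
    methylome, spikein = simulate_methylome(genome, truth_dmrs, config, rng, ctx_tables)
    counts, truth_genes, lengths = simulate_expression(genes, truth_dmrs, config, rng)
    return Fixture(
        config=config,
        genome=genome,
        genes=genes,
        tes=tes,
        methylome=methylome,
        spikein=spikein,
        truth_dmrs=truth_dmrs,
        truth_genes=truth_genes,
        counts=counts,
        gene_lengths=lengths,
    )
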