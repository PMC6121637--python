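"""File formats: FASTA, GFF3, BED6, Bismark-style cytosine reports and
count tables.

Cytosine reports are TSV with one row per cytosine per sample file:
chrom, 1-based position, strand, count_methylated, count_unmethylated,
context (CG/CHG/CHH), trinucleotide.  All interval files follow their
standard coordinate conventions (GFF3 1-based closed, BED 0-based
half-open); in-memory intervals are 0-based half-open throughout the
package.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from .features import GeneModel
from .methylation import Methylome
from .simulate import Fixture, SPIKEIN_CHROM

CX_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "trinucleotide"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """gene / mRNA / exon features, 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.start + 1, g.end
            fh.write(
                f"{g.chrom}\tmethlink\tgene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tmethlink\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(sorted(g.exons)):
                fh.write(
                    f"{g.chrom}\tmethlink\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.t1.exon{i + 1};Parent={g.gene_id}.t1\n"
                )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
        dtype={"chrom": str},
    )

    def attr(attrs: str, key: str) -> str | None:
        for part in attrs.split(";"):
            k, _, v = part.partition("=")
            if k == key:
                return v
        return None

    genes: dict[str, dict] = {}
    parent_of_mrna: dict[str, str] = {}
    for row in df.itertuples():
        if row.type == "gene":
            gid = attr(row.attrs, "ID")
            genes[gid] = {
                "gene_id": gid,
                "chrom": row.chrom,
                "strand": row.strand,
                "start": int(row.start) - 1,
                "end": int(row.end),
                "exons": [],
            }
        elif row.type == "mRNA":
            parent_of_mrna[attr(row.attrs, "ID")] = attr(row.attrs, "Parent")
    for row in df.itertuples():
        if row.type == "exon":
            gid = parent_of_mrna.get(attr(row.attrs, "Parent"))
            if gid in genes:
                genes[gid]["exons"].append((int(row.start) - 1, int(row.end)))
    return [GeneModel(**fields) for fields in genes.values()]


def write_te_bed(tes: pd.DataFrame, path: str | os.PathLike) -> None:
    """BED6 with class and family in the name field: "classI:Copia"."""
    out = tes.copy()
    out["name"] = out["te_class"] + ":" + out["family"] + ":" + out["te_id"]
    out["score"] = 0
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_te_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    parts = df["name"].str.split(":", expand=True)
    df["te_class"] = parts[0]
    df["family"] = parts[1]
    df["te_id"] = parts[2] if parts.shape[1] > 2 else [f"te{i + 1:04d}" for i in range(len(df))]
    return df[["chrom", "start", "end", "te_id", "te_class", "family", "strand"]]


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def _trinucleotide(seq: str, pos1: int, strand: str) -> str:
    i = pos1 - 1
    if strand == "+":
        tri = seq[i : i + 3]
    else:
        comp = str.maketrans("ACGT", "TGCA")
        tri = seq[max(i - 2, 0) : i + 1].translate(comp)[::-1]
    return (tri + "NN")[:3]


def write_cx_report(
    methylome: Methylome, sample: str, genome: Mapping[str, str], path: str | os.PathLike
) -> None:
    sites = methylome.sites
    tri = [
        _trinucleotide(genome[c], p, s)
        for c, p, s in zip(sites["chrom"], sites["pos"], sites["strand"])
    ]
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "strand": sites["strand"],
            "meth": sites[f"meth_{sample}"],
            "unmeth": sites[f"unmeth_{sample}"],
            "context": sites["context"],
            "trinucleotide": tri,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cx_reports(
    paths: Mapping[str, str | os.PathLike],
    conditions: Mapping[str, list[str]] | None = None,
) -> Methylome:
    """Merge per-sample cytosine reports (identical site universes) into
    a wide :class:`Methylome`."""
    merged = None
    samples = list(paths)
    for sample, path in paths.items():
        df = pd.read_csv(path, sep="\t", header=None, names=CX_COLUMNS, dtype={"chrom": str})
        part = df[["chrom", "pos", "strand", "context"]].copy()
        part[f"meth_{sample}"] = df["meth"]
        part[f"unmeth_{sample}"] = df["unmeth"]
        if merged is None:
            merged = part
        else:
            merged = merged.merge(part, on=["chrom", "pos", "strand", "context"], how="outer")
    for s in samples:
        for col in (f"meth_{s}", f"unmeth_{s}"):
            merged[col] = merged[col].fillna(0).astype(int)
    merged = merged.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return Methylome(sites=merged, samples=samples, conditions=dict(conditions or {}))


# ---------------------------------------------------------------------------
# counts and fixture set
# ---------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, lengths: pd.Series, path: str | os.PathLike) -> None:
    out = counts.copy()
    out.insert(0, "length_bp", lengths.reindex(counts.index))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    lengths = df.pop("length_bp")
    return df, lengths


def write_fixture(fixture: Fixture, outdir: str | os.PathLike) -> dict[str, Path]:
    """Serialise a synthetic fixture to its on-disk file set.

    Returns the path map: genome, genes, tes, cx_<sample>...,
    spikein_<sample>..., counts, truth_dmrs, truth_genes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(fixture.genome, paths["genome"])
    paths["genes"] = outdir / "genes.gff3"
    write_gff3(fixture.genes, paths["genes"])
    paths["tes"] = outdir / "tes.bed"
    write_te_bed(fixture.tes, paths["tes"])
    for s in fixture.methylome.samples:
        paths[f"cx_{s}"] = outdir / f"{s}.cx.tsv"
        write_cx_report(fixture.methylome, s, fixture.genome, paths[f"cx_{s}"])
        paths[f"spikein_{s}"] = outdir / f"{s}.spikein.cx.tsv"
        write_cx_report(fixture.spikein, s, fixture.genome, paths[f"spikein_{s}"])
    paths["counts"] = outdir / "counts.tsv"
    write_counts(fixture.counts, fixture.gene_lengths, paths["counts"])
    paths["truth_dmrs"] = outdir / "truth_dmrs.tsv"
    fixture.truth_dmrs.to_csv(paths["truth_dmrs"], sep="\t", index=False)
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    fixture.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    return paths
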