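"""Readers and writers for the pipeline's file formats.

Tabular interchange is plain TSV; genomic intervals are BED (0-based
half-open, read/written natively) or GFF3 (1-based inclusive, converted
on read); gene sets are GMT; pooled counts can also round-trip through a
minimal two-sample VCF whose AD fields carry the per-pool read counts
(written with pysam, read with cyvcf2).
"""

from __future__ import annotations

import contextlib
import gzip
import io as _io
from pathlib import Path

import pandas as pd

from .fst import COUNT_COLUMNS


@contextlib.contextmanager
def open_text(source, mode: str = "rt"):
    """Yield a text handle from a path (``.gz`` transparent) or pass one through."""
    if isinstance(source, (str, Path)):
        p = Path(source)
        opener = gzip.open if p.suffix == ".gz" else open
        with opener(p, mode) as fh:
            yield fh
    else:
        yield source


# ---------------------------------------------------------------------------
# pooled allele counts


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    cols = [c for c in COUNT_COLUMNS if c in counts.columns]
    counts[cols].to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    return df


def write_counts_vcf(counts: pd.DataFrame, path, sample_names=("pool1", "pool2")) -> None:
    """Minimal biallelic VCF with per-pool AD (ref,alt depths)."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in pd.unique(counts["chrom"]):
        header.contigs.add(str(chrom))
    header.add_meta(
        "FORMAT",
        items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
               ("Description", "Allelic depths for the ref and alt alleles")],
    )
    for s in sample_names:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in counts.itertuples(index=False):
            rec = vcf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=("A", "C"),
            )
            rec.samples[sample_names[0]]["AD"] = (int(row.ref_count_1), int(row.alt_count_1))
            rec.samples[sample_names[1]]["AD"] = (int(row.ref_count_2), int(row.alt_count_2))
            vcf.write(rec)


def read_counts_vcf(path) -> pd.DataFrame:
    """Read a two-sample VCF with AD fields into the count-table layout.

    Multi-allelic records are rejected; the two samples are taken as the
    two pools in header order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 2:
        raise ValueError(f"expected exactly 2 pool samples, found {len(vcf.samples)}")
    rows = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic site at {v.CHROM}:{v.POS}; split upstream")
        ad = v.format("AD")
        rows.append(
            (v.CHROM, v.POS, int(ad[0][0]), int(ad[0][1]), int(ad[1][0]), int(ad[1][1]))
        )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


# ---------------------------------------------------------------------------
# FASTQ


def write_fastq(records, dest) -> None:
    """Write ``(title, seq, qual)`` tuples as 4-line FASTQ (``.gz`` by suffix)."""
    with open_text(dest, "wt") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# pedigree / phenotypes


def write_pedigree_tsv(ped: pd.DataFrame, path) -> None:
    ped[["id", "sire", "dam"]].to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("id", "sire", "dam") if c not in df.columns]
    if missing:
        raise ValueError(f"pedigree missing columns: {missing}")
    return df


def write_phenotypes_tsv(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("id", "cage_tier", "kb_level") if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# windows / regions


def write_windows_tsv(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    with open_text(path, "wt") as fh:
        for r in regions.itertuples(index=False):
            name = f"region_{r.n_windows_merged}w" if hasattr(r, "n_windows_merged") else "region"
            score = getattr(r, "max_window_fst", 0.0)
            fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{name}\t{score:.4f}\t.\n")


def read_regions_bed(path) -> pd.DataFrame:
    rows = []
    with open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            if len(parts) >= 5:
                try:
                    row["max_window_fst"] = float(parts[4])
                except ValueError:
                    pass
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genes (BED6 / GFF3) and gene sets (GMT)


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    with open_text(path, "wt") as fh:
        for g in genes.itertuples(index=False):
            fh.write(
                f"{g.chrom}\t{int(g.start)}\t{int(g.end)}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def read_genes_bed(path) -> pd.DataFrame:
    rows = []
    with open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "gene_id": p[3] if len(p) > 3 else f"gene_{len(rows)}",
                    "chrom": p[0],
                    "start": int(p[1]),
                    "end": int(p[2]),
                    "strand": p[5] if len(p) > 5 else ".",
                }
            )
    return pd.DataFrame(rows)


def write_genes_gff3(genes: pd.DataFrame, path) -> None:
    """Write genes as GFF3 (1-based inclusive coordinates)."""
    with open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            fh.write(
                f"{g.chrom}\tkeelscan\tgene\t{int(g.start) + 1}\t{int(g.end)}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_genes_gff3(path) -> pd.DataFrame:
    """Read gene features from GFF3 into 0-based half-open coordinates."""
    import gffutils

    with open_text(path) as fh:
        text = fh.read()
    db = gffutils.create_db(
        _io.StringIO(text).getvalue(),
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    for feat in db.all_features(featuretype="gene"):
        rows.append(
            {
                "gene_id": feat.id,
                "chrom": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open_text(path, "wt") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {line!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_id_map(path) -> dict[str, str]:
    """Two-column TSV mapping source gene ids to target (e.g. ortholog) ids."""
    df = pd.read_csv(path, sep="\t", header=None, names=["source", "target"], dtype=str)
    return dict(zip(df["source"], df["target"]))
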