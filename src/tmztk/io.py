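"""Readers and writers for the pipeline's on-disk formats.

Tabular interchange is TSV throughout: library manifests, count matrices
(with a sample-metadata sidecar), mutation catalogs, signature matrices
in the COSMIC v2 two-key layout (Substitution Type + Trinucleotide),
cohort tables and truth tables.  Variants use VCF v4.2 with DP and AD
FORMAT fields (via pysam); exon regions use 0-based half-open BED.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .contexts import CONTEXTS_96, label_parts
from .screen_quant import CountMatrix

__all__ = [
    "read_library", "write_library",
    "read_counts", "write_counts",
    "read_bed", "read_known_sites",
    "read_vcf", "write_vcf",
    "read_signature_matrix", "write_signature_matrix",
    "read_catalog", "write_catalog",
]


# --- library manifests -----------------------------------------------------

def write_library(library: pd.DataFrame, path: str) -> None:
    library.to_csv(path, sep="\t", index=False)


def read_library(path: str) -> pd.DataFrame:
    lib = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "spacer": str},
                      keep_default_na=False)
    lib["is_control"] = lib["is_control"].astype(str).str.lower().isin(
        ["true", "1", "yes"]
    )
    return lib


# --- count matrices --------------------------------------------------------

def write_counts(mat: CountMatrix, counts_path: str, meta_path: str) -> None:
    mat.counts.rename_axis("guide_id").to_csv(counts_path, sep="\t")
    mat.samples.rename_axis("sample").to_csv(meta_path, sep="\t")


def read_counts(counts_path: str, meta_path: str, normalized: bool = False,
                norm_constant: float | None = None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="guide_id")
    samples = pd.read_csv(meta_path, sep="\t", index_col="sample")
    return CountMatrix(counts, samples, normalized=normalized,
                       norm_constant=norm_constant)


# --- regions and known sites ----------------------------------------------

def read_bed(path: str) -> pd.DataFrame:
    """Read a BED3(+) file into a chrom/start/end DataFrame (0-based
    half-open)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return bed.astype({"start": int, "end": int})


def read_known_sites(path: str) -> set[tuple[str, int, str, str]]:
    """Known polymorphism sites as exact (chrom, pos, ref, alt) tuples,
    from a VCF or a 4-column TSV (chrom, pos, ref, alt)."""
    sites: set[tuple[str, int, str, str]] = set()
    if path.endswith((".vcf", ".vcf.gz")):
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    sites.add((rec.chrom, rec.pos, rec.ref, alt))
    else:
        tab = pd.read_csv(path, sep="\t", comment="#",
                          names=["chrom", "pos", "ref", "alt"], header=None,
                          skiprows=_tsv_has_header(path))
        for row in tab.itertuples(index=False):
            sites.add((str(row.chrom), int(row.pos), str(row.ref), str(row.alt)))
    return sites


def _tsv_has_header(path: str) -> int:
    with open(path) as fh:
        first = fh.readline().split("\t")
    return 1 if len(first) > 1 and not first[1].strip().isdigit() else 0


# --- variants (VCF) --------------------------------------------------------

def write_vcf(records: pd.DataFrame, path: str,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a variant table as a multi-sample VCF v4.2 with DP/AD FORMAT
    fields; genotype fields are filled only for each record's own sample."""
    samples = sorted(records["sample"].astype(str).unique())
    if contig_lengths is None:
        contig_lengths = {
            str(c): int(sub["pos"].max()) + 10
            for c, sub in records.groupby("chrom")
        }
    header = pysam.VariantHeader()
    header.add_line('##source=tmztk')
    for c, ln in contig_lengths.items():
        header.add_line(f"##contig=<ID={c},length={ln}>")
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allelic depths (ref,alt)">')
    header.add_line('##INFO=<ID=TCTX,Number=1,Type=String,'
                    'Description="Reference-strand trinucleotide context">')
    for s in samples:
        header.add_sample(s)
    ordered = records.sort_values(["chrom", "pos"]).reset_index(drop=True)
    with pysam.VariantFile(path, "w", header=header) as out:
        for row in ordered.itertuples(index=False):
            rec = out.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1,
                alleles=(str(row.ref), str(row.alt)),
            )
            filt = getattr(row, "filter", "PASS")
            rec.filter.add(str(filt) if isinstance(filt, str) and filt else "PASS")
            ctx = getattr(row, "context", None)
            if isinstance(ctx, str) and ctx:
                rec.info["TCTX"] = ctx
            depth, alt_reads = int(row.depth), int(row.alt_reads)
            rec.samples[str(row.sample)]["DP"] = depth
            rec.samples[str(row.sample)]["AD"] = (depth - alt_reads, alt_reads)
            out.write(rec)


def read_vcf(path: str) -> pd.DataFrame:
    """Read a VCF into the variant-table schema, one row per (site, alt,
    sample with a called AD).  Multi-allelic records are split into
    biallelic rows."""
    rows = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            filt = ";".join(rec.filter.keys()) or "PASS"
            ctx = rec.info.get("TCTX") if "TCTX" in rec.info else None
            for sample, call in rec.samples.items():
                ad = call.get("AD")
                dp = call.get("DP")
                if ad is None or all(a is None for a in np.atleast_1d(ad)):
                    continue
                ad = list(ad)
                for i, alt in enumerate(rec.alts or ()):
                    alt_reads = int(ad[i + 1]) if len(ad) > i + 1 and ad[i + 1] is not None else 0
                    depth = int(dp) if dp is not None else int(sum(a or 0 for a in ad))
                    rows.append(
                        (rec.chrom, rec.pos, rec.ref, alt, depth, alt_reads,
                         sample, ctx, filt)
                    )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "depth", "alt_reads",
                       "sample", "context", "filter"]
    )


# --- signature matrices and catalogs ---------------------------------------

def write_signature_matrix(signatures: pd.DataFrame, path: str) -> None:
    """Write 96 x K signatures in the COSMIC v2 layout (first two columns
    Substitution Type and Trinucleotide)."""
    parts = [label_parts(lab) for lab in signatures.index]
    out = signatures.copy()
    out.insert(0, "Trinucleotide", [f"{p[0]}{p[1]}{p[3]}" for p in parts])
    out.insert(0, "Substitution Type", [f"{p[1]}>{p[2]}" for p in parts])
    out.to_csv(path, sep="\t", index=False)


def read_signature_matrix(path: str) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    sub = tab["Substitution Type"].astype(str)
    tri = tab["Trinucleotide"].astype(str)
    labels = [f"{t[0]}[{s}]{t[2]}" for s, t in zip(sub, tri)]
    out = tab.drop(columns=["Substitution Type", "Trinucleotide"])
    out.index = pd.Index(labels, name="context")
    missing = set(CONTEXTS_96) - set(out.index)
    if missing:
        raise ValueError(f"signature matrix missing {len(missing)} contexts")
    return out.loc[list(CONTEXTS_96)]


def write_catalog(catalog: pd.DataFrame, path: str) -> None:
    write_signature_matrix(catalog, path)


def read_catalog(path: str) -> pd.DataFrame:
    return read_signature_matrix(path).astype(int)
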