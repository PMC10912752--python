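"""Somatic variant post-filtering and mutation-catalog construction.

Variants arrive as called records (one row per sample x site x alt
allele); this module applies the bespoke somatic filter chain used after
Mutect2-style calling — mutant allele frequency >= 10%, coverage >= 10x,
>= 3 supporting reads, indels longer than 10 bp removed, known
polymorphisms removed, and restriction to captured exon regions — then
bins passing SNVs into the 96 trinucleotide-context channels (pyrimidine
convention) and splits the six substitution classes into the two
TMZ-lesion patterns: Pattern I (C>T, attributed to O6-methylguanine) and
Pattern II (the other five classes, attributed to N3-methyladenine and
N7-methylguanine).

Variant tables use the columns: ``chrom, pos, ref, alt, depth, alt_reads,
sample`` plus optional ``context`` (3-base reference-strand sequence
centred on the variant) and ``filter`` (upstream caller verdict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .contexts import CONTEXTS_96, canonicalize

__all__ = [
    "FilterThresholds",
    "apply_filter_chain",
    "classify_snv",
    "build_catalog",
    "six_class_counts",
    "pattern_decomposition",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Somatic post-filter thresholds; every bound is inclusive except the
    indel length, which removes indels strictly longer than ``max_indel_len``."""

    min_vaf: float = 0.10
    min_depth: int = 10
    min_alt_reads: int = 3
    max_indel_len: int = 10

    def __post_init__(self) -> None:
        if self.min_vaf < 0 or self.min_depth < 1 or self.min_alt_reads < 0:
            raise ValueError("invalid filter thresholds")


def _is_indel(ref: str, alt: str) -> bool:
    return len(ref) != len(alt)


def _indel_len(ref: str, alt: str) -> int:
    return abs(len(ref) - len(alt))


def _exon_trees(exon_regions: pd.DataFrame) -> dict[str, IntervalTree]:
    """Build per-chromosome interval trees from 0-based half-open BED rows."""
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in exon_regions.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(int)
        ends = sub["end"].to_numpy(int)
        if (starts < 0).any() or (ends <= starts).any():
            raise ValueError(f"malformed interval on {chrom}")
        trees[chrom] = IntervalTree.from_tuples(zip(starts, ends))
    return trees


def apply_filter_chain(
    records: pd.DataFrame,
    known_sites: set[tuple] | pd.DataFrame | None = None,
    exon_regions: pd.DataFrame | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
    honor_caller_filter: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the somatic post-filter chain; return survivors and a tally.

    A record survives iff it passes every filter (conjunction).  The
    tally attributes each removed record to the first filter it fails,
    in the order: caller PASS flag, indel length, allele frequency,
    coverage, supporting reads, known polymorphism, exon overlap — so
    filter order affects only the tally, never the surviving set.

    Parameters
    ----------
    records
        Variant table (see module docstring for columns).
    known_sites
        Known-polymorphism sites matched on exact (chrom, pos, ref, alt)
        tuples; a DataFrame with those columns or a set of tuples.
    exon_regions
        BED-style DataFrame (``chrom, start, end``; 0-based half-open).
        A variant overlaps iff its (1-based) start lies inside a region.
        None disables the exon filter.
    honor_caller_filter
        If a ``filter`` column is present, keep only records marked PASS
        (or '.').
    """
    rec = records.reset_index(drop=True)
    depth = rec["depth"].to_numpy(float)
    alt_reads = rec["alt_reads"].to_numpy(float)
    if (depth <= 0).any():
        raise ValueError("record with zero or negative depth")
    if (alt_reads > depth).any():
        raise ValueError("malformed record: alt-supporting reads exceed depth")

    refs = rec["ref"].astype(str)
    alts = rec["alt"].astype(str)
    is_indel = np.array([_is_indel(r, a) for r, a in zip(refs, alts)])
    indel_len = np.array([_indel_len(r, a) for r, a in zip(refs, alts)])

    checks: list[tuple[str, np.ndarray]] = []
    if honor_caller_filter and "filter" in rec.columns:
        ok = rec["filter"].astype(str).isin(["PASS", ".", "nan", ""]).to_numpy()
        checks.append(("caller_filter", ok))
    checks.append(("indel_length", ~(is_indel & (indel_len > thresholds.max_indel_len))))
    checks.append(("allele_frequency", alt_reads / depth >= thresholds.min_vaf))
    checks.append(("coverage", depth >= thresholds.min_depth))
    checks.append(("supporting_reads", alt_reads >= thresholds.min_alt_reads))

    if known_sites is not None:
        if isinstance(known_sites, pd.DataFrame):
            site_set = set(
                zip(
                    known_sites["chrom"].astype(str),
                    known_sites["pos"].astype(int),
                    known_sites["ref"].astype(str),
                    known_sites["alt"].astype(str),
                )
            )
        else:
            site_set = set(known_sites)
        keys = list(
            zip(rec["chrom"].astype(str), rec["pos"].astype(int), refs, alts)
        )
        checks.append(("known_site", np.array([k not in site_set for k in keys])))

    if exon_regions is not None:
        trees = _exon_trees(exon_regions)
        pos0 = rec["pos"].astype(int).to_numpy() - 1  # 1-based VCF -> 0-based
        chroms = rec["chrom"].astype(str).to_numpy()
        in_exon = np.array(
            [
                c in trees and bool(trees[c].overlaps_point(p))
                for c, p in zip(chroms, pos0)
            ]
        )
        checks.append(("exon_overlap", in_exon))

    alive = np.ones(len(rec), dtype=bool)
    tally: dict[str, int] = {"input": len(rec)}
    for name, ok in checks:
        removed = alive & ~ok
        tally[name] = int(removed.sum())
        alive &= ok
    tally["passing"] = int(alive.sum())
    return rec[alive].reset_index(drop=True), tally


def classify_snv(ref: str, alt: str, context: str) -> tuple[str, str]:
    """Substitution class and 96-channel label for one SNV.

    If the reference allele is a purine, alleles and context are
    reverse-complemented so the class is expressed on the pyrimidine
    strand; applying the map to an already-canonical record is a no-op.
    """
    return canonicalize(ref, alt, context)


def _fetch_context(fasta, chrom: str, pos: int) -> str | None:
    try:
        seq = fasta.fetch(chrom, pos - 2, pos + 1).upper()
    except (KeyError, ValueError):
        return None
    return seq if len(seq) == 3 else None


def build_catalog(
    records: pd.DataFrame,
    reference: str | None = None,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Bin passing SNVs into the 96-channel x samples mutation catalog.

    Contexts come from the ``context`` column when present, otherwise
    from a FASTA lookup at each variant position (``reference`` path).
    Indels are excluded.  Records whose context cannot be resolved (e.g.
    at a chromosome edge) are skipped with a warning and counted in the
    returned skip tally.  Column sums equal the number of catalogued SNVs
    per sample.
    """
    snv = records[
        (records["ref"].astype(str).str.len() == 1)
        & (records["alt"].astype(str).str.len() == 1)
    ]
    fasta = None
    if reference is not None:
        import pysam

        fasta = pysam.FastaFile(reference)

    sample_ids = samples if samples is not None else sorted(
        records["sample"].astype(str).unique()
    )
    catalog = pd.DataFrame(
        0, index=pd.Index(CONTEXTS_96, name="context"), columns=sample_ids, dtype=int
    )
    skipped = 0
    for row in snv.itertuples(index=False):
        ctx = getattr(row, "context", None)
        if (ctx is None or (isinstance(ctx, float) and np.isnan(ctx))) and fasta is not None:
            ctx = _fetch_context(fasta, str(row.chrom), int(row.pos))
        if ctx is None or (isinstance(ctx, float) and np.isnan(ctx)):
            skipped += 1
            continue
        try:
            _, label = canonicalize(str(row.ref), str(row.alt), str(ctx))
        except ValueError:
            skipped += 1
            continue
        catalog.loc[label, str(row.sample)] += 1
    if fasta is not None:
        fasta.close()
    if skipped:
        warnings.warn(f"skipped {skipped} SNV(s) with unresolvable context")
    return catalog, skipped


def six_class_counts(catalog: pd.DataFrame) -> pd.DataFrame:
    """Collapse a 96-channel catalog to the six substitution classes."""
    classes = catalog.index.str.extract(r"\[(.>.)\]", expand=False)
    return catalog.groupby(classes.values).sum().rename_axis("class")


def pattern_decomposition(counts: pd.DataFrame) -> pd.DataFrame:
    """Split counts into Pattern I (C>T) and Pattern II (all other classes).

    Accepts either a 96-channel catalog or a six-class table (rows are
    substitution classes).  Pattern I + Pattern II equals the total SNV
    count per sample.
    """
    if counts.index.str.contains(r"\[").any():
        counts = six_class_counts(counts)
    pattern_i = counts.loc["C>T"] if "C>T" in counts.index else counts.iloc[0] * 0
    pattern_ii = counts.drop(index="C>T", errors="ignore").sum(axis=0)
    out = pd.DataFrame({"pattern_I": pattern_i, "pattern_II": pattern_ii})
    out.index.name = "sample"
    return out
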