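"""Guide quantification for pooled CRISPR dropout screens.

Turns cassette-amplicon FASTQ reads into a guide count matrix by exact
spacer matching between universal flanking sequences, and normalizes raw
counts to a fixed per-sample total so that samples sequenced at different
depths are comparable.  All downstream screen statistics are invariant to
the normalization constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

__all__ = ["CountMatrix", "count_guides", "normalize_counts"]

SAMPLE_META_COLS = ("genotype", "treatment", "timepoint", "replicate")


@dataclass
class CountMatrix:
    """Guides x samples count matrix with per-sample screen metadata.

    Attributes
    ----------
    counts
        DataFrame indexed by guide id with one column per sample.  Raw
        matrices hold non-negative integers; normalized matrices hold
        non-negative reals whose columns each sum to the normalization
        constant.
    samples
        DataFrame indexed by sample id with columns ``genotype``,
        ``treatment``, ``timepoint`` and ``replicate``.
    normalized
        Whether :func:`normalize_counts` has been applied.
    norm_constant
        The per-sample total after normalization (None for raw counts).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    normalized: bool = False
    norm_constant: float | None = None

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.counts.columns)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate guide ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if not self.counts.columns.equals(self.samples.index):
            self.samples = self.samples.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def guide_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


def _spacer_lookup(library: pd.DataFrame) -> tuple[dict[str, str], set[int]]:
    spacers = library["spacer"].astype(str)
    if spacers.duplicated().any():
        dups = spacers[spacers.duplicated()].unique()
        raise ValueError(f"guides share identical spacers: {list(dups)[:5]}")
    lookup = dict(zip(spacers, library["guide_id"].astype(str)))
    lengths = {len(s) for s in spacers}
    return lookup, lengths


def _one_mismatch_lookup(lookup: dict[str, str]) -> dict[str, str | None]:
    """Map every 1-substitution neighbour of each spacer to its guide;
    neighbours claimed by more than one guide map to None (ambiguous)."""
    from .contexts import BASES

    fuzzy: dict[str, str | None] = {}
    for spacer, guide in lookup.items():
        for i, orig in enumerate(spacer):
            for b in BASES:
                if b == orig:
                    continue
                variant = spacer[:i] + b + spacer[i + 1 :]
                fuzzy[variant] = None if variant in fuzzy else guide
    return fuzzy


def count_guides(
    fastq: str,
    library: pd.DataFrame,
    flank5: str,
    flank3: str,
    sample_id: str = "sample",
    revcomp: bool = False,
    one_mismatch: bool = False,
) -> tuple[CountMatrix, int]:
    """Count cassette reads per guide by exact spacer matching.

    A read is assigned to a guide iff it contains ``flank5`` followed
    immediately by the guide's full spacer followed by as much of
    ``flank3`` as fits before the read end, with every base matching
    exactly.  Reads matching no guide are tallied as unmapped;
    mapped + unmapped always equals the number of input reads.

    Parameters
    ----------
    fastq
        Path to a FASTQ file (gzip accepted).
    library
        Guide manifest with columns ``guide_id`` and ``spacer``.
    flank5, flank3
        Universal sequences flanking the spacer in the cassette.
    revcomp
        Also search the reverse complement of each read.
    one_mismatch
        Additionally accept spacers with a single substitution, provided
        the mismatched sequence identifies a unique guide (off by
        default; flanks are still matched exactly).

    Returns
    -------
    (CountMatrix, int)
        Raw single-sample count matrix over all library guides (zero for
        unobserved guides) and the unmapped-read tally.
    """
    from .contexts import revcomp as _rc

    if not flank5 or not flank3:
        raise ValueError("flanking sequences must be non-empty")
    lookup, spacer_lens = _spacer_lookup(library)
    fuzzy = _one_mismatch_lookup(lookup) if one_mismatch else None

    counts: dict[str, int] = {}
    unmapped = 0
    total = 0

    def _match(seq: str) -> str | None:
        start = 0
        while True:
            i = seq.find(flank5, start)
            if i < 0:
                return None
            pos = i + len(flank5)
            for slen in spacer_lens:
                spacer = seq[pos : pos + slen]
                if len(spacer) < slen:
                    continue
                guide = lookup.get(spacer)
                if guide is None and fuzzy is not None:
                    guide = fuzzy.get(spacer)  # None on miss or ambiguity
                if guide is None:
                    continue
                tail = seq[pos + slen : pos + slen + len(flank3)]
                if flank3.startswith(tail):
                    return guide
            start = i + 1

    with pysam.FastxFile(fastq) as fh:
        for read in fh:
            total += 1
            seq = read.sequence.upper()
            guide = _match(seq)
            if guide is None and revcomp:
                guide = _match(_rc(seq))
            if guide is None:
                unmapped += 1
            else:
                counts[guide] = counts.get(guide, 0) + 1

    if total == 0:
        warnings.warn(f"empty FASTQ {fastq}: returning all-zero counts")
    col = pd.Series(counts, dtype="int64").reindex(
        library["guide_id"].astype(str), fill_value=0
    )
    mat = CountMatrix(col.to_frame(sample_id))
    assert int(mat.counts[sample_id].sum()) + unmapped == total
    return mat, unmapped


def normalize_counts(raw: CountMatrix, constant: float = 1e7) -> CountMatrix:
    """Scale each sample to a fixed total (counts-per-``constant``).

    value' = value / (sample total) * constant.  Rank order within a
    sample is preserved and every normalized column sums to ``constant``.
    """
    if constant <= 0:
        raise ValueError("normalization constant must be positive")
    totals = raw.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"cannot normalize all-zero sample(s): {list(zero.index)}"
        )
    norm = raw.counts.astype(float).div(totals, axis=1) * constant
    return replace(raw, counts=norm, normalized=True, norm_constant=float(constant))
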