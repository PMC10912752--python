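"""Trinucleotide mutation contexts in the 96-channel pyrimidine convention.

Single-base substitutions are reported on the pyrimidine strand: a mutation
whose reference base is a purine (A or G) is reverse-complemented, together
with its flanking bases, so that every substitution falls into one of six
classes (C>A, C>G, C>T, T>A, T>C, T>G) and one of 96 trinucleotide context
categories.  Channel ordering follows the COSMIC v2 layout: substitution
classes in alphabetical order, and within each class the 16 flank pairs in
alphabetical order (ACA, ACC, ... TTT).
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = ("C", "T")

#: The six substitution classes, pyrimidine convention, canonical order.
SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in {seq!r}") from exc


def _build_channels() -> tuple[str, ...]:
    channels = []
    for sub in SUB_CLASSES:
        ref = sub[0]
        for five in BASES:
            for three in BASES:
                channels.append(f"{five}[{sub}]{three}")
        del ref
    return tuple(channels)


#: Canonical 96 context labels, e.g. "A[C>A]A", in COSMIC v2 order.
CONTEXTS_96 = _build_channels()
CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


def canonicalize(ref: str, alt: str, context: str) -> tuple[str, str]:
    """Map a substitution and its reference-strand context to the pyrimidine
    convention.

    Parameters
    ----------
    ref, alt
        Reference and alternate alleles (single bases, reference strand).
    context
        The 3-base reference-strand sequence centred on the variant.

    Returns
    -------
    (sub_class, label)
        The substitution class (e.g. ``"C>T"``) and 96-channel label
        (e.g. ``"G[C>T]A"``).
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        raise ValueError("expected single-base ref/alt and 3-base context")
    if any(b not in BASES for b in ref + alt + context):
        raise ValueError(f"non-ACGT base in {ref}>{alt} {context}")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    if context[1] != ref:
        raise ValueError(
            f"context {context!r} does not have ref allele {ref!r} at its centre"
        )
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context = revcomp(context)
    sub = f"{ref}>{alt}"
    label = f"{context[0]}[{sub}]{context[2]}"
    return sub, label


def label_parts(label: str) -> tuple[str, str, str, str]:
    """Split ``"A[C>T]G"`` into (five, ref, alt, three)."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five, ref, alt, three
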