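"""Synthetic inputs for the screen, mutagenesis and cohort analyses.

Everything the pipeline consumes can be generated here with known ground
truth: a DDR-focused sgRNA library manifest, negative-binomial guide
counts for a PD0 -> PD20 dropout screen across genotype x treatment arms,
cassette FASTQ reads, per-clone somatic SNV catalogs drawn from mutational
signature mixtures, and a patient cohort with a proliferation-correlated
expression variable and a logistic hypermutation model.

Default calibrations follow the biology being emulated:

* library: 504 DDR genes x 10 guides + 1000 non-targeting controls;
* primary TMZ lesion spectrum: 70% N7-methylguanine, 25%
  N3-methyladenine, 5% O6-methylguanine;
* mean TMZ-induced de novo SNV increments of 396 (RAD18+/+ MLH1+/+) and
  378 (RAD18-/- MLH1+/+), with MMR-deficient clones accumulating far more
  basal mutations and the RAD18-/- MLH1-/- double knockout showing no
  TMZ induction;
* an alkylation-signature-like profile (non-CpG C>T) dominating the TMZ
  arms so hypermutation calls and exposure refits are exercised;
* a cohort in which RAD18 expression correlates with proliferation at
  rho = 0.75 and hypermutation follows a logistic model on
  proliferation-adjusted RAD18 and MGMT status.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import BASES, CONTEXTS_96, label_parts, revcomp
from .screen_quant import CountMatrix

__all__ = [
    "ScreenDesign",
    "EffectSpec",
    "CatalogDesign",
    "CohortDesign",
    "DEFAULT_PATHWAY_LABELS",
    "LESION_SPECTRUM",
    "draw_primary_lesions",
    "gen_library",
    "gen_screen_counts",
    "gen_cassette_reads",
    "synthetic_signature_matrix",
    "synthetic_reference",
    "gen_mutation_catalogs",
    "gen_cohort",
    "gen_expression_matrix",
]

# ---------------------------------------------------------------------------
# primary lesion spectrum

#: Fractions of TMZ-induced primary DNA lesions by adduct class.
LESION_SPECTRUM: dict[str, float] = {"N7mG": 0.70, "N3mA": 0.25, "O6mG": 0.05}


def draw_primary_lesions(
    n: int, spectrum: dict[str, float] | None = None, seed: int = 0
) -> pd.Series:
    """Draw ``n`` primary alkylation lesions; returns counts per class."""
    spec = dict(LESION_SPECTRUM if spectrum is None else spectrum)
    probs = np.array(list(spec.values()), float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("lesion spectrum must be a probability vector")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    return pd.Series(counts, index=list(spec.keys()), name="lesions")


# ---------------------------------------------------------------------------
# sgRNA library

DEFAULT_PATHWAY_LABELS = (
    "MMR", "BER", "TLS", "FA", "HR", "NHEJ", "NER", "CS", "M/ASC",
    "PARP", "NM", "TS",
)


def gen_library(
    n_genes: int = 504,
    guides_per_gene: int = 10,
    n_controls: int = 1000,
    pathway_map: dict[str, list[str]] | None = None,
    spacer_len: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a DDR-style sgRNA library manifest.

    Returns a DataFrame with columns ``guide_id, spacer, gene, pathways,
    is_control``; ``pathways`` is a semicolon-joined label list.  Spacers
    are unique random sequences.  Without an explicit ``pathway_map``,
    genes are assigned cyclically to the default DDR pathway labels, with
    every ninth gene also carrying a second label (pathway membership is
    many-to-many in real annotations).
    """
    if min(n_genes, guides_per_gene) < 1 or n_controls < 0:
        raise ValueError("library dimensions must be positive")
    if spacer_len < 10:
        raise ValueError("spacer_len must be >= 10")
    genes = [f"DDR{i + 1:04d}" for i in range(n_genes)]
    if pathway_map is None:
        labels = DEFAULT_PATHWAY_LABELS
        pathway_map = {}
        for i, g in enumerate(genes):
            pws = [labels[i % len(labels)]]
            if i % 9 == 0:
                pws.append(labels[(i + 5) % len(labels)])
            pathway_map[g] = pws
    else:
        genes = list(pathway_map.keys()) if set(pathway_map) != set(genes) else genes
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene names")
        missing = [g for g in genes if not pathway_map.get(g)]
        if missing:
            raise KeyError(f"pathway_map missing genes: {missing[:5]}")
        if len(genes) != n_genes:
            raise ValueError("pathway_map size disagrees with n_genes")

    rng = np.random.default_rng(seed)
    n_spacers = n_genes * guides_per_gene + n_controls
    spacers: list[str] = []
    seen: set[str] = set()
    while len(spacers) < n_spacers:
        draw = rng.integers(0, 4, size=(n_spacers, spacer_len))
        for row in draw:
            s = "".join(BASES[b] for b in row)
            if s not in seen:
                seen.add(s)
                spacers.append(s)
                if len(spacers) == n_spacers:
                    break

    rows = []
    k = 0
    for g in genes:
        pws = ";".join(pathway_map[g])
        for j in range(guides_per_gene):
            rows.append((f"{g}_sg{j + 1}", spacers[k], g, pws, False))
            k += 1
    for j in range(n_controls):
        rows.append((f"NTC_sg{j + 1}", spacers[k], "", "", True))
        k += 1
    return pd.DataFrame(
        rows, columns=["guide_id", "spacer", "gene", "pathways", "is_control"]
    )


def pathway_table(library: pd.DataFrame) -> pd.DataFrame:
    """Explode a manifest's semicolon-joined pathways into a gene->pathway map."""
    targ = library[~library["is_control"].astype(bool)]
    pairs = (
        targ[["gene", "pathways"]]
        .drop_duplicates()
        .assign(pathway=lambda d: d["pathways"].str.split(";"))
        .explode("pathway")[["gene", "pathway"]]
    )
    return pairs[pairs["pathway"] != ""].reset_index(drop=True)


# ---------------------------------------------------------------------------
# screen counts

@dataclass
class ScreenDesign:
    """Arms and sampling parameters of a dropout screen.

    Each (genotype, treatment, replicate) arm is sequenced at both
    timepoints; ``depth`` is the expected total reads per sample and
    ``dispersion`` the negative-binomial dispersion alpha in
    Var = mu + alpha * mu^2.
    """

    genotypes: tuple[str, ...] = ("RAD18+/+", "RAD18-/-")
    treatments: tuple[str, ...] = ("TMZ", "DMSO")
    timepoints: tuple[str, str] = ("PD0", "PD20")
    replicates: int = 3
    depth: float = 1.5e6
    dispersion: float = 0.05
    pd0_log_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.depth <= 0 or self.dispersion <= 0:
            raise ValueError("depth and dispersion must be positive")


@dataclass
class EffectSpec:
    """Injected per-gene selection coefficients.

    ``effects`` maps (gene, genotype, treatment) to a log2 fold change
    applied multiplicatively to the PD20 expected abundance; unlisted
    combinations (and all control guides) have coefficient 0.
    ``guide_noise_sd`` is the SD of a per-guide log2 efficacy drawn once
    per (guide, genotype, treatment) and shared across replicates.
    """

    effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    guide_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.guide_noise_sd < 0:
            raise ValueError("guide_noise_sd must be >= 0")
        for key, val in self.effects.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite effect for {key}")

    def coefficient(self, gene: str, genotype: str, treatment: str) -> float:
        return float(self.effects.get((gene, genotype, treatment), 0.0))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with Var = mu + alpha mu^2 via gamma-Poisson."""
    mean = np.asarray(mean, float)
    if alpha <= 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=np.maximum(mean, 1e-300) * alpha)
    return rng.poisson(lam)


def gen_screen_counts(
    library: pd.DataFrame,
    design: ScreenDesign = ScreenDesign(),
    effects: EffectSpec = EffectSpec(),
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate raw guide counts for every sample of a dropout screen.

    PD0 abundances are log-normal around uniform (library skew); the PD20
    expected abundance multiplies in 2^(gene effect + guide noise), and
    every sample is drawn negative-binomially at the design dispersion
    around depth-scaled proportions.  Returns the raw CountMatrix (with
    sample metadata) and a truth table of per-(gene, genotype, treatment)
    coefficients.
    """
    lib_genes = set(library.loc[~library["is_control"].astype(bool), "gene"])
    for gene, *_ in effects.effects:
        if gene not in lib_genes:
            raise KeyError(f"effect references gene {gene!r} absent from library")

    rng = np.random.default_rng(seed)
    guides = library["guide_id"].astype(str).to_numpy()
    genes = library["gene"].astype(str).to_numpy()
    is_control = library["is_control"].astype(bool).to_numpy()
    n_guides = guides.size

    base_abund = np.exp(rng.normal(0.0, design.pd0_log_sd * np.log(10), n_guides))

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    t0, t1 = design.timepoints
    for gt in design.genotypes:
        for trt in design.treatments:
            coef = np.array(
                [
                    0.0 if ctl else effects.coefficient(g, gt, trt)
                    for g, ctl in zip(genes, is_control)
                ]
            )
            noise = rng.normal(0.0, effects.guide_noise_sd, n_guides)
            abund20 = base_abund * np.power(2.0, coef + noise)
            for rep in range(1, design.replicates + 1):
                for tp, abund in ((t0, base_abund), (t1, abund20)):
                    sid = f"{gt}_{trt}_{tp}_r{rep}"
                    mean = design.depth * abund / abund.sum()
                    cols[sid] = _nb_draw(rng, mean, design.dispersion)
                    meta_rows.append((sid, gt, trt, tp, rep))

    counts = pd.DataFrame(cols, index=pd.Index(guides, name="guide_id"))
    samples = pd.DataFrame(
        meta_rows, columns=["sample", "genotype", "treatment", "timepoint", "replicate"]
    ).set_index("sample")
    truth = pd.DataFrame(
        [
            (g, gt, trt, effects.coefficient(g, gt, trt))
            for g in sorted(lib_genes)
            for gt in design.genotypes
            for trt in design.treatments
        ],
        columns=["gene", "genotype", "treatment", "effect"],
    )
    return CountMatrix(counts, samples), truth


def gen_cassette_reads(
    library: pd.DataFrame,
    counts: pd.Series | dict[str, int],
    path: str,
    flank5: str = "ACCG",
    flank3: str = "GTTT",
    read_len: int = 50,
    error_rate: float = 0.0,
    seed: int = 0,
) -> int:
    """Write cassette FASTQ reads for one sample; returns reads written.

    Each guide contributes ``counts[guide_id]`` reads of the form
    flank5 + spacer + flank3, padded to ``read_len`` with a fixed filler,
    with independent per-base substitution errors at ``error_rate``.
    Qualities are constant.  Gzip output when ``path`` ends in ``.gz``.
    """
    for name, fl in (("flank5", flank5), ("flank3", flank3)):
        if not fl or any(b not in BASES for b in fl):
            raise ValueError(f"{name} must be a non-empty ACGT string")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    counts = pd.Series(counts)
    if (counts < 0).any() or (counts != counts.astype(int)).any():
        raise ValueError("counts must be non-negative integers")
    spacer_of = dict(zip(library["guide_id"].astype(str), library["spacer"].astype(str)))
    max_spacer = max((len(s) for s in spacer_of.values()), default=0)
    if read_len < len(flank5) + max_spacer + len(flank3):
        raise ValueError("read_len too short for flank5 + spacer + flank3")

    rng = np.random.default_rng(seed)
    base_idx = {b: i for i, b in enumerate(BASES)}
    filler = itertools.cycle("GATC")
    opener = gzip.open if str(path).endswith(".gz") else open
    written = 0
    with opener(path, "wt") as fh:
        for guide_id, n in counts.items():
            if guide_id not in spacer_of:
                raise KeyError(f"count for unknown guide {guide_id!r}")
            cassette = flank5 + spacer_of[guide_id] + flank3
            pad = "".join(next(filler) for _ in range(read_len - len(cassette)))
            template = np.array([base_idx[b] for b in cassette + pad], dtype=np.int64)
            for i in range(int(n)):
                read = template.copy()
                if error_rate > 0:
                    hit = rng.random(read.size) < error_rate
                    # substitute with one of the three other bases
                    read[hit] = (read[hit] + rng.integers(1, 4, hit.sum())) % 4
                seq = "".join(BASES[b] for b in read)
                fh.write(f"@{guide_id}:{i}\n{seq}\n+\n{'I' * read_len}\n")
                written += 1
    return written


# ---------------------------------------------------------------------------
# mutational signatures and clone catalogs

def synthetic_signature_matrix() -> pd.DataFrame:
    """A bundled synthetic 5-signature reference matrix (96 x 5).

    Columns:

    * ``SigAlkyl`` — alkylation-damage-like: C>T concentrated at non-CpG
      contexts (3' flank != G), the profile used to emulate COSMIC v2
      Signature 11;
    * ``SigClock`` — age-like: C>T at CpG contexts;
    * ``SigOx`` — C>A dominated;
    * ``SigTrans`` — T>C dominated;
    * ``SigFlat`` — uniform background.

    The matrix is a fixed reference object (deterministic); every column
    sums to 1.
    """
    idx = pd.Index(CONTEXTS_96, name="context")
    sigs = pd.DataFrame(0.0, index=idx, columns=[
        "SigAlkyl", "SigClock", "SigOx", "SigTrans", "SigFlat"
    ])
    rng = np.random.default_rng(96)  # fixed: shapes the within-class profile
    for label in idx:
        five, ref, alt, three = label_parts(label)
        sub = f"{ref}>{alt}"
        jitter = 0.5 + rng.random()
        if sub == "C>T" and three != "G":
            sigs.loc[label, "SigAlkyl"] = 2.0 * jitter
        if sub == "C>T" and three == "G":
            sigs.loc[label, "SigClock"] = 3.0 * jitter
        if sub == "C>T":
            sigs.loc[label, "SigClock"] += 0.2 * jitter
        if sub == "C>A":
            sigs.loc[label, "SigOx"] = 1.0 + jitter
        if sub == "T>C":
            sigs.loc[label, "SigTrans"] = 1.0 + jitter
        sigs.loc[label, "SigFlat"] = 1.0
    return sigs / sigs.sum(axis=0)


def _arm_id(rad18: str, mlh1: str, treatment: str) -> str:
    return f"{rad18}_{mlh1}_{treatment}"


@dataclass
class CatalogDesign:
    """Arms and calibration of the clonal mutagenesis experiment.

    Eight arms: RAD18 status x MLH1 status x treatment.  ``basal_means``
    give the expected de novo SNV count accumulated over 20 population
    doublings without drug; ``induced_means`` the additional expectation
    under TMZ.  ``signature_mix`` maps each arm to a simplex over the
    reference signatures.  ``overdispersion`` is the negative-binomial
    alpha on clone totals (Var = mu + alpha mu^2).
    """

    rad18_statuses: tuple[str, ...] = ("RAD18+/+", "RAD18-/-")
    mlh1_statuses: tuple[str, ...] = ("MLH1+/+", "MLH1-/-")
    treatments: tuple[str, ...] = ("TMZ", "DMSO")
    clones_per_arm: int = 6
    basal_means: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("RAD18+/+", "MLH1+/+"): 150.0,
            ("RAD18-/-", "MLH1+/+"): 280.0,
            ("RAD18+/+", "MLH1-/-"): 1200.0,
            ("RAD18-/-", "MLH1-/-"): 1500.0,
        }
    )
    induced_means: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("RAD18+/+", "MLH1+/+"): 396.0,
            ("RAD18-/-", "MLH1+/+"): 378.0,
            ("RAD18+/+", "MLH1-/-"): 500.0,
            ("RAD18-/-", "MLH1-/-"): 0.0,
        }
    )
    signature_mix: dict[str, dict[str, float]] | None = None
    overdispersion: float = 0.05

    def __post_init__(self) -> None:
        if self.clones_per_arm < 1:
            raise ValueError("clones_per_arm must be >= 1")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.signature_mix is None:
            self.signature_mix = self._default_mix()
        for arm, mix in self.signature_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-8 or min(mix.values()) < 0:
                raise ValueError(f"signature mix for {arm} is not a simplex")

    def _default_mix(self) -> dict[str, dict[str, float]]:
        # TMZ arms are dominated by the alkylation-like signature; the
        # RAD18 knockout shifts more of its (similar) total into it,
        # emulating the ~2-fold Signature-11 excess seen without RAD18.
        mix = {}
        for r in self.rad18_statuses:
            for m in self.mlh1_statuses:
                mix[_arm_id(r, m, "DMSO")] = {"SigClock": 0.5, "SigFlat": 0.5}
                if m == "MLH1+/+":
                    frac = 0.8 if r == "RAD18-/-" else 0.5
                else:
                    frac = 0.3
                mix[_arm_id(r, m, "TMZ")] = {
                    "SigAlkyl": frac,
                    "SigClock": round(0.7 * (1 - frac), 10),
                    "SigFlat": round(0.3 * (1 - frac), 10),
                }
        return mix

    def arm_mean(self, rad18: str, mlh1: str, treatment: str) -> float:
        mean = self.basal_means[(rad18, mlh1)]
        if treatment == "TMZ":
            mean += self.induced_means[(rad18, mlh1)]
        return mean

    def arms(self):
        for r in self.rad18_statuses:
            for m in self.mlh1_statuses:
                for t in self.treatments:
                    yield r, m, t


def synthetic_reference(copies: int = 1) -> tuple[str, dict[str, list[int]]]:
    """A tiny reference sequence containing every trinucleotide context.

    The sequence is the concatenation of all 64 trinucleotides (repeated
    ``copies`` times); the centre base of each block has that block's
    trinucleotide as its context regardless of neighbours.  Returns the
    sequence and a map context -> 1-based centre positions.
    """
    trinucs = ["".join(t) for t in itertools.product(BASES, repeat=3)]
    seq_parts: list[str] = []
    positions: dict[str, list[int]] = {t: [] for t in trinucs}
    offset = 0
    for _ in range(max(copies, 1)):
        for t in trinucs:
            positions[t].append(offset + 2)  # 1-based centre
            seq_parts.append(t)
            offset += 3
    return "".join(seq_parts), positions


def write_reference_fasta(path: str, copies: int = 1, chrom: str = "chrS") -> None:
    """Write the synthetic context reference as a FASTA file."""
    seq, _ = synthetic_reference(copies)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def gen_mutation_catalogs(
    design: CatalogDesign = CatalogDesign(),
    signature_matrix: pd.DataFrame | None = None,
    reference_contexts: dict[str, list[int]] | None = None,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-clone somatic SNV records with known signature truth.

    Per clone the total SNV count is negative-binomial around the arm
    mean (basal, plus induced under TMZ); each mutation draws a signature
    from the arm's mixture and a 96-channel context from that signature's
    profile.  Records carry depth / alt-read / VAF values that pass the
    default somatic filter chain, and each record's strand representation
    is randomized (half are emitted as the purine-strand equivalent) so
    canonicalization is exercised.

    Returns
    -------
    (variants, truth)
        ``variants``: one row per emitted SNV with columns ``chrom, pos,
        ref, alt, depth, alt_reads, sample, context, filter``.
        ``truth``: one row per clone with the arm labels, the drawn total
        and the drawn per-signature mutation counts (exposures).
    """
    sigs = synthetic_signature_matrix() if signature_matrix is None else signature_matrix
    sig_cols = {s: sigs[s].to_numpy(float) for s in sigs.columns}
    if reference_contexts is None:
        _, reference_contexts = synthetic_reference()
    for label in CONTEXTS_96:
        five, ref, alt, three = label_parts(label)
        for ctx in (five + ref + three, revcomp(five + ref + three)):
            if not reference_contexts.get(ctx):
                raise ValueError(f"no reference locus for context {ctx}")

    rng = np.random.default_rng(seed)
    channel_meta = [label_parts(lab) for lab in CONTEXTS_96]
    var_rows: list[pd.DataFrame] = []
    truth_rows = []
    for rad18, mlh1, trt in design.arms():
        arm = _arm_id(rad18, mlh1, trt)
        mix = design.signature_mix[arm]
        mix_names = list(mix)
        mix_probs = np.array([mix[s] for s in mix_names], float)
        for s in mix_names:
            if s not in sig_cols:
                raise KeyError(f"mixture references unknown signature {s!r}")
        mean = design.arm_mean(rad18, mlh1, trt)
        for c in range(1, design.clones_per_arm + 1):
            sample = f"{arm}_c{c}"
            total = int(_nb_draw(rng, np.array([mean]), design.overdispersion)[0])
            sig_counts = rng.multinomial(total, mix_probs)
            chan_counts = np.zeros(96, dtype=int)
            for s_name, k in zip(mix_names, sig_counts):
                if k:
                    chan_counts += rng.multinomial(k, sig_cols[s_name])
            row = {
                "sample": sample, "rad18": rad18, "mlh1": mlh1,
                "treatment": trt, "total": total,
            }
            row.update({f"true_{s}": 0 for s in sigs.columns})
            row.update({f"true_{s}": int(k) for s, k in zip(mix_names, sig_counts)})
            truth_rows.append(row)
            if total == 0:
                continue
            chan_idx = np.repeat(np.arange(96), chan_counts)
            flip = rng.random(total) < 0.5  # purine-strand representation
            depth = rng.integers(40, 101, total)
            vaf = rng.uniform(0.2, 0.6, total)
            alt_reads = np.maximum(3, np.round(vaf * depth)).astype(int)
            refs, alts, ctxs, poss = [], [], [], []
            for i, ch in enumerate(chan_idx):
                five, ref, alt, three = channel_meta[ch]
                ctx = five + ref + three
                if flip[i]:
                    ctx = revcomp(ctx)
                    ref, alt = revcomp(ref), revcomp(alt)
                loci = reference_contexts[ctx]
                poss.append(loci[int(rng.integers(0, len(loci)))])
                refs.append(ref)
                alts.append(alt)
                ctxs.append(ctx)
            var_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": poss,
                        "ref": refs,
                        "alt": alts,
                        "depth": depth,
                        "alt_reads": alt_reads,
                        "sample": sample,
                        "context": ctxs,
                        "filter": "PASS",
                    }
                )
            )
    variants = (
        pd.concat(var_rows, ignore_index=True)
        if var_rows
        else pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "depth", "alt_reads",
                     "sample", "context", "filter"]
        )
    )
    truth = pd.DataFrame(truth_rows)
    return variants, truth


def induced_increment(
    rad18: str,
    mlh1: str,
    n_clones: int,
    design: CatalogDesign | None = None,
    seed: int = 0,
) -> float:
    """Mean TMZ-arm minus mean DMSO-arm de novo SNV count for one genotype,
    measured on ``n_clones`` simulated clones per arm by counting emitted
    variant records."""
    base = design if design is not None else CatalogDesign()
    sub = CatalogDesign(
        rad18_statuses=(rad18,),
        mlh1_statuses=(mlh1,),
        treatments=("TMZ", "DMSO"),
        clones_per_arm=n_clones,
        basal_means=base.basal_means,
        induced_means=base.induced_means,
        overdispersion=base.overdispersion,
    )
    variants, truth = gen_mutation_catalogs(sub, seed=seed)
    per_clone = (
        variants.groupby("sample").size().reindex(truth["sample"], fill_value=0)
    )
    totals = truth.set_index("sample").assign(observed=per_clone)
    means = totals.groupby("treatment")["observed"].mean()
    return float(means["TMZ"] - means["DMSO"])


# ---------------------------------------------------------------------------
# patient cohort

@dataclass
class CohortDesign:
    """Size, correlation structure and logistic model of the synthetic
    recurrent-GBM cohort.

    ``rho`` is the target Pearson correlation between RAD18 expression
    and the proliferation score; ``beta_*`` are logit-scale coefficients
    of the hypermutation model on proliferation-adjusted RAD18 and the
    MGMT-low indicator.
    """

    n_samples: int = 200
    rho: float = 0.75
    beta0: float = -1.0
    beta_rad18: float = -1.5
    beta_mgmt: float = 1.5
    mgmt_low_fraction: float = 0.5
    pole_fraction: float = 0.03

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly inside (-1, 1)")
        if not 0.0 <= self.mgmt_low_fraction <= 1.0:
            raise ValueError("mgmt_low_fraction must be in [0, 1]")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")


def gen_cohort(
    design: CohortDesign = CohortDesign(), seed: int = 0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate a patient cohort table with known model coefficients.

    RAD18 expression is ``rho * proliferation + sqrt(1 - rho^2) * noise``
    with standard-normal components, so the empirical RAD18–proliferation
    correlation converges to ``rho``.  Hypermutation is Bernoulli with
    logit = beta0 + beta_rad18 * adjusted_RAD18 + beta_mgmt * MGMT_low,
    where adjusted RAD18 is the noise component (what the OLS residual
    estimates).  Signature mutation counts are drawn so that hypermutant
    samples strictly exceed 500 and non-hypermutants never do.

    Returns the cohort table (``sample, rad18, proliferation, mgmt_low,
    pole_mutant, hypermutation, sig11_count``) and the truth coefficients.
    """
    rng = np.random.default_rng(seed)
    n, rho = design.n_samples, design.rho
    prolif = rng.normal(0.0, 1.0, n)
    noise = rng.normal(0.0, 1.0, n)
    rad18 = rho * prolif + np.sqrt(1.0 - rho**2) * noise
    adj_true = rad18 - rho * prolif
    mgmt_low = (rng.random(n) < design.mgmt_low_fraction).astype(int)
    logit = design.beta0 + design.beta_rad18 * adj_true + design.beta_mgmt * mgmt_low
    hyper = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    sig11 = np.where(
        hyper == 1,
        501 + rng.poisson(400.0, n),
        np.minimum(500, rng.poisson(120.0, n)),
    )
    pole = rng.random(n) < design.pole_fraction
    cohort = pd.DataFrame(
        {
            "sample": [f"rGBM{i + 1:04d}" for i in range(n)],
            "rad18": rad18,
            "proliferation": prolif,
            "mgmt_low": mgmt_low,
            "pole_mutant": pole,
            "hypermutation": hyper,
            "sig11_count": sig11,
        }
    )
    truth = {
        "rho": rho,
        "beta0": design.beta0,
        "beta_rad18": design.beta_rad18,
        "beta_mgmt": design.beta_mgmt,
    }
    return cohort, truth


def gen_expression_matrix(
    cohort: pd.DataFrame,
    n_cycle_genes: int = 20,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Cell-cycle marker expression consistent with the cohort's
    proliferation scores (genes x samples), for exercising the
    single-sample proliferation score.  Returns the matrix and the gene
    set; the matrix also carries the RAD18 expression row."""
    rng = np.random.default_rng(seed)
    prolif = cohort["proliferation"].to_numpy(float)
    genes = [f"CCG{i + 1:03d}" for i in range(n_cycle_genes)]
    rows = {}
    for g in genes:
        loading = rng.uniform(0.7, 1.3)
        rows[g] = loading * prolif + rng.normal(0.0, noise_sd, prolif.size)
    rows["RAD18"] = cohort["rad18"].to_numpy(float)
    mat = pd.DataFrame(rows, index=cohort["sample"]).T
    return mat, genes
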