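"""Dropout statistics for pooled CRISPR screens.

Implements the statistics used to rank genes and DNA-repair pathways in a
PD0 -> PD20 dropout screen run with and without drug:

* per-guide log2 fold changes of normalized counts (PD20 vs PD0),
* the SigmaFC (SUMLFC) gene score — the sum of log fold changes of all
  guides targeting a gene,
* empirical permutation p-values against resampled non-targeting control
  guides,
* a two-sample gene Z-statistic comparing drug to vehicle arms,
  Z_g = X_g / S_g, where X_g is the difference in mean guide log fold
  change and S_g the standard error of that difference,
* a pathway-combined statistic Z_P = (sum X_g) / sqrt(sum S_g^2), which is
  standard normal under the null, and
* pathway dropout summaries (paired t-test on log10 counts and pooled
  log2 fold change) for heatmap/radar displays.

All statistics are invariant to the count-normalization constant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .screen_quant import CountMatrix

__all__ = [
    "guide_lfc",
    "gene_sigma_fc",
    "permutation_pvalue",
    "permutation_pvalues",
    "gene_zstat",
    "gene_zstats",
    "pathway_zstat",
    "pathway_zstats",
    "pathway_dropout_stats",
]

ARM_KEYS = ["genotype", "treatment", "replicate"]


def guide_lfc(
    norm: CountMatrix,
    pseudocount: float = 1.0,
    timepoints: tuple[str, str] = ("PD0", "PD20"),
) -> pd.DataFrame:
    """Per-guide log2 ratio of late vs early timepoint, per screen arm.

    Returns a long table with one row per guide x (genotype, treatment,
    replicate): ``lfc = log2((n_late + c) / (n_early + c))`` on normalized
    counts.  With a positive pseudocount every value is finite, and a
    guide absent at both timepoints scores 0.
    """
    if not norm.normalized:
        warnings.warn("guide_lfc called on a matrix not flagged as normalized")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    t0, t1 = timepoints
    meta = norm.samples
    out = []
    for arm, group in meta.groupby(ARM_KEYS, sort=False, dropna=False):
        early = group.index[group["timepoint"] == t0]
        late = group.index[group["timepoint"] == t1]
        if len(early) != 1 or len(late) != 1:
            raise ValueError(
                f"arm {arm}: expected exactly one {t0} and one {t1} sample, "
                f"got {len(early)} and {len(late)}"
            )
        n0 = norm.counts[early[0]].to_numpy(float)
        n1 = norm.counts[late[0]].to_numpy(float)
        lfc = np.log2(n1 + pseudocount) - np.log2(n0 + pseudocount)
        frame = pd.DataFrame(
            {
                "guide_id": norm.guide_ids,
                "genotype": arm[0],
                "treatment": arm[1],
                "replicate": arm[2],
                "lfc": lfc,
            }
        )
        out.append(frame)
    return pd.concat(out, ignore_index=True)


def _attach_genes(lfc: pd.DataFrame, library: pd.DataFrame) -> pd.DataFrame:
    cols = ["guide_id", "gene", "is_control"]
    merged = lfc.merge(library[cols], on="guide_id", how="left", validate="m:1")
    if merged["is_control"].isna().any():
        missing = merged.loc[merged["is_control"].isna(), "guide_id"].unique()
        raise KeyError(f"guides absent from library manifest: {missing[:5]}")
    return merged


def _guide_means(lfc: pd.DataFrame, library: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean LFC per guide per (genotype, treatment)."""
    merged = _attach_genes(lfc, library)
    return (
        merged.groupby(["genotype", "treatment", "gene", "guide_id", "is_control"],
                       sort=False, dropna=False)["lfc"]
        .mean()
        .reset_index()
    )


def gene_sigma_fc(
    lfc: pd.DataFrame, library: pd.DataFrame, gene: str | None = None
) -> pd.DataFrame | pd.Series:
    """SigmaFC gene score: sum over a gene's guides of replicate-mean LFC.

    Note the score scales with the number of guides per gene; it is a sum,
    not a mean, by construction.
    """
    means = _guide_means(lfc, library)
    targeting = means[~means["is_control"].astype(bool)]
    sigma = (
        targeting.groupby(["gene", "genotype", "treatment"], sort=False)["lfc"]
        .sum()
        .rename("sigma_fc")
    )
    if gene is not None:
        if gene not in sigma.index.get_level_values("gene"):
            raise KeyError(f"unknown gene {gene!r}")
        return sigma.xs(gene, level="gene")
    return sigma.reset_index()


def control_guide_means(lfc: pd.DataFrame, library: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean LFC of non-targeting control guides per arm."""
    means = _guide_means(lfc, library)
    return means[means["is_control"].astype(bool)].reset_index(drop=True)


def permutation_pvalue(
    observed: float,
    control_lfcs: np.ndarray,
    m: int,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided empirical permutation p for one gene's SigmaFC.

    The null distribution is built by drawing ``m`` control guides without
    replacement ``B`` times and scoring each draw by the sum of their
    replicate-mean LFCs.  p = (1 + #{|null| >= |obs|}) / (B + 1), bounded
    below by 1/(B+1).
    """
    null = _null_sigma(np.asarray(control_lfcs, float), m, B, seed)
    return float((1 + np.sum(np.abs(null) >= abs(observed))) / (B + 1))


def _null_sigma(
    controls: np.ndarray, m: int, B: int, seed: int | np.random.Generator
) -> np.ndarray:
    if controls.ndim != 1:
        raise ValueError("control LFCs must be a 1-d array of per-guide means")
    if m > controls.size:
        raise ValueError(
            f"cannot resample {m} guides from {controls.size} controls"
        )
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    # vectorized without-replacement resampling: argpartition of random keys
    keys = rng.random((B, controls.size))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    return controls[idx].sum(axis=1)


def permutation_pvalues(
    observed: pd.Series,
    control_lfcs: np.ndarray,
    m: int,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Permutation p-values for many genes against a shared control null.

    All genes with the same guide count share one resampled null
    distribution, which is how the screen-scale test is run in practice.
    """
    null = np.sort(np.abs(_null_sigma(np.asarray(control_lfcs, float), m, B, seed)))
    obs = np.abs(observed.to_numpy(float))
    # count of |null| >= |obs| via searchsorted on the sorted null
    ge = B - np.searchsorted(null, obs, side="left")
    return pd.Series((1 + ge) / (B + 1), index=observed.index, name="perm_p")


def _zstat(x_obs: np.ndarray, y_obs: np.ndarray) -> tuple[float, float, float]:
    x_obs, y_obs = np.asarray(x_obs, float), np.asarray(y_obs, float)
    if x_obs.size < 2 or y_obs.size < 2:
        raise ValueError("need >= 2 observations per condition")
    X = float(x_obs.mean() - y_obs.mean())
    S = float(
        np.sqrt(x_obs.var(ddof=1) / x_obs.size + y_obs.var(ddof=1) / y_obs.size)
    )
    if S == 0.0:
        if X == 0.0:
            return 0.0, 0.0, 0.0
        raise ValueError("zero variance with non-zero mean difference")
    return X, S, X / S


def gene_zstat(
    lfc: pd.DataFrame,
    library: pd.DataFrame,
    gene: str,
    genotype: str,
    treatment_test: str = "TMZ",
    treatment_ref: str = "DMSO",
    collapse_replicates: bool = True,
) -> tuple[float, float, float]:
    """Two-sample Z-statistic for one gene: drug vs vehicle guide LFCs.

    X_g is the difference in sample means (test - reference), S_g the
    standard error of that difference (Welch form), Z_g = X_g / S_g.
    By default each guide contributes one observation per condition (its
    replicate-mean LFC): guides carry a shared per-guide efficacy
    component across replicates, so replicate-mean units are the
    exchangeable ones and the only pooling under which Z_P is standard
    normal under the null.  ``collapse_replicates=False`` pools raw
    guide x replicate values instead.
    """
    merged = _attach_genes(lfc, library)
    sub = merged[(merged["gene"] == gene) & (merged["genotype"] == genotype)]
    if sub.empty:
        raise KeyError(f"no guides for gene {gene!r} in genotype {genotype!r}")
    if collapse_replicates:
        sub = (
            sub.groupby(["treatment", "guide_id"], sort=False)["lfc"]
            .mean()
            .reset_index()
        )
    x = sub.loc[sub["treatment"] == treatment_test, "lfc"].to_numpy()
    y = sub.loc[sub["treatment"] == treatment_ref, "lfc"].to_numpy()
    return _zstat(x, y)


def gene_zstats(
    lfc: pd.DataFrame,
    library: pd.DataFrame,
    genotype: str,
    treatment_test: str = "TMZ",
    treatment_ref: str = "DMSO",
    collapse_replicates: bool = True,
) -> pd.DataFrame:
    """Gene Z-statistics for every targeted gene in one genotype.

    Returns a DataFrame indexed by gene with columns X, S, Z.
    """
    merged = _attach_genes(lfc, library)
    merged = merged[~merged["is_control"].astype(bool)]
    merged = merged[merged["genotype"] == genotype]
    if collapse_replicates:
        merged = (
            merged.groupby(["gene", "treatment", "guide_id"], sort=False)["lfc"]
            .mean()
            .reset_index()
        )
    rows = {}
    for gene, sub in merged.groupby("gene", sort=False):
        x = sub.loc[sub["treatment"] == treatment_test, "lfc"].to_numpy()
        y = sub.loc[sub["treatment"] == treatment_ref, "lfc"].to_numpy()
        rows[gene] = _zstat(x, y)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["X", "S", "Z"])
    out.index.name = "gene"
    return out


def pathway_zstat(gene_scores: pd.DataFrame, members: list[str]) -> tuple[float, float]:
    """Combine member-gene statistics into Z_P = (sum X_g)/sqrt(sum S_g^2).

    ``gene_scores`` is the output of :func:`gene_zstats`.  Under the null
    Z_P is standard normal; the returned p is the two-sided normal tail
    probability.  For a single-gene pathway Z_P equals that gene's Z_g.
    """
    if not members:
        raise ValueError("empty pathway")
    missing = [g for g in members if g not in gene_scores.index]
    if missing:
        raise KeyError(f"pathway members without gene scores: {missing[:5]}")
    sub = gene_scores.loc[members]
    denom = float(np.sqrt((sub["S"] ** 2).sum()))
    if denom == 0.0:
        raise ValueError("all member genes have zero-variance statistics")
    z = float(sub["X"].sum()) / denom
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, p


def pathway_zstats(
    gene_scores: pd.DataFrame, pathway_map: pd.DataFrame
) -> pd.DataFrame:
    """Z_P and p for every pathway in a many-to-many gene->pathway map.

    ``pathway_map`` has columns ``gene`` and ``pathway``; a gene listed
    under several pathways contributes to each.
    """
    rows = {}
    for pw, sub in pathway_map.groupby("pathway", sort=False):
        genes = [g for g in sub["gene"].unique() if g in gene_scores.index]
        if not genes:
            continue
        rows[pw] = pathway_zstat(gene_scores, genes)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["Z_P", "p_Z"])
    out.index.name = "pathway"
    return out


def pathway_dropout_stats(
    norm: CountMatrix,
    library: pd.DataFrame,
    members: list[str],
    genotype: str,
    treatment: str,
    pseudocount: float = 1.0,
    timepoints: tuple[str, str] = ("PD0", "PD20"),
) -> tuple[float, float]:
    """Heatmap statistics for one pathway in one screen arm.

    Pairs are guide x replicate units; the paired t-test compares
    log10(PD20 + c) against log10(PD0 + c), and the pooled log2 fold
    change is log2(sum PD20 / sum PD0) over the pathway's guides.

    Degenerate conventions: all paired differences exactly zero -> p = 1;
    zero variance with a non-zero mean difference -> p = 0 with a warning.
    """
    guides = library.loc[
        library["gene"].isin(members) & ~library["is_control"].astype(bool),
        "guide_id",
    ].astype(str)
    mask = norm.guide_ids.isin(guides)
    t0, t1 = timepoints
    meta = norm.samples
    early_v, late_v = [], []
    for _, group in meta[
        (meta["genotype"] == genotype) & (meta["treatment"] == treatment)
    ].groupby("replicate", sort=False):
        early = group.index[group["timepoint"] == t0]
        late = group.index[group["timepoint"] == t1]
        if len(early) != 1 or len(late) != 1:
            raise ValueError("each replicate needs exactly one sample per timepoint")
        early_v.append(norm.counts.loc[mask, early[0]].to_numpy(float))
        late_v.append(norm.counts.loc[mask, late[0]].to_numpy(float))
    n0 = np.concatenate(early_v)
    n1 = np.concatenate(late_v)
    if n0.size < 2:
        raise ValueError("pathway has fewer than 2 guide observations")
    d = np.log10(n1 + pseudocount) - np.log10(n0 + pseudocount)
    if np.allclose(d.var(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            p = 1.0
        else:
            warnings.warn("zero-variance non-zero paired differences; p set to 0")
            p = 0.0
    else:
        p = float(stats.ttest_rel(np.log10(n1 + pseudocount),
                                  np.log10(n0 + pseudocount)).pvalue)
    tot0, tot1 = n0.sum(), n1.sum()
    if tot0 <= 0:
        raise ValueError("pathway PD0 counts sum to zero")
    log2fc = float(np.log2(tot1 / tot0)) if tot1 > 0 else -np.inf
    return p, log2fc
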