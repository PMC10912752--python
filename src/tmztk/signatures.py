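"""Mutational-signature refitting and hypermutation classification.

Signature exposures are obtained by non-negative least squares: for each
sample's 96-channel mutation count vector m and a reference signature
matrix S (96 x K, columns are probability vectors), the exposures e >= 0
minimize ||m - S e||_2.  Exposures are reported in mutation counts, so
the count attributed to an alkylation signature (COSMIC v2 Signature 11
in the reference set) can be thresholded directly: a sample with strictly
more than 500 mutations attributed to that signature is classified as
hypermutant.

Group comparisons of per-clone exposures use pairwise two-sided t tests
with Tukey HSD adjustment via the studentized-range distribution.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

__all__ = [
    "validate_signature_matrix",
    "fit_exposures",
    "classify_hypermutation",
    "compare_groups",
]


def validate_signature_matrix(signatures: pd.DataFrame, atol: float = 1e-8) -> None:
    """Check that every signature column is a 96-entry probability vector."""
    vals = signatures.to_numpy(float)
    if (vals < 0).any():
        raise ValueError("signature matrix has negative entries")
    sums = vals.sum(axis=0)
    bad = signatures.columns[np.abs(sums - 1.0) > max(atol, 1e-6)]
    if len(bad):
        raise ValueError(f"signature column(s) not normalized: {list(bad)}")


def fit_exposures(catalog: pd.DataFrame, signatures: pd.DataFrame) -> pd.DataFrame:
    """Refit signature exposures per sample by non-negative least squares.

    Solved with the Lawson–Hanson active-set algorithm, which returns the
    exact KKT-satisfying minimizer, so results are deterministic.

    Parameters
    ----------
    catalog
        96-channel x samples mutation counts.
    signatures
        96-channel x K signature matrix sharing the catalog's context
        index (same labels, same order).

    Returns
    -------
    DataFrame samples x (K signatures + ``residual``), exposures in
    mutation counts and the per-sample residual 2-norm.
    """
    if not catalog.index.equals(signatures.index):
        raise ValueError("catalog and signature matrix context orderings differ")
    validate_signature_matrix(signatures)
    S = signatures.to_numpy(float)
    rows = {}
    for sample in catalog.columns:
        m = catalog[sample].to_numpy(float)
        e, rnorm = nnls(S, m)
        rows[sample] = np.append(e, rnorm)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=[*signatures.columns, "residual"]
    )
    out.index.name = "sample"
    return out


def classify_hypermutation(
    exposures: pd.DataFrame, signature_id: str, threshold: float = 500.0
) -> pd.Series:
    """Flag samples whose exposure on one signature strictly exceeds the
    threshold (default: > 500 mutation counts)."""
    if signature_id not in exposures.columns:
        raise KeyError(f"signature {signature_id!r} not in exposure table")
    return (exposures[signature_id] > threshold).rename("hypermutation")


def compare_groups(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """All pairwise group comparisons with Tukey HSD adjustment.

    One-way layout: the pooled within-group variance with N - k error
    degrees of freedom studentizes each pairwise mean difference, and the
    adjusted p-value is the tail probability of the studentized range
    with k groups.  For k = 2 this reduces exactly to the pooled
    two-sided two-sample t test (q = |t| * sqrt(2)).

    Returns a DataFrame with one row per group pair: ``group1, group2,
    mean_diff, t, p_adj``.
    """
    values = pd.Series(np.asarray(values, float))
    groups = pd.Series(np.asarray(groups)).astype(str)
    labels = groups.unique()
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    by = {g: values[groups.values == g].to_numpy() for g in labels}
    ns = {g: v.size for g, v in by.items()}
    if min(ns.values()) < 2:
        raise ValueError("every group needs at least two values")
    N = int(sum(ns.values()))
    df_err = N - k
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by.values())
    ms_within = ss_within / df_err
    if ms_within <= 0:
        raise ValueError("zero pooled within-group variance")

    rows = []
    for g1, g2 in combinations(labels, 2):
        v1, v2 = by[g1], by[g2]
        diff = v1.mean() - v2.mean()
        se = np.sqrt(ms_within * (1.0 / v1.size + 1.0 / v2.size))
        t = diff / se
        q = abs(t) * np.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, df_err))
        rows.append((g1, g2, float(diff), float(t), min(max(p, 0.0), 1.0)))
    return pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "t", "p_adj"])
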