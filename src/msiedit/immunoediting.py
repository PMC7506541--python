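"""Immunoediting statistics: does immunogenicity predict mutation depletion?

Under immunoediting, tumor-cell clones carrying strongly immunogenic
frameshift peptides are counter-selected in immune-competent hosts, so
across coding microsatellites the mutation frequency should correlate
negatively with peptide immunogenicity (GELS) — but only in tumors with
intact antigen presentation (B2M wild type), and for allele-restricted
scores only in carriers of that allele.  This module provides the
correlation, stratification, length adjustment, clustering and embedding
machinery for that analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import KernelPCA

from .cohort import CohortMatrix
from .reframe import CmsLocus


@dataclass
class CorrelationResult:
    """Pearson correlation with Fisher-z confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    stratum: str = "all"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"r={self.r:+.3f} [{self.ci_low:+.3f}, {self.ci_high:+.3f}], "
            f"p={self.p_value:.3g}, n={self.n} ({self.stratum})"
        )


def pearson_with_ci(
    x: Sequence[float],
    y: Sequence[float],
    stratum: str = "all",
    confidence: float = 0.95,
) -> CorrelationResult:
    """Pearson r with two-sided t-test p-value and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    # Fisher z: atanh(r) is ~normal with sd 1/sqrt(n-3)
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.5 + confidence / 2) / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    else:
        lo, hi = -1.0, 1.0
    return CorrelationResult(
        r=r, ci_low=float(lo), ci_high=float(hi), p_value=float(res.pvalue), n=n, stratum=stratum
    )


def gels_mutation_correlation(
    cohort: CohortMatrix,
    gels: Mapping[str, float] | pd.Series,
    stratum: str = "all",
    tumor_type: str | None = None,
    frequency_mode: str = "prevalence",
) -> CorrelationResult:
    """Correlate per-cMS M1 mutation frequency against M1-peptide GELS.

    One paired observation per cMS; the stratum filters tumors before the
    mutation frequency is computed (B2M-wild-type tumors are the
    immune-competent stratum where editing is expected).
    """
    samples = cohort.select_samples(stratum, tumor_type)
    if not samples:
        raise ValueError(f"stratum {stratum!r} contains no tumors")
    pairs = []
    for locus_id in cohort.loci:
        if locus_id not in gels:
            continue
        freq = cohort.m1_frequency(locus_id, stratum, tumor_type, mode=frequency_mode)
        if np.isnan(freq):
            continue
        pairs.append((float(gels[locus_id]), freq))
    if len(pairs) < 3:
        raise ValueError("fewer than 3 cMS with both GELS and mutation frequency")
    x, y = zip(*pairs)
    return pearson_with_ci(x, y, stratum=stratum)


def relative_mutation_frequency(
    frequencies: Mapping[str, float] | pd.Series,
    loci: Mapping[str, CmsLocus],
) -> pd.Series:
    """Length-adjusted mutation frequencies.

    Subtracts from each cMS's observed frequency the mean frequency of
    all cMS sharing its repeat length, removing the dominant
    length-dependence of slippage rates.  Adjusted values are mean-zero
    within every length bin.
    """
    freq = pd.Series(dict(frequencies), dtype=float)
    lengths = pd.Series({l: loci[l].repeat_length for l in freq.index})
    adjusted = freq - freq.groupby(lengths).transform("mean")
    return adjusted


def hla_restricted_correlation(
    cohort: CohortMatrix,
    epitope_counts: Mapping[str, int],
    p_binding: float = 0.5,
    tumor_type: str | None = None,
    unit: str = "cms",
    frequency_mode: str = "prevalence",
    min_group: int = 3,
) -> dict[str, CorrelationResult]:
    """Allele-restricted editing test (HLA-A*02:01 carriers vs non-carriers).

    The immunogenicity score is the binding factor of ELS alone,
    ``s(n) = 1 - (1 - p_binding)^k(n)`` with k(n) the number of predicted
    binders of the peptide for the restricting allele — the carrier term
    is dropped because the cohort is stratified by actual carrier status.
    Returns one correlation per status group.

    ``unit="cms"`` correlates per-cMS mutation frequencies (n = number of
    loci); ``unit="pair"`` correlates per tumor×cMS binary mutation
    indicators against s(n) across all non-missing pairs.
    """
    scores = {
        l: 1.0 - (1.0 - p_binding) ** int(epitope_counts[l])
        for l in cohort.loci
        if l in epitope_counts
    }
    if len(scores) < 3:
        raise ValueError("fewer than 3 loci with epitope counts")
    out: dict[str, CorrelationResult] = {}
    for stratum, label in (("hla_pos", "positive"), ("hla_neg", "negative")):
        samples = cohort.select_samples(stratum, tumor_type)
        if len(samples) < min_group:
            raise ValueError(f"HLA {label} group has fewer than {min_group} tumors")
        if unit == "cms":
            x, y = [], []
            for locus_id, s in scores.items():
                freq = cohort.m1_frequency(locus_id, stratum, tumor_type, mode=frequency_mode)
                if not np.isnan(freq):
                    x.append(s)
                    y.append(freq)
            out[label] = pearson_with_ci(x, y, stratum=label)
        elif unit == "pair":
            x, y = [], []
            for locus_id, s in scores.items():
                for sample in samples:
                    call = cohort.calls.get((sample, locus_id))
                    if call is None:
                        continue
                    x.append(s)
                    y.append(
                        1.0 if call.is_mutant and call.dominant_frame == "M1" else 0.0
                    )
            out[label] = pearson_with_ci(x, y, stratum=label)
        else:
            raise ValueError(f"unknown unit {unit!r}")
    return out


# ---------------------------------------------------------------------------
# clustering features
# ---------------------------------------------------------------------------


@dataclass
class CmsFeatureMatrix:
    """Frame-abundance features (M2, M1, wt) with a mean-imputation mask.

    ``values`` is (rows × features); rows are cMS candidates (features
    concatenated over tumors) or tumors, per ``group_by``.  ``mask``
    marks cells that were missing and replaced by the column mean.
    """

    values: np.ndarray
    mask: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def build_feature_matrix(
    cohort: CohortMatrix,
    group_by: str = "cms",
    stratum: str = "all",
) -> CmsFeatureMatrix:
    """Frame-summary feature matrix for clustering.

    For ``group_by="cms"`` each row is a cMS and the columns are the
    (M2, M1, wt) triple of every tumor; ``group_by="tumor"`` transposes
    the arrangement.  Missing cells are imputed with the column mean
    (mean over rows observed for that column); all-missing rows are
    dropped with a warning.
    """
    samples = cohort.select_samples(stratum)
    if group_by == "cms":
        rows, cols = list(cohort.loci), samples
    elif group_by == "tumor":
        rows, cols = samples, list(cohort.loci)
    else:
        raise ValueError(f"unknown grouping {group_by!r}")

    n_feat = 3 * len(cols)
    values = np.full((len(rows), n_feat), np.nan)
    for i, row_key in enumerate(rows):
        for j, col_key in enumerate(cols):
            key = (col_key, row_key) if group_by == "cms" else (row_key, col_key)
            fs = cohort.frames.get(key)
            if fs is not None:
                values[i, 3 * j : 3 * j + 3] = (fs.m2_fraction, fs.m1_fraction, fs.m0_fraction)

    keep = ~np.all(np.isnan(values), axis=1)
    if not keep.all():
        dropped = [r for r, k in zip(rows, keep) if not k]
        warnings.warn(f"dropping all-missing rows: {dropped}", stacklevel=2)
        values = values[keep]
        rows = [r for r, k in zip(rows, keep) if k]

    mask = np.isnan(values)
    col_means = np.nanmean(np.where(mask, np.nan, values), axis=0)
    col_means = np.nan_to_num(col_means)  # columns with no observation at all
    values = np.where(mask, col_means, values)

    col_labels = [f"{c}:{f}" for c in cols for f in ("M2", "M1", "wt")]
    return CmsFeatureMatrix(values=values, mask=mask, row_labels=list(rows), col_labels=col_labels)


def cluster_cms(
    features: CmsFeatureMatrix,
    n_clusters: int = 3,
    dissimilarity_threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ward hierarchical clustering of the feature rows.

    Returns ``(linkage, labels)``: the SciPy linkage matrix and 1-based
    flat cluster labels obtained by cutting the dendrogram into
    ``n_clusters`` groups, or at ``dissimilarity_threshold`` when given
    (a cut below which no merges are accepted — if all merges lie below
    it, a single cluster results, i.e. "no clustering at the threshold").
    """
    if features.n_rows < n_clusters:
        raise ValueError(
            f"cannot extract {n_clusters} clusters from {features.n_rows} rows"
        )
    linkage = hierarchy.linkage(features.values, method="ward")
    if dissimilarity_threshold is not None:
        labels = hierarchy.fcluster(linkage, t=dissimilarity_threshold, criterion="distance")
    else:
        labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return linkage, labels


def kernel_pca_embed(
    features: CmsFeatureMatrix,
    n_components: int = 2,
    gamma: float | None = None,
) -> np.ndarray:
    """2-D RBF kernel PCA embedding of the feature rows.

    gamma defaults to 1/(number of feature columns).  The embedding is
    deterministic: each component's sign is fixed so its
    largest-magnitude coordinate is positive.  Degenerate input (all rows
    identical) returns the all-zero embedding with a warning.
    """
    if features.n_rows < 2:
        raise ValueError("need at least 2 rows to embed")
    X = features.values
    if np.allclose(X, X[0]):
        warnings.warn("all rows identical; returning zero embedding", stacklevel=2)
        return np.zeros((features.n_rows, n_components))
    if gamma is None:
        gamma = 1.0 / X.shape[1]
    kpca = KernelPCA(n_components=n_components, kernel="rbf", gamma=gamma)
    emb = kpca.fit_transform(X)
    for k in range(emb.shape[1]):
        i = np.argmax(np.abs(emb[:, k]))
        if emb[i, k] < 0:
            emb[:, k] = -emb[:, k]
    return emb


def editing_report(results: Mapping[str, CorrelationResult]) -> pd.DataFrame:
    """Tabulate correlation results (stratum, n, r, CI, p)."""
    rows = [
        {
            "stratum": res.stratum,
            "n": res.n,
            "r": res.r,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p_value": res.p_value,
        }
        for res in results.values()
    ]
    return pd.DataFrame(rows)
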