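"""Epitope-likelihood scoring of frameshift peptides.

Given MHC class I binding predictions (IC50 in nM per candidate short
peptide and HLA allele) and population HLA allele frequencies, three
nested probabilities are computed per frameshift peptide n:

* ``ELS_H(n) = (1 - (1 - f_H)^2) * (1 - (1 - p_binding)^|E_H(n)|)`` —
  the probability that a random individual of the population carries at
  least one copy of HLA allele H (Hardy–Weinberg carrier term) and that
  at least one of the |E_H(n)| predicted binders is a true binder, with
  p_binding the assumed true-positive rate of the predictor.
* ``GELS_X(n) = 1 - prod_H (1 - ELS_H(n))`` over the panel of locus-X
  alleles (X ∈ {A, B}), and ``GELS = GELS_A + GELS_B - GELS_A*GELS_B``.
* ``IRS(n) = p_mut(n) * GELS(n)`` — joint probability that the mutation
  is present in a tumor and an HLA-presented binder exists.

Predicted binders are classed by affinity: high (< 50 nM), low
(< 500 nM), very low (< 5000 nM); predictions at or above 5000 nM are
discarded.  Candidate peptide lengths of interest are 8–14 residues.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reframe import CmsLocus

#: IC50 class boundaries (nM); intervals are half-open [lo, hi)
AFFINITY_CLASSES = (("high", 0.0, 50.0), ("low", 50.0, 500.0), ("very_low", 500.0, 5000.0))
DISCARD_THRESHOLD_NM = 5000.0
THRESHOLDS_NM = (50.0, 500.0, 5000.0)
MER_LENGTHS = range(8, 15)

#: HLA supertype representative panel used for scoring
SUPERTYPE_PANEL_A = ("A*01:01", "A*02:01", "A*03:01", "A*24:02", "A*26:01")
SUPERTYPE_PANEL_B = (
    "B*07:02",
    "B*08:01",
    "B*27:05",
    "B*39:01",
    "B*40:01",
    "B*58:01",
    "B*15:01",
)

#: p_binding grid at which score tables are computed (10% steps)
P_BINDING_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))
DEFAULT_P_BINDING = 0.5
DEFAULT_THRESHOLD_NM = 500.0


@dataclass(frozen=True)
class EpitopePrediction:
    """One predicted MHC ligand: a short mer of a frameshift peptide."""

    peptide_id: str
    hla_allele: str
    mer: str
    ic50: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50}")


@dataclass
class HlaFrequencyTable:
    """Population HLA allele frequencies (one population)."""

    population: str
    frequencies: dict[str, float]
    sample_size: int

    def __post_init__(self) -> None:
        for allele, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency for {allele} outside [0, 1]: {f}")

    def frequency(self, allele: str) -> float:
        return self.frequencies.get(allele, 0.0)


def hla_locus(allele: str) -> str:
    """HLA locus letter (A or B) of an allele name like ``A*02:01``."""
    prefix = allele.split("*")[0].removeprefix("HLA-").strip()
    if prefix in ("A", "B"):
        return prefix
    raise ValueError(f"allele {allele!r} is not at a supported locus (A or B)")


# ---------------------------------------------------------------------------
# prediction tables
# ---------------------------------------------------------------------------

_ALLELE_RE = r"^(HLA-)?[AB]\*\d{2}:\d{2}$"


def _norm_allele(name: str) -> str:
    name = name.strip().removeprefix("HLA-")
    # NetMHCpan-style names come without separators, e.g. A0201 / HLA-A02:01
    if "*" not in name and len(name) >= 5:
        name = f"{name[0]}*{name[1:3]}:{name[3:]}" if name[1].isdigit() else name
    return name


def read_predictions(path: str | Path, dialect: str = "generic") -> list[EpitopePrediction]:
    """Read MHC binding predictions.

    ``generic``: TSV with columns peptide_id, hla_allele, mer, ic50.
    ``netmhcpan``: whitespace-delimited long-format export with columns
    including HLA, Peptide, Identity and Aff(nM) (comment lines starting
    with ``#`` or dashes are skipped).

    Predictions at or above 5000 nM are retained but classed ``discarded``.
    """
    if dialect == "generic":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = {"peptide_id", "hla_allele", "mer", "ic50"} - set(df.columns)
        if missing:
            raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    elif dialect == "netmhcpan":
        rows = []
        with open(path) as fh:
            header: list[str] | None = None
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "-")):
                    continue
                parts = line.split()
                if header is None:
                    header = parts
                    continue
                rec = dict(zip(header, parts))
                rows.append(
                    {
                        "peptide_id": rec["Identity"],
                        "hla_allele": rec["HLA"],
                        "mer": rec["Peptide"],
                        "ic50": float(rec["Aff(nM)"]),
                    }
                )
        df = pd.DataFrame(rows)
        if df.empty:
            raise ValueError(f"no prediction rows parsed from {path}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    preds = []
    for row in df.itertuples(index=False):
        allele = _norm_allele(str(row.hla_allele))
        if not re.match(_ALLELE_RE, allele):
            raise ValueError(f"malformed HLA allele name {row.hla_allele!r}")
        preds.append(
            EpitopePrediction(
                peptide_id=str(row.peptide_id),
                hla_allele=allele,
                mer=str(row.mer),
                ic50=float(row.ic50),
            )
        )
    return preds


def classify_affinity(ic50: float) -> str:
    """Affinity class of a predicted binder (half-open IC50 intervals)."""
    if ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    for name, lo, hi in AFFINITY_CLASSES:
        if lo <= ic50 < hi:
            return name
    return "discarded"


def count_epitopes(
    predictions: Iterable[EpitopePrediction],
    peptide_id: str,
    hla_allele: str,
    threshold: float,
) -> int:
    """|E_H(n)|: distinct predicted mers below the IC50 threshold."""
    if threshold not in THRESHOLDS_NM:
        raise ValueError(f"threshold must be one of {THRESHOLDS_NM} nM")
    mers = {
        p.mer
        for p in predictions
        if p.peptide_id == peptide_id and p.hla_allele == hla_allele and p.ic50 < threshold
    }
    return len(mers)


def count_table(predictions: Iterable[EpitopePrediction]) -> pd.DataFrame:
    """Distinct-mer epitope counts per (peptide_id, hla_allele, threshold)."""
    preds = list(predictions)
    rows = []
    keys = sorted({(p.peptide_id, p.hla_allele) for p in preds})
    for pid, hla in keys:
        row = {"peptide_id": pid, "hla_allele": hla}
        for thr in THRESHOLDS_NM:
            row[f"n_lt_{int(thr)}"] = count_epitopes(preds, pid, hla, thr)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


def epitope_likelihood_score(f_h: float, count: int, p_binding: float) -> float:
    """ELS for one HLA allele: carrier probability × P(≥1 true binder)."""
    if not 0.0 <= f_h <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    if not 0.0 <= p_binding <= 1.0:
        raise ValueError("p_binding must be in [0, 1]")
    if count < 0:
        raise ValueError("epitope count must be non-negative")
    return (1.0 - (1.0 - f_h) ** 2) * (1.0 - (1.0 - p_binding) ** count)


def general_epitope_likelihood_score(
    els_by_allele: Mapping[str, float],
    locus_of: Mapping[str, str] | None = None,
) -> tuple[float, float, float]:
    """(GELS_A, GELS_B, GELS) from per-allele ELS values.

    Alleles are assigned to HLA locus A or B via ``locus_of`` or, by
    default, their name prefix.  An empty locus contributes GELS_X = 0.
    """
    gels: dict[str, float] = {"A": 0.0, "B": 0.0}
    prod: dict[str, float] = {"A": 1.0, "B": 1.0}
    for allele, els in els_by_allele.items():
        locus = locus_of[allele] if locus_of is not None else hla_locus(allele)
        if locus not in prod:
            raise ValueError(f"allele {allele!r} assigned to unknown HLA locus {locus!r}")
        prod[locus] *= 1.0 - els
    gels["A"] = 1.0 - prod["A"] if prod["A"] < 1.0 else 0.0
    gels["B"] = 1.0 - prod["B"] if prod["B"] < 1.0 else 0.0
    combined = gels["A"] + gels["B"] - gels["A"] * gels["B"]
    return gels["A"], gels["B"], combined


def immune_relevance_score(p_mut: float, gels: float) -> float:
    """IRS: joint probability of mutation presence and a presentable binder."""
    for name, v in (("p_mut", p_mut), ("GELS", gels)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return p_mut * gels


def load_hla_frequencies(
    path: str | Path,
    population: str | None = None,
    min_sample_size: int = 10_000,
    force: bool = False,
) -> HlaFrequencyTable:
    """Load one population's allele frequencies from a CSV.

    Columns: allele, frequency, population, sample_size.  Populations
    whose sample size falls below ``min_sample_size`` data points are
    rejected unless ``force`` is set — small panels give unstable carrier
    probabilities.
    """
    df = pd.read_csv(path)
    missing = {"allele", "frequency", "population", "sample_size"} - set(df.columns)
    if missing:
        raise ValueError(f"HLA frequency table missing columns: {sorted(missing)}")
    if population is None:
        population = str(df["population"].iloc[0])
    sub = df[df["population"] == population]
    if sub.empty:
        raise ValueError(f"population {population!r} not present in {path}")
    n = int(sub["sample_size"].iloc[0])
    if n < min_sample_size and not force:
        raise ValueError(
            f"population {population!r} has only {n} data points "
            f"(< {min_sample_size}); pass force=True to accept"
        )
    freqs = {
        _norm_allele(str(r.allele)): float(r.frequency) for r in sub.itertuples(index=False)
    }
    return HlaFrequencyTable(population=population, frequencies=freqs, sample_size=n)


def score_table(
    counts: pd.DataFrame,
    freqs: HlaFrequencyTable,
    p_mut: Mapping[str, float] | None = None,
    p_binding: float | Sequence[float] = DEFAULT_P_BINDING,
    threshold: float = DEFAULT_THRESHOLD_NM,
) -> pd.DataFrame:
    """Per-peptide ELS/GELS/IRS table.

    ``counts`` is the output of :func:`count_table`; ``p_mut`` maps
    peptide_id (or its gene part) to a mutation frequency — peptides
    without one get IRS = NaN.  Scores are computed at each requested
    ``p_binding`` and the given affinity ``threshold``.
    """
    col = f"n_lt_{int(threshold)}"
    if col not in counts.columns:
        raise ValueError(f"counts table has no column {col!r}")
    p_grid = [p_binding] if np.isscalar(p_binding) else list(p_binding)
    rows = []
    for pid, grp in counts.groupby("peptide_id"):
        for pb in p_grid:
            els = {}
            for r in grp.itertuples(index=False):
                f_h = freqs.frequency(r.hla_allele)
                els[r.hla_allele] = epitope_likelihood_score(f_h, getattr(r, col), pb)
            gels_a, gels_b, gels = general_epitope_likelihood_score(els)
            pm = None
            if p_mut is not None:
                pm = p_mut.get(pid, p_mut.get(str(pid).split("|")[0]))
            row = {
                "peptide_id": pid,
                "p_binding": pb,
                "threshold_nm": threshold,
                "population": freqs.population,
                "GELS_A": gels_a,
                "GELS_B": gels_b,
                "GELS": gels,
                "p_mut": np.nan if pm is None else pm,
                "IRS": np.nan if pm is None else immune_relevance_score(pm, gels),
            }
            for allele, v in els.items():
                row[f"ELS[{allele}]"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def gels_by_repeat_base(
    scores: pd.DataFrame,
    loci: Mapping[str, CmsLocus],
) -> dict[str, float]:
    """Median GELS by repeat-base group (A/T pooled vs G/C pooled).

    Peptide ids are linked to loci by their gene part.  Empty groups are
    omitted with a warning.
    """
    base_of = {}
    for locus in loci.values():
        base_of[locus.gene] = locus.repeat_base
        base_of[locus.locus_id] = locus.repeat_base
    groups: dict[str, list[float]] = {"A/T": [], "G/C": []}
    for r in scores.itertuples(index=False):
        gene = str(r.peptide_id).split("|")[0]
        base = base_of.get(gene)
        if base is None:
            continue
        groups["A/T" if base in "AT" else "G/C"].append(float(r.GELS))
    out = {}
    for name, vals in groups.items():
        if not vals:
            warnings.warn(f"no peptides in repeat-base group {name}", stacklevel=2)
            continue
        out[name] = float(np.median(vals))
    return out
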