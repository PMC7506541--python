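"""Cohort-level aggregation of per-sample allele distributions.

A cohort is a set of tumors (annotated with tumor type, B2M mutation
status and HLA-A*02:01 carrier status) profiled across a panel of coding
microsatellites.  Not every tumor is measurable at every locus; missing
cells are tracked explicitly and excluded from every denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .reframe import (
    OFFSETS,
    AlleleDistribution,
    CmsLocus,
    FrameSummary,
    MutationCall,
    call_mutation_status,
    classify_frames,
    frame_of,
)

ANNOTATION_COLUMNS = ["sample_id", "tumor_type", "b2m_status", "hla_a0201_status"]

#: recognised stratum labels for subgroup analyses
STRATA = ("all", "b2m_wt", "b2m_mut", "hla_pos", "hla_neg")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a cohort annotation TSV (sample_id, tumor_type, b2m_status, hla_a0201_status)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df.set_index("sample_id")


@dataclass
class CohortMatrix:
    """Tumors × cMS mutant-allele fractions with an explicit missingness mask.

    ``annotations`` is indexed by sample_id; ``cells`` maps
    (sample_id, locus_id) to an :class:`AlleleDistribution` — absent keys
    are missing data points.
    """

    annotations: pd.DataFrame
    cells: dict[tuple[str, str], AlleleDistribution]
    loci: list[str]
    mutation_cutoff: float = 0.15
    biallelic_cutoff: float = 0.5
    calls: dict[tuple[str, str], MutationCall] = field(default_factory=dict)
    frames: dict[tuple[str, str], FrameSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, dist in self.cells.items():
            if key not in self.calls:
                self.calls[key] = call_mutation_status(
                    dist, self.mutation_cutoff, self.biallelic_cutoff
                )
            if key not in self.frames:
                self.frames[key] = classify_frames(dist)

    # -- sample selection ---------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.annotations.index)

    def select_samples(self, stratum: str = "all", tumor_type: str | None = None) -> list[str]:
        """Sample ids in a stratum (``all``/``b2m_wt``/``b2m_mut``/``hla_pos``/``hla_neg``)."""
        ann = self.annotations
        if tumor_type is not None:
            ann = ann[ann["tumor_type"] == tumor_type]
        if stratum == "all":
            pass
        elif stratum == "b2m_wt":
            ann = ann[ann["b2m_status"] == "wildtype"]
        elif stratum == "b2m_mut":
            ann = ann[ann["b2m_status"] == "mutant"]
        elif stratum == "hla_pos":
            ann = ann[ann["hla_a0201_status"] == "positive"]
        elif stratum == "hla_neg":
            ann = ann[ann["hla_a0201_status"] == "negative"]
        else:
            raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
        return list(ann.index)

    # -- per-locus summaries ------------------------------------------------

    def _present(self, locus_id: str, samples: Iterable[str]) -> list[str]:
        return [s for s in samples if (s, locus_id) in self.cells]

    def p_mut(self, locus_id: str, stratum: str = "all", tumor_type: str | None = None) -> float:
        """Fraction of non-missing tumors called mutant at ``locus_id``."""
        present = self._present(locus_id, self.select_samples(stratum, tumor_type))
        if not present:
            return float("nan")
        return sum(self.calls[(s, locus_id)].is_mutant for s in present) / len(present)

    def biallelic_fraction(self, locus_id: str, stratum: str = "all") -> float:
        """Fraction of non-missing tumors with wild-type allele fraction < 50%."""
        present = self._present(locus_id, self.select_samples(stratum))
        if not present:
            return float("nan")
        return sum(self.calls[(s, locus_id)].status == "biallelic" for s in present) / len(present)

    def mean_allele_ratios(self, locus_id: str, stratum: str = "all") -> np.ndarray:
        """Mean allele fraction per indel class (m4..p4) over non-missing tumors."""
        present = self._present(locus_id, self.select_samples(stratum))
        if not present:
            return np.full(9, np.nan)
        return np.mean([self.cells[(s, locus_id)].fractions for s in present], axis=0)

    def m1_frequency(
        self,
        locus_id: str,
        stratum: str = "all",
        tumor_type: str | None = None,
        mode: str = "prevalence",
    ) -> float:
        """Per-cMS frequency of M1-frame mutation.

        ``prevalence`` (default): fraction of non-missing tumors carrying a
        mutation whose dominant frame is M1.  ``ratio``: mean M1-frame
        allele mass across non-missing tumors.
        """
        present = self._present(locus_id, self.select_samples(stratum, tumor_type))
        if not present:
            return float("nan")
        if mode == "prevalence":
            return (
                sum(
                    self.calls[(s, locus_id)].is_mutant
                    and self.calls[(s, locus_id)].dominant_frame == "M1"
                    for s in present
                )
                / len(present)
            )
        if mode == "ratio":
            return float(np.mean([self.frames[(s, locus_id)].m1_fraction for s in present]))
        raise ValueError(f"unknown frequency mode {mode!r}")

    def p_mut_series(self, stratum: str = "all", tumor_type: str | None = None) -> pd.Series:
        return pd.Series(
            {l: self.p_mut(l, stratum, tumor_type) for l in self.loci}, name="p_mut"
        )

    def frame_distribution(self, stratum: str = "all") -> pd.Series:
        """Cohort-wide distribution of mutant allele mass over frames M0/M1/M2.

        Wild-type mass (Δ=0) is excluded; the three frame shares of the
        remaining (mutant) mass are normalized to sum to 1.
        """
        totals = {"M0": 0.0, "M1": 0.0, "M2": 0.0}
        samples = set(self.select_samples(stratum))
        for (s, locus_id), dist in self.cells.items():
            if s not in samples:
                continue
            for d in OFFSETS:
                if d != 0:
                    totals[frame_of(int(d))] += dist.fractions[d + 4]
        grand = sum(totals.values())
        if grand == 0:
            return pd.Series({k: 0.0 for k in totals})
        return pd.Series({k: v / grand for k, v in totals.items()})

    def summary_table(self, stratum: str = "all") -> pd.DataFrame:
        """Per-cMS summary: n, %mut, %wt<0.5, mean allele ratios m4..p4."""
        rows = []
        for locus_id in self.loci:
            present = self._present(locus_id, self.select_samples(stratum))
            ratios = self.mean_allele_ratios(locus_id, stratum)
            row = {
                "locus_id": locus_id,
                "n": len(present),
                "p_mut": self.p_mut(locus_id, stratum),
                "biallelic_fraction": self.biallelic_fraction(locus_id, stratum),
            }
            for d in OFFSETS:
                key = f"mean_{'m' if d < 0 else 'p'}{abs(d)}" if d != 0 else "mean_wt"
                row[key] = ratios[d + 4]
            rows.append(row)
        return pd.DataFrame(rows).set_index("locus_id")


def summarize_cohort(
    distributions: Iterable[AlleleDistribution],
    annotations: pd.DataFrame,
    loci: Mapping[str, CmsLocus] | Iterable[str],
    mutation_cutoff: float = 0.15,
    biallelic_cutoff: float = 0.5,
) -> CohortMatrix:
    """Assemble per-sample allele distributions into a :class:`CohortMatrix`.

    Loci with no measurable tumor at all are excluded with a warning.
    """
    locus_ids = list(loci.keys() if isinstance(loci, Mapping) else loci)
    cells: dict[tuple[str, str], AlleleDistribution] = {}
    for dist in distributions:
        cells[(dist.sample_id, dist.locus_id)] = dist
    covered = {l for (_, l) in cells}
    kept = [l for l in locus_ids if l in covered]
    dropped = [l for l in locus_ids if l not in covered]
    if dropped:
        warnings.warn(f"excluding loci with no data: {dropped}", stacklevel=2)
    if not kept:
        raise ValueError("no locus has any non-missing cell")
    return CohortMatrix(
        annotations=annotations,
        cells=cells,
        loci=kept,
        mutation_cutoff=mutation_cutoff,
        biallelic_cutoff=biallelic_cutoff,
    )


def m1_m2_binomial_test(
    cohort: CohortMatrix,
    null_p_m1: float | str = "cohort",
    n_tests: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exact binomial test for frame bias (M1 vs M2) at each cMS.

    For each locus, tumors with a frame-shifted mutation are counted by
    dominant frame and the M1 count is tested two-sided against the null
    M1 share (cohort-wide M1/(M1+M2) when ``null_p_m1="cohort"``).
    P-values are Bonferroni-adjusted over ``n_tests`` (default: number of
    testable loci).
    """
    counts: dict[str, tuple[int, int]] = {}
    for locus_id in cohort.loci:
        n_m1 = n_m2 = 0
        for s in cohort.samples:
            call = cohort.calls.get((s, locus_id))
            if call is None or not call.is_mutant:
                continue
            if call.dominant_frame == "M1":
                n_m1 += 1
            elif call.dominant_frame == "M2":
                n_m2 += 1
        if n_m1 + n_m2 > 0:
            counts[locus_id] = (n_m1, n_m2)

    if null_p_m1 == "cohort":
        tot_m1 = sum(v[0] for v in counts.values())
        tot_m2 = sum(v[1] for v in counts.values())
        if tot_m1 + tot_m2 == 0:
            raise ValueError("no frame-shifted mutant tumors in cohort")
        null_p = tot_m1 / (tot_m1 + tot_m2)
    else:
        null_p = float(null_p_m1)
    if not 0.0 < null_p < 1.0:
        raise ValueError(f"null M1 probability must be in (0, 1), got {null_p}")

    m = n_tests if n_tests is not None else len(counts)
    rows = []
    for locus_id, (n_m1, n_m2) in counts.items():
        p_raw = stats.binomtest(n_m1, n_m1 + n_m2, null_p, alternative="two-sided").pvalue
        p_adj = min(1.0, p_raw * m)
        rows.append(
            {
                "locus_id": locus_id,
                "n_m1": n_m1,
                "n_m2": n_m2,
                "null_p_m1": null_p,
                "p_value": p_raw,
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")
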