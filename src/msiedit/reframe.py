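"""Regression-based deconvolution of PCR stutter at coding microsatellites.

PCR amplification of a mononucleotide repeat produces, besides the band of
the template allele, a ladder of "stutter" fragments one or more repeat
units shorter (rarely longer) than the template.  In mismatch-repair
deficient tumors true somatic indels produce the same kind of side bands,
so an observed fragment-length profile is a mixture of allele signal and
amplification artifact.  This module separates the two: a stutter model is
calibrated on MMR-proficient control samples, turned into a per-locus
linear operator mapping true allele fractions to observed band fractions,
and inverted by bounded least squares.

All offsets are measured in base pairs relative to the wild-type fragment
length and live on the fixed window ``Δ ∈ [-4, +4]`` (index 0 ↔ Δ=-4).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

#: offset window: deletions of up to 4 bp to insertions of up to 4 bp
OFFSETS: np.ndarray = np.arange(-4, 5)
N_OFFSETS: int = 9
#: index of Δ = 0 (the wild-type band) in the offset window
WT_INDEX: int = 4

_FRAME_OF_MOD = {0: "M0", 2: "M1", 1: "M2"}


def offset_index(delta: int) -> int:
    """Array index of offset ``delta`` within the [-4, +4] window."""
    if not -4 <= delta <= 4:
        raise ValueError(f"offset {delta} outside window [-4, +4]")
    return delta + 4


def frame_of(delta: int) -> str:
    """Reading frame produced by an indel of ``delta`` bases.

    In-frame changes (Δ ≡ 0 mod 3) keep frame M0; 1-bp deletions and 2-bp
    insertions (Δ ≡ 2 mod 3) shift to M1; 2-bp deletions and 1-bp
    insertions (Δ ≡ 1 mod 3) shift to M2.
    """
    return _FRAME_OF_MOD[delta % 3]


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CmsLocus:
    """A coding mononucleotide microsatellite (cMS).

    Parameters
    ----------
    locus_id : str
        Unique identifier, conventionally the gene symbol.
    gene : str
        Gene the repeat lies in.
    repeat_base : str
        The repeated nucleotide, one of A/C/G/T.
    repeat_length : int
        Number of repeated bases in the reference (the length ``L`` the
        stutter model is parameterized by).
    wt_fragment_length : int
        Fragment length (bp) of the unmutated amplicon; observed fragment
        lengths are converted to offsets relative to this.
    cds_offset : int, optional
        0-based start of the repeat within the coding sequence.
    """

    locus_id: str
    gene: str
    repeat_base: str
    repeat_length: int
    wt_fragment_length: int
    cds_offset: int | None = None

    def __post_init__(self) -> None:
        if self.repeat_base not in "ACGT":
            raise ValueError(f"repeat_base must be one of A/C/G/T, got {self.repeat_base!r}")
        if self.repeat_length < 1:
            raise ValueError("repeat_length must be >= 1")
        if self.wt_fragment_length <= 0:
            raise ValueError("wt_fragment_length must be positive")


@dataclass
class PeakProfile:
    """Raw fragment-length peak heights for one sample at one locus.

    ``heights`` is the 9-vector over offsets -4..+4; entries are
    non-negative signal intensities (arbitrary units).
    """

    sample_id: str
    locus_id: str
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.shape != (N_OFFSETS,):
            raise ValueError("heights must be a 9-vector over offsets -4..+4")
        if np.any(self.heights < 0):
            raise ValueError("peak heights must be non-negative")

    @property
    def total(self) -> float:
        return float(self.heights.sum())

    def normalized(self) -> np.ndarray:
        """Heights rescaled to a probability vector (sums to 1)."""
        if self.total <= 0:
            raise ValueError(
                f"profile {self.sample_id}/{self.locus_id} has zero total signal"
            )
        return self.heights / self.total


@dataclass
class StutterModel:
    """Length-dependent stutter behaviour calibrated on control samples.

    The fraction of signal remaining in the main band decays with repeat
    length ``L`` and is modelled by the 2-parameter logistic

        p(L) = 1 / (1 + exp(a * (L - b))),   a > 0,

    so longer repeats stutter more.  ``reference_stutter`` holds, per
    locus, the mean normalized control band profile p_ref(δ) over
    δ ∈ [-4, +4] (δ = 0 is the control main-band fraction).
    """

    slope: float
    midpoint: float
    reference_stutter: dict[str, np.ndarray]
    n_controls: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("logistic slope must be positive (p(L) decreasing)")

    def main_fraction(self, length: float) -> float:
        """Expected main-band fraction p(L) at repeat length ``length``."""
        return float(1.0 / (1.0 + math.exp(self.slope * (length - self.midpoint))))

    def inverse(self, p: float) -> float:
        """Repeat length at which the fitted main-band fraction equals ``p``."""
        if not 0.0 < p < 1.0:
            raise ValueError("main-band fraction must be in (0, 1) to invert")
        return float(self.midpoint + math.log(1.0 / p - 1.0) / self.slope)

    def p_ref(self, locus_id: str) -> np.ndarray:
        try:
            return self.reference_stutter[locus_id]
        except KeyError:
            raise KeyError(f"no reference stutter profile for locus {locus_id!r}") from None


@dataclass
class ContributionMatrix:
    """The 9×9 stutter operator C for one locus.

    ``entries[i, j]`` is the fraction of the signal of a true allele at
    offset Δ = j-4 that is observed at offset Δ' = i-4.  Columns sum to 1
    (signal conservation); entries with \\|Δ'-Δ\\| ≥ 5 are zero.
    """

    locus_id: str
    entries: np.ndarray
    effective_length: float

    def forward(self, true_fractions: np.ndarray) -> np.ndarray:
        """Expected observed band fractions for true allele fractions."""
        return self.entries @ np.asarray(true_fractions, dtype=float)


@dataclass
class AlleleDistribution:
    """Deconvolved true allele fractions at one locus in one sample."""

    sample_id: str
    locus_id: str
    fractions: np.ndarray
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (N_OFFSETS,):
            raise ValueError("fractions must be a 9-vector over offsets -4..+4")

    @property
    def wt_fraction(self) -> float:
        return float(self.fractions[WT_INDEX])

    @property
    def mutant_fraction(self) -> float:
        return 1.0 - self.wt_fraction

    def fraction(self, delta: int) -> float:
        return float(self.fractions[offset_index(delta)])


@dataclass
class FrameSummary:
    """Allele mass pooled by resulting reading frame."""

    m0_fraction: float
    m1_fraction: float
    m2_fraction: float
    indel_fractions: np.ndarray

    @property
    def total(self) -> float:
        return self.m0_fraction + self.m1_fraction + self.m2_fraction


@dataclass
class MutationCall:
    """Mutation status of one tumor at one cMS."""

    status: str  # wildtype | mutant | biallelic
    mutant_fraction: float
    dominant_frame: str  # M1 | M2 | none

    @property
    def is_mutant(self) -> bool:
        return self.status in ("mutant", "biallelic")


# ---------------------------------------------------------------------------
# I/O: locus catalog and peak tables
# ---------------------------------------------------------------------------

LOCUS_COLUMNS = ["locus_id", "gene", "repeat_base", "repeat_length", "wt_fragment_length", "cds_offset"]
PEAK_COLUMNS = ["sample_id", "locus_id", "fragment_length", "height"]


def read_locus_catalog(path: str | Path) -> dict[str, CmsLocus]:
    """Read a tab-separated locus catalog into a mapping locus_id → CmsLocus."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(LOCUS_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"locus catalog missing columns: {sorted(missing)}")
    loci: dict[str, CmsLocus] = {}
    for row in df.itertuples(index=False):
        off = getattr(row, "cds_offset", None)
        if off is not None and pd.isna(off):
            off = None
        loci[str(row.locus_id)] = CmsLocus(
            locus_id=str(row.locus_id),
            gene=str(row.gene),
            repeat_base=str(row.repeat_base),
            repeat_length=int(row.repeat_length),
            wt_fragment_length=int(row.wt_fragment_length),
            cds_offset=None if off is None else int(off),
        )
    return loci


def write_locus_catalog(loci: Iterable[CmsLocus], path: str | Path) -> None:
    rows = [
        {
            "locus_id": l.locus_id,
            "gene": l.gene,
            "repeat_base": l.repeat_base,
            "repeat_length": l.repeat_length,
            "wt_fragment_length": l.wt_fragment_length,
            "cds_offset": "" if l.cds_offset is None else l.cds_offset,
        }
        for l in loci
    ]
    pd.DataFrame(rows, columns=LOCUS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peak_profiles(
    path: str | Path,
    loci: Mapping[str, CmsLocus],
    noise_floor: float = 0.01,
) -> list[PeakProfile]:
    """Read a peak table (TSV: sample_id, locus_id, fragment_length, height).

    Fragment lengths are converted to offsets relative to the locus
    wt_fragment_length; rows falling outside the [-4, +4] window are
    dropped with a warning.  Heights below ``noise_floor`` × (profile
    maximum) are zeroed to suppress baseline noise.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"peak table {path} is empty")
    if (df["height"] < 0).any():
        bad = df.loc[df["height"] < 0].iloc[0]
        raise ValueError(
            f"negative peak height for {bad.sample_id}/{bad.locus_id}"
        )
    unknown = set(df["locus_id"].astype(str)) - set(loci)
    if unknown:
        raise KeyError(f"peak table references unknown loci: {sorted(unknown)}")

    profiles: list[PeakProfile] = []
    for (sample_id, locus_id), grp in df.groupby(["sample_id", "locus_id"], sort=True):
        locus = loci[str(locus_id)]
        heights = np.zeros(N_OFFSETS)
        for row in grp.itertuples(index=False):
            delta = int(row.fragment_length) - locus.wt_fragment_length
            if not -4 <= delta <= 4:
                warnings.warn(
                    f"dropping band at offset {delta:+d} (length {row.fragment_length}) "
                    f"for {sample_id}/{locus_id}: outside [-4, +4] window",
                    stacklevel=2,
                )
                continue
            heights[delta + 4] += float(row.height)
        if heights.max() > 0 and noise_floor > 0:
            heights[heights < noise_floor * heights.max()] = 0.0
        profiles.append(PeakProfile(str(sample_id), str(locus_id), heights))
    return profiles


def write_allele_table(
    records: Iterable[tuple[AlleleDistribution, FrameSummary, MutationCall]],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write deconvolution results as a TSV allele table."""
    rows = []
    for dist, frames, call in records:
        row = {"sample_id": dist.sample_id, "locus_id": dist.locus_id}
        for d in OFFSETS:
            key = f"fraction_{'m' if d < 0 else 'p'}{abs(d)}" if d != 0 else "fraction_wt"
            row[key] = dist.fractions[d + 4]
        row.update(
            m0=frames.m0_fraction,
            m1=frames.m1_fraction,
            m2=frames.m2_fraction,
            status=call.status,
            dominant_frame=call.dominant_frame,
            residual_norm=dist.residual_norm,
        )
        rows.append(row)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# stutter model calibration
# ---------------------------------------------------------------------------


def fit_stutter_model(
    control_profiles: Iterable[PeakProfile],
    loci: Mapping[str, CmsLocus],
) -> StutterModel:
    """Calibrate the stutter model on MMR-proficient control profiles.

    The logistic main-band curve p(L) is fitted by unweighted least
    squares to the (repeat length, main-band fraction) points of every
    control profile.  Per-locus reference stutter p_ref(δ) is the mean
    normalized control profile, renormalized to sum to 1 over the window.
    """
    by_locus: dict[str, list[np.ndarray]] = {}
    for prof in control_profiles:
        if prof.locus_id not in loci:
            raise KeyError(f"control profile references unknown locus {prof.locus_id!r}")
        if prof.total <= 0:
            raise ValueError(f"control profile {prof.sample_id}/{prof.locus_id} has zero signal")
        by_locus.setdefault(prof.locus_id, []).append(prof.normalized())
    if not by_locus:
        raise ValueError("no control profiles supplied")

    lengths = []
    main_fracs = []
    for locus_id, norms in by_locus.items():
        L = loci[locus_id].repeat_length
        for v in norms:
            lengths.append(L)
            main_fracs.append(v[WT_INDEX])
    if len(set(lengths)) < 2:
        raise ValueError("cannot fit logistic: all control loci share one repeat length")

    x = np.asarray(lengths, dtype=float)
    y = np.asarray(main_fracs, dtype=float)

    def logistic(L, a, b):
        return 1.0 / (1.0 + np.exp(np.clip(a * (L - b), -500, 500)))

    # start from a gentle decay centred mid-range; a bounded below to keep
    # p(L) strictly decreasing
    p0 = (0.3, float(np.median(x)))
    popt, _ = optimize.curve_fit(
        logistic, x, y, p0=p0, bounds=([1e-6, -1000.0], [10.0, 1000.0]), maxfev=20000
    )
    a, b = float(popt[0]), float(popt[1])

    reference: dict[str, np.ndarray] = {}
    n_controls = 0
    for locus_id, norms in by_locus.items():
        n_controls = max(n_controls, len(norms))
        mean = np.mean(norms, axis=0)
        mean = np.clip(mean, 0.0, None)
        reference[locus_id] = mean / mean.sum()

    return StutterModel(slope=a, midpoint=b, reference_stutter=reference, n_controls=n_controls)


# ---------------------------------------------------------------------------
# contribution matrix and deconvolution
# ---------------------------------------------------------------------------

_P_EPS = 1e-9  # clamp for p_effective outside (0, 1)


def build_contribution_matrix(
    locus: CmsLocus,
    model: StutterModel,
    p_ref: np.ndarray | None = None,
) -> ContributionMatrix:
    """Construct the stutter operator C for ``locus`` from a fitted model.

    Each locus is anchored to its observed control behaviour: the
    effective length L_eff solves p(L_eff) = p_ref(0), so an allele with
    indel Δ behaves like a repeat of length L_eff + Δ and keeps the
    fraction p_effective(Δ) = p(L_eff + Δ) of its signal in its own band.
    The remaining 1 - p_effective is spread over neighbouring bands in
    proportion to the control stutter shape p_ref(δ)/(1 - p_ref(0)),
    truncated at \\|δ\\| ≤ 4; columns truncated by the window edge are
    renormalized to sum to 1.

    If the controls show no stutter at all (p_ref(0) = 1) the operator
    degenerates to the identity.
    """
    ref = model.p_ref(locus.locus_id) if p_ref is None else np.asarray(p_ref, dtype=float)
    if ref.shape != (N_OFFSETS,):
        raise ValueError("p_ref must be a 9-vector over offsets -4..+4")
    p0 = float(ref[WT_INDEX])
    if p0 <= 0:
        raise ValueError(f"control main-band fraction is zero for {locus.locus_id}")

    if p0 >= 1.0 - 1e-12:
        return ContributionMatrix(
            locus_id=locus.locus_id,
            entries=np.eye(N_OFFSETS),
            effective_length=float(locus.repeat_length),
        )

    l_eff = model.inverse(p0)
    C = np.zeros((N_OFFSETS, N_OFFSETS))
    clamped = False
    for j, delta in enumerate(OFFSETS):  # true allele offset
        p_eff = model.main_fraction(l_eff + delta)
        if not _P_EPS < p_eff < 1.0 - _P_EPS:
            p_eff = float(np.clip(p_eff, _P_EPS, 1.0 - _P_EPS))
            clamped = True
        scale = (1.0 - p_eff) / (1.0 - p0)
        for i, delta_obs in enumerate(OFFSETS):  # observed band offset
            d = delta_obs - delta
            if d == 0:
                C[i, j] = p_eff
            elif abs(d) < 5 and -4 <= d <= 4:
                C[i, j] = ref[d + 4] * scale
        C[:, j] /= C[:, j].sum()
    if clamped:
        warnings.warn(
            f"p_effective clamped into (0, 1) for locus {locus.locus_id}", stacklevel=2
        )
    return ContributionMatrix(locus_id=locus.locus_id, entries=C, effective_length=l_eff)


def deconvolve(profile: PeakProfile, matrix: ContributionMatrix) -> AlleleDistribution:
    """Recover true allele fractions from an observed peak profile.

    Solves ``argmin ‖C p − p_obs‖₂ subject to 0 ≤ p ≤ 1`` (active-set
    non-negative least squares; the upper bound is enforced by clipping,
    with a bounded-variable fallback in the rare case it binds), then
    renormalizes the solution onto the simplex.  Deterministic.
    """
    if profile.locus_id != matrix.locus_id:
        raise ValueError(
            f"locus mismatch: profile {profile.locus_id!r} vs matrix {matrix.locus_id!r}"
        )
    p_obs = profile.normalized()
    sol, _ = optimize.nnls(matrix.entries, p_obs)
    if sol.max() > 1.0:
        res = optimize.lsq_linear(matrix.entries, p_obs, bounds=(0.0, 1.0), method="bvls")
        sol = res.x
    residual = float(np.linalg.norm(matrix.entries @ sol - p_obs))
    total = sol.sum()
    if total <= 0:
        raise ValueError("deconvolution produced an all-zero solution")
    return AlleleDistribution(
        sample_id=profile.sample_id,
        locus_id=profile.locus_id,
        fractions=sol / total,
        residual_norm=residual,
    )


# ---------------------------------------------------------------------------
# frame classification and mutation calls
# ---------------------------------------------------------------------------


def classify_frames(dist: AlleleDistribution) -> FrameSummary:
    """Pool allele mass by the reading frame each indel produces."""
    sums = {"M0": 0.0, "M1": 0.0, "M2": 0.0}
    for delta in OFFSETS:
        sums[frame_of(int(delta))] += dist.fractions[delta + 4]
    return FrameSummary(
        m0_fraction=sums["M0"],
        m1_fraction=sums["M1"],
        m2_fraction=sums["M2"],
        indel_fractions=dist.fractions.copy(),
    )


def call_mutation_status(
    dist: AlleleDistribution,
    mutation_cutoff: float = 0.15,
    biallelic_cutoff: float = 0.5,
    tie_break: str = "M1",
) -> MutationCall:
    """Call a tumor wildtype / mutant / biallelic at one cMS.

    A sample is mutant when at least ``mutation_cutoff`` (default 15%) of
    allele mass is non-wild-type, and biallelic when the wild-type
    fraction falls below ``biallelic_cutoff`` (default 50%, i.e. >50%
    mutated — both copies hit).  The dominant frame is the frameshift
    frame (M1 or M2) carrying more mutant mass; ties go to ``tie_break``.
    """
    for name, c in (("mutation_cutoff", mutation_cutoff), ("biallelic_cutoff", biallelic_cutoff)):
        if not 0.0 < c < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {c}")
    mutant_fraction = dist.mutant_fraction
    if mutant_fraction < mutation_cutoff:
        status = "wildtype"
    elif dist.wt_fraction < biallelic_cutoff:
        status = "biallelic"
    else:
        status = "mutant"

    m1_mass = sum(dist.fractions[d + 4] for d in OFFSETS if d != 0 and frame_of(int(d)) == "M1")
    m2_mass = sum(dist.fractions[d + 4] for d in OFFSETS if d != 0 and frame_of(int(d)) == "M2")
    if status == "wildtype" or (m1_mass == 0.0 and m2_mass == 0.0):
        dominant = "none"
    elif m1_mass > m2_mass:
        dominant = "M1"
    elif m2_mass > m1_mass:
        dominant = "M2"
    else:
        dominant = tie_break
    return MutationCall(status=status, mutant_fraction=mutant_fraction, dominant_frame=dominant)


def classify_msi_status(
    marker_results: Mapping[str, str],
    threshold: float = 0.30,
) -> str:
    """Classify a tumor MSI vs MSS from a marker instability panel.

    A tumor is MSI when strictly more than ``threshold`` (default 30%) of
    scored markers are unstable.
    """
    if not marker_results:
        raise ValueError("no markers scored")
    unstable = sum(1 for v in marker_results.values() if v == "unstable")
    return "MSI" if unstable / len(marker_results) > threshold else "MSS"
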