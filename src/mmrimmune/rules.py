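"""Threshold rules assigning molecular status to endometrial tumors.

These are the laboratory decision rules of the study design: a
five-mononucleotide-locus microsatellite instability (MSI) call, an MLH1
promoter methylation call from pyrosequencing triplicates, a four-protein
mismatch-repair (MMR) immunohistochemistry call, PD-L1 positivity on tumor
and immune cells, and the combination of these into the three molecular
cohorts (Lynch-associated MMR-deficient, sporadic MMR-deficient via MLH1
hypermethylation, and MMR-proficient).

All thresholds are strict ("greater than") per the printed wording, and every
rule is a pure function of already-interpreted inputs — no signal processing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

from .records import CohortLabel, Pdl1Pattern

MONONUCLEOTIDE_LOCI = ("BAT-25", "BAT-26", "NR-21", "NR-24", "MONO-27")
MMR_PROTEINS = ("MLH1", "MSH2", "MSH6", "PMS2")


class LocusStatus(str, enum.Enum):
    MATCH = "MATCH"          # tumor allele sizes match normal tissue
    DISCREPANT = "DISCREPANT"


class MsiStatus(str, enum.Enum):
    MSS = "MSS"
    MSI = "MSI"
    INDETERMINATE = "INDETERMINATE"


class MethylationStatus(str, enum.Enum):
    METHYLATED = "METHYLATED"
    UNMETHYLATED = "UNMETHYLATED"


class MmrStatus(str, enum.Enum):
    PROFICIENT = "PROFICIENT"
    DEFICIENT = "DEFICIENT"


class Pdl1Call(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


class CohortAssignment(str, enum.Enum):
    LS_MMRD = CohortLabel.LS_MMRD.value
    SPORADIC_MMRD = CohortLabel.SPORADIC_MMRD.value
    MMRP = CohortLabel.MMRP.value
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class MsiPanelResult:
    """Per-locus concordance between tumor and matched normal tissue for the
    five mononucleotide repeats of the Promega panel."""

    locus_status: Mapping[str, LocusStatus]

    def __post_init__(self) -> None:
        if set(self.locus_status) != set(MONONUCLEOTIDE_LOCI):
            raise ValueError(
                f"panel must cover exactly the loci {MONONUCLEOTIDE_LOCI}, "
                f"got {sorted(self.locus_status)}"
            )

    @property
    def n_discrepant(self) -> int:
        return sum(
            1 for s in self.locus_status.values() if LocusStatus(s) is LocusStatus.DISCREPANT
        )


@dataclass(frozen=True)
class MethylationRun:
    """Pyrosequencing methylation percentages, one list of per-cytosine
    values per replicate (triplicates in routine use)."""

    replicate_methylation: Sequence[Sequence[float]]

    def __post_init__(self) -> None:
        if len(self.replicate_methylation) == 0:
            raise ValueError("methylation run needs at least one replicate")
        widths = {len(r) for r in self.replicate_methylation}
        if len(widths) != 1 or 0 in widths:
            raise ValueError("replicates must share a common, non-zero cytosine count")
        for rep in self.replicate_methylation:
            for v in rep:
                if not 0 <= v <= 100:
                    raise ValueError(f"methylation percent {v} outside [0, 100]")


@dataclass(frozen=True)
class MmrIhcResult:
    """Fraction of tumor expressing each of the four MMR proteins."""

    expression_fraction: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.expression_fraction) != set(MMR_PROTEINS):
            raise ValueError(f"IHC result must cover exactly {MMR_PROTEINS}")
        for protein, frac in self.expression_fraction.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"{protein} expression fraction {frac} outside [0, 1]")

    def lost_proteins(self, threshold: float = 0.8) -> frozenset[str]:
        return frozenset(p for p, f in self.expression_fraction.items() if f <= threshold)


def call_msi(panel: MsiPanelResult, two_or_more_is_msi: bool = False) -> MsiStatus:
    """MSI status from the 5-locus mononucleotide panel.

    Text-literal rule: matching sizes at >=4 loci -> MSS; discrepancy at
    more than two loci -> MSI; exactly two discrepant loci satisfies neither
    printed condition and returns INDETERMINATE. Set ``two_or_more_is_msi``
    to use the common criterion calling >=2 discrepant loci MSI instead.
    """
    d = panel.n_discrepant
    if two_or_more_is_msi and d >= 2:
        return MsiStatus.MSI
    if 5 - d >= 4:
        return MsiStatus.MSS
    if d > 2:
        return MsiStatus.MSI
    return MsiStatus.INDETERMINATE


def call_mlh1_methylation(
    run: MethylationRun,
    pct_threshold: float = 10.0,
    replicate_fraction: Fraction = Fraction(2, 3),
) -> MethylationStatus:
    """MLH1 promoter methylation call.

    A replicate passes when *every* cytosine is strictly above
    ``pct_threshold`` percent; the run is METHYLATED when the passing
    fraction strictly exceeds ``replicate_fraction``. The printed ">66% of
    the triplicates" is read as the exact fraction 2/3, so 2 of 3 passing
    replicates does not qualify.
    """
    reps = run.replicate_methylation
    passing = sum(1 for rep in reps if all(v > pct_threshold for v in rep))
    if Fraction(passing, len(reps)) > Fraction(replicate_fraction):
        return MethylationStatus.METHYLATED
    return MethylationStatus.UNMETHYLATED


def call_mmr_ihc(ihc: MmrIhcResult, threshold: float = 0.8) -> MmrStatus:
    """MMR proficient iff every one of the four proteins is expressed in
    strictly more than ``threshold`` of the tumor."""
    if all(f > threshold for f in ihc.expression_fraction.values()):
        return MmrStatus.PROFICIENT
    return MmrStatus.DEFICIENT


def call_pdl1_tumor(
    pct_by_intensity: Mapping[int, float], pct_threshold: float = 5.0
) -> Pdl1Call:
    """Tumor PD-L1 positivity: strictly more than ``pct_threshold`` percent of
    tumor cells staining at moderate (2+) or strong (3+) intensity."""
    at_least_2plus = pct_by_intensity.get(2, 0.0) + pct_by_intensity.get(3, 0.0)
    return Pdl1Call.POSITIVE if at_least_2plus > pct_threshold else Pdl1Call.NEGATIVE


def call_pdl1_immune(pattern: Pdl1Pattern) -> Pdl1Call:
    """Immune-cell PD-L1: focal or diffuse staining is positive."""
    pattern = Pdl1Pattern(pattern)
    if pattern in (Pdl1Pattern.FOCAL, Pdl1Pattern.DIFFUSE):
        return Pdl1Call.POSITIVE
    return Pdl1Call.NEGATIVE


def assign_cohort(
    msi: MsiStatus,
    ihc: MmrStatus,
    lost_proteins: frozenset[str] | set[str] = frozenset(),
    mlh1_methylated: Optional[bool] = None,
    germline_ls: bool = False,
) -> CohortAssignment:
    """Molecular cohort from the study's triage flow.

    Germline-proven Lynch syndrome defines the LS cohort outright. MSI
    tumors with MLH1/PMS2 loss and MLH1 promoter hypermethylation are
    sporadic MMR-deficient. MSS tumors expressing all four MMR proteins are
    MMR-proficient. Any other evidence pattern is UNRESOLVED — the rule
    never guesses.
    """
    if germline_ls:
        return CohortAssignment.LS_MMRD
    msi = MsiStatus(msi)
    ihc = MmrStatus(ihc)
    if (
        msi is MsiStatus.MSI
        and ihc is MmrStatus.DEFICIENT
        and ({"MLH1", "PMS2"} & set(lost_proteins))
        and mlh1_methylated is True
    ):
        return CohortAssignment.SPORADIC_MMRD
    if msi is MsiStatus.MSS and ihc is MmrStatus.PROFICIENT:
        return CohortAssignment.MMRP
    return CohortAssignment.UNRESOLVED
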