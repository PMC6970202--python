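"""Apply the molecular triage rules that define the study cohorts.

MSI from the 5-mononucleotide-locus panel, MLH1 promoter methylation from
pyrosequencing triplicates, MMR protein immunohistochemistry, and their
combination into a cohort assignment.
"""

from mmrimmune.rules import (
    MONONUCLEOTIDE_LOCI,
    LocusStatus,
    MethylationRun,
    MmrIhcResult,
    MsiPanelResult,
    assign_cohort,
    call_mlh1_methylation,
    call_mmr_ihc,
    call_msi,
)

panel = MsiPanelResult(
    {
        locus: LocusStatus.DISCREPANT if i < 4 else LocusStatus.MATCH
        for i, locus in enumerate(MONONUCLEOTIDE_LOCI)
    }
)
msi = call_msi(panel)
print(f"4 of 5 loci discrepant -> {msi.value}")

ihc = MmrIhcResult({"MLH1": 0.05, "PMS2": 0.10, "MSH2": 0.95, "MSH6": 0.95})
mmr = call_mmr_ihc(ihc)
print(f"MLH1/PMS2 lost on IHC -> {mmr.value} (lost: {sorted(ihc.lost_proteins())})")

run = MethylationRun([[42.0, 38.0, 51.0]] * 3)
methylation = call_mlh1_methylation(run)
print(f"all cytosines >10% in 3/3 replicates -> {methylation.value}")

cohort = assign_cohort(msi, mmr, lost_proteins=ihc.lost_proteins(),
                       mlh1_methylated=True, germline_ls=False)
print(f"\ncombined evidence -> {cohort.value}")
print("(MSI + MLH1 loss + promoter hypermethylation, no germline variant:")
print(" the tumor's MMR deficiency is sporadic, not Lynch syndrome.)")
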