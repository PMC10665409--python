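"""Phase transmitted gametes and score per-meiosis recombination phenotypes.

Runs the full QC + phasing stack (Mendel check, segregation-distortion
filter, greedy minimum-recombination orientation chains) on an error-free
simulation, then compares the detected crossover counts against the
simulator's truth table.
"""
import meiokit as mk
from meiokit.simulate import FamilyDesign

genome, panel, landscape, trait, _ = mk.desk_preset()
res = mk.simulate_population(
    genome, panel, landscape, trait, FamilyDesign(6, 6, 20),
    error_rate=0.0, missing_rate=0.0, seed=11,
)

vectors = mk.phase_population(res.pedigree, res.genotypes, min_offspring=4)
print(f"phased gametes: {len(vectors)}")

pheno, summary = mk.phenotype_table(vectors, genome, panel, min_support=1)
print("\nper-sex summary (detected):")
print(summary.round(4).to_string(index=False))

merged = pheno.merge(
    res.truth[["fid", "offspring", "parent_sex", "cc", "rbar"]],
    on=["fid", "offspring", "parent_sex"], suffixes=("", "_true"),
)
exact = (merged.cc == merged.cc_true).mean()
print(f"\nmeioses with detected CC exactly equal to truth: {exact:.1%}")
print(
    "Residual differences come from crossovers outside the informative-marker\n"
    "span of a gamete (mostly in the male sub-telomeric hotspot) — a marker-\n"
    "coverage limit, not a phasing error."
)
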