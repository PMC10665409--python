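"""Repeatability animal model and weighted LOCO GWAS on simulated phenotypes.

Simulates FID-level polygenic variation in crossover rate, fits the
GRM-based repeatability model by AI-REML (heritability, repeatability,
inbreeding regression), and runs the weighted leave-one-chromosome-out
mixed-model association on the FID means.
"""
import numpy as np
import pandas as pd

import meiokit as mk

rng = np.random.default_rng(7)
q, nrep, m = 400, 10, 900
dos = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(q, m)).astype(np.int8)
ids = [f"F{i}" for i in range(q)]
grm = mk.vanraden_grm(dos, ids=ids)

# phenotypes from the repeatability model: Va=0.3, Vpe=0.1, Ve=0.6
L = np.linalg.cholesky(grm.matrix + 1e-4 * np.eye(q))
a = L @ rng.normal(0, np.sqrt(0.3), q)
pe = rng.normal(0, np.sqrt(0.1), q)
y = np.repeat(a + pe, nrep) + rng.normal(0, np.sqrt(0.6), q * nrep)
obs = pd.DataFrame({"fid": np.repeat(ids, nrep), "value": y})

vc = mk.fit_repeatability(obs, grm)
print(
    f"AI-REML: Va={vc.v_a:.3f} (SE {vc.se_a:.3f})  Vpe={vc.v_pe:.3f}  "
    f"Ve={vc.v_e:.3f}\n         h2={vc.h2:.3f} (SE {vc.h2_se:.3f})  "
    f"repeatability={vc.repeatability:.3f}  converged={vc.converged}"
)
print("truth:   Va=0.300 Vpe=0.100 Ve=0.600  h2=0.300  t=0.400")

# GWAS on the FID means, weighted by observation count
genome = mk.GenomeSpec(
    tuple(mk.Chromosome(f"c{i}", 40_000_000, 0) for i in range(5))
)
chroms = sum([[f"c{i}"] * (m // 5) for i in range(5)], [])
pos = sum([list(range(200_000, 200_000 * (m // 5 + 1), 200_000)) for _ in range(5)], [])
panel = mk.MarkerPanel(tuple(f"s{j}" for j in range(m)), tuple(chroms), tuple(pos))
geno = mk.GenotypeMatrix(ids, panel, dos)

means = mk.collapse_and_weight(obs, h2=vc.h2, t=vc.repeatability)
res = mk.mlma_loco(means, geno, genome)
print(
    f"\nGWAS: {len(res.table)} SNPs tested, Bonferroni threshold "
    f"{res.threshold:.2e}, significant hits: {int(res.table.significant.sum())}"
)
print(
    "A purely polygenic trait yields no genome-wide significant SNP, matching\n"
    "the absence of detectable large-effect recombination loci in this design."
)
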