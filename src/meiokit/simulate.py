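"""Forward simulator for three-generation full-sib populations.

The simulator works at the bivalent level: chiasma counts per chromosome are
Poisson with a sex-specific intensity (optionally forced to at least one,
the obligate rule), chiasma positions are i.i.d. draws from a sex-specific
piecewise-linear density over relative chromosome position, and each chiasma
is transmitted to a sampled gamete independently with probability 1/2 (two of
four chromatids, no chromatid interference).  One obligate chiasma therefore
yields an expected 0.5 crossovers per gamete — a 50 cM map — which a
gamete-level Poisson shortcut would get wrong by a factor of two.

Individual variation in crossover rate is multiplicative on the chiasma
intensity through a log-link: ``rate_i = exp(a_i + pe_i - v/2)`` where ``a_i``
is an additive polygenic value over ``n_causal`` founder-segregating SNPs,
``pe_i`` a permanent-environment deviate and ``v`` the total variance (so the
multiplier has mean one).  Effects are drawn per sex with a configurable
cross-sex correlation, giving downstream variance-component and GWAS stages
a known truth to recover.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import Chromosome, GenomeSpec, GenotypeMatrix, MarkerPanel, Pedigree
from .datasets import salmon_genome

__all__ = [
    "PiecewiseLinearDensity",
    "SexLandscape",
    "LandscapeModel",
    "TraitArchitecture",
    "FamilyDesign",
    "SimulationResult",
    "simulate_founder_haplotypes",
    "sample_chiasmata",
    "meiosis",
    "simulate_population",
    "desk_genome",
    "desk_preset",
    "salmon_preset",
    "rbar_from_breakpoints",
]


class PiecewiseLinearDensity:
    """Piecewise-linear probability density on [0, 1], sampled by inverse CDF.

    Knot x values are non-decreasing (repeat an x to make a jump); the density
    is normalized at construction.
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape or len(x) < 2:
            raise ValueError("need matching 1-d knot arrays of length >= 2")
        if np.any(np.diff(x) < 0) or x[0] != 0.0 or x[-1] != 1.0:
            raise ValueError("knot x must be non-decreasing from 0 to 1")
        if np.any(y < 0):
            raise ValueError("density values must be non-negative")
        seg_mass = np.diff(x) * (y[:-1] + y[1:]) / 2.0
        total = seg_mass.sum()
        if total <= 0:
            raise ValueError("density integrates to zero")
        self.x = x
        self.y = y / total
        self._cum = np.concatenate([[0.0], np.cumsum(seg_mass / total)])
        self._cum[-1] = 1.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        seg = np.searchsorted(self._cum, u, side="right") - 1
        seg = np.clip(seg, 0, len(self.x) - 2)
        x0, x1 = self.x[seg], self.x[seg + 1]
        y0, y1 = self.y[seg], self.y[seg + 1]
        du = u - self._cum[seg]
        w = x1 - x0
        out = np.empty(n)
        flat = np.abs(y1 - y0) * w < 1e-14
        with np.errstate(divide="ignore", invalid="ignore"):
            out[flat] = x0[flat] + np.where(
                y0[flat] > 0, du[flat] / np.maximum(y0[flat], 1e-300), 0.5 * w[flat]
            )
        q = ~flat
        slope = (y1[q] - y0[q]) / w[q]
        # solve y0*t + slope*t^2/2 = du for t in [0, w]
        disc = np.maximum(y0[q] ** 2 + 2 * slope * du[q], 0.0)
        out[q] = x0[q] + (np.sqrt(disc) - y0[q]) / slope
        return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class SexLandscape:
    """Chiasma model for one sex: genome-total intensity, per-chromosome
    weights (summing to 1) and a positional density over relative position."""

    lambda_total: float
    density: PiecewiseLinearDensity
    weights: dict[str, float] | None = None  # None -> uniform over genome
    obligate: bool = False

    def lambda_for(self, chrom_id: str, n_chromosomes: int) -> float:
        if self.weights is None:
            return self.lambda_total / n_chromosomes
        return self.lambda_total * self.weights[chrom_id]


@dataclass(frozen=True)
class LandscapeModel:
    male: SexLandscape
    female: SexLandscape

    def for_sex(self, sex: str) -> SexLandscape:
        if sex == "male":
            return self.male
        if sex == "female":
            return self.female
        raise ValueError(f"no landscape for sex {sex!r}")


@dataclass(frozen=True)
class TraitArchitecture:
    """Polygenic architecture of the individual chiasma-rate deviation."""

    sigma2_a: dict[str, float] = field(
        default_factory=lambda: {"male": 0.02, "female": 0.02}
    )
    sigma2_pe: dict[str, float] = field(
        default_factory=lambda: {"male": 0.01, "female": 0.01}
    )
    r_g_sim: float = 0.0
    n_causal: int = 200

    def __post_init__(self):
        if not -1.0 <= self.r_g_sim <= 1.0:
            raise ValueError("cross-sex genetic correlation must be in [-1, 1]")
        for d in (self.sigma2_a, self.sigma2_pe):
            if any(v < 0 for v in d.values()):
                raise ValueError("variances must be non-negative")


@dataclass(frozen=True)
class FamilyDesign:
    n_sires: int = 60
    n_dams: int = 60
    offspring_per_family: int = 20
    grandparents_genotyped: float = 0.0

    def __post_init__(self):
        if min(self.n_sires, self.n_dams, self.offspring_per_family) < 1:
            raise ValueError("design counts must be positive")

    @property
    def n_families(self) -> int:
        return max(self.n_sires, self.n_dams)


def simulate_founder_haplotypes(
    genome: GenomeSpec,
    panel: MarkerPanel,
    n_founders: int,
    maf_range: tuple[float, float] = (0.2, 0.5),
    seed: int | np.random.Generator = 0,
):
    """Draw founder haplotypes (n_founders, 2, m) and the allele frequencies
    used, with per-marker frequency uniform in ``maf_range``."""
    if len(panel) == 0:
        raise ValueError("empty marker panel")
    if n_founders < 2:
        raise ValueError("need at least two founders")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs = rng.uniform(lo, hi, size=len(panel))
    haps = (rng.random((n_founders, 2, len(panel))) < freqs).astype(np.int8)
    return haps, freqs


def sample_chiasmata(
    chrom: Chromosome,
    landscape: SexLandscape,
    rate_multiplier: float = 1.0,
    seed: int | np.random.Generator = 0,
    n_chromosomes: int = 1,
) -> np.ndarray:
    """Sample sorted chiasma positions (bp) on one bivalent."""
    if chrom.length_bp <= 0:
        raise ValueError("zero-length chromosome")
    if rate_multiplier <= 0:
        raise ValueError("rate_multiplier must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lam = landscape.lambda_for(chrom.chrom_id, n_chromosomes) * rate_multiplier
    n = rng.poisson(lam)
    if landscape.obligate:
        n = max(n, 1)
    rel = landscape.density.sample(n, rng)
    pos = np.sort(rel * chrom.length_bp)
    return pos


def meiosis(
    parent_haplopair: np.ndarray,
    chiasmata_bp: np.ndarray,
    marker_pos_bp: np.ndarray,
    seed: int | np.random.Generator = 0,
    chrom_length_bp: int | None = None,
):
    """One meiosis on one chromosome.

    Each chiasma is independently present in the sampled gamete with
    probability 1/2; present chiasmata toggle the copied parental strand at
    their position.  Returns (gamete haplotype over the markers, bp positions
    of the crossovers realized in this gamete).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chiasmata_bp = np.asarray(chiasmata_bp, dtype=float)
    if chrom_length_bp is not None and np.any(
        (chiasmata_bp < 0) | (chiasmata_bp > chrom_length_bp)
    ):
        raise ValueError("chiasma position outside chromosome")
    include = rng.random(len(chiasmata_bp)) < 0.5
    crossovers = chiasmata_bp[include]
    start = rng.integers(0, 2)
    # strand at marker = start XOR (number of crossovers left of it, mod 2)
    n_left = np.searchsorted(crossovers, marker_pos_bp, side="right")
    strand = (start + n_left) % 2
    gamete = parent_haplopair[strand, np.arange(parent_haplopair.shape[1])]
    return gamete.astype(np.int8), crossovers, int(start)


def rbar_from_breakpoints(
    breakpoints: dict[str, np.ndarray], genome: GenomeSpec
) -> float:
    """Intra-chromosomal shuffling of a gamete with known crossover positions.

    For each chromosome the origin alternates at the breakpoints; p_k is the
    physical fraction carrying one origin label and the statistic is
    sum_k 2 p_k (1 - p_k) L_k^2 with L_k the genome-length fraction.
    """
    L = genome.length_fractions()
    total = 0.0
    for chrom in genome.chromosomes:
        bps = np.sort(np.asarray(breakpoints.get(chrom.chrom_id, ()), dtype=float))
        edges = np.concatenate([[0.0], bps, [float(chrom.length_bp)]])
        seg = np.diff(edges)
        p = seg[::2].sum() / chrom.length_bp
        total += 2.0 * p * (1.0 - p) * L[chrom.chrom_id] ** 2
    return total


@dataclass
class SimulationResult:
    genome: GenomeSpec
    panel: MarkerPanel
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    truth: pd.DataFrame  # one row per meiosis
    breeding_values: pd.DataFrame  # per FID: sex, a (log-scale), pe, multiplier
    landscape: LandscapeModel
    trait: TraitArchitecture
    fid_haplotypes: dict[str, np.ndarray] | None = None  # (2, m) per FID


def _polygenic_values(
    fid_dosages: np.ndarray,
    fid_sexes: np.ndarray,
    freqs: np.ndarray,
    arch: TraitArchitecture,
    rng: np.random.Generator,
):
    """Additive values with target per-sex variance and cross-sex correlation."""
    n, m = fid_dosages.shape
    a = np.zeros(n)
    if arch.n_causal > 0 and (max(arch.sigma2_a.values()) > 0):
        causal = rng.choice(m, size=min(arch.n_causal, m), replace=False)
        r = np.clip(arch.r_g_sim, -1.0, 1.0)
        cov = np.array([[1.0, r], [r, 1.0]])
        eff = rng.multivariate_normal([0.0, 0.0], cov, size=len(causal))
        centered = fid_dosages[:, causal] - 2.0 * freqs[causal]
        raw = {"male": centered @ eff[:, 0], "female": centered @ eff[:, 1]}
        for sex in ("male", "female"):
            mask = fid_sexes == sex
            tgt = arch.sigma2_a.get(sex, 0.0)
            if mask.any() and tgt > 0:
                sd = raw[sex][mask].std()
                if sd > 0:
                    a[mask] = (raw[sex][mask] - raw[sex][mask].mean()) / sd * np.sqrt(tgt)
    pe = np.zeros(n)
    for sex in ("male", "female"):
        mask = fid_sexes == sex
        s2 = arch.sigma2_pe.get(sex, 0.0)
        if mask.any() and s2 > 0:
            pe[mask] = rng.normal(0.0, np.sqrt(s2), mask.sum())
    return a, pe


def _perturb(dosages: np.ndarray, error_rate: float, missing_rate: float, rng):
    """Symmetric allele-flip genotyping error plus random missingness."""
    out = dosages.copy()
    if error_rate > 0:
        n_a1 = np.clip(out, 0, 2)
        flips_down = rng.binomial(n_a1, error_rate)
        flips_up = rng.binomial(2 - n_a1, error_rate)
        out = (n_a1 - flips_down + flips_up).astype(np.int8)
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = -1
    return out


def simulate_population(
    genome: GenomeSpec,
    panel: MarkerPanel,
    landscape: LandscapeModel,
    trait: TraitArchitecture | None = None,
    design: FamilyDesign | None = None,
    error_rate: float = 0.001,
    missing_rate: float = 0.003,
    maf_range: tuple[float, float] = (0.2, 0.5),
    seed: int | np.random.Generator = 0,
) -> SimulationResult:
    """Simulate a three-generation full-sib population with ground truth.

    Each focal parent (FID) is itself bred from a dedicated pair of founder
    grandparents via true meioses, so grandparent anchoring can be exercised.
    Families pair sire ``f mod n_sires`` with dam ``f mod n_dams``; each
    offspring corresponds to one sire meiosis and one dam meiosis, each
    recorded in the truth table with its chiasma and gamete crossover
    positions, crossover count and shuffling statistic.
    """
    trait = trait or TraitArchitecture()
    design = design or FamilyDesign()
    if not (0 <= error_rate < 1 and 0 <= missing_rate < 1):
        raise ValueError("error_rate and missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n_chrom = len(genome.chromosomes)
    chrom_idx = {c.chrom_id: panel.indices_for(c.chrom_id) for c in genome.chromosomes}
    chrom_pos = {c.chrom_id: panel.positions_for(c.chrom_id) for c in genome.chromosomes}

    sires = [f"S{i:04d}" for i in range(design.n_sires)]
    dams = [f"D{i:04d}" for i in range(design.n_dams)]
    fids = sires + dams
    fid_sexes = np.array(["male"] * design.n_sires + ["female"] * design.n_dams)

    # founder grandparents: one dedicated pair per FID
    n_founders = 2 * len(fids)
    founder_haps, freqs = simulate_founder_haplotypes(
        genome, panel, n_founders, maf_range, rng
    )

    def gamete_from(haps: np.ndarray, sex: str, mult: float):
        """Full-genome meiosis; returns gamete haplotype + per-chrom crossovers."""
        land = landscape.for_sex(sex)
        gam = np.empty(len(panel), dtype=np.int8)
        xovers: dict[str, np.ndarray] = {}
        chias: dict[str, np.ndarray] = {}
        starts: dict[str, int] = {}
        for c in genome.chromosomes:
            idx = chrom_idx[c.chrom_id]
            ch = sample_chiasmata(c, land, mult, rng, n_chromosomes=n_chrom)
            g, xo, start = meiosis(
                haps[:, idx], ch, chrom_pos[c.chrom_id], rng, c.length_bp
            )
            gam[idx] = g
            xovers[c.chrom_id] = xo
            chias[c.chrom_id] = ch
            starts[c.chrom_id] = start
        return gam, xovers, chias, starts

    # breed each FID from its two grandparent founders (baseline rate)
    fid_haps = np.empty((len(fids), 2, len(panel)), dtype=np.int8)
    gp_rows = []
    gp_genos = []
    for i, fid in enumerate(fids):
        gsire, gdam = founder_haps[2 * i], founder_haps[2 * i + 1]
        sex = fid_sexes[i]
        h1, _, _, _ = gamete_from(gsire, "male", 1.0)
        h2, _, _, _ = gamete_from(gdam, "female", 1.0)
        fid_haps[i, 0] = h1
        fid_haps[i, 1] = h2
        if rng.random() < design.grandparents_genotyped:
            gp_rows.append((f"GS_{fid}", None, None, "male"))
            gp_rows.append((f"GD_{fid}", None, None, "female"))
            gp_genos.append(gsire.sum(axis=0).astype(np.int8))
            gp_genos.append(gdam.sum(axis=0).astype(np.int8))

    fid_dosages = fid_haps.sum(axis=1).astype(np.int8)
    a_vals, pe_vals = _polygenic_values(fid_dosages, fid_sexes, freqs, trait, rng)
    v_tot = np.array(
        [
            trait.sigma2_a.get(s, 0.0) + trait.sigma2_pe.get(s, 0.0)
            for s in fid_sexes
        ]
    )
    multipliers = np.exp(a_vals + pe_vals - v_tot / 2.0)

    ped_rows = list(gp_rows)
    geno_ids = [r[0] for r in gp_rows]
    geno_rows = list(gp_genos)
    gp_ids = {r[0] for r in gp_rows}
    for i, fid in enumerate(fids):
        gs, gd = f"GS_{fid}", f"GD_{fid}"
        ped_rows.append(
            (fid, gs if gs in gp_ids else None, gd if gd in gp_ids else None, fid_sexes[i])
        )
        geno_ids.append(fid)
        geno_rows.append(fid_dosages[i])

    mult_of = dict(zip(fids, multipliers))
    hap_of = {fid: fid_haps[i] for i, fid in enumerate(fids)}

    truth_rows = []
    for f in range(design.n_families):
        sire = sires[f % design.n_sires]
        dam = dams[f % design.n_dams]
        for k in range(design.offspring_per_family):
            off = f"O{f:04d}_{k:03d}"
            dosage = np.zeros(len(panel), dtype=np.int8)
            for parent, psex in ((sire, "male"), (dam, "female")):
                gam, xovers, chias, starts = gamete_from(
                    hap_of[parent], psex, mult_of[parent]
                )
                dosage += gam
                cc = int(sum(len(v) for v in xovers.values()))
                truth_rows.append(
                    {
                        "fid": parent,
                        "offspring": off,
                        "parent_sex": psex,
                        "cc": cc,
                        "rbar": rbar_from_breakpoints(xovers, genome),
                        "crossovers": xovers,
                        "chiasmata": chias,
                        "start_strand": starts,
                    }
                )
            ped_rows.append((off, sire, dam, "unknown"))
            geno_ids.append(off)
            geno_rows.append(dosage)

    pedigree = Pedigree(
        pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "sex"]).astype(
            {"id": str}
        )
    )
    dosages = _perturb(
        np.vstack(geno_rows).astype(np.int8), error_rate, missing_rate, rng
    )
    genotypes = GenotypeMatrix(geno_ids, panel, dosages)
    truth = pd.DataFrame(truth_rows)
    breeding = pd.DataFrame(
        {
            "fid": fids,
            "sex": fid_sexes,
            "a": a_vals,
            "pe": pe_vals,
            "multiplier": multipliers,
        }
    )
    return SimulationResult(
        genome, panel, pedigree, genotypes, truth, breeding, landscape, trait,
        fid_haplotypes=hap_of,
    )


def obligate_chiasma_map_length(
    n_gametes: int = 2000,
    n_markers: int = 200,
    length_bp: int = 100_000_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Estimated map length (cM) when every meiosis carries exactly one
    chiasma at a uniform position, transmitted with probability 1/2.

    With fully informative markers the expected gamete crossover count is
    0.5, so the theoretical map length is 50 cM regardless of chromosome
    size — the obligate-crossover floor.
    """
    from .linkmap import estimate_sex_map
    from .phasing import OriginVector

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chrom = Chromosome("obligate", length_bp)
    land = SexLandscape(
        0.0, PiecewiseLinearDensity([0.0, 1.0], [1.0, 1.0]), obligate=True
    )
    pos = np.linspace(1, length_bp, n_markers).round().astype(int)
    panel = MarkerPanel(
        tuple(f"m{i}" for i in range(n_markers)), ("obligate",) * n_markers, tuple(pos)
    )
    hap = np.vstack([np.zeros(n_markers), np.ones(n_markers)]).astype(np.int8)
    vectors = []
    for i in range(n_gametes):
        ch = sample_chiasmata(chrom, land, 1.0, rng)
        _, xo, start = meiosis(hap, ch, pos, rng, length_bp)
        origins = ((start + np.searchsorted(np.sort(xo), pos, side="right")) % 2).astype(np.int8)
        vectors.append(
            OriginVector("F", f"g{i}", "female", {"obligate": origins}, {"obligate": False})
        )
    lmap = estimate_sex_map(vectors, panel)
    return lmap.total_cM


# ---------------------------------------------------------------------------
# presets

MALE_DENSITY = PiecewiseLinearDensity([0.0, 0.9, 0.9, 1.0], [0.0, 0.0, 1.0, 1.0])
FEMALE_DENSITY = PiecewiseLinearDensity(
    [0.0, 0.05, 0.3, 0.7, 1.0], [0.5, 2.0, 1.6, 0.6, 0.05]
)


def obligate_lambda(target_gamete_cc_per_chrom: float) -> float:
    """Chiasma intensity so that E[max(Poisson(lam), 1)] / 2 hits the target
    mean gamete crossover count per chromosome (obligate rule on)."""
    c = 2.0 * target_gamete_cc_per_chrom
    if c < 1.0:
        raise ValueError("obligate floor: mean gamete CC per chromosome >= 0.5")
    return brentq(lambda lam: lam + np.exp(-lam) - c, 1e-9, 50.0)


def desk_genome() -> GenomeSpec:
    return GenomeSpec(
        tuple(
            Chromosome(f"chr{i + 1}", 40_000_000, 0, True) for i in range(5)
        )
    )


def desk_preset():
    """Desk-scale study conditions: 5 x 40 Mb acrocentric chromosomes,
    200 markers each, 60 families of 20 offspring, female:male CC ratio 1.6."""
    from .containers import even_panel

    genome = desk_genome()
    panel = even_panel(genome, 200)
    female_lam = 5 * obligate_lambda(1.0)  # mean gamete CC 1.0/chrom -> 5.0 total
    male_lam = 5 * 2 * 0.625  # non-obligate, mean gamete CC 0.625/chrom -> 3.125
    landscape = LandscapeModel(
        male=SexLandscape(male_lam, MALE_DENSITY, obligate=False),
        female=SexLandscape(female_lam, FEMALE_DENSITY, obligate=True),
    )
    return genome, panel, landscape, TraitArchitecture(), FamilyDesign()


def salmon_preset(markers_per_chrom: int = 1200):
    """Paper-scale conditions: the 29 salmon chromosome lengths, ~35K markers,
    chiasma intensities calibrated so true mean gamete CC is 19.6 (female,
    obligate) and 12.1 (male, non-obligate: the observed male mean lies below
    the 29-chromosome obligate floor of 14.5, consistent with undetected male
    crossovers on a few chromosomes)."""
    from .containers import even_panel

    genome = salmon_genome()
    panel = even_panel(genome, markers_per_chrom)
    n = len(genome.chromosomes)
    female_lam = n * obligate_lambda(19.6 / n)
    male_lam = 2 * 12.1
    landscape = LandscapeModel(
        male=SexLandscape(male_lam, MALE_DENSITY, obligate=False),
        female=SexLandscape(female_lam, FEMALE_DENSITY, obligate=True),
    )
    trait = TraitArchitecture(
        sigma2_a={"male": 0.006, "female": 0.004},
        sigma2_pe={"male": 0.003, "female": 0.002},
        r_g_sim=0.0,
        n_causal=500,
    )
    design = FamilyDesign(n_sires=150, n_dams=300, offspring_per_family=30)
    return genome, panel, landscape, trait, design
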