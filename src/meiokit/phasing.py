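"""Full-sib family construction and gamete phasing.

For every sire x dam mating pair (the focal individuals, FIDs) with genotyped
parents and offspring, the transmitted gamete of each offspring is resolved
into a grandparental-origin sequence at the markers where the focal parent is
heterozygous and the transmitted allele is identifiable (other parent
homozygous, or offspring homozygous).  The parental phase is solved as a
binary orientation chain over informative markers in genome order by greedy
majority vote: at each step the orientation keeping the majority of offspring
origins unchanged relative to the previous informative marker is chosen.
Because the crossover-minimization objective decomposes over adjacent
informative-marker pairs (pairwise-complete counting), this greedy chain is
an exact minimum-recombination phasing, which the tests verify against
exhaustive enumeration on small instances.

Origin labels are anchored to the grandparental origin where grandparents are
genotyped; otherwise labels are arbitrary per chromosome, which leaves both
crossover counts and the shuffling statistic unchanged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chisquare

from .containers import GenotypeMatrix, MarkerPanel, Pedigree

log = logging.getLogger("meiokit")

H1, H2, MISSING = np.int8(0), np.int8(1), np.int8(-1)


@dataclass
class FullSibFamily:
    sire_id: str
    dam_id: str
    offspring_ids: list[str]
    grandparents: dict[str, str] = field(default_factory=dict)
    # keys among {"sire_sire", "sire_dam", "dam_sire", "dam_dam"}

    def __post_init__(self):
        if self.sire_id == self.dam_id:
            raise ValueError("sire and dam must differ")
        if not self.offspring_ids:
            raise ValueError("family needs at least one offspring")

    def parent(self, which: str) -> str:
        return self.sire_id if which == "sire" else self.dam_id


@dataclass
class OriginVector:
    """Grandparental-origin calls for one transmitted gamete.

    ``origins[chrom]`` is panel-aligned (one entry per panel marker on that
    chromosome): 0 = H1, 1 = H2, -1 = missing / not informative.
    """

    fid: str
    offspring_id: str
    parent_sex: str
    origins: dict[str, np.ndarray]
    anchored: dict[str, bool]


@dataclass
class MendelReport:
    sire_id: str
    dam_id: str
    per_marker: np.ndarray  # incompatibility count per panel marker
    n_flagged: int


def build_families(pedigree: Pedigree, genotyped: set[str]) -> list[FullSibFamily]:
    """One family per distinct sire x dam pair with >= 1 genotyped offspring
    and both parents genotyped.  An individual may be an FID in several
    families; each meiosis belongs to exactly one."""
    t = pedigree.table
    rows = t.dropna(subset=["sire", "dam"])
    rows = rows[rows["id"].isin(genotyped)]
    parent_of = dict(zip(t["id"], zip(t["sire"], t["dam"])))
    out: list[FullSibFamily] = []
    for (sire, dam), grp in rows.groupby(["sire", "dam"], sort=True):
        if sire not in genotyped or dam not in genotyped:
            log.info("family %s x %s skipped: ungenotyped parent", sire, dam)
            continue
        gps: dict[str, str] = {}
        for role, pid in (("sire", sire), ("dam", dam)):
            gs, gd = parent_of.get(pid, (None, None))
            if pd.notna(gs) and gs in genotyped:
                gps[f"{role}_sire"] = gs
            if pd.notna(gd) and gd in genotyped:
                gps[f"{role}_dam"] = gd
        out.append(FullSibFamily(sire, dam, sorted(grp["id"]), gps))
    return out


def _transmittable(dosage: int) -> tuple[int, ...]:
    """A1 counts a parent with this dosage can pass on (missing -> both)."""
    if dosage == 0:
        return (0,)
    if dosage == 2:
        return (1,)
    return (0, 1)


def mendel_check(
    family: FullSibFamily, genotypes: GenotypeMatrix
) -> tuple[MendelReport, GenotypeMatrix]:
    """Flag offspring genotypes impossible given both parents and set them
    missing in a cleaned copy; parents are untouched."""
    panel = genotypes.panel
    ds = genotypes.row(family.sire_id).astype(int)
    dd = genotypes.row(family.dam_id).astype(int)
    cleaned = genotypes.dosages.copy()
    per_marker = np.zeros(len(panel), dtype=int)
    # possible child dosages per (sire, dam) dosage pair
    possible = np.zeros((3, 3, 3), dtype=bool)
    for a in range(3):
        for b in range(3):
            for x in _transmittable(a):
                for y in _transmittable(b):
                    possible[a, b, x + y] = True
    n_flagged = 0
    for off in family.offspring_ids:
        i = genotypes._index[off]
        c = cleaned[i].astype(int)
        ok = (ds >= 0) & (dd >= 0) & (c >= 0)
        bad = ok & ~possible[np.clip(ds, 0, 2), np.clip(dd, 0, 2), np.clip(c, 0, 2)]
        cleaned[i, bad] = -1
        per_marker += bad
        n_flagged += int(bad.sum())
    report = MendelReport(family.sire_id, family.dam_id, per_marker, n_flagged)
    return report, GenotypeMatrix(list(genotypes.ids), panel, cleaned)


# expected offspring dosage distribution by (sire dosage, dam dosage)
_EXPECTED: dict[tuple[int, int], dict[int, float]] = {}
for _a in range(3):
    for _b in range(3):
        dist: dict[int, float] = {}
        for _x in _transmittable(_a):
            for _y in _transmittable(_b):
                w = (0.5 if _a == 1 else 1.0) * (0.5 if _b == 1 else 1.0)
                dist[_x + _y] = dist.get(_x + _y, 0.0) + w
        _EXPECTED[(_a, _b)] = dist


def segregation_filter(
    family: FullSibFamily, genotypes: GenotypeMatrix, alpha: float = 0.01
) -> np.ndarray:
    """Per-marker keep mask from a chi-square goodness-of-fit test of offspring
    genotype counts against Mendelian expectations given parental genotypes.

    Markers without a testable expectation (a missing parent, a single
    expected class, or fewer than two scored offspring) are kept.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    panel = genotypes.panel
    ds = genotypes.row(family.sire_id).astype(int)
    dd = genotypes.row(family.dam_id).astype(int)
    off = np.stack([genotypes.row(o) for o in family.offspring_ids]).astype(int)
    keep = np.ones(len(panel), dtype=bool)
    counts = np.stack([(off == d).sum(axis=0) for d in range(3)])  # (3, m)
    for j in range(len(panel)):
        if ds[j] < 0 or dd[j] < 0:
            continue
        dist = _EXPECTED[(ds[j], dd[j])]
        if len(dist) < 2:
            continue
        cats = sorted(dist)
        obs = np.array([counts[d, j] for d in cats], dtype=float)
        n = obs.sum()
        if n < 2:
            continue
        exp = np.array([dist[d] * n for d in cats])
        p = chisquare(obs, exp).pvalue
        if p < alpha:
            keep[j] = False
    return keep


def _transmitted_matrix(
    d_parent: np.ndarray, d_other: np.ndarray, child: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per (offspring, marker) A1-count transmitted by the focal parent.

    Returns (informative marker index array, T matrix in {0,1,-1}).
    Informative = focal parent heterozygous; resolvable when the other parent
    is homozygous or the offspring is homozygous, else missing for that
    offspring only.
    """
    inf = np.flatnonzero(d_parent == 1)
    c = child[:, inf].astype(int)
    other = d_other[inf].astype(int)
    T = np.full(c.shape, -1, dtype=np.int8)
    hom_other = (other == 0) | (other == 2)
    t_hom = c - (other // 2)[None, :]
    valid = hom_other[None, :] & (c >= 0) & (t_hom >= 0) & (t_hom <= 1)
    T[valid] = t_hom[valid]
    # other parent het or missing: only homozygous offspring resolve
    rest = ~hom_other[None, :] & (c >= 0)
    T[rest & (c == 0)] = 0
    T[rest & (c == 2)] = 1
    return inf, T


def _greedy_orientation(T: np.ndarray) -> np.ndarray:
    """Greedy majority-vote orientation chain over informative markers.

    Orientation s_j in {0,1} fixes which parental haplotype carries the A1
    allele at marker j; offspring origin is T[o, j] XOR s_j.  Ties keep the
    previous orientation.
    """
    n_off, m = T.shape
    s = np.zeros(m, dtype=np.int8)
    if m == 0:
        return s
    # each offspring's most recent assigned origin; comparing against these
    # rather than a single previous marker keeps the vote wide even when
    # adjacent markers are scored in barely-overlapping offspring subsets
    last = np.full(n_off, -1, dtype=np.int8)
    scored0 = T[:, 0] >= 0
    last[scored0] = T[scored0, 0]  # s[0] = 0 by convention
    for j in range(1, m):
        scored = T[:, j] >= 0
        valid = scored & (last >= 0)
        n = int(valid.sum())
        same = int((T[valid, j] == last[valid]).sum())
        flip = n - same
        if same == flip:
            s[j] = s[j - 1]
        else:
            s[j] = np.int8(0) if same > flip else np.int8(1)
        last[scored] = T[scored, j] ^ s[j]
    return s


def _fill_neighbors(O: np.ndarray):
    """Per (offspring, marker): origin at the nearest scored marker strictly
    before / after, -1 when none."""
    n_off, m = O.shape
    prev = np.full_like(O, -1)
    nxt = np.full_like(O, -1)
    cur = np.full(n_off, -1, dtype=np.int8)
    for j in range(m):
        prev[:, j] = cur
        upd = O[:, j] >= 0
        cur[upd] = O[upd, j]
    cur = np.full(n_off, -1, dtype=np.int8)
    for j in range(m - 1, -1, -1):
        nxt[:, j] = cur
        upd = O[:, j] >= 0
        cur[upd] = O[upd, j]
    return prev, nxt


def _repair_orientation(T: np.ndarray, s: np.ndarray, max_sweeps: int = 3) -> np.ndarray:
    """Coordinate-descent repair of the orientation chain.

    Flips any single marker orientation that strictly reduces the total number
    of per-offspring origin switches given its scored neighbors on both sides.
    This never increases the recombination cost and fixes isolated markers the
    forward chain could only link through an empty offspring overlap.
    """
    n_off, m = T.shape
    s = s.copy()
    for _ in range(max_sweeps):
        changed = False
        O = np.where(T >= 0, T ^ s[None, :], np.int8(-1))
        prev, nxt = _fill_neighbors(O)
        for j in range(m):
            scored = T[:, j] >= 0
            if not scored.any():
                continue
            cur = T[scored, j] ^ s[j]
            flp = cur ^ 1
            pv, nx = prev[scored, j], nxt[scored, j]
            cost_cur = int(((pv >= 0) & (cur != pv)).sum() + ((nx >= 0) & (cur != nx)).sum())
            cost_flip = int(((pv >= 0) & (flp != pv)).sum() + ((nx >= 0) & (flp != nx)).sum())
            if cost_flip < cost_cur:
                s[j] ^= 1
                changed = True
                O = np.where(T >= 0, T ^ s[None, :], np.int8(-1))
                prev, nxt = _fill_neighbors(O)
        if not changed:
            break
    return s


def _anchor_votes(
    d_parent: np.ndarray,
    inf: np.ndarray,
    s: np.ndarray,
    gs_dosage: np.ndarray | None,
    gd_dosage: np.ndarray | None,
) -> int:
    """Vote whether H1 (under orientation s) is the grandpaternal haplotype.

    Returns +votes for H1 = grandsire, negative for H2 = grandsire, 0 when
    unresolvable.  At an informative marker the parent is A1/A2; the allele
    inherited from the grandsire is known when either grandparent is
    homozygous there.
    """
    votes = 0
    for k, j in enumerate(inf):
        pat_a1 = None  # A1 count of the allele the parent got from its sire
        if gs_dosage is not None and gs_dosage[j] in (0, 2):
            pat_a1 = gs_dosage[j] // 2
        elif gd_dosage is not None and gd_dosage[j] in (0, 2):
            pat_a1 = 1 - gd_dosage[j] // 2  # maternal allele known -> other one
        if pat_a1 is None:
            continue
        # origin H1 means T == s[k], so the H1 haplotype carries s[k] A1 copies
        h1_a1 = int(s[k])
        votes += 1 if h1_a1 == pat_a1 else -1
    return votes


def phase_gametes(
    family: FullSibFamily,
    genotypes: GenotypeMatrix,
    parent: str,
    panel: MarkerPanel | None = None,
    min_offspring: int = 4,
    parent_sex: str | None = None,
) -> list[OriginVector]:
    """Infer origin vectors for every gamete the focal parent transmitted.

    ``parent`` is "sire" or "dam".  Families with fewer genotyped offspring
    than ``min_offspring`` are skipped (empty list, logged).
    """
    panel = panel or genotypes.panel
    pid = family.parent(parent)
    if not genotypes.has(pid):
        raise KeyError(f"parent {pid} not genotyped")
    offspring = [o for o in family.offspring_ids if genotypes.has(o)]
    if len(offspring) < min_offspring:
        log.info(
            "family %s x %s skipped for %s phasing: %d offspring < %d",
            family.sire_id, family.dam_id, parent, len(offspring), min_offspring,
        )
        return []
    sex = parent_sex or ("male" if parent == "sire" else "female")
    other_id = family.parent("dam" if parent == "sire" else "sire")
    d_parent = genotypes.row(pid).astype(int)
    d_other = (
        genotypes.row(other_id).astype(int)
        if genotypes.has(other_id)
        else np.full(len(panel), -1)
    )
    child = np.stack([genotypes.row(o) for o in offspring]).astype(int)

    gs_key, gd_key = f"{parent}_sire", f"{parent}_dam"
    gs = family.grandparents.get(gs_key)
    gd = family.grandparents.get(gd_key)
    gs_dos = genotypes.row(gs).astype(int) if gs and genotypes.has(gs) else None
    gd_dos = genotypes.row(gd).astype(int) if gd and genotypes.has(gd) else None

    per_chrom: dict[str, np.ndarray] = {}
    anchored: dict[str, bool] = {}
    for chrom in panel.chromosomes:
        idx = panel.indices_for(chrom)
        inf, T = _transmitted_matrix(d_parent[idx], d_other[idx], child[:, idx])
        s = _repair_orientation(T, _greedy_orientation(T))
        if gs_dos is not None or gd_dos is not None:
            votes = _anchor_votes(
                d_parent[idx], inf, s,
                gs_dos[idx] if gs_dos is not None else None,
                gd_dos[idx] if gd_dos is not None else None,
            )
            if votes < 0:
                s = s ^ 1  # relabel so H1 is the grandpaternal haplotype
            anchored[chrom] = votes != 0
        else:
            anchored[chrom] = False
        origins = np.full((len(offspring), len(idx)), MISSING, dtype=np.int8)
        known = T >= 0
        vals = (T ^ s[None, :]).astype(np.int8)
        origins[:, inf] = np.where(known, vals, MISSING)
        per_chrom[chrom] = origins

    return [
        OriginVector(
            fid=pid,
            offspring_id=o,
            parent_sex=sex,
            origins={c: per_chrom[c][i] for c in per_chrom},
            anchored=dict(anchored),
        )
        for i, o in enumerate(offspring)
    ]


def phase_population(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    min_offspring: int = 4,
    segregation_alpha: float | None = 0.01,
    run_mendel: bool = True,
) -> list[OriginVector]:
    """End-to-end phasing: families, Mendel QC, segregation filter, phasing
    of both parents of every family."""
    families = build_families(pedigree, set(genotypes.ids))
    vectors: list[OriginVector] = []
    for fam in families:
        geno = genotypes
        if run_mendel:
            _, geno = mendel_check(fam, geno)
        if segregation_alpha is not None and len(fam.offspring_ids) >= 2:
            keep = segregation_filter(fam, geno, segregation_alpha)
            if not keep.all():
                masked = geno.dosages.copy()
                rows = [geno._index[o] for o in fam.offspring_ids]
                masked[np.ix_(rows, np.flatnonzero(~keep))] = -1
                geno = GenotypeMatrix(list(geno.ids), geno.panel, masked)
        for parent in ("sire", "dam"):
            vectors.extend(
                phase_gametes(fam, geno, parent, min_offspring=min_offspring)
            )
    return vectors


def origins_to_frame(vectors: list[OriginVector], panel: MarkerPanel) -> pd.DataFrame:
    """Long-format TSV payload: one row per informative (gamete, marker)."""
    rows = []
    for v in vectors:
        for chrom, orig in v.origins.items():
            idx = panel.indices_for(chrom)
            pos = np.asarray(panel.pos_bp)[idx]
            for p, o in zip(pos[orig >= 0], orig[orig >= 0]):
                rows.append((v.fid, v.offspring_id, v.parent_sex, chrom, int(p), "H1" if o == 0 else "H2"))
    return pd.DataFrame(
        rows, columns=["fid", "offspring", "parent_sex", "chrom", "pos_bp", "origin"]
    )


def origins_from_frame(df: pd.DataFrame, panel: MarkerPanel) -> list[OriginVector]:
    """Rebuild origin vectors from the long-format TSV payload."""
    pos_index = {
        chrom: {int(p): k for k, p in enumerate(panel.positions_for(chrom))}
        for chrom in panel.chromosomes
    }
    out: list[OriginVector] = []
    for (fid, off, sex), grp in df.groupby(["fid", "offspring", "parent_sex"], sort=False):
        origins = {
            chrom: np.full(len(pos_index[chrom]), MISSING, dtype=np.int8)
            for chrom in panel.chromosomes
        }
        for chrom, cg in grp.groupby("chrom"):
            lookup = pos_index[str(chrom)]
            for p, o in zip(cg["pos_bp"], cg["origin"]):
                origins[str(chrom)][lookup[int(p)]] = H1 if o == "H1" else H2
        out.append(
            OriginVector(str(fid), str(off), str(sex), origins,
                         {c: False for c in origins})
        )
    return out
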