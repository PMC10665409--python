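from itertools import product

import numpy as np
import pandas as pd
import pytest

import meiokit as mk
from meiokit.phasing import (
    FullSibFamily,
    _greedy_orientation,
    _transmitted_matrix,
    build_families,
    mendel_check,
    origins_from_frame,
    origins_to_frame,
    phase_gametes,
    segregation_filter,
)
from meiokit.simulate import FamilyDesign


def _chain_cost(T: np.ndarray, s: np.ndarray) -> int:
    """Total recombinations over per-offspring origin sequences (skip missing)."""
    cost = 0
    for o in range(T.shape[0]):
        scored = np.flatnonzero(T[o] >= 0)
        vals = T[o, scored] ^ s[scored]
        cost += int((np.diff(vals) != 0).sum())
    return cost


def _exhaustive_min_cost(T: np.ndarray) -> int:
    m = T.shape[1]
    best = None
    for bits in product([0, 1], repeat=m - 1):
        s = np.array([0, *bits], dtype=np.int8)
        c = _chain_cost(T, s)
        best = c if best is None else min(best, c)
    return best


class TestBuildFamilies:
    def test_sire_with_two_dams_is_fid_in_two_families(self):
        ped = mk.Pedigree(
            pd.DataFrame(
                {
                    "id": ["S", "D1", "D2", "k1", "k2"],
                    "sire": [None, None, None, "S", "S"],
                    "dam": [None, None, None, "D1", "D2"],
                    "sex": ["male", "female", "female", "unknown", "unknown"],
                }
            )
        )
        fams = build_families(ped, {"S", "D1", "D2", "k1", "k2"})
        assert len(fams) == 2
        assert all(f.sire_id == "S" for f in fams)
        assert {f.dam_id for f in fams} == {"D1", "D2"}

    def test_single_trio(self, toy_pedigree):
        fams = build_families(toy_pedigree, {"S1", "D1", "K1"})
        assert len(fams) == 1 and fams[0].offspring_ids == ["K1"]

    def test_matches_exhaustive_pair_scan(self):
        rng = np.random.default_rng(0)
        sires = [f"S{i}" for i in range(4)]
        dams = [f"D{i}" for i in range(4)]
        rows = [(s, None, None, "male") for s in sires]
        rows += [(d, None, None, "female") for d in dams]
        kids = []
        for k in range(25):
            s, d = rng.choice(sires), rng.choice(dams)
            rows.append((f"k{k}", s, d, "unknown"))
            kids.append((s, d, f"k{k}"))
        ped = mk.Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"]))
        genotyped = {r[0] for r in rows}
        fams = build_families(ped, genotyped)
        expected = {}
        for s, d, k in kids:
            expected.setdefault((s, d), set()).add(k)
        assert {(f.sire_id, f.dam_id): set(f.offspring_ids) for f in fams} == expected

    def test_ungenotyped_parent_excludes_family(self, toy_pedigree):
        fams = build_families(toy_pedigree, {"D1", "K1", "K2"})
        assert fams == []


class TestMendelCheck:
    def _family(self, sire_dos, dam_dos, kid_dos, panel):
        ids = ["S", "D", "K"]
        dos = np.array([sire_dos, dam_dos, kid_dos], dtype=np.int8)
        geno = mk.GenotypeMatrix(ids, panel, dos)
        return FullSibFamily("S", "D", ["K"]), geno

    def test_impossible_offspring_set_missing(self, toy_panel):
        fam, geno = self._family([0] * 6, [0] * 6, [2, 0, 0, 0, 0, 0], toy_panel)
        report, cleaned = mendel_check(fam, geno)
        assert report.n_flagged == 1
        assert cleaned.row("K")[0] == -1
        assert cleaned.row("S")[0] == 0  # parents untouched

    def test_consistent_family_zero_flags(self, toy_panel):
        fam, geno = self._family([1] * 6, [1] * 6, [0, 1, 2, 1, 0, 2], toy_panel)
        report, _ = mendel_check(fam, geno)
        assert report.n_flagged == 0

    def test_flagged_fraction_matches_enumeration(self, desk):
        """With symmetric allele-flip error at rate e, the Mendel-detectable
        fraction is computable by enumerating flip outcomes per (parents,
        child) configuration; the observed flag count must agree."""
        genome, panel, landscape, trait, _ = desk
        res = mk.simulate_population(
            genome, panel, landscape, trait, FamilyDesign(4, 4, 15),
            error_rate=0.0, missing_rate=0.0, seed=21,
        )
        geno = res.genotypes
        e = 0.01
        rng = np.random.default_rng(99)
        fams = build_families(res.pedigree, set(geno.ids))
        # perturb offspring only, so parental genotypes stay exact
        from meiokit.simulate import _perturb
        dos = geno.dosages.copy()
        kid_rows = [geno._index[o] for f in fams for o in f.offspring_ids]
        dos[kid_rows] = _perturb(geno.dosages[kid_rows], e, 0.0, rng)
        noisy = mk.GenotypeMatrix(list(geno.ids), panel, dos)

        # enumeration oracle: P(observed child impossible | parents, true child)
        def possible(a, b):
            out = set()
            for x in ((0,) if a == 0 else (1,) if a == 2 else (0, 1)):
                for y in ((0,) if b == 0 else (1,) if b == 2 else (0, 1)):
                    out.add(x + y)
            return out

        def flip_dist(c):
            # child dosage after independent allele flips at rate e
            n1 = c
            probs = {}
            for down in range(n1 + 1):
                for up in range(2 - n1 + 1):
                    from math import comb
                    p = (
                        comb(n1, down) * e**down * (1 - e) ** (n1 - down)
                        * comb(2 - n1, up) * e**up * (1 - e) ** (2 - n1 - up)
                    )
                    probs[c - down + up] = probs.get(c - down + up, 0.0) + p
            return probs

        expected = 0.0
        observed = 0
        for fam in fams:
            ds = geno.row(fam.sire_id)
            dd = geno.row(fam.dam_id)
            rep, _ = mendel_check(fam, noisy)
            observed += rep.n_flagged
            for off in fam.offspring_ids:
                c_true = geno.row(off)
                for j in range(len(panel)):
                    ok = possible(int(ds[j]), int(dd[j]))
                    for c_obs, p in flip_dist(int(c_true[j])).items():
                        if c_obs not in ok:
                            expected += p
        se = np.sqrt(expected)  # Poisson-scale error on the count
        assert abs(observed - expected) < 4 * se


class TestSegregationFilter:
    def _mating(self, counts, toy_panel):
        """1x1 het mating with given offspring dosage counts at marker 0."""
        kids = []
        dos = []
        k = 0
        for dosage, n in counts.items():
            for _ in range(n):
                kids.append(f"K{k}")
                row = [dosage] + [1] * 5
                dos.append(row)
                k += 1
        ids = ["S", "D"] + kids
        allr = [[1] * 6, [1] * 6] + dos
        geno = mk.GenotypeMatrix(ids, toy_panel, np.array(allr, dtype=np.int8))
        return FullSibFamily("S", "D", kids), geno

    def test_exact_mendelian_ratio_kept(self, toy_panel):
        fam, geno = self._mating({0: 25, 1: 50, 2: 25}, toy_panel)
        keep = segregation_filter(fam, geno, alpha=0.01)
        assert keep[0]

    def test_extreme_distortion_masked(self, toy_panel):
        fam, geno = self._mating({0: 100}, toy_panel)
        keep = segregation_filter(fam, geno, alpha=0.01)
        assert not keep[0]

    def test_single_offspring_kept(self, toy_panel):
        fam, geno = self._mating({0: 1}, toy_panel)
        keep = segregation_filter(fam, geno, alpha=0.01)
        assert keep.all()

    def test_invalid_alpha_rejected(self, toy_panel):
        fam, geno = self._mating({0: 5, 1: 5}, toy_panel)
        with pytest.raises(ValueError):
            segregation_filter(fam, geno, alpha=1.5)


class TestGreedyPhasing:
    def _random_instance(self, rng, n_off, m, n_crossovers=1):
        h1 = rng.integers(0, 2, m, dtype=np.int8)
        T = np.empty((n_off, m), dtype=np.int8)
        for o in range(n_off):
            origin = np.zeros(m, dtype=np.int8)
            start = rng.integers(0, 2)
            cuts = rng.choice(m - 1, size=rng.integers(0, n_crossovers + 1), replace=False)
            origin[:] = start
            for c in sorted(cuts):
                origin[c + 1 :] ^= 1
            T[o] = np.where(origin == 0, h1, 1 - h1)
        return T

    @pytest.mark.parametrize("n_off,m", [(2, 4), (3, 8), (4, 12), (6, 10)])
    def test_greedy_matches_exhaustive_minimum(self, n_off, m):
        """The majority-vote chain attains the exhaustive minimum-recombination
        cost on complete-data instances of up to 12 informative markers."""
        rng = np.random.default_rng(100 + n_off * m)
        for _ in range(10):
            T = self._random_instance(rng, n_off, m, n_crossovers=2)
            s = _greedy_orientation(T)
            assert _chain_cost(T, s) == _exhaustive_min_cost(T)

    def test_two_offspring_four_marker_worked_family(self):
        # one offspring crosses over after marker 1, the other does not;
        # the single switch cannot be absorbed by a phase flip, so the
        # minimum-recombination solution costs exactly 1
        h1 = np.array([0, 1, 1, 0], dtype=np.int8)
        T = np.empty((2, 4), dtype=np.int8)
        origin0 = np.array([0, 0, 1, 1])
        origin1 = np.array([1, 1, 1, 1])
        T[0] = np.where(origin0 == 0, h1, 1 - h1)
        T[1] = np.where(origin1 == 0, h1, 1 - h1)
        s = _greedy_orientation(T)
        assert _chain_cost(T, s) == _exhaustive_min_cost(T) == 1


class TestPhaseGametes:
    def test_homozygous_parent_chromosome_has_no_origins(self, toy_panel):
        ids = ["S", "D", "K1", "K2", "K3", "K4"]
        dos = np.array(
            [
                [0, 0, 0, 1, 1, 1],  # sire hom across c1
                [1, 1, 1, 0, 0, 0],
                [0, 0, 0, 0, 1, 0],
                [0, 1, 0, 1, 0, 1],
                [1, 0, 0, 0, 0, 0],
                [0, 0, 1, 1, 1, 0],
            ],
            dtype=np.int8,
        )
        geno = mk.GenotypeMatrix(ids, toy_panel, dos)
        fam = FullSibFamily("S", "D", ["K1", "K2", "K3", "K4"])
        vecs = phase_gametes(fam, geno, "sire", panel=toy_panel)
        assert all((v.origins["c1"] == -1).all() for v in vecs)
        assert any((v.origins["c2"] >= 0).any() for v in vecs)

    def test_min_offspring_skips_small_families(self, toy_panel):
        ids = ["S", "D", "K1"]
        dos = np.ones((3, 6), dtype=np.int8)
        geno = mk.GenotypeMatrix(ids, toy_panel, dos)
        fam = FullSibFamily("S", "D", ["K1"])
        assert phase_gametes(fam, geno, "sire", panel=toy_panel, min_offspring=4) == []
        assert len(phase_gametes(fam, geno, "sire", panel=toy_panel, min_offspring=1)) == 1

    def test_invariant_to_offspring_order(self, clean_sim):
        fams = build_families(clean_sim.pedigree, set(clean_sim.genotypes.ids))
        fam = fams[0]
        fwd = phase_gametes(fam, clean_sim.genotypes, "dam")
        rev_fam = FullSibFamily(
            fam.sire_id, fam.dam_id, list(reversed(fam.offspring_ids)), fam.grandparents
        )
        rev = phase_gametes(rev_fam, clean_sim.genotypes, "dam")
        by_off = {v.offspring_id: v for v in rev}
        for v in fwd:
            w = by_off[v.offspring_id]
            for chrom in v.origins:
                np.testing.assert_array_equal(v.origins[chrom], w.origins[chrom])

    def test_recovers_truth_origins_with_grandparent_anchoring(self, desk):
        """With genotyped grandparents and error-free data, anchored origin
        labels match the simulator's true grandparental origins."""
        genome, panel, landscape, trait, _ = desk
        res = mk.simulate_population(
            genome, panel, landscape, trait,
            FamilyDesign(2, 2, 25, grandparents_genotyped=1.0),
            error_rate=0.0, missing_rate=0.0, seed=31,
        )
        fams = build_families(res.pedigree, set(res.genotypes.ids))
        t = res.truth.set_index(["fid", "offspring", "parent_sex"])
        n_checked = n_agree = 0
        for fam in fams:
            for parent, sex in (("sire", "male"), ("dam", "female")):
                for v in phase_gametes(fam, res.genotypes, parent):
                    row = t.loc[(v.fid, v.offspring_id, sex)]
                    for chrom, origins in v.origins.items():
                        if not v.anchored[chrom]:
                            continue
                        pos = panel.positions_for(chrom)
                        xo = np.sort(row["crossovers"][chrom])
                        true = (row["start_strand"][chrom] + np.searchsorted(xo, pos, side="right")) % 2
                        inf = origins >= 0
                        n_checked += int(inf.sum())
                        n_agree += int((origins[inf] == true[inf]).sum())
        assert n_checked > 1000
        assert n_agree / n_checked > 0.99

    def test_round_trip_through_long_format_frame(self, clean_vectors, clean_sim):
        panel = clean_sim.panel
        sub = clean_vectors[:5]
        frame = origins_to_frame(sub, panel)
        back = origins_from_frame(frame, panel)
        assert len(back) == len(sub)
        lookup = {(v.fid, v.offspring_id, v.parent_sex): v for v in back}
        for v in sub:
            w = lookup[(v.fid, v.offspring_id, v.parent_sex)]
            for chrom in v.origins:
                np.testing.assert_array_equal(v.origins[chrom], w.origins[chrom])
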