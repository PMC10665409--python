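"""Sex-specific linkage maps from origin vectors.

Marker order is taken from the genome (no de-novo ordering).  For every
adjacent pair of ever-informative markers the recombination fraction is the
share of recombinant meioses among meioses with a non-missing origin at both
ends (pairwise-complete), converted to map distance with the Haldane mapping
function d = -50 ln(1 - 2r) cM.  Fractions at or above 0.5 are capped at 0.49
with a warning (Haldane is undefined there and sparse intervals fluctuate).
Markers that are never informative get cM interpolated by physical position.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenomeSpec, MarkerPanel
from .phasing import OriginVector

log = logging.getLogger("meiokit")

__all__ = [
    "haldane_cM",
    "haldane_inverse",
    "LinkageMap",
    "origin_matrix",
    "estimate_sex_map",
    "map_summary",
    "aggregate_map_summary",
    "bin_rates",
    "relative_profile",
]

R_CAP = 0.49


def haldane_cM(r):
    """Haldane map distance in cM for recombination fraction(s) r < 0.5."""
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log1p(-2.0 * r)


def haldane_inverse(d_cM):
    """Recombination fraction for a Haldane distance in cM."""
    d = np.asarray(d_cM, dtype=float)
    return 0.5 * (1.0 - np.exp(-d / 50.0))


@dataclass
class LinkageMap:
    """Per-chromosome marker cM positions for one sex.

    ``tables[chrom]`` has columns marker_id, pos_bp, cM (non-decreasing,
    starting at 0) and informative (meioses informing the interval ending at
    that marker; 0 for the first marker and interpolated markers).
    """

    sex: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def chrom_length_cM(self, chrom: str) -> float:
        t = self.tables[chrom]
        return float(t["cM"].iloc[-1]) if len(t) else 0.0

    @property
    def total_cM(self) -> float:
        return float(sum(self.chrom_length_cM(c) for c in self.tables))

    def to_frame(self) -> pd.DataFrame:
        out = []
        for chrom, t in self.tables.items():
            tt = t.copy()
            tt.insert(0, "chrom", chrom)
            out.append(tt)
        return pd.concat(out, ignore_index=True)


def origin_matrix(vectors: list[OriginVector], chrom: str) -> np.ndarray:
    """Stack origin calls for one chromosome: (n_meioses, n_markers) int8."""
    rows = [v.origins[chrom] for v in vectors if chrom in v.origins]
    if not rows:
        return np.zeros((0, 0), dtype=np.int8)
    return np.stack(rows)


def estimate_sex_map(
    vectors: list[OriginVector],
    panel: MarkerPanel,
    sex: str | None = None,
) -> LinkageMap:
    """Estimate a linkage map from the origin vectors of one sex."""
    if not vectors:
        raise ValueError("no origin vectors supplied")
    sex = sex or vectors[0].parent_sex
    lmap = LinkageMap(sex=sex)
    for chrom in panel.chromosomes:
        M = origin_matrix(vectors, chrom)
        pos = panel.positions_for(chrom)
        ids = np.asarray(panel.marker_ids, dtype=object)[panel.indices_for(chrom)]
        if M.size == 0 or not (M >= 0).any():
            log.warning("chromosome %s: no informative meioses; map omitted", chrom)
            continue
        scored = M >= 0
        ever = np.flatnonzero(scored.any(axis=0))
        n_int = len(ever) - 1
        # crossover events per meiosis between its consecutive scored markers,
        # localized to the union interval containing the event midpoint; the
        # denominator is the number of meioses whose scored span covers the
        # interval.  On fully informative data this reduces to the share of
        # recombinant meioses between adjacent markers.
        ev_counts = np.zeros(n_int)
        first = np.full(M.shape[0], -1)
        last = np.full(M.shape[0], -1)
        union_pos = pos[ever]
        for i in range(M.shape[0]):
            cols = np.flatnonzero(scored[i])
            if len(cols) == 0:
                continue
            first[i], last[i] = cols[0], cols[-1]
            vals = M[i, cols]
            sw = np.flatnonzero(np.diff(vals) != 0)
            if len(sw):
                mids = (pos[cols[sw]] + pos[cols[sw + 1]]) / 2.0
                which = np.clip(
                    np.searchsorted(union_pos, mids, side="right") - 1, 0, n_int - 1
                )
                np.add.at(ev_counts, which, 1.0)
        ok = first >= 0
        # coverage: meiosis has a scored marker at/left of the interval start
        # and at/right of the interval end
        informative = np.array(
            [
                int(((first[ok] <= ever[j]) & (last[ok] >= ever[j + 1])).sum())
                for j in range(n_int)
            ]
        )
        d = np.zeros(n_int)
        for j in range(n_int):
            if informative[j] == 0:
                continue
            r = ev_counts[j] / informative[j]
            if r >= 0.5:
                warnings.warn(
                    f"{chrom}: interval recombination fraction {r:.3f} >= 0.5 "
                    f"capped at {R_CAP}",
                    stacklevel=2,
                )
                r = R_CAP
            d[j] = float(haldane_cM(r))
        cM_inf = np.concatenate([[0.0], np.cumsum(d)])
        # interpolate never-informative markers by physical position
        cM = np.interp(pos, pos[ever], cM_inf)
        inf_per_marker = np.zeros(len(pos), dtype=int)
        inf_per_marker[ever[1:]] = informative
        lmap.tables[chrom] = pd.DataFrame(
            {"marker_id": ids, "pos_bp": pos, "cM": cM, "informative": inf_per_marker}
        )
        assert np.all(np.diff(cM) >= -1e-12), f"{chrom}: cM not monotone"
    return lmap


def aggregate_map_summary(per_chrom: pd.DataFrame) -> pd.DataFrame:
    """Append a Total row to a per-chromosome summary with columns
    chrom, length_mb, male_cM, female_cM (ratio/rates recomputed)."""
    t = per_chrom.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t["female_male_ratio"] = np.where(
            t["male_cM"] > 0, t["female_cM"] / t["male_cM"], np.nan
        )
        t["male_rate"] = t["male_cM"] / t["length_mb"]
        t["female_rate"] = t["female_cM"] / t["length_mb"]
    tot_mb = t["length_mb"].sum()
    tot_m = t["male_cM"].sum()
    tot_f = t["female_cM"].sum()
    total = pd.DataFrame(
        [
            {
                "chrom": "Total",
                "length_mb": tot_mb,
                "male_cM": tot_m,
                "female_cM": tot_f,
                "female_male_ratio": tot_f / tot_m if tot_m > 0 else np.nan,
                "male_rate": tot_m / tot_mb,
                "female_rate": tot_f / tot_mb,
            }
        ]
    )
    return pd.concat([t, total], ignore_index=True)


def map_summary(
    male_map: LinkageMap, female_map: LinkageMap, genome: GenomeSpec
) -> pd.DataFrame:
    """Per-chromosome and total map lengths, female/male ratios and cM/Mb."""
    chroms = [c for c in genome.chrom_ids if c in male_map.tables or c in female_map.tables]
    rows = []
    for chrom in chroms:
        rows.append(
            {
                "chrom": chrom,
                "length_mb": genome[chrom].length_bp / 1e6,
                "male_cM": male_map.chrom_length_cM(chrom) if chrom in male_map.tables else np.nan,
                "female_cM": female_map.chrom_length_cM(chrom) if chrom in female_map.tables else np.nan,
            }
        )
    return aggregate_map_summary(pd.DataFrame(rows))


def bin_rates(
    lmap: LinkageMap, genome: GenomeSpec, bin_width_bp: int = 1_000_000
) -> pd.DataFrame:
    """1 Mb binned cM/Mb: (cM_last - cM_first) / (Mb_last - Mb_first) over the
    markers inside each half-open bin; missing with < 2 markers or zero span."""
    if not lmap.tables:
        raise ValueError("empty linkage map")
    rows = []
    for chrom, t in lmap.tables.items():
        length = genome[chrom].length_bp
        pos = t["pos_bp"].to_numpy()
        cm = t["cM"].to_numpy()
        n_bins = int(np.ceil(length / bin_width_bp))
        which = np.minimum(pos // bin_width_bp, n_bins - 1)
        for b in range(n_bins):
            sel = which == b
            n = int(sel.sum())
            rate = np.nan
            if n >= 2:
                span_mb = (pos[sel].max() - pos[sel].min()) / 1e6
                if span_mb > 0:
                    rate = (cm[sel].max() - cm[sel].min()) / span_mb
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start_bp": b * bin_width_bp,
                    "bin_end_bp": min((b + 1) * bin_width_bp, length),
                    "n_markers": n,
                    "rate": rate,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["sex"] = lmap.sex
    return out


def relative_profile(
    binned_by_sex: dict[str, pd.DataFrame],
    genome: GenomeSpec,
    n_bins: int = 40,
) -> pd.DataFrame:
    """Average binned rates across acrocentric chromosomes on a relative axis
    (0 = centromere, 1 = telomeric end), per sex."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    rows = []
    for sex, binned in binned_by_sex.items():
        acc = np.zeros(n_bins)
        cnt = np.zeros(n_bins)
        for chrom, grp in binned.groupby("chrom"):
            spec = genome[chrom]
            if not spec.acrocentric:
                continue
            arm = spec.length_bp - spec.centromere_bp
            mid_bp = (grp["bin_start_bp"] + grp["bin_end_bp"]) / 2.0
            rel = (mid_bp - spec.centromere_bp) / arm
            ok = (rel >= 0) & (rel <= 1) & grp["rate"].notna()
            which = np.clip(np.searchsorted(edges, rel[ok], side="right") - 1, 0, n_bins - 1)
            np.add.at(acc, which, grp.loc[ok, "rate"])
            np.add.at(cnt, which, 1.0)
        with np.errstate(invalid="ignore"):
            mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        for m, v, c in zip(mids, mean, cnt):
            rows.append({"sex": sex, "rel_pos": m, "mean_rate": v, "n_bins": int(c)})
    return pd.DataFrame(rows)
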