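"""Per-meiosis recombination phenotypes: crossover count and shuffling.

A crossover is called at every origin state change along a cleaned origin
vector and localized to the bracketing informative-marker interval.  Isolated
short runs (fewer than ``min_support`` markers flanked on both sides by the
opposite origin) are treated as genotyping error and masked before counting.

Intra-chromosomal genetic shuffling is the probability that a randomly chosen
pair of loci on the same chromosome had different grandparental origins in
the gamete:

    rbar = sum_k 2 p_k (1 - p_k) L_k^2

where p_k is the fraction of chromosome k carrying one origin label and L_k
is the chromosome's length as a fraction of the genome.  Breakpoints are
placed at the physical midpoint of each crossover interval; chromosome ends
extend the nearest observed origin.  p_k is physical-length-weighted by
default (marker-count weighting available for sensitivity analysis).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenomeSpec, MarkerPanel
from .phasing import MISSING, OriginVector

__all__ = [
    "CrossoverEvent",
    "detect_crossovers",
    "crossover_count",
    "shuffling_rbar",
    "compute_phenotypes",
    "phenotype_table",
    "sex_summary",
]


@dataclass(frozen=True)
class CrossoverEvent:
    fid: str
    offspring_id: str
    chrom: str
    left_bp: int
    right_bp: int
    support_left: int
    support_right: int

    def __post_init__(self):
        if not self.left_bp < self.right_bp:
            raise ValueError("crossover interval must have left_bp < right_bp")


def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop, value) runs over a 1-d array (stop exclusive)."""
    out = []
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and values[j] == values[i]:
            j += 1
        out.append((i, j, int(values[i])))
        i = j
    return out


def _clean_chrom(origins: np.ndarray, min_support: int) -> np.ndarray:
    """Mask isolated short runs flanked on both sides by the opposite origin."""
    inf = np.flatnonzero(origins >= 0)
    if len(inf) == 0:
        return origins
    vals = origins[inf].copy()
    runs = _runs(vals)
    for r, (a, b, v) in enumerate(runs):
        if b - a < min_support and 0 < r < len(runs) - 1:
            if runs[r - 1][2] != v and runs[r + 1][2] != v:
                vals[a:b] = MISSING
    cleaned = origins.copy()
    cleaned[inf] = vals
    return cleaned


def detect_crossovers(
    vector: OriginVector,
    panel: MarkerPanel,
    min_support: int = 3,
) -> tuple[OriginVector, list[CrossoverEvent]]:
    """QC the origin vector and call crossovers at origin state changes."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    cleaned: dict[str, np.ndarray] = {}
    events: list[CrossoverEvent] = []
    for chrom, origins in vector.origins.items():
        pos = panel.positions_for(chrom)
        c = _clean_chrom(origins, min_support)
        cleaned[chrom] = c
        inf = np.flatnonzero(c >= 0)
        vals = c[inf]
        runs = _runs(vals)
        for r in range(1, len(runs)):
            a_prev, b_prev, _ = runs[r - 1]
            a, b, _ = runs[r]
            left = int(pos[inf[b_prev - 1]])
            right = int(pos[inf[a]])
            events.append(
                CrossoverEvent(
                    vector.fid,
                    vector.offspring_id,
                    chrom,
                    left,
                    right,
                    b_prev - a_prev,
                    b - a,
                )
            )
    out = OriginVector(
        vector.fid, vector.offspring_id, vector.parent_sex, cleaned, dict(vector.anchored)
    )
    return out, events


def crossover_count(events: list[CrossoverEvent]) -> tuple[int, dict[str, int]]:
    """Total and per-chromosome crossover counts for one gamete."""
    per_chrom: dict[str, int] = {}
    for e in events:
        per_chrom[e.chrom] = per_chrom.get(e.chrom, 0) + 1
    return sum(per_chrom.values()), per_chrom


def shuffling_rbar(
    vector: OriginVector,
    genome: GenomeSpec,
    panel: MarkerPanel,
    events: list[CrossoverEvent] | None = None,
    p_mode: str = "physical",
) -> tuple[float, dict[str, float], dict[str, bool]]:
    """Shuffling statistic of a cleaned gamete.

    Returns (rbar, p_k per chromosome, covered flag per chromosome).
    Chromosomes without informative markers contribute zero and are flagged
    uncovered.  When ``events`` is omitted they are derived from the vector
    with ``min_support=1`` semantics (every state change is a breakpoint).
    """
    L = genome.length_fractions()
    p_k: dict[str, float] = {}
    covered: dict[str, bool] = {}
    rbar = 0.0
    ev_by_chrom: dict[str, list[CrossoverEvent]] = {}
    if events is not None:
        for e in events:
            ev_by_chrom.setdefault(e.chrom, []).append(e)
    for chrom, origins in vector.origins.items():
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom} absent from genome spec")
        length = genome[chrom].length_bp
        pos = panel.positions_for(chrom)
        inf = np.flatnonzero(origins >= 0)
        if len(inf) == 0:
            p_k[chrom] = float("nan")
            covered[chrom] = False
            continue
        covered[chrom] = True
        vals = origins[inf]
        if p_mode == "marker":
            p = float((vals == 0).mean())
        elif p_mode == "physical":
            if events is None:
                switch = np.flatnonzero(np.diff(vals) != 0)
                mids = (pos[inf[switch]] + pos[inf[switch + 1]]) / 2.0
            else:
                mids = np.array(
                    sorted((e.left_bp + e.right_bp) / 2.0 for e in ev_by_chrom.get(chrom, []))
                )
            edges = np.concatenate([[0.0], mids, [float(length)]])
            seg = np.diff(edges)
            first = int(vals[0])
            # segments alternate starting from the origin at the first marker
            share0 = seg[0::2].sum() if first == 0 else seg[1::2].sum()
            p = float(share0 / length)
        else:
            raise ValueError(f"unknown p_mode {p_mode!r}")
        p_k[chrom] = p
        rbar += 2.0 * p * (1.0 - p) * L[chrom] ** 2
    return rbar, p_k, covered


def compute_phenotypes(
    vectors: list[OriginVector],
    genome: GenomeSpec,
    panel: MarkerPanel,
    min_support: int = 3,
    p_mode: str = "physical",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-meiosis phenotype table + crossover-event table for a gamete set."""
    pheno_rows = []
    event_rows = []
    for v in vectors:
        cleaned, events = detect_crossovers(v, panel, min_support)
        cc, per_chrom = crossover_count(events)
        rbar, p_k, covered = shuffling_rbar(cleaned, genome, panel, events, p_mode)
        pheno_rows.append(
            {
                "fid": v.fid,
                "offspring": v.offspring_id,
                "parent_sex": v.parent_sex,
                "cc": cc,
                "rbar": rbar,
                "n_chrom_covered": int(sum(covered.values())),
                "n_chrom": len(covered),
            }
        )
        for e in events:
            event_rows.append(
                {
                    "fid": e.fid,
                    "offspring": e.offspring_id,
                    "parent_sex": v.parent_sex,
                    "chrom": e.chrom,
                    "left_bp": e.left_bp,
                    "right_bp": e.right_bp,
                }
            )
    pheno = pd.DataFrame(pheno_rows)
    events_df = pd.DataFrame(
        event_rows, columns=["fid", "offspring", "parent_sex", "chrom", "left_bp", "right_bp"]
    )
    return pheno, events_df


def sex_summary(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-sex descriptive summary: N_FIDs, N_obs, mean and SD of CC and rbar."""
    if pheno.empty:
        raise ValueError("no phenotypes to summarize")
    rows = []
    for sex, grp in pheno.groupby("parent_sex"):
        rows.append(
            {
                "sex": sex,
                "n_fids": grp["fid"].nunique(),
                "n_obs": len(grp),
                "cc_mean": grp["cc"].mean(),
                "cc_sd": grp["cc"].std(ddof=1),
                "rbar_mean": grp["rbar"].mean(),
                "rbar_sd": grp["rbar"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def phenotype_table(
    vectors: list[OriginVector],
    genome: GenomeSpec,
    panel: MarkerPanel,
    min_support: int = 3,
    p_mode: str = "physical",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-meiosis TSV payload plus the per-sex summary."""
    pheno, _ = compute_phenotypes(vectors, genome, panel, min_support, p_mode)
    return pheno, sex_summary(pheno)
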