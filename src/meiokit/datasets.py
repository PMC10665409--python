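"""Bundled reference tables for Atlantic salmon recombination.

``salmon_map_table()`` is the published sex-specific linkage-map summary for
the 29 salmon autosomes (per-chromosome physical length in Mb and male/female
map lengths in cM); ``salmon_trait_table()`` is the published descriptive
summary of per-meiosis crossover count and intra-chromosomal shuffling by sex.
Both are used as worked-example inputs (aggregation checks, the chromosome
lengths of the full-scale simulator genome), not as outputs of this package.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .containers import Chromosome, GenomeSpec


def _load(name: str) -> pd.DataFrame:
    with resources.files("meiokit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def salmon_map_table() -> pd.DataFrame:
    """Per-chromosome linkage-map summary (29 rows)."""
    return _load("salmon_linkage_map.tsv")


def salmon_trait_table() -> pd.DataFrame:
    """Per-sex descriptive statistics for CC and r-bar."""
    return _load("salmon_trait_summary.tsv")


def salmon_genome(acrocentric_from: str = "ssa8") -> GenomeSpec:
    """GenomeSpec with the 29 salmon chromosome lengths.

    Centromere coordinates are not part of the bundled table; acrocentric
    chromosomes (ssa8 onwards) get a centromere at bp 0 and the remaining
    (meta/submetacentric) chromosomes a synthetic placement at 40% of their
    length, which only matters for relative-position landscape profiles.
    """
    t = salmon_map_table()
    chroms = []
    acro = False
    for row in t.itertuples():
        if row.chrom == acrocentric_from:
            acro = True
        length = int(round(row.length_mb * 1e6))
        chroms.append(
            Chromosome(
                chrom_id=row.chrom,
                length_bp=length,
                centromere_bp=0 if acro else int(0.4 * length),
                acrocentric=acro,
            )
        )
    return GenomeSpec(tuple(chroms))
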