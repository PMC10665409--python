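"""Pipeline configuration: a single YAML file, every stage parameter defaulted.

Unknown keys are rejected so typos cannot silently fall back to defaults, and
the fully resolved configuration (defaults included) is echoed to the log by
the CLI — the reproducibility contract for every run.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .containers import Chromosome, GenomeSpec, ValidationError

log = logging.getLogger("meiokit")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    preset: str = "desk"
    n_sires: int = Field(60, ge=1)
    n_dams: int = Field(60, ge=1)
    offspring_per_family: int = Field(20, ge=1)
    grandparents_genotyped: float = Field(0.0, ge=0.0, le=1.0)
    error_rate: float = Field(0.001, ge=0.0, lt=1.0)
    missing_rate: float = Field(0.003, ge=0.0, lt=1.0)


class PhaseConfig(_Strict):
    min_offspring: int = Field(4, ge=1)
    segregation_alpha: float = Field(0.01, gt=0.0, lt=1.0)


class PhenotypeConfig(_Strict):
    min_support: int = Field(3, ge=1)
    p_mode: str = "physical"  # or "marker" for marker-count-weighted p_k


class MapConfig(_Strict):
    bin_width_bp: int = Field(1_000_000, ge=1)
    n_profile_bins: int = Field(40, ge=1)


class VarcompConfig(_Strict):
    max_iter: int = Field(200, ge=1)
    tol: float = Field(1e-8, gt=0.0)


class GwasConfig(_Strict):
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    weighted: bool = True


class PipelineConfig(_Strict):
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    phase: PhaseConfig = PhaseConfig()
    phenotypes: PhenotypeConfig = PhenotypeConfig()
    map: MapConfig = MapConfig()
    varcomp: VarcompConfig = VarcompConfig()
    gwas: GwasConfig = GwasConfig()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load YAML config; ``None`` yields the full default set."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**raw)


def read_genome_table(path: str | Path) -> GenomeSpec:
    """Read a genome spec TSV with columns chrom, length_bp, centromere_bp
    and optional acrocentric (0/1)."""
    t = pd.read_csv(path, sep="\t")
    required = {"chrom", "length_bp", "centromere_bp"}
    missing = sorted(required - set(t.columns))
    if missing:
        raise ValidationError(f"genome table missing columns: {missing}")
    chroms = []
    for row in t.itertuples():
        chroms.append(
            Chromosome(
                chrom_id=str(row.chrom),
                length_bp=int(row.length_bp),
                centromere_bp=int(row.centromere_bp),
                acrocentric=bool(getattr(row, "acrocentric", True)),
            )
        )
    return GenomeSpec(tuple(chroms))


def write_genome_table(genome: GenomeSpec, path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": genome.chrom_ids,
            "length_bp": [c.length_bp for c in genome.chromosomes],
            "centromere_bp": [c.centromere_bp for c in genome.chromosomes],
            "acrocentric": [int(c.acrocentric) for c in genome.chromosomes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_tables(genome_path: str | Path, config_path: str | Path | None):
    """Read the genome spec TSV and the YAML config together."""
    genome = read_genome_table(genome_path)
    cfg = load_config(config_path)
    log.info("resolved config: %s", cfg.model_dump())
    return genome, cfg
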