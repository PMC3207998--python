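"""Pipeline configuration: every numeric threshold in one place.

Defaults are the survey's operating values: conservation cutoff
(PhastCons >= 0.57), down-regulation score cutoff (mirSVR <= -0.6), LD proxy
cutoff (r^2 > 0.8), resampling-universe MAF floor (1%), 1000 resampling
replicates, 2-SD F_ST outlier cut, a 6-base density window with 18-base
flanks, and 22-base flanks around SNPs for created-site detection.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # input/output paths (filled per run; empty = stage skipped)
    mirs_fasta: str = ""
    utrs_fasta: str = ""
    utrs_bed: str = ""
    snps_vcf: str = ""
    ld_tsv: str = ""
    catalog_tsv: str = ""
    group_freqs_tsv: str = ""
    outdir: str = "seedvar_out"

    # thresholds
    phastcons_min: float = 0.57
    mirsvr_max: float = -0.6
    r2_min: float = 0.8
    maf_min: float = 0.01
    score_min: float = 70.0
    energy_max: float = -20.0
    reps: int = 1000
    outlier_k: float = 2.0
    window: int = 6
    flank: int = 18
    cnm_flank: int = 22

    rng_seed: int = 0
    # population label -> VCF INFO key holding that population's allele freq
    pop_af_keys: Mapping[str, str] = field(
        default_factory=lambda: {
            "AFR": "AF_AFR", "ASN": "AF_ASN", "EUR": "AF_EUR", "AMR": "AF_AMR"
        }
    )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
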