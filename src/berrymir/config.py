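"""Simulation configuration.

A :class:`SimulationConfig` fixes every tunable of the synthetic dataset:
genome size and base composition, how many miRNA hairpins are planted and
with how many duplex defects, sequencing depth and noise for the small-RNA
library, and the shape of the toy annotation (genes, isoforms, UTRs,
tissues). Identical config + seed always produces byte-identical output
files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    n_chromosomes: int = 3
    chrom_length: int = 50_000
    gc_fraction: float = 0.39  # woodland strawberry genome is AT rich
    # planted miRNA loci
    n_true_mirnas: int = 20
    mature_length: int = 21
    loop_length: int = 15
    star_mispairings: int = 0
    star_bulges: int = 0
    conserved_fraction: float = 0.5
    # sRNA library
    read_depth: int = 10_000
    noise_fraction: float = 0.2
    low_quality_fraction: float = 0.05
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    abundance_ratio: float = 0.8
    # annotation / expression
    n_genes: int = 50
    n_tissues: int = 46
    planted_target_fraction: float = 0.3
    utr_fraction: float = 0.8
    isoform_fraction: float = 0.3
    expressed_fraction: float = 0.8
    # degradome
    degradome_reads_per_site: int = 5
    degradome_noise_tags: int = 50

    def __post_init__(self) -> None:
        counts = (
            "seed n_chromosomes chrom_length n_true_mirnas mature_length "
            "loop_length star_mispairings star_bulges read_depth n_genes "
            "n_tissues degradome_reads_per_site degradome_noise_tags"
        ).split()
        for name in counts:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        fracs = (
            "gc_fraction noise_fraction low_quality_fraction conserved_fraction "
            "planted_target_fraction utr_fraction isoform_fraction "
            "expressed_fraction"
        ).split()
        for name in fracs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 20 <= self.mature_length <= 22:
            raise ConfigurationError("mature_length must be in [20, 22]")
        if not 0.0 < self.abundance_ratio <= 1.0:
            raise ConfigurationError("abundance_ratio must be in (0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
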