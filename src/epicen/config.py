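"""Simulation configuration shared across the synthetic-data generators."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimulationConfig", "stream"]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic genome and its readouts.

    The defaults encode the design the analyses assume: 100 scored mitotic
    cells per genotype, 30 chromocenters per immunofluorescence group, and
    suppressor segregant pools of 15 suppressors vs 45 non-suppressors.
    Crossover rates are expected counts per chromosome per meiosis, with the
    centromeric rate well below the arm rate.
    """

    seed: int = 0
    n_chromosomes: int = 5
    chrom_length: int = 50_000
    coverage_mean: float = 20.0
    n_recombinant_lines: int = 20
    crossover_rate_arm: float = 1.0
    crossover_rate_centromere: float = 0.1
    n_cells_scored: int = 100
    n_chromocenters: int = 30
    suppressor_pool_sizes: tuple[int, int] = (15, 45)

    def __post_init__(self) -> None:
        if self.crossover_rate_centromere >= self.crossover_rate_arm:
            raise ValueError(
                "crossover_rate_centromere must be below crossover_rate_arm"
            )
        for name in (
            "n_chromosomes",
            "chrom_length",
            "n_recombinant_lines",
            "n_cells_scored",
            "n_chromocenters",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(n <= 0 for n in self.suppressor_pool_sizes):
            raise ValueError("suppressor pool sizes must be positive")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")


def stream(seed: int, *keys: object) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a root seed.

    Each generator operation draws from its own named stream so that modules
    are reproducible independently of call order.
    """

    entropy = [int(seed) & 0x7FFFFFFF]
    for key in keys:
        entropy.append(zlib.crc32(str(key).encode()))
    return np.random.default_rng(entropy)
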