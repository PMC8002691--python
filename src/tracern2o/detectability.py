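"""Expected recovery of a single-copy fungal gene from a shotgun metagenome.

Whether a diagnostic gene such as the fungal nitric oxide reductase
(P450nor) can be expected in a metagenome is a sequencing-depth question:
with a fungal community contributing a small fraction of all classifiable
reads, the number of reads landing on one particular gene in one fungal
genome is Poisson with mean

    λ = total_reads × fungal_fraction × copies_per_genome
        × gene_length / genome_size,

and the probability of recovering at least one read is 1 − e^(−λ). This is
the read-level approximation (a read "hits" iff its start lies in the
gene); passing a read length switches the hit window to
gene_length + read_length − 1, counting any overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import DomainError


@dataclass(frozen=True)
class DetectabilityInputs:
    """Sequencing depth and genome/gene geometry for one sample."""

    total_reads: int
    fungal_fraction: float
    genome_size_bp: float = 30e6  # typical fungal genome
    gene_length_bp: float = 1500.0  # typical P450 ORF
    copies_per_genome: int = 1

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise DomainError(f"total_reads must be > 0, got {self.total_reads}")
        if not (0.0 <= self.fungal_fraction <= 1.0):
            raise DomainError(
                f"fungal_fraction must be in [0, 1], got {self.fungal_fraction}"
            )
        if self.genome_size_bp <= 0:
            raise DomainError("genome_size_bp must be > 0")
        if not (0 < self.gene_length_bp <= self.genome_size_bp):
            raise DomainError(
                f"gene_length_bp must be in (0, genome_size_bp], got "
                f"{self.gene_length_bp}"
            )
        if self.copies_per_genome <= 0:
            raise DomainError("copies_per_genome must be > 0")


@dataclass(frozen=True)
class DetectabilityResult:
    expected_reads: float  # Poisson mean λ
    p_at_least_one: float  # 1 − exp(−λ)


def expected_gene_reads(
    d: DetectabilityInputs, read_length_bp: Optional[float] = None
) -> DetectabilityResult:
    """Expected gene-read count λ and P(≥1 read) under Poisson sampling."""
    window = d.gene_length_bp
    if read_length_bp is not None:
        if read_length_bp <= 0:
            raise DomainError(f"read_length_bp must be > 0, got {read_length_bp}")
        window = d.gene_length_bp + read_length_bp - 1.0
    lam = (
        d.total_reads
        * d.fungal_fraction
        * d.copies_per_genome
        * window
        / d.genome_size_bp
    )
    return DetectabilityResult(expected_reads=lam, p_at_least_one=-math.expm1(-lam))
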