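"""Cellular RNA mass bookkeeping.

Back-of-the-envelope but load-bearing arithmetic: how much RNA a read of a
given length represents, how many reads are needed to sequence through the
whole RNA pool of one cell, and what fraction of the non-ribosomal,
non-mitochondrial RNA a polyA selection actually captures. A mammalian
cell holds ~20 pg of total RNA, of which only ~6% (range 4-8%) is
non-ribosomal, non-mitochondrial; a typical polyA selection yields 1-2% of
the input mass, about half of which is still ribosomal or mitochondrial.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

AVOGADRO = 6.02214076e23

#: Mean residue mass (g/mol) of an internal ribonucleotide monophosphate;
#: reproduces ~2e-20 g for a 35-base read at one significant figure.
DEFAULT_RESIDUE_MASS = 340.0


@dataclass(frozen=True)
class CellRnaModel:
    """Parameters of the per-cell RNA budget (all masses in grams)."""

    total_rna_g: float = 20e-12
    informative_fraction: float = 0.06
    informative_fraction_range: Tuple[float, float] = (0.04, 0.08)
    mean_read_length: float = 35.0
    residue_mass: float = DEFAULT_RESIDUE_MASS
    polya_yield_range: Tuple[float, float] = (0.01, 0.02)
    polya_contamination: float = 0.5

    def __post_init__(self) -> None:
        if self.total_rna_g <= 0 or self.mean_read_length <= 0 or self.residue_mass <= 0:
            raise ValueError("masses and lengths must be positive")
        for frac in (
            self.informative_fraction,
            *self.informative_fraction_range,
            *self.polya_yield_range,
        ):
            if not (0 < frac < 1):
                raise ValueError("fractions must lie in (0, 1)")
        if not (0 <= self.polya_contamination <= 1):
            raise ValueError("polya_contamination must lie in [0, 1]")


def read_mass(length_nt: float, residue_mass: float = DEFAULT_RESIDUE_MASS) -> float:
    """Mass in grams of an RNA molecule of ``length_nt`` residues."""
    if length_nt < 0:
        raise ValueError("length must be >= 0")
    return length_nt * residue_mass / AVOGADRO


def reads_needed(model: CellRnaModel = CellRnaModel()) -> float:
    """Reads required to sequence through one cell's whole RNA pool.

    The informative (non-ribosomal, non-mitochondrial) fraction cannot be
    physically pre-selected without loss, so the divisor is the *total*
    undepleted RNA mass: 20 pg / 2e-20 g per read = ~1e9 reads, comfortably
    above a hundred million.
    """
    per_read = read_mass(model.mean_read_length, model.residue_mass)
    if per_read == 0:
        raise ValueError("read mass is zero")
    return model.total_rna_g / per_read


def informative_reads_among(model: CellRnaModel = CellRnaModel()) -> float:
    """Of the reads_needed total, how many would be informative."""
    return reads_needed(model) * model.informative_fraction


def polya_informative_fraction(
    model: CellRnaModel = CellRnaModel(),
) -> Tuple[float, float]:
    """Bounds on the share of informative RNA captured by polyA selection.

    fraction = polyA yield x (1 - contamination) / informative fraction,
    evaluated at the extreme pairings: (min yield, max informative
    fraction) for the lower bound and (max yield, min informative
    fraction) for the upper. Defaults give (6.25%, 25%).
    """
    clean = 1.0 - model.polya_contamination
    lo = model.polya_yield_range[0] * clean / model.informative_fraction_range[1]
    hi = model.polya_yield_range[1] * clean / model.informative_fraction_range[0]
    return lo, hi
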