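"""Screen-design planning arithmetic.

Before a pooled screen is run, the wet-lab scale follows from three
numbers: the pool size (distinct shRNAs), the representation to maintain
(infected cells per shRNA — 1,000 is a robust choice for depletion and
enrichment detection), and the multiplicity of infection (kept <= 1,
typically 0.7, to limit multiple integrations per cell). From these:

    infected_cells  = n_shRNA * representation
    maintained_cells = infected_cells / MOI   (cells to keep in culture)
    dna_mass        = infected_cells * 6 pg   (diploid human genomic DNA)
    n_pcr           = ceil(dna_mass / 2 ug)   (parallel PCRs at 2 ug each)

For the standard 10,000-shRNA pool at representation 1,000 and MOI 0.7
this gives 1e7 infected cells, ~1.43e7 maintained cells, 60 ug genomic
DNA, and 30 parallel PCR reactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

DNA_PG_PER_CELL = 6.0     # diploid human genomic DNA content, pg
UG_PER_PCR = 2.0          # genomic DNA input per PCR reaction, ug


@dataclass(frozen=True)
class DesignPlan:
    n_shrna: int
    representation: float     # cells per shRNA
    moi: float
    infected_cells: float
    maintained_cells: float
    dna_mass_ug: float
    n_pcr: int


def plan_screen(n_shrna: int, representation: float, moi: float) -> DesignPlan:
    """Derive cell numbers, DNA mass, and PCR count for a pooled screen."""
    if n_shrna <= 0 or representation <= 0 or moi <= 0:
        raise ValueError("all planning inputs must be positive")
    if moi > 1:
        raise ValueError("MOI > 1 (multi-integration planning) is unsupported")
    infected = n_shrna * representation
    maintained = infected / moi
    dna_ug = infected * DNA_PG_PER_CELL * 1e-6  # pg -> ug
    n_pcr = math.ceil(dna_ug / UG_PER_PCR)
    return DesignPlan(
        n_shrna=n_shrna,
        representation=representation,
        moi=moi,
        infected_cells=infected,
        maintained_cells=maintained,
        dna_mass_ug=dna_ug,
        n_pcr=n_pcr,
    )
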