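"""Canonical state-vector layout for the single-cell Delta1/Notch1 network.

The model tracks five genes (hes1, rbpj, notch1, mash1, hes6), each with a
two-compartment mRNA/protein chain, plus two heterodimer pools, two NICD
pools and the nuclear NICD-RBPJ (NRB) complex: 25 components in total.
The ordering defined here is used everywhere (integration, CSV output,
plotting, tests) and must never change silently.
"""

from __future__ import annotations

GENES: tuple[str, ...] = ("hes1", "rbpj", "notch1", "mash1", "hes6")

#: per-gene compartments, in chain order (transcription -> export ->
#: translation -> nuclear import)
_GENE_SUFFIXES: tuple[str, ...] = ("mrna_nuc", "mrna_cyt", "prot_cyt", "prot_nuc")

#: the 25 named components, canonical order
SPECIES: tuple[str, ...] = tuple(
    f"{g}_{s}" for g in GENES for s in _GENE_SUFFIXES
) + (
    "dimer_hes1_hes6",
    "dimer_mash1_e47",
    "nicd_cyt",
    "nicd_nuc",
    "nrb",
)

N_SPECIES: int = len(SPECIES)
assert N_SPECIES == 25

SPECIES_INDEX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

# convenience index helpers ------------------------------------------------


def gene_index(gene: str) -> int:
    """Position of ``gene`` in the canonical gene ordering."""
    try:
        return GENES.index(gene)
    except ValueError:
        raise KeyError(f"unknown gene {gene!r}; expected one of {GENES}") from None


def mrna_nuc(gene: str) -> int:
    return 4 * gene_index(gene)


def mrna_cyt(gene: str) -> int:
    return 4 * gene_index(gene) + 1


def prot_cyt(gene: str) -> int:
    return 4 * gene_index(gene) + 2


def prot_nuc(gene: str) -> int:
    return 4 * gene_index(gene) + 3


DIMER_HES1_HES6 = SPECIES_INDEX["dimer_hes1_hes6"]
DIMER_MASH1_E47 = SPECIES_INDEX["dimer_mash1_e47"]
NICD_CYT = SPECIES_INDEX["nicd_cyt"]
NICD_NUC = SPECIES_INDEX["nicd_nuc"]
NRB = SPECIES_INDEX["nrb"]
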