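"""Regulatory wiring of the five-gene network, as data.

The wiring (which nuclear species represses or activates which gene,
through how many binding sites, binding as monomer or dimer, and how many
RBPJ sites carry NRB activation) is loaded from a JSON document rather
than hard-coded, so alternative Hill-constant assignments and activation
forms can be tested without touching the right-hand side.

The default wiring encodes: hes1 repressed by Hes1 dimers at 3 N boxes
and by free RBPJ at 2 RBPJ sites; rbpj by Hes1 dimers (3 N boxes) and
itself (3 RBPJ sites); notch1 by Hes1 dimers (1 N box) and RBPJ (2
sites); mash1 by Hes1 dimers (1 N box) with the Hes1 dominant-negative
attenuation of Mash1-E47 formation; hes6 activated only through the
Mash1-E47 E-box term.  NRB activation multiplies transcription by
``1 + sites * [NRB]`` while a delta signal is present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .parameters import PARAM_INDEX
from .species import DIMER_MASH1_E47, GENES, SPECIES_INDEX

__all__ = ["HillTerm", "EBoxTerm", "GeneRegulation", "Wiring", "default_wiring"]

#: supported E-box activation compositions:
#:   "gated"  -- transcription multiplied by D^g / (H^g + D^g) (no basal
#:               transcription without activator);
#:   "basal"  -- multiplied by 1 + D^g / (H^g + D^g) (basal rate retained,
#:               activator up to doubles it).
EBOX_MODES = ("gated", "basal")


@dataclass(frozen=True)
class HillTerm:
    """One repressive generalised-Hill factor H^(n*h)/(H^(n*h)+x^(n*h)).

    ``h`` counts binding sites; ``n`` is 2 when the repressor binds as a
    dimer and 1 when it binds as a monomer, so the effective exponent is
    ``n*h``.
    """

    regulator: str  # species name (nuclear protein pool)
    H: str  # parameter key of the Hill constant
    h: int
    n: int

    def __post_init__(self) -> None:
        if self.regulator not in SPECIES_INDEX:
            raise ValueError(f"unknown regulator species {self.regulator!r}")
        if self.H not in PARAM_INDEX:
            raise ValueError(f"unknown Hill-constant key {self.H!r}")
        if self.h < 1:
            raise ValueError("h (binding sites) must be >= 1")
        if self.n not in (1, 2):
            raise ValueError("n (stoichiometry) must be 1 or 2")


@dataclass(frozen=True)
class EBoxTerm:
    """Mash1-E47 activation at an E box: ``act = D^g/(H^g + D^g)``.

    ``mode`` selects the composition for this gene ("gated": multiply by
    ``act``; "basal": multiply by ``1 + act``); ``None`` inherits the
    wiring-level default.
    """

    H: str
    g: int = 1
    mode: str | None = None

    def __post_init__(self) -> None:
        if self.H not in PARAM_INDEX:
            raise ValueError(f"unknown Hill-constant key {self.H!r}")
        if self.g < 1:
            raise ValueError("g must be >= 1")
        if self.mode is not None and self.mode not in EBOX_MODES:
            raise ValueError(f"ebox mode must be one of {EBOX_MODES}")


@dataclass(frozen=True)
class GeneRegulation:
    gene: str
    k0: str
    repressors: tuple[HillTerm, ...] = ()
    rbp_site_count: int = 0
    ebox: EBoxTerm | None = None
    dominant_negative: bool = False

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"unknown gene {self.gene!r}")
        if self.k0 not in PARAM_INDEX:
            raise ValueError(f"unknown transcription-constant key {self.k0!r}")
        if self.rbp_site_count < 0:
            raise ValueError("rbp_site_count must be >= 0")


@dataclass(frozen=True)
class Wiring:
    """Complete regulatory map plus numeric arrays for the ODE kernel.

    ``h16_returns_monomers`` selects the Hes1-Hes6 dissociation
    convention: True returns both monomers to their free nuclear pools
    (reversible reservoir); False treats sequestration as terminal
    (the dimer constituents are degraded, as for Mash1 in Mash1-E47).
    """

    genes: tuple[GeneRegulation, ...]
    ebox_mode: str = "basal"
    h16_returns_monomers: bool = True
    h16_compartment: str = "nuclear"  # where Hes1-Hes6 dimerisation drains monomers
    _arrays: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.ebox_mode not in EBOX_MODES:
            raise ValueError(f"ebox_mode must be one of {EBOX_MODES}")
        if self.h16_compartment not in ("nuclear", "cytoplasmic"):
            raise ValueError("h16_compartment must be 'nuclear' or 'cytoplasmic'")
        if tuple(g.gene for g in self.genes) != GENES:
            raise ValueError(f"wiring must define all genes in order {GENES}")
        self._arrays.update(self._compile())

    def regulation(self, gene: str) -> GeneRegulation:
        for g in self.genes:
            if g.gene == gene:
                return g
        raise KeyError(gene)

    def _compile(self) -> dict:
        """Flatten the wiring into arrays consumed by the numba kernel."""
        rep_gene, rep_reg, rep_H, rep_h, rep_n = [], [], [], [], []
        k0_idx = np.zeros(len(GENES), dtype=np.int64)
        nrb_sites = np.zeros(len(GENES), dtype=np.float64)
        ebox_H = np.full(len(GENES), -1, dtype=np.int64)
        ebox_g = np.zeros(len(GENES), dtype=np.int64)
        ebox_basal = np.zeros(len(GENES), dtype=np.bool_)
        domneg = np.zeros(len(GENES), dtype=np.bool_)
        for gi, reg in enumerate(self.genes):
            k0_idx[gi] = PARAM_INDEX[reg.k0]
            nrb_sites[gi] = reg.rbp_site_count
            domneg[gi] = reg.dominant_negative
            if reg.ebox is not None:
                ebox_H[gi] = PARAM_INDEX[reg.ebox.H]
                ebox_g[gi] = reg.ebox.g
                ebox_basal[gi] = self.ebox_mode_for(reg.gene) == "basal"
            for term in reg.repressors:
                rep_gene.append(gi)
                rep_reg.append(SPECIES_INDEX[term.regulator])
                rep_H.append(PARAM_INDEX[term.H])
                rep_h.append(term.h)
                rep_n.append(term.n)
        return {
            "rep_gene": np.array(rep_gene, dtype=np.int64),
            "rep_reg": np.array(rep_reg, dtype=np.int64),
            "rep_H": np.array(rep_H, dtype=np.int64),
            "rep_nh": np.array(rep_h, dtype=np.float64)
            * np.array(rep_n, dtype=np.float64),
            "k0_idx": k0_idx,
            "nrb_sites": nrb_sites,
            "ebox_H": ebox_H,
            "ebox_g": ebox_g,
            "domneg": domneg,
            "ebox_basal": ebox_basal,
            "h16_return": np.bool_(self.h16_returns_monomers),
            "h16_nuclear": np.bool_(self.h16_compartment == "nuclear"),
            "dme_index": np.int64(DIMER_MASH1_E47),
        }

    def ebox_mode_for(self, gene: str) -> str:
        """Effective E-box composition for a gene (term override or the
        wiring default)."""
        reg = self.regulation(gene)
        if reg.ebox is None:
            raise ValueError(f"gene {gene!r} has no E-box term")
        return reg.ebox.mode or self.ebox_mode

    @property
    def arrays(self) -> dict:
        return self._arrays

    # ---- (de)serialisation ----

    @classmethod
    def from_dict(cls, doc: dict) -> "Wiring":
        genes = []
        for name in GENES:
            spec = doc["genes"][name]
            ebox = spec.get("ebox")
            genes.append(
                GeneRegulation(
                    gene=name,
                    k0=spec["k0"],
                    repressors=tuple(
                        HillTerm(
                            regulator=t["regulator"],
                            H=t["H"],
                            h=int(t["h"]),
                            n=int(t["n"]),
                        )
                        for t in spec.get("repressors", ())
                    ),
                    rbp_site_count=int(spec.get("rbp_site_count", 0)),
                    ebox=EBoxTerm(
                        H=ebox["H"], g=int(ebox.get("g", 1)), mode=ebox.get("mode")
                    )
                    if ebox
                    else None,
                    dominant_negative=bool(spec.get("dominant_negative", False)),
                )
            )
        return cls(
            genes=tuple(genes),
            ebox_mode=doc.get("ebox_mode", "basal"),
            h16_returns_monomers=doc.get("h16_returns_monomers", True),
            h16_compartment=doc.get("h16_compartment", "nuclear"),
        )

    def to_dict(self) -> dict:
        return {
            "ebox_mode": self.ebox_mode,
            "h16_returns_monomers": self.h16_returns_monomers,
            "h16_compartment": self.h16_compartment,
            "genes": {
                g.gene: {
                    "k0": g.k0,
                    "repressors": [
                        {"regulator": t.regulator, "H": t.H, "h": t.h, "n": t.n}
                        for t in g.repressors
                    ],
                    "rbp_site_count": g.rbp_site_count,
                    **(
                        {
                            "ebox": {
                                "H": g.ebox.H,
                                "g": g.ebox.g,
                                **({"mode": g.ebox.mode} if g.ebox.mode else {}),
                            }
                        }
                        if g.ebox
                        else {}
                    ),
                    **({"dominant_negative": True} if g.dominant_negative else {}),
                }
                for g in self.genes
            },
        }

    @classmethod
    def load(cls, path: str | Path) -> "Wiring":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def default_wiring() -> Wiring:
    """The packaged default wiring (see module docstring)."""
    text = resources.files("notchfate.data").joinpath("wiring.json").read_text()
    return Wiring.from_dict(json.loads(text))
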