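"""Parameter sets for the Delta1/Notch1 model.

Thirty-one constants are calibrated (degradation, dissociation,
transcription, translation and Hill constants); a further block of
constants is held fixed (compartment transfer rates, NICD kinetics, the
E47 pool).  Keys follow the symbol names used in the model's parameter
tables, e.g. ``"k_d,HRN"`` for the hes1 mRNA degradation rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "FREE_PARAMETERS",
    "FIXED_PARAMETERS",
    "ParameterSet",
    "ParameterSpace",
    "table1_parameters",
    "table2_parameters",
]

#: the 31 calibrated parameters, in the canonical (printed-table) order
FREE_PARAMETERS: tuple[str, ...] = (
    "k_d,HRN",
    "k_d,RRN",
    "k_d,NRN",
    "k_d,MRN",
    "k_d,H6RN",
    "k_d,HES1",
    "k_d,RBP",
    "k_d,NOTCH",
    "k_d,MASH1",
    "k_d,HES6",
    "k_d,[M-E47]",
    "k_d,HES1,6",
    "k_d,NRB",
    "k_dom,neg",
    "k_0,HES1",
    "k_0,RBP-J",
    "k_0,NOTCH1",
    "k_0,MASH1",
    "k_0,[M-E47]",
    "k_0,HES6",
    "k_0,HES1,6",
    "c_HES1",
    "c_RBP-J",
    "c_NOTCH1",
    "c_MASH1",
    "c_HES6",
    "H_HES1",
    "H_RBP-J",
    "K_HES1",
    "H_MASH1",
    "H_HES6",
)

#: constants excluded from calibration (min^-1 unless noted).  k_NICD and
#: k_NICD,import are the Vmax of NICD generation and of its saturating
#: nuclear import; neither has a literature value, so both default to the
#: same order of magnitude as the NRB formation constant.
FIXED_PARAMETERS: Mapping[str, float] = {
    "a_mRNA": 0.05,
    "b_prot": 0.05,
    "k_d,NICD": 0.0385,
    "k_0,Nicd-RBP": 0.1,
    "K_NICD": 1.0,
    "K_RBP-J": 1.0,
    "k_NICD": 0.1,
    "E47_total": 1.0,
    "k_NICD,import": 0.1,
}

ALL_PARAMETERS: tuple[str, ...] = FREE_PARAMETERS + tuple(FIXED_PARAMETERS)
PARAM_INDEX: dict[str, int] = {name: i for i, name in enumerate(ALL_PARAMETERS)}
N_FREE = len(FREE_PARAMETERS)


def _load_packaged(name: str) -> dict[str, float]:
    text = resources.files("notchfate.data").joinpath(name).read_text()
    return {str(k): float(v) for k, v in json.loads(text).items()}


@dataclass(frozen=True)
class ParameterSet:
    """Immutable named map of all model constants (free + fixed).

    Missing fixed constants are filled from :data:`FIXED_PARAMETERS`.
    """

    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(FIXED_PARAMETERS)
        merged.update(self.values)
        missing = [k for k in FREE_PARAMETERS if k not in merged]
        if missing:
            raise ValueError(f"parameter set is missing {missing}")
        unknown = [k for k in merged if k not in PARAM_INDEX]
        if unknown:
            raise ValueError(f"unknown parameter names {unknown}")
        bad = [k for k, v in merged.items() if not np.isfinite(v) or v < 0]
        if bad:
            raise ValueError(f"non-finite or negative parameter values for {bad}")
        object.__setattr__(self, "values", merged)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def __iter__(self) -> Iterator[str]:
        return iter(ALL_PARAMETERS)

    def replace(self, **updates: float) -> "ParameterSet":
        """Return a copy with named values replaced (``k_d,HRN`` etc. are
        not valid python identifiers, so use ``replace_named`` for those)."""
        return self.replace_named(updates)

    def replace_named(self, updates: Mapping[str, float]) -> "ParameterSet":
        merged = dict(self.values)
        for k, v in updates.items():
            if k not in PARAM_INDEX:
                raise KeyError(f"unknown parameter {k!r}")
            merged[k] = float(v)
        return ParameterSet(merged)

    def to_vector(self) -> np.ndarray:
        """Full numeric vector in canonical ``ALL_PARAMETERS`` order."""
        return np.array([self.values[k] for k in ALL_PARAMETERS], dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ParameterSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(ALL_PARAMETERS),):
            raise ValueError(f"expected vector of length {len(ALL_PARAMETERS)}")
        return cls(dict(zip(ALL_PARAMETERS, vec.tolist())))

    def free_vector(self) -> np.ndarray:
        return np.array([self.values[k] for k in FREE_PARAMETERS], dtype=float)

    def with_free_vector(self, free: np.ndarray) -> "ParameterSet":
        free = np.asarray(free, dtype=float)
        if free.shape != (N_FREE,):
            raise ValueError(f"expected {N_FREE} free parameters")
        return self.replace_named(dict(zip(FREE_PARAMETERS, free.tolist())))

    # ---- round-trippable flat file format (JSON key/value map) ----

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: self.values[k] for k in ALL_PARAMETERS}, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSet":
        return cls({k: float(v) for k, v in json.loads(Path(path).read_text()).items()})

    def to_dict(self) -> dict[str, float]:
        return {k: self.values[k] for k in ALL_PARAMETERS}


def table1_parameters() -> ParameterSet:
    """The initial (literature / order-of-magnitude) parameter values."""
    return ParameterSet(_load_packaged("table1.json"))


def table2_parameters() -> ParameterSet:
    """The calibrated optimum of the qualitative-cost Sobol search."""
    return ParameterSet(_load_packaged("table2.json"))


@dataclass(frozen=True)
class ParameterSpace:
    """The 31-dimensional hypercube searched during calibration / GSA.

    Bounds are ``center * (1 +/- span)`` per coordinate (default span 0.9,
    i.e. +/-90% of the center value).
    """

    center: ParameterSet
    span: float = 0.9
    names: tuple[str, ...] = FREE_PARAMETERS

    def __post_init__(self) -> None:
        if not 0 < self.span < 1:
            raise ValueError("span must be in (0, 1) so bounds stay positive")

    @property
    def dimension(self) -> int:
        return len(self.names)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.array([self.center[k] for k in self.names])
        return c * (1.0 - self.span), c * (1.0 + self.span)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Affinely map points in [0,1]^d to the hypercube."""
        lo, hi = self.bounds()
        return lo + np.asarray(u, dtype=float) * (hi - lo)

    def contains(self, x: np.ndarray) -> bool:
        lo, hi = self.bounds()
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= lo - 1e-12) and np.all(x <= hi + 1e-12))

    def parameter_set(self, x: np.ndarray) -> ParameterSet:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dimension,):
            raise ValueError(f"expected point of dimension {self.dimension}")
        return self.center.replace_named(dict(zip(self.names, x.tolist())))
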