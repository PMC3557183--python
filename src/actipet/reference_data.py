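"""Physical constants and tissue-composition reference tables.

High-energy photon beams (above the ~15–18 MeV photoneutron threshold)
activate the light elements of tissue through (γ,n) reactions:
¹²C → ¹¹C, ¹⁶O → ¹⁵O, ¹⁴N → ¹³N.  This module bundles the physical
half-lives of those products (plus the bone-relevant ³⁰P and ³⁹Ca used as
simulator stress components) and the elemental mass fractions of the two
reference tissues the package compares against.

Fractions are unit fractions (0..1) everywhere inside the package; percent
appears only at I/O boundaries.  "Hydrogen-adjusted" compositions drop ¹H
(which yields no positron emitter) and every trace element, renormalizing
C, N and O to sum to one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator, Mapping

import yaml

__all__ = [
    "Nuclide",
    "NuclideTable",
    "CompositionTable",
    "get_nuclide",
    "get_adjusted_composition",
    "get_raw_composition",
    "default_nuclide_table",
    "BUNDLED_TISSUES",
]

#: Elements whose (γ,n) products are positron emitters followed here.
ACTIVATABLE_ELEMENTS = ("C", "O", "N")


@dataclass(frozen=True)
class Nuclide:
    """A positron-emitting activation product.

    Parameters
    ----------
    symbol : str
        Nuclide symbol, e.g. ``"C11"``.
    half_life : float
        Physical half-life in minutes; strictly positive.
    parent_element : str
        Element symbol of the stable parent, e.g. ``"C"``.
    reaction : str
        Production channel, e.g. ``"(g,n)"``.
    """

    symbol: str
    half_life: float
    parent_element: str
    reaction: str = "(g,n)"

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise ValueError(
                f"half_life must be > 0, got {self.half_life!r} for {self.symbol}"
            )


@dataclass(frozen=True)
class NuclideTable:
    """Lookup table of :class:`Nuclide` entries with unique symbols."""

    entries: tuple[Nuclide, ...]

    def __post_init__(self) -> None:
        symbols = [n.symbol for n in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate nuclide symbols in table")

    def __iter__(self) -> Iterator[Nuclide]:
        return iter(self.entries)

    def get(self, symbol: str) -> Nuclide:
        for n in self.entries:
            if n.symbol == symbol:
                return n
        raise KeyError(f"unknown nuclide symbol: {symbol!r}")

    def by_parent(self, element: str) -> Nuclide:
        for n in self.entries:
            if n.parent_element == element:
                return n
        raise KeyError(f"no nuclide with parent element {element!r}")


@dataclass(frozen=True)
class CompositionTable:
    """Elemental mass fractions of one tissue.

    ``fractions`` maps element symbol to a unit mass fraction.  ``adjusted``
    marks a hydrogen-omitted table, which contains only C, N and O and sums
    to 1 (within print rounding when built from rounded percentages).
    """

    tissue_name: str
    fractions: Mapping[str, float] = field(default_factory=dict)
    adjusted: bool = False

    def __post_init__(self) -> None:
        for el, f in self.fractions.items():
            if f < 0:
                raise ValueError(f"negative fraction for {el}: {f}")
        if self.adjusted:
            extra = set(self.fractions) - set(ACTIVATABLE_ELEMENTS)
            if extra:
                raise ValueError(f"adjusted table has non-CNO elements: {extra}")
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 0.005:
                raise ValueError(
                    f"adjusted fractions sum to {total:.4f}, expected 1 within 0.5%"
                )

    def as_percent(self) -> Dict[str, float]:
        """Fractions expressed in percent (I/O convenience)."""
        return {el: 100.0 * f for el, f in self.fractions.items()}


def _load_nuclide_table() -> NuclideTable:
    text = resources.files("actipet.data").joinpath("nuclides.tsv").read_text()
    rows = []
    for rec in csv.reader(
        (ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")),
        delimiter="\t",
    ):
        symbol, half_life, parent, reaction = rec
        rows.append(Nuclide(symbol, float(half_life), parent, reaction))
    return NuclideTable(tuple(rows))


def _load_raw_compositions() -> Dict[str, CompositionTable]:
    text = resources.files("actipet.data").joinpath("compositions.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: CompositionTable(name, dict(fractions), adjusted=False)
        for name, fractions in raw.items()
    }


_NUCLIDES = _load_nuclide_table()
_RAW_COMPOSITIONS = _load_raw_compositions()

#: Names of the tissues shipped with the package.
BUNDLED_TISSUES = tuple(sorted(_RAW_COMPOSITIONS))


def default_nuclide_table() -> NuclideTable:
    """The bundled table of activation products."""
    return _NUCLIDES


def get_nuclide(symbol: str) -> Nuclide:
    """Look up a bundled nuclide by symbol (e.g. ``"O15"`` → T½ 2.04 min)."""
    return _NUCLIDES.get(symbol)


def get_raw_composition(tissue: str) -> CompositionTable:
    """Bundled raw (unadjusted) C/N/O mass fractions for ``tissue``."""
    try:
        return _RAW_COMPOSITIONS[tissue]
    except KeyError:
        raise KeyError(
            f"unknown tissue {tissue!r}; bundled tissues: {BUNDLED_TISSUES}"
        ) from None


def get_adjusted_composition(tissue: str) -> CompositionTable:
    """Hydrogen-adjusted C/N/O composition for a bundled tissue.

    The adjustment renormalizes the C, N and O mass fractions over their sum,
    discarding hydrogen and trace elements — the convention used when
    comparing activation-derived count-rate fractions to tabulated tissue
    compositions.
    """
    from .composition import h_adjust  # local import: avoid cycle at import time

    return h_adjust(get_raw_composition(tissue))
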