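"""Tissue composition from fitted count-rate fractions.

Because each activation product descends from exactly one tissue element
(¹¹C ← C, ¹⁵O ← O, ¹³N ← N) and hydrogen yields no positron emitter, the
normalized count-rate fractions of a fitted TAC can be read as elemental
fractions of the hydrogen-omitted tissue and compared directly against
adjusted reference compositions.  The identification assumes equal
activation yield per unit mass for every element; optional per-element
yield weights relax this without asserting particular values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np

from .fitting import FitResult
from .reference_data import (
    ACTIVATABLE_ELEMENTS,
    CompositionTable,
    NuclideTable,
    default_nuclide_table,
    get_adjusted_composition,
)

__all__ = [
    "CompositionComparison",
    "h_adjust",
    "fractions_to_composition",
    "label_half_life",
    "compare_to_reference",
    "HALF_LIFE_LABEL_TOLERANCE",
]

#: Relative tolerance for claiming a nuclide label from a fitted half-life.
#: Wide enough that measured values like 19.4 or 20.9 min label as ¹¹C and
#: 1.99 or 2.01 min as ¹⁵O; a 2.5-min ³⁰P component also falls in the ¹⁵O
#: window — physically the two are not distinguishable on this protocol.
HALF_LIFE_LABEL_TOLERANCE = 0.35


@dataclass(frozen=True)
class CompositionComparison:
    """Fitted vs reference elemental fractions for one tissue (descriptive:
    no accept/reject verdict is attached)."""

    tissue_name: str
    fitted_fractions: Dict[str, float]
    reference_fractions: Dict[str, float]
    per_element_difference: Dict[str, float]
    ci95_overlap: Dict[str, Optional[bool]]
    missing_elements: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "tissue_name": self.tissue_name,
            "fitted_fractions": self.fitted_fractions,
            "reference_fractions": self.reference_fractions,
            "per_element_difference": self.per_element_difference,
            "ci95_overlap": self.ci95_overlap,
            "missing_elements": list(self.missing_elements),
        }

    def to_text(self) -> str:
        """Fixed-width table of the comparison."""
        lines = [
            f"Tissue: {self.tissue_name}",
            f"{'element':>8} {'fitted':>9} {'reference':>10} {'diff':>9} {'CI overlap':>11}",
        ]
        for el in sorted(self.reference_fractions):
            ov = self.ci95_overlap.get(el)
            ov_s = "-" if ov is None else ("yes" if ov else "no")
            flag = " (missing)" if el in self.missing_elements else ""
            lines.append(
                f"{el:>8} {self.fitted_fractions.get(el, 0.0):>9.4f} "
                f"{self.reference_fractions[el]:>10.4f} "
                f"{self.per_element_difference[el]:>+9.4f} {ov_s:>11}{flag}"
            )
        return "\n".join(lines)


def h_adjust(raw: Mapping[str, float] | CompositionTable) -> CompositionTable:
    """Hydrogen-omitted composition: C, N, O renormalized over their sum.

    Hydrogen (and every trace element) is dropped because (γ,n) activation
    of ¹H yields no positron emitter; the remaining C/N/O mass fractions
    are divided by their total.  Idempotent and invariant to uniform
    rescaling of the input (so percent or unit-fraction input both work).
    """
    if isinstance(raw, CompositionTable):
        name, fractions = raw.tissue_name, raw.fractions
    else:
        name, fractions = "user", raw
    cno = {el: float(fractions.get(el, 0.0)) for el in ACTIVATABLE_ELEMENTS}
    if any(v < 0 for v in fractions.values()):
        raise ValueError("fractions must be non-negative")
    total = sum(cno.values())
    if total <= 0:
        raise ValueError("C+N+O must be positive to hydrogen-adjust")
    return CompositionTable(
        tissue_name=name,
        fractions={el: v / total for el, v in cno.items()},
        adjusted=True,
    )


def label_half_life(
    half_life: float,
    nuclide_table: Optional[NuclideTable] = None,
    tolerance: float = HALF_LIFE_LABEL_TOLERANCE,
) -> Optional[str]:
    """Nuclide label for a fitted half-life, or None if nothing is close.

    The nearest physical half-life among the C/O/N activation products
    claims the label when within ``tolerance`` relative distance.
    """
    table = nuclide_table or default_nuclide_table()
    candidates = [table.by_parent(el) for el in ACTIVATABLE_ELEMENTS]
    best, best_rel = None, np.inf
    for nuc in candidates:
        rel = abs(half_life - nuc.half_life) / nuc.half_life
        if rel < best_rel:
            best, best_rel = nuc, rel
    return best.symbol if best is not None and best_rel <= tolerance else None


def fractions_to_composition(
    result: FitResult,
    nuclide_table: Optional[NuclideTable] = None,
    yield_weights: Optional[Mapping[str, float]] = None,
) -> Dict[str, float]:
    """Elemental fractions implied by a fit's normalized amplitudes.

    Each component's normalized amplitude is assigned to the parent element
    of its nuclide label; free-mode components are labelled by nearest
    physical half-life (within the labelling tolerance), else reported
    under ``"unassigned"``.  Optional per-element yield weights divide the
    fractions before renormalization (a component produced more efficiently
    per unit mass is down-weighted into mass terms).
    """
    if result.normalized_fractions is None:
        raise ValueError("fit has no defined fractions (all amplitudes zero)")
    table = nuclide_table or default_nuclide_table()
    out: Dict[str, float] = {el: 0.0 for el in ACTIVATABLE_ELEMENTS}
    for frac, label, t_half, ident in zip(
        result.normalized_fractions,
        result.labels,
        result.half_lives,
        result.identified or (True,) * len(result.labels),
    ):
        if label is None and result.mode == "fixed":
            raise RuntimeError("fixed-mode component without a nuclide label")
        if not ident:
            continue  # numerically-zero component: no label, nothing to assign
        if label is None:
            label = label_half_life(t_half, table)
        if label is None:
            out["unassigned"] = out.get("unassigned", 0.0) + float(frac)
            continue
        element = table.get(label).parent_element
        out[element] = out.get(element, 0.0) + float(frac)
    if yield_weights:
        for el in list(out):
            w = float(yield_weights.get(el, 1.0))
            if w <= 0:
                raise ValueError(f"yield weight for {el} must be > 0")
            out[el] = out[el] / w
        total = sum(out.values())
        out = {el: v / total for el, v in out.items()}
    return out


def compare_to_reference(
    fitted: Mapping[str, float],
    tissue: str | CompositionTable,
    fitted_ci: Optional[Mapping[str, tuple[float, float]]] = None,
) -> CompositionComparison:
    """Per-element difference between fitted and reference fractions.

    ``tissue`` is a bundled tissue name or an (adjusted) CompositionTable.
    ``fitted_ci`` optionally maps element → (lo, hi) 95% bounds on the
    fitted fraction; the overlap flag records whether the reference value
    lies inside.  Elements absent from ``fitted`` enter with 0 and are
    flagged missing.
    """
    if isinstance(tissue, CompositionTable):
        ref = tissue if tissue.adjusted else h_adjust(tissue)
    else:
        ref = get_adjusted_composition(tissue)
    missing = tuple(
        el for el in ref.fractions if el not in fitted and ref.fractions[el] > 0
    )
    fitted_full = {el: float(fitted.get(el, 0.0)) for el in ref.fractions}
    diff = {el: fitted_full[el] - ref.fractions[el] for el in ref.fractions}
    overlap: Dict[str, Optional[bool]] = {}
    for el in ref.fractions:
        if fitted_ci and el in fitted_ci:
            lo, hi = fitted_ci[el]
            overlap[el] = bool(lo <= ref.fractions[el] <= hi)
        else:
            overlap[el] = None
    return CompositionComparison(
        tissue_name=ref.tissue_name,
        fitted_fractions=fitted_full,
        reference_fractions=dict(ref.fractions),
        per_element_difference=diff,
        ci95_overlap=overlap,
        missing_elements=missing,
    )
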