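"""Inhibition-mode classification from a thermodynamic cycle of equilibrium
constants.

For the four equilibria

    E + S ⇌ ES   (K1)        E + I ⇌ EI   (Ka)
    EI + S ⇌ EIS (K4)        ES + I ⇌ ESI (Kb)

closure of the cycle forces ``Kb = K4 · Ka / K1``. A noncompetitive
inhibitor binds E and ES alike, so its directly estimated Kb agrees with the
cycle prediction; a competitive or uncompetitive inhibitor breaks the cycle.
The verdict is an explicit fold-ratio threshold on
``max(Kb_direct, Kb_pred) / min(Kb_direct, Kb_pred)``.

Only ratios and products of the constants are used, so the classification is
insensitive to whether the inputs are association or dissociation constants,
as long as they form a self-consistent set in one unit (µM here).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from collections import Counter
from collections.abc import Iterable, Sequence

__all__ = [
    "Verdict",
    "BindingConstantSet",
    "InhibitionModeResult",
    "BatchResult",
    "DEFAULT_THRESHOLD",
    "predicted_kb",
    "fold_discrepancy",
    "classify_mode",
    "classify_batch",
]

#: Default fold-ratio above which the direct and cycle-predicted Kb are
#: considered inconsistent. Any value in roughly (1.29, 2.11) reproduces the
#: bundled reference table; 1.5 is a round midpoint.
DEFAULT_THRESHOLD = 1.5


class Verdict(str, enum.Enum):
    NONCOMPETITIVE = "noncompetitive"
    COMPETITIVE_OR_UNCOMPETITIVE = "competitive_or_uncompetitive"


def _check_positive(value: float, name: str) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class BindingConstantSet:
    """The four equilibrium constants (µM) for one enzyme/substrate/inhibitor
    triple.

    ``K1``: E+S⇌ES, ``Ka``: E+I⇌EI, ``K4``: EI+S⇌EIS, ``Kb_direct``: ES+I⇌ESI
    as estimated directly (e.g. from a multi-ligand docking run).
    ``e_binding_EI`` optionally records the EI binding energy in kcal/mol.
    """

    ligand_id: str
    substrate_id: str
    target_id: str
    K1: float
    Ka: float
    K4: float
    Kb_direct: float
    e_binding_EI: float | None = None

    def __post_init__(self) -> None:
        for name in ("ligand_id", "substrate_id", "target_id"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        for name in ("K1", "Ka", "K4", "Kb_direct"):
            _check_positive(getattr(self, name), name)
        if self.e_binding_EI is not None and not math.isfinite(self.e_binding_EI):
            raise ValueError(f"e_binding_EI must be finite, got {self.e_binding_EI!r}")


@dataclass(frozen=True)
class InhibitionModeResult:
    """Per-ligand classification outcome with all intermediate numbers."""

    ligand_id: str
    kb_predicted: float
    kb_direct: float
    fold_discrepancy: float
    verdict: Verdict
    threshold_used: float


@dataclass(frozen=True)
class BatchResult:
    results: tuple[InhibitionModeResult, ...]
    counts: dict[str, int]

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)


def predicted_kb(constants: BindingConstantSet) -> float:
    """Cycle-predicted ES·I ⇌ ESI constant: Kb_pred = K4 · Ka / K1 (µM).

    Homogeneous of degree 0 when K1 and K4 are scaled together and of
    degree 1 in Ka.
    """
    return constants.K4 * constants.Ka / constants.K1


def fold_discrepancy(kb_direct: float, kb_predicted: float) -> float:
    """Symmetric fold ratio max/min ≥ 1 between two positive constants."""
    _check_positive(kb_direct, "kb_direct")
    _check_positive(kb_predicted, "kb_predicted")
    hi, lo = max(kb_direct, kb_predicted), min(kb_direct, kb_predicted)
    return hi / lo


def classify_mode(
    constants: BindingConstantSet,
    threshold: float = DEFAULT_THRESHOLD,
) -> InhibitionModeResult:
    """Classify one ligand: noncompetitive iff the direct and cycle-predicted
    Kb agree within ``threshold`` fold (ties classify as noncompetitive)."""
    if not (math.isfinite(threshold) and threshold > 1):
        raise ValueError(f"threshold must be > 1, got {threshold!r}")
    kb_pred = predicted_kb(constants)
    fold = fold_discrepancy(constants.Kb_direct, kb_pred)
    verdict = Verdict.NONCOMPETITIVE if fold <= threshold else Verdict.COMPETITIVE_OR_UNCOMPETITIVE
    return InhibitionModeResult(
        ligand_id=constants.ligand_id,
        kb_predicted=kb_pred,
        kb_direct=constants.Kb_direct,
        fold_discrepancy=fold,
        verdict=verdict,
        threshold_used=threshold,
    )


def classify_batch(
    sets: Iterable[BindingConstantSet] | Sequence[BindingConstantSet],
    threshold: float = DEFAULT_THRESHOLD,
) -> BatchResult:
    """Classify a sequence of ligands, preserving order.

    Rejects an empty input and duplicate ligand ids; attaches summary counts
    per verdict.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("classify_batch requires at least one BindingConstantSet")
    seen: set[str] = set()
    for s in sets:
        if s.ligand_id in seen:
            raise ValueError(f"duplicate ligand_id {s.ligand_id!r}")
        seen.add(s.ligand_id)
    results = tuple(classify_mode(s, threshold) for s in sets)
    counts = Counter(r.verdict.value for r in results)
    # always report both categories
    for v in Verdict:
        counts.setdefault(v.value, 0)
    return BatchResult(results=results, counts=dict(counts))
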