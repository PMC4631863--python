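"""One-shot reproduction of the bundled reference results.

Runs the whole pipeline on the packaged fixtures and checks every derived
number against its published counterpart: cycle-predicted Kb values and
verdicts, the mean replicate IC50, the binding-energy → Ki table, and the
mass-to-molar Ki conversion (which documents the published 314 µM against
the unrounded ≈316 µM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ..mode_classifier import DEFAULT_THRESHOLD, classify_batch
from ..thermo import InhibitionMode, deltaG_to_ki, ic50_to_ki, mass_to_molar
from . import fixtures

__all__ = ["ReproduceCheck", "ReproduceReport", "reproduce_paper"]

#: relative tolerance for numbers derived from published values rounded to
#: two decimals
_REL_TOL = 0.01


@dataclass(frozen=True)
class ReproduceCheck:
    name: str
    passed: bool
    detail: str


@dataclass(frozen=True)
class ReproduceReport:
    checks: tuple[ReproduceCheck, ...]
    classification: tuple[dict, ...]
    dg_to_ki: tuple[dict, ...]
    mean_ic50_mg_ml: float
    ki_conversion_uM: float

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_dict(self) -> dict:
        return {
            "all_passed": self.all_passed,
            "checks": [c.__dict__ for c in self.checks],
            "classification": list(self.classification),
            "dg_to_ki": list(self.dg_to_ki),
            "mean_ic50_mg_ml": self.mean_ic50_mg_ml,
            "ki_conversion_uM": self.ki_conversion_uM,
        }

    def to_text(self) -> str:
        lines = ["mechcycle reproduce", "=" * 60, "", "Cycle classification:"]
        for row in self.classification:
            lines.append(
                f"  {row['ligand_id']:<22s} Kb_pred {row['kb_pred_um']:>10.4g} µM"
                f"  Kb_direct {row['kb_direct_um']:>10.4g} µM"
                f"  fold {row['fold']:>8.4g}  -> {row['verdict']}"
            )
        lines.append("")
        lines.append("Binding energy -> Ki:")
        for row in self.dg_to_ki:
            lines.append(
                f"  {row['ligand_id']:<22s} {row['e_binding_kcal_mol']:>6.2f} kcal/mol"
                f"  -> {row['ki_um']:.2f} µM (reference {row['reference_ki_um']:.2f})"
            )
        lines.append("")
        lines.append(f"Mean replicate IC50: {self.mean_ic50_mg_ml:.4f} mg/mL "
                     f"(reference {fixtures.REFERENCE_MEAN_IC50_MG_ML:.2f})")
        lines.append(
            f"IC50 -> Ki (noncompetitive, MW {fixtures.BETULIN.molecular_weight}): "
            f"{self.ki_conversion_uM:.1f} µM; reference value "
            f"{fixtures.REFERENCE_INVITRO_KI_UM:.0f} µM (unrounded conversion ≈316 µM)"
        )
        lines.append("")
        lines.append("Checks:")
        for c in self.checks:
            lines.append(f"  [{'PASS' if c.passed else 'FAIL'}] {c.name}: {c.detail}")
        lines.append("")
        lines.append("ALL CHECKS PASSED" if self.all_passed else "SOME CHECKS FAILED")
        return "\n".join(lines)


def _rel_err(value: float, reference: float) -> float:
    return abs(value - reference) / abs(reference)


def reproduce_paper(threshold: float = DEFAULT_THRESHOLD) -> ReproduceReport:
    """Recompute every fixture-derived quantity and compare with the
    published values. Deterministic: repeated runs give identical reports."""
    sets = fixtures.load_binding_sets()
    batch = classify_batch(sets, threshold=threshold)

    checks: list[ReproduceCheck] = []
    classification = []
    for result in batch:
        expected_verdict = fixtures.REFERENCE_VERDICTS[result.ligand_id]
        expected_kb = fixtures.REFERENCE_PREDICTED_KB_UM[result.ligand_id]
        classification.append({
            "ligand_id": result.ligand_id,
            "kb_pred_um": result.kb_predicted,
            "kb_direct_um": result.kb_direct,
            "fold": result.fold_discrepancy,
            "verdict": result.verdict.value,
        })
        err = _rel_err(result.kb_predicted, expected_kb)
        checks.append(ReproduceCheck(
            name=f"predicted Kb ({result.ligand_id})",
            passed=err <= _REL_TOL,
            detail=f"{result.kb_predicted:.4g} µM vs {expected_kb:.4g} µM "
                   f"({err:.2%} relative)",
        ))
        checks.append(ReproduceCheck(
            name=f"verdict ({result.ligand_id})",
            passed=result.verdict is expected_verdict,
            detail=f"{result.verdict.value} vs {expected_verdict.value} "
                   f"(fold {result.fold_discrepancy:.4g}, threshold {threshold})",
        ))

    dg_to_ki = []
    for s in sets:
        ki = deltaG_to_ki(s.e_binding_EI)
        reference = fixtures.REFERENCE_KI_UM[s.ligand_id]
        err = _rel_err(ki, reference)
        dg_to_ki.append({
            "ligand_id": s.ligand_id,
            "e_binding_kcal_mol": s.e_binding_EI,
            "ki_um": ki,
            "reference_ki_um": reference,
        })
        checks.append(ReproduceCheck(
            name=f"ΔG→Ki ({s.ligand_id})",
            passed=err <= _REL_TOL,
            detail=f"{ki:.2f} µM vs {reference:.2f} µM ({err:.2%} relative)",
        ))

    replicates = fixtures.load_ic50_replicates()
    mean_ic50 = sum(replicates.values()) / len(replicates)
    checks.append(ReproduceCheck(
        name="mean replicate IC50",
        passed=round(mean_ic50, 2) == fixtures.REFERENCE_MEAN_IC50_MG_ML,
        detail=f"mean {mean_ic50:.4f} mg/mL rounds to {round(mean_ic50, 2)} "
               f"vs {fixtures.REFERENCE_MEAN_IC50_MG_ML}",
    ))

    ic50_uM = mass_to_molar(round(mean_ic50, 2), fixtures.BETULIN,
                            use_mass_fraction=False)
    ki_uM = ic50_to_ki(ic50_uM, InhibitionMode.NONCOMPETITIVE)
    err = _rel_err(ki_uM, fixtures.REFERENCE_INVITRO_KI_UM)
    checks.append(ReproduceCheck(
        name="IC50→Ki conversion",
        passed=err <= 0.02,
        detail=f"{ki_uM:.1f} µM vs published {fixtures.REFERENCE_INVITRO_KI_UM:.0f} µM "
               f"({err:.2%} relative; exact arithmetic gives 316.2 µM)",
    ))

    return ReproduceReport(
        checks=tuple(checks),
        classification=tuple(classification),
        dg_to_ki=tuple(dg_to_ki),
        mean_ic50_mg_ml=mean_ic50,
        ki_conversion_uM=ki_uM,
    )
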