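"""Ground-truth generators for every pipeline input.

Three generators, all pure functions of their config (seed included):

* labeled docking-constant sets whose thermodynamic cycle is consistent or
  inconsistent by a known fold factor;
* starch-iodine assay plates produced from Michaelis-Menten kinetics with a
  chosen inhibition mode and Gaussian absorbance noise;
* normally distributed group measurements (truncated at 0) from given
  means/SDs.

The kinetic model uses a linear-in-time digestion approximation: the
fraction of starch digested in ``t`` minutes is ``v·t/s0`` with
``v`` the inhibited Michaelis-Menten rate at ``s0``. For noncompetitive
inhibition the rate scales by ``1/(1+[I]/Ki)``, so the implied IC50 equals
Ki exactly — the identity the downstream pipeline is expected to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .assay import AssayReading
from .invivo_stats import GroupData
from .mode_classifier import (
    DEFAULT_THRESHOLD,
    BindingConstantSet,
    Verdict,
    predicted_kb,
)
from .thermo import InhibitionMode

__all__ = [
    "DockingSetConfig",
    "KineticsConfig",
    "LabeledBindingSet",
    "generate_docking_sets",
    "generate_assay_plate",
    "generate_groups",
]


class DockingSetConfig(BaseModel):
    """Configuration for labeled docking-constant generation.

    ``fold_factors`` are true ``max/min`` ratios between the direct and
    cycle-predicted Kb; a single entry is broadcast to all sets. Constants
    are drawn log-uniformly from the given (low, high) ranges in µM.
    """

    model_config = ConfigDict(extra="forbid")

    n_sets: int = Field(ge=1)
    fold_factors: list[float]
    k1_range: tuple[float, float] = (1e4, 1e6)
    ka_range: tuple[float, float] = (1.0, 1e3)
    k4_range: tuple[float, float] = (1e4, 1e6)
    label_threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "DockingSetConfig":
        if len(self.fold_factors) not in (1, self.n_sets):
            raise ValueError(
                f"fold_factors must have length 1 or n_sets={self.n_sets}, "
                f"got {len(self.fold_factors)}"
            )
        if any(not (math.isfinite(f) and f > 0) for f in self.fold_factors):
            raise ValueError("fold_factors must be positive and finite")
        for name in ("k1_range", "ka_range", "k4_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < low < high, got ({lo}, {hi})")
        if not self.label_threshold > 1:
            raise ValueError("label_threshold must be > 1")
        return self


@dataclass(frozen=True)
class LabeledBindingSet:
    """A generated constant set with its ground truth attached."""

    constants: BindingConstantSet
    true_fold: float
    true_verdict: Verdict


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_docking_sets(config: DockingSetConfig) -> list[LabeledBindingSet]:
    """Draw K1, Ka, K4 log-uniformly, set Kb_direct = Kb_pred × fold (the
    direction of the deviation is randomized), and attach the true label:
    noncompetitive iff fold ≤ ``label_threshold``."""
    rng = np.random.default_rng(config.seed)
    folds = config.fold_factors
    if len(folds) == 1:
        folds = folds * config.n_sets
    out = []
    for i, fold in enumerate(folds):
        k1 = _loguniform(rng, *config.k1_range)
        ka = _loguniform(rng, *config.ka_range)
        k4 = _loguniform(rng, *config.k4_range)
        constants = BindingConstantSet(
            ligand_id=f"synthetic_{i:03d}",
            substrate_id="synthetic_substrate",
            target_id="synthetic_target",
            K1=k1, Ka=ka, K4=k4,
            Kb_direct=1.0,  # placeholder, replaced below
        )
        kb_pred = predicted_kb(constants)
        kb_direct = kb_pred * fold if rng.random() < 0.5 else kb_pred / fold
        constants = BindingConstantSet(
            ligand_id=constants.ligand_id,
            substrate_id=constants.substrate_id,
            target_id=constants.target_id,
            K1=k1, Ka=ka, K4=k4,
            Kb_direct=kb_direct,
        )
        verdict = (Verdict.NONCOMPETITIVE if fold <= config.label_threshold
                   else Verdict.COMPETITIVE_OR_UNCOMPETITIVE)
        out.append(LabeledBindingSet(constants=constants, true_fold=fold,
                                     true_verdict=verdict))
    return out


class KineticsConfig(BaseModel):
    """Michaelis-Menten generator settings for a synthetic assay plate.

    Units: ``vmax`` mg/mL/min, ``km``/``s0``/``concentrations`` mg/mL,
    ``true_ki`` µM, ``inhibitor_mw`` g/mol, absorbances in OD at 581 nm.
    Defaults mirror the assay protocol (0.4 mg/mL starch, 7.5 min
    incubation); Km defaults to s0 for lack of a measured value.
    """

    model_config = ConfigDict(extra="forbid")

    true_ki: float = Field(gt=0)
    mode: InhibitionMode = InhibitionMode.NONCOMPETITIVE
    concentrations: list[float]
    inhibitor_mw: float = Field(default=442.72, gt=0)
    vmax: float = Field(default=0.08, gt=0)
    km: float = Field(default=0.4, gt=0)
    s0: float = Field(default=0.4, gt=0)
    incubation_min: float = Field(default=7.5, gt=0)
    n_replicates: int = Field(default=3, ge=1)
    noise_sd_abs: float = Field(default=0.01, ge=0)
    blank_abs: float = Field(default=0.8, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "KineticsConfig":
        if not self.concentrations:
            raise ValueError("concentrations must be non-empty")
        if any(not (math.isfinite(c) and c > 0) for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        # uninhibited digested fraction v0·t/s0 must not exceed 1
        f0 = self.vmax * self.incubation_min / (self.km + self.s0)
        if f0 > 1.0:
            raise ValueError(
                f"config digests {f0:.3f} of the starch with no inhibitor; "
                "require vmax*incubation_min <= km + s0"
            )
        return self

    @property
    def ic50_mg_per_ml(self) -> float:
        """Inhibitor mass concentration at which [I] equals Ki."""
        return self.true_ki * self.inhibitor_mw / 1e6


def _rate_factor(mode: InhibitionMode, i_over_ki: float, km: float, s0: float) -> float:
    """v(I)/v(0) for the chosen mechanism at substrate concentration s0."""
    a = 1.0 + i_over_ki
    if mode is InhibitionMode.NONCOMPETITIVE:
        return 1.0 / a
    if mode is InhibitionMode.COMPETITIVE:
        return (km + s0) / (km * a + s0)
    return (km + s0) / (km + s0 * a)  # uncompetitive


def generate_assay_plate(config: KineticsConfig) -> list[AssayReading]:
    """Simulate blank/sample absorbance pairs per replicate per
    concentration, including concentration-0 controls.

    E_S = blank × (1 − digested fraction) + Normal(0, noise_sd), floored at
    0; the expected E_S is monotone increasing in inhibitor concentration.
    """
    rng = np.random.default_rng(config.seed)
    v0 = config.vmax * config.s0 / (config.km + config.s0)
    f0 = v0 * config.incubation_min / config.s0
    readings = []
    for rep in range(1, config.n_replicates + 1):
        rep_id = f"R{rep}"
        for conc in [0.0, *config.concentrations]:
            i_uM = conc / config.inhibitor_mw * 1e6
            frac = f0 * _rate_factor(config.mode, i_uM / config.true_ki,
                                     config.km, config.s0)
            frac = min(max(frac, 0.0), 1.0)
            es = config.blank_abs * (1.0 - frac)
            if config.noise_sd_abs > 0:
                es += rng.normal(0.0, config.noise_sd_abs)
            readings.append(AssayReading(
                replicate_id=rep_id,
                concentration=conc,
                absorbance_blank_EB1=config.blank_abs,
                absorbance_sample_ES=max(es, 0.0),
            ))
    return readings


def generate_groups(
    means: dict[str, float],
    sds: dict[str, float],
    n: int,
    seed: int = 0,
    timepoint: str | None = None,
) -> list[GroupData]:
    """Seeded Normal(mean, sd) draws per group, truncated at 0.

    ``means`` and ``sds`` are keyed by group label and must match; SD = 0
    gives a constant group. Truncation at zero is a mild deviation from
    normality appropriate for non-negative physiological measurements.
    """
    if set(means) != set(sds):
        raise ValueError("means and sds must have identical group labels")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    for label, sd in sds.items():
        if sd < 0:
            raise ValueError(f"group {label!r} has negative SD {sd}")
    rng = np.random.default_rng(seed)
    out = []
    for label in means:
        draws = rng.normal(means[label], sds[label], size=n)
        out.append(GroupData(group_label=label,
                             values=np.maximum(draws, 0.0),
                             timepoint=timepoint))
    return out
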