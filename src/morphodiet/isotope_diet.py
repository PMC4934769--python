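"""Carbon/nitrogen diet endmember model for bone-collagen isotope values.

The model interprets collagen delta13C as lying between reference values of
pure dietary sources in a landscape where C3 vegetation dominates and millet
(a C4 crop) is the cultivated exception.  Modern plant reference values are
corrected for the fossil-fuel (Suess) effect (+1.5 per mil) before the +5 per
mil diet-protein-to-collagen enrichment; archaeological seed values take only
the enrichment.  Derived collagen ranges (per mil VPDB):

* pure C3 diet: (-22.5, -18.5), mean -20
* millet-seed diet: (-6.9, -4.6)
* millet-leaf diet: (-8.1, -5.8)

delta15N tracks trophic level with a 3-4 per mil step per level; herbivore
and carnivore baselines (e.g. deer and tiger values from the same ecosystem)
anchor a three-band classification.  Third-molar (M3) length separates
wild-boar-sized from domestic-sized suids at a 37.9 mm cutoff.  All
thresholds are approximations intended to describe trends, not to compute
precise diet proportions; the indicative millet fraction is reported as a
descriptive number only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_clustering import MixtureFit, select_model
from .shape_statistics import size_summary
from .tps_io import IsotopeRecord

__all__ = [
    "DietEndmemberModel",
    "DietClassification",
    "suess_correct",
    "diet_to_collagen",
    "endmember_collagen_range",
    "classify_d13C",
    "trophic_category",
    "classify_M3",
    "filter_weaned",
    "phase_comparison",
    "cluster_d13C",
]


@dataclass(frozen=True)
class DietEndmemberModel:
    """Plant endmember delta13C ranges and correction/enrichment constants."""

    c3_plant_range_modern: tuple[float, float] = (-29.0, -25.0)
    c3_plant_mean_modern: float = -26.5
    millet_seed_range_archaeological: tuple[float, float] = (-11.9, -9.6)
    millet_leaf_range_modern: tuple[float, float] = (-14.6, -12.3)
    suess_correction: float = 1.5
    collagen_enrichment: float = 5.0
    canopy_cutoff_modern_plants: float = -31.5
    canopy_collagen_threshold: float = -25.0
    no_millet_collagen_bound: float = -18.5
    trophic_step_d15N: tuple[float, float] = (3.0, 4.0)

    def __post_init__(self) -> None:
        for name in (
            "c3_plant_range_modern",
            "millet_seed_range_archaeological",
            "millet_leaf_range_modern",
        ):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} must be an ordered finite interval")
        for name in ("suess_correction", "collagen_enrichment"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DietClassification:
    specimen_id: str
    d13C_category: str                     # pure_C3 | mixed_C3_C4 | C4_dominant | forest_C3_contribution
    millet_fraction_indicative: float | None = None   # descriptive %, [0, 100]
    trophic_category: str | None = None    # herbivore_like | omnivore_like | carnivore_like


def suess_correct(modern_d13C: float, correction: float = 1.5) -> float:
    """Shift a modern plant delta13C up by the fossil-fuel depletion amount."""
    return modern_d13C + correction


def diet_to_collagen(plant_d13C: float, enrichment: float = 5.0) -> float:
    """Apply the diet-protein-to-collagen 13C enrichment."""
    return plant_d13C + enrichment


def endmember_collagen_range(
    model: DietEndmemberModel, endmember: str
) -> tuple[float, float]:
    """Collagen delta13C interval expected from a pure-endmember diet.

    The Suess correction applies only to modern plant reference ranges (C3,
    millet leaf); archaeological millet seeds carry pre-industrial carbon and
    take the collagen enrichment alone.
    """
    if endmember == "c3":
        lo, hi = model.c3_plant_range_modern
        shift = model.suess_correction + model.collagen_enrichment
    elif endmember == "millet_seed":
        lo, hi = model.millet_seed_range_archaeological
        shift = model.collagen_enrichment
    elif endmember == "millet_leaf":
        lo, hi = model.millet_leaf_range_modern
        shift = model.suess_correction + model.collagen_enrichment
    else:
        raise ValueError(f"unknown endmember {endmember!r}")
    return (lo + shift, hi + shift)


def _c4_dominant_bound(model: DietEndmemberModel) -> float:
    # lower bound of the millet-leaf collagen band; configurable via the model
    return endmember_collagen_range(model, "millet_leaf")[0]


def _millet_collagen_mean(model: DietEndmemberModel) -> float:
    seed = endmember_collagen_range(model, "millet_seed")
    leaf = endmember_collagen_range(model, "millet_leaf")
    return (np.mean(seed) + np.mean(leaf)) / 2.0


def _c3_collagen_mean(model: DietEndmemberModel) -> float:
    return diet_to_collagen(
        suess_correct(model.c3_plant_mean_modern, model.suess_correction),
        model.collagen_enrichment,
    )


def classify_d13C(
    record: IsotopeRecord, model: DietEndmemberModel | None = None
) -> DietClassification:
    """Categorical diet class from collagen delta13C.

    The real line is partitioned with no gaps or overlaps:
    values at or below the canopy collagen threshold indicate a forest C3
    contribution; values up to the no-millet bound a pure open-environment C3
    diet; values at or above the C4-dominance bound (the millet-leaf collagen
    lower bound) a millet-dominated diet; anything between is a C3/C4 mix.
    The indicative millet fraction interpolates linearly between the C3 and
    millet collagen means, clamped to [0, 100]; it describes a trend, not a
    precise diet proportion.
    """
    model = model or DietEndmemberModel()
    v = record.d13C
    if v is None or not np.isfinite(v):
        raise ValueError(f"{record.specimen_id}: missing d13C")
    c4_bound = _c4_dominant_bound(model)
    if v <= model.canopy_collagen_threshold:
        cat = "forest_C3_contribution"
    elif v < model.no_millet_collagen_bound:
        cat = "pure_C3"
    elif v >= c4_bound:
        cat = "C4_dominant"
    else:
        cat = "mixed_C3_C4"
    c3_mean = _c3_collagen_mean(model)
    millet_mean = _millet_collagen_mean(model)
    frac = 100.0 * (v - c3_mean) / (millet_mean - c3_mean)
    frac = float(np.clip(frac, 0.0, 100.0))
    return DietClassification(
        specimen_id=record.specimen_id,
        d13C_category=cat,
        millet_fraction_indicative=frac,
    )


def trophic_category(
    record: IsotopeRecord,
    baselines: dict,
    model: DietEndmemberModel | None = None,
) -> str:
    """Trophic band from delta15N relative to ecosystem baselines.

    ``baselines`` holds ``herbivore_mean_d15N`` and ``carnivore_mean_d15N``
    (e.g. deer and tiger means from the same deposit).  Assignment is by the
    nearest of three anchors: the herbivore baseline, the omnivore midpoint
    between the baselines, and the carnivore baseline.
    """
    if "herbivore_mean_d15N" not in baselines or "carnivore_mean_d15N" not in baselines:
        raise ValueError("both herbivore_mean_d15N and carnivore_mean_d15N required")
    herb = baselines["herbivore_mean_d15N"]
    carn = baselines["carnivore_mean_d15N"]
    mid = (herb + carn) / 2.0
    v = record.d15N
    anchors = {
        "herbivore_like": herb,
        "omnivore_like": mid,
        "carnivore_like": carn,
    }
    return min(anchors, key=lambda k: abs(v - anchors[k]))


def classify_M3(length: float, cutoff: float = 37.9) -> str:
    """Wild/domestic size class from lower third molar length (mm).

    Strictly above the cutoff is wild; values at or below (including the
    cutoff itself) are domestic.
    """
    if not np.isfinite(length) or length <= 0:
        raise ValueError(f"M3 length must be positive, got {length}")
    return "wild" if length > cutoff else "domestic"


def filter_weaned(
    records: Iterable[IsotopeRecord], min_stage: int = 10, strict: bool = False
) -> list[IsotopeRecord]:
    """Drop records young enough for suckling to inflate delta15N.

    Keeps records whose dental stage is ``min_stage`` or older.  Records
    without a stage are kept by default (flagged use); in ``strict`` mode
    they are dropped too.
    """
    out = []
    for r in records:
        if r.dental_stage is None:
            if not strict:
                out.append(r)
            continue
        if r.dental_stage >= min_stage:
            out.append(r)
    return out


def phase_comparison(records: Sequence[IsotopeRecord], value: str = "d13C") -> dict:
    """One-way ANOVA of an isotope variable across phases, with phase spans.

    Reports the ANOVA F/p (when at least two phases have two or more
    records) plus the per-phase n, mean, min, max and inter-individual range.
    """
    if value not in ("d13C", "d15N"):
        raise ValueError("value must be 'd13C' or 'd15N'")
    vals = np.array([getattr(r, value) for r in records], dtype=float)
    phases = np.array([r.phase for r in records])
    summary = size_summary(vals, phases)
    per_phase = {}
    for ph in pd.unique(phases):
        v = vals[phases == ph]
        per_phase[str(ph)] = {
            "n": int(len(v)),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "min": float(v.min()),
            "max": float(v.max()),
            "range": float(np.ptp(v)),
        }
    return {
        "value": value,
        "anova_F": summary.anova_F,
        "anova_p": summary.anova_p,
        "per_phase": per_phase,
    }


def cluster_d13C(
    records: Sequence[IsotopeRecord],
    G_range=(1, 2, 3),
    families=("E",),
    seed: int | None = None,
) -> MixtureFit:
    """BIC-selected Gaussian mixture of the delta13C values.

    Delegates to :func:`morphodiet.model_clustering.select_model` on the 1-D
    delta13C vector; the default candidate family is the equal-variance
    model (the convention matching a df of 2G for G components).  The
    returned fit carries the full BIC table.
    """
    vals = np.array([r.d13C for r in records], dtype=float)
    if len(vals) < 5:
        raise ValueError("cluster_d13C requires at least 5 records")
    return select_model(vals, G_range=G_range, families=families, seed=seed)
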