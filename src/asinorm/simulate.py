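"""Synthetic hierarchical cohorts with the statistical structure the analysis assumes.

The generator is the exact generative inverse of the mixed models fitted by
:mod:`asinorm.lme`: per mouse a Gaussian random intercept, per dendrite a
truncated-normal diameter and length, a nested dendrite intercept and a
sqrt-normal synapse-bearing spine density; per synapse-bearing spine

    log ASI = intercept + condition effect + slope * diameter
              [+ endosome effect + condition-by-endosome interaction]
              + u_mouse + u_dendrite + eps

so that fitting the generating model specification recovers the packaged
parameters.  Spine counts are the rounded product of the drawn density and the
dendrite's lateral cylinder surface (the density, not the count, is the
modelled quantity); spines without a synapse are appended in the configured
per-condition proportion.

Packaged configurations ``p13_table1.json`` and ``p30_table1.json`` transcribe
the published model-parameter and descriptive tables; see the JSON ``notes``
fields for which blocks are transcribed and which are derived.
"""

from __future__ import annotations

import importlib.resources as resources
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import truncnorm

from .geometry import Contour, ContourStack

__all__ = [
    "GeneratorConfig",
    "load_packaged_config",
    "generate_cohort",
    "generate_contour_stack",
    "generate_study_fixture",
    "expected_spines_per_dendrite",
    "StudyFixture",
]


class AsiModel(BaseModel):
    reference: str
    intercept: float
    diameter_slope: float
    condition_effects: dict[str, float]
    endosome_effect: Optional[float] = None
    endosome_interaction: Optional[dict[str, float]] = None
    sd_mouse: float = Field(ge=0)
    sd_dendrite: float = Field(ge=0)
    sd_residual: float = Field(ge=0)


class DensityModel(BaseModel):
    reference: str
    intercept: float
    condition_effects: dict[str, float]
    sd_mouse: float = Field(ge=0)
    sd_residual: float = Field(ge=0)


class Moments(BaseModel):
    mean: float
    sd: float = Field(ge=0)


class LogVolume(BaseModel):
    mean: dict[str, float]
    sd: float = Field(ge=0)


class GeneratorConfig(BaseModel):
    """Full parameterisation of one synthetic cohort (see module docstring)."""

    age_group: str
    conditions: list[str]
    n_mice: dict[str, int]
    n_dendrites_per_mouse: int
    asi_model: AsiModel
    density_model: DensityModel
    diameter_um: dict[str, Moments]
    diameter_range_um: tuple[float, float]
    length_um: dict[str, Moments]
    length_range_um: tuple[float, float] = (5.0, 60.0)
    frac_without_synapse: dict[str, float]
    endosome_prob: dict[str, float]
    spine_apparatus_prob: dict[str, float]
    endosome_log_volume: LogVolume
    sa_log_volume: LogVolume
    oblique_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    thickness_um: float = Field(default=0.045, gt=0)
    study_n_mice: Optional[dict[str, int]] = None
    study_spine_totals: Optional[dict[str, int]] = None
    seed: Optional[int] = None
    notes: str = ""

    @model_validator(mode="after")
    def _check(self):
        for name, mapping in [
            ("n_mice", self.n_mice),
            ("asi condition_effects", self.asi_model.condition_effects),
            ("density condition_effects", self.density_model.condition_effects),
            ("diameter_um", self.diameter_um),
            ("length_um", self.length_um),
            ("frac_without_synapse", self.frac_without_synapse),
            ("endosome_prob", self.endosome_prob),
            ("spine_apparatus_prob", self.spine_apparatus_prob),
        ]:
            missing = set(self.conditions) - set(mapping)
            if missing:
                raise ValueError(f"{name} missing conditions {sorted(missing)}")
        for p in list(self.frac_without_synapse.values()) + list(
            self.endosome_prob.values()
        ) + list(self.spine_apparatus_prob.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.asi_model.reference not in self.conditions:
            raise ValueError("ASI reference level not among conditions")
        return self


def load_packaged_config(age_group: str) -> GeneratorConfig:
    """Load the packaged generator configuration for ``"P13"`` or ``"P30"``."""
    name = {"P13": "p13_table1.json", "P30": "p30_table1.json"}.get(age_group)
    if name is None:
        raise ValueError(f"no packaged config for age group {age_group!r}")
    text = resources.files("asinorm.data").joinpath(name).read_text()
    return GeneratorConfig.model_validate(json.loads(text))


def _truncnorm_rvs(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _truncnorm_mean(mean, sd, lo, hi) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.mean(a, b, loc=mean, scale=sd))


def expected_spines_per_dendrite(config: GeneratorConfig, condition: str) -> float:
    """Closed-form expected synapse-bearing spines per dendrite under the config.

    E[count] ~= E[density] * pi * E[diameter] * E[length] with
    E[density] = mu^2 + sd_mouse^2 + sd_residual^2 for the sqrt-normal density.
    """
    dm = config.density_model
    mu = dm.intercept + dm.condition_effects[condition]
    e_density = mu**2 + dm.sd_mouse**2 + dm.sd_residual**2
    d = config.diameter_um[condition]
    ln = config.length_um[condition]
    e_d = _truncnorm_mean(d.mean, d.sd, *config.diameter_range_um)
    e_l = _truncnorm_mean(ln.mean, ln.sd, *config.length_range_um)
    return e_density * np.pi * e_d * e_l


def _dendrite_rows(rng, config, condition, mouse_id, dendrite_id, u_asi, u_dens):
    """Generate all spine rows of one dendrite; returns a list of dicts."""
    am, dm = config.asi_model, config.density_model
    lo_d, hi_d = config.diameter_range_um
    lo_l, hi_l = config.length_range_um
    d = config.diameter_um[condition]
    ln = config.length_um[condition]
    diameter = float(_truncnorm_rvs(rng, d.mean, d.sd, lo_d, hi_d))
    length = float(_truncnorm_rvs(rng, ln.mean, ln.sd, lo_l, hi_l))
    u_dend = rng.normal(0.0, am.sd_dendrite)

    s = dm.intercept + dm.condition_effects[condition] + u_dens + rng.normal(
        0.0, dm.sd_residual
    )
    density = max(s, 0.0) ** 2
    n_syn = int(round(density * np.pi * diameter * length))
    p_no = config.frac_without_synapse[condition]
    n_no = int(round(n_syn * p_no / (1.0 - p_no))) if p_no < 1 else 0

    cond_eff = am.condition_effects[condition]
    p_endo = config.endosome_prob[condition]
    p_sa = config.spine_apparatus_prob[condition]
    ev = config.endosome_log_volume
    sv = config.sa_log_volume

    rows = []
    for i in range(n_syn + n_no):
        with_synapse = i < n_syn
        oblique = bool(with_synapse and rng.random() < config.oblique_fraction)
        has_endo = bool(rng.random() < p_endo)
        has_sa = bool(rng.random() < p_sa)
        asi = np.nan
        if with_synapse and not oblique:
            mu = am.intercept + cond_eff + am.diameter_slope * diameter + u_asi + u_dend
            if am.endosome_effect is not None and has_endo:
                mu += am.endosome_effect
                if am.endosome_interaction is not None:
                    mu += am.endosome_interaction[condition]
            asi = float(np.exp(mu + rng.normal(0.0, am.sd_residual)))
        rows.append(
            {
                "mouse_id": mouse_id,
                "condition": condition,
                "age_group": config.age_group,
                "dendrite_id": dendrite_id,
                "diameter_um": diameter,
                "length_um": length,
                "n_shaft_synapses": 0,
                "spine_id": f"{dendrite_id}_s{i}",
                "has_synapse": with_synapse,
                "oblique": oblique,
                "asi_um2": asi,
                "has_endosome": has_endo,
                "endosome_vol_um3": float(np.exp(rng.normal(ev.mean[condition], ev.sd)))
                if has_endo
                else np.nan,
                "has_spine_apparatus": has_sa,
                "sa_vol_um3": float(np.exp(rng.normal(sv.mean[condition], sv.sd)))
                if has_sa
                else np.nan,
                "vesicle_count_within_50nm": int(rng.integers(1, 8)) if with_synapse else 0,
                "has_cleft": with_synapse,
                "has_psd": with_synapse,
            }
        )
    return rows


def generate_cohort(
    config: GeneratorConfig,
    seed: Optional[int] = None,
    n_mice: Optional[dict | int] = None,
    n_dendrites_per_mouse: Optional[int] = None,
) -> pd.DataFrame:
    """Draw one cohort from the generative model; deterministic given the seed.

    ``n_mice`` / ``n_dendrites_per_mouse`` override the config counts (an int
    applies to every condition).
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    if n_mice is None:
        mice = dict(config.n_mice)
    elif isinstance(n_mice, int):
        mice = {c: n_mice for c in config.conditions}
    else:
        mice = dict(n_mice)
    n_dend = n_dendrites_per_mouse or config.n_dendrites_per_mouse

    rows = []
    for cond in config.conditions:
        for m in range(mice[cond]):
            mouse_id = f"{config.age_group}_{cond}_m{m}"
            u_asi = rng.normal(0.0, config.asi_model.sd_mouse)
            u_dens = rng.normal(0.0, config.density_model.sd_mouse)
            for k in range(n_dend):
                rows.extend(
                    _dendrite_rows(
                        rng, config, cond, mouse_id, f"{mouse_id}_d{k}", u_asi, u_dens
                    )
                )
    return pd.DataFrame(rows)


def generate_contour_stack(
    target_area: float,
    n_sections: int,
    thickness: float = 0.045,
    seed: Optional[int] = None,
    pixel_size: float = 0.004,
) -> ContourStack:
    """Ribbon stack whose apposed area reproduces ``target_area``.

    Each section carries a straight 1-pixel-wide rectangular trace; the trace
    length is solved from the apposed-surface closed form so the roundtrip
    through :func:`asinorm.geometry.asi_area` (window=1) is exact up to
    floating point.  Sections receive rigid in-plane jitter, which the surface
    estimate is invariant to.
    """
    if target_area <= 0:
        raise ValueError("target_area must be positive")
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    w = pixel_size
    if n_sections == 1:
        denom = thickness - w
        length = (target_area - w * thickness) / denom if denom > 0 else -1.0
    else:
        denom = thickness * (n_sections - 1) - w
        length = (
            (target_area - w * thickness * (n_sections - 1)) / denom
            if denom > 0
            else -1.0
        )
    if denom <= 0 or length < w:
        raise ValueError(
            "infeasible ribbon geometry: required trace length is below the pixel size"
        )
    rng = np.random.default_rng(seed)
    contours = []
    for z in range(n_sections):
        x0, y0 = rng.normal(0.0, 0.02, size=2)
        contours.append(
            Contour(
                section_index=z,
                vertices=np.array(
                    [
                        [x0, y0],
                        [x0 + length, y0],
                        [x0 + length, y0 + w],
                        [x0, y0 + w],
                    ]
                ),
            )
        )
    return ContourStack(
        contours=tuple(contours), thickness_per_section=thickness, stack_id=""
    )


@dataclass
class StudyFixture:
    """Study-matched synthetic dataset: spine-level cohort plus one contour
    stack per measured spine (keyed by spine_id)."""

    cohort: pd.DataFrame
    stacks: dict


def generate_study_fixture(
    age_group: str, seed: int = 0, with_stacks: bool = True
) -> StudyFixture:
    """Synthetic cohort at the study's sample sizes.

    Mouse counts follow the study (P13: S 4, EW4 3, EW15 4, Rec 3; P30: S, SW,
    EW 4 each, CSR 3).  Within each condition, dendrites are added round-robin
    across the group's mice until the cumulative synapse-bearing spine count
    reaches the study total, mirroring how the study accumulated a target
    number of measured synapses per animal; group totals therefore land within
    about half a dendrite's worth of spines of the published counts.
    """
    config = load_packaged_config(age_group)
    rng = np.random.default_rng(seed)
    mice = config.study_n_mice or config.n_mice
    totals = config.study_spine_totals
    if totals is None:
        raise ValueError("packaged config lacks study spine totals")

    rows = []
    for cond in config.conditions:
        n_m = mice[cond]
        mouse_ids = [f"{config.age_group}_{cond}_m{m}" for m in range(n_m)]
        u_asi = {mid: rng.normal(0.0, config.asi_model.sd_mouse) for mid in mouse_ids}
        u_dens = {
            mid: rng.normal(0.0, config.density_model.sd_mouse) for mid in mouse_ids
        }
        half_dendrite = expected_spines_per_dendrite(config, cond) / 2.0
        target = totals[cond]
        count = 0
        k = 0
        per_mouse_k = {mid: 0 for mid in mouse_ids}
        while count < target - half_dendrite:
            mid = mouse_ids[k % n_m]
            dend_id = f"{mid}_d{per_mouse_k[mid]}"
            per_mouse_k[mid] += 1
            new_rows = _dendrite_rows(
                rng, config, cond, mid, dend_id, u_asi[mid], u_dens[mid]
            )
            rows.extend(new_rows)
            count += sum(r["has_synapse"] for r in new_rows)
            k += 1
    cohort = pd.DataFrame(rows)

    stacks = {}
    if with_stacks:
        T = config.thickness_um
        measured = cohort[
            cohort["has_synapse"] & ~cohort["oblique"] & cohort["asi_um2"].notna()
        ]
        for spine_id, area in zip(measured["spine_id"], measured["asi_um2"]):
            n_sections = max(1, 1 + int(round(np.sqrt(area) / T)))
            stacks[spine_id] = generate_contour_stack(
                area,
                n_sections,
                thickness=T,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
    return StudyFixture(cohort=cohort, stacks=stacks)
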