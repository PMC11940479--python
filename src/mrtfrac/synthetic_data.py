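"""Synthetic colony-formation-assay datasets with the study's design.

Emulates the reference experiment: two lung cell lines (A549 tumor,
MRC-5 normal fibroblast), three treatment arms — four-fraction broad beam
(BB_fx4), four overlapping microbeam fractions (MRT_fx4) and four
microbeam fractions rotated 45° each (MRT_fx4+R) — delivered at 24 h
intervals, assayed with three biological replicates of six technical
replicates each.  Colony counts are Poisson around
``seeded * PE * SF_plan``, where ``SF_plan`` is the linear-quadratic
survival of the delivered dose field.

Dose levels are interpreted either as per-fraction peak doses
(``dose_mode="peak"``) or, mirroring the study's equal-survival planning,
as target single-fraction equivalent uniform doses for which per-fraction
peak doses are solved per cell line and arm (``dose_mode="matched_eud"``,
the default).

Departures from pure LQ behavior (e.g. normal-tissue sparing under
spatial fractionation mediated by intercellular communication) can be
injected as per-arm multiplicative survival effects; they default to none
so that, by construction, all arms share one dose-response.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cfa import CSV_COLUMNS, CFARecord
from .dose_field import (
    FractionPlan,
    FractionSpec,
    IntegrationDomain,
    MicrobeamGeometry,
)
from .lqm import (
    CELL_LINE_PARAMS,
    LQParams,
    eud_single_fraction,
    peak_dose_for_target_sf,
    plan_sf,
    sf_uniform,
)

__all__ = [
    "CellLineSpec",
    "ModalitySpec",
    "StudyDesign",
    "default_design",
    "simulate_cfa_counts",
    "simulate_study",
    "plan_for",
    "STUDY_MODALITIES",
]


@dataclass(frozen=True)
class CellLineSpec:
    """A cell line's ground-truth radiosensitivity and plating efficiency."""

    label: str
    params: LQParams
    pe: float  # plating efficiency as a fraction in (0, 1]

    def __post_init__(self) -> None:
        if not (0 < self.pe <= 1):
            raise ValueError("pe must lie in (0, 1]")


@dataclass(frozen=True)
class ModalitySpec:
    """A treatment arm: beam kind and the stripe angle of each fraction."""

    label: str
    kind: Literal["broad_beam", "microbeam"]
    angles_deg: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("broad_beam", "microbeam"):
            raise ValueError("kind must be 'broad_beam' or 'microbeam'")
        if len(self.angles_deg) < 1:
            raise ValueError("need at least one fraction")

    @property
    def n_fractions(self) -> int:
        return len(self.angles_deg)


#: The three arms of the reference study: 4 fractions at 24 h intervals.
STUDY_MODALITIES = (
    ModalitySpec("BB_fx4", "broad_beam", (0.0, 0.0, 0.0, 0.0)),
    ModalitySpec("MRT_fx4", "microbeam", (0.0, 0.0, 0.0, 0.0)),
    ModalitySpec("MRT_fx4+R", "microbeam", (0.0, 45.0, 90.0, 135.0)),
)


@dataclass(frozen=True)
class StudyDesign:
    """Full factorial design of a synthetic clonogenic study."""

    geometry: MicrobeamGeometry
    domain: IntegrationDomain
    cell_lines: tuple[CellLineSpec, ...]
    modalities: tuple[ModalitySpec, ...]
    dose_levels_gy: tuple[float, ...]
    n_bio: int = 3
    n_tech: int = 6
    seeded_min: int = 100
    seeded_max: int = 2000
    #: cells per unirradiated control well; sized so the pooled control
    #: gives a precise plating-efficiency estimate with countable colonies
    control_seeded: int = 250
    dose_mode: Literal["matched_eud", "peak"] = "matched_eud"
    bio_sd: float = 0.0  # lognormal sd of per-replicate PE multipliers
    noise: Literal["poisson", "none"] = "poisson"
    interval_hours: float = 24.0
    #: multiplicative survival effects per (cell_line, modality), default 1
    modality_effects: tuple[tuple[tuple[str, str], float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("n_bio and n_tech must be >= 1")
        if not self.cell_lines or not self.modalities or not self.dose_levels_gy:
            raise ValueError("cell_lines, modalities and dose_levels_gy must be non-empty")
        if any(d < 0 for d in self.dose_levels_gy):
            raise ValueError("dose levels must be >= 0")
        if not (0 < self.seeded_min <= self.seeded_max):
            raise ValueError("need 0 < seeded_min <= seeded_max")

    def effect(self, cell_line: str, modality: str) -> float:
        return dict(self.modality_effects).get((cell_line, modality), 1.0)


def default_design(seed: int = 0, **overrides) -> StudyDesign:
    """The reference study's layout with realistic defaults.

    Plating efficiencies (0.70 for A549, 0.35 for MRC-5) are typical for
    these lines; the integration patch is a 3 mm square (ten stripe
    periods), over which the periodic survival integral has converged.
    """
    base = StudyDesign(
        geometry=MicrobeamGeometry(),
        domain=IntegrationDomain(shape="square", extent_mm=3.0, resolution_um=5.0),
        cell_lines=(
            CellLineSpec("A549", CELL_LINE_PARAMS["A549"], pe=0.70),
            CellLineSpec("MRC-5", CELL_LINE_PARAMS["MRC-5"], pe=0.35),
        ),
        modalities=STUDY_MODALITIES,
        dose_levels_gy=(1.0, 2.0, 4.0, 6.0, 8.0),
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


@functools.lru_cache(maxsize=4096)
def _matched_peak_dose(
    params: LQParams,
    geometry: MicrobeamGeometry,
    modality: ModalitySpec,
    eud_gy: float,
    domain: IntegrationDomain,
) -> float:
    """Per-fraction dose whose plan matches the survival of ``eud_gy``."""
    target_sf = sf_uniform(params, [eud_gy])
    if modality.kind == "broad_beam":
        # uniform fractions: N*(alpha*d + beta*d**2) = -ln(target_sf),
        # solved exactly by the stable quadratic inversion
        per_fraction_sf = target_sf ** (1.0 / modality.n_fractions)
        return eud_single_fraction(params, per_fraction_sf)
    return peak_dose_for_target_sf(
        params, geometry, modality.angles_deg, modality.n_fractions,
        target_sf, domain,
    )


def plan_for(
    design: StudyDesign, cell_line: str, modality: str, dose_level_gy: float
) -> FractionPlan:
    """The FractionPlan actually delivered for one design condition."""
    mod = next(m for m in design.modalities if m.label == modality)
    if design.dose_mode == "peak" or dose_level_gy == 0:
        per_fraction = float(dose_level_gy)
    else:
        cl = next(c for c in design.cell_lines if c.label == cell_line)
        per_fraction = _matched_peak_dose(
            cl.params, design.geometry, mod, float(dose_level_gy), design.domain
        )
    fracs = tuple(
        FractionSpec(modality=mod.kind, peak_dose_gy=per_fraction, angle_deg=a)
        for a in mod.angles_deg
    )
    return FractionPlan(design.geometry, fracs, design.interval_hours)


def simulate_cfa_counts(
    truth: LQParams,
    pe_true: float,
    plan: FractionPlan,
    seeded: int,
    rng: np.random.Generator,
    domain: IntegrationDomain | None = None,
    sf_multiplier: float = 1.0,
) -> int:
    """Draw one well's colony count: Poisson(seeded * PE * SF_plan)."""
    if not (seeded > 0):
        raise ValueError("seeded must be > 0")
    if domain is None:
        domain = IntegrationDomain()
    sf = min(plan_sf(truth, plan, domain) * sf_multiplier, 1.0)
    mean = seeded * pe_true * sf
    return int(rng.poisson(mean))


def _seeding_ladder(design: StudyDesign) -> dict[float, int]:
    """Cells seeded per well, increasing with dose so colonies stay countable."""
    levels = sorted(set(design.dose_levels_gy))
    if len(levels) == 1:
        return {levels[0]: design.seeded_max, 0.0: design.control_seeded}
    ladder = np.geomspace(design.seeded_min, design.seeded_max, len(levels))
    out = {lvl: int(round(s)) for lvl, s in zip(levels, ladder)}
    out[0.0] = design.control_seeded
    return out


def simulate_study(design: StudyDesign) -> pd.DataFrame:
    """Simulate the full factorial study, controls included.

    One record per (cell line x modality x dose level x biological x
    technical replicate), plus ``n_tech`` sham-handled 0 Gy control wells
    per (cell line x biological replicate), labelled modality
    ``"control"``.  All arms share one schedule (equal fraction count and
    interval), so a single sham-handled control per biological replicate
    serves every arm — as a lab would run it, and what makes the
    between-arm contrast insensitive to the control's own counting noise.

    Randomness is split deterministically from the design seed: one child
    stream for biological-replicate PE multipliers, then one child stream
    per well, in the fixed order cell line -> biological replicate ->
    (control wells, then modality -> dose level) -> technical replicate.
    """
    bio_ss, wells_ss = np.random.SeedSequence(design.seed).spawn(2)
    bio_rng = np.random.default_rng(bio_ss)
    pe_mult: dict[tuple[str, int], float] = {}
    for cl in design.cell_lines:
        for b in range(1, design.n_bio + 1):
            m = float(np.exp(bio_rng.normal(0.0, design.bio_sd))) if design.bio_sd > 0 else 1.0
            pe_mult[(cl.label, b)] = m

    ladder = _seeding_ladder(design)
    doses = sorted(set(design.dose_levels_gy) - {0.0})
    n_wells = (
        len(design.cell_lines)
        * design.n_bio
        * (1 + len(design.modalities) * len(doses))
        * design.n_tech
    )
    well_streams = iter(wells_ss.spawn(n_wells))

    rows: list[dict] = []

    def emit(cl: CellLineSpec, mod_label: str, dose: float, b: int, t: int) -> None:
        seeded = ladder[dose]
        pe = min(cl.pe * pe_mult[(cl.label, b)], 1.0)
        if dose == 0:
            sf = 1.0
        else:
            plan = plan_for(design, cl.label, mod_label, dose)
            sf = min(
                plan_sf(cl.params, plan, design.domain) * design.effect(cl.label, mod_label),
                1.0,
            )
        mean = seeded * pe * sf
        rng = np.random.default_rng(next(well_streams))
        if design.noise == "poisson":
            colonies: float = int(rng.poisson(mean))
        else:
            colonies = mean  # noiseless mode: expected count, stream still consumed
        rows.append(
            {
                "cell_line": cl.label,
                "modality": mod_label,
                "dose_level_gy": dose,
                "bio_rep": b,
                "tech_rep": t,
                "cells_seeded": seeded,
                "colonies": colonies,
            }
        )

    for cl in design.cell_lines:
        for b in range(1, design.n_bio + 1):
            for t in range(1, design.n_tech + 1):
                emit(cl, "control", 0.0, b, t)
            for mod in design.modalities:
                for dose in doses:
                    for t in range(1, design.n_tech + 1):
                        emit(cl, mod.label, dose, b, t)

    return pd.DataFrame(rows, columns=CSV_COLUMNS)
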