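"""Colony-formation-assay reduction and LQ parameter fitting.

Reduces well-level colony counts to plating efficiency (PE), survival
fractions (SF) normalized by each biological replicate's own unirradiated
control, per-condition summaries with an attached equivalent uniform dose,
and a least-squares linear-quadratic fit of ``-ln SF = alpha*D + beta*D**2``
with nonnegativity enforced by clamp-and-refit projection.

CSV schema (header required)::

    cell_line,modality,dose_level_gy,bio_rep,tech_rep,cells_seeded,colonies

Rows with ``dose_level_gy == 0`` are unirradiated (sham-handled) controls.
Colony counting (the >= 50-cell rule) happens upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_field import FractionPlan, IntegrationDomain
from .lqm import LQParams, eud_single_fraction, plan_sf

__all__ = [
    "CFARecord",
    "SurvivalPoint",
    "LQFit",
    "CSV_COLUMNS",
    "read_records",
    "write_records",
    "records_to_frame",
    "plating_efficiency",
    "survival_fraction",
    "survival_table",
    "bio_pooled_survival",
    "summarize_replicates",
    "fit_lq",
]

CSV_COLUMNS = [
    "cell_line",
    "modality",
    "dose_level_gy",
    "bio_rep",
    "tech_rep",
    "cells_seeded",
    "colonies",
]


@dataclass(frozen=True)
class CFARecord:
    """One well of a colony formation assay."""

    cell_line: str
    modality: str
    dose_level_gy: float
    bio_rep: int
    tech_rep: int
    cells_seeded: float
    colonies: float

    def __post_init__(self) -> None:
        if not (self.cells_seeded > 0):
            raise ValueError("cells_seeded must be > 0")
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")


@dataclass(frozen=True)
class SurvivalPoint:
    """Per-condition survival summary with its equivalent uniform dose."""

    cell_line: str
    modality: str
    dose_level_gy: float
    eud_gy: float
    sf_mean: float
    sf_sem: float
    n: int


@dataclass(frozen=True)
class LQFit:
    """Fitted LQ parameters with the unconstrained-fit covariance."""

    alpha: float
    beta: float
    cov: np.ndarray  # 2x2, order (alpha, beta)
    clamped: bool = False

    @property
    def se_alpha(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def se_beta(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    @property
    def params(self) -> LQParams:
        return LQParams(alpha=self.alpha, beta=self.beta)


def records_to_frame(records: Sequence[CFARecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in CSV_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"records frame missing columns: {missing}")
        return records.copy()
    return pd.DataFrame([r.__dict__ for r in records], columns=CSV_COLUMNS)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read the CFA record CSV, validating the schema row-wise."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[(df["cells_seeded"] <= 0) | (df["colonies"] < 0)].tolist()
    if bad:
        raise ValueError(f"{path}: invalid counts in rows {bad[:10]}")
    return df


def write_records(records: Sequence[CFARecord] | pd.DataFrame, path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def plating_efficiency(colonies: float, seeded: float) -> float:
    """Percentage of seeded cells that grew into countable colonies."""
    if not (seeded > 0):
        raise ValueError("seeded must be > 0")
    return 100.0 * colonies / seeded


def survival_fraction(colonies: float, seeded: float, control_pe_percent: float) -> float:
    """Colony yield normalized by seeding and the control plating efficiency."""
    if not (seeded > 0):
        raise ValueError("seeded must be > 0")
    if not (control_pe_percent > 0):
        raise ValueError("control plating efficiency must be > 0")
    return colonies / (seeded * control_pe_percent / 100.0)


def _control_pe_lookup(df: pd.DataFrame) -> dict[tuple[str, str, int], float]:
    """PE (%) per (cell_line, modality, bio_rep) from pooled 0 Gy wells.

    A biological replicate lacking a sham control for its own modality
    falls back to that replicate's controls pooled across modalities.
    """
    controls = df[df["dose_level_gy"] == 0]
    pe: dict[tuple[str, str, int], float] = {}
    by_mod = controls.groupby(["cell_line", "modality", "bio_rep"])
    for key, grp in by_mod:
        pe[key] = plating_efficiency(grp["colonies"].sum(), grp["cells_seeded"].sum())
    pooled: dict[tuple[str, int], float] = {}
    for key, grp in controls.groupby(["cell_line", "bio_rep"]):
        pooled[key] = plating_efficiency(grp["colonies"].sum(), grp["cells_seeded"].sum())

    out: dict[tuple[str, str, int], float] = {}
    missing: list[tuple[str, str, int]] = []
    treated = df[df["dose_level_gy"] > 0]
    for cl, mod, br in (
        treated[["cell_line", "modality", "bio_rep"]].drop_duplicates().itertuples(index=False)
    ):
        if (cl, mod, br) in pe:
            out[(cl, mod, br)] = pe[(cl, mod, br)]
        elif (cl, br) in pooled:
            out[(cl, mod, br)] = pooled[(cl, br)]
        else:
            missing.append((cl, mod, br))
    if missing:
        raise ValueError(
            "no unirradiated control for biological replicate(s): "
            + ", ".join(map(str, missing))
        )
    return out


def survival_table(records: Sequence[CFARecord] | pd.DataFrame) -> pd.DataFrame:
    """Well-level survival fractions for every treated well.

    PE is computed per biological replicate from its own 0 Gy control.
    """
    df = records_to_frame(records)
    pe = _control_pe_lookup(df)
    treated = df[df["dose_level_gy"] > 0].copy()
    treated["control_pe_percent"] = [
        pe[(r.cell_line, r.modality, r.bio_rep)] for r in treated.itertuples()
    ]
    treated["sf"] = treated["colonies"] / (
        treated["cells_seeded"] * treated["control_pe_percent"] / 100.0
    )
    return treated.reset_index(drop=True)


def bio_pooled_survival(records: Sequence[CFARecord] | pd.DataFrame) -> pd.DataFrame:
    """SF per biological replicate, pooling technical-replicate counts.

    Pooled counts (sum colonies / sum seeded) keep low-survival conditions
    well-defined even when an individual well counts zero colonies.
    """
    df = records_to_frame(records)
    pe = _control_pe_lookup(df)
    treated = df[df["dose_level_gy"] > 0]
    rows = []
    for (cl, mod, dose, br), grp in treated.groupby(
        ["cell_line", "modality", "dose_level_gy", "bio_rep"]
    ):
        sf = survival_fraction(
            grp["colonies"].sum(), grp["cells_seeded"].sum(), pe[(cl, mod, br)]
        )
        rows.append(
            {"cell_line": cl, "modality": mod, "dose_level_gy": dose, "bio_rep": br,
             "sf": sf, "n_wells": len(grp)}
        )
    return pd.DataFrame(rows)


def summarize_replicates(
    records: Sequence[CFARecord] | pd.DataFrame,
    params_by_line: Mapping[str, LQParams],
    plan_lookup: Callable[[str, str, float], FractionPlan],
    domain: IntegrationDomain,
) -> pd.DataFrame:
    """Per-condition mean SF, SEM and equivalent uniform dose.

    ``plan_lookup(cell_line, modality, dose_level)`` must return the
    delivered FractionPlan so the condition's EUD can be computed from the
    modeled dose field.
    """
    wells = survival_table(records)
    rows = []
    for (cl, mod, dose), grp in wells.groupby(["cell_line", "modality", "dose_level_gy"]):
        sf = grp["sf"].to_numpy(dtype=float)
        n = sf.size
        sem = float(sf.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        plan = plan_lookup(cl, mod, dose)
        params = params_by_line[cl]
        eud = eud_single_fraction(params, plan_sf(params, plan, domain))
        rows.append(
            SurvivalPoint(cl, mod, float(dose), eud, float(sf.mean()), sem, int(n)).__dict__
        )
    return pd.DataFrame(rows).sort_values(
        ["cell_line", "modality", "dose_level_gy"], ignore_index=True
    )


def fit_lq(
    doses_gy: Sequence[float],
    sf: Sequence[float],
    weights: Sequence[float] | None = None,
) -> LQFit:
    """Least-squares LQ fit of ``-ln SF = alpha*D + beta*D**2``.

    No intercept (SF(0) = 1 by normalization).  Negative estimates are
    projected to the boundary: the offending parameter is clamped at zero
    and the other refitted.  The covariance reported is that of the
    unconstrained fit, ``sigma**2 * (X'X)**-1``.
    """
    d = np.asarray(doses_gy, dtype=float)
    s = np.asarray(sf, dtype=float)
    if d.shape != s.shape or d.ndim != 1:
        raise ValueError("doses and sf must be 1-D and the same length")
    if np.any(s <= 0) or np.any(s > 1):
        raise ValueError("all sf must lie in (0, 1]")
    if np.unique(d[d > 0]).size < 2:
        raise ValueError("need >= 2 distinct positive doses")
    y = -np.log(s)
    X = np.column_stack([d, d**2])
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    # covariance of the unconstrained estimator
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    dof = max(len(y) - 2, 1)
    resid = yw - Xw @ coef
    sigma2 = float(resid @ resid) / dof if len(y) > 2 else 0.0
    cov = sigma2 * xtx_inv

    alpha, beta = float(coef[0]), float(coef[1])
    clamped = False
    if beta < 0:
        beta, clamped = 0.0, True
        alpha = float((Xw[:, 0] @ yw) / (Xw[:, 0] @ Xw[:, 0]))
        alpha = max(alpha, 0.0)
    elif alpha < 0:
        alpha, clamped = 0.0, True
        beta = float((Xw[:, 1] @ yw) / (Xw[:, 1] @ Xw[:, 1]))
        beta = max(beta, 0.0)
    if alpha == 0.0 and beta == 0.0:
        raise ValueError("degenerate fit: no radiation kill in the data")
    return LQFit(alpha=alpha, beta=beta, cov=cov, clamped=clamped)
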