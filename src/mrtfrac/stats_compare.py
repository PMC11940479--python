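"""Pairwise ANCOVA comparison of survival curves across treatment arms.

For each pair of arms a common-slope linear model

    response = b0 + b1 * EUD + b2 * 1[arm B]

is fitted to replicate-level observations (response = ln SF by default,
variance-stabilizing for survival curves; the covariate is the equivalent
uniform single-fraction dose).  The reported p-value is the two-sided test
of the group term ``b2``, which for one degree of freedom coincides with
the partial F test of adding the group to the dose-only regression.  An
interaction model is fitted alongside and its slope-difference p-value is
kept as a secondary diagnostic.  Raw pairwise p-values are reported by
default, matching how such 3-arm comparisons are usually tabulated; Holm
adjustment across the pairs is available as an option.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ComparisonResult", "ancova_pairwise", "significance_table"]


@dataclass(frozen=True)
class ComparisonResult:
    """Symmetric matrix of pairwise p-values over treatment arms."""

    cell_line: str
    modalities: tuple[str, ...]
    pvalues: pd.DataFrame  # symmetric, NaN diagonal
    slope_pvalues: pd.DataFrame  # interaction-model slope-difference p
    model: str
    alpha_level: float = 0.05
    dose_range_gy: tuple[float, float] | None = None


def _pair_pvalues(
    sub: pd.DataFrame, a: str, b: str, response: str
) -> tuple[float, float]:
    y = sub[response].to_numpy(dtype=float)
    eud = sub["eud_gy"].to_numpy(dtype=float)
    grp = (sub["modality"] == b).to_numpy(dtype=float)
    if np.unique(eud).size < 2:
        raise ValueError("singular design: need >= 2 distinct dose (EUD) levels")
    X = sm.add_constant(np.column_stack([eud, grp]))
    fit = sm.OLS(y, X).fit()
    p_group = float(fit.pvalues[2])
    Xi = sm.add_constant(np.column_stack([eud, grp, eud * grp]))
    fit_i = sm.OLS(y, Xi).fit()
    p_slope = float(fit_i.pvalues[3])
    return p_group, p_slope


def _holm(p: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    items = sorted(p.items(), key=lambda kv: kv[1])
    m = len(items)
    adj, running = {}, 0.0
    for i, (k, v) in enumerate(items):
        running = max(running, min(1.0, (m - i) * v))
        adj[k] = running
    return adj


def ancova_pairwise(
    observations: pd.DataFrame,
    cell_line: str = "",
    response_scale: Literal["log", "linear"] = "log",
    dose_range_gy: tuple[float, float] | None = None,
    alpha_level: float = 0.05,
    holm: bool = False,
) -> ComparisonResult:
    """Pairwise common-slope ANCOVA over all arms in ``observations``.

    ``observations`` needs columns ``modality``, ``eud_gy`` and ``sf`` at
    replicate level (one row per assay well, or per pooled biological
    replicate).  ``dose_range_gy`` restricts observations to an EUD window
    before testing.
    """
    df = observations.copy()
    for col in ("modality", "eud_gy", "sf"):
        if col not in df.columns:
            raise ValueError(f"observations missing column '{col}'")
    if dose_range_gy is not None:
        lo, hi = dose_range_gy
        df = df[(df["eud_gy"] >= lo) & (df["eud_gy"] <= hi)]
    mods = tuple(sorted(df["modality"].unique()))
    if len(mods) < 2:
        raise ValueError("need at least two treatment arms")
    counts = df.groupby("modality").size()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"need >= 3 observations per arm, got {dict(small)}")
    if response_scale == "log":
        bad = df.index[df["sf"] <= 0]
        if len(bad):
            raise ValueError(
                f"sf <= 0 on the log response scale in rows {bad.tolist()[:10]}"
            )
        df = df.assign(response=np.log(df["sf"]))
        model = "ln(SF) ~ EUD + arm (common slope)"
    else:
        df = df.assign(response=df["sf"])
        model = "SF ~ EUD + arm (common slope)"

    pvals: dict[tuple[str, str], float] = {}
    slopes: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(mods, 2):
        sub = df[df["modality"].isin([a, b])]
        pvals[(a, b)], slopes[(a, b)] = _pair_pvalues(sub, a, b, "response")
    if holm:
        pvals = _holm(pvals)

    def matrix(d: dict[tuple[str, str], float]) -> pd.DataFrame:
        m = pd.DataFrame(np.nan, index=mods, columns=mods)
        for (a, b), v in d.items():
            m.loc[a, b] = m.loc[b, a] = v
        return m

    return ComparisonResult(
        cell_line=cell_line,
        modalities=mods,
        pvalues=matrix(pvals),
        slope_pvalues=matrix(slopes),
        model=model,
        alpha_level=alpha_level,
        dose_range_gy=dose_range_gy,
    )


def format_p(p: float) -> str:
    """p-value with significance stars: <= 0.05 '*', <= 0.001 '**'."""
    text = f"{p:.3f}" if p >= 0.001 else f"{p:.1e}"
    if p <= 0.001:
        return f"{text} **"
    if p <= 0.05:
        return f"{text} *"
    return text


def significance_table(result: ComparisonResult) -> pd.DataFrame:
    """Star-annotated symmetric p-value matrix, CSV-serializable."""
    mods = result.modalities
    out = pd.DataFrame("-", index=mods, columns=mods)
    for a in mods:
        for b in mods:
            if a != b:
                out.loc[a, b] = format_p(float(result.pvalues.loc[a, b]))
    return out
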