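"""Bliss-independence synergy scoring for fixed-dose sensitizer combinations.

Two independently acting drugs with single-agent inhibition fractions E1
and E2 are expected, under Bliss independence, to inhibit

    Additive = E1 + E2 − E1·E2

of the population (surviving fraction multiplies). The *excess* of the
observed combination inhibition over this additive reference is the
synergy score at each dose; a combination is called synergistic when the
mean excess across the dilution series clears a threshold and most doses
show positive excess. The sensitizer is modelled at one fixed
concentration (its IC15), so E2 is dose-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SynergyCall",
    "inhibition_from_viability",
    "bliss_additive",
    "score_combination",
    "call_synergy",
]


def inhibition_from_viability(viability, control=1.0):
    """Inhibition fraction E = clip(1 − viability/control, 0, 1).

    ``control`` is the untreated-well viability the series is normalized
    to; it must be positive.
    """
    control = np.asarray(control, dtype=float)
    if np.any(control <= 0):
        raise ValueError("control viability must be > 0")
    v = np.asarray(viability, dtype=float)
    out = np.clip(1.0 - v / control, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def bliss_additive(e1, e2):
    """Bliss additive reference: E1 + E2 − E1·E2 for E1, E2 in [0, 1]."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if np.any((e1 < 0) | (e1 > 1)) or np.any((e2 < 0) | (e2 > 1)):
        raise ValueError("inhibition fractions must lie in [0, 1]")
    out = e1 + e2 - e1 * e2
    return float(out) if out.ndim == 0 else out


def score_combination(
    single_curve: pd.DataFrame,
    sensitizer_inhibition: float,
    combo_curve: pd.DataFrame,
    control: float = 1.0,
) -> pd.DataFrame:
    """Per-dose Bliss excess of a combination over its additive reference.

    ``single_curve`` and ``combo_curve`` are DataFrames with ``dose`` and
    ``viability`` columns on identical dose grids (replicates are
    averaged per dose). Returns one row per dose with columns
    ``dose, E1, E2, E_obs, additive, excess``.
    """
    if not 0 <= sensitizer_inhibition <= 1:
        raise ValueError("sensitizer inhibition must lie in [0, 1]")

    def per_dose(df: pd.DataFrame) -> pd.Series:
        return df.groupby("dose")["viability"].mean()

    vs, vc = per_dose(single_curve), per_dose(combo_curve)
    if not vs.index.equals(vc.index):
        off = sorted(set(vs.index).symmetric_difference(vc.index))
        raise ValueError(f"single and combo dose grids differ at doses: {off}")

    e1 = inhibition_from_viability(vs.to_numpy(), control)
    e_obs = inhibition_from_viability(vc.to_numpy(), control)
    additive = bliss_additive(e1, sensitizer_inhibition)
    return pd.DataFrame(
        {
            "dose": vs.index.to_numpy(),
            "E1": e1,
            "E2": sensitizer_inhibition,
            "E_obs": e_obs,
            "additive": additive,
            "excess": e_obs - additive,
        }
    )


@dataclass
class SynergyCall:
    """Summary synergy decision for one drug × sample combination."""

    mean_excess: float
    n_doses: int
    n_doses_above_additive: int
    is_synergistic: bool
    ci_low: float
    ci_high: float
    drug: str = ""
    sample: str = ""


def call_synergy(
    points: pd.DataFrame,
    min_excess: float = 0.1,
    min_fraction_doses: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
    drug: str = "",
    sample: str = "",
) -> SynergyCall:
    """Call a combination synergistic from its per-dose excess scores.

    Synergy requires mean excess > ``min_excess`` AND positive excess at
    at least ``min_fraction_doses`` of the tested doses. The confidence
    interval on the mean excess is a seeded percentile bootstrap over
    doses (2.5/97.5 percentiles).
    """
    excess = np.asarray(points["excess"], dtype=float)
    n = len(excess)
    if n < 3:
        raise ValueError("need >= 3 dose points to call synergy")
    mean_excess = float(excess.mean())
    n_above = int((excess > 0).sum())
    is_syn = mean_excess > min_excess and n_above >= min_fraction_doses * n

    rng = np.random.default_rng(seed)
    boot = excess[rng.integers(0, n, size=(n_boot, n))].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return SynergyCall(
        mean_excess=mean_excess,
        n_doses=n,
        n_doses_above_additive=n_above,
        is_synergistic=bool(is_syn),
        ci_low=float(lo),
        ci_high=float(hi),
        drug=drug,
        sample=sample,
    )
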