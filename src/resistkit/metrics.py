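"""Closed-form assay statistics: proteasome ΔRFU and caliper tumor volume."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["proteasome_activity", "proteasome_activity_table", "tumor_volume"]


def proteasome_activity(rfu1, rfu2, irfu1, irfu2):
    """Proteasome activity as inhibitor-corrected fluorescence gain.

    ΔRFU = (RFU2 − iRFU2) − (RFU1 − iRFU1), where RFU are total
    proteolytic reads at two times and iRFU the matched reads with a
    proteasome inhibitor present (non-proteasome background). Adding a
    common constant to all four reads leaves the result unchanged.
    Accepts scalars or arrays.
    """
    out = (np.asarray(rfu2, float) - np.asarray(irfu2, float)) - (
        np.asarray(rfu1, float) - np.asarray(irfu1, float)
    )
    return float(out) if np.ndim(out) == 0 else out


def proteasome_activity_table(kinetics: pd.DataFrame) -> pd.DataFrame:
    """Apply the ΔRFU statistic to a kinetic read table.

    Expects columns ``rfu1, rfu2, irfu1, irfu2``; returns the table with
    a ``delta_rfu`` column appended.
    """
    required = {"rfu1", "rfu2", "irfu1", "irfu2"}
    missing = required - set(kinetics.columns)
    if missing:
        raise ValueError(f"kinetic table missing columns: {sorted(missing)}")
    out = kinetics.copy()
    out["delta_rfu"] = proteasome_activity(
        out["rfu1"], out["rfu2"], out["irfu1"], out["irfu2"]
    )
    return out


def tumor_volume(a, b):
    """Caliper tumor volume V = (a² × b)/2, a = width, b = length (mm).

    If a measurement pair arrives with width > length the two are
    swapped (calipers are order-ambiguous in practice) and a warning is
    logged. Non-positive measurements are an error. Accepts scalars or
    arrays; volume is in mm³.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("tumor measurements must be > 0")
    swapped = a > b
    if np.any(swapped):
        logger.warning(
            "%d measurement pair(s) had width > length; swapped", int(np.sum(swapped))
        )
        a, b = np.where(swapped, b, a), np.where(swapped, a, b)
    out = a**2 * b / 2.0
    return float(out) if out.ndim == 0 else out
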