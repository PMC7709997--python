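"""4PL dose-response fitting, ECk estimation and resistance classification.

The viability model is the four-parameter logistic

    v(d) = bottom + (top - bottom) / (1 + (d / IC50)^h)

with viability expressed as fraction of untreated control (top bounded
at 1.2 to accommodate luminescence fractions slightly above 1, bottom
bounded at 0). IC50 is the curve midpoint (relative IC50). A drug is
called resistant when IC50(resistant line)/IC50(parental line) exceeds
5-fold (strict >), and a resistant drug is called reversed when the
fixed-dose sensitizer combination lowers the resistant line's IC50 more
than 5-fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseFit",
    "fit_4pl",
    "fit_panel",
    "ec_k",
    "classify_resistance",
    "DEFAULT_FOLD_THRESHOLD",
]

DEFAULT_FOLD_THRESHOLD = 5.0


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters for one drug × cell line × arm curve."""

    ic50: float
    hill_slope: float
    top: float
    bottom: float
    rss: float
    ic50_censored: str = "none"  # none | above_max_dose | below_min_dose
    drug: str = ""
    cell_line: str = ""
    arm: str = ""
    min_dose: float = np.nan
    max_dose: float = np.nan
    diagnostic: str = ""

    def predict(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (dose / self.ic50) ** self.hill_slope
        )


def _model(dose, bottom, span, hill, log10_ic50):
    return bottom + span / (1.0 + (dose / 10.0**log10_ic50) ** hill)


def fit_4pl(
    doses: Iterable[float],
    viability: Iterable[float],
    drug: str = "",
    cell_line: str = "",
    arm: str = "",
    top_max: float = 1.2,
    average_replicates: bool = True,
) -> DoseResponseFit:
    """Least-squares 4PL fit of a dilution-series viability curve.

    Initialization is data-driven (top = max, bottom = min, IC50 = dose
    nearest half-range, slope 1). The IC50 is censored when it falls
    outside [min_dose/10, 10*max_dose] or when the fitted curve never
    crosses its own midpoint within the tested dose range; in that case
    ``ic50`` holds the relevant dose-range bound. Non-convergence yields
    a censored fit with a diagnostic, never an exception.
    """
    d = np.asarray(list(doses), dtype=float)
    v = np.asarray(list(viability), dtype=float)
    if d.shape != v.shape:
        raise ValueError("doses and viability must have equal length")
    if np.any(d <= 0):
        raise ValueError("doses must be > 0")
    if average_replicates:
        df = pd.DataFrame({"dose": d, "v": v}).groupby("dose", as_index=False).mean()
        d, v = df["dose"].to_numpy(), df["v"].to_numpy()
    if len(np.unique(d)) < 4:
        raise ValueError("need >= 4 distinct doses for a 4PL fit")

    lo, hi = float(d.min()), float(d.max())
    top0, bot0 = float(v.max()), float(v.min())
    mid0 = (top0 + bot0) / 2.0
    ic50_0 = float(d[np.argmin(np.abs(v - mid0))])
    p0 = [max(bot0, 0.0), max(top0 - bot0, 1e-3), 1.0, np.log10(ic50_0)]
    bounds = (
        [0.0, 0.0, 0.1, np.log10(lo) - 3],
        [top_max, top_max, 10.0, np.log10(hi) + 3],
    )
    p0 = np.clip(p0, bounds[0], bounds[1])

    try:
        popt, _ = curve_fit(
            _model, d, v, p0=p0, bounds=bounds, maxfev=20000,
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        bottom, span, hill, log10_ic50 = popt
        ic50 = 10.0**log10_ic50
        top = bottom + span
        rss = float(np.sum((v - _model(d, *popt)) ** 2))
        diagnostic = ""
    except RuntimeError as exc:  # pragma: no cover - hard to trigger reliably
        bottom, top, hill, ic50 = bot0, top0, 1.0, np.nan
        rss = float("nan")
        diagnostic = f"fit did not converge: {exc}"

    fit = DoseResponseFit(
        ic50=float(ic50),
        hill_slope=float(hill),
        top=float(top),
        bottom=float(bottom),
        rss=rss,
        drug=drug,
        cell_line=cell_line,
        arm=arm,
        min_dose=lo,
        max_dose=hi,
        diagnostic=diagnostic,
    )
    _apply_censoring(fit, v)
    return fit


def _apply_censoring(fit: DoseResponseFit, v: np.ndarray) -> None:
    """Censor IC50s outside the informative range of the tested doses."""
    mid = (fit.top + fit.bottom) / 2.0
    flat = (fit.top - fit.bottom) < 0.05
    if not np.isfinite(fit.ic50):
        fit.ic50_censored = "above_max_dose" if np.mean(v) > 0.5 else "below_min_dose"
        fit.ic50 = fit.max_dose if fit.ic50_censored == "above_max_dose" else fit.min_dose
        return
    if flat:
        # no dose-dependent kill observed: direction from overall level
        fit.ic50_censored = "above_max_dose" if np.mean(v) > 0.5 else "below_min_dose"
    elif fit.predict(fit.max_dose) > mid or fit.ic50 > 10 * fit.max_dose:
        fit.ic50_censored = "above_max_dose"
    elif fit.predict(fit.min_dose) < mid or fit.ic50 < fit.min_dose / 10:
        fit.ic50_censored = "below_min_dose"
    else:
        fit.ic50_censored = "none"
        return
    fit.ic50 = fit.max_dose if fit.ic50_censored == "above_max_dose" else fit.min_dose


def fit_panel(dose_table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Fit every (drug, cell_line, arm) curve in a DoseTable.

    Returns one row per curve with the fitted parameters and censoring
    status.
    """
    rows = []
    for (drug, line, arm), grp in dose_table.groupby(["drug", "cell_line", "arm"]):
        fit = fit_4pl(
            grp["dose"], grp["viability"], drug=drug, cell_line=line, arm=arm, **kwargs
        )
        rows.append(
            {
                "drug": drug,
                "cell_line": line,
                "arm": arm,
                "ic50": fit.ic50,
                "hill_slope": fit.hill_slope,
                "top": fit.top,
                "bottom": fit.bottom,
                "rss": fit.rss,
                "ic50_censored": fit.ic50_censored,
                "min_dose": fit.min_dose,
                "max_dose": fit.max_dose,
            }
        )
    return pd.DataFrame(rows)


def ec_k(
    fit: DoseResponseFit, k: float, reference: str = "absolute"
) -> tuple[float, str]:
    """Dose producing k % inhibition under the fitted curve.

    ``reference="absolute"`` measures inhibition against untreated
    control (viability 1.0): the returned dose solves v(d) = 1 − k/100,
    the convention behind statements like "sensitizer at its IC15".
    ``reference="relative"`` measures k % of the fitted top→bottom span,
    so ec_k(50) is the fitted IC50 for any top/bottom.

    Returns ``(dose, censored)`` with censored in {"none",
    "below_min_effect", "above_max_effect"} when the requested effect
    lies outside the span the curve can produce.
    """
    if not 0 < k < 100:
        raise ValueError("k must be in (0, 100)")
    if fit.ic50_censored != "none":
        raise ValueError("cannot invert a censored fit")
    top, bottom, h = fit.top, fit.bottom, fit.hill_slope
    if reference == "relative":
        ratio = (k / 100.0) / (1.0 - k / 100.0)
        return float(fit.ic50 * ratio ** (1.0 / h)), "none"
    if reference != "absolute":
        raise ValueError(f"unknown reference {reference!r}")
    v_k = 1.0 - k / 100.0
    if v_k >= top:
        # even at zero dose the curve sits below the requested viability
        return 0.0, "below_min_effect"
    if v_k <= bottom:
        return float("inf"), "above_max_effect"
    ratio = (top - v_k) / (v_k - bottom)
    return float(fit.ic50 * ratio ** (1.0 / h)), "none"


def _fold_change(
    num_ic50: float,
    num_cens: str,
    den_ic50: float,
    den_cens: str,
) -> tuple[float, str]:
    """Fold change num/den with censoring propagated as a bound qualifier.

    Returns (fold, qualifier) where qualifier is "" for a point estimate,
    ">" when the true fold is at least the returned value, "<" when at
    most, and "indeterminate" when both IC50s are censored in the same
    direction and no bound exists.
    """
    if num_cens != "none" and num_cens == den_cens:
        return float("nan"), "indeterminate"
    fold = num_ic50 / den_ic50
    qual = ""
    if num_cens == "above_max_dose" or den_cens == "below_min_dose":
        qual = ">"
    if num_cens == "below_min_dose" or den_cens == "above_max_dose":
        qual = "<"
    return float(fold), qual


def classify_resistance(
    fits: pd.DataFrame,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    parental_line: str = "parental",
    resistant_line: str = "resistant",
) -> pd.DataFrame:
    """Per-drug resistance and reversal calls from a table of panel fits.

    ``fits`` is the output of :func:`fit_panel`. For each drug:

    * fold_change_resistance = IC50(resistant, single)/IC50(parental,
      single); ``is_resistant`` iff the fold (or its lower bound, when an
      IC50 is censored) strictly exceeds ``fold_threshold``;
    * category is exactly one of {resistant, more_toxic_to_resistant
      (fold below 1/threshold), unchanged, indeterminate};
    * for resistant drugs with a combination-arm fit,
      fold_change_reversal = IC50(resistant, single)/IC50(resistant,
      combo); ``is_reversed`` iff it strictly exceeds the threshold.
    """
    idx = fits.set_index(["drug", "cell_line", "arm"])
    rows = []
    for drug in fits["drug"].unique():
        try:
            par = idx.loc[(drug, parental_line, "single")]
            res = idx.loc[(drug, resistant_line, "single")]
        except KeyError as exc:
            raise ValueError(f"drug {drug!r} lacks a parental or resistant single-arm fit") from exc

        fold_r, qual_r = _fold_change(
            res["ic50"], res["ic50_censored"], par["ic50"], par["ic50_censored"]
        )
        if qual_r == "indeterminate":
            category = "indeterminate"
            is_resistant = False
            logger.warning("drug %s: both IC50s censored in the same direction", drug)
        else:
            # conservative with bounds: call only when the bound itself clears
            is_resistant = bool(fold_r > fold_threshold) and qual_r != "<"
            more_toxic = bool(fold_r < 1.0 / fold_threshold) and qual_r != ">"
            if is_resistant:
                category = "resistant"
            elif more_toxic:
                category = "more_toxic_to_resistant"
            else:
                category = "unchanged"

        fold_v, qual_v, is_reversed = float("nan"), "", False
        if is_resistant and (drug, resistant_line, "combo") in idx.index:
            combo = idx.loc[(drug, resistant_line, "combo")]
            fold_v, qual_v = _fold_change(
                res["ic50"], res["ic50_censored"], combo["ic50"], combo["ic50_censored"]
            )
            if qual_v != "indeterminate":
                is_reversed = bool(fold_v > fold_threshold) and qual_v != "<"

        rows.append(
            {
                "drug": drug,
                "ic50_parental": par["ic50"],
                "ic50_resistant": res["ic50"],
                "fold_change_resistance": fold_r,
                "resistance_qualifier": qual_r,
                "is_resistant": is_resistant,
                "category": category,
                "fold_change_reversal": fold_v,
                "reversal_qualifier": qual_v,
                "is_reversed": is_reversed,
            }
        )
    return pd.DataFrame(rows)
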