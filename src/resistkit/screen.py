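"""RNAi screen scoring: normalization, Z-scores, hit calling, enrichment.

The screen statistic follows the hybrid convention used in large
viability screens: z = (x − μ)/σ with μ the screen-wide *median* of the
experimental value x and σ the ordinary standard deviation. The
experimental value defaults to the log2 drug-arm fraction-of-control
viability, so that a sensitizing knockdown (stronger killing under
drug) has x << 0; a paired-ratio mode (x = log2 drug/vehicle) is
available for screens where reagent-intrinsic viability effects must be
cancelled against the vehicle arm.

Scores are reported on a *sensitivity-oriented* scale: the sign is
flipped so that sensitizing genes receive positive z, matching the
convention in which genes with z >= +2.5 form the sensitive list and
genes with z <= −2.5 the resistant list (both thresholds inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenStats",
    "normalize_wells",
    "sirna_log2_ratio",
    "zscore",
    "aggregate_gene",
    "score_screen",
    "call_hits",
    "enrich",
    "intersect_gene_lists",
]

DEFAULT_Z_THRESHOLD = 2.5


@dataclass(frozen=True)
class ScreenStats:
    """Screen-wide location/scale: median center and standard deviation."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


def normalize_wells(wells: pd.DataFrame, design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Express each well as a fraction of its plate/arm control median.

    Dividing by the median of the negative-control wells on the same
    plate and arm removes multiplicative plate effects. Raises if any
    plate lacks control wells for an arm, naming the plate.
    """
    required = {"plate", "well", "arm", "signal", "is_control"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")

    ctrl = wells[wells["is_control"]]
    ctrl_median = ctrl.groupby(["plate", "arm"])["signal"].median()

    for (plate, arm), _ in wells.groupby(["plate", "arm"]):
        if (plate, arm) not in ctrl_median.index:
            raise ValueError(f"plate {plate!r} has no control wells for arm {arm!r}")

    keys = pd.MultiIndex.from_frame(wells[["plate", "arm"]])
    out = wells.copy()
    out["norm"] = wells["signal"].to_numpy() / ctrl_median.reindex(keys).to_numpy()
    return out


def sirna_log2_ratio(norm: pd.DataFrame, mode: str = "ratio") -> pd.Series:
    """Per-siRNA experimental value x.

    ``mode="ratio"``: x = log2(drug-arm / vehicle-arm normalized
    viability), averaging replicates within an arm first — cancels
    reagent-intrinsic (drug-independent) viability effects against the
    vehicle arm at the cost of doubling the technical variance of x.
    ``mode="drug"``: x = log2(drug-arm normalized viability) alone.
    siRNAs with a non-positive or missing vehicle value are excluded
    with a logged count.
    """
    samples = norm[~norm["is_control"] & (norm["sirna_id"] != "")]
    by_arm = samples.groupby(["sirna_id", "arm"])["norm"].mean().unstack("arm")
    if "drug" not in by_arm.columns:
        raise ValueError("no drug-arm wells found")
    if mode == "drug":
        drug = by_arm["drug"]
        bad = ~(drug > 0) | drug.isna()
        if bad.any():
            logger.warning("excluded %d siRNAs with non-positive drug-arm value", bad.sum())
        return np.log2(drug[~bad]).rename("x")
    if mode != "ratio":
        raise ValueError(f"unknown mode {mode!r}")
    if "vehicle" not in by_arm.columns:
        raise ValueError("no vehicle-arm wells found; use mode='drug'")
    bad = ~(by_arm["vehicle"] > 0) | by_arm["vehicle"].isna() | by_arm["drug"].isna()
    if bad.any():
        logger.warning(
            "excluded %d siRNAs with missing or non-positive vehicle-arm value",
            int(bad.sum()),
        )
    ok = by_arm[~bad]
    return np.log2(ok["drug"] / ok["vehicle"]).rename("x")


def zscore(
    values: pd.Series | np.ndarray, stats: ScreenStats | None = None
) -> tuple[pd.Series, ScreenStats]:
    """Screen Z-score: z = (x − μ)/σ, μ = median of x, σ = its std (ddof=1).

    When ``stats`` is supplied (e.g. computed once over the whole screen)
    it is used as-is; otherwise μ and σ are estimated from ``values``,
    which then must contain at least three finite entries.
    """
    s = pd.Series(values, dtype=float)
    if stats is None:
        finite = s.dropna()
        if len(finite) < 3:
            raise ValueError("need >= 3 values to estimate screen stats")
        sigma = float(finite.std(ddof=1))
        if sigma == 0:
            raise ValueError("sigma is zero: all values identical")
        stats = ScreenStats(mu=float(finite.median()), sigma=sigma)
    return (s - stats.mu) / stats.sigma, stats


def aggregate_gene(
    sirna_values: pd.Series,
    design: pd.DataFrame,
    method: str = "median",
) -> pd.Series:
    """Collapse per-siRNA values to one value per gene.

    ``median`` (default) is robust to a single off-target siRNA out of
    three; ``mean`` and ``second_best`` (second-lowest value, i.e. the
    second-strongest sensitizing reagent, a guard against single-siRNA
    artifacts) are also available. Genes whose siRNAs all dropped out are
    excluded with a logged count.
    """
    mapping = design.set_index("sirna_id")["gene_id"]
    unmapped = sirna_values.index.difference(mapping.index)
    if len(unmapped) > 0:
        raise ValueError(f"{len(unmapped)} siRNAs missing from design, e.g. {unmapped[0]!r}")
    genes = mapping.reindex(sirna_values.index)
    grouped = sirna_values.groupby(genes)
    if method == "median":
        out = grouped.median()
    elif method == "mean":
        out = grouped.mean()
    elif method == "second_best":
        out = grouped.apply(lambda v: v.sort_values().iloc[min(1, len(v) - 1)])
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    n_lost = design["gene_id"].nunique() - len(out)
    if n_lost > 0:
        logger.warning("%d genes had no surviving siRNAs and were excluded", n_lost)
    return out.rename("x_gene")


def score_screen(
    wells: pd.DataFrame,
    design: pd.DataFrame,
    aggregation: str = "median",
    level: str = "gene",
    threshold: float = DEFAULT_Z_THRESHOLD,
    mode: str = "drug",
) -> pd.DataFrame:
    """Full scoring pipeline: normalize → x → aggregate → z → hit class.

    ``level="gene"`` (default) aggregates siRNA x values per gene and
    z-scores the gene-level summary; ``level="sirna"`` z-scores per siRNA
    first, then aggregates the z values. The default experimental value
    is the drug-arm fraction of control (``mode="drug"``); pass
    ``mode="ratio"`` to score the paired drug/vehicle log2 ratio instead.
    Returns one row per gene with ``gene_id, n_sirnas, x_gene, z,
    hit_class``; z is sensitivity-oriented (positive = knockdown
    sensitizes to the drug).
    """
    norm = normalize_wells(wells, design)
    x = sirna_log2_ratio(norm, mode=mode)
    if level == "gene":
        x_gene = aggregate_gene(x, design, method=aggregation)
        z_raw, _ = zscore(x_gene)
    elif level == "sirna":
        z_sirna, _ = zscore(x)
        z_raw = aggregate_gene(z_sirna, design, method=aggregation)
        x_gene = aggregate_gene(x, design, method=aggregation)
    else:
        raise ValueError(f"unknown level {level!r}")

    n_sirnas = design.groupby("gene_id")["sirna_id"].nunique()
    scores = pd.DataFrame(
        {
            "gene_id": x_gene.index,
            "n_sirnas": n_sirnas.reindex(x_gene.index).to_numpy(),
            "x_gene": x_gene.to_numpy(),
            # flip: viability loss under drug (x << 0) scores positive
            "z": -z_raw.reindex(x_gene.index).to_numpy(),
        }
    ).reset_index(drop=True)
    scores["hit_class"] = np.select(
        [scores["z"] >= threshold, scores["z"] <= -threshold],
        ["sensitive", "resistant"],
        default="neutral",
    )
    return scores.sort_values(["z", "gene_id"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


def call_hits(
    gene_scores: pd.DataFrame, threshold: float = DEFAULT_Z_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Split scored genes into sensitive and resistant lists at ±threshold.

    Thresholds are inclusive (z >= +t sensitive, z <= −t resistant) and
    the two lists are disjoint; every remaining gene is neutral.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    z = gene_scores["z"]
    sensitive = gene_scores.loc[z >= threshold, "gene_id"].tolist()
    resistant = gene_scores.loc[z <= -threshold, "gene_id"].tolist()
    return sensitive, resistant


def enrich(
    hit_list: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a hit list.

    For a universe of M genes, a set of K genes (after intersection with
    the universe) and n hits of which k fall in the set, the p-value is
    the upper tail P(X >= k) of Hypergeom(M, K, n). q-values are
    Benjamini–Hochberg; rows are sorted by p (stable).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    hits = set(hit_list)
    if not hits:
        raise ValueError("hit list is empty")
    stray = hits - universe_set
    if stray:
        raise ValueError(f"{len(stray)} hits not in universe, e.g. {next(iter(stray))!r}")

    M, n = len(universe_set), len(hits)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe_set
        K = len(in_universe)
        k = len(in_universe & hits)
        p = float(hypergeom.sf(k - 1, M, K, n)) if K > 0 else 1.0
        rows.append(
            {
                "set_name": name,
                "universe_size": M,
                "set_size": K,
                "n_hits": n,
                "n_hits_in_set": k,
                "p_value": min(p, 1.0),
            }
        )
    res = pd.DataFrame(rows)
    res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
    return res.sort_values("p_value", kind="stable").reset_index(drop=True)


def intersect_gene_lists(*lists: Iterable[str]) -> list[str]:
    """Exact intersection of two or more gene lists.

    Order follows the first list; duplicates collapse to first occurrence.
    """
    if len(lists) == 1 and not isinstance(lists[0], str):
        first = list(lists[0])
        if first and isinstance(first[0], (list, tuple, set)):
            lists = tuple(first)  # called with a list of lists
    if len(lists) < 2:
        raise ValueError("need at least two lists to intersect")
    rest = [set(l) for l in lists[1:]]
    seen: set[str] = set()
    out = []
    for g in lists[0]:
        if g in seen:
            continue
        seen.add(g)
        if all(g in s for s in rest):
            out.append(g)
    return out
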