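"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates one experimental design from the study and
attaches ground-truth labels so that downstream recovery can be measured:

* :func:`simulate_screen` — a paired drug/vehicle genome-wide siRNA
  viability screen with planted sensitizer and resistor genes;
* :func:`simulate_dose_response` — seven-point threefold dilution
  viability panels for a parental and a resistant line, with and without
  a fixed-dose sensitizer;
* :func:`simulate_fret_movie` — paired CFP/YFP image stacks of
  Gaussian-blob cells whose YFP/CFP ratio drops at a planted caspase
  activation time;
* :func:`simulate_proteasome_kinetics` — fluorogenic-substrate kinetic
  reads with and without a proteasome inhibitor.

All generators take an explicit integer seed and never touch global
random state; identical configs and seeds reproduce output tables
exactly.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenSimConfig",
    "DoseResponseSimConfig",
    "FretSimConfig",
    "GroundTruth",
    "ImageStackPair",
    "simulate_screen",
    "simulate_dose_response",
    "simulate_fret_movie",
    "simulate_proteasome_kinetics",
]

# standard microplate geometries (rows, columns)
_PLATE_LAYOUTS = {
    6: (2, 3),
    12: (3, 4),
    24: (4, 6),
    48: (6, 8),
    96: (8, 12),
    384: (16, 24),
    1536: (32, 48),
}


def _plate_geometry(plate_size: int) -> tuple[int, int]:
    if plate_size in _PLATE_LAYOUTS:
        return _PLATE_LAYOUTS[plate_size]
    nrows = int(math.ceil(math.sqrt(plate_size)))
    ncols = int(math.ceil(plate_size / nrows))
    return nrows, ncols


def _row_label(i: int) -> str:
    letters = string.ascii_uppercase
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = letters[rem] + label
    return label


def well_address(index: int, plate_size: int) -> str:
    """Row/column address (e.g. ``A01``) of the index-th well on a plate."""
    nrows, ncols = _plate_geometry(plate_size)
    if index >= nrows * ncols:
        raise ValueError(f"well index {index} exceeds {nrows}x{ncols} plate")
    row, col = divmod(index, ncols)
    return f"{_row_label(row)}{col + 1:02d}"


@dataclass
class GroundTruth:
    """Planted truth attached to simulated datasets.

    Only the fields relevant to the generating call are populated.
    """

    true_hit_labels: dict[str, str] = field(default_factory=dict)
    true_ic50: dict[tuple[str, str, str], float] = field(default_factory=dict)
    true_activation: dict[str, float | None] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# RNAi screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Configuration of a paired-arm (drug vs vehicle) siRNA screen.

    Effects are in log2 viability-ratio units: a planted sensitizer gene
    with ``sensitizer_effect = -1.5`` roughly halves the drug-arm
    viability of its siRNA wells relative to vehicle. ``noise_sd`` is the
    Gaussian noise on the per-siRNA log2 drug/vehicle ratio; each arm
    receives an independent draw of ``noise_sd / sqrt(2)`` so the ratio
    carries exactly ``noise_sd``.

    The library is laid out as ``sirnas_per_gene`` replicate plate sets:
    siRNA copy k of every gene sits at the same position of plate set k,
    the standard organisation of multi-reagent genome libraries, so
    per-gene summaries average over plates.
    """

    n_genes: int
    sirnas_per_gene: int = 3
    n_sensitizers: int = 0
    n_resistors: int = 0
    sensitizer_effect: float = -1.5
    resistor_effect: float = 1.5
    noise_sd: float = 0.5
    plate_size: int = 384
    control_fraction: float = 1.0 / 12.0  # two control columns per 384-well plate
    n_replicates: int = 1
    baseline_signal: float = 1000.0
    drug_arm_viability: float = 0.7  # ~EC30 drug dose: controls keep 70 %
    plate_effect_sd: float = 0.0  # optional multiplicative plate effect (log2)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.sirnas_per_gene < 1:
            raise ValueError("n_genes and sirnas_per_gene must be >= 1")
        if self.n_sensitizers + self.n_resistors > self.n_genes:
            raise ValueError("n_sensitizers + n_resistors exceeds n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.control_fraction < 1:
            raise ValueError("control_fraction must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        n_ctrl = self._controls_per_plate()
        if self.plate_size - n_ctrl < 1:
            raise ValueError(
                "plate layout not addressable: no sample wells remain after "
                f"reserving {n_ctrl} control wells on a {self.plate_size}-well plate"
            )

    def _controls_per_plate(self) -> int:
        return max(1, int(round(self.control_fraction * self.plate_size)))


def simulate_screen(
    cfg: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a paired drug/vehicle siRNA viability screen.

    Returns
    -------
    design : DataFrame
        One row per siRNA reagent: ``gene_id, sirna_id, plate, well``.
    wells : DataFrame
        One row per physical well per arm:
        ``plate, well, arm, sirna_id, signal, is_control``. Raw signal for
        a drug-arm siRNA well is
        ``baseline * drug_arm_viability * 2**(gene_effect + noise)``;
        vehicle-arm wells carry no gene effect.
    truth : GroundTruth
        ``true_hit_labels`` maps every gene to sensitizer/resistor/neutral.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    width = max(5, len(str(cfg.n_genes)))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)])
    labels = np.array(["neutral"] * cfg.n_genes, dtype=object)
    labels[: cfg.n_sensitizers] = "sensitizer"
    labels[cfg.n_sensitizers : cfg.n_sensitizers + cfg.n_resistors] = "resistor"
    # random placement so planted hits are not confounded with plate position
    order = rng.permutation(cfg.n_genes)
    labels = labels[order]
    effects = np.where(
        labels == "sensitizer",
        cfg.sensitizer_effect,
        np.where(labels == "resistor", cfg.resistor_effect, 0.0),
    )

    n_sirnas = cfg.n_genes * cfg.sirnas_per_gene
    gene_of_sirna = np.repeat(np.arange(cfg.n_genes), cfg.sirnas_per_gene)
    copy_of_sirna = np.tile(np.arange(cfg.sirnas_per_gene), cfg.n_genes)
    sirna_ids = np.array(
        [f"{genes[g]}_s{k + 1}" for g, k in zip(gene_of_sirna, copy_of_sirna)]
    )

    n_ctrl = cfg._controls_per_plate()
    samples_per_plate = cfg.plate_size - n_ctrl
    plates_per_set = int(math.ceil(cfg.n_genes / samples_per_plate))
    n_plates = plates_per_set * cfg.sirnas_per_gene

    # replicate plate sets: siRNA copy k of gene g sits at sample slot g
    # of plate set k
    plate_idx = copy_of_sirna * plates_per_set + gene_of_sirna // samples_per_plate
    slot = gene_of_sirna % samples_per_plate
    plate_names = [f"P{p + 1:04d}" for p in plate_idx]
    well_names = [well_address(n_ctrl + s, cfg.plate_size) for s in slot]

    ctrl_plates, ctrl_wells = [], []
    for p in range(n_plates):
        pname = f"P{p + 1:04d}"
        for j in range(n_ctrl):
            ctrl_plates.append(pname)
            ctrl_wells.append(well_address(j, cfg.plate_size))

    design = pd.DataFrame(
        {
            "gene_id": genes[gene_of_sirna],
            "sirna_id": sirna_ids,
            "plate": plate_names,
            "well": well_names,
        }
    )

    plate_effects = {
        f"P{p + 1:04d}": (
            rng.normal(0.0, cfg.plate_effect_sd) if cfg.plate_effect_sd > 0 else 0.0
        )
        for p in range(n_plates)
    }

    frames = []
    sirna_effects = effects[gene_of_sirna]
    arm_sd = cfg.noise_sd / math.sqrt(2)  # per arm, so the ratio carries noise_sd
    for rep in range(1, cfg.n_replicates + 1):
        for arm in ("drug", "vehicle"):
            arm_eff = sirna_effects if arm == "drug" else 0.0
            scale = cfg.drug_arm_viability if arm == "drug" else 1.0
            pe = np.array([plate_effects[p] for p in plate_names])
            noise = rng.normal(0.0, arm_sd, n_sirnas)
            sig = cfg.baseline_signal * scale * 2.0 ** (arm_eff + noise + pe)
            frames.append(
                pd.DataFrame(
                    {
                        "plate": plate_names,
                        "well": well_names,
                        "arm": arm,
                        "replicate": rep,
                        "sirna_id": sirna_ids,
                        "signal": sig,
                        "is_control": False,
                    }
                )
            )
            pe_c = np.array([plate_effects[p] for p in ctrl_plates])
            noise_c = rng.normal(0.0, arm_sd, len(ctrl_plates))
            sig_c = cfg.baseline_signal * scale * 2.0 ** (noise_c + pe_c)
            frames.append(
                pd.DataFrame(
                    {
                        "plate": ctrl_plates,
                        "well": ctrl_wells,
                        "arm": arm,
                        "replicate": rep,
                        "sirna_id": "",
                        "signal": sig_c,
                        "is_control": True,
                    }
                )
            )
    wells = pd.concat(frames, ignore_index=True)

    truth = GroundTruth(true_hit_labels=dict(zip(genes, labels)))
    return design, wells, truth


# ---------------------------------------------------------------------------
# Dose-response panels
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseSimConfig:
    """Configuration of a drug-panel dilution-series viability experiment.

    Per drug, three curves are generated: parental line / single agent,
    resistant line / single agent, and resistant line / combination with
    the fixed-dose sensitizer. The resistant-line IC50 is the parental
    IC50 shifted by a fold drawn log-uniformly from ``resistance_fold``;
    the combination arm divides the resistant IC50 by a fold drawn from
    ``sensitizer_reversal_fold``.
    """

    n_drugs: int = 69
    n_doses: int = 7
    dilution_factor: float = 3.0
    top_dose: float | None = None  # molar; None -> per-drug anchored top dose
    top_dose_fold: float = 100.0  # top dose = this fold of the parental IC50
    hill_slope: float = 1.0
    ic50_parental: float | Sequence[float] | None = None  # drawn if None
    ic50_range: tuple[float, float] = (3e-8, 3e-6)
    resistance_fold: float | tuple[float, float] = (2.0, 100.0)
    sensitizer_reversal_fold: float | tuple[float, float] = (1.0, 50.0)
    noise_sd: float = 0.05  # viability-fraction units
    n_replicates: int = 3  # assays run in triplicate
    seed: int = 0

    def validate(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.n_doses < 2:
            raise ValueError("n_doses must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        folds = np.atleast_1d(np.asarray(self.resistance_fold, dtype=float))
        if np.any(folds < 1):
            raise ValueError("resistance_fold must be >= 1")


def four_pl(dose, ic50, hill_slope=1.0, top=1.0, bottom=0.0):
    """Four-parameter logistic viability curve, decreasing in dose."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill_slope)


def _draw_fold(rng: np.random.Generator, spec, n: int) -> np.ndarray:
    if np.isscalar(spec):
        return np.full(n, float(spec))
    lo, hi = spec
    return np.exp(rng.uniform(np.log(lo), np.log(hi), n))


def simulate_dose_response(
    cfg: DoseResponseSimConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate seven-point threefold dilution viability panels.

    Returns a DoseTable (``drug, cell_line, arm, dose, viability,
    replicate``) and a GroundTruth with ``true_ic50`` keyed by
    ``(drug, cell_line, arm)``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    drugs = [f"D{i:03d}" for i in range(1, cfg.n_drugs + 1)]

    if cfg.ic50_parental is None:
        lo, hi = cfg.ic50_range
        ic50_par = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_drugs))
    else:
        ic50_par = np.broadcast_to(
            np.atleast_1d(np.asarray(cfg.ic50_parental, dtype=float)), (cfg.n_drugs,)
        ).copy()

    # panel design: each drug is titrated around its own potency, as in
    # practice, unless a common absolute top dose is requested
    if cfg.top_dose is None:
        top_doses = cfg.top_dose_fold * ic50_par
    else:
        top_doses = np.full(cfg.n_drugs, float(cfg.top_dose))
    dose_steps = cfg.dilution_factor ** np.arange(cfg.n_doses)

    res_fold = _draw_fold(rng, cfg.resistance_fold, cfg.n_drugs)
    rev_fold = _draw_fold(rng, cfg.sensitizer_reversal_fold, cfg.n_drugs)

    curves = {}  # (drug, line, arm) -> true ic50
    for i, drug in enumerate(drugs):
        curves[(drug, "parental", "single")] = ic50_par[i]
        curves[(drug, "resistant", "single")] = ic50_par[i] * res_fold[i]
        curves[(drug, "resistant", "combo")] = (
            ic50_par[i] * res_fold[i] / rev_fold[i]
        )

    top_of_drug = dict(zip(drugs, top_doses))
    rows = []
    for (drug, line, arm), ic50 in curves.items():
        doses = top_of_drug[drug] / dose_steps
        clean = four_pl(doses, ic50, cfg.hill_slope)
        for rep in range(1, cfg.n_replicates + 1):
            noisy = clean + rng.normal(0.0, cfg.noise_sd, cfg.n_doses)
            noisy = np.clip(noisy, 0.0, 1.2)
            rows.append(
                pd.DataFrame(
                    {
                        "drug": drug,
                        "cell_line": line,
                        "arm": arm,
                        "dose": doses,
                        "viability": noisy,
                        "replicate": rep,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    return table, GroundTruth(true_ic50=curves)


# ---------------------------------------------------------------------------
# FRET caspase-3 biosensor movies
# ---------------------------------------------------------------------------


@dataclass
class ImageStackPair:
    """Time-ordered paired CFP/YFP image stacks from one field of view."""

    cfp_stack: np.ndarray  # (T, H, W)
    yfp_stack: np.ndarray
    pixel_size: float = 1.0  # micrometres
    frame_interval: float = 1.0  # hours

    def __post_init__(self) -> None:
        if self.cfp_stack.shape != self.yfp_stack.shape:
            raise ValueError("CFP and YFP stacks must have identical shape")


@dataclass
class FretSimConfig:
    """Configuration of a synthetic caspase-3 FRET biosensor movie.

    Cells are rendered as isotropic Gaussian spots (sigma =
    ``blob_radius_px``) on a dark background. At a cell's activation
    time its YFP amplitude falls and CFP amplitude rises so that the
    YFP/CFP ratio drops by exactly ``ratio_drop``; total blob brightness
    is approximately conserved, mimicking loss of FRET after biosensor
    cleavage.
    """

    n_cells: int = 12
    n_timepoints: int = 25
    frame_interval: float = 2.0  # hours -> 48-50 h observation window
    activation_times: Sequence[float | None] | None = None  # drawn if None
    activated_fraction: float = 0.5
    ratio_drop: float = 0.5
    blob_radius_px: float = 4.0
    image_shape: tuple[int, int] = (128, 128)
    intensity_noise_sd: float = 0.0
    cfp_amplitude: float = 100.0
    yfp_amplitude: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.ratio_drop < 1:
            raise ValueError("ratio_drop must be in (0, 1)")
        if self.n_cells < 1 or self.n_timepoints < 1:
            raise ValueError("n_cells and n_timepoints must be >= 1")
        if self.activation_times is not None and len(self.activation_times) != self.n_cells:
            raise ValueError("activation_times must have one entry per cell")
        if self.intensity_noise_sd < 0:
            raise ValueError("intensity_noise_sd must be >= 0")


def _place_blobs(
    rng: np.random.Generator, cfg: FretSimConfig
) -> np.ndarray:
    """Rejection-sample non-overlapping blob centres; error when impossible."""
    margin = 3.0 * cfg.blob_radius_px + 1
    min_sep = 6.0 * cfg.blob_radius_px + 2
    h, w = cfg.image_shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("image_shape too small for requested blob radius")
    centres: list[tuple[float, float]] = []
    attempts = 0
    while len(centres) < cfg.n_cells:
        attempts += 1
        if attempts > 10000 * cfg.n_cells:
            raise ValueError(
                f"cannot place {cfg.n_cells} non-overlapping blobs in "
                f"{cfg.image_shape} with radius {cfg.blob_radius_px}"
            )
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2 for cy, cx in centres):
            centres.append((y, x))
    return np.asarray(centres)


def simulate_fret_movie(
    cfg: FretSimConfig,
) -> tuple[ImageStackPair, pd.DataFrame, GroundTruth]:
    """Simulate a paired CFP/YFP movie plus the matching per-cell traces.

    Returns
    -------
    pair : ImageStackPair
    traces : DataFrame
        ``cell_id, timepoint, time_h, cfp_mean, yfp_mean, fret_ratio``
        computed from the rendered (noisy) images within each cell's
        planted mask — a drop-in replacement for the imaging stage.
    truth : GroundTruth
        ``true_activation`` maps cell id to activation time in hours, or
        ``None`` for cells that never activate.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    centres = _place_blobs(rng, cfg)

    total_h = (cfg.n_timepoints - 1) * cfg.frame_interval
    if cfg.activation_times is None:
        n_act = int(round(cfg.activated_fraction * cfg.n_cells))
        act = rng.uniform(0.2 * total_h, 0.8 * total_h, n_act)
        activation: list[float | None] = list(act) + [None] * (cfg.n_cells - n_act)
        rng.shuffle(activation)  # object array shuffle keeps None entries
    else:
        activation = list(cfg.activation_times)

    h, w = cfg.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    sigma2 = cfg.blob_radius_px**2
    blobs, masks = [], []
    for cy, cx in centres:
        b = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma2))
        m = b > np.exp(-4.5)
        blobs.append(b * m)  # truncate at 3-sigma so cells are compact
        masks.append(m)

    scale = math.sqrt(1.0 - cfg.ratio_drop)
    times = np.arange(cfg.n_timepoints) * cfg.frame_interval
    cfp = np.zeros((cfg.n_timepoints, h, w))
    yfp = np.zeros_like(cfp)
    for i, blob in enumerate(blobs):
        t_act = activation[i]
        active = np.zeros(cfg.n_timepoints, dtype=bool)
        if t_act is not None:
            active = times >= t_act
        c_amp = np.where(active, cfg.cfp_amplitude / scale, cfg.cfp_amplitude)
        y_amp = np.where(active, cfg.yfp_amplitude * scale, cfg.yfp_amplitude)
        cfp += c_amp[:, None, None] * blob[None, :, :]
        yfp += y_amp[:, None, None] * blob[None, :, :]
    if cfg.intensity_noise_sd > 0:
        cfp = np.clip(cfp + rng.normal(0, cfg.intensity_noise_sd, cfp.shape), 0, None)
        yfp = np.clip(yfp + rng.normal(0, cfg.intensity_noise_sd, yfp.shape), 0, None)

    pair = ImageStackPair(
        cfp_stack=cfp, yfp_stack=yfp, frame_interval=cfg.frame_interval
    )

    rows = []
    cell_ids = [f"C{i + 1:03d}" for i in range(cfg.n_cells)]
    for i, cid in enumerate(cell_ids):
        m = masks[i]
        cmeans = cfp[:, m].mean(axis=1)
        ymeans = yfp[:, m].mean(axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": cid,
                    "timepoint": np.arange(cfg.n_timepoints),
                    "time_h": times,
                    "cfp_mean": cmeans,
                    "yfp_mean": ymeans,
                    "fret_ratio": np.where(cmeans > 0, ymeans / cmeans, np.nan),
                }
            )
        )
    traces = pd.concat(rows, ignore_index=True)
    truth = GroundTruth(
        true_activation={
            cid: (None if activation[i] is None else float(activation[i]))
            for i, cid in enumerate(cell_ids)
        }
    )
    return pair, traces, truth


# ---------------------------------------------------------------------------
# Proteasome kinetics
# ---------------------------------------------------------------------------


def simulate_proteasome_kinetics(
    n_samples: int,
    signal_rate: float,
    background_rate: float,
    noise_sd: float,
    seed: int,
    t1: float = 0.0,
    t2: float = 60.0,
    baseline_rfu: float = 50.0,
) -> pd.DataFrame:
    """Simulate paired fluorogenic kinetic reads (± proteasome inhibitor).

    Without the inhibitor, fluorescence accumulates at
    ``signal_rate + background_rate`` RFU/min; with the inhibitor only the
    non-proteasome ``background_rate`` remains. With ``noise_sd=0`` the
    ΔRFU statistic recovers ``signal_rate * (t2 - t1)`` exactly.
    """
    if signal_rate < 0 or background_rate < 0:
        raise ValueError("rates must be >= 0")
    if t2 <= t1:
        raise ValueError("t2 must be > t1")
    rng = np.random.default_rng(seed)

    def read(rate_total: float, t: float) -> np.ndarray:
        clean = baseline_rfu + rate_total * t
        return clean + rng.normal(0.0, noise_sd, n_samples)

    total = signal_rate + background_rate
    return pd.DataFrame(
        {
            "sample": [f"S{i + 1:03d}" for i in range(n_samples)],
            "t1_min": t1,
            "t2_min": t2,
            "rfu1": read(total, t1),
            "rfu2": read(total, t2),
            "irfu1": read(background_rate, t1),
            "irfu2": read(background_rate, t2),
        }
    )
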