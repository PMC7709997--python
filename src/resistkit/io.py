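"""Shared readers/writers, run configuration, and the pipeline driver.

Interchange formats are deliberately plain: CSV for all tabular data
(with ``# key: value`` provenance header comments), GMT for gene sets,
multi-page TIFF per fluorescence channel, YAML for run configuration.
Every output file carries the config hash and seed so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from resistkit import doseresponse, fret, metrics, screen, simulate, synergy

logger = logging.getLogger(__name__)

__all__ = [
    "TABLE_SCHEMAS",
    "SchemaError",
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "write_image_stack",
    "read_image_stack",
    "RunConfig",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A table failed validation against its declared schema."""


#: required columns per interchange table
TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "well": ("plate", "well", "arm", "signal", "is_control"),
    "design": ("gene_id", "sirna_id", "plate", "well"),
    "dose": ("drug", "cell_line", "arm", "dose", "viability"),
    "trace": ("cell_id", "time_h", "cfp_mean", "yfp_mean"),
    "kinetic": ("rfu1", "rfu2", "irfu1", "irfu2"),
    "gene_score": ("gene_id", "x_gene", "z", "hit_class"),
}


def read_table(path: str | Path, schema: str | Sequence[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, skipping provenance comments, and validate it.

    ``schema`` is either a key of :data:`TABLE_SCHEMAS` or an explicit
    sequence of required column names; a missing column raises
    :class:`SchemaError` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    if schema is not None:
        required = TABLE_SCHEMAS[schema] if isinstance(schema, str) else tuple(schema)
        for col in required:
            if col not in df.columns:
                raise SchemaError(f"{path.name}: missing required column {col!r}")
    return df


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> Path:
    """Write a CSV table with optional ``# key: value`` provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name TAB description TAB members..."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"GMT line {ln}: expected name, description, >=1 member")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path, description: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
    return path


def write_image_stack(stack: np.ndarray, path: str | Path) -> Path:
    """Write a (T, H, W) stack as a multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, np.asarray(stack, dtype=np.float32), photometric="minisblack"
    )
    return path


def read_image_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# Run configuration and pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Parameters for one end-to-end pipeline run.

    Stage blocks mirror the analysis defaults: screen z threshold 2.5,
    resistance fold threshold 5, synergy mean-excess threshold 0.1,
    FRET ratio-drop fraction 0.3. Simulation sizes default to a small
    demo screen that completes in well under a minute.
    """

    seed: int = 0
    outdir: str = "resistkit_run"
    screen: dict = field(
        default_factory=lambda: {
            "n_genes": 500,
            "n_sensitizers": 10,
            "n_resistors": 10,
            "z_threshold": 2.5,
            "aggregation": "median",
        }
    )
    dose_response: dict = field(
        default_factory=lambda: {"n_drugs": 12, "fold_threshold": 5.0, "k": 15.0}
    )
    synergy: dict = field(
        default_factory=lambda: {
            "sensitizer_inhibition": 0.15,
            "min_excess": 0.1,
            "min_fraction_doses": 0.5,
            "n_boot": 1000,
        }
    )
    fret: dict = field(
        default_factory=lambda: {"n_cells": 10, "drop_fraction": 0.3, "min_area_px": 20}
    )

    def validate(self) -> None:
        for name, val in [
            ("screen.z_threshold", self.screen["z_threshold"]),
            ("dose_response.fold_threshold", self.dose_response["fold_threshold"]),
            ("synergy.min_excess", self.synergy["min_excess"]),
            ("fret.drop_fraction", self.fret["drop_fraction"]),
        ]:
            if not val > 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    def digest(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        payload = asdict(self)
        payload.pop("outdir", None)
        canon = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute simulate → screen → dose-response → synergy → FRET → metrics.

    Each stage writes its outputs under ``cfg.outdir`` with a provenance
    header (config hash + seed); a ``manifest.json`` records the file
    list. Re-running with the same config reproduces every table
    byte-identically. A stage failure raises immediately with the stage
    name in the message.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": cfg.digest(), "seed": cfg.seed, "resistkit": _version()}
    written: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        write_table(df, outdir / name, provenance=prov)
        written.append(name)

    try:
        # --- RNAi screen ---------------------------------------------------
        scr = cfg.screen
        design, wells, truth = simulate.simulate_screen(
            simulate.ScreenSimConfig(
                n_genes=scr["n_genes"],
                n_sensitizers=scr["n_sensitizers"],
                n_resistors=scr["n_resistors"],
                seed=cfg.seed,
            )
        )
        emit(design, "screen_design.csv")
        emit(wells, "screen_wells.csv")
        scores = screen.score_screen(
            wells, design, aggregation=scr["aggregation"], threshold=scr["z_threshold"]
        )
        emit(scores, "gene_scores.csv")
        sensitive, resistant = screen.call_hits(scores, threshold=scr["z_threshold"])
        emit(pd.DataFrame({"gene_id": sensitive, "list": "sensitive"}), "hits_sensitive.csv")
        emit(pd.DataFrame({"gene_id": resistant, "list": "resistant"}), "hits_resistant.csv")

        universe = scores["gene_id"].tolist()
        rng = np.random.default_rng(cfg.seed)
        planted = [g for g, lab in truth.true_hit_labels.items() if lab == "sensitizer"]
        gene_sets = {
            "planted_sensitizers": planted,
            "random_set_a": list(rng.choice(universe, size=min(25, len(universe)), replace=False)),
            "random_set_b": list(rng.choice(universe, size=min(40, len(universe)), replace=False)),
        }
        if sensitive:
            emit(screen.enrich(sensitive, gene_sets, universe), "enrichment.csv")
    except Exception as exc:
        raise RuntimeError(f"screen stage failed: {exc}") from exc

    try:
        # --- dose-response panel --------------------------------------------
        dr = cfg.dose_response
        dose_table, dr_truth = simulate.simulate_dose_response(
            simulate.DoseResponseSimConfig(n_drugs=dr["n_drugs"], seed=cfg.seed + 1)
        )
        emit(dose_table, "dose_table.csv")
        fits = doseresponse.fit_panel(dose_table)
        emit(fits, "dose_fits.csv")
        calls = doseresponse.classify_resistance(fits, fold_threshold=dr["fold_threshold"])
        emit(calls, "resistance_calls.csv")
    except Exception as exc:
        raise RuntimeError(f"dose-response stage failed: {exc}") from exc

    try:
        # --- synergy ---------------------------------------------------------
        syn = cfg.synergy
        syn_rows = []
        for drug, grp in dose_table[dose_table["cell_line"] == "resistant"].groupby("drug"):
            single = grp[grp["arm"] == "single"]
            combo = grp[grp["arm"] == "combo"]
            points = synergy.score_combination(
                single, syn["sensitizer_inhibition"], combo
            )
            call = synergy.call_synergy(
                points,
                min_excess=syn["min_excess"],
                min_fraction_doses=syn["min_fraction_doses"],
                n_boot=syn["n_boot"],
                seed=cfg.seed,
                drug=drug,
            )
            syn_rows.append(
                {
                    "drug": drug,
                    "mean_excess": call.mean_excess,
                    "n_doses_above_additive": call.n_doses_above_additive,
                    "is_synergistic": call.is_synergistic,
                    "ci_low": call.ci_low,
                    "ci_high": call.ci_high,
                }
            )
        emit(pd.DataFrame(syn_rows), "synergy_calls.csv")
    except Exception as exc:
        raise RuntimeError(f"synergy stage failed: {exc}") from exc

    try:
        # --- FRET movie -------------------------------------------------------
        fr = cfg.fret
        pair, trace_table, fr_truth = simulate.simulate_fret_movie(
            simulate.FretSimConfig(n_cells=fr["n_cells"], seed=cfg.seed + 2)
        )
        write_image_stack(pair.cfp_stack, outdir / "fret_cfp.tiff")
        write_image_stack(pair.yfp_stack, outdir / "fret_yfp.tiff")
        written += ["fret_cfp.tiff", "fret_yfp.tiff"]
        emit(trace_table, "fret_traces.csv")
        traces = fret.extract_traces(pair, min_area_px=fr["min_area_px"])
        for tr in traces:
            fret.classify_apoptosis(tr, drop_fraction=fr["drop_fraction"])
        emit(fret.activation_curve(traces), "fret_activation_curve.csv")
    except Exception as exc:
        raise RuntimeError(f"fret stage failed: {exc}") from exc

    try:
        # --- proteasome kinetics ----------------------------------------------
        kin = simulate.simulate_proteasome_kinetics(
            n_samples=8, signal_rate=5.0, background_rate=1.0, noise_sd=2.0,
            seed=cfg.seed + 3,
        )
        emit(metrics.proteasome_activity_table(kin), "proteasome_activity.csv")
    except Exception as exc:
        raise RuntimeError(f"metrics stage failed: {exc}") from exc

    manifest = {
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "resistkit_version": _version(),
        "outputs": written,
        "config": asdict(cfg),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _version() -> str:
    from resistkit import __version__

    return __version__
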