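"""End-to-end orchestration of the survey analysis.

One run: obtain a sample table (simulated or from CSV), split it into a
calibration set used for all model fitting and interpolation and a held-out
validation set, then per metal fit variograms, krige OK and COK surfaces,
validate both against the held-out samples, assess pollution (SPI/NCPI
tables), detect Gi* hotspots of each pollution index, and build the
toxicity-weighted MVIK composite risk map. Every artifact is plain text
(CSV / ESRI ASCII / JSON) and fully determined by the seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import comparison_table
from .gridio import write_esri_ascii, write_prediction_grid, write_samples, read_samples
from .hotspots import hotspot_analysis
from .indicator_mvik import (
    TOXICITY_COEFFICIENTS,
    ik_probability,
    mvik_combine,
    toxicity_weights,
)
from .kriging import GridSpec, cok_predict, krige_grid, ok_predict
from .pollution_indices import StandardsTable, assess, summarize_grades
from .synthetic_data import METALS, SyntheticConfig, simulate_fields, split_calibration_validation
from .variogram import (
    VariogramModel,
    empirical_cross_variogram,
    empirical_semivariogram,
    fit_lmc,
    fit_model,
)

__all__ = ["PipelineConfig", "run_pipeline", "bundle_checksums"]


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    out_dir: str | Path = "soilkrige_out"
    seed: int = 0
    mode: str = "synthetic"  # "synthetic" | "csv"
    csv_path: str | None = None
    synthetic: SyntheticConfig | None = None
    metals: tuple[str, ...] = METALS
    standards: StandardsTable = field(default_factory=StandardsTable)
    toxicity: dict[str, float] = field(default_factory=lambda: dict(TOXICITY_COEFFICIENTS))
    grid_shape: tuple[int, int] = (100, 100)  # rows, cols over padded bbox
    grid_pad: float = 0.05
    neighborhood: int | str | None = None
    hotspot_band: float | None = None  # default: fitted variogram range of each index
    assess_subset: str = "calibration"  # "calibration" | "all"
    mvik_spi_threshold: float = 1.0  # SPI >= 1 marks exceedance of the standard

    def __post_init__(self):
        if not self.metals:
            raise ValueError("metal list must be non-empty")
        for m in self.metals:
            if m not in self.toxicity:
                raise ValueError(f"missing toxicity coefficient for {m!r}")
            if m not in self.standards.values:
                raise ValueError(f"missing reference standard for {m!r}")
        if self.mode == "synthetic" and self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        if self.mode == "csv" and not self.csv_path:
            raise ValueError("csv mode requires csv_path")

    def config_echo(self) -> dict:
        echo = {
            "seed": self.seed,
            "mode": self.mode,
            "csv_path": self.csv_path,
            "metals": list(self.metals),
            "toxicity": self.toxicity,
            "standards": {k: list(v) for k, v in self.standards.values.items()},
            "grid_shape": list(self.grid_shape),
            "grid_pad": self.grid_pad,
            "neighborhood": self.neighborhood,
            "hotspot_band": self.hotspot_band,
            "assess_subset": self.assess_subset,
            "mvik_spi_threshold": self.mvik_spi_threshold,
        }
        if self.synthetic is not None:
            s = self.synthetic
            echo["synthetic"] = {
                "n_sites": s.n_sites,
                "n_calibration": s.n_calibration,
                "domain_extent": list(s.domain_extent),
                "marginals": {k: list(v) for k, v in s.marginals.items()},
                "sensor_r2": s.sensor_r2,
                "sensor_bias": list(s.sensor_bias),
                "variograms": {k: v.to_dict() for k, v in s.variograms.items()},
                "cross_corr": np.asarray(s.cross_corr).tolist(),
                "seed": s.seed,
            }
        return echo


def _config_hash(echo: dict) -> str:
    return hashlib.sha256(json.dumps(echo, sort_keys=True).encode()).hexdigest()[:16]


def bundle_checksums(out_dir) -> dict[str, str]:
    """SHA-256 of every artifact in a run directory, excluding the run log."""
    out = {}
    for p in sorted(Path(out_dir).rglob("*")):
        if p.is_file() and p.suffix != ".log":
            out[str(p.relative_to(out_dir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


class _Log:
    def __init__(self, path):
        self.path = Path(path)
        self.path.write_text("")

    def __call__(self, msg):
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        with open(self.path, "a") as fh:
            fh.write(f"{stamp} {msg}\n")


def _fit_index_band(samples: pd.DataFrame, column: str, fallback: float) -> float:
    """Distance band for Gi*: the fitted variogram range of the index."""
    try:
        emp = empirical_semivariogram(samples, column)
        model = fit_model(emp, family="auto")
        if model.partial_sill > 0 and model.range_ > 0:
            return float(model.range_)
    except Exception:
        pass
    return fallback


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")
    stage = "setup"
    try:
        # --- data
        stage = "data"
        if config.mode == "synthetic":
            samples = simulate_fields(config.synthetic)
            n_cal = config.synthetic.n_calibration
        else:
            samples, _ = read_samples(config.csv_path)
            n_cal = min(97, len(samples) - 1)
        write_samples(out / "samples.csv", samples, {"seed": config.seed})
        cal, val = split_calibration_validation(samples, n_cal, seed=config.seed)
        log(f"data: {len(samples)} samples, {len(cal)} calibration / {len(val)} validation")

        xmin, ymin = samples[["x", "y"]].min()
        xmax, ymax = samples[["x", "y"]].max()
        spec = GridSpec.from_bounds(
            xmin, ymin, xmax, ymax, *config.grid_shape, pad=config.grid_pad
        )

        # --- per-metal variograms, kriging, validation predictions
        models: dict[str, dict] = {}
        obs, pred_ok, pred_cok = {}, {}, {}
        val_pts = val[["x", "y"]].to_numpy(dtype=float)
        for m in config.metals:
            stage = f"variogram:{m}"
            lab, pxrf = f"{m}_lab", f"{m}_pxrf"
            emp = empirical_semivariogram(cal, lab)
            model = fit_model(emp, family="auto")
            emp.to_frame().to_csv(out / f"variogram_{m}.csv", index=False)

            emp_c = empirical_semivariogram(cal, pxrf)
            emp_x = empirical_cross_variogram(cal, lab, pxrf)
            structures = [("nugget", 1.0), (model.family, model.range_)]
            lmc = fit_lmc(
                {(lab, lab): emp, (pxrf, pxrf): emp_c, (lab, pxrf): emp_x}, structures
            )
            models[m] = {
                "direct": model.to_dict(),
                "lmc_structures": [[f, r] for f, r in lmc.structures],
                "lmc_matrices": [B.tolist() for B in lmc.matrices],
            }

            stage = f"kriging:{m}"
            ok_grid = krige_grid(
                cal, lab, spec, "OK", model=model, neighborhood=config.neighborhood
            )
            cok_grid = krige_grid(
                cal, lab, spec, "COK", lmc=lmc, covariate=pxrf,
                neighborhood=config.neighborhood,
            )
            write_prediction_grid(out, ok_grid)
            write_prediction_grid(out, cok_grid)

            stage = f"validation:{m}"
            obs[m] = val[lab].to_numpy(dtype=float)
            pred_ok[m] = ok_predict(cal, lab, model, val_pts)[0]
            pred_cok[m] = cok_predict(cal, lab, pxrf, lmc, val_pts)[0]
            log(f"{m}: variogram {model.family}"
                f"(nugget {model.nugget:.3g}, psill {model.partial_sill:.3g},"
                f" range {model.range_:.3g}); OK and COK kriged and validated")

        stage = "validation-report"
        report = comparison_table(obs, pred_ok, pred_cok)
        report.to_csv(out / "validation_report.csv", index=False)
        with open(out / "variogram_models.json", "w") as fh:
            json.dump(models, fh, indent=2, sort_keys=True)

        # --- pollution assessment
        stage = "assessment"
        subset = cal if config.assess_subset == "calibration" else samples
        assessment = assess(subset, config.metals, config.standards)
        assessment.table.to_csv(out / "assessment.csv", index=False)
        summaries = summarize_grades(assessment)
        summaries["spi"].to_csv(out / "spi_grade_summary.csv", index=False)
        summaries["ncpi"].to_csv(out / "ncpi_grade_summary.csv", index=False)
        log(f"assessment: {len(subset)} samples ({config.assess_subset} subset)")

        # --- hotspots of each pollution index
        stage = "hotspots"
        idx_table = subset[["id", "x", "y"]].reset_index(drop=True).join(
            assessment.table[[f"{m}_spi" for m in config.metals] + ["ncpi"]]
        )
        diag = float(np.hypot(xmax - xmin, ymax - ymin))
        for name in [f"{m}_spi" for m in config.metals] + ["ncpi"]:
            band = config.hotspot_band or _fit_index_band(idx_table, name, 0.25 * diag)
            hs = hotspot_analysis(idx_table, name, band)
            hs.table.to_csv(out / f"hotspots_{name}.csv", index=False)
        log("hotspots: Gi* computed for each SPI and the NCPI")

        # --- MVIK composite risk
        stage = "mvik"
        weights = toxicity_weights({m: config.toxicity[m] for m in config.metals})
        fields = []
        for m in config.metals:
            f = ik_probability(idx_table, f"{m}_spi", config.mvik_spi_threshold, spec)
            f.variable = m
            fields.append(f)
            write_esri_ascii(out / f"ik_{m}.asc", f.probability, spec)
        risk = mvik_combine(fields, weights)
        write_esri_ascii(out / "mvik_risk.asc", risk.probability, spec)
        pd.DataFrame(
            {
                "metal": list(config.metals),
                "spi_threshold": config.mvik_spi_threshold,
                "toxicity": [config.toxicity[m] for m in config.metals],
                "weight": [weights[m] for m in config.metals],
            }
        ).to_csv(out / "mvik_weights.csv", index=False)
        log("mvik: composite risk surface written")

        # --- manifest
        stage = "manifest"
        echo = config.config_echo()
        manifest = {
            "package_version": __version__,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "seed": config.seed,
            "config": echo,
            "config_hash": _config_hash(echo),
            "n_samples": int(len(samples)),
            "n_calibration": int(len(cal)),
            "n_validation": int(len(val)),
            "outputs": bundle_checksums(out),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log("done")
        return manifest
    except Exception as exc:
        log(f"FAILED at stage {stage}: {exc!r}")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
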