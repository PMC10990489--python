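"""End-to-end runs: configuration, stage orchestration and reporting.

A run configuration is a single JSON/YAML-style dictionary; every tunable
(bin widths, xA_min, R0, error-propagation method, the bias map with its
explicit numerator/denominator ordering, seeds) lives there so a run is
self-documenting.  ``run_pipeline`` executes the requested stages in order,
writes each stage's CSV outputs plus a machine-readable summary JSON and a
log of versions/parameters, and aborts on the first stage failure (partial
outputs are retained).
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, bias, datasets, dose_response, qifret, synthetic

__all__ = ["run_pipeline", "compute_bias_table", "reference_bias_table"]

KNOWN_STAGES = ("synth", "doseresponse", "bias", "qifret")


def compute_bias_table(
    fits: pd.DataFrame,
    bias_map: list[dict],
    method: str = "functional",
    seed: int | None = None,
) -> pd.DataFrame:
    """Evaluate a bias map against a fits table (dose_response CSV layout)."""
    indexed = fits.set_index(["response_name", "ligand"])

    def _fit(response: str, ligand: str) -> dose_response.HillFit:
        row = indexed.loc[(response, ligand)]
        return dose_response.HillFit(
            etop=float(row["etop"]),
            ec50=float(row["ec50_M"]),
            se_etop=float(row.get("se_etop", np.nan)),
            se_ec50=float(row.get("se_ec50_M", np.nan)),
        )

    rows = []
    for entry in bias_map:
        ligand, reference = entry["ligand"], entry["reference"]
        num, den = entry["response_num"], entry["response_den"]
        result = bias.beta(
            _fit(num, ligand),
            _fit(den, ligand),
            _fit(num, reference),
            _fit(den, reference),
            ligand=ligand,
            reference=reference,
            response_num=num,
            response_den=den,
            method=method,
            seed=seed,
        )
        rows.append(
            {
                "label": entry.get("label", f"{num} / {den}"),
                "ligand": ligand,
                "reference": reference,
                "response_num": num,
                "response_den": den,
                "beta": result.beta,
                "se_beta": result.se_beta,
                "beta_prime_ligand": result.beta_prime_ligand,
                "se_beta_prime_ligand": result.se_beta_prime_ligand,
                "beta_prime_reference": result.beta_prime_reference,
                "se_beta_prime_reference": result.se_beta_prime_reference,
                "method": method,
            }
        )
    return pd.DataFrame(rows)


def reference_bias_table(method: str = "functional") -> pd.DataFrame:
    """The full bundled bias map evaluated on the bundled fit parameters."""
    return compute_bias_table(
        datasets.reference_fit_table(), datasets.reference_bias_map(), method=method
    )


def _stage_doseresponse(config: dict, outdir: Path, outputs: dict) -> None:
    bands = outputs.get("bands")
    if bands is None:
        bands = pd.read_csv(config["inputs"]["bands"])
    glue = outputs.get("glue")
    if glue is None and "glue" in config.get("inputs", {}):
        glue = {None: pd.read_csv(config["inputs"]["glue"])}

    if config.get("loss_transform", False):
        bands = dose_response.loss_transform(bands)
        averaged = dose_response.average_replicates(bands, renormalize=False)
    else:
        scaled = dose_response.scale_within_gel(bands)
        averaged = dose_response.average_replicates(scaled)
        if glue is not None:
            parts = []
            for response, gtable in glue.items():
                part = (
                    averaged
                    if response is None
                    else averaged[averaged["response_name"] == response]
                )
                parts.append(dose_response.glue_scale(part, gtable))
            averaged = pd.concat(parts, ignore_index=True)
    fits = dose_response.fit_response_table(averaged)
    averaged.to_csv(outdir / "curves_scaled.csv", index=False)
    fits.to_csv(outdir / "fits.csv", index=False)
    outputs["averaged"] = averaged
    outputs["fits"] = fits


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the summary dictionary."""
    stages = config.get("stages", [])
    if not stages:
        raise ValueError("empty stage list")
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}; known: {KNOWN_STAGES}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    summary: dict = {
        "lbkit_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "stages": list(stages),
        "results": {},
    }
    outputs: dict = {}

    for stage in stages:
        try:
            if stage == "synth":
                truths = {
                    (t["response"], t["ligand"]): (t["etop"], t["ec50"])
                    for t in config["synth"]["truths"]
                }
                bands, glue = synthetic.simulate_study(
                    truths,
                    seed=seed,
                    n_gels=config["synth"].get("n_gels", 3),
                    noise_sd=config["synth"].get("noise_sd", 0.07),
                )
                bands.to_csv(outdir / "bands.csv", index=False)
                outputs["bands"], outputs["glue"] = bands, glue
                summary["results"]["synth"] = {"n_rows": int(len(bands))}
            elif stage == "doseresponse":
                _stage_doseresponse(config, outdir, outputs)
                summary["results"]["doseresponse"] = {
                    "n_curves": int(len(outputs["fits"]))
                }
            elif stage == "bias":
                fits = outputs.get("fits")
                if fits is None:
                    fits = pd.read_csv(config["inputs"]["fits"])
                table = compute_bias_table(
                    fits,
                    config["bias_map"],
                    method=config.get("error_method", "functional"),
                    seed=seed,
                )
                table.to_csv(outdir / "bias.csv", index=False)
                outputs["bias"] = table
                summary["results"]["bias"] = {
                    row["label"] + " " + row["ligand"]: round(row["beta"], 4)
                    for _, row in table.iterrows()
                }
            elif stage == "qifret":
                vesicles = pd.read_csv(config["inputs"]["vesicles"])
                fs = qifret.summarize_vesicles(
                    vesicles,
                    condition=config.get("condition", ""),
                    r0=config.get("r0_A", qifret.DEFAULT_R0_A),
                    xa_min=config.get("xa_min", qifret.DEFAULT_XA_MIN),
                )
                pd.DataFrame(
                    [
                        {
                            "condition": fs.condition,
                            "n_vesicles": fs.n_vesicles,
                            "e_tilde_mean": fs.e_tilde_mean,
                            "se_e_tilde": fs.se_e_tilde,
                            "distance_A": fs.distance_A,
                            "se_distance_A": fs.se_distance_A,
                            "r0_A": fs.r0_A,
                        }
                    ]
                ).to_csv(outdir / "fret_summary.csv", index=False)
                summary["results"]["qifret"] = {
                    "e_tilde_mean": round(fs.e_tilde_mean, 4),
                    "distance_A": round(fs.distance_A, 2),
                }
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
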