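"""Seeded synthetic data with the statistical structure the analysis assumes.

Three generators stand in for the raw experimental inputs:

* photon-counting membrane images with a known oligomer-size distribution
  (for the FIF stage),
* multi-gel band-intensity tables with hidden per-gel scales and known
  (Etop, EC50) truth (for the dose-response/bias chain), including the
  gluing gel and an optional biphasic high-dose decline,
* per-vesicle FRET records with E linear in the acceptor fraction (for the
  QI-FRET stage).

Every generator is a pure function of (spec, seed): identical inputs give
bit-identical outputs, and no global random state is touched.  The defaults
mirror the measured regimes: receptor densities of 100-200/um^2, 15x15-pixel
ROIs, >= 3 gels per ligand with 5-10% multiplicative blot noise (default 7%),
a few hundred vesicles per condition with sigma_E = 0.05.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import fif

__all__ = [
    "FifSimSpec",
    "DoseSimSpec",
    "FretSimSpec",
    "simulate_fif_image",
    "simulate_brightness_sample",
    "simulate_dose_response",
    "simulate_glue_gel",
    "simulate_study",
    "simulate_vesicles",
    "default_concentration_grid",
]

#: maximum tolerated per-pixel Poisson rate before the generator refuses
_MAX_RATE = 1e9


@dataclasses.dataclass
class FifSimSpec:
    """One simulated cell-membrane image.

    ``oligomer_sizes`` maps oligomer size k to its probability; receptor
    density counts individual receptors (a dimer consumes two).  Each
    oligomer sits at one random pixel and contributes
    k * counts_per_fluorophore to that pixel's Poisson rate (no PSF —
    physical optics is out of scope); ``background`` is a uniform Poisson
    rate in counts/pixel.
    """

    field_size: int = 120
    receptor_density_um2: float = 150.0
    oligomer_sizes: dict[int, float] = dataclasses.field(default_factory=lambda: {1: 1.0})
    counts_per_fluorophore: float = 5.0
    pixel_area_um2: float = 0.0049  # 70 nm pixels
    background: float = 0.0

    def __post_init__(self) -> None:
        probs = np.array(list(self.oligomer_sizes.values()), dtype=float)
        if probs.size == 0 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("oligomer size probabilities must be >= 0 and sum to 1")
        if self.receptor_density_um2 < 0 or self.background < 0:
            raise ValueError("rates must be non-negative")
        if self.counts_per_fluorophore <= 0:
            raise ValueError("counts per fluorophore must be positive")


@dataclasses.dataclass
class DoseSimSpec:
    """One ligand/response truth for the band-intensity generator.

    Band intensity = gel_scale * Hill(x; Etop, EC50) * (1 + N(0, noise_sd)),
    clipped at 0.  Per-gel scales are log-normal with spread
    ``gel_scale_sigma`` (in log units) — the hidden blot-to-blot factor the
    scaling protocol must remove.  A biphasic decline (seen for some ligands
    at high dose) is emulated phenomenologically: doses above
    ``decline_conc`` are multiplied by (decline_conc / x)^decline_exponent.
    """

    etop: float = 1.0
    ec50: float = 1e-9
    concentrations: np.ndarray | None = None  # molar grid incl. 0
    n_gels: int = 3
    gel_scale_sigma: float = 0.3
    noise_sd: float = 0.07
    decline_conc: float | None = None
    decline_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.etop <= 0 or self.ec50 <= 0:
            raise ValueError("Etop and EC50 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.concentrations is None:
            self.concentrations = default_concentration_grid()
        self.concentrations = np.asarray(self.concentrations, dtype=float)


@dataclasses.dataclass
class FretSimSpec:
    """Per-vesicle FRET generator: E = E_tilde * xA + N(0, noise_sd).

    Donor and acceptor concentrations are drawn log-uniform over
    ``conc_range`` (arbitrary but consistent units), giving the broad
    expression range of vesicle preparations.
    """

    n_vesicles: int = 300
    e_tilde: float = 0.42
    conc_range: tuple[float, float] = (50.0, 2000.0)
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.e_tilde < 1.0:
            raise ValueError("intrinsic FRET must lie in (0, 1)")
        if self.n_vesicles < 1:
            raise ValueError("need at least one vesicle")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def default_concentration_grid(
    low: float = 1e-11, high: float = 1e-7, n: int = 7, include_zero: bool = True
) -> np.ndarray:
    """Log-spaced molar dose grid, optionally with the zero-ligand baseline."""
    grid = np.logspace(np.log10(low), np.log10(high), n)
    if include_zero:
        grid = np.concatenate([[0.0], grid])
    return grid


def simulate_fif_image(spec: FifSimSpec, seed: int) -> tuple[np.ndarray, dict]:
    """One photon-count image plus its ground truth.

    With zero background the expected ROI brightness is
    epsilon = counts_per_fluorophore * mean oligomer size (shot noise alone
    would give epsilon = 0).
    """
    rng = np.random.default_rng(seed)
    n_pixels = spec.field_size**2
    area = n_pixels * spec.pixel_area_um2
    sizes = np.array(list(spec.oligomer_sizes.keys()), dtype=int)
    probs = np.array(list(spec.oligomer_sizes.values()), dtype=float)
    mean_size = float((sizes * probs).sum())
    n_oligomers = rng.poisson(spec.receptor_density_um2 * area / mean_size)
    rate = np.full(n_pixels, float(spec.background))
    if n_oligomers > 0:
        k = rng.choice(sizes, size=n_oligomers, p=probs)
        pos = rng.integers(0, n_pixels, size=n_oligomers)
        np.add.at(rate, pos, spec.counts_per_fluorophore * k)
    if rate.max() > _MAX_RATE:
        raise ValueError("Poisson rate overflow: density or brightness too high")
    image = rng.poisson(rate).reshape(spec.field_size, spec.field_size)
    truth = {
        "n_oligomers": int(n_oligomers),
        "mean_oligomer_size": mean_size,
        "expected_epsilon": spec.counts_per_fluorophore * mean_size,
    }
    return image, truth


def simulate_brightness_sample(
    spec: FifSimSpec,
    n_cells: int,
    seed: int,
    condition: str = "synthetic",
    roi_size: int = fif.DEFAULT_ROI_SIZE,
) -> fif.BrightnessSample:
    """Simulate ``n_cells`` membrane images and run ROI brightness on them."""
    rng = np.random.default_rng(seed)
    grids = []
    for i in range(n_cells):
        image, _ = simulate_fif_image(spec, seed=int(rng.integers(0, 2**31)))
        grids.append(fif.segment_membrane(image, roi_size=roi_size, image_id=f"cell{i}"))
    return fif.brightness_sample(grids, condition=condition, n_cells=n_cells)


def _band_intensity(spec: DoseSimSpec, x: np.ndarray, rng) -> np.ndarray:
    y = x * spec.etop / (x + spec.ec50)
    if spec.decline_conc is not None:
        factor = np.where(
            x > spec.decline_conc,
            (spec.decline_conc / np.where(x > 0, x, 1.0)) ** spec.decline_exponent,
            1.0,
        )
        y = y * factor
    noisy = y * (1.0 + rng.normal(0.0, spec.noise_sd, size=y.shape)) if spec.noise_sd else y
    return np.clip(noisy, 0.0, None)


def simulate_dose_response(
    spec: DoseSimSpec,
    seed: int,
    ligand: str = "L1",
    response: str = "R1",
) -> pd.DataFrame:
    """Raw multi-gel band-intensity table (long format) from one truth."""
    rng = np.random.default_rng(seed)
    frames = []
    for g in range(spec.n_gels):
        scale = float(np.exp(rng.normal(0.0, spec.gel_scale_sigma)))
        intensity = scale * _band_intensity(spec, spec.concentrations, rng)
        frames.append(
            pd.DataFrame(
                {
                    "response_name": response,
                    "ligand": ligand,
                    "gel_id": f"{ligand}_{response}_gel{g}",
                    "concentration_M": spec.concentrations,
                    "replicate": g,
                    "intensity": intensity,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_glue_gel(
    specs: dict[str, DoseSimSpec],
    seed: int,
    n_lanes: int = 3,
) -> pd.DataFrame:
    """Gluing gel: the maximal-response sample of each ligand re-run together.

    Each ligand contributes ``n_lanes`` lanes at its top grid concentration;
    all lanes share one hidden gel scale (it cancels in the coefficients).
    """
    rng = np.random.default_rng(seed)
    scale = float(np.exp(rng.normal(0.0, 0.3)))
    rows = []
    for ligand, spec in specs.items():
        x_max = float(np.max(spec.concentrations))
        level = scale * spec.etop * x_max / (x_max + spec.ec50)
        for lane in range(n_lanes):
            noise = 1.0 + rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 1.0
            rows.append(
                {"ligand": ligand, "replicate": lane, "intensity": max(level * noise, 0.0)}
            )
    return pd.DataFrame(rows)


def simulate_study(
    truths: dict[tuple[str, str], tuple[float, float]],
    seed: int,
    concentrations: np.ndarray | None = None,
    n_gels: int = 3,
    noise_sd: float = 0.07,
    gel_scale_sigma: float = 0.3,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Full multi-ligand, multi-response study.

    ``truths`` maps (response, ligand) to true (Etop, EC50).  Returns the
    combined raw band table and one gluing-gel table per response (the glue
    step is per response: its lanes come from that response's blots).
    """
    rng = np.random.default_rng(seed)
    bands = []
    glue: dict[str, pd.DataFrame] = {}
    responses = sorted({r for r, _ in truths})
    for response in responses:
        specs = {}
        for (r, ligand), (etop, ec50) in truths.items():
            if r != response:
                continue
            specs[ligand] = DoseSimSpec(
                etop=etop,
                ec50=ec50,
                concentrations=concentrations,
                n_gels=n_gels,
                noise_sd=noise_sd,
                gel_scale_sigma=gel_scale_sigma,
            )
            bands.append(
                simulate_dose_response(
                    specs[ligand],
                    seed=int(rng.integers(0, 2**31)),
                    ligand=ligand,
                    response=response,
                )
            )
        glue[response] = simulate_glue_gel(specs, seed=int(rng.integers(0, 2**31)))
    return pd.concat(bands, ignore_index=True), glue


def simulate_vesicles(spec: FretSimSpec, seed: int) -> pd.DataFrame:
    """Per-vesicle FRET table with E = E_tilde * xA plus additive noise."""
    rng = np.random.default_rng(seed)
    lo, hi = spec.conc_range
    donor = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_vesicles))
    acceptor = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_vesicles))
    xa = acceptor / (donor + acceptor)
    e = spec.e_tilde * xa
    if spec.noise_sd:
        e = e + rng.normal(0.0, spec.noise_sd, size=spec.n_vesicles)
    return pd.DataFrame(
        {
            "vesicle_id": [f"v{i}" for i in range(spec.n_vesicles)],
            "donor_conc": donor,
            "acceptor_conc": acceptor,
            "E": e,
        }
    )
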