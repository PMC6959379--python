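"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions of a mesh-bag incubation
experiment: NEXAFS spectra composed of the canonical pi* components on
top of an error-function edge jump and broad sigma* resonances; FTIR
spectra with mass in the six diagnostic vibrational regions; chemistry
tables in which carbon decays exponentially, delta-13C mixes two
end-members and C/N rises relative to the initial material; and OTU
count tables with technical replicates, guild structure, uneven read
depths and a known set of OTUs engineered to fail the rare-OTU filter.

Every generator is deterministic under a fixed seed, and each returns
its ground truth so downstream estimators can be tested as round trips.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from . import nexafs
from .ftir import DEFAULT_BANDS, FTIR_RANGE
from .spectrum import AXIS_ENERGY_EV, AXIS_WAVENUMBER_CM1, Spectrum

HORIZONS = ("humus", "mineral")
TREATMENTS = ("control", "fertilized")


# ---------------------------------------------------------------------
# NEXAFS
# ---------------------------------------------------------------------

@dataclass
class NexafsGroundTruth:
    """Generative parameters of one synthetic NEXAFS spectrum.

    ``true_relative_abundances`` maps canonical pi* component labels of
    the edge to fractions summing to 1; they set the pre-edge Gaussian
    areas (total area ``pi_total_area`` intensity*eV).  ``sigma_area``
    is the area of each broad sigma* resonance and ``step_width`` the
    Gaussian broadening (eV) of the error-function edge jump.
    """

    edge: str
    true_relative_abundances: dict[str, float]
    edge_jump_height: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    pi_total_area: float = 2.0
    sigma_area: float = 0.5
    step_width: float = 0.35

    def __post_init__(self) -> None:
        info = nexafs.edge_info(self.edge)
        bad = set(self.true_relative_abundances) - set(info["pi"])
        if bad:
            raise ValueError(
                f"unknown component label(s) for {self.edge}: {sorted(bad)}"
            )
        vals = np.array(list(self.true_relative_abundances.values()), float)
        if len(vals) == 0:
            raise ValueError("at least one pi* component required")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("abundance fractions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {vals.sum()!r}, expected 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.edge_jump_height < 0:
            raise ValueError("edge_jump_height must be >= 0")


def _gaussian(x: np.ndarray, area: float, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm * nexafs.FWHM_TO_SIGMA
    return area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(
        -((x - center) ** 2) / (2.0 * sigma ** 2))


def _erf_step(x: np.ndarray, height: float, center: float, width: float) -> np.ndarray:
    return height * 0.5 * (1.0 + erf((x - center) / (width * math.sqrt(2.0))))


def gen_nexafs_spectrum(truth: NexafsGroundTruth,
                        grid: np.ndarray | None = None
                        ) -> tuple[Spectrum, NexafsGroundTruth]:
    """Generate one NEXAFS spectrum from known component abundances.

    The spectrum is the sum of pi* Gaussians at the edge's canonical
    centers (areas proportional to the true abundances), the
    error-function edge jump, two broad sigma* resonances (FWHM 4 eV)
    and i.i.d. Gaussian intensity noise.
    """
    info = nexafs.edge_info(truth.edge)
    if grid is None:
        grid = np.arange(info["range"][0], info["range"][1] + 1e-9, 0.05)
    grid = np.asarray(grid, float)
    if grid[0] > info["range"][0] + 1e-9 or grid[-1] < info["range"][1] - 1e-9:
        raise ValueError(
            f"grid must cover the recorded {truth.edge} range {info['range']}"
        )
    y = _erf_step(grid, truth.edge_jump_height, info["step"], truth.step_width)
    for c in info["sigma"]:
        y += _gaussian(grid, truth.sigma_area, c, fwhm=4.0)
    for label, frac in truth.true_relative_abundances.items():
        y += _gaussian(grid, truth.pi_total_area * frac, info["pi"][label],
                       fwhm=nexafs.PI_FWHM_EV)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=grid.shape)
    spec = Spectrum(grid, y, AXIS_ENERGY_EV,
                    meta={"edge": truth.edge, "synthetic": True, "seed": truth.seed})
    return spec, truth


# ---------------------------------------------------------------------
# FTIR
# ---------------------------------------------------------------------

_FTIR_LABELS = {b.label: b for b in DEFAULT_BANDS}


def gen_ftir_spectrum(band_weights: dict[str, float], noise_sd: float = 0.0,
                      seed: int = 0, step: float = 1.0) -> Spectrum:
    """Generate an FTIR spectrum with mass in weighted vibrational regions.

    Each weighted band contributes a broad Gaussian centered at the band
    midpoint with FWHM = half the band width and area proportional to
    its weight, on a 900-1850 cm^-1 grid.  All-zero weights with zero
    noise return a flat spectrum flagged ``meta["all_zero"]`` with a
    warning.
    """
    bad = set(band_weights) - set(_FTIR_LABELS)
    if bad:
        raise ValueError(f"unknown band label(s): {sorted(bad)}")
    if any(w < 0 for w in band_weights.values()):
        raise ValueError("band weights must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = np.arange(FTIR_RANGE[0], FTIR_RANGE[1] + 1e-9, step)
    y = np.zeros_like(grid)
    for label, w in band_weights.items():
        if w == 0:
            continue
        band = _FTIR_LABELS[label]
        center = 0.5 * (band.lo + band.hi)
        fwhm = 0.5 * (band.hi - band.lo)
        y += _gaussian(grid, w, center, fwhm)
    all_zero = not np.any(y) and noise_sd == 0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=grid.shape)
    meta = {"synthetic": True, "seed": seed}
    if all_zero:
        meta["all_zero"] = True
        warnings.warn("all band weights zero and no noise: flat zero spectrum",
                      stacklevel=2)
    return Spectrum(grid, y, AXIS_WAVENUMBER_CM1, meta)


# ---------------------------------------------------------------------
# Chemistry tables
# ---------------------------------------------------------------------

_DEFAULT_SD = {"C": 0.7, "N": 0.06, "delta13C": 0.3, "pH": 0.05}


@dataclass
class ChemistryScenario:
    """Ground-truth parameters of a synthetic mesh-bag chemistry table.

    Defaults emulate the study conditions: 3 plots per treatment,
    initial material at 12.1 g C kg^-1 and 1.02 g N kg^-1, per-horizon
    decay constants of 0.11 (humus) and 0.29 (mineral) yr^-1, maize
    end-member -13.36 per mil vs new fungal carbon at -25.82 per mil
    with 10% new C, and a 21% rise of C/N over the initial ratio.
    ``between_plot_sd`` is a per-variable map of additive Gaussian
    between-plot standard deviations (a scalar applies to all).
    """

    n_plots_per_treatment: int = 3
    initial_C: float = 12.1
    initial_N: float = 1.02
    horizon_decay_rates: dict[str, float] = field(
        default_factory=lambda: {"humus": 0.11, "mineral": 0.29})
    delta13c_c4: float = -13.36
    delta13c_new: float = -25.82
    new_c_fraction: float = 0.10
    cn_increase_factor: float = 1.21
    ph_mean: float = 4.2
    between_plot_sd: dict[str, float] | float = field(
        default_factory=lambda: dict(_DEFAULT_SD))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_C <= 0 or self.initial_N <= 0:
            raise ValueError("initial C and N must be positive")
        if any(k < 0 for k in self.horizon_decay_rates.values()):
            raise ValueError("decay rates must be >= 0")
        if not 0.0 <= self.new_c_fraction <= 1.0:
            raise ValueError("new_c_fraction must lie in [0, 1]")
        if self.delta13c_c4 <= self.delta13c_new:
            raise ValueError("the C4 end-member must be heavier than new carbon")
        if isinstance(self.between_plot_sd, (int, float)):
            self.between_plot_sd = {k: float(self.between_plot_sd)
                                    for k in _DEFAULT_SD}
        if any(v < 0 for v in self.between_plot_sd.values()):
            raise ValueError("between-plot SDs must be >= 0")


def gen_chemistry_table(scn: ChemistryScenario, t_years: float
                        ) -> tuple[pd.DataFrame, dict]:
    """Generate a per-plot chemistry table after ``t_years`` of incubation.

    Per plot x horizon x treatment: final C = initial_C * e^(-k_h * t)
    plus noise; delta-13C mixes the two end-members at the scenario's
    ``new_c_fraction``; N is drawn so that C/N equals the initial ratio
    times ``cn_increase_factor`` (before noise).  Ground truth (decay
    rates, mixing fraction, target C/N) is returned alongside.
    """
    if t_years <= 0:
        raise ValueError("t_years must be positive")
    rng = np.random.default_rng(scn.seed)
    sd = scn.between_plot_sd
    cn_initial = scn.initial_C / scn.initial_N
    cn_target = cn_initial * scn.cn_increase_factor
    f_new = scn.new_c_fraction
    delta_true = (1.0 - f_new) * scn.delta13c_c4 + f_new * scn.delta13c_new

    rows = []
    for treatment in TREATMENTS:
        for horizon in HORIZONS:
            k = scn.horizon_decay_rates[horizon]
            for plot in range(1, scn.n_plots_per_treatment + 1):
                c = scn.initial_C * math.exp(-k * t_years) + rng.normal(0, sd["C"])
                n = c / cn_target + rng.normal(0, sd["N"])
                rows.append({
                    "plot": f"{treatment[:4]}-{plot}",
                    "horizon": horizon,
                    "treatment": treatment,
                    "C": c,
                    "N": n,
                    "delta13C": delta_true + rng.normal(0, sd["delta13C"]),
                    "pH": scn.ph_mean + rng.normal(0, sd["pH"]),
                })
    table = pd.DataFrame(rows)
    truth = {
        "initial_C": scn.initial_C,
        "initial_N": scn.initial_N,
        "cn_initial": cn_initial,
        "cn_target": cn_target,
        "horizon_decay_rates": dict(scn.horizon_decay_rates),
        "new_c_fraction": f_new,
        "delta13C_true": delta_true,
        "end_members": (scn.delta13c_c4, scn.delta13c_new),
        "t_years": t_years,
        "seed": scn.seed,
    }
    return table, truth


# ---------------------------------------------------------------------
# OTU experiments
# ---------------------------------------------------------------------

@dataclass
class OtuScenario:
    """Design of a synthetic OTU sequencing experiment.

    ``rare_otu_fraction`` of the OTUs are engineered to fail the default
    rare-OTU filter (< 10 total reads in a single column); the remaining
    OTUs share a per-sample composition that all technical replicates of
    a sample resample multinomially.  ``depth_range`` emulates uneven
    per-column read depths.
    """

    n_otus: int = 60
    n_samples: int = 6
    n_tech_reps: int = 3
    guild_proportions: dict[str, float] = field(
        default_factory=lambda: {"ECM": 0.4, "saprotroph": 0.5,
                                 "pathogen": 0.05, "unknown": 0.05})
    depth_range: tuple[int, int] = (12000, 25000)
    rare_otu_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.array(list(self.guild_proportions.values()), float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("guild proportions must sum to 1")
        if (props < 0).any():
            raise ValueError("guild proportions must be >= 0")
        if self.n_otus < len(self.guild_proportions):
            raise ValueError("need at least one OTU per guild")
        lo, hi = self.depth_range
        if lo > hi:
            raise ValueError("depth_range min must be <= max")
        if lo < 1:
            raise ValueError("read depth must be >= 1")
        if not 0.0 <= self.rare_otu_fraction < 1.0:
            raise ValueError("rare_otu_fraction must lie in [0, 1)")
        if self.n_tech_reps < 1 or self.n_samples < 1:
            raise ValueError("need >= 1 sample and >= 1 technical replicate")


def _largest_remainder(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Integer allocation of n items to labeled proportions."""
    raw = {g: n * p for g, p in proportions.items()}
    alloc = {g: int(math.floor(v)) for g, v in raw.items()}
    rest = n - sum(alloc.values())
    for g in sorted(raw, key=lambda g: raw[g] - alloc[g], reverse=True)[:rest]:
        alloc[g] += 1
    return alloc


def gen_otu_experiment(scn: OtuScenario):
    """Generate an OTU count table with technical replicates and truth.

    Returns ``(OtuTable, truth)`` where truth records the intended
    per-sample relative composition, the guild of every OTU, per-column
    depths, and exactly which OTUs were planted to fail the rare-OTU
    filter.
    """
    from .community import OtuTable  # local import avoids a cycle

    rng = np.random.default_rng(scn.seed)
    n_rare = int(round(scn.rare_otu_fraction * scn.n_otus))
    n_abund = scn.n_otus - n_rare
    otus = [f"OTU{i + 1:04d}" for i in range(scn.n_otus)]
    rare_ids = otus[n_abund:]

    # Guild labels allocated by largest remainder over all OTUs, shuffled.
    alloc = _largest_remainder(scn.n_otus, scn.guild_proportions)
    labels = [g for g, c in alloc.items() for _ in range(c)]
    labels = [labels[i] for i in rng.permutation(len(labels))]
    guild = dict(zip(otus, labels))

    # Shared per-sample composition over abundant OTUs: Dirichlet mixed
    # with a uniform floor so no abundant OTU can fail the filter.
    samples = [f"S{j + 1}" for j in range(scn.n_samples)]
    comp = np.zeros((scn.n_otus, scn.n_samples))
    for j in range(scn.n_samples):
        base = rng.dirichlet(np.full(n_abund, 5.0))
        comp[:n_abund, j] = 0.9 * base + 0.1 / n_abund

    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    depths: dict[str, int] = {}
    for j, sample in enumerate(samples):
        for r in range(1, scn.n_tech_reps + 1):
            col = f"{sample}_r{r}"
            depth = int(rng.integers(scn.depth_range[0], scn.depth_range[1] + 1))
            columns[col] = rng.multinomial(depth, comp[:, j])
            groups[col] = sample
            depths[col] = depth
    counts = pd.DataFrame(columns, index=otus)

    # Plant the rare OTUs: < 10 total reads confined to one column each,
    # so they fail both the read and the occupancy condition.
    all_cols = list(counts.columns)
    for otu in rare_ids:
        col = all_cols[int(rng.integers(len(all_cols)))]
        counts.loc[otu, col] = int(rng.integers(1, 10))

    taxonomy = {otu: f"Fungus sp. {i + 1}" for i, otu in enumerate(otus)}
    table = OtuTable(counts=counts, replicate_groups=groups,
                     taxonomy=taxonomy, guild=guild,
                     meta={"synthetic": True, "seed": scn.seed})
    truth = {
        "composition": pd.DataFrame(comp, index=otus, columns=samples),
        "guild": guild,
        "filter_targets": rare_ids,
        "depths": depths,
        "seed": scn.seed,
    }
    return table, truth
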