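"""Synthetic calibration data: historical-like series from known ground truth.

The public aggregates the model is calibrated against (annual mental-health
ED presentations, self-harm hospitalisations, suicide deaths, distress
prevalence, delivered subsidised sessions) have no deposited machine-readable
accession, so this module generates statistically similar stand-ins by
running the historical-era baseline (trend plus COVID-era shocks) from a
known ground-truth :class:`~mhsd.params.ParameterSet` and adding seeded
multiplicative log-normal observation noise.  Noise touches observations
only, never the dynamics — the model itself is deterministic.

Because ground truth is known, the generator and the calibrator are mutually
verifying: a noiseless fixture must be recovered exactly, and noisy fixtures
quantify parameter identifiability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import sector
from .calibration import ObservedSeries, simulated_observables, write_observed
from .params import ParameterSet
from .scenarios import baseline
from .sd_core import DEFAULT_DT, StockVector, integrate

__all__ = ["SyntheticSpec", "generate", "write_fixture", "make_fixture_population"]

DEFAULT_SERIES = tuple(sector.OBSERVABLES)


def lognormal_noise(rng: np.random.Generator, sigma: float, size: int) -> np.ndarray:
    """Multiplicative log-normal noise factors with mean exactly 1
    (``exp(sigma*Z - sigma^2/2)``), so noisy observations are unbiased on the
    natural scale and ``E[log(obs/true)] = -sigma^2/2``."""
    return np.exp(sigma * rng.standard_normal(size) - sigma**2 / 2.0)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic calibration fixture."""

    params: ParameterSet = field(default_factory=ParameterSet.reference)
    first_year: int = 2011
    last_year: int = 2021
    noise_sigma: float = 0.05
    seed: int = 0
    covid: bool = True
    series: tuple[str, ...] = DEFAULT_SERIES
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not (2011 <= self.first_year <= self.last_year <= 2028):
            raise ValueError("observation period must lie within 2011-2028")
        unknown = set(self.series) - set(sector.OBSERVABLES)
        if unknown:
            raise KeyError(f"not model observables: {sorted(unknown)}")


def generate(spec: SyntheticSpec) -> tuple[list[ObservedSeries], dict]:
    """Run the historical-era baseline and emit noisy annual observations.

    Observation times are mid-period dates (year + 0.5).  Noise is
    multiplicative log-normal with mean 1 (``exp(sigma*Z - sigma^2/2)``), one
    seeded generator across every series so a fixture is reproduced
    byte-identically from (spec, seed).  Returns the series plus a provenance
    record (seed, sigma, true parameter values).
    """
    scenario = baseline(spec.params, covid=spec.covid)
    years = np.arange(spec.first_year, spec.last_year + 1)
    times = years + 0.5
    traj = integrate(
        sector.flow_field, spec.params, scenario, 2011.0, spec.last_year + 1.0, spec.dt
    )
    skeleton = [ObservedSeries(name, times, np.ones_like(times)) for name in spec.series]
    truth = simulated_observables(traj, skeleton)

    rng = np.random.default_rng(spec.seed)
    observed = []
    for name in spec.series:
        clean = truth[name]
        if spec.noise_sigma > 0:
            noisy = clean * lognormal_noise(rng, spec.noise_sigma, clean.size)
        else:
            noisy = clean.copy()
        observed.append(ObservedSeries(name, times.copy(), noisy))
    provenance = {
        "seed": spec.seed,
        "noise_sigma": spec.noise_sigma,
        "first_year": spec.first_year,
        "last_year": spec.last_year,
        "covid": spec.covid,
        "series": list(spec.series),
        "true_parameters": spec.params.as_dict(),
    }
    return observed, provenance


def write_fixture(spec: SyntheticSpec, out_dir) -> tuple[Path, Path]:
    """Write a fixture in the calibration file dialect plus its provenance
    record; returns the two paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    observed, provenance = generate(spec)
    series_path = out / "observed.tsv"
    prov_path = out / "provenance.json"
    write_observed(observed, series_path)
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return series_path, prov_path


def make_fixture_population(
    scale: float,
    distress_prevalence: float,
    band_shares: tuple[float, float, float] = (0.19, 0.13, 0.68),
) -> StockVector:
    """A valid initial stock vector at the given population scale and
    moderate+ prevalence (%), everyone initially not seeking care."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not (0.0 <= distress_prevalence <= 100.0):
        raise ValueError("prevalence must lie in [0, 100]")
    shares = np.asarray(band_shares, dtype=float)
    shares = shares / shares.sum()
    values = np.zeros((len(sector.BANDS), len(sector.STATES)))
    for b, share in enumerate(shares):
        n = scale * share
        values[b, 1] = n * distress_prevalence / 100.0  # dist
        values[b, 0] = n - values[b, 1]  # low
    return StockVector(sector.STOCK_NAMES, values.ravel(), 2011.0)
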