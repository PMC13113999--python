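"""Synthetic plate-reader data and association tables with known truth.

The simulator works on the absorbance scale, the quantity the plate
reader actually measures: a true scavenging curve is inverted through
the configured assay convention to an expected well absorbance, and
Gaussian noise is added there.  Rate-scale noise then inherits the
convention's nonlinearity, as it does on a real plate.

Blank wells draw from Normal(blank_mean, blank_sd); the default blank
of 0.70 +/- 0.05 AU is read as a ~95% range, so blank_sd defaults to
0.05 / 1.96.  Three technical replicates per concentration is the
default design.  Each well gets its own counter-derived random
substream, so replicate or well ordering never changes the draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .assay import AbtsConvention, Assay, WellReading
from .errors import ValidationError
from .isobole import MixtureRatio

DEFAULT_BLANK_MEAN = 0.70
DEFAULT_BLANK_SD = 0.05 / 1.96


@dataclass(frozen=True)
class TrueCurve:
    """Ground-truth scavenging curve for simulation.

    ``linear`` mirrors the estimation model; ``logistic`` (Hill) is a
    saturating truth model used to probe the linear estimator's
    robustness — it never enters the estimation path.
    """

    model: Literal["linear", "logistic"]
    slope: float = 0.0
    intercept: float = 0.0
    ic50: float = 50.0
    hill: float = 1.0
    max_effect: float = 100.0

    def __post_init__(self) -> None:
        if self.model == "logistic":
            if self.ic50 <= 0 or self.hill <= 0:
                raise ValidationError("logistic curve needs ic50 > 0 and hill > 0")
            if self.max_effect > 100.0:
                raise ValidationError("max effect cannot exceed 100%")


def true_scavenging(curve: TrueCurve, conc: float) -> float:
    """Evaluate the ground-truth scavenging (%) at one concentration."""
    if conc < 0:
        raise ValidationError("concentration must be >= 0")
    if curve.model == "linear":
        return curve.intercept + curve.slope * conc
    return curve.max_effect * conc**curve.hill / (conc**curve.hill + curve.ic50**curve.hill)


@dataclass(frozen=True)
class SimulationConfig:
    """Plate-simulation settings (absorbance units, ug/mL, counts)."""

    assay: Assay = "DPPH"
    blank_mean: float = DEFAULT_BLANK_MEAN
    blank_sd: float = DEFAULT_BLANK_SD
    noise_sd_abs: float = 0.005
    replicates: int = 3
    concentrations: tuple[float, ...] = (12.5, 25.0, 50.0, 100.0, 150.0)
    seed: int = 0
    convention: AbtsConvention = "as_printed"

    def __post_init__(self) -> None:
        if self.blank_sd < 0 or self.noise_sd_abs < 0:
            raise ValidationError("noise SDs must be >= 0")
        if self.replicates < 1:
            raise ValidationError("need >= 1 replicate")
        concs = self.concentrations
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValidationError("concentrations must be strictly increasing")


def make_mixture_design(
    ratio: MixtureRatio, axis_concs: Sequence[float]
) -> list[tuple[float, float]]:
    """Expand axis concentrations (lower-proportion component) to (conc_a, conc_b) pairs."""
    if any(c <= 0 for c in axis_concs):
        raise ValidationError("axis concentrations must be positive")
    if any(b <= a for a, b in zip(axis_concs, list(axis_concs)[1:])):
        raise ValidationError("axis concentrations must be strictly increasing")
    pairs = []
    for x in axis_concs:
        if ratio.axis_component == "A":
            pairs.append((x, x * ratio.k_b / ratio.k_a))
        else:
            pairs.append((x * ratio.k_a / ratio.k_b, x))
    return pairs


def _invert_rate_to_absorbance(
    rate: float, a_blank: float, assay: Assay, convention: AbtsConvention
) -> float:
    """Expected sample-well absorbance producing ``rate`` given the blank."""
    if assay == "DPPH":
        # A_control simulated as 0, so A_measure = A_blank (1 - rate/100).
        return a_blank * (1.0 - rate / 100.0)
    if convention == "as_printed":
        return 100.0 * a_blank / (100.0 + rate)
    return a_blank * (1.0 - rate / 100.0)


@dataclass(frozen=True)
class PlateSimulation:
    """Simulated plate plus provenance and the negative-clip counter."""

    readings: tuple[WellReading, ...]
    curve: TrueCurve
    config: SimulationConfig
    design: tuple[tuple[float, float], ...]
    n_clipped: int


def _well_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_plate(
    curve: TrueCurve,
    design: Sequence[tuple[float, float]],
    config: SimulationConfig,
) -> PlateSimulation:
    """Simulate a plate: blanks per replicate plus sample wells per design row.

    Identical seeds give bit-identical plates.  With all noise SDs at
    zero, converting the simulated wells back to rates recovers the true
    curve exactly (round-trip identity).  Absorbances driven below zero
    by the inversion or noise are clipped to 0 and counted.
    """
    readings: list[WellReading] = []
    n_clipped = 0
    blanks: dict[int, float] = {}
    for rep in range(1, config.replicates + 1):
        rng = _well_rng(config.seed, 0, rep)
        a = config.blank_mean + (config.blank_sd * rng.standard_normal() if config.blank_sd else 0.0)
        if a < 0:
            a, n_clipped = 0.0, n_clipped + 1
        blanks[rep] = a
        readings.append(
            WellReading(
                assay=config.assay, role="blank", absorbance=a, replicate=rep,
                well=f"blank-r{rep}",
            )
        )
    for ci, (conc_a, conc_b) in enumerate(design):
        rate = true_scavenging(curve, conc_a + conc_b)
        for rep in range(1, config.replicates + 1):
            expected = _invert_rate_to_absorbance(rate, blanks[rep], config.assay, config.convention)
            rng = _well_rng(config.seed, 1, ci, rep)
            a = expected + (config.noise_sd_abs * rng.standard_normal() if config.noise_sd_abs else 0.0)
            if a < 0:
                a, n_clipped = 0.0, n_clipped + 1
            readings.append(
                WellReading(
                    assay=config.assay, role="sample", absorbance=a, replicate=rep,
                    conc_a=conc_a, conc_b=conc_b, well=f"s{ci}-r{rep}",
                )
            )
    return PlateSimulation(
        readings=tuple(readings),
        curve=curve,
        config=config,
        design=tuple((a, b) for a, b in design),
        n_clipped=n_clipped,
    )


def truth_sidecar(sim: PlateSimulation) -> dict:
    """JSON-serializable record of the simulation's ground truth."""
    c = sim.curve
    truth = {"model": c.model}
    if c.model == "linear":
        truth.update(slope=c.slope, intercept=c.intercept)
    else:
        truth.update(true_ic50=c.ic50, hill=c.hill, max_effect=c.max_effect)
    return {
        "truth": truth,
        "seed": sim.config.seed,
        "config": {
            "assay": sim.config.assay,
            "blank_mean": sim.config.blank_mean,
            "blank_sd": sim.config.blank_sd,
            "noise_sd_abs": sim.config.noise_sd_abs,
            "replicates": sim.config.replicates,
            "concentrations": list(sim.config.concentrations),
            "convention": sim.config.convention,
        },
        "n_clipped": sim.n_clipped,
    }


@dataclass(frozen=True)
class PlantedLink:
    """A monotone taxon-marker association to plant in synthetic tables."""

    taxon: str
    marker: str
    sign: Literal["positive", "negative"] = "positive"


def simulate_association_tables(
    n_samples: int,
    taxa: Sequence[str],
    markers: Sequence[str],
    links: Sequence[PlantedLink] = (),
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x taxon abundances and sample x marker expressions with
    planted monotone links.

    Abundances are log-normal (strictly positive, heavy-tailed, as
    relative-abundance data tend to be).  A linked marker is a strictly
    monotone transform of its taxon's abundance plus Gaussian noise on
    the log scale, so at ``noise=0`` the planted Spearman correlation is
    exactly +/-1; unlinked pairs are independent.  Returns (abundance,
    biomarker) DataFrames with taxa/markers as rows and samples as
    columns.
    """
    if n_samples < 4:
        raise ValidationError("need at least 4 samples")
    taxa = list(taxa)
    markers = list(markers)
    link_map: dict[str, PlantedLink] = {}
    for link in links:
        if link.taxon not in taxa:
            raise ValidationError(f"planted link names unknown taxon {link.taxon!r}")
        if link.marker not in markers:
            raise ValidationError(f"planted link names unknown marker {link.marker!r}")
        link_map[link.marker] = link
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    samples = [f"S{i+1}" for i in range(n_samples)]
    log_abund = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(taxa), n_samples)), index=taxa, columns=samples
    )
    abund = np.exp(log_abund)
    expr = pd.DataFrame(index=markers, columns=samples, dtype=float)
    for m in markers:
        if m in link_map:
            link = link_map[m]
            base = log_abund.loc[link.taxon].to_numpy()
            if link.sign == "negative":
                base = -base
        else:
            base = rng.normal(0.0, 1.0, size=n_samples)
        eps = rng.normal(0.0, noise, size=n_samples) if noise > 0 else 0.0
        expr.loc[m] = np.exp(base + eps)
    abund.index.name = "taxon"
    expr.index.name = "marker"
    return abund, expr


def write_truth_json(path: str | Path, sim: PlateSimulation) -> None:
    Path(path).write_text(json.dumps(truth_sidecar(sim), indent=2, sort_keys=True) + "\n")
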