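"""Plate-reader I/O and radical-scavenging rate computation.

Two colorimetric assays are supported.  DPPH (515 nm) uses a blank, a
measure well (sample + radical) and a color-control well (sample +
solvent, no radical):

    scavenging % = 100 * [A_blank - (A_measure - A_control)] / A_blank

ABTS (734 nm) uses a blank and a sample well.  Two conventions exist
for the denominator:

    as_printed:  100 * (A_blank - A_sample) / A_sample
    standard:    100 * (A_blank - A_sample) / A_blank

``as_printed`` follows the formula some assay write-ups print (it
reaches 100% when the sample halves the absorbance); ``standard`` is the
usual fractional-inhibition form.  Neither is asserted as correct; the
convention used is carried through every report.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BlankAbsorbanceError,
    ConfigurationError,
    ConsistencyError,
    TableParseError,
    ValidationError,
)
from .isobole import MixtureRatio

Assay = Literal["ABTS", "DPPH"]
Role = Literal["blank", "sample", "color_control"]
AbtsConvention = Literal["as_printed", "standard"]

PLATE_COLUMNS = ["well", "assay", "role", "replicate", "conc_a", "conc_b", "absorbance"]
DOSE_COLUMNS = ["assay", "ratio", "conc_caa", "conc_cha", "scavenging_pct"]


@dataclass(frozen=True)
class WellReading:
    """One absorbance measurement from a plate well."""

    assay: Assay
    role: Role
    absorbance: float
    replicate: int
    conc_a: float = 0.0
    conc_b: float = 0.0
    well: str = ""

    def __post_init__(self) -> None:
        if self.absorbance < 0 or not math.isfinite(self.absorbance):
            raise ValidationError(f"absorbance must be finite and >= 0 (well {self.well!r})")
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")
        if self.conc_a < 0 or self.conc_b < 0:
            raise ValidationError("concentrations must be >= 0")
        if self.role == "blank" and (self.conc_a != 0 or self.conc_b != 0):
            raise ValidationError("blank wells must have zero concentrations")
        if self.role == "color_control" and self.assay != "DPPH":
            raise ValidationError("color-control wells occur only in the DPPH assay")


@dataclass(frozen=True)
class Point:
    """One dose-response observation."""

    axis_conc: float
    conc_a: float
    conc_b: float
    scavenging: float


@dataclass(frozen=True)
class DoseResponseSeries:
    """Scavenging rate vs concentration for one composition and assay.

    ``axis_conc`` is the plotting axis: the concentration of the
    lower-proportion component for fixed-ratio mixtures (the
    per-component concentration for 1:1).
    """

    assay: Assay
    label: str
    points: tuple[Point, ...]
    ratio: MixtureRatio | None = None

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValidationError(f"series {self.label!r} needs >= 2 points")
        axis = [p.axis_conc for p in self.points]
        if any(b <= a for a, b in zip(axis, axis[1:])):
            raise ValidationError(
                f"series {self.label!r}: axis concentrations must be strictly increasing"
            )
        for p in self.points:
            if p.scavenging > 100.0 + 1e-9:
                raise ValidationError(f"series {self.label!r}: scavenging > 100%")
        if self.ratio is not None:
            for p in self.points:
                total = p.conc_a + p.conc_b
                if total <= 0:
                    raise ValidationError(f"series {self.label!r}: zero total concentration")
                if abs(p.conc_a / total - self.ratio.k_a) > 1e-9:
                    raise ValidationError(
                        f"series {self.label!r}: concentrations inconsistent with ratio "
                        f"{self.ratio.label()}"
                    )

    @property
    def x(self) -> np.ndarray:
        return np.array([p.axis_conc for p in self.points], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([p.scavenging for p in self.points], dtype=float)


def compute_dpph_scavenging(a_blank: float, a_measure: float, a_control: float) -> float:
    """DPPH scavenging %: 100 * [A_blank - (A_measure - A_control)] / A_blank."""
    for name, v in (("a_blank", a_blank), ("a_measure", a_measure), ("a_control", a_control)):
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"{name} must be finite and >= 0")
    if a_blank == 0:
        raise BlankAbsorbanceError("blank well absorbance is zero; cannot divide")
    return 100.0 * (a_blank - (a_measure - a_control)) / a_blank


def compute_abts_scavenging(
    a_blank: float, a_sample: float, convention: AbtsConvention = "as_printed"
) -> float:
    """ABTS scavenging % under the chosen denominator convention."""
    for name, v in (("a_blank", a_blank), ("a_sample", a_sample)):
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"{name} must be finite and >= 0")
    if convention == "as_printed":
        if a_sample == 0:
            raise BlankAbsorbanceError("sample absorbance is zero; cannot divide (as_printed)")
        return 100.0 * (a_blank - a_sample) / a_sample
    if convention == "standard":
        if a_blank == 0:
            raise BlankAbsorbanceError("blank well absorbance is zero; cannot divide")
        return 100.0 * (a_blank - a_sample) / a_blank
    raise ConfigurationError(f"unknown ABTS convention {convention!r}")


@dataclass(frozen=True)
class ReplicateRate:
    """Scavenging rate of one sample well after blank pairing."""

    assay: Assay
    conc_a: float
    conc_b: float
    replicate: int
    scavenging: float


@dataclass(frozen=True)
class AggregatedRate:
    """Replicate-averaged scavenging at one concentration.

    ``sd`` is NaN when only one replicate is available.
    """

    mean: float
    sd: float
    n: int

    @property
    def sd_defined(self) -> bool:
        return not math.isnan(self.sd)


def rates_from_plate(
    readings: Iterable[WellReading], convention: AbtsConvention = "as_printed"
) -> list[ReplicateRate]:
    """Convert raw plate wells to per-replicate scavenging rates.

    Each sample well is paired with the blank of its own replicate (and,
    for DPPH, the color-control well at matching concentrations if one
    exists, else A_control = 0).
    """
    readings = list(readings)
    blanks: dict[tuple[str, int], float] = {}
    controls: dict[tuple[str, int, float, float], float] = {}
    for r in readings:
        if r.role == "blank":
            key = (r.assay, r.replicate)
            if key in blanks:
                raise ConsistencyError(f"duplicate blank for {key}")
            blanks[key] = r.absorbance
        elif r.role == "color_control":
            controls[(r.assay, r.replicate, r.conc_a, r.conc_b)] = r.absorbance
    out: list[ReplicateRate] = []
    for r in readings:
        if r.role != "sample":
            continue
        try:
            a_blank = blanks[(r.assay, r.replicate)]
        except KeyError:
            raise ConsistencyError(
                f"no blank well for assay {r.assay} replicate {r.replicate}"
            ) from None
        if r.assay == "DPPH":
            a_ctrl = controls.get((r.assay, r.replicate, r.conc_a, r.conc_b), 0.0)
            rate = compute_dpph_scavenging(a_blank, r.absorbance, a_ctrl)
        else:
            rate = compute_abts_scavenging(a_blank, r.absorbance, convention)
        out.append(
            ReplicateRate(
                assay=r.assay,
                conc_a=r.conc_a,
                conc_b=r.conc_b,
                replicate=r.replicate,
                scavenging=rate,
            )
        )
    return out


def aggregate_replicates(rates: Sequence[ReplicateRate]) -> AggregatedRate:
    """Mean and sample SD of replicate rates at one (assay, conc) condition."""
    if len(rates) == 0:
        raise ConsistencyError("no replicate rates to aggregate")
    first = rates[0]
    for r in rates[1:]:
        if (r.assay, r.conc_a, r.conc_b) != (first.assay, first.conc_a, first.conc_b):
            raise ConsistencyError(
                "replicates to aggregate must share assay and concentrations"
            )
    values = np.array([r.scavenging for r in rates], dtype=float)
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")
    return AggregatedRate(mean=float(np.mean(values)), sd=sd, n=len(values))


def aggregate_plate(
    readings: Iterable[WellReading], convention: AbtsConvention = "as_printed"
) -> pd.DataFrame:
    """Full plate -> tidy table of replicate-averaged rates.

    Columns: assay, conc_a, conc_b, scavenging_mean, scavenging_sd, n;
    sorted by assay then total concentration.
    """
    rates = rates_from_plate(readings, convention)
    groups: dict[tuple[str, float, float], list[ReplicateRate]] = {}
    for r in rates:
        groups.setdefault((r.assay, r.conc_a, r.conc_b), []).append(r)
    rows = []
    for (assay, ca, cb), grp in sorted(groups.items()):
        agg = aggregate_replicates(grp)
        rows.append(
            {
                "assay": assay,
                "conc_a": ca,
                "conc_b": cb,
                "scavenging_mean": agg.mean,
                "scavenging_sd": agg.sd,
                "n": agg.n,
            }
        )
    return pd.DataFrame(rows, columns=["assay", "conc_a", "conc_b",
                                       "scavenging_mean", "scavenging_sd", "n"])


def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text.splitlines() else ""
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_plate_csv(path: str | Path) -> list[WellReading]:
    """Read a plate table (columns well, assay, role, replicate, conc_a, conc_b, absorbance)."""
    text = Path(path).read_text()
    delim = _sniff_delimiter(text)
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    missing = set(PLATE_COLUMNS) - set(reader.fieldnames or [])
    if missing:
        raise TableParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in enumerate(reader, start=2):
        try:
            out.append(
                WellReading(
                    assay=row["assay"].strip(),  # type: ignore[arg-type]
                    role=row["role"].strip(),  # type: ignore[arg-type]
                    absorbance=float(row["absorbance"]),
                    replicate=int(row["replicate"]),
                    conc_a=float(row["conc_a"]),
                    conc_b=float(row["conc_b"]),
                    well=row["well"].strip(),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise TableParseError(f"{path} line {i}: {exc}") from exc
    return out


def write_plate_csv(path: str | Path, readings: Iterable[WellReading]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PLATE_COLUMNS)
        for r in readings:
            w.writerow(
                [r.well, r.assay, r.role, r.replicate,
                 repr(r.conc_a), repr(r.conc_b), repr(r.absorbance)]
            )


def _axis_point(ratio: MixtureRatio, conc_a: float, conc_b: float) -> float:
    return conc_a if ratio.axis_component == "A" else conc_b


def read_dose_response_table(path: str | Path) -> list[DoseResponseSeries]:
    """Read a mixture dose-response table into one series per (assay, ratio).

    Expected columns: assay, ratio (A:B mass ratio), conc_caa, conc_cha,
    scavenging_pct.  Comma or tab delimited, autodetected.  Points are
    sorted by the axis (lower-proportion component) concentration and
    validated against the declared ratio.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise TableParseError(f"{path}: empty file")
    delim = _sniff_delimiter(text)
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    missing = set(DOSE_COLUMNS) - set(reader.fieldnames or [])
    if missing:
        raise TableParseError(f"{path}: missing columns {sorted(missing)}")

    groups: dict[tuple[str, str], list[Point]] = {}
    for i, row in enumerate(reader, start=2):
        try:
            assay = row["assay"].strip()
            ratio = MixtureRatio.from_string(row["ratio"])
            ca = float(row["conc_caa"])
            cb = float(row["conc_cha"])
            sc = float(row["scavenging_pct"])
        except (ValueError, ValidationError) as exc:
            raise TableParseError(f"{path} line {i}: {exc}") from exc
        groups.setdefault((assay, ratio.label()), []).append(
            Point(axis_conc=_axis_point(ratio, ca, cb), conc_a=ca, conc_b=cb, scavenging=sc)
        )

    series = []
    for (assay, ratio_label), pts in groups.items():
        pts = sorted(pts, key=lambda p: p.axis_conc)
        axis = [p.axis_conc for p in pts]
        if len(set(axis)) != len(axis):
            raise TableParseError(
                f"{path}: duplicate axis concentration in series ({assay}, {ratio_label})"
            )
        try:
            series.append(
                DoseResponseSeries(
                    assay=assay,  # type: ignore[arg-type]
                    label=f"{assay} {ratio_label}",
                    points=tuple(pts),
                    ratio=MixtureRatio.from_string(ratio_label),
                )
            )
        except ValidationError as exc:
            raise TableParseError(f"{path}: {exc}") from exc
    return series


def write_dose_response_table(path: str | Path, series: Iterable[DoseResponseSeries]) -> None:
    """Write series back to the tabular layout (tab-delimited, lossless floats)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(DOSE_COLUMNS)
        for s in series:
            ratio_label = s.ratio.label() if s.ratio else "1:1"
            for p in s.points:
                w.writerow([s.assay, ratio_label, repr(p.conc_a), repr(p.conc_b),
                            repr(p.scavenging)])
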