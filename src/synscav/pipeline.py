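"""End-to-end synergy pipeline: dose-response tables -> Table-style synergy report.

For each mixture series the pipeline fits the dose-effect line,
inverse-predicts the mixture IC50 on the lower-proportion-component
axis, reads that number as total mixture concentration (the scale on
which the interaction index is defined), and combines it with the
single-compound IC50s into the Loewe additivity assessment.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .assay import DoseResponseSeries, read_dose_response_table
from .dose_response import (
    CIMethod,
    IC50Estimate,
    estimate_ic50,
    fit_line,
)
from .errors import ConfigurationError
from .isobole import (
    IsoboleEnvelope,
    SynergyAssessment,
    assess_synergy,
    isobole_envelope,
)

#: Single-compound IC50s and mixture tables measured in this study ship
#: as package fixtures so the full analysis is reproducible offline.
DATA_PACKAGE = "synscav.data"
MIXTURE_TABLE = "mixture_scavenging.tsv"
SINGLE_IC50_JSON = "single_compound_ic50.json"


def packaged_mixture_table() -> Path:
    return Path(str(resources.files(DATA_PACKAGE) / MIXTURE_TABLE))


def load_packaged_series() -> list[DoseResponseSeries]:
    return read_dose_response_table(packaged_mixture_table())


def load_packaged_single_ic50s() -> dict[str, dict[str, float]]:
    """{assay: {compound: IC50 ug/mL}} for the two pure compounds."""
    text = (resources.files(DATA_PACKAGE) / SINGLE_IC50_JSON).read_text()
    return json.loads(text)


def _round_sig(value: float, sig: int = 4) -> float:
    if value == 0 or not math.isfinite(value):
        return value
    return round(value, sig - 1 - int(math.floor(math.log10(abs(value)))))


@dataclass(frozen=True)
class SynergyEntry:
    """One (assay, ratio) row of the report."""

    assay: str
    ratio_label: str
    fit_slope: float
    fit_intercept: float
    r_squared: float
    ic50_mix: IC50Estimate
    assessment: SynergyAssessment
    ic50_add_flag: str | None = None

    def to_dict(self) -> dict:
        a = self.assessment
        return {
            "assay": self.assay,
            "ratio": self.ratio_label,
            "fit": {
                "slope": self.fit_slope,
                "intercept": self.fit_intercept,
                "r_squared": self.r_squared,
            },
            "ic50_mix": {
                "value": self.ic50_mix.value,
                "ci_low": self.ic50_mix.ci_low,
                "ci_high": self.ic50_mix.ci_high,
                "level": self.ic50_mix.level,
                "method": self.ic50_mix.method,
                "extrapolated": self.ic50_mix.extrapolated,
            },
            "synergy": {
                "r": a.potency_ratio_r,
                "ic50_add": a.ic50_add,
                "ic50_mix_axis": a.ic50_mix_axis,
                "ic50_mix_total": a.ic50_mix_total,
                "dose_a": a.dose_a_at_mix,
                "dose_b": a.dose_b_at_mix,
                "gamma": a.gamma,
                "classification": a.classification,
            },
            **({"ic50_add_flag": self.ic50_add_flag} if self.ic50_add_flag else {}),
        }


@dataclass(frozen=True)
class SynergyReport:
    """Complete pipeline output plus the conventions used to produce it."""

    entries: tuple[SynergyEntry, ...]
    ci_method: CIMethod
    ci_level: float
    abts_convention: str
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "ci_method": self.ci_method,
            "ci_level": self.ci_level,
            "abts_convention": self.abts_convention,
            "ic50_mix_scale_note": (
                "ic50_mix_axis is the fitted IC50 on the lower-proportion-component "
                "axis; ic50_mix_total reads the same number as total mixture "
                "concentration and splits it by the mass fractions for gamma."
            ),
            "entries": [e.to_dict() for e in self.entries],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_table_tsv(self, path: str | Path) -> None:
        """Write the assay x ratio summary table (additive IC50, mixture
        IC50, interaction index) at display precision."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["assay", "ratio", "ic50_add_ug_ml", "ic50_mix_ug_ml",
                        "gamma", "classification"])
            for e in self.entries:
                a = e.assessment
                w.writerow(
                    [e.assay, e.ratio_label, f"{a.ic50_add:.2f}",
                     f"{_round_sig(a.ic50_mix_axis):g}", f"{a.gamma:.2f}",
                     a.classification]
                )


def run_synergy_pipeline(
    series: Sequence[DoseResponseSeries],
    single_ic50s: Mapping[str, Mapping[str, float | IC50Estimate]],
    ci_method: CIMethod = "fieller",
    ci_level: float = 0.95,
    abts_convention: str = "as_printed",
    gamma_tol: float = 0.05,
    expected_ic50_add: Mapping[tuple[str, str], float] | None = None,
) -> SynergyReport:
    """Run fits + Loewe analysis for every mixture series.

    ``single_ic50s`` maps assay -> {"A": ..., "B": ...} (plain floats or
    :class:`IC50Estimate`; with estimates carrying finite CIs, the
    isobole-envelope classifier is used, otherwise the gamma fallback).
    ``expected_ic50_add`` optionally supplies externally reported
    additive IC50s; a flag is recorded whenever recomputation disagrees
    by more than 1%.
    """
    if not series:
        raise ConfigurationError("no dose-response series supplied")
    entries = []
    for s in series:
        if s.ratio is None:
            raise ConfigurationError(f"series {s.label!r} has no mixture ratio")
        try:
            singles = single_ic50s[s.assay]
            raw_a, raw_b = singles["A"], singles["B"]
        except KeyError as exc:
            raise ConfigurationError(
                f"missing single-compound IC50 for assay {s.assay!r}: {exc}"
            ) from exc
        est_a = raw_a if isinstance(raw_a, IC50Estimate) else IC50Estimate(value=float(raw_a))
        est_b = raw_b if isinstance(raw_b, IC50Estimate) else IC50Estimate(value=float(raw_b))

        fit = fit_line(s)
        x = s.x
        mix = estimate_ic50(fit, x_range=(float(x.min()), float(x.max())),
                            level=ci_level, method=ci_method)
        envelope: IsoboleEnvelope | None = None
        if all(math.isfinite(v) for v in (est_a.ci_low, est_a.ci_high,
                                          est_b.ci_low, est_b.ci_high)):
            envelope = isobole_envelope(est_a, est_b)
        assessment = assess_synergy(
            mix.value, s.ratio, est_a.value, est_b.value,
            envelope=envelope, gamma_tol=gamma_tol,
        )
        flag = None
        if expected_ic50_add:
            expected = expected_ic50_add.get((s.assay, s.ratio.label()))
            if expected is not None and abs(assessment.ic50_add - expected) > 0.01 * expected:
                flag = (
                    f"recomputed additive IC50 {assessment.ic50_add:.2f} disagrees with "
                    f"supplied expectation {expected:.2f} (>1%)"
                )
        entries.append(
            SynergyEntry(
                assay=s.assay,
                ratio_label=s.ratio.label(),
                fit_slope=fit.slope,
                fit_intercept=fit.intercept,
                r_squared=fit.r_squared,
                ic50_mix=mix,
                assessment=assessment,
                ic50_add_flag=flag,
            )
        )
    entries.sort(key=lambda e: (e.assay, e.ratio_label))
    return SynergyReport(
        entries=tuple(entries),
        ci_method=ci_method,
        ci_level=ci_level,
        abts_convention=abts_convention,
    )
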