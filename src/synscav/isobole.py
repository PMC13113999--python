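"""Loewe-additivity (isobolographic) analysis of two-compound mixtures.

For two antioxidants A and B with single-agent half-maximal scavenging
concentrations IC50_A and IC50_B, Loewe additivity predicts that any
dose pair (d_A, d_B) achieving 50% scavenging satisfies

    d_A / IC50_A + d_B / IC50_B = 1,

a straight line (the additive isobole) between (IC50_A, 0) and
(0, IC50_B).  For a fixed-ratio mixture with mass fractions
(k_A, k_B), the additive prediction on the total-concentration scale is

    IC50_add = IC50_A / (k_A + R * k_B),    R = IC50_A / IC50_B,

and the observed mixture is summarized by the interaction index

    gamma = d_A / IC50_A + d_B / IC50_B
          = k_A * IC50_mix / IC50_A + k_B * IC50_mix / IC50_B,

where IC50_mix is the total mixture concentration at 50% scavenging and
(d_A, d_B) = (k_A, k_B) * IC50_mix.  gamma < 1 indicates synergy,
gamma ~ 1 additivity, gamma > 1 antagonism.  When confidence intervals
on the single-agent IC50s are available, classification instead uses the
95% envelope around the additive line (a point below the lower-bound
isobole is synergistic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal

import numpy as np

from .errors import EnvelopeUndefinedError, RatioError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .dose_response import IC50Estimate

_SUM_TOL = 1e-12

Classification = Literal["synergistic", "additive", "antagonistic"]


@dataclass(frozen=True)
class MixtureRatio:
    """Fixed-ratio binary mixture composition by mass fraction.

    ``axis_component`` names the lower-proportion component, the one
    whose concentration the mixture dose-response is plotted against
    (ties resolve to A).
    """

    k_a: float
    k_b: float

    def __post_init__(self) -> None:
        if not (0.0 < self.k_a < 1.0 and 0.0 < self.k_b < 1.0):
            raise RatioError(
                f"mass fractions must be interior to (0, 1); got k_a={self.k_a}, k_b={self.k_b}"
            )
        if abs(self.k_a + self.k_b - 1.0) > _SUM_TOL:
            raise RatioError(
                f"mass fractions must sum to 1 (got {self.k_a + self.k_b!r})"
            )

    @property
    def axis_component(self) -> Literal["A", "B"]:
        return "A" if self.k_a <= self.k_b else "B"

    @property
    def axis_fraction(self) -> float:
        """Mass fraction of the axis (lower-proportion) component."""
        return self.k_a if self.axis_component == "A" else self.k_b

    @classmethod
    def from_string(cls, text: str) -> "MixtureRatio":
        """Parse ``"1:2"``-style A:B mass ratios."""
        parts = text.strip().split(":")
        if len(parts) != 2:
            raise RatioError(f"ratio must look like 'a:b', got {text!r}")
        try:
            a, b = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise RatioError(f"non-numeric ratio {text!r}") from exc
        if a <= 0 or b <= 0:
            raise RatioError(f"ratio parts must be positive, got {text!r}")
        return cls(k_a=a / (a + b), k_b=b / (a + b))

    def label(self) -> str:
        """Canonical ``a:b`` label with minimal integer parts when exact."""
        for denom in range(1, 100):
            a = self.k_a * denom
            if abs(a - round(a)) < 1e-9 and round(a) >= 1 and denom - round(a) >= 1:
                return f"{round(a)}:{denom - round(a)}"
        return f"{self.k_a:.6g}:{self.k_b:.6g}"

    def swapped(self) -> "MixtureRatio":
        return MixtureRatio(k_a=self.k_b, k_b=self.k_a)


def potency_ratio(ic50_a: float, ic50_b: float) -> float:
    """Relative potency R = IC50_A / IC50_B placing B on A's dose scale."""
    if ic50_a <= 0 or ic50_b <= 0:
        raise ValidationError("single-agent IC50s must be positive")
    return ic50_a / ic50_b


def additive_ic50(ic50_a: float, ic50_b: float, ratio: MixtureRatio) -> float:
    """Loewe-additive IC50 of the mixture on the total-concentration scale.

    IC50_add = IC50_A / (k_A + R * k_B) with R = IC50_A / IC50_B; a
    dose-weighted harmonic-type mean, always between the two single-agent
    values for interior ratios.
    """
    r = potency_ratio(ic50_a, ic50_b)
    return ic50_a / (ratio.k_a + r * ratio.k_b)


def component_doses(ic50_mix_total: float, ratio: MixtureRatio) -> tuple[float, float]:
    """Per-component doses (d_A, d_B) delivered at the mixture's IC50."""
    if ic50_mix_total <= 0:
        raise ValidationError("mixture IC50 must be positive")
    return ratio.k_a * ic50_mix_total, ratio.k_b * ic50_mix_total


def interaction_index(
    ic50_mix_total: float, ratio: MixtureRatio, ic50_a: float, ic50_b: float
) -> float:
    """Interaction index gamma; < 1 synergy, ~ 1 additive, > 1 antagonism."""
    if ic50_a <= 0 or ic50_b <= 0:
        raise ValidationError("single-agent IC50s must be positive")
    dose_a, dose_b = component_doses(ic50_mix_total, ratio)
    return dose_a / ic50_a + dose_b / ic50_b


@dataclass(frozen=True)
class IsoboleEnvelope:
    """Additive isobole with its 95%-CI envelope in the (d_A, d_B) plane.

    The central line connects (IC50_A, 0) and (0, IC50_B); the lower and
    upper envelope lines connect the corresponding CI-bound intercepts
    (endpoint-connected bands).
    """

    ic50_a: float
    ic50_b: float
    ci_low_a: float
    ci_low_b: float
    ci_high_a: float
    ci_high_b: float
    coordinates: np.ndarray = field(repr=False)  # (n, 3): d_a, d_b, line code
    line_names: tuple[str, ...] = ("lower", "central", "upper")

    def sum_on_line(self, dose_a: float, dose_b: float, line: str = "central") -> float:
        """Normalized dose sum of a point relative to one envelope line."""
        a, b = {
            "central": (self.ic50_a, self.ic50_b),
            "lower": (self.ci_low_a, self.ci_low_b),
            "upper": (self.ci_high_a, self.ci_high_b),
        }[line]
        return dose_a / a + dose_b / b


def isobole_envelope(
    ic50_a: "IC50Estimate", ic50_b: "IC50Estimate", n_points: int = 50
) -> IsoboleEnvelope:
    """Build the additive isobole and its endpoint-connected CI envelope."""
    bounds = (ic50_a.ci_low, ic50_a.ci_high, ic50_b.ci_low, ic50_b.ci_high)
    if any(not math.isfinite(v) for v in bounds):
        raise EnvelopeUndefinedError(
            "infinite IC50 confidence bound; classify via the interaction index instead"
        )
    rows = []
    t = np.linspace(0.0, 1.0, n_points)
    for code, (a, b) in enumerate(
        [
            (ic50_a.ci_low, ic50_b.ci_low),
            (ic50_a.value, ic50_b.value),
            (ic50_a.ci_high, ic50_b.ci_high),
        ]
    ):
        rows.append(np.column_stack([a * (1 - t), b * t, np.full_like(t, code)]))
    return IsoboleEnvelope(
        ic50_a=ic50_a.value,
        ic50_b=ic50_b.value,
        ci_low_a=ic50_a.ci_low,
        ci_low_b=ic50_b.ci_low,
        ci_high_a=ic50_a.ci_high,
        ci_high_b=ic50_b.ci_high,
        coordinates=np.vstack(rows),
    )


def classify_interaction(
    doses: tuple[float, float], envelope: IsoboleEnvelope
) -> Classification:
    """Place the mixture's IC50 point relative to the CI envelope.

    The point lies below the lower-bound isobole iff
    d_A/ciLow_A + d_B/ciLow_B < 1 (synergistic), above the upper-bound
    isobole iff d_A/ciHigh_A + d_B/ciHigh_B > 1 (antagonistic), and is
    additive otherwise.
    """
    dose_a, dose_b = doses
    if dose_a <= 0 or dose_b <= 0:
        raise ValidationError("component doses must be positive")
    if envelope.sum_on_line(dose_a, dose_b, "lower") < 1.0:
        return "synergistic"
    if envelope.sum_on_line(dose_a, dose_b, "upper") > 1.0:
        return "antagonistic"
    return "additive"


def classify_by_gamma(gamma: float, tol: float = 0.05) -> Classification:
    """Fallback classifier when no CI envelope is available.

    ``tol`` guards against declaring synergy from rounding noise.
    """
    if gamma < 1.0 - tol:
        return "synergistic"
    if gamma > 1.0 + tol:
        return "antagonistic"
    return "additive"


@dataclass(frozen=True)
class SynergyAssessment:
    """Full Loewe analysis of one mixture ratio in one assay.

    ``ic50_mix_axis`` is the IC50 on the fitted axis (concentration of
    the lower-proportion component); ``ic50_mix_total`` is the same
    quantity read as total mixture concentration, the scale on which
    gamma and the per-component doses are defined.
    """

    ratio: MixtureRatio
    potency_ratio_r: float
    ic50_add: float
    ic50_mix_axis: float
    ic50_mix_total: float
    dose_a_at_mix: float
    dose_b_at_mix: float
    gamma: float
    classification: Classification

    def __post_init__(self) -> None:
        ident = self.dose_a_at_mix + self.dose_b_at_mix
        if abs(ident - self.ic50_mix_total) > 1e-9 * max(1.0, self.ic50_mix_total):
            raise ValidationError("component doses must sum to the mixture IC50")


def assess_synergy(
    ic50_mix: float,
    ratio: MixtureRatio,
    ic50_a: float,
    ic50_b: float,
    envelope: IsoboleEnvelope | None = None,
    gamma_tol: float = 0.05,
) -> SynergyAssessment:
    """Assemble the complete synergy assessment for one mixture.

    ``ic50_mix`` is the mixture IC50 interpreted as total mixture
    concentration (numerically identical to the axis-scale fit result;
    the two interpretations are both reported).
    """
    dose_a, dose_b = component_doses(ic50_mix, ratio)
    gamma = interaction_index(ic50_mix, ratio, ic50_a, ic50_b)
    if envelope is not None:
        classification = classify_interaction((dose_a, dose_b), envelope)
    else:
        classification = classify_by_gamma(gamma, tol=gamma_tol)
    return SynergyAssessment(
        ratio=ratio,
        potency_ratio_r=potency_ratio(ic50_a, ic50_b),
        ic50_add=additive_ic50(ic50_a, ic50_b, ratio),
        ic50_mix_axis=ic50_mix,
        ic50_mix_total=ic50_mix,
        dose_a_at_mix=dose_a,
        dose_b_at_mix=dose_b,
        gamma=gamma,
        classification=classification,
    )
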