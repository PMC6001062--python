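"""Predictive-genomics calculations: PPV, sensitivity and specificity.

Treats a qualifying rare genotype in a disease gene as a screening test.
With A = "develops the disease" and B = "carries a qualifying variant in the
gene", Bayes' theorem gives the positive predictive value

    PPV = P(A|B) = P(B|A) * P(A) / P(B)

where P(B|A) is the fraction of affected individuals explained by the gene
(the test's sensitivity), P(A) the disease incidence, and P(B) the population
carrier fraction queried from a burden table.  Specificity is 1 - P(B).
Incidences are handled as exact rationals ("1:21500") so precision is not
lost at the 1e-5 scales typical of rare disorders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "PredictiveInputs",
    "parse_incidence",
    "ppv",
    "sensitivity_specificity",
    "f_upper_bound",
]


def parse_incidence(value: str | float | Fraction) -> Fraction:
    """Parse an incidence given as '1:21500', '1/21500', a float or Fraction."""
    if isinstance(value, Fraction):
        return value
    if isinstance(value, str):
        for sep in (":", "/"):
            if sep in value:
                num, den = value.split(sep)
                return Fraction(int(num), int(den))
        return Fraction(value)
    return Fraction(value).limit_denominator(10**12)


@dataclass(frozen=True)
class PredictiveInputs:
    """Inputs to the Bayesian screening calculation.

    sensitivity = P(B|A), incidence = P(A), carrier_fraction = P(B).
    Coherence requires P(B) >= P(B|A) * P(A) (carriers among the affected are
    also carriers in the population); violations warn rather than error since
    the three quantities typically come from heterogeneous sources.
    """

    sensitivity: float
    incidence: Fraction
    carrier_fraction: Fraction

    def __post_init__(self) -> None:
        for name in ("sensitivity", "incidence", "carrier_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.carrier_fraction < Fraction(self.sensitivity) * self.incidence:
            warnings.warn(
                "incoherent inputs: carrier_fraction < sensitivity * incidence; "
                "the implied PPV exceeds 1",
                stacklevel=2,
            )


def ppv(inputs: PredictiveInputs) -> float:
    """Positive predictive value P(A|B) = P(B|A) * P(A) / P(B), clamped to 1."""
    if inputs.carrier_fraction == 0:
        raise ValueError(
            "carrier_fraction is 0: no PPV is defined; use f_upper_bound to "
            "bound f from a larger reference cohort"
        )
    value = float(
        Fraction(inputs.sensitivity).limit_denominator(10**12)
        * inputs.incidence
        / inputs.carrier_fraction
    )
    if value > 1:
        warnings.warn(f"PPV {value:.3g} exceeds 1; clamping", stacklevel=2)
        return 1.0
    return value


def sensitivity_specificity(inputs: PredictiveInputs) -> tuple[float, float]:
    """(sensitivity P(B|A), specificity 1 - P(B)) of the genotype as a test."""
    return inputs.sensitivity, float(1 - inputs.carrier_fraction)


def f_upper_bound(
    observed_count: int, reference_size: int, conservative: bool = False
) -> Fraction:
    """Bound on the carrier fraction when a reference cohort shows no carriers.

    With zero carriers among ``reference_size`` individuals, f is below
    1/reference_size; the conservative variant returns 3/reference_size (the
    usual rule-of-three upper confidence bound).
    """
    if observed_count > 0:
        raise ValueError(
            "carriers were observed; use the exact fraction from the table "
            "instead of an upper bound"
        )
    if observed_count < 0 or reference_size <= 0:
        raise ValueError("need observed_count = 0 and reference_size > 0")
    return Fraction(3 if conservative else 1, reference_size)
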