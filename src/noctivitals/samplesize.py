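"""Diagnostic-accuracy sample-size estimation.

The design question: how many cases and controls are needed so that the
two-sided normal-approximation confidence interval for the expected
sensitivity (cases) and specificity (controls) has a stated half-width?
For a proportion p and absolute half-width d at two-sided level alpha,

    n = ceil( z_{1-alpha/2}^2 * p (1 - p) / d^2 ),

with d expressed as a fraction of p (relative tolerance). The group whose
precision demand is larger (under a 1:2 case:control allocation, the
specificity side) fixes the size of the larger group; the other group follows
from the allocation ratio. Totals are reported both before and after dropout
inflation; the headline total excludes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import scipy.stats as st

__all__ = ["SampleSizeSpec", "SampleSizeResult", "required_sizes"]


@dataclass(frozen=True)
class SampleSizeSpec:
    """Precision design for a sensitivity/specificity study.

    ``tolerance_fraction`` is the CI half-width as a fraction of the
    proportion it bounds; ``case_control_ratio`` is cases per control.
    """

    sensitivity: float = 0.90
    specificity: float = 0.90
    alpha: float = 0.01
    tolerance_fraction: float = 0.10
    case_control_ratio: float = 0.5  # 1:2
    dropout: float = 0.10

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly in (0, 1)")
        if self.tolerance_fraction <= 0:
            raise ValueError("tolerance_fraction must be positive")
        if self.case_control_ratio <= 0:
            raise ValueError("case_control_ratio must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    n_cases: int
    n_controls: int
    n_total: int
    n_cases_inflated: int
    n_controls_inflated: int
    n_total_inflated: int
    driver: str  # which precision demand fixed the allocation


def _n_for_proportion(p: float, d: float, z: float) -> int:
    return math.ceil(z * z * p * (1.0 - p) / (d * d))


def required_sizes(spec: SampleSizeSpec) -> SampleSizeResult:
    """Group sizes meeting the precision design of ``spec``.

    The larger of the sensitivity-side and specificity-side demands is
    assigned to the group it measures; the other group follows from the
    allocation ratio, rounded up.
    """
    z = st.norm.ppf(1.0 - spec.alpha / 2.0)
    n_se = _n_for_proportion(
        spec.sensitivity, spec.tolerance_fraction * spec.sensitivity, z
    )
    n_sp = _n_for_proportion(
        spec.specificity, spec.tolerance_fraction * spec.specificity, z
    )
    if n_sp >= n_se:
        driver = "specificity"
        n_controls = n_sp
        n_cases = math.ceil(n_controls * spec.case_control_ratio)
    else:
        driver = "sensitivity"
        n_cases = n_se
        n_controls = math.ceil(n_cases / spec.case_control_ratio)

    inflate = lambda n: math.ceil(n / (1.0 - spec.dropout))
    return SampleSizeResult(
        n_cases=n_cases,
        n_controls=n_controls,
        n_total=n_cases + n_controls,
        n_cases_inflated=inflate(n_cases),
        n_controls_inflated=inflate(n_controls),
        n_total_inflated=inflate(n_cases) + inflate(n_controls),
        driver=driver,
    )
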