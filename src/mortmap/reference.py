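"""Published reference estimates from a national state-level analysis.

These posterior means and printed relative risks come from a published
Bayesian spatio-temporal analysis of state-level maternal mortality ratios
(19 major states, five three-year periods).  They are input data: the
package uses them as realistic magnitudes for simulation defaults and to
round-trip the relative-risk transform RR = exp(posterior mean).

The ``anc`` row is internally inconsistent in its source table (its printed
RR equals exp(-0.5), not exp of its printed mean of -0.050) and is flagged
``consistent=False``; it must not be used as a check value.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceEstimate", "REFERENCE_ESTIMATES", "REFERENCE_DIC",
           "REFERENCE_INTERCEPT", "REFERENCE_TREND"]


@dataclass(frozen=True)
class ReferenceEstimate:
    name: str
    posterior_mean: float
    printed_rr: float
    consistent: bool


REFERENCE_ESTIMATES = [
    # maternal-health covariates
    ReferenceEstimate("birth_order_gt3", 0.4048, 1.49900267, True),
    ReferenceEstimate("low_birth_interval", 0.4939, 1.638695, True),
    ReferenceEstimate("c_section", -0.125, 0.8824969, True),
    ReferenceEstimate("contraception", -0.116, 0.8904752, True),
    ReferenceEstimate("anemia", 0.0594, 1.0612, True),
    ReferenceEstimate("low_bmi", 0.2912, 1.338032, True),
    # health-system covariates
    ReferenceEstimate("population", 0.1655, 1.179982963, True),
    ReferenceEstimate("anc", -0.050, 0.60653066, False),
    ReferenceEstimate("pnc", -0.036, 0.964640293, True),
    ReferenceEstimate("institutional_delivery", -0.720, 0.486752, True),
    ReferenceEstimate("health_index", -0.486, 0.615082, True),
    ReferenceEstimate("accreditation", -0.041, 0.959829, True),
    ReferenceEstimate("nqas", -0.198, 0.82037, True),
    ReferenceEstimate("ghe", -0.083, 0.920351, True),
    ReferenceEstimate("oope", 0.2601, 1.29706, True),
    ReferenceEstimate("jsy", 0.3266, 1.386247, True),
    ReferenceEstimate("skilled_attendance", -0.968, 0.379842, True),
]

# Deviance information criteria of the three published model variants.
REFERENCE_DIC = {1: 1858.0, 2: 1819.0, 3: 1781.0}

# Baseline-model intercept and the overall linear time trend (per period)
# with its 95% credible interval.
REFERENCE_INTERCEPT = 2.345
REFERENCE_TREND = (-0.121, -0.142, -0.10)
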