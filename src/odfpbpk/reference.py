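"""Reference study endpoints used for validation.

Observed values are the mean supralingual endpoints from the four-dog
crossover study (1 mg dose); predicted values are the original simulation
study's reported predictions for the same arm. They serve as validation
anchors for the fold-error criterion and as regression references in
tests — they are inputs to this package, not outputs of it.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ReportedEndpoint",
    "TABLE3_SUPRALINGUAL",
    "REGIONAL_ORAL_FRACTIONS",
    "REPORTED_SENSITIVITY_FACTORS",
]


@dataclass(frozen=True)
class ReportedEndpoint:
    observed: float
    predicted: float
    unit: str


#: Supralingual validation endpoints: observed vs originally predicted.
TABLE3_SUPRALINGUAL: dict[str, ReportedEndpoint] = {
    "tmax": ReportedEndpoint(observed=0.62, predicted=0.53, unit="h"),
    "cmax": ReportedEndpoint(observed=59.38, predicted=38.43, unit="ug/L"),
    "auc_inf": ReportedEndpoint(observed=101.87, predicted=91.56, unit="ug*h/L"),
}

#: Reported oral-mucosal absorbed fraction vs residence time (min -> fraction).
REGIONAL_ORAL_FRACTIONS: dict[float, float] = {2.0: 0.070, 5.0: 0.114, 10.0: 0.195}

#: Reported residence-time sensitivity factors per exposure metric.
REPORTED_SENSITIVITY_FACTORS: dict[str, float] = {
    "tmax": 0.26, "cmax": 0.10, "auc_inf": 0.11, "bioavailability": 0.11,
}
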