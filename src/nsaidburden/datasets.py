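"""Published England reference inputs.

Indicator prevalence counts come from the national prescribing-safety
audit of English general practices (1060 practices reporting at two or
more time points, 10,906,453 registered patients, baseline April 2020);
the registered population of England is the GP-registration count on
1 December 2023.  The per-person and national summary estimates are the
published study results for these five indicators and are used as worked
inputs for the incremental and aggregation arithmetic — they are not
outputs of this package's synthetic parameter sets.
"""

from __future__ import annotations

import pandas as pd

from .burden import PopulationSpec, PrevalenceRecord

#: Registered patients in the audited practice sample.
SAMPLE_DENOMINATOR = 10_906_453

#: Patients registered with an English GP practice on 1 December 2023.
ENGLAND_REGISTERED = 63_049_603

_PREVALENCE_COUNTS = {
    "older_no_gpa": (1_355_707, 18_591),
    "peptic_ulcer_no_gpa": (83_104, 1_188),
    "oral_anticoagulant": (245_778, 4_005),
    "heart_failure": (87_804, 1_544),
    "chronic_kidney_disease": (136_749, 2_733),
}

#: Published per-person discounted means over 10 years (GBP; QALYs):
#: (cost HPE arm, cost comparator arm, QALYs HPE arm, QALYs comparator arm).
PER_PERSON_MEANS = {
    "older_no_gpa": (258.0, 234.0, 5.836, 5.853),
    "peptic_ulcer_no_gpa": (277.0, 253.0, 6.700, 6.715),
    "oral_anticoagulant": (2526.0, 1429.0, 4.812, 4.904),
    "heart_failure": (12_607.0, 12_594.0, 2.998, 3.045),
    "chronic_kidney_disease": (50_215.0, 50_008.0, 4.523, 4.634),
}

#: Published national base-case components over 10 years:
#: QALY loss (positive = loss) and cost in GBP millions.
NATIONAL_COMPONENTS = {
    "older_no_gpa": (1929.0, 2.46),
    "peptic_ulcer_no_gpa": (114.0, 0.16),
    "oral_anticoagulant": (2143.0, 25.41),
    "heart_failure": (411.0, 0.13),
    "chronic_kidney_disease": (1738.0, 3.27),
}


def england_prevalence() -> dict[str, PrevalenceRecord]:
    """Indicator prevalence records from the audited practice sample."""
    return {
        indication: PrevalenceRecord(
            indication=indication,
            n_at_risk=at_risk,
            n_affected=affected,
            denominator=SAMPLE_DENOMINATOR,
        )
        for indication, (at_risk, affected) in _PREVALENCE_COUNTS.items()
    }


def england_population() -> PopulationSpec:
    """The England GP-registered population the prevalence scales up to."""
    return PopulationSpec(n_registered=ENGLAND_REGISTERED, reference_date="2023-12-01")


def per_person_means_frame() -> pd.DataFrame:
    """Published per-person arm means as a tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "indication": k,
                "cost_hpe": ch,
                "cost_comparator": cc,
                "qalys_hpe": qh,
                "qalys_comparator": qc,
            }
            for k, (ch, cc, qh, qc) in PER_PERSON_MEANS.items()
        ]
    )
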