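"""Controlled vocabularies shared by the generator and the ingest defaults.

MedDRA itself is licensed and not bundled; the preferred terms (PTs) and
system-organ-class (SOC) labels below are a small synthetic vocabulary used
by the report generator and by the default PT->SOC map it emits.  Real
analyses supply their own PT->SOC table.
"""

from __future__ import annotations

TARGET_DRUG = "INFLIXIMAB"

# Default synonym list for the target drug (generic + trade name).
DEFAULT_SYNONYMS = ("INFLIXIMAB", "REMICADE")

# Default indication PT list for the cohort definition.
DEFAULT_INDICATIONS = (
    "Crohn's disease",
    "Ulcerative colitis",
    "Inflammatory bowel disease",
)

# Background primary-suspect drugs: small, synonym-free vocabulary.
BACKGROUND_DRUGS = (
    "IBUPROFEN",
    "METFORMIN",
    "ATORVASTATIN",
    "OMEPRAZOLE",
    "LISINOPRIL",
    "AMOXICILLIN",
    "SERTRALINE",
    "SALBUTAMOL",
)

# Concomitant medications commonly co-reported with the target drug.
CONCOMITANT_DRUGS = (
    "PREDNISONE",
    "AZATHIOPRINE",
    "METHOTREXATE",
    "MESALAMINE",
    "HUMIRA",
)

# Non-target indications assigned to background reports.
BACKGROUND_INDICATIONS = (
    "Rheumatoid arthritis",
    "Hypertension",
    "Type 2 diabetes mellitus",
    "Depression",
    "Asthma",
)

# PT -> SOC map for the synthetic vocabulary.
PT_SOC = {
    "Headache": "Nervous system disorders",
    "Nausea": "Gastrointestinal disorders",
    "Pyrexia": "General disorders and administration site conditions",
    "Fatigue": "General disorders and administration site conditions",
    "Drug ineffective": "General disorders and administration site conditions",
    "Rash": "Skin and subcutaneous tissue disorders",
    "Arthralgia": "Musculoskeletal and connective tissue disorders",
    "Lupus-like syndrome": "Musculoskeletal and connective tissue disorders",
    "Blood pressure fluctuation": "Vascular disorders",
    "Flushing": "Vascular disorders",
    "Pulmonary tuberculosis": "Infections and infestations",
    "Pneumonia": "Infections and infestations",
    "Serum sickness": "Immune system disorders",
    "Bradycardia": "Cardiac disorders",
    "Infusion related reaction": "Injury, poisoning and procedural complications",
    "Dyspnoea": "Respiratory, thoracic and mediastinal disorders",
}

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

OCCUPATION_CODES = ("MD", "PH", "CN", "OT", "HP", "RN", "LW")

COUNTRIES = ("CA", "US", "BR", "FR", "JP", "GB", "DE", "AU")


def normalize_name(name: str) -> str:
    """Trim, collapse internal whitespace, and uppercase a drug name."""
    return " ".join(str(name).split()).upper()
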