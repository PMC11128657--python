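"""MedDRA hierarchy lookup (PT -> HLT -> HLGT -> SOC) and SMQ membership.

MedDRA codes every reaction as a Preferred Term (PT); PTs roll up through
High-Level Terms and High-Level Group Terms to System Organ Classes (SOC).
A PT can be multiaxial (linked to several SOCs) but has exactly one primary
SOC, which is what aggregate tabulations use. Standardised MedDRA Queries
(SMQs) are curated PT sets for a clinical topic (e.g. skin malignancies).

MedDRA itself is licensed and cannot be redistributed, so this module
accepts user-supplied TSV tables and ships a small synthetic hierarchy
(invented HLT/HLGT labels, real SOC names) sufficient for testing and for
synthetic corpora.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

logger = logging.getLogger("faerspv")

UNMAPPED = "UNMAPPED"

HIERARCHY_COLUMNS = ("pt", "hlt", "hlgt", "soc", "primary_soc_flag")
SMQ_COLUMNS = ("smq", "pt", "scope")


def _norm(term: str) -> str:
    return " ".join(str(term).split()).casefold()


@dataclass
class HierarchyTable:
    """PT-level hierarchy rows; lookup by case-normalized exact PT text."""

    rows: pd.DataFrame

    def __post_init__(self):
        df = self.rows.copy()
        missing = [c for c in HIERARCHY_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"hierarchy table missing columns: {missing}")
        if "primary_soc_flag" not in df.columns:
            df["primary_soc_flag"] = "Y"
        df["_key"] = df["pt"].map(_norm)
        self.rows = df
        primary: dict[str, str] = {}
        any_soc: dict[str, str] = {}
        for pt, soc, flag, key in zip(df["pt"], df["soc"], df["primary_soc_flag"], df["_key"]):
            any_soc.setdefault(key, soc)
            if str(flag).upper().startswith("Y"):
                if key in primary and primary[key] != soc:
                    raise ValueError(f"PT {pt!r} has more than one primary SOC")
                primary[key] = soc
        self._primary = primary
        self._any = any_soc

    @classmethod
    def from_tsv(cls, path) -> "HierarchyTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))

    def socs(self) -> list[str]:
        return sorted(set(self.rows["soc"]))

    def pts(self) -> list[str]:
        return sorted(set(self.rows["pt"]))


def pt_to_soc(pt: str, hierarchy: HierarchyTable) -> str:
    """Primary SOC of a PT; ``UNMAPPED`` (with a warning) if unknown.

    A multiaxial PT resolves to the SOC carrying its primary flag; if no
    row is flagged primary, the first listed SOC is used.
    """
    key = _norm(pt)
    soc = hierarchy._primary.get(key) or hierarchy._any.get(key)
    if soc is None:
        logger.warning("PT %r not in hierarchy; mapping to %s", pt, UNMAPPED)
        return UNMAPPED
    return soc


def case_socs(reactions: Iterable[str], hierarchy: HierarchyTable) -> set[str]:
    """Distinct primary SOCs touched by a report's PT list."""
    return {pt_to_soc(pt, hierarchy) for pt in reactions}


@dataclass(frozen=True)
class SMQDefinition:
    """One Standardised MedDRA Query: a named PT set with a scope."""

    smq_name: str
    member_pts: frozenset[str]
    scope: str = "narrow"

    def __post_init__(self):
        if not self.member_pts:
            raise ValueError("SMQ must have at least one member PT")
        object.__setattr__(self, "_keys", frozenset(_norm(p) for p in self.member_pts))


def load_smqs(path) -> dict[str, SMQDefinition]:
    """Read SMQ membership from a TSV with columns (smq, pt, scope)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SMQ_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"SMQ table missing columns: {missing}")
    out: dict[str, SMQDefinition] = {}
    for name, grp in df.groupby("smq"):
        scope = grp["scope"].iloc[0] if "scope" in grp.columns and len(grp) else "narrow"
        out[name] = SMQDefinition(name, frozenset(grp["pt"]), scope or "narrow")
    return out


def smq_members(smq: SMQDefinition, caseset) -> dict[str, int]:
    """Unique-report counts per member PT within the SMQ (zeros omitted)."""
    counts: dict[str, int] = {}
    for case in caseset.cases:
        seen = {_norm(pt) for pt in case.reactions}
        for pt in smq.member_pts:
            if _norm(pt) in seen:
                counts[pt] = counts.get(pt, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Built-in synthetic hierarchy
# ---------------------------------------------------------------------------

# Synthetic stand-in for the licensed MedDRA tables: real PT and SOC names
# (the SOCs of a haematology-drug safety profile), invented HLT/HLGT labels.
_BUILTIN_HIERARCHY_TSV = """\
pt	hlt	hlgt	soc	primary_soc_flag
Pyrexia	HLT-FEBRILE	HLGT-GENERAL	General disorders and administration site conditions	Y
Fatigue	HLT-ASTHENIC	HLGT-GENERAL	General disorders and administration site conditions	Y
Infusion site reaction	HLT-INFUSION	HLGT-GENERAL	General disorders and administration site conditions	Y
Infusion site phlebitis	HLT-INFUSION	HLGT-GENERAL	General disorders and administration site conditions	Y
Injection site vasculitis	HLT-INFUSION	HLGT-GENERAL	General disorders and administration site conditions	Y
General physical health deterioration	HLT-ASTHENIC	HLGT-GENERAL	General disorders and administration site conditions	Y
Chills	HLT-FEBRILE	HLGT-GENERAL	General disorders and administration site conditions	Y
Neutropenia	HLT-CYTOPENIA	HLGT-HAEM	Blood and lymphatic system disorders	Y
Febrile neutropenia	HLT-CYTOPENIA	HLGT-HAEM	Blood and lymphatic system disorders	Y
Thrombocytopenia	HLT-CYTOPENIA	HLGT-HAEM	Blood and lymphatic system disorders	Y
Anaemia	HLT-CYTOPENIA	HLGT-HAEM	Blood and lymphatic system disorders	Y
Pancytopenia	HLT-CYTOPENIA	HLGT-HAEM	Blood and lymphatic system disorders	Y
Autoimmune haemolytic anaemia	HLT-HAEMOLYSIS	HLGT-HAEM	Blood and lymphatic system disorders	Y
Aplasia pure red cell	HLT-CYTOPENIA	HLGT-HAEM	Blood and lymphatic system disorders	Y
Hypogammaglobulinaemia	HLT-IMMUNOGLOBULIN	HLGT-IMMUNE	Immune system disorders	Y
Anaphylactic reaction	HLT-ALLERGIC	HLGT-IMMUNE	Immune system disorders	Y
Cytokine release syndrome	HLT-ALLERGIC	HLGT-IMMUNE	Immune system disorders	Y
Haemophagocytic lymphohistiocytosis	HLT-ALLERGIC	HLGT-IMMUNE	Immune system disorders	Y
Pneumonia	HLT-LRTI	HLGT-INFECTION	Infections and infestations	Y
Lung infection	HLT-LRTI	HLGT-INFECTION	Infections and infestations	Y
Sepsis	HLT-SYSTEMIC-INF	HLGT-INFECTION	Infections and infestations	Y
Septic shock	HLT-SYSTEMIC-INF	HLGT-INFECTION	Infections and infestations	Y
Cytomegalovirus infection	HLT-VIRAL	HLGT-INFECTION	Infections and infestations	Y
Cytomegalovirus viraemia	HLT-VIRAL	HLGT-INFECTION	Infections and infestations	Y
Cytomegalovirus chorioretinitis	HLT-VIRAL	HLGT-INFECTION	Infections and infestations	Y
Pneumocystis jirovecii pneumonia	HLT-FUNGAL	HLGT-INFECTION	Infections and infestations	Y
Progressive multifocal leukoencephalopathy	HLT-VIRAL	HLGT-INFECTION	Infections and infestations	Y
Coronavirus pneumonia	HLT-VIRAL	HLGT-INFECTION	Infections and infestations	Y
Infection	HLT-SYSTEMIC-INF	HLGT-INFECTION	Infections and infestations	Y
Neuropathy peripheral	HLT-NEUROPATHY	HLGT-NEURO	Nervous system disorders	Y
Headache	HLT-NEURO-GEN	HLGT-NEURO	Nervous system disorders	Y
Dizziness	HLT-NEURO-GEN	HLGT-NEURO	Nervous system disorders	Y
Nausea	HLT-GI-UPPER	HLGT-GI	Gastrointestinal disorders	Y
Vomiting	HLT-GI-UPPER	HLGT-GI	Gastrointestinal disorders	Y
Constipation	HLT-GI-LOWER	HLGT-GI	Gastrointestinal disorders	Y
Diarrhoea	HLT-GI-LOWER	HLGT-GI	Gastrointestinal disorders	Y
Rash	HLT-SKIN-ERUPTION	HLGT-SKIN	Skin and subcutaneous tissue disorders	Y
Pruritus	HLT-SKIN-ERUPTION	HLGT-SKIN	Skin and subcutaneous tissue disorders	Y
Stevens-Johnson syndrome	HLT-SKIN-SEVERE	HLGT-SKIN	Skin and subcutaneous tissue disorders	Y
Toxic skin eruption	HLT-SKIN-SEVERE	HLGT-SKIN	Skin and subcutaneous tissue disorders	Y
Dermatitis exfoliative generalised	HLT-SKIN-SEVERE	HLGT-SKIN	Skin and subcutaneous tissue disorders	Y
Drug reaction with eosinophilia and systemic symptoms	HLT-SKIN-SEVERE	HLGT-SKIN	Skin and subcutaneous tissue disorders	Y
Erythema multiforme	HLT-SKIN-SEVERE	HLGT-SKIN	Skin and subcutaneous tissue disorders	Y
Acute generalised exanthematous pustulosis	HLT-SKIN-SEVERE	HLGT-SKIN	Skin and subcutaneous tissue disorders	Y
Cutaneous vasculitis	HLT-SKIN-SEVERE	HLGT-SKIN	Skin and subcutaneous tissue disorders	Y
Keratoacanthoma	HLT-SKIN-NEOPLASM	HLGT-SKIN	Skin and subcutaneous tissue disorders	N
Keratoacanthoma	HLT-SKIN-NEOPLASM	HLGT-NEOPLASM	Neoplasms benign, malignant and unspecified (incl cysts and polyps)	Y
Basal cell carcinoma	HLT-SKIN-NEOPLASM	HLGT-NEOPLASM	Neoplasms benign, malignant and unspecified (incl cysts and polyps)	Y
Squamous cell carcinoma of skin	HLT-SKIN-NEOPLASM	HLGT-NEOPLASM	Neoplasms benign, malignant and unspecified (incl cysts and polyps)	Y
Lentigo maligna	HLT-SKIN-NEOPLASM	HLGT-NEOPLASM	Neoplasms benign, malignant and unspecified (incl cysts and polyps)	Y
Neuroendocrine carcinoma of the skin	HLT-SKIN-NEOPLASM	HLGT-NEOPLASM	Neoplasms benign, malignant and unspecified (incl cysts and polyps)	Y
Bowen's disease	HLT-SKIN-NEOPLASM	HLGT-NEOPLASM	Neoplasms benign, malignant and unspecified (incl cysts and polyps)	Y
Malignant neoplasm progression	HLT-PROGRESSION	HLGT-NEOPLASM	Neoplasms benign, malignant and unspecified (incl cysts and polyps)	Y
Disease progression	HLT-PROGRESSION	HLGT-GENERAL	General disorders and administration site conditions	Y
Tumour lysis syndrome	HLT-METAB-TUMOUR	HLGT-METAB	Metabolism and nutrition disorders	Y
Decreased appetite	HLT-METAB-GEN	HLGT-METAB	Metabolism and nutrition disorders	Y
Dehydration	HLT-METAB-GEN	HLGT-METAB	Metabolism and nutrition disorders	Y
Atrial fibrillation	HLT-ARRHYTHMIA	HLGT-CARDIAC	Cardiac disorders	Y
Cardiac failure	HLT-FAILURE	HLGT-CARDIAC	Cardiac disorders	Y
Neutrophil count decreased	HLT-LAB-HAEM	HLGT-INVESTIGATION	Investigations	Y
Platelet count decreased	HLT-LAB-HAEM	HLGT-INVESTIGATION	Investigations	Y
Lymphocyte count decreased	HLT-LAB-HAEM	HLGT-INVESTIGATION	Investigations	Y
White blood cell count decreased	HLT-LAB-HAEM	HLGT-INVESTIGATION	Investigations	Y
CD4 lymphocytes decreased	HLT-LAB-HAEM	HLGT-INVESTIGATION	Investigations	Y
Blood lactate dehydrogenase increased	HLT-LAB-CHEM	HLGT-INVESTIGATION	Investigations	Y
Hepatic function abnormal	HLT-HEPATIC	HLGT-HEPATOBILIARY	Hepatobiliary disorders	Y
Hyperbilirubinaemia	HLT-HEPATIC	HLGT-HEPATOBILIARY	Hepatobiliary disorders	Y
Acute kidney injury	HLT-RENAL	HLGT-RENAL	Renal and urinary disorders	Y
Nephrogenic diabetes insipidus	HLT-RENAL	HLGT-RENAL	Renal and urinary disorders	Y
Dyspnoea	HLT-RESP	HLGT-RESP	Respiratory, thoracic and mediastinal disorders	Y
Cough	HLT-RESP	HLGT-RESP	Respiratory, thoracic and mediastinal disorders	Y
Embolism	HLT-VASC	HLGT-VASC	Vascular disorders	Y
Vasculitis	HLT-VASC	HLGT-VASC	Vascular disorders	Y
Deafness neurosensory	HLT-EAR	HLGT-EAR	Ear and labyrinth disorders	Y
Vertigo	HLT-EAR	HLGT-EAR	Ear and labyrinth disorders	Y
Vision blurred	HLT-EYE	HLGT-EYE	Eye disorders	Y
Anxiety	HLT-PSYCH	HLGT-PSYCH	Psychiatric disorders	Y
Insomnia	HLT-PSYCH	HLGT-PSYCH	Psychiatric disorders	Y
Arthralgia	HLT-MSK	HLGT-MSK	Musculoskeletal and connective tissue disorders	Y
Myalgia	HLT-MSK	HLGT-MSK	Musculoskeletal and connective tissue disorders	Y
"""

_BUILTIN_SMQ_TSV = """\
smq	pt	scope
Malignant tumours of the skin	Basal cell carcinoma	narrow
Malignant tumours of the skin	Lentigo maligna	narrow
Malignant tumours of the skin	Neuroendocrine carcinoma of the skin	narrow
Malignant tumours of the skin	Squamous cell carcinoma of skin	narrow
Cutaneous premalignant diseases	Bowen's disease	narrow
Serious adverse skin reactions	Keratoacanthoma	narrow
Serious adverse skin reactions	Acute generalised exanthematous pustulosis	narrow
Serious adverse skin reactions	Cutaneous vasculitis	narrow
Serious adverse skin reactions	Dermatitis exfoliative generalised	narrow
Serious adverse skin reactions	Drug reaction with eosinophilia and systemic symptoms	narrow
Serious adverse skin reactions	Erythema multiforme	narrow
Serious adverse skin reactions	Stevens-Johnson syndrome	narrow
Serious adverse skin reactions	Toxic skin eruption	narrow
"""


def builtin_hierarchy() -> HierarchyTable:
    """The bundled synthetic PT->SOC hierarchy (not licensed MedDRA data)."""
    return HierarchyTable(
        pd.read_csv(io.StringIO(_BUILTIN_HIERARCHY_TSV), sep="\t", dtype=str,
                    keep_default_na=False)
    )


def builtin_smqs() -> dict[str, SMQDefinition]:
    """Synthetic skin-safety SMQ definitions matching the bundled hierarchy."""
    df = pd.read_csv(io.StringIO(_BUILTIN_SMQ_TSV), sep="\t", dtype=str,
                     keep_default_na=False)
    out: dict[str, SMQDefinition] = {}
    for name, grp in df.groupby("smq"):
        out[name] = SMQDefinition(name, frozenset(grp["pt"]), grp["scope"].iloc[0])
    return out
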