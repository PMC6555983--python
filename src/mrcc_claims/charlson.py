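"""Modified Deyo-Charlson Comorbidity Index (DCCI) from claims codes.

The Deyo adaptation maps ICD-9/ICD-10-CM diagnosis codes to Charlson
categories with fixed weights.  This variant is "modified" in that the
malignancy and metastatic-solid-tumour categories are removed — every
patient in an mRCC cohort would score them, so only non-cancer burden is
counted.  Code lists are abbreviated prefix sets suitable for synthetic
claims; swap in a full mapping for real data via ``categories=``.

Standard hierarchy rules apply: complicated diabetes supersedes
uncomplicated, and moderate/severe liver disease supersedes mild.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .claims_model import CodeSet


@dataclass(frozen=True)
class CharlsonCategory:
    name: str
    weight: int
    code_set: CodeSet
    superseded_by: str | None = None


def _cat(name: str, weight: int, prefixes: Sequence[str], superseded_by: str | None = None):
    return CharlsonCategory(name, weight, CodeSet(f"dcci:{name}", tuple(prefixes)), superseded_by)


#: Non-cancer Deyo-Charlson categories (abbreviated prefix lists).
DEFAULT_CATEGORIES: tuple[CharlsonCategory, ...] = (
    _cat("myocardial_infarction", 1, ["410", "412", "I21", "I22", "I252"]),
    _cat("congestive_heart_failure", 1, ["428", "I50"]),
    _cat("peripheral_vascular", 1, ["441", "4439", "I70", "I71"]),
    _cat("cerebrovascular", 1, ["430", "431", "432", "433", "434", "435",
                                "436", "437", "438", "I6"]),
    _cat("dementia", 1, ["290", "F00", "F01", "F02", "F03", "G30"]),
    _cat("chronic_pulmonary", 1, ["490", "491", "492", "493", "494", "495",
                                  "496", "J40", "J41", "J42", "J43", "J44",
                                  "J45", "J46", "J47"]),
    _cat("rheumatic", 1, ["7100", "7101", "7104", "714", "M05", "M06", "M32", "M34"]),
    _cat("peptic_ulcer", 1, ["531", "532", "533", "534", "K25", "K26", "K27", "K28"]),
    _cat("mild_liver", 1, ["571", "K70", "K73", "K74", "K76"],
         superseded_by="moderate_severe_liver"),
    _cat("diabetes", 1, ["250", "E10", "E11"], superseded_by="diabetes_complicated"),
    _cat("diabetes_complicated", 2, ["2504", "2505", "2506",
                                     "E102", "E103", "E104", "E105",
                                     "E112", "E113", "E114", "E115"]),
    _cat("hemiplegia", 2, ["342", "344", "G81", "G82"]),
    _cat("renal", 2, ["582", "583", "585", "586", "588", "N03", "N05", "N18", "N19"]),
    _cat("moderate_severe_liver", 3, ["5722", "5723", "5724", "5728",
                                      "K72", "K766", "K767", "I85"]),
    _cat("aids", 6, ["042", "B20", "B21", "B22", "B24"]),
)


def charlson_categories_present(
    codes: Iterable[str],
    categories: Sequence[CharlsonCategory] = DEFAULT_CATEGORIES,
) -> set[str]:
    """Names of Charlson categories matched by any code, after hierarchy."""
    codes = list(codes)
    present = {
        c.name for c in categories if any(code in c.code_set for code in codes)
    }
    for c in categories:
        if c.superseded_by and c.name in present and c.superseded_by in present:
            present.discard(c.name)
    return present


def compute_dcci(
    codes: Iterable[str],
    categories: Sequence[CharlsonCategory] = DEFAULT_CATEGORIES,
) -> int:
    """DCCI score: sum of weights of the categories present."""
    weights = {c.name: c.weight for c in categories}
    return sum(weights[n] for n in charlson_categories_present(codes, categories))
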