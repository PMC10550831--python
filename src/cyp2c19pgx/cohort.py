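"""EHR-style cohort construction from coded events and prescriptions.

The analysis cohort is: participants with linked prescribing data, at least
one acute-MI code (ICD-10 I21 family) and at least one 75 mg clopidogrel
prescription. The outcome is a subsequent-MI code (I22 family). Comorbidity
covariates, smoking status and a PCI-with-stent flag (ICD-10 Z955, missing
when the participant has no secondary-care coverage) are attached, together
with the metabolizer exposure from the phenotyping stage.

Code matching is by (vocabulary, prefix): "I21" matches "I21.4" but never a
SNOMED code of the same spelling. No date or interval logic is applied — the
source records carry no timeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("participant_id", "code", "vocabulary")
PRESCRIPTION_COLUMNS = ("participant_id", "drug_name", "dose_mg")

CLOPIDOGREL_DOSE_MG = 75.0


@dataclass(frozen=True)
class CodeList:
    """Named set of (vocabulary, code-prefix) entries."""

    name: str
    entries: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"code list {self.name!r} is empty")

    def matches(self, vocabulary: str, code: str) -> bool:
        return any(
            vocabulary == voc and code.startswith(prefix)
            for voc, prefix in self.entries
        )


def _codelist(name: str, vocabulary: str, *prefixes: str) -> CodeList:
    return CodeList(name, frozenset((vocabulary, p) for p in prefixes))


#: Default condition and smoking code lists. ICD-10 lists follow the curated
#: phenotype definitions (I21 acute MI, I22 subsequent MI, E10/E11/E13/E14
#: diabetes, E78 dyslipidemia, E66 obesity, N18 CKD, I10 hypertension, Z955
#: coronary angioplasty implant/graft); SNOMED smoking concepts are a minimal
#: working set — real deployments supply their own curated lists.
DEFAULT_CODE_LISTS: dict[str, CodeList] = {
    "acute_mi": _codelist("acute_mi", "ICD10", "I21"),
    "recurrent_mi": _codelist("recurrent_mi", "ICD10", "I22"),
    "diabetes": _codelist("diabetes", "ICD10", "E10", "E11", "E13", "E14"),
    "dyslipidemia": _codelist("dyslipidemia", "ICD10", "E78"),
    "obesity": _codelist("obesity", "ICD10", "E66"),
    "ckd": _codelist("ckd", "ICD10", "N18"),
    "hypertension": _codelist("hypertension", "ICD10", "I10"),
    "pci": _codelist("pci", "ICD10", "Z955"),
    "smoking_current": _codelist("smoking_current", "SNOMED", "77176002", "449868002"),
    "smoking_ex": _codelist("smoking_ex", "SNOMED", "8517006"),
    "smoking_never": _codelist("smoking_never", "SNOMED", "266919005", "8392000"),
}

CONDITION_NAMES = ("diabetes", "hypertension", "dyslipidemia", "obesity", "ckd")


def _matching_ids(events: pd.DataFrame, codelist: CodeList) -> set:
    if events.empty:
        return set()
    code = events["code"].astype(str)
    voc = events["vocabulary"].astype(str)
    mask = pd.Series(False, index=events.index)
    for v, prefix in codelist.entries:
        mask |= (voc == v) & code.str.startswith(prefix)
    return set(events.loc[mask, "participant_id"])


def flag_condition(
    events: pd.DataFrame, codelist: CodeList, participant_ids: Sequence
) -> pd.Series:
    """Boolean per participant: has at least one event matching the code list."""
    hits = _matching_ids(events, codelist)
    return pd.Series(
        [pid in hits for pid in participant_ids], index=participant_ids, name=codelist.name
    )


def classify_smoking(
    events: pd.DataFrame,
    participant_ids: Sequence,
    code_lists: Mapping[str, CodeList] = DEFAULT_CODE_LISTS,
) -> pd.Series:
    """Ever / never / unknown smoking status.

    Ever if any current- or ex-smoker code (smoker codes dominate); never if
    no smoker code and at least one never/currently-not code; unknown with no
    smoking information at all.
    """
    ever_ids = _matching_ids(events, code_lists["smoking_current"]) | _matching_ids(
        events, code_lists["smoking_ex"]
    )
    never_ids = _matching_ids(events, code_lists["smoking_never"])
    out = []
    for pid in participant_ids:
        if pid in ever_ids:
            out.append("ever")
        elif pid in never_ids:
            out.append("never")
        else:
            out.append("unknown")
    return pd.Series(out, index=participant_ids, name="smoking")


def flag_pci(
    events: pd.DataFrame,
    participants: pd.DataFrame,
    code_lists: Mapping[str, CodeList] = DEFAULT_CODE_LISTS,
) -> pd.Series:
    """PCI-with-stent flag: True iff a Z955 event exists; missing (pd.NA) when
    the participant has no secondary-care record coverage."""
    hits = _matching_ids(events, code_lists["pci"])
    covered = (
        participants.set_index("participant_id")["has_secondary_care_data"]
        if "has_secondary_care_data" in participants.columns
        else pd.Series(True, index=participants["participant_id"])
    )
    values = []
    for pid in participants["participant_id"]:
        if not bool(covered.get(pid, True)):
            values.append(pd.NA)
        else:
            values.append(pid in hits)
    return pd.Series(
        values, index=list(participants["participant_id"]), name="pci", dtype="boolean"
    )


def flag_recurrent_mi(
    events: pd.DataFrame,
    participant_ids: Sequence,
    code_lists: Mapping[str, CodeList] = DEFAULT_CODE_LISTS,
) -> pd.Series:
    """True iff at least one subsequent-MI (I22-prefix) event."""
    return flag_condition(events, code_lists["recurrent_mi"], participant_ids).rename(
        "recurrent_mi"
    )


def _clopidogrel_75mg_ids(prescriptions: pd.DataFrame) -> set:
    if prescriptions.empty:
        return set()
    name = prescriptions["drug_name"].astype(str).str.strip().str.lower()
    dose = pd.to_numeric(prescriptions["dose_mg"], errors="coerce")
    mask = name.str.startswith("clopidogrel") & (dose == CLOPIDOGREL_DOSE_MG)
    return set(prescriptions.loc[mask, "participant_id"])


def select_analysis_cohort(
    participants: pd.DataFrame,
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    code_lists: Mapping[str, CodeList] = DEFAULT_CODE_LISTS,
) -> tuple[set, dict[str, int]]:
    """Participants with prescribing data, an acute-MI code, and a 75 mg
    clopidogrel prescription. Returns (ids, filter-stage counts).

    Drug names are matched case-insensitively as a word prefix of the product
    string; any qualifying prescription suffices (no date logic).
    """
    all_ids = set(participants["participant_id"])
    if "has_prescribing_data" in participants.columns:
        linked = set(
            participants.loc[
                participants["has_prescribing_data"].astype(bool), "participant_id"
            ]
        )
    else:
        linked = set(all_ids)
    acute = _matching_ids(events, code_lists["acute_mi"])
    clopi = _clopidogrel_75mg_ids(prescriptions)
    cohort = all_ids & linked & acute & clopi
    flow = {
        "participants": len(all_ids),
        "with_prescribing_data": len(all_ids & linked),
        "with_acute_mi": len(all_ids & linked & acute),
        "with_clopidogrel_75mg": len(cohort),
    }
    acute_linked = all_ids & linked & acute
    if acute_linked:
        logger.info(
            "clopidogrel 75 mg prescription rate among linked acute-MI "
            "participants: %.1f%%",
            100.0 * len(cohort) / len(acute_linked),
        )
    return cohort, flow


def build_analysis_table(
    cohort: Iterable,
    phenotypes: pd.DataFrame,
    events: pd.DataFrame,
    participants: pd.DataFrame,
    code_lists: Mapping[str, CodeList] = DEFAULT_CODE_LISTS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One analysis row per classified cohort member.

    Drops cohort members absent from the phenotype table or with an
    INDETERMINATE metabolizer class (counts logged and returned). Smoking
    "unknown" is coded as never for the binary ever-smoker covariate, with the
    unknown count logged. PCI missing is retained as missing; downstream
    models that adjust for PCI drop those rows themselves.
    """
    cohort_ids = list(dict.fromkeys(cohort))  # stable order, de-duplicated
    pheno = phenotypes.set_index("sample_id")
    part = participants.set_index("participant_id")

    missing_pheno = [pid for pid in cohort_ids if pid not in pheno.index]
    if missing_pheno:
        logger.warning(
            "%d cohort members absent from the phenotype table; dropped",
            len(missing_pheno),
        )
    kept = [pid for pid in cohort_ids if pid in pheno.index]
    indet = [pid for pid in kept if pheno.loc[pid, "metabolizer"] == "INDETERMINATE"]
    if indet:
        logger.info("%d cohort members with indeterminate phenotype; dropped", len(indet))
    kept = [pid for pid in kept if pid not in set(indet)]

    cohort_events = events[events["participant_id"].isin(set(kept))]
    recurrent = flag_recurrent_mi(cohort_events, kept, code_lists)
    smoking = classify_smoking(cohort_events, kept, code_lists)
    unknown_smoking = int((smoking == "unknown").sum())
    if unknown_smoking:
        logger.info(
            "%d cohort members with unknown smoking status coded as never",
            unknown_smoking,
        )
    part_kept = part.loc[kept]
    pci = flag_pci(
        cohort_events,
        part_kept.reset_index().rename(columns={part_kept.index.name or "index": "participant_id"}),
        code_lists,
    )

    pheno_kept = pheno.loc[kept]
    df = pd.DataFrame({"participant_id": kept})
    df["recurrent_mi"] = recurrent.to_numpy()
    df["metabolizer"] = pheno_kept["metabolizer"].to_numpy()
    df["lof_count"] = pd.array(pheno_kept["lof_count"].to_numpy(), dtype="Int64")
    df["male"] = (part_kept["sex"].astype(str).str.lower() == "male").to_numpy()
    df["age"] = part_kept["age_at_enrollment"].astype(float).to_numpy()
    for name in CONDITION_NAMES:
        df[name] = flag_condition(cohort_events, code_lists[name], kept).to_numpy()
    df["ever_smoker"] = (smoking == "ever").to_numpy()
    df["pci"] = pci.to_numpy()
    pc_cols = [c for c in participants.columns if c.startswith("pc_")]
    for c in sorted(pc_cols, key=lambda s: int(s.split("_")[1])):
        df[c] = part_kept[c].astype(float).to_numpy()
    if "unrelated_flag" in participants.columns:
        df["unrelated_flag"] = part_kept["unrelated_flag"].astype(bool).to_numpy()

    log = {
        "cohort_size": len(cohort_ids),
        "dropped_missing_phenotype": len(missing_pheno),
        "dropped_indeterminate": len(indet),
        "rows": len(df),
        "unknown_smoking_coded_never": unknown_smoking,
        "pci_missing": int(df["pci"].isna().sum()),
    }
    assert log["rows"] == (
        log["cohort_size"]
        - log["dropped_missing_phenotype"]
        - log["dropped_indeterminate"]
    )
    return df, log
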