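import numpy as np
import pandas as pd
import pytest

from cyp2c19pgx import CYP2C19_SITES


@pytest.fixture
def vcf_writer(tmp_path):
    """Write a small VCF with given per-sample GT strings per site.

    ``records`` maps rsid -> (ref, alt, [gt strings]); sites not listed are
    omitted from the file.
    """

    def _write(records, sample_ids, filename="test.vcf"):
        path = tmp_path / filename
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr10,length=133797422>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids),
        ]
        by_rsid = {s.rsid: s for s in CYP2C19_SITES}
        for rsid, (ref, alt, gts) in records.items():
            site = by_rsid[rsid]
            lines.append(
                f"{site.chromosome}\t{site.position}\t{rsid}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)
            )
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def hand_cohort():
    """Ten hand-written participants exercising every linkage branch.

    Expected analysis-table fields are worked out by hand in the docstrings
    of the tests that consume this fixture.
    """
    participants = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(1, 11)],
            "sex": ["male", "female", "male", "male", "female",
                    "male", "male", "female", "male", "male"],
            "age_at_enrollment": [60.0, 55.0, 70.0, 65.0, 50.0,
                                  62.0, 58.0, 67.0, 71.0, 45.0],
            "has_prescribing_data": [True] * 9 + [False],
            "has_secondary_care_data": [True, True, False, True, True,
                                        True, True, True, True, True],
            "unrelated_flag": [True] * 10,
        }
    )
    events = pd.DataFrame(
        [
            # P1: acute MI, recurrent MI, diabetes, PCI, current smoker
            ("P1", "I21.4", "ICD10"),
            ("P1", "I22", "ICD10"),
            ("P1", "E11.9", "ICD10"),
            ("P1", "Z955", "ICD10"),
            ("P1", "77176002", "SNOMED"),
            # P2: acute MI, never smoker, hypertension
            ("P2", "I21", "ICD10"),
            ("P2", "266919005", "SNOMED"),
            ("P2", "I10", "ICD10"),
            # P3: acute MI, no secondary care coverage (PCI missing), ex-smoker
            ("P3", "I21.0", "ICD10"),
            ("P3", "8517006", "SNOMED"),
            # P4: acute MI only, no other events
            ("P4", "I21", "ICD10"),
            # P5: acute MI + both never and current smoker codes (ever wins)
            ("P5", "I21", "ICD10"),
            ("P5", "266919005", "SNOMED"),
            ("P5", "77176002", "SNOMED"),
            # P6: acute MI, dyslipidemia, obesity, CKD
            ("P6", "I21.9", "ICD10"),
            ("P6", "E78.5", "ICD10"),
            ("P6", "E66", "ICD10"),
            ("P6", "N18.3", "ICD10"),
            # P7: no MI at all
            ("P7", "I10", "ICD10"),
            # P8: acute MI but prescribed ticagrelor only
            ("P8", "I21", "ICD10"),
            # P9: acute MI but clopidogrel 300 mg only
            ("P9", "I21", "ICD10"),
            # P10: acute MI but no prescribing data linkage
            ("P10", "I21", "ICD10"),
        ],
        columns=["participant_id", "code", "vocabulary"],
    )
    prescriptions = pd.DataFrame(
        [
            ("P1", "Clopidogrel 75mg tablets", 75.0),
            ("P2", "clopidogrel", 75.0),
            ("P3", "CLOPIDOGREL", 75.0),
            ("P4", "clopidogrel", 75.0),
            ("P5", "clopidogrel", 75.0),
            ("P6", "clopidogrel", 75.0),
            ("P7", "clopidogrel", 75.0),
            ("P8", "ticagrelor", 90.0),
            ("P9", "clopidogrel", 300.0),
            ("P10", "clopidogrel", 75.0),
        ],
        columns=["participant_id", "drug_name", "dose_mg"],
    )
    # Dosage triples (d2, d3, d17): P1 *1/*2 IM, P2 *1/*1 NM, P3 *2/*2 PM,
    # P4 *1/*17 RM, P5 *17/*17 UM, P6 *2/*17 IM; the rest NM.
    phenotypes = pd.DataFrame(
        {
            "sample_id": [f"P{i}" for i in range(1, 11)],
            "star_diplotype": ["*1/*2", "*1/*1", "*2/*2", "*1/*17", "*17/*17",
                               "*2/*17", "*1/*1", "*1/*1", "*1/*1", "*1/*1"],
            "metabolizer": ["IM", "NM", "PM", "RM", "UM",
                            "IM", "NM", "NM", "NM", "NM"],
            "lof_count": pd.array([1, 0, 2, 0, 0, 1, 0, 0, 0, 0], dtype="Int64"),
        }
    )
    return {
        "participants": participants,
        "events": events,
        "prescriptions": prescriptions,
        "phenotypes": phenotypes,
    }
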