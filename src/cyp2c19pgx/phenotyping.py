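"""Diplotype calling and CPIC-style metabolizer classification.

The calling is unphased and participant-level: loss-of-function (LOF) alleles
*2 and *3 dominate, and the gain-of-function *17 allele counts only on
haplotypes not already carrying a LOF allele. Two LOF alleles define a poor
metabolizer (PM), one an intermediate metabolizer (IM); with no LOF allele,
two *17 copies define an ultrarapid (UM), one a rapid (RM), and none a normal
metabolizer (NM). An optional sensitivity reclassification moves *2/*17 and
*3/*17 diplotypes from IM to NM.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

from cyp2c19pgx.qc import MISSING, GenotypeMatrix


class MetabolizerClass(str, Enum):
    """Inferred CYP2C19 enzyme-activity class (the exposure variable)."""

    PM = "PM"
    IM = "IM"
    NM = "NM"
    RM = "RM"
    UM = "UM"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class PhenotypeConfig:
    """``sensitivity_reclass`` moves one-LOF + *17 carriers from IM to NM."""

    sensitivity_reclass: bool = False


# Canonical allele ordering for diplotype strings: numeric-ascending.
_ALLELE_ORDER = {"*1": 1, "*2": 2, "*3": 3, "*17": 17}


@dataclass(frozen=True)
class DiplotypeCall:
    """Unphased star-allele pair for one participant.

    ``consistent`` is False when the dosages cannot fit two haplotypes
    (more than two LOF alleles); ``missing_input`` when any site dosage is
    missing. ``gof_truncated`` notes excess *17 dosage discarded because it
    would have to sit on a haplotype already carrying a LOF allele.
    """

    sample_id: str | None
    lof_count: int | None
    gof_count: int | None
    star_string: str | None
    consistent: bool
    missing_input: bool = False
    gof_truncated: bool = False


def call_diplotype(
    d2: int, d3: int, d17: int, sample_id: str | None = None
) -> DiplotypeCall:
    """Call an unphased diplotype from dosages at *2, *3 and *17.

    Variants are assigned to distinct haplotypes whenever capacity allows
    (trans assumption); a cis *2+*17 haplotype would conventionally be
    classified as *2 anyway, so the participant-level class is unaffected.
    """
    dosages = (d2, d3, d17)
    if any(d == MISSING or d is None or (isinstance(d, float) and d != d) for d in dosages):
        return DiplotypeCall(sample_id, None, None, None, True, missing_input=True)
    for d in dosages:
        if d not in (0, 1, 2):
            raise ValueError(f"dosage must be 0, 1, 2 or missing; got {d}")
    lof = d2 + d3
    if lof > 2:
        return DiplotypeCall(sample_id, None, None, None, consistent=False)
    gof = min(d17, 2 - lof)
    truncated = d17 > gof
    alleles = ["*2"] * d2 + ["*3"] * d3 + ["*17"] * gof
    alleles += ["*1"] * (2 - len(alleles))
    alleles.sort(key=_ALLELE_ORDER.__getitem__)
    return DiplotypeCall(
        sample_id,
        lof_count=lof,
        gof_count=gof,
        star_string="/".join(alleles),
        consistent=True,
        gof_truncated=truncated,
    )


def classify_metabolizer(
    call: DiplotypeCall, config: PhenotypeConfig = PhenotypeConfig()
) -> MetabolizerClass:
    """Map a diplotype call to a metabolizer class."""
    if call.missing_input or not call.consistent:
        return MetabolizerClass.INDETERMINATE
    if call.lof_count == 2:
        return MetabolizerClass.PM
    if call.lof_count == 1:
        if config.sensitivity_reclass and call.gof_count >= 1:
            return MetabolizerClass.NM
        return MetabolizerClass.IM
    if call.gof_count == 2:
        return MetabolizerClass.UM
    if call.gof_count == 1:
        return MetabolizerClass.RM
    return MetabolizerClass.NM


def lof_allele_count(call: DiplotypeCall) -> int:
    """LOF allele dose in {0, 1, 2}: the unit of the allele-dose model."""
    if call.missing_input or not call.consistent:
        raise ValueError("LOF count undefined for inconsistent or missing calls")
    return int(call.lof_count)


def phenotype_frequencies(classes: Iterable[MetabolizerClass]) -> pd.DataFrame:
    """Count and proportion per metabolizer class.

    Proportions are over determinate (non-INDETERMINATE) calls; a combined
    ``PM+IM`` row gives the share carrying at least one LOF allele.
    """
    values = [MetabolizerClass(c) for c in classes]
    if not values:
        raise ValueError("no classes supplied")
    order = [
        MetabolizerClass.PM,
        MetabolizerClass.IM,
        MetabolizerClass.NM,
        MetabolizerClass.RM,
        MetabolizerClass.UM,
    ]
    counts = {c: 0 for c in order}
    indet = 0
    for v in values:
        if v is MetabolizerClass.INDETERMINATE:
            indet += 1
        else:
            counts[v] += 1
    n_det = sum(counts.values())
    rows = []
    for c in order:
        rows.append(
            {
                "class": c.value,
                "count": counts[c],
                "proportion": counts[c] / n_det if n_det else float("nan"),
            }
        )
    pm_im = counts[MetabolizerClass.PM] + counts[MetabolizerClass.IM]
    rows.append(
        {
            "class": "PM+IM",
            "count": pm_im,
            "proportion": pm_im / n_det if n_det else float("nan"),
        }
    )
    rows.append({"class": "INDETERMINATE", "count": indet, "proportion": float("nan")})
    return pd.DataFrame(rows)


def phenotype_table(
    matrix: GenotypeMatrix, config: PhenotypeConfig = PhenotypeConfig()
) -> pd.DataFrame:
    """Per-sample phenotype table: sample_id, star_diplotype, metabolizer,
    lof_count (NA for indeterminate calls)."""
    try:
        j2 = matrix.site_index("*2")
        j3 = matrix.site_index("*3")
        j17 = matrix.site_index("*17")
    except KeyError as exc:
        raise ValueError(f"genotype matrix lacks site {exc}") from exc
    records = []
    for i, sid in enumerate(matrix.sample_ids):
        call = call_diplotype(
            int(matrix.dosage[i, j2]),
            int(matrix.dosage[i, j3]),
            int(matrix.dosage[i, j17]),
            sample_id=sid,
        )
        cls = classify_metabolizer(call, config)
        records.append(
            {
                "sample_id": sid,
                "star_diplotype": call.star_string,
                "metabolizer": cls.value,
                "lof_count": call.lof_count
                if cls is not MetabolizerClass.INDETERMINATE
                else pd.NA,
            }
        )
    df = pd.DataFrame(records)
    df["lof_count"] = df["lof_count"].astype("Int64")
    return df
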