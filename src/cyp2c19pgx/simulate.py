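"""Synthetic pharmacogenomic cohort generator.

Emulates the statistical structure the analysis assumes: metabolizer-class
frequencies typical of a South Asian ancestry population (PM 13%, IM 44%, NM 25%,
RM 15.3%, UM 2.7% — the RM value is the residual making the classes sum to
one), baseline covariate margins of an acute-MI clopidogrel cohort, a
logistic outcome model whose exposure effects default to the adjusted odds
ratios of that cohort (PM 3.12, IM 1.47, UM 10.49, age 1.04 per year) with the
intercept calibrated by bisection to a 5.6% marginal recurrence rate, and the
PCI missingness pattern (14 participants missing, exactly 1 among cases).

Every participant carries an acute-MI code and a 75 mg clopidogrel
prescription, so the generated tables exercise the full cohort-linkage path.
Outputs are written in the pipeline's own input formats (VCF + three
delimited tables) and round-trip losslessly. Covariates are sampled
independently; the generator does not emulate linkage disequilibrium,
pedigree structure beyond a single inbreeding coefficient, or prescription
timelines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cyp2c19pgx.qc import CYP2C19_SITES, GenotypeMatrix
from cyp2c19pgx.phenotyping import call_diplotype, classify_metabolizer

logger = logging.getLogger(__name__)

CLASSES = ("PM", "IM", "NM", "RM", "UM")

#: Default class probabilities; RM is the residual of the printed classes.
DEFAULT_CLASS_PROBS = {"PM": 0.13, "IM": 0.44, "NM": 0.25, "RM": 0.153, "UM": 0.027}

#: Haplotype frequencies implied by the stated carrier rates (56% carry *2,
#: 1.2% carry *3, 27.6% carry *17) under random mating.
DEFAULT_HAPLOTYPE_FREQS = {"*1": 0.508, "*2": 0.337, "*3": 0.006, "*17": 0.149}

DEFAULT_COVARIATE_PREVALENCES = {
    "male": 0.80,
    "diabetes": 0.71,
    "hypertension": 0.91,
    "dyslipidemia": 0.90,
    "obesity": 0.31,
    "ckd": 0.38,
    "ever_smoker": 0.90,
    "pci": 0.60,
}

#: ICD-10 code emitted per true covariate flag.
_CONDITION_CODES = {
    "diabetes": "E11",
    "hypertension": "I10",
    "dyslipidemia": "E78",
    "obesity": "E66",
    "ckd": "N18",
}
_SMOKER_SNOMED = "77176002"       # current smoker
_NEVER_SMOKER_SNOMED = "266919005"  # never smoked


@dataclass
class OutcomeModel:
    """Logistic outcome model: logit P(recurrent MI) = intercept + effects.

    In categorical mode the exposure contributes per-class log-ORs; in
    lof_dose mode a single per-LOF-allele log-OR times the 0/1/2 allele
    count. Age enters per year, uncentered (the calibrated intercept absorbs
    the offset). When ``intercept`` is None it is calibrated by deterministic
    bisection so the marginal event rate matches ``target_event_rate``.
    """

    mode: str = "categorical"
    class_log_or: dict[str, float] = field(
        default_factory=lambda: {
            "PM": math.log(3.12),
            "IM": math.log(1.47),
            "UM": math.log(10.49),
        }
    )
    lof_log_or: float = math.log(1.95)
    age_log_or_per_year: float = math.log(1.04)
    covariate_log_or: dict[str, float] = field(default_factory=dict)
    target_event_rate: float = 0.056
    intercept: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("categorical", "lof_dose"):
            raise ValueError(f"unknown outcome mode {self.mode!r}")


@dataclass
class SimulationConfig:
    """All frequencies, effect sizes, missingness counts and the seed."""

    n: int = 697
    seed: int = 0
    diplotype_mode: str = "class_frequencies"
    class_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    haplotype_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAPLOTYPE_FREQS)
    )
    inbreeding_f: float = 0.0
    # Diplotype composition within classes, implied by the carrier rates:
    pm_star3_fraction: float = 0.035   # *2/*3 (vs *2/*2) among PMs
    im_star3_fraction: float = 0.017   # *3 as the LOF allele among IMs
    im_gof_fraction: float = 0.227     # *17 on the non-LOF haplotype among IMs
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    age_mean: float = 61.0
    age_sd: float = 12.0
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    pci_missing_count: int = 14
    pci_missing_pattern: str = "single_case"  # or "random"
    pc_count: int = 20

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.diplotype_mode not in ("class_frequencies", "hwe_haplotype"):
            raise ValueError(f"unknown diplotype mode {self.diplotype_mode!r}")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_probs sum to {total}, expected 1")
        if any(not 0 <= p <= 1 for p in self.class_probs.values()):
            raise ValueError("class probabilities must be in [0, 1]")
        htotal = sum(self.haplotype_freqs.values())
        if abs(htotal - 1.0) > 1e-3:
            raise ValueError(f"haplotype_freqs sum to {htotal}, expected 1")
        for k, v in self.covariate_prevalences.items():
            if not 0 <= v <= 1:
                raise ValueError(f"prevalence {k}={v} outside [0, 1]")
        if self.pci_missing_count > self.n:
            raise ValueError("pci_missing_count exceeds cohort size")
        if self.pci_missing_pattern not in ("single_case", "random"):
            raise ValueError("pci_missing_pattern must be 'single_case' or 'random'")
        if isinstance(self.outcome, dict):
            self.outcome = OutcomeModel(**self.outcome)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """In-memory cohort in the pipeline's input schema, plus the truth record."""

    genotypes: GenotypeMatrix
    participants: pd.DataFrame
    events: pd.DataFrame
    prescriptions: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _class_dosages(
    classes: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Dosage triples (d2, d3, d17) consistent with each sampled class."""
    n = classes.size
    d = np.zeros((n, 3), dtype=np.int8)
    pm = classes == "PM"
    star23 = pm & (rng.random(n) < config.pm_star3_fraction)
    d[pm, 0] = 2
    d[star23, 0] = 1
    d[star23, 1] = 1
    im = classes == "IM"
    im3 = im & (rng.random(n) < config.im_star3_fraction)
    d[im, 0] = 1
    d[im3, 0] = 0
    d[im3, 1] = 1
    im17 = im & (rng.random(n) < config.im_gof_fraction)
    d[im17, 2] = 1
    d[classes == "RM", 2] = 1
    d[classes == "UM", 2] = 2
    return d


def _haplotype_dosages(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw two haplotypes per participant; with probability F (inbreeding)
    the second copies the first."""
    haps = list(config.haplotype_freqs)
    probs = np.array([config.haplotype_freqs[h] for h in haps], dtype=float)
    probs = probs / probs.sum()
    h1 = rng.choice(len(haps), size=n, p=probs)
    h2 = rng.choice(len(haps), size=n, p=probs)
    ibd = rng.random(n) < config.inbreeding_f
    h2[ibd] = h1[ibd]
    d = np.zeros((n, 3), dtype=np.int8)
    for j, star in enumerate(("*2", "*3", "*17")):
        k = haps.index(star) if star in haps else -1
        if k >= 0:
            d[:, j] = (h1 == k).astype(np.int8) + (h2 == k).astype(np.int8)
    return d


def sample_diplotypes(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample metabolizer classes and consistent dosage triples.

    In class_frequencies mode the class is drawn first and a dosage triple
    consistent with it emitted; in hwe_haplotype mode two haplotypes are drawn
    (with inbreeding coefficient F) and the class derived. Either way the
    emitted dosages reclassify to the recorded class through the phenotyping
    path.
    """
    n = config.n
    if config.diplotype_mode == "class_frequencies":
        probs = np.array([config.class_probs[c] for c in CLASSES], dtype=float)
        probs = probs / probs.sum()
        classes = np.array(CLASSES)[rng.choice(len(CLASSES), size=n, p=probs)]
        dosages = _class_dosages(classes, config, rng)
    else:
        dosages = _haplotype_dosages(config, rng, n)
        classes = np.array(
            [
                classify_metabolizer(call_diplotype(*map(int, row))).value
                for row in dosages
            ]
        )
    return pd.DataFrame(
        {
            "class": classes,
            "d2": dosages[:, 0],
            "d3": dosages[:, 1],
            "d17": dosages[:, 2],
            "lof_count": dosages[:, 0] + dosages[:, 1],
        }
    )


def sample_covariates(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> pd.DataFrame:
    """Independent Bernoulli covariates plus normal age truncated at 18."""
    out = {}
    for name, rate in config.covariate_prevalences.items():
        out[name] = rng.random(n) < rate
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    for _ in range(100):
        low = age < 18
        if not low.any():
            break
        age[low] = rng.normal(config.age_mean, config.age_sd, size=int(low.sum()))
    age = np.maximum(age, 18.0)
    out["age"] = np.round(age, 3)
    return pd.DataFrame(out)


def _linear_predictor_no_intercept(
    config: SimulationConfig, rows: pd.DataFrame
) -> np.ndarray:
    model = config.outcome
    eta = np.zeros(len(rows))
    if model.mode == "categorical":
        for cls, log_or in model.class_log_or.items():
            eta += log_or * (rows["class"] == cls).to_numpy(dtype=float)
    else:
        eta += model.lof_log_or * rows["lof_count"].to_numpy(dtype=float)
    eta += model.age_log_or_per_year * rows["age"].to_numpy(dtype=float)
    for cov, log_or in model.covariate_log_or.items():
        eta += log_or * rows[cov].to_numpy(dtype=float)
    return eta


def calibrate_intercept(
    eta_no_intercept: np.ndarray, target_rate: float, *, lo: float = -40.0, hi: float = 10.0
) -> float:
    """Deterministic bisection for the intercept making the cohort-average
    event probability equal the target rate."""
    if not 0 < target_rate < 1:
        raise ValueError("target rate must be in (0, 1)")
    if eta_no_intercept.size == 0:
        # No cohort to average over; return the marginal-rate logit.
        return float(np.log(target_rate / (1.0 - target_rate)))

    def mean_rate(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(c + eta_no_intercept)))))

    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sample_outcome(
    config: SimulationConfig, rng: np.random.Generator, rows: pd.DataFrame
) -> tuple[np.ndarray, float, np.ndarray]:
    """Bernoulli recurrent-MI outcome. Returns (outcome, intercept, eta)."""
    eta0 = _linear_predictor_no_intercept(config, rows)
    intercept = config.outcome.intercept
    if intercept is None:
        intercept = calibrate_intercept(eta0, config.outcome.target_event_rate)
    eta = intercept + eta0
    p = 1.0 / (1.0 + np.exp(-eta))
    outcome = rng.random(len(rows)) < p
    return outcome, intercept, eta


def inject_missingness(
    config: SimulationConfig, rng: np.random.Generator, participants: pd.DataFrame
) -> pd.DataFrame:
    """Mark exactly ``pci_missing_count`` participants as lacking secondary-care
    coverage; in the default "single_case" pattern exactly one is drawn from the
    recurrent-MI cases (when cases exist and the count permits)."""
    k = config.pci_missing_count
    if k > len(participants):
        raise ValueError("pci_missing_count exceeds cohort size")
    out = participants.copy()
    out["has_secondary_care_data"] = True
    if k == 0:
        return out
    cases = np.flatnonzero(out["recurrent_mi"].to_numpy(dtype=bool))
    controls = np.flatnonzero(~out["recurrent_mi"].to_numpy(dtype=bool))
    if config.pci_missing_pattern == "single_case" and cases.size >= 1 and controls.size >= k - 1:
        chosen = np.concatenate(
            [
                rng.choice(cases, size=1, replace=False),
                rng.choice(controls, size=k - 1, replace=False),
            ]
        )
    else:
        chosen = rng.choice(len(out), size=k, replace=False)
    out.iloc[chosen, out.columns.get_loc("has_secondary_care_data")] = False
    return out


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort in the pipeline's input schema.

    Identical config+seed reproduces the cohort exactly. Every participant
    receives an acute-MI (I21) event and a clopidogrel 75 mg prescription;
    cases additionally receive an I22 event; condition codes mirror the true
    covariate flags; Z955 marks PCI, omitted (with coverage withdrawn) for
    the PCI-missing participants.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        logger.warning("generating an empty cohort (n = 0)")
    sample_ids = [f"S{i:06d}" for i in range(n)]

    dipl = sample_diplotypes(config, rng)
    cov = sample_covariates(config, rng, n)
    rows = pd.concat([dipl, cov], axis=1)
    outcome, intercept, eta = sample_outcome(config, rng, rows)
    rows["recurrent_mi"] = outcome

    participants = pd.DataFrame(
        {
            "participant_id": sample_ids,
            "sex": np.where(cov["male"], "male", "female"),
            "age_at_enrollment": cov["age"],
            "has_prescribing_data": True,
            "unrelated_flag": True,
            "recurrent_mi": outcome,
        }
    )
    pcs = rng.standard_normal((n, config.pc_count))
    for j in range(config.pc_count):
        participants[f"pc_{j + 1}"] = np.round(pcs[:, j], 6)
    participants = inject_missingness(config, rng, participants)
    participants = participants.drop(columns=["recurrent_mi"])

    ids = np.array(sample_ids)
    ev_pid: list[np.ndarray] = [ids]
    ev_code: list[np.ndarray] = [np.full(n, "I21")]
    ev_voc: list[np.ndarray] = [np.full(n, "ICD10")]
    case_ids = ids[outcome]
    ev_pid.append(case_ids)
    ev_code.append(np.full(case_ids.size, "I22"))
    ev_voc.append(np.full(case_ids.size, "ICD10"))
    for cov_name, code in _CONDITION_CODES.items():
        hit = ids[cov[cov_name].to_numpy()]
        ev_pid.append(hit)
        ev_code.append(np.full(hit.size, code))
        ev_voc.append(np.full(hit.size, "ICD10"))
    smokers = cov["ever_smoker"].to_numpy()
    ev_pid.append(ids[smokers])
    ev_code.append(np.full(int(smokers.sum()), _SMOKER_SNOMED))
    ev_voc.append(np.full(int(smokers.sum()), "SNOMED"))
    ev_pid.append(ids[~smokers])
    ev_code.append(np.full(int((~smokers).sum()), _NEVER_SMOKER_SNOMED))
    ev_voc.append(np.full(int((~smokers).sum()), "SNOMED"))
    covered = participants["has_secondary_care_data"].to_numpy(dtype=bool)
    pci_hit = cov["pci"].to_numpy() & covered
    ev_pid.append(ids[pci_hit])
    ev_code.append(np.full(int(pci_hit.sum()), "Z955"))
    ev_voc.append(np.full(int(pci_hit.sum()), "ICD10"))
    events = pd.DataFrame(
        {
            "participant_id": np.concatenate(ev_pid) if n else np.array([], dtype=str),
            "code": np.concatenate(ev_code) if n else np.array([], dtype=str),
            "vocabulary": np.concatenate(ev_voc) if n else np.array([], dtype=str),
        }
    )

    prescriptions = pd.DataFrame(
        {
            "participant_id": sample_ids,
            "drug_name": ["clopidogrel"] * n,
            "dose_mg": [75.0] * n,
        }
    )

    genotypes = GenotypeMatrix(
        sample_ids, CYP2C19_SITES, dipl[["d2", "d3", "d17"]].to_numpy(dtype=np.int8)
    )

    truth = pd.DataFrame(
        {
            "participant_id": sample_ids,
            "class": dipl["class"],
            "lof_count": dipl["lof_count"],
            "linear_predictor": np.round(eta, 8),
            "recurrent_mi": outcome,
            "pci_observed": covered,
        }
    )
    for name in cov.columns:  # every sampled latent covariate
        truth[name] = cov[name]
    truth.attrs["intercept"] = intercept
    return SyntheticCohort(genotypes, participants, events, prescriptions, truth, config)


def truth_analysis_rows(cohort: SyntheticCohort) -> pd.DataFrame:
    """Analysis-rows frame built directly from the truth record.

    Bypasses the event-linkage path (which reconstructs the same flags from
    the generated coded events); useful for simulation studies where only the
    statistical stage is exercised.
    """
    t = cohort.truth
    rows = pd.DataFrame(
        {
            "participant_id": t["participant_id"],
            "recurrent_mi": t["recurrent_mi"].astype(bool),
            "metabolizer": t["class"],
            "lof_count": pd.array(t["lof_count"], dtype="Int64"),
            "male": t["male"].astype(bool),
            "age": t["age"].astype(float),
            "diabetes": t["diabetes"].astype(bool),
            "hypertension": t["hypertension"].astype(bool),
            "dyslipidemia": t["dyslipidemia"].astype(bool),
            "obesity": t["obesity"].astype(bool),
            "ckd": t["ckd"].astype(bool),
            "ever_smoker": t["ever_smoker"].astype(bool),
        }
    )
    pci = pd.array(t["pci"].astype(bool), dtype="boolean")
    pci[~t["pci_observed"].to_numpy(dtype=bool)] = pd.NA
    rows["pci"] = pci
    for c in (c for c in cohort.participants.columns if c.startswith("pc_")):
        rows[c] = cohort.participants[c].to_numpy(dtype=float)
    return rows


_VCF_HEADER = """##fileformat=VCFv4.2
##reference=GRCh38
##contig=<ID=chr10,length=133797422>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write the genotype matrix as an uncompressed VCF with GT fields.

    Unphased genotypes: dosage 0 -> 0/0, 1 -> 0/1, 2 -> 1/1, missing -> ./.
    Records are emitted in position order.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    order = np.argsort([s.position for s in genotypes.sites])
    with open(path, "wt") as fh:
        fh.write(_VCF_HEADER)
        header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if genotypes.n_samples:  # zero samples -> sites-only VCF, no FORMAT
            header_cols += ["FORMAT", *genotypes.sample_ids]
        fh.write("\t".join(header_cols) + "\n")
        for j in order:
            site = genotypes.sites[j]
            fields = [
                site.chromosome, str(site.position), site.rsid,
                site.ref_allele, site.alt_allele, ".", "PASS", ".",
            ]
            if genotypes.n_samples:
                fields += ["GT", *(gt_map[int(d)] for d in genotypes.dosage[:, j])]
            fh.write("\t".join(fields) + "\n")


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort in the pipeline's input formats.

    Produces genotypes.vcf, events.tsv, prescriptions.tsv, participants.tsv,
    truth.tsv and config.yaml under ``directory``; returns the paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if cohort.genotypes.n_samples == 0:
        logger.warning("writing an empty cohort")
    paths = {
        "genotypes": directory / "genotypes.vcf",
        "events": directory / "events.tsv",
        "prescriptions": directory / "prescriptions.tsv",
        "participants": directory / "participants.tsv",
        "truth": directory / "truth.tsv",
        "config": directory / "config.yaml",
    }
    write_vcf(cohort.genotypes, paths["genotypes"])
    cohort.events.to_csv(paths["events"], sep="\t", index=False)
    cohort.prescriptions.to_csv(paths["prescriptions"], sep="\t", index=False)
    cohort.participants.to_csv(paths["participants"], sep="\t", index=False)
    truth = cohort.truth.copy()
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "wt") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
    return paths
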