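"""Genotype loading and per-site quality control for the three CYP2C19 SNPs.

Genotypes are held as alternate-allele dosages in {0, 1, 2} with an explicit
``MISSING`` sentinel (-1). Half-missing genotypes (one allele uncalled) count
as missing. QC metrics are minor allele frequency, missingness, an exact
Hardy-Weinberg test, and (when supplied) the imputation INFO score. A HWE
departure is reported but never excludes a site by default: in founder or
endogamous cohorts it typically reflects relatedness rather than genotyping
error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype; distinct from any valid dosage.
MISSING: int = -1


@dataclass(frozen=True)
class VariantSite:
    """One star-allele-defining SNP (GRCh38, 1-based coordinates)."""

    rsid: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    star_label: str
    effect: str  # "LOF" or "GOF"

    def __post_init__(self) -> None:
        if self.effect not in ("LOF", "GOF"):
            raise ValueError(f"effect must be LOF or GOF, got {self.effect!r}")


#: The three clinically validated CYP2C19 sites: *2 and *3 introduce premature
#: stop codons (loss of function); *17 is a promoter variant increasing
#: expression (gain of function).
CYP2C19_SITES: tuple[VariantSite, ...] = (
    VariantSite("rs4244285", "chr10", 94781859, "G", "A", "*2", "LOF"),
    VariantSite("rs4986893", "chr10", 94780653, "G", "A", "*3", "LOF"),
    VariantSite("rs12248560", "chr10", 94761900, "C", "T", "*17", "GOF"),
)


@dataclass
class GenotypeMatrix:
    """Per-sample alternate-allele dosages at a fixed set of sites.

    ``dosage`` has shape (n_samples, n_sites), dtype int8, entries in
    {0, 1, 2, MISSING}.
    """

    sample_ids: list[str]
    sites: tuple[VariantSite, ...]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows must match sample_ids")
        if m != len(self.sites):
            raise ValueError("dosage columns must match sites")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.dosage[~valid][0]
            raise ValueError(f"invalid dosage value {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def site_index(self, star_label: str) -> int:
        for i, s in enumerate(self.sites):
            if s.star_label == star_label:
                return i
        raise KeyError(star_label)

    def to_frame(self) -> pd.DataFrame:
        """Dosage table with one column per rsid, MISSING as pandas NA."""
        df = pd.DataFrame(
            self.dosage, columns=[s.rsid for s in self.sites], dtype="Int64"
        )
        df = df.mask(df == MISSING)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class SiteQC:
    """QC metrics and pass/fail decision for one site."""

    site: VariantSite
    maf: float
    missingness: float
    hwe_p: float
    info_score: float | None
    passed: bool
    hwe_flag: bool
    reasons: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class QCThresholds:
    """Pass/fail thresholds. ``min_hwe_p`` is opt-in: by default a HWE
    departure is flagged, not excluded."""

    max_missingness: float = 0.05
    min_info: float = 0.7
    min_hwe_p: float | None = None

    def __post_init__(self) -> None:
        for name in ("max_missingness", "min_info"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_hwe_p is not None and not 0.0 <= self.min_hwe_p <= 1.0:
            raise ValueError("min_hwe_p must be in [0, 1]")


def _harden_dosage(value: float) -> int:
    """Round a fractional (imputed) dosage; distant from an integer -> missing."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    nearest = round(float(value))
    if nearest not in (0, 1, 2) or abs(float(value) - nearest) > 0.1:
        return MISSING
    return int(nearest)


def _load_vcf(path: Path, sites: Sequence[VariantSite]) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed input
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    dosage = np.full((n, len(sites)), MISSING, dtype=np.int8)
    by_pos = {(s.chromosome.removeprefix("chr"), s.position): j for j, s in enumerate(sites)}
    seen: set[int] = set()
    for variant in vcf:
        key = (str(variant.CHROM).removeprefix("chr"), variant.POS)
        j = by_pos.get(key)
        if j is None:
            continue
        site = sites[j]
        if len(variant.ALT) > 1:
            raise ValueError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS} "
                f"(declared site {site.rsid}); split or normalize the VCF first"
            )
        if j in seen:
            raise ValueError(
                f"duplicate record at declared position {variant.CHROM}:{variant.POS}"
            )
        alt = variant.ALT[0] if variant.ALT else ""
        if variant.REF == site.ref_allele and alt == site.alt_allele:
            flip = False
        elif variant.REF == site.alt_allele and alt == site.ref_allele:
            flip = True
            logger.warning(
                "REF/ALT at %s are swapped relative to the declared alleles; "
                "flipping dosages",
                site.rsid,
            )
        else:
            raise ValueError(
                f"alleles {variant.REF}>{alt} at {site.rsid} do not match the "
                f"declared {site.ref_allele}>{site.alt_allele} in either orientation"
            )
        col = np.full(n, MISSING, dtype=np.int8)
        gts = variant.genotypes  # [allele0, allele1, phased] per sample
        if gts is not None and len(gts) == n:
            for i, gt in enumerate(gts):
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:
                    continue  # half-missing counts as missing
                col[i] = (a > 0) + (b > 0)
        if n and (col == MISSING).all():
            try:
                ds = variant.format("DS")
            except KeyError:
                ds = None
            if ds is not None:
                for i, value in enumerate(np.asarray(ds, dtype=float).ravel()[:n]):
                    col[i] = _harden_dosage(value)
        if flip:
            present = col != MISSING
            col[present] = 2 - col[present]
        dosage[:, j] = col
        seen.add(j)
    for j, site in enumerate(sites):
        if j not in seen:
            logger.warning("site %s (%s) absent from %s; column set to missing",
                           site.rsid, site.star_label, path)
    return GenotypeMatrix(sample_ids, tuple(sites), dosage)


def _load_dosage_table(path: Path, sites: Sequence[VariantSite]) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except Exception as exc:
        raise ValueError(f"cannot parse dosage table {path}: {exc}") from exc
    if "sample_id" not in df.columns:
        raise ValueError(f"dosage table {path} lacks a sample_id column")
    n = len(df)
    dosage = np.full((n, len(sites)), MISSING, dtype=np.int8)
    for j, site in enumerate(sites):
        if site.rsid not in df.columns:
            logger.warning("site %s absent from %s; column set to missing",
                           site.rsid, path)
            continue
        for i, value in enumerate(pd.to_numeric(df[site.rsid], errors="coerce")):
            dosage[i, j] = _harden_dosage(value)
    return GenotypeMatrix(list(df["sample_id"]), tuple(sites), dosage)


def load_genotypes(
    path: str | Path, sites: Sequence[VariantSite] = CYP2C19_SITES
) -> GenotypeMatrix:
    """Load dosages at the declared sites from a VCF or a tab-delimited table.

    Alt-allele dosage is counted against the declared alt allele; a VCF record
    whose REF/ALT are swapped relative to the declaration is flipped with a
    warning. Declared sites absent from the file yield all-missing columns.

    Parameters
    ----------
    path
        VCF (v4.x, GT or DS fields) or a table with header
        ``sample_id  rs4244285  rs4986893  rs12248560`` and values 0/1/2/NA.
    sites
        Declared sites; positions must be unique.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    positions = [(s.chromosome, s.position) for s in sites]
    if len(set(positions)) != len(positions):
        raise ValueError("declared sites must have unique positions")
    with open(path, "rt") as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return _load_vcf(path, sites)
    return _load_dosage_table(path, sites)


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of a dosage vector, ignoring missing entries.

    Returns min(p, 1-p) with p the alt-allele frequency.
    """
    d = np.asarray(dosages)
    present = d != MISSING
    n = int(present.sum())
    if n == 0:
        raise ValueError("cannot compute MAF: all dosages missing")
    p = float(d[present].sum()) / (2 * n)
    return min(p, 1.0 - p)


def compute_missingness(dosages: np.ndarray) -> float:
    """Fraction of missing entries in a dosage vector."""
    d = np.asarray(dosages)
    if d.size == 0:
        raise ValueError("cannot compute missingness of an empty vector")
    return float((d == MISSING).sum()) / d.size


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, the heterozygote count follows
    a hypergeometric-type distribution under random mating; the p-value is
    the sum of the probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed count (standard exact
    formulation, no mid-p correction). Symmetric in ref/alt labelling.
    """
    for name, v in (("n_hom_ref", n_hom_ref), ("n_het", n_het), ("n_hom_alt", n_hom_alt)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotype required")
    n_alt = 2 * n_hom_alt + n_het
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0  # monomorphic: single possible configuration
    # log P(het = h | n, allele counts) up to a shared constant:
    #   log n! - log hr! - log h! - log ha! + h log 2
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * math.log(2.0)
        - _lgamma_arr(hom_common + 1)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(hom_rare + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs_het = n_het
    p_obs = probs[np.nonzero(hets == obs_het)[0][0]]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


def _genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    d = np.asarray(dosages)
    present = d[d != MISSING]
    return int((present == 0).sum()), int((present == 1).sum()), int((present == 2).sum())


def qc_filter(
    matrix: GenotypeMatrix,
    info_scores: Sequence[float | None] | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[list[SiteQC], GenotypeMatrix]:
    """Per-site QC metrics and the matrix restricted to passing sites.

    A site fails on missingness above ``max_missingness`` or INFO below
    ``min_info``. A HWE departure (p < 0.05) only sets ``hwe_flag`` unless an
    explicit ``min_hwe_p`` threshold was requested.
    """
    if info_scores is None:
        info_scores = [None] * len(matrix.sites)
    if len(info_scores) != len(matrix.sites):
        raise ValueError("info_scores length must match sites")
    reports: list[SiteQC] = []
    keep: list[int] = []
    for j, site in enumerate(matrix.sites):
        col = matrix.dosage[:, j]
        miss = compute_missingness(col)
        all_missing = miss == 1.0
        maf = float("nan") if all_missing else compute_maf(col)
        if all_missing:
            hwe_p = float("nan")
        else:
            hwe_p = hwe_exact_test(*_genotype_counts(col))
        info = info_scores[j]
        reasons: list[str] = []
        if miss > thresholds.max_missingness:
            reasons.append(
                f"missingness {miss:.3f} > {thresholds.max_missingness}"
            )
        if info is not None and info < thresholds.min_info:
            reasons.append(f"info {info:.3f} < {thresholds.min_info}")
        hwe_flag = (not all_missing) and hwe_p < 0.05
        if (
            thresholds.min_hwe_p is not None
            and not all_missing
            and hwe_p < thresholds.min_hwe_p
        ):
            reasons.append(f"hwe_p {hwe_p:.3g} < {thresholds.min_hwe_p}")
        passed = not reasons
        if passed:
            keep.append(j)
        reports.append(SiteQC(site, maf, miss, hwe_p, info, passed, hwe_flag, reasons))
    restricted = GenotypeMatrix(
        list(matrix.sample_ids),
        tuple(matrix.sites[j] for j in keep),
        matrix.dosage[:, keep].copy(),
    )
    return reports, restricted


def qc_report_frame(reports: Sequence[SiteQC]) -> pd.DataFrame:
    """Tabular QC report (one row per site)."""
    return pd.DataFrame(
        {
            "rsid": [r.site.rsid for r in reports],
            "star": [r.site.star_label for r in reports],
            "maf": [r.maf for r in reports],
            "missingness": [r.missingness for r in reports],
            "hwe_p": [r.hwe_p for r in reports],
            "info": [r.info_score for r in reports],
            "hwe_flag": [r.hwe_flag for r in reports],
            "pass": [r.passed for r in reports],
            "reasons": ["; ".join(r.reasons) for r in reports],
        }
    )
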