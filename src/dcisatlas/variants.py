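"""Tumor-only somatic-variant filtering cascade and multi-region presence calls.

Without a matched normal, somatic mutations must be prioritized
computationally.  The cascade applies four independent predicates, each of
which *labels* records rather than dropping them, so the audit trail of a
multi-rule pipeline survives and the final outcome is invariant to the
order the filters run in:

* ``quality_fail`` — read-level evidence thresholds (depth, mapping
  quality, position-in-read, mismatch load, microsatellite context,
  caller log-odds, strand bias, VAF).  Threshold senses are strict or
  inclusive exactly as stated, e.g. mapping quality must *exceed* 45.
* ``common_germline`` — population allele frequency > 1e-3 or more than 9
  carriers in any population database, unless the variant sits in a
  Cancer Gene Census tier-1 gene and is known to COSMIC or ClinVar.
* ``vaf_germline`` — VAF >= 0.9 outside LOH segments (a high VAF inside a
  loss-of-heterozygosity interval is expected for a somatic event on the
  retained allele, so LOH positions are exempt).
* ``pon`` — seen in more than 2 patients of a pool of unrelated normals.

``rescued_hotspot`` marks recurrent COSMIC hotspots (>= 15 patients) in a
curated breast-cancer driver-gene list; rescued records survive the
common-germline rule.  A record passes the cascade (``somatic_pass``)
when it carries no disqualifying label.

:func:`call_presence` classifies each variant as present/absent/unknown in
each region of a sample by a Bayes factor comparing a real-variant model
(binomial with allele fraction integrated uniformly above ``f_min``)
against a sequencing-error model (binomial at error rate ``e``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "VariantRecord",
    "FilterParams",
    "PresenceParams",
    "apply_quality_filters",
    "flag_germline",
    "apply_pon_filter",
    "rescue_hotspots",
    "somatic_pass",
    "run_cascade",
    "call_presence",
    "presence_bayes_factor",
    "read_vcf",
    "write_vcf",
    "read_bed_intervals",
]

FILTER_LABELS = (
    "quality_fail",
    "common_germline",
    "vaf_germline",
    "pon",
    "rescued_hotspot",
    "somatic_pass",
)


@dataclass
class VariantRecord:
    """One candidate mutation with evidence metrics and annotations."""

    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    vaf: float | None = None
    depth: int | None = None
    mapping_quality: float | None = None
    mean_read_position: float | None = None
    mean_mismatches: float | None = None
    microsatellite_length: int | None = None
    tlod: float | None = None
    fs_phred: float | None = None
    population_af: float | None = None
    population_count: int | None = None
    gene: str = ""
    cgc_tier1: bool = False
    in_cosmic: bool = False
    cosmic_patient_count: int = 0
    in_clinvar: bool = False
    filter_labels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.depth is not None and self.depth < 0:
            raise ValueError("negative depth")
        bad = self.filter_labels - set(FILTER_LABELS)
        if bad:
            raise ValueError(f"unknown filter labels: {bad}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class FilterParams:
    """Cascade thresholds; senses are applied exactly as printed."""

    min_depth: int = 5  # at least 5 reads (>=)
    min_mq: float = 45.0  # strictly > 45
    min_read_pos: float = 15.0  # strictly > 15
    max_mismatches: float = 2.5  # strictly < 2.5
    max_ms_length: int = 5  # strictly < 5
    min_tlod: float = 10.0  # strictly > 10
    max_fs: float = 10.0  # strictly < 10
    min_vaf: float = 0.1  # strictly > 0.1
    max_pop_af: float = 1e-3  # strictly > 1e-3 flags
    max_pop_count: int = 9  # strictly > 9 flags
    germline_vaf: float = 0.9  # >= 0.9 flags
    max_pon_patients: int = 2  # strictly > 2 flags
    hotspot_min_patients: int = 15  # >= 15 rescues

    def __post_init__(self) -> None:
        if not self.min_vaf < self.germline_vaf:
            raise ValueError("min_vaf must be below germline_vaf")


@dataclass(frozen=True)
class PresenceParams:
    """Bayes-factor presence caller settings."""

    error_rate: float = 0.02
    f_min: float = 0.05
    bf_present: float = 10.0
    bf_absent: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error_rate must lie in (0, 0.5)")
        if not 0.0 < self.f_min < 1.0:
            raise ValueError("f_min must lie in (0, 1)")


def _fails(value, threshold, sense: str) -> bool:
    """True when ``value`` violates the threshold; missing values pass."""
    if value is None:
        return False
    if sense == "ge":
        return not value >= threshold
    if sense == "gt":
        return not value > threshold
    if sense == "lt":
        return not value < threshold
    raise AssertionError(sense)


def _strict_missing(record: VariantRecord, fields: Sequence[str]) -> bool:
    return any(getattr(record, f) is None for f in fields)


_QUALITY_RULES = (
    ("depth", "ge", "min_depth"),
    ("mapping_quality", "gt", "min_mq"),
    ("mean_read_position", "gt", "min_read_pos"),
    ("mean_mismatches", "lt", "max_mismatches"),
    ("microsatellite_length", "lt", "max_ms_length"),
    ("tlod", "gt", "min_tlod"),
    ("fs_phred", "lt", "max_fs"),
    ("vaf", "gt", "min_vaf"),
)


def apply_quality_filters(
    records: Iterable[VariantRecord],
    params: FilterParams | None = None,
    strict: bool = False,
) -> list[VariantRecord]:
    """Label records violating any read-level quality threshold.

    Records are labeled, never dropped.  A missing metric does not fail a
    record (upstream callers may not emit every field) unless ``strict``
    is set.
    """
    params = params or FilterParams()
    out = []
    for rec in records:
        fail = any(
            _fails(getattr(rec, attr), getattr(params, p), sense)
            for attr, sense, p in _QUALITY_RULES
        )
        if strict and _strict_missing(rec, [r[0] for r in _QUALITY_RULES]):
            fail = True
        if fail:
            rec.filter_labels.add("quality_fail")
        out.append(rec)
    return out


def _in_any_interval(
    chromosome: str, position: int, intervals: Iterable[tuple[str, int, int]]
) -> bool:
    """1-based position against 0-based half-open intervals."""
    for iv in intervals:
        if len(iv) != 3 or iv[1] > iv[2]:
            raise ValueError(f"malformed interval {iv!r}")
        chrom, start, end = iv
        if chrom == chromosome and start <= position - 1 < end:
            return True
    return False


def flag_germline(
    records: Iterable[VariantRecord],
    loh_segments: Sequence[tuple[str, int, int]] = (),
    params: FilterParams | None = None,
) -> list[VariantRecord]:
    """Label likely germline records.

    ``common_germline``: population AF above 1e-3 or seen in more than 9
    individuals — unless the gene is Cancer Gene Census tier 1 and the
    variant is in COSMIC or ClinVar (driver rescue).  ``vaf_germline``:
    VAF at or above 0.9 outside every supplied LOH interval.
    """
    params = params or FilterParams()
    out = []
    for rec in records:
        common = False
        if rec.population_af is not None and rec.population_af > params.max_pop_af:
            common = True
        if rec.population_count is not None and rec.population_count > params.max_pop_count:
            common = True
        if common and rec.cgc_tier1 and (rec.in_cosmic or rec.in_clinvar):
            common = False
        if common:
            rec.filter_labels.add("common_germline")
        if (
            rec.vaf is not None
            and rec.vaf >= params.germline_vaf
            and not _in_any_interval(rec.chromosome, rec.position, loh_segments)
        ):
            rec.filter_labels.add("vaf_germline")
        out.append(rec)
    return out


def apply_pon_filter(
    records: Iterable[VariantRecord],
    pon_patient_counts: Mapping[tuple[str, int, str, str], int] | None = None,
    params: FilterParams | None = None,
) -> list[VariantRecord]:
    """Label variants recurring in more than 2 pool-of-normal patients."""
    params = params or FilterParams()
    pon_patient_counts = pon_patient_counts or {}
    out = []
    for rec in records:
        if pon_patient_counts.get(rec.key, 0) > params.max_pon_patients:
            rec.filter_labels.add("pon")
        out.append(rec)
    return out


def rescue_hotspots(
    records: Iterable[VariantRecord],
    driver_genes: set[str] | frozenset[str],
    params: FilterParams | None = None,
) -> list[VariantRecord]:
    """Label recurrent COSMIC hotspots inside the driver-gene list.

    Rescued records survive the cascade regardless of ``common_germline``.
    """
    params = params or FilterParams()
    out = []
    for rec in records:
        if rec.cosmic_patient_count >= params.hotspot_min_patients and rec.gene in driver_genes:
            rec.filter_labels.add("rescued_hotspot")
        out.append(rec)
    return out


def somatic_pass(record: VariantRecord) -> bool:
    """Final cascade verdict as a pure function of the labels."""
    labels = record.filter_labels
    if {"quality_fail", "vaf_germline", "pon"} & labels:
        return False
    if "common_germline" in labels and "rescued_hotspot" not in labels:
        return False
    return True


def run_cascade(
    records: Iterable[VariantRecord],
    loh_segments: Sequence[tuple[str, int, int]] = (),
    pon_patient_counts: Mapping[tuple[str, int, str, str], int] | None = None,
    driver_genes: set[str] | frozenset[str] = frozenset(),
    params: FilterParams | None = None,
    strict: bool = False,
) -> list[VariantRecord]:
    """Apply all four filters, then stamp ``somatic_pass`` survivors."""
    params = params or FilterParams()
    recs = list(records)
    apply_quality_filters(recs, params, strict=strict)
    flag_germline(recs, loh_segments, params)
    apply_pon_filter(recs, pon_patient_counts, params)
    rescue_hotspots(recs, driver_genes, params)
    for rec in recs:
        if somatic_pass(rec):
            rec.filter_labels.add("somatic_pass")
        else:
            rec.filter_labels.discard("somatic_pass")
    return recs


# ---------------------------------------------------------------------------
# multi-region presence calling


def presence_bayes_factor(k: int, n: int, params: PresenceParams | None = None) -> float:
    """Bayes factor for variant presence from alt count ``k`` of depth ``n``.

    BF = [integral over f in (f_min, 1) of Binom(k; n, f) df]
         / Binom(k; n, e).

    The numerator has the closed form (1 - I_{f_min}(k+1, n-k+1))/(n+1)
    with I the regularized incomplete beta function.
    """
    params = params or PresenceParams()
    if n < 0 or k < 0:
        raise ValueError("negative count")
    if k > n:
        raise ValueError(f"alt count {k} exceeds depth {n}")
    if n == 0:
        return float("nan")
    log_num = math.log1p(-special.betainc(k + 1, n - k + 1, params.f_min)) - math.log(n + 1) \
        if special.betainc(k + 1, n - k + 1, params.f_min) < 1.0 else -math.inf
    log_den = stats.binom.logpmf(k, n, params.error_rate)
    return float(np.exp(log_num - log_den))


def call_presence(
    alt_counts: np.ndarray | Sequence[Sequence[int]],
    depths: np.ndarray | Sequence[Sequence[int]],
    params: PresenceParams | None = None,
) -> np.ndarray:
    """Presence matrix over regions x variants.

    Returns an object array of ``"present"`` / ``"absent"`` /
    ``"unknown"``.  A cell is present when its Bayes factor exceeds
    ``bf_present``, absent when below ``bf_absent``, unknown otherwise or
    when the position is uncovered (depth 0).
    """
    params = params or PresenceParams()
    k = np.asarray(alt_counts, dtype=int)
    n = np.asarray(depths, dtype=int)
    if k.shape != n.shape:
        raise ValueError("alt_counts and depths must share a shape")
    if np.any(k > n):
        raise ValueError("alt count exceeds depth")
    out = np.full(k.shape, "unknown", dtype=object)
    for idx in np.ndindex(k.shape):
        if n[idx] == 0:
            continue
        bf = presence_bayes_factor(int(k[idx]), int(n[idx]), params)
        if bf > params.bf_present:
            out[idx] = "present"
        elif bf < params.bf_absent:
            out[idx] = "absent"
    return out


# ---------------------------------------------------------------------------
# VCF / BED I/O

_INFO_FIELDS = [
    ("VAF", "vaf", "Float", "Variant allele fraction"),
    ("DP", "depth", "Integer", "Read depth"),
    ("MQ", "mapping_quality", "Float", "Mean mapping quality"),
    ("MPOS", "mean_read_position", "Float", "Mean position in read"),
    ("NM", "mean_mismatches", "Float", "Mean read mismatches"),
    ("MSILEN", "microsatellite_length", "Integer", "Microsatellite length"),
    ("TLOD", "tlod", "Float", "Tumor log odds"),
    ("FS", "fs_phred", "Float", "Phred-scaled strand bias"),
    ("POP_AF", "population_af", "Float", "Max population allele frequency"),
    ("POP_N", "population_count", "Integer", "Max population carrier count"),
    ("COSMIC_N", "cosmic_patient_count", "Integer", "COSMIC patient count"),
]
_INFO_FLAGS = [
    ("CGC1", "cgc_tier1", "Cancer Gene Census tier 1 gene"),
    ("COSMIC", "in_cosmic", "Variant present in COSMIC"),
    ("CLINVAR", "in_clinvar", "Variant present in ClinVar"),
]


def write_vcf(records: Sequence[VariantRecord], path: str) -> None:
    """Write records to an uncompressed VCF; labels go to FILTER."""
    import pysam

    header = pysam.VariantHeader()
    contigs = sorted({r.chromosome for r in records})
    for c in contigs:
        header.contigs.add(c)
    for label in FILTER_LABELS:
        if label != "somatic_pass":
            header.filters.add(label, None, None, f"dcisatlas cascade label {label}")
    for key, _, typ, desc in _INFO_FIELDS:
        header.info.add(key, 1, typ, desc)
    for key, _, desc in _INFO_FLAGS:
        header.info.add(key, 0, "Flag", desc)
    header.info.add("GENE", 1, "String", "Gene symbol")

    with pysam.VariantFile(path, "w", header=header) as vcf:
        for rec in records:
            row = vcf.new_record(
                contig=rec.chromosome,
                start=rec.position - 1,
                stop=rec.position - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
            )
            for key, attr, typ, _ in _INFO_FIELDS:
                value = getattr(rec, attr)
                if value is not None:
                    row.info[key] = value
            for key, attr, _ in _INFO_FLAGS:
                if getattr(rec, attr):
                    row.info[key] = True
            if rec.gene:
                row.info["GENE"] = rec.gene
            labels = rec.filter_labels - {"somatic_pass", "rescued_hotspot"}
            if labels:
                for label in sorted(labels):
                    row.filter.add(label)
            else:
                row.filter.add("PASS")
            vcf.write(row)


def read_vcf(path: str) -> list[VariantRecord]:
    """Read a VCF written by :func:`write_vcf` (or any VCF using its keys)."""
    import pysam

    out = []
    with pysam.VariantFile(path) as vcf:
        for row in vcf:
            rec = VariantRecord(
                chromosome=row.contig,
                position=row.pos,
                ref=row.ref,
                alt=row.alts[0] if row.alts else "",
            )
            info = row.info
            for key, attr, typ, _ in _INFO_FIELDS:
                if key in info:
                    value = info[key]
                    cast = int if typ == "Integer" else float
                    setattr(rec, attr, cast(value))
            for key, attr, _ in _INFO_FLAGS:
                setattr(rec, attr, key in info)
            if "GENE" in info:
                rec.gene = str(info["GENE"])
            rec.filter_labels = {f for f in row.filter.keys() if f != "PASS"}
            out.append(rec)
    return out


def read_bed_intervals(path: str) -> list[tuple[str, int, int]]:
    """Read BED (0-based half-open) intervals, e.g. LOH segments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            chrom, start, end, *_ = line.split("\t")
            out.append((chrom, int(start), int(end)))
    return out
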