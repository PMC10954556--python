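"""Selection of haplotype-diagnostic SNP markers from a variant table.

Variants called against the phased haplotype-1 assembly are filtered to
allelic SNPs usable as genotyping markers: high mapping quality, moderate
alternate-allele coverage and an allele frequency near 0.5, as expected for
a heterozygous site in pooled reads from a single heterozygous individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

__all__ = [
    "VariantRecord",
    "FilterSpec",
    "PhasedMarkerSet",
    "load_variants",
    "select_markers",
    "marker_spacing_stats",
]


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    mapping_quality: float
    alt_coverage: int
    allele_frequency: float
    is_indel: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(f"allele frequency outside [0,1]: {self.allele_frequency}")


@dataclass
class FilterSpec:
    """Marker-retention thresholds.

    Mapping quality is a strict lower bound (> min_mq); coverage and
    allele-frequency bounds are inclusive. Defaults reproduce the study's
    marker definition (MQ > 50, 5 <= alt coverage <= 30, 0.4 <= AF <= 0.6,
    SNPs only).
    """

    min_mq: float = 50.0
    min_alt_cov: int = 5
    max_alt_cov: int = 30
    min_af: float = 0.4
    max_af: float = 0.6
    snps_only: bool = True

    def keeps(self, v: VariantRecord) -> bool:
        if self.snps_only and v.is_indel:
            return False
        return (
            v.mapping_quality > self.min_mq
            and self.min_alt_cov <= v.alt_coverage <= self.max_alt_cov
            and self.min_af <= v.allele_frequency <= self.max_af
        )


@dataclass
class PhasedMarkerSet:
    """Ordered haplotype-diagnostic markers per chromosome.

    ``by_chrom[chrom]`` holds sorted unique 1-based ``pos`` with
    ``hap1``/``hap2`` allele arrays (``hap1`` = reference allele of the
    hap1 assembly, ``hap2`` = the diagnostic alternate).
    """

    by_chrom: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return sum(d["pos"].size for d in self.by_chrom.values())

    def positions(self, chrom: str) -> np.ndarray:
        if chrom not in self.by_chrom:
            return np.array([], dtype=np.int64)
        return self.by_chrom[chrom]["pos"]

    def validate(self) -> None:
        for chrom, d in self.by_chrom.items():
            pos = d["pos"]
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            if np.any(np.asarray(d["hap1"]) == np.asarray(d["hap2"])):
                raise ValueError(f"identical haplotype alleles on {chrom}")


def load_variants(
    path: str,
    *,
    mq_field: str = "MQ",
    alt_cov_field: str = "AO",
    af_field: str = "AF",
    expand_multiallelic: bool = False,
) -> list[VariantRecord]:
    """Read biallelic variant records from a VCF 4.x file.

    Mapping quality, alternate coverage and allele frequency are taken from
    the named INFO fields. Multiallelic sites are skipped by default (only
    allelic SNPs serve as haplotype markers) or expanded into one record
    per alternate allele; per-site INFO scalars are then shared.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(path) as vf:
        for i, rec in enumerate(vf):
            try:
                alts = rec.alts or ()
                if len(alts) == 0:
                    continue
                if len(alts) > 1 and not expand_multiallelic:
                    continue
                # absent INFO fields default to values that fail retention
                mq = float(_info_scalar(rec, mq_field, default=0.0))
                cov = int(_info_scalar(rec, alt_cov_field, default=0))
                af = float(_info_scalar(rec, af_field, default=0.0))
                for alt in alts:
                    records.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            mapping_quality=mq,
                            alt_coverage=cov,
                            allele_frequency=af,
                            is_indel=len(rec.ref) != 1 or len(alt) != 1,
                        )
                    )
            except (ValueError, TypeError, KeyError) as exc:
                raise ValueError(f"malformed VCF record #{i + 1} at {rec.chrom}:{rec.pos}: {exc}") from exc
    return records


def _info_scalar(rec, key: str, default):
    try:
        val = rec.info.get(key, default)
    except (KeyError, ValueError):  # key absent from the header
        return default
    if isinstance(val, (tuple, list)):
        val = val[0]
    return val


def select_markers(variants: list[VariantRecord], thresholds: FilterSpec | None = None) -> PhasedMarkerSet:
    """Apply the marker-retention predicate and assemble sorted markers.

    Idempotent; the output markers are a subset of the input sites.
    Duplicate positions (e.g. from expanded multiallelics) keep the first
    passing record.
    """
    spec = thresholds or FilterSpec()
    kept: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if spec.keeps(v):
            kept.setdefault(v.chrom, []).append(v)
    by_chrom = {}
    for chrom, vs in kept.items():
        vs.sort(key=lambda v: v.pos)
        pos, h1, h2 = [], [], []
        last = None
        for v in vs:
            if v.pos == last:
                continue
            last = v.pos
            pos.append(v.pos)
            h1.append(v.ref)
            h2.append(v.alt)
        by_chrom[chrom] = {
            "pos": np.array(pos, dtype=np.int64),
            "hap1": np.array(h1, dtype=object),
            "hap2": np.array(h2, dtype=object),
        }
    out = PhasedMarkerSet(by_chrom=by_chrom)
    out.validate()
    return out


def marker_spacing_stats(markers: PhasedMarkerSet, chrom_lengths: dict[str, int]) -> dict:
    """Genome-wide marker count, mean spacing and per-chromosome density.

    Mean spacing is defined as total chromosome length divided by marker
    count (so 1,000 markers on 449 kb gives 449 bp).
    """
    total_len = sum(chrom_lengths.values())
    n = markers.n_markers
    if n == 0:
        raise ValueError("no markers on any chromosome")
    per_chrom = {}
    for chrom, L in chrom_lengths.items():
        k = markers.positions(chrom).size
        per_chrom[chrom] = {
            "n_markers": int(k),
            "density_per_bp": k / L if L else 0.0,
            "mean_spacing_bp": (L / k) if k else np.inf,
        }
    return {
        "n_markers": int(n),
        "mean_spacing_bp": total_len / n,
        "per_chromosome": per_chrom,
    }
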