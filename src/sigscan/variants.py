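"""Somatic variant ingest, read-support filtering, and record model.

Somatic calls enter either as per-tumor VCFs (Mutect2-style, one tumor vs
matched normal) or as a flat TSV of pre-called substitutions.  Records are
normalized into :class:`MutationRecord` and passed through the read-support
filter used for whole-genome tumor calls: at least 3 reads supporting the
variant, at least 10 total reads at the site, variant allele frequency
strictly above 0.05, and no mitochondrial sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
import pysam

from .genome import GenomeSequence

logger = logging.getLogger(__name__)

_ALLELE_BASES = frozenset("ACGT")

#: Common aliases for the mitochondrial contig, excluded by default.
DEFAULT_MITO_CONTIGS = frozenset({"chrM", "MT", "M"})


@dataclass(frozen=True)
class MutationRecord:
    """One somatic substitution or indel with read support.

    ``position`` is 1-based, as in VCF.  Indels use the left-anchored VCF
    representation (shared first base).  ``vaf`` must equal
    ``alt_depth / total_depth`` when both depths are present.
    """

    sample_id: str
    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    alt_depth: int | None = None
    total_depth: int | None = None
    vaf: float | None = None

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        for allele in (self.ref_allele, self.alt_allele):
            if set(allele) - _ALLELE_BASES:
                raise ValueError(f"allele {allele!r} outside alphabet ACGT")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.alt_depth is not None and self.total_depth:
            if self.vaf is not None:
                if abs(self.vaf - self.alt_depth / self.total_depth) > 1e-9:
                    raise ValueError(
                        f"vaf {self.vaf} inconsistent with "
                        f"{self.alt_depth}/{self.total_depth}"
                    )

    @property
    def is_sbs(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)


@dataclass(frozen=True)
class FilterPolicy:
    """Read-support thresholds for somatic calls.

    The VAF comparison is strict (``vaf > min_vaf``), reading the "over
    0.05" rule literally; records at exactly the threshold are removed.
    """

    min_alt_reads: int = 3
    min_total_reads: int = 10
    min_vaf: float = 0.05
    exclude_contigs: frozenset[str] = DEFAULT_MITO_CONTIGS

    def __post_init__(self) -> None:
        if self.min_alt_reads < 0 or self.min_total_reads < 0:
            raise ValueError("read thresholds must be non-negative")
        if not 0 <= self.min_vaf < 1:
            raise ValueError("min_vaf must be in [0, 1)")


def read_vcf_somatic(path: str, sample_id: str) -> list[MutationRecord]:
    """Read somatic calls from a VCF, one record per ALT allele.

    Only FILTER-pass records (``PASS`` or ``.``) are kept; multi-allelic
    sites are split.  Depths come from the tumor sample's ``AD`` field.
    If the VCF carries a sample column named ``sample_id`` that column is
    used; otherwise a single-sample VCF's only column is used.  Records
    lacking both ``AD`` and ``AF`` get ``None`` depths and are flagged when
    a depth-requiring filter is later applied.
    """
    records: list[MutationRecord] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if sample_id in samples:
            column = sample_id
        elif len(samples) == 1:
            column = samples[0]
        elif not samples:
            column = None
        else:
            raise ValueError(
                f"{path}: multiple samples {samples} and none named {sample_id!r}"
            )
        last_pos: dict[str, int] = {}
        for rec in vcf:
            filters = set(rec.filter.keys())
            if filters and filters != {"PASS"}:
                continue
            if rec.contig in last_pos and rec.pos < last_pos[rec.contig]:
                logger.info("%s: unsorted input at %s:%d", path, rec.contig, rec.pos)
            last_pos[rec.contig] = rec.pos
            if rec.alts is None:
                continue
            ad = None
            if column is not None and "AD" in rec.format:
                ad = rec.samples[column].get("AD")
            for i, alt in enumerate(rec.alts):
                if alt is None or set(alt) - _ALLELE_BASES:
                    continue  # symbolic / spanning-deletion alleles
                alt_depth = total_depth = vaf = None
                if ad is not None and ad[0] is not None:
                    alt_depth = int(ad[i + 1])
                    total_depth = int(sum(d for d in ad if d is not None))
                    vaf = alt_depth / total_depth if total_depth else None
                elif column is not None and "AF" in rec.format:
                    af = rec.samples[column].get("AF")
                    if af is not None:
                        vaf = float(af[i] if isinstance(af, tuple) else af)
                records.append(
                    MutationRecord(
                        sample_id=sample_id,
                        contig=rec.contig,
                        position=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        alt_depth=alt_depth,
                        total_depth=total_depth,
                        vaf=vaf,
                    )
                )
    return records


def apply_filters(
    records: list[MutationRecord], policy: FilterPolicy | None = None
) -> list[MutationRecord]:
    """Keep records satisfying the read-support policy; order preserved.

    Removal counts per rule are logged.  A record lacking depth fields
    under a depth-requiring policy is an error: silent leniency would
    corrupt downstream burden comparisons.
    """
    policy = policy or FilterPolicy()
    kept: list[MutationRecord] = []
    removed = {"alt_reads": 0, "total_reads": 0, "vaf": 0, "contig": 0}
    for rec in records:
        if rec.contig in policy.exclude_contigs:
            removed["contig"] += 1
            continue
        needs_depth = policy.min_alt_reads > 0 or policy.min_total_reads > 0
        if needs_depth and (rec.alt_depth is None or rec.total_depth is None):
            raise ValueError(
                f"record {rec.contig}:{rec.position} {rec.ref_allele}>"
                f"{rec.alt_allele} lacks depth fields required by the policy"
            )
        if rec.alt_depth is not None and rec.alt_depth < policy.min_alt_reads:
            removed["alt_reads"] += 1
            continue
        if rec.total_depth is not None and rec.total_depth < policy.min_total_reads:
            removed["total_reads"] += 1
            continue
        vaf = rec.vaf
        if vaf is None and rec.alt_depth is not None and rec.total_depth:
            vaf = rec.alt_depth / rec.total_depth
        if vaf is None:
            raise ValueError(
                f"record {rec.contig}:{rec.position} lacks VAF under a "
                "VAF-requiring policy"
            )
        if not vaf > policy.min_vaf:
            if vaf == policy.min_vaf:
                logger.info(
                    "record %s:%d at VAF boundary %.4g removed (strict rule)",
                    rec.contig, rec.position, vaf,
                )
            removed["vaf"] += 1
            continue
        kept.append(rec)
    logger.info(
        "filters removed %d by alt reads, %d by total reads, %d by VAF, "
        "%d by contig exclusion (%d kept of %d)",
        removed["alt_reads"], removed["total_reads"], removed["vaf"],
        removed["contig"], len(kept), len(records),
    )
    return kept


_TSV_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "alt_depth", "total_depth"]


def read_records_tsv(path: str) -> list[MutationRecord]:
    """Read the TSV fallback format (columns: sample, chrom, pos, ref, alt,
    alt_depth, total_depth)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(_TSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        alt_depth = getattr(row, "alt_depth", None)
        total_depth = getattr(row, "total_depth", None)
        alt_depth = None if pd.isna(alt_depth) else int(alt_depth)
        total_depth = None if pd.isna(total_depth) else int(total_depth)
        vaf = alt_depth / total_depth if alt_depth is not None and total_depth else None
        records.append(
            MutationRecord(
                sample_id=str(row.sample),
                contig=str(row.chrom),
                position=int(row.pos),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                alt_depth=alt_depth,
                total_depth=total_depth,
                vaf=vaf,
            )
        )
    return records


def write_records_tsv(records: list[MutationRecord], path: str) -> None:
    rows = [
        {
            "sample": r.sample_id,
            "chrom": r.contig,
            "pos": r.position,
            "ref": r.ref_allele,
            "alt": r.alt_allele,
            "alt_depth": r.alt_depth,
            "total_depth": r.total_depth,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_vcf(
    records: list[MutationRecord],
    path: str,
    genome: GenomeSequence | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write records for one sample as a minimal VCF 4.2 file.

    Records must all carry the same ``sample_id``.  Output is plain text,
    position-sorted within the input contig order, with AD/DP per sample —
    sufficient for a lossless round trip through :func:`read_vcf_somatic`.
    """
    if not records:
        raise ValueError("no records to write")
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) > 1:
        raise ValueError(f"write_vcf writes one sample, got {sorted(sample_ids)}")
    sample_id = records[0].sample_id
    if contig_lengths is None:
        if genome is not None:
            contig_lengths = {c: genome.length(c) for c in genome}
        else:
            contig_lengths = {}
            for r in records:
                end = r.position + len(r.ref_allele) - 1
                contig_lengths[r.contig] = max(contig_lengths.get(r.contig, 0), end)
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(sample_id)
    order = {c: i for i, c in enumerate(contig_lengths)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (order[r.contig], r.position)):
            v = out.new_record(
                contig=rec.contig,
                start=rec.position - 1,
                alleles=(rec.ref_allele, rec.alt_allele),
            )
            v.samples[sample_id]["GT"] = (0, 1)
            if rec.alt_depth is not None and rec.total_depth is not None:
                v.samples[sample_id]["AD"] = (
                    rec.total_depth - rec.alt_depth,
                    rec.alt_depth,
                )
                v.samples[sample_id]["DP"] = rec.total_depth
            out.write(v)
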