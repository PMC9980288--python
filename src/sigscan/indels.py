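"""Insertion/deletion classification and per-sample indel spectra.

Indels up to 200 bp are binned by kind and net size — 1 bp events split
into T/A vs C/G by the affected base, sizes 2, 3, 4, and a 5+ category
covering 5-200 bp — with a microhomology flag on deletions of 2 bp and
larger.  Microhomology here means at least one base of identity between
the start of the deleted sequence and the reference immediately 3' of the
deletion junction, the hallmark of microhomology-mediated end joining.
This scheme is deliberately coarser than the 83-class indel catalog:
homopolymer/repeat-unit subclassification is not performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import pandas as pd

from .enrichment import EnrichmentResult, associate
from .genome import GenomeSequence
from .variants import MutationRecord

logger = logging.getLogger(__name__)

SIZE_CATEGORIES = ("1", "2", "3", "4", "5plus")
#: Indels longer than this are out of spectrum (tallied separately).
MAX_SPECTRUM_LENGTH = 200


class IndelClass(NamedTuple):
    kind: Literal["insertion", "deletion"]
    size_category: Literal["1", "2", "3", "4", "5plus"]
    one_bp_subtype: Literal["T/A", "C/G", "not_applicable"]
    microhomology: bool

    @property
    def label(self) -> str:
        base = "ins" if self.kind == "insertion" else "del"
        if self.size_category == "1":
            sub = "TA" if self.one_bp_subtype == "T/A" else "CG"
            return f"{base}_1_{sub}"
        suffix = "_mh" if self.microhomology else ""
        return f"{base}_{self.size_category}{suffix}"


def _all_classes() -> tuple[IndelClass, ...]:
    classes = []
    for kind in ("deletion", "insertion"):
        for sub in ("T/A", "C/G"):
            classes.append(IndelClass(kind, "1", sub, False))
        for size in ("2", "3", "4", "5plus"):
            classes.append(IndelClass(kind, size, "not_applicable", False))
            if kind == "deletion":
                classes.append(IndelClass(kind, size, "not_applicable", True))
    return tuple(classes)


ALL_INDEL_CLASSES: tuple[IndelClass, ...] = _all_classes()
ALL_INDEL_LABELS: tuple[str, ...] = tuple(c.label for c in ALL_INDEL_CLASSES)


def _size_category(size: int) -> str:
    return str(size) if size <= 4 else "5plus"


def classify_indel(
    m: MutationRecord, genome: GenomeSequence, mh_scan: int = 10
) -> IndelClass:
    """Classify a left-anchored indel record.

    Net length 0 (a balanced substitution) is an error.  Events longer
    than 200 bp are classified (5plus) but excluded from spectra by
    :func:`summarize_indels`.  Complex indels (both alleles > 1 base,
    unequal lengths) are classified by net length; their microhomology is
    not assessed.
    """
    if not m.is_indel:
        raise ValueError(
            f"{m.contig}:{m.position} {m.ref_allele}>{m.alt_allele} is not an indel"
        )
    ref, alt = m.ref_allele, m.alt_allele
    size = abs(len(ref) - len(alt))
    kind = "deletion" if len(ref) > len(alt) else "insertion"
    if size > MAX_SPECTRUM_LENGTH:
        logger.info(
            "indel at %s:%d has length %d > %d (out of spectrum)",
            m.contig, m.position, size, MAX_SPECTRUM_LENGTH,
        )
    # the run of bases gained/lost, for simple (anchored prefix) events
    longer, shorter = (ref, alt) if kind == "deletion" else (alt, ref)
    simple = longer.startswith(shorter)
    indel_seq = longer[len(shorter):] if simple else longer[1:]

    if size == 1:
        subtype = "T/A" if indel_seq[0] in "TA" else "C/G"
        return IndelClass(kind, "1", subtype, False)

    microhomology = False
    if kind == "deletion" and simple:
        # deleted bases occupy positions pos+len(alt) .. pos+len(alt)+size-1
        after_start = m.position + len(alt) + size
        following = genome.slice(
            m.contig, after_start, after_start + min(size, mh_scan) - 1
        )
        microhomology = len(following) > 0 and indel_seq[0] == following[0]
    return IndelClass(kind, _size_category(size), "not_applicable", microhomology)


@dataclass
class IndelSummary:
    """Per-sample counts over the indel classes (events <= 200 bp)."""

    sample_id: str
    counts: dict[str, int] = field(
        default_factory=lambda: {label: 0 for label in ALL_INDEL_LABELS}
    )
    over_200: int = 0

    def __post_init__(self) -> None:
        full = {label: int(self.counts.get(label, 0)) for label in ALL_INDEL_LABELS}
        extra = set(self.counts) - set(ALL_INDEL_LABELS)
        if extra:
            raise ValueError(f"unknown indel classes {sorted(extra)}")
        self.counts = full

    @property
    def total_under_200(self) -> int:
        return sum(self.counts.values())

    def as_series(self) -> pd.Series:
        s = pd.Series(self.counts, index=list(ALL_INDEL_LABELS), name=self.sample_id)
        s["total_under_200"] = self.total_under_200
        return s


def summarize_indels(
    records: Iterable[MutationRecord],
    genome: GenomeSequence,
    sample_id: str,
    mh_scan: int = 10,
) -> IndelSummary:
    """Count a sample's indels per class; >200 bp events tallied separately."""
    summary = IndelSummary(sample_id)
    for rec in records:
        if not rec.is_indel:
            continue
        cls = classify_indel(rec, genome, mh_scan)
        if abs(len(rec.ref_allele) - len(rec.alt_allele)) > MAX_SPECTRUM_LENGTH:
            summary.over_200 += 1
            continue
        summary.counts[cls.label] += 1
    return summary


def summaries_to_frame(summaries: Sequence[IndelSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_series() for s in summaries])


def indel_enrichment_association(
    summaries: Sequence[IndelSummary],
    scores: Sequence[EnrichmentResult],
    per_class: bool = True,
) -> pd.DataFrame:
    """Spearman association of indel class counts with enrichment scores.

    Rows: each indel class (when ``per_class``) plus the total under
    200 bp.  Samples must match one-to-one between inputs.
    """
    by_sample = {s.sample_id: s for s in summaries}
    score_ids = [r.sample_id for r in scores]
    unmatched = set(by_sample) ^ set(score_ids)
    if unmatched:
        raise ValueError(f"sample mismatch between summaries and scores: {sorted(unmatched)}")
    ordered = [by_sample[sid] for sid in score_ids]
    es = [r.score for r in scores]
    rows = []
    targets = list(ALL_INDEL_LABELS) if per_class else []
    for label in targets + ["total_under_200"]:
        if label == "total_under_200":
            counts = [s.total_under_200 for s in ordered]
        else:
            counts = [s.counts[label] for s in ordered]
        rho, p = associate(es, counts, method="spearman")
        rows.append({"class": label, "spearman_rho": rho, "p_value": p})
    return pd.DataFrame(rows)
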