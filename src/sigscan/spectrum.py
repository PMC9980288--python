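"""96-context single-base-substitution spectra.

Every substitution is expressed on the pyrimidine strand: events with a
purine reference are reverse-complemented together with their flanking
bases, so the 96 classes are the six pyrimidine substitutions (C>A, C>G,
C>T, T>A, T>C, T>G) crossed with the 16 combinations of 5' and 3' flank.
Flanks are always read from the reference genome, never from annotations
carried in the input files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

from .genome import GenomeSequence, reverse_complement
from .variants import MutationRecord

logger = logging.getLogger(__name__)

_PYRIMIDINE_SUBS = [
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
]
_BASES = "ACGT"


class SbsClass(NamedTuple):
    """One of the 96 pyrimidine-strand trinucleotide substitution classes."""

    five_prime: str
    ref: str
    alt: str
    three_prime: str

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.ref}>{self.alt}]{self.three_prime}"

    @classmethod
    def from_label(cls, label: str) -> "SbsClass":
        # format: X[R>A]Y
        if len(label) != 7 or label[1] != "[" or label[3] != ">" or label[5] != "]":
            raise ValueError(f"malformed SBS class label {label!r}")
        return cls(label[0], label[2], label[4], label[6])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

#: Canonical catalog ordering: substitutions C>A..T>G, flanks lexicographic.
SBS96_CLASSES: tuple[SbsClass, ...] = tuple(
    SbsClass(five, ref, alt, three)
    for ref, alt in _PYRIMIDINE_SUBS
    for five in _BASES
    for three in _BASES
)
SBS96_LABELS: tuple[str, ...] = tuple(c.label for c in SBS96_CLASSES)

#: The APOBEC-preferred TC-motif C>T classes (T[C>T]N).
TC_TO_TT_LABELS = frozenset(f"T[C>T]{b}" for b in _BASES)


class ReferenceMismatchError(ValueError):
    """The record's REF allele disagrees with the genome (wrong build?)."""


class ContextUnavailableError(ValueError):
    """Trinucleotide context cannot be determined (N flank or contig edge)."""


def classify_sbs(m: MutationRecord, genome: GenomeSequence) -> SbsClass:
    """Pyrimidine-strand trinucleotide class of a single-base substitution.

    Raises :class:`ReferenceMismatchError` if the genome base at the site
    differs from the record's REF, and :class:`ContextUnavailableError`
    when a flank is N or the site sits on a contig edge.
    """
    if not m.is_sbs:
        raise ValueError("classify_sbs requires a single-base substitution")
    ref_base = genome.base(m.contig, m.position)
    if ref_base != m.ref_allele:
        raise ReferenceMismatchError(
            f"{m.contig}:{m.position} genome has {ref_base}, record claims "
            f"{m.ref_allele} (check genome build)"
        )
    if m.position < 2 or m.position > genome.length(m.contig) - 1:
        raise ContextUnavailableError(
            f"{m.contig}:{m.position} has no full trinucleotide context"
        )
    tri = genome.slice(m.contig, m.position - 1, m.position + 1)
    alt = m.alt_allele
    if "N" in tri:
        raise ContextUnavailableError(
            f"{m.contig}:{m.position} context {tri} contains N"
        )
    if m.ref_allele in "AG":  # purine reference: flip to pyrimidine strand
        tri = reverse_complement(tri)
        alt = reverse_complement(alt)
    return SbsClass(tri[0], tri[1], alt, tri[2])


@dataclass
class Spectrum96:
    """Counts over the 96 substitution classes for one sample."""

    sample_id: str
    counts: dict[str, int] = field(
        default_factory=lambda: {label: 0 for label in SBS96_LABELS}
    )

    def __post_init__(self) -> None:
        full = {label: int(self.counts.get(label, 0)) for label in SBS96_LABELS}
        extra = set(self.counts) - set(SBS96_LABELS)
        if extra:
            raise ValueError(f"unknown SBS classes: {sorted(extra)[:3]}...")
        if any(v < 0 for v in full.values()):
            raise ValueError("negative class count")
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(SBS96_LABELS), name=self.sample_id)

    def scaled(self, k: int) -> "Spectrum96":
        return Spectrum96(self.sample_id, {c: v * k for c, v in self.counts.items()})


def build_spectrum(
    records: Iterable[MutationRecord],
    genome: GenomeSequence,
    sample_id: str,
) -> Spectrum96:
    """Build a per-sample 96-context spectrum from filtered records.

    Non-SBS records are skipped (count logged); SBS whose context contains
    N or sits on a contig edge are excluded rather than imputed.
    """
    counts = {label: 0 for label in SBS96_LABELS}
    skipped_non_sbs = skipped_context = 0
    for rec in records:
        if not rec.is_sbs:
            skipped_non_sbs += 1
            continue
        try:
            cls = classify_sbs(rec, genome)
        except ContextUnavailableError:
            skipped_context += 1
            continue
        counts[cls.label] += 1
    if skipped_non_sbs or skipped_context:
        logger.info(
            "spectrum %s: skipped %d non-SBS and %d context-less records",
            sample_id, skipped_non_sbs, skipped_context,
        )
    spectrum = Spectrum96(sample_id, counts)
    if spectrum.total == 0:
        logger.warning("spectrum %s is empty", sample_id)
    return spectrum


def tc_to_tt_fraction(
    records: Iterable[MutationRecord], genome: GenomeSequence
) -> float:
    """Fraction of classifiable SBS that are TC->TT (class T[C>T]N).

    Returns 0.0 (with a log flag) when there are no classifiable SBS.
    """
    num = den = 0
    for rec in records:
        if not rec.is_sbs:
            continue
        try:
            cls = classify_sbs(rec, genome)
        except ContextUnavailableError:
            continue
        den += 1
        if cls.label in TC_TO_TT_LABELS:
            num += 1
    if den == 0:
        logger.warning("tc_to_tt_fraction: no classifiable SBS; returning 0")
        return 0.0
    return num / den


def spectra_to_frame(spectra: Iterable[Spectrum96]) -> pd.DataFrame:
    """Wide matrix (samples x 96), columns in catalog order."""
    return pd.DataFrame([s.as_series() for s in spectra])


def write_spectrum_tsv(spectrum: Spectrum96, path: str) -> None:
    """96-row (class, count) table for one sample."""
    spectrum.as_series().rename_axis("class").rename("count").to_csv(path, sep="\t")


def write_spectra_matrix(spectra: Iterable[Spectrum96], path: str) -> None:
    spectra_to_frame(spectra).rename_axis("sample").to_csv(path, sep="\t")


def read_spectra_matrix(path: str) -> list[Spectrum96]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(SBS96_LABELS) - set(df.columns)
    if missing:
        raise ValueError(f"spectra matrix missing classes: {sorted(missing)[:3]}...")
    return [
        Spectrum96(str(sample), {c: int(df.at[sample, c]) for c in SBS96_LABELS})
        for sample in df.index
    ]
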