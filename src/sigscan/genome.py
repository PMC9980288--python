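"""Reference genome container and FASTA input.

The genome is held in memory as plain uppercase strings, one per contig.
This is adequate for the mouse-scale references this package targets when
restricted to the contigs actually analyzed, and for the synthetic genomes
used in testing; random access is by 1-based position throughout, matching
VCF coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """An ordered collection of named contig sequences.

    Parameters
    ----------
    contigs
        Mapping of contig name to uppercase nucleotide sequence over
        ``{A, C, G, T, N}``.  Every contig must be non-empty and names
        must be unique (guaranteed by dict semantics; enforced again by
        :func:`read_fasta` at parse time).
    """

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("contig name must be non-empty")
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            upper = seq.upper()
            bad = set(upper) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )
            self.contigs[name] = upper

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def base(self, contig: str, position: int) -> str:
        """Base at a 1-based position; total for 1 <= position <= length."""
        seq = self.contigs[contig]
        if not 1 <= position <= len(seq):
            raise IndexError(
                f"position {position} outside contig {contig!r} (length {len(seq)})"
            )
        return seq[position - 1]

    def slice(self, contig: str, start: int, end: int) -> str:
        """Subsequence covering 1-based inclusive positions [start, end].

        The range is truncated at the contig edges, so the returned string
        may be shorter than ``end - start + 1``.
        """
        seq = self.contigs[contig]
        return seq[max(start, 1) - 1 : min(end, len(seq))]

    def reverse_complemented(self) -> "GenomeSequence":
        """A new genome with every contig reverse-complemented."""
        return GenomeSequence(
            {name: reverse_complement(seq) for name, seq in self.contigs.items()}
        )


def read_fasta(path: str) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Contigs are keyed by the first whitespace-delimited token of each
    header and sequences are uppercased.  ``U`` (RNA) is rejected, as are
    duplicate contig names and files that do not start with a header line.
    """
    contigs: dict[str, str] = {}
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith(">"):
            raise FastaParseError(
                f"{path}: line 1 does not start a FASTA record: {first.strip()!r}"
            )
        handle.seek(0)
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0] if header.split() else ""
            if not name:
                raise FastaParseError(f"{path}: record with empty header")
            if name in contigs:
                raise FastaParseError(f"{path}: duplicate contig name {name!r}")
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FastaParseError(
                    f"{path}: contig {name!r} contains invalid characters "
                    f"{sorted(bad)} (RNA 'U' is not accepted)"
                )
            if not seq:
                raise FastaParseError(f"{path}: contig {name!r} has no sequence")
            contigs[name] = seq
    if not contigs:
        raise FastaParseError(f"{path}: no FASTA records found")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str, width: int = 70) -> None:
    """Write a genome to FASTA with fixed line width."""
    with open(path, "w") as handle:
        for name, seq in genome.contigs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
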