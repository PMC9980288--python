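"""APOBEC TCW fold-enrichment score with Fisher/BH inference.

The statistic asks whether a sample's mutated cytosines sit in the
APOBEC-preferred TCW motif (TCA/TCT; W = A or T) more often than the local
sequence context makes available.  For each retained substitution a 41-base
window (20 bases either side of the site) is extracted from the reference;
motif and cytosine counts are aggregated over all windows of the sample and

    enrichment = (Mut_TCW / Con_TCW) / (Mut_C / Con_C)

where Mut_TCW / Mut_C count mutated cytosines in/out of the motif and
Con_TCW / Con_C count motif and cytosine occurrences in the aggregated
windows.  Significance is a one-sided Fisher exact test on the 2x2 table
of these counts, BH-corrected across the cohort; samples with q < 0.1 are
called enrichment-high.

Retained substitutions are those surviving four rules: single-base
substitutions only, C:G reference base pairs only, no mitochondrial sites,
and no C-to-A events (G-to-T on the reference strand), which are not an
APOBEC product.  Windows of G-reference sites are reverse-complemented so
the motif is always counted on the strand presenting the mutated cytosine.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeSequence, reverse_complement
from .variants import DEFAULT_MITO_CONTIGS, MutationRecord

logger = logging.getLogger(__name__)

Motif = Literal["TCW", "TCA"]

#: 3' bases completing the motif, per motif mode.
_MOTIF_THREE_PRIME = {"TCW": frozenset("AT"), "TCA": frozenset("A")}


@dataclass(frozen=True)
class EnrichmentCounts:
    """The four aggregated counts behind the enrichment ratio."""

    mut_tcw: int
    mut_c: int
    con_tcw: int
    con_c: int

    def __post_init__(self) -> None:
        if not 0 <= self.mut_tcw <= self.mut_c:
            raise ValueError("need 0 <= mut_tcw <= mut_c")
        if not 0 <= self.con_tcw <= self.con_c:
            raise ValueError("need 0 <= con_tcw <= con_c")
        if self.mut_c > 0 and self.con_c == 0:
            raise ValueError("con_c must be positive when mutations are present")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-sample enrichment score with its Fisher/BH significance.

    ``score`` is NaN (and ``defined`` False) for samples with no retained
    mutated cytosines; such samples are excluded from BH correction and
    always classed low.  ``es_class`` is set cohort-wide by
    :func:`classify_es` once q-values exist.
    """

    sample_id: str
    counts: EnrichmentCounts
    score: float
    p_value: float
    q_value: float | None = None
    es_class: Literal["high", "low"] | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.score)


def filter_for_enrichment(
    records: Iterable[MutationRecord],
    exclude_contigs: frozenset[str] = DEFAULT_MITO_CONTIGS,
) -> list[MutationRecord]:
    """Apply the four organizing rules for the enrichment analysis.

    Keeps single-base substitutions at C or G reference bases, off the
    mitochondrial contigs, excluding pyrimidine-strand C>A (hence also
    G>T).  Retained events are exactly C>T, C>G, G>A, G>C.
    """
    kept = []
    removed = {"non_sbs": 0, "non_cg": 0, "mito": 0, "c_to_a": 0}
    for rec in records:
        if not rec.is_sbs:
            removed["non_sbs"] += 1
            continue
        if rec.ref_allele not in "CG":
            removed["non_cg"] += 1
            continue
        if rec.contig in exclude_contigs:
            removed["mito"] += 1
            continue
        pair = (rec.ref_allele, rec.alt_allele)
        if pair == ("C", "A") or pair == ("G", "T"):
            removed["c_to_a"] += 1
            continue
        kept.append(rec)
    logger.info(
        "enrichment filter removed %d non-SBS, %d non-C:G, %d mitochondrial, "
        "%d C>A (%d kept)",
        removed["non_sbs"], removed["non_cg"], removed["mito"],
        removed["c_to_a"], len(kept),
    )
    return kept


def window_context(
    m: MutationRecord, genome: GenomeSequence, half_width: int = 20
) -> str:
    """Reference window of ``half_width`` bases either side of the site.

    Truncated at contig edges (shorter windows are used as-is).  Windows
    of G-reference sites are reverse-complemented so the mutated base is
    presented as C on the analyzed strand.
    """
    window = genome.slice(m.contig, m.position - half_width, m.position + half_width)
    if len(window) < 2 * half_width + 1:
        logger.debug(
            "window at %s:%d truncated to %d bases", m.contig, m.position, len(window)
        )
    if m.ref_allele == "G":
        window = reverse_complement(window)
    return window


def count_motifs(window: str, motif: Motif = "TCW") -> tuple[int, int]:
    """(motif count, cytosine count) on the presented strand of a window.

    The motif is counted at cytosine-centered positions (window[i-1..i+1]
    equal to TCA/TCT for TCW mode); N never matches.
    """
    three_prime = _MOTIF_THREE_PRIME[motif]
    c = window.count("C")
    tcw = sum(
        1
        for i in range(1, len(window) - 1)
        if window[i] == "C" and window[i - 1] == "T" and window[i + 1] in three_prime
    )
    return tcw, c


def _is_motif_site(m: MutationRecord, genome: GenomeSequence, motif: Motif) -> bool:
    """Whether the mutated cytosine's strand-oriented trinucleotide is TCW.

    Sites on contig edges (missing a flank) cannot complete the motif and
    count as non-TCW.
    """
    if m.position < 2 or m.position > genome.length(m.contig) - 1:
        return False
    tri = genome.slice(m.contig, m.position - 1, m.position + 1)
    if m.ref_allele == "G":
        tri = reverse_complement(tri)
    return tri[0] == "T" and tri[1] == "C" and tri[2] in _MOTIF_THREE_PRIME[motif]


def enrichment_score(
    records: Sequence[MutationRecord],
    genome: GenomeSequence,
    half_width: int = 20,
    motif: Motif = "TCW",
    sample_id: str | None = None,
) -> EnrichmentResult:
    """Aggregate one sample's counts and compute score and Fisher p-value.

    ``records`` must already have passed :func:`filter_for_enrichment`.
    The q-value is left unset; apply :func:`bh_adjust` /
    :func:`classify_es` cohort-wide.
    """
    if sample_id is None:
        sample_id = records[0].sample_id if records else "sample"
    mut_tcw = mut_c = con_tcw = con_c = 0
    for rec in records:
        mut_c += 1
        if _is_motif_site(rec, genome, motif):
            mut_tcw += 1
        w_tcw, w_c = count_motifs(window_context(rec, genome, half_width), motif)
        con_tcw += w_tcw
        con_c += w_c
    counts = EnrichmentCounts(mut_tcw, mut_c, con_tcw, con_c)
    if mut_c == 0:
        logger.warning("sample %s has no retained mutated cytosines", sample_id)
        return EnrichmentResult(sample_id, counts, float("nan"), 1.0)
    if con_tcw == 0 and mut_tcw > 0:
        raise RuntimeError(
                f"sample {sample_id}: mut_tcw={mut_tcw} but no motif in any "
            "window — windows must contain their own site's motif; "
            "this indicates a context bug"
        )
    return EnrichmentResult(
        sample_id, counts, score_from_counts(counts), fisher_one_sided(counts)
    )


def score_from_counts(counts: EnrichmentCounts) -> float:
    """The fold-enrichment ratio of ratios, (Mut_TCW/Con_TCW)/(Mut_C/Con_C)."""
    if counts.mut_c == 0 or counts.con_c == 0:
        return float("nan")
    if counts.con_tcw == 0:
        return 0.0
    return (counts.mut_tcw / counts.con_tcw) / (counts.mut_c / counts.con_c)


def fisher_one_sided(counts: EnrichmentCounts) -> float:
    """One-sided (greater) Fisher exact p for motif enrichment.

    Tests the 2x2 table [[mut_tcw, mut_c - mut_tcw],
    [con_tcw, con_c - con_tcw]] against the alternative that mutations
    favor the motif more than context availability does.
    """
    table = [
        [counts.mut_tcw, counts.mut_c - counts.mut_tcw],
        [counts.con_tcw, counts.con_c - counts.con_tcw],
    ]
    if any(cell < 0 for row in table for cell in row):
        raise ValueError(f"negative cell in Fisher table {table}")
    return float(stats.fisher_exact(table, alternative="greater")[1])


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def attach_q_values(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """BH-correct the defined samples' p-values across one cohort.

    The correction family is all defined samples in ``results``; samples
    with undefined scores keep ``q_value=None``.
    """
    defined = [r for r in results if r.defined]
    q = bh_adjust([r.p_value for r in defined]) if defined else []
    q_map = {id(r): qv for r, qv in zip(defined, q)}
    return [replace(r, q_value=q_map.get(id(r))) for r in results]


def classify_es(
    results: Sequence[EnrichmentResult], q_threshold: float = 0.1
) -> list[EnrichmentResult]:
    """Dichotomize samples: enrichment-high iff q < threshold (strict).

    Undefined-score samples are classed low.  A defined sample without a
    q-value is an error — the cohort correction was skipped.
    """
    out = []
    n_high = 0
    for r in results:
        if not r.defined:
            out.append(replace(r, es_class="low"))
            continue
        if r.q_value is None:
            raise ValueError(f"sample {r.sample_id} has no q-value; run attach_q_values")
        high = r.q_value < q_threshold
        n_high += high
        out.append(replace(r, es_class="high" if high else "low"))
    logger.info("classified %d/%d samples enrichment-high", n_high, len(out))
    return out


def cohort_enrichment(
    records_by_sample: dict[str, Sequence[MutationRecord]],
    genome: GenomeSequence,
    half_width: int = 20,
    motif: Motif = "TCW",
    q_threshold: float = 0.1,
    prefiltered: bool = False,
) -> list[EnrichmentResult]:
    """Score every sample, BH-correct across the cohort, and classify.

    ``prefiltered`` skips :func:`filter_for_enrichment` when records were
    already reduced to the retained substitution classes.
    """
    results = []
    for sample_id, records in records_by_sample.items():
        recs = list(records) if prefiltered else filter_for_enrichment(records)
        results.append(
            enrichment_score(recs, genome, half_width, motif, sample_id=sample_id)
        )
    return classify_es(attach_q_values(results), q_threshold)


def associate(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    Used for enrichment score vs expression, indel counts, or mutation
    burden.  Zero variance in either vector yields (nan, nan) with a log
    flag rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance input: correlation undefined")
        return float("nan"), float("nan")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction.

    The group comparison used for non-normally distributed per-sample
    quantities (e.g. structural-variation counts in enrichment-high vs
    -low samples).
    """
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(values_a, values_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
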