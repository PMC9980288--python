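"""Synthetic cohorts with planted, recoverable APOBEC signal.

Every analysis stage in this package has a matching generator here, so the
pipeline can be validated end to end by parameter recovery with no
external data.  A cohort consists of:

* a random multi-contig genome of controllable base composition;
* per-sample somatic SBS sets mixing a uniform background process with an
  APOBEC process confined to strand-oriented TCW cytosines (C>T with
  probability ``apobec_ct_cg_split``, else C>G), at a controllable
  mixing fraction — the quantity the enrichment score estimates;
* indel sets (1-200 bp) drawn from a controllable length distribution,
  optionally with a rate coupled to the sample's APOBEC fraction;
* a replication-timing track tiling the genome so the five quintiles have
  geometric mutation-attraction weights (1, r, r^2, r^3, r^4).

Background SBS are uniform over sites: the enrichment score's null
depends only on context proportions, and uniform placement keeps the
closed-form expectation exact.  The default ``apobec_ct_cg_split`` of 1
emulates a pure C>T (SBS2-like, no SBS13) process; set 0.5 for classic
joint SBS2/SBS13 cohorts.  Read-support fields are synthesized (depth 50,
VAF uniform on [0.1, 0.5]) so filter logic is exercised, not bypassed.
All generators are deterministic given their seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSequence, write_fasta
from .refit import SignatureCatalog
from .spectrum import SBS96_LABELS
from .timing import TimingInterval, TimingTrack, quintilize, write_timing_bed
from .variants import MutationRecord, write_vcf

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(b) for b in "ACGT")


@dataclass
class SyntheticCohortConfig:
    """All parameters of the planted-signal simulation.

    ``apobec_fraction`` may be a scalar (shared by all samples) or one
    value per sample.  ``timing_bias_ratio`` r < 1 concentrates mutations
    in early-replicating quintiles with weights (1, r, r^2, r^3, r^4);
    r = 1 is unbiased.
    """

    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 250_000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_samples: int = 20
    sbs_per_sample: int = 2000
    apobec_fraction: float | Sequence[float] = 0.0
    apobec_ct_cg_split: float = 1.0
    indels_per_sample: int = 100
    indel_length_distribution: dict[str, float] = field(
        default_factory=lambda: {"1": 0.6, "2": 0.15, "3": 0.08, "4": 0.05, "5plus": 0.12}
    )
    timing_bias_ratio: float = 1.0
    indel_rate_couples_to_apobec: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if any(not 0 <= p <= 1 for p in self.base_composition):
            raise ValueError("base_composition entries must be in [0, 1]")
        if abs(sum(self.indel_length_distribution.values()) - 1) > 1e-9:
            raise ValueError("indel_length_distribution must sum to 1")
        if not 0 <= self.apobec_ct_cg_split <= 1:
            raise ValueError("apobec_ct_cg_split must be in [0, 1]")
        if self.timing_bias_ratio <= 0:
            raise ValueError("timing_bias_ratio must be positive")
        for f in self.sample_fractions():
            if not 0 <= f <= 1:
                raise ValueError("apobec_fraction values must be in [0, 1]")

    def sample_fractions(self) -> list[float]:
        if isinstance(self.apobec_fraction, (int, float)):
            return [float(self.apobec_fraction)] * self.n_samples
        fractions = list(self.apobec_fraction)
        if len(fractions) != self.n_samples:
            raise ValueError(
                f"apobec_fraction vector length {len(fractions)} != "
                f"n_samples {self.n_samples}"
            )
        return [float(f) for f in fractions]


class GenomeIndex:
    """Numpy view of a genome with global 0-based site indexing.

    Precomputes the site classes the generators sample from: all sites,
    C/G sites, and strand-oriented TCW cytosine sites (plus-strand TCA/TCT
    centers and their reverse complements, minus-strand G centers in
    TGA/AGA plus-strand context).
    """

    def __init__(self, genome: GenomeSequence):
        self.genome = genome
        self.names = list(genome.contigs)
        self.offsets: dict[str, int] = {}
        arrays = []
        offset = 0
        for name in self.names:
            self.offsets[name] = offset
            arr = np.frombuffer(genome.contigs[name].encode(), dtype=np.uint8)
            arrays.append(arr)
            offset += len(arr)
        self.seq = np.concatenate(arrays)
        self.total_length = offset
        self._bounds = np.array(
            [self.offsets[n] for n in self.names] + [offset], dtype=np.int64
        )
        # per-contig TCW masks to avoid motifs straddling contig joins
        tcw_parts = []
        for name, arr in zip(self.names, arrays):
            base = self.offsets[name]
            if len(arr) < 3:
                continue
            left, center, right = arr[:-2], arr[1:-1], arr[2:]
            plus = (center == _C) & (left == _T) & ((right == _A) | (right == _T))
            minus = (center == _G) & (right == _A) & ((left == _T) | (left == _A))
            (idx,) = np.nonzero(plus | minus)
            tcw_parts.append(idx + 1 + base)
        self.tcw_sites = (
            np.concatenate(tcw_parts) if tcw_parts else np.empty(0, dtype=np.int64)
        )

    def to_site(self, global_index: int) -> tuple[str, int]:
        """(contig, 1-based position) of a global 0-based index."""
        i = int(np.searchsorted(self._bounds, global_index, side="right") - 1)
        name = self.names[i]
        return name, int(global_index - self.offsets[name] + 1)

    def base_at(self, global_index: int) -> str:
        return chr(self.seq[global_index])


def generate_genome(config: SyntheticCohortConfig) -> GenomeSequence:
    """I.i.d. random genome from the config's composition and seed."""
    rng = np.random.default_rng(config.seed)
    contigs = {}
    for i in range(config.n_contigs):
        draws = rng.choice(_BASES, size=config.contig_length, p=config.base_composition)
        contigs[f"c{i + 1}"] = draws.tobytes().decode()
    return GenomeSequence(contigs)


def _synthesize_support(rng: np.random.Generator) -> tuple[int, int, float]:
    vaf = rng.uniform(0.1, 0.5)
    alt = int(round(vaf * 50))
    return alt, 50, alt / 50


def _choose(
    rng: np.random.Generator,
    candidates: np.ndarray,
    n: int,
    site_weights: np.ndarray | None,
) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if len(candidates) < n:
        raise ValueError(
            f"need {n} sites but only {len(candidates)} are eligible "
            f"(deficit {n - len(candidates)})"
        )
    if site_weights is None:
        return rng.choice(candidates, size=n, replace=False)
    w = site_weights[candidates].astype(float)
    return rng.choice(candidates, size=n, replace=False, p=w / w.sum())


def spawn_sbs(
    genome: GenomeSequence | GenomeIndex,
    n: int,
    apobec_fraction: float,
    ct_cg_split: float,
    seed: int,
    sample_id: str = "S1",
    site_weights: np.ndarray | None = None,
) -> list[MutationRecord]:
    """Plant ``round(n * apobec_fraction)`` APOBEC events at TCW cytosines
    and fill the rest with uniform background substitutions.

    APOBEC events are C>T with probability ``ct_cg_split``, else C>G
    (G>A / G>C on minus-strand sites).  Background events draw a uniform
    non-reference alternate.  ``site_weights`` (per global position)
    biases both processes, e.g. toward early-replicating tiles.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    rng = np.random.default_rng(seed)
    n_apobec = int(round(n * apobec_fraction))
    if n_apobec > 0 and len(index.tcw_sites) == 0:
        raise ValueError("genome has no TCW sites; cannot plant APOBEC events")
    apobec_idx = _choose(rng, index.tcw_sites, n_apobec, site_weights)
    taken = set(apobec_idx.tolist())
    background_idx: list[int] = []
    n_background = n - n_apobec
    all_sites = np.arange(index.total_length)
    for _ in range(20):  # redraw collisions, deterministically bounded
        need = n_background - len(background_idx)
        if need == 0:
            break
        draw = _choose(rng, all_sites, need, site_weights)
        for g in draw.tolist():
            if g not in taken:
                taken.add(g)
                background_idx.append(g)
    else:
        raise RuntimeError("could not place background mutations without collision")

    records = []
    for g in apobec_idx.tolist():
        contig, pos = index.to_site(g)
        ref = index.base_at(g)
        ct = rng.random() < ct_cg_split
        alt = ("T" if ct else "G") if ref == "C" else ("A" if ct else "C")
        alt_depth, total, vaf = _synthesize_support(rng)
        records.append(
            MutationRecord(sample_id, contig, pos, ref, alt, alt_depth, total, vaf)
        )
    for g in background_idx:
        contig, pos = index.to_site(g)
        ref = index.base_at(g)
        others = [b for b in "ACGT" if b != ref]
        alt = others[rng.integers(3)]
        alt_depth, total, vaf = _synthesize_support(rng)
        records.append(
            MutationRecord(sample_id, contig, pos, ref, alt, alt_depth, total, vaf)
        )
    return records


_SIZE_CHOICES = ("1", "2", "3", "4", "5plus")


def spawn_indels(
    genome: GenomeSequence | GenomeIndex,
    n: int,
    length_distribution: dict[str, float],
    seed: int,
    sample_id: str = "S1",
    return_truth: bool = False,
):
    """Uniformly placed insertions/deletions with lengths drawn per
    category (5plus uniform on 5-200).

    With ``return_truth`` the drawn (kind, size category) per event is
    returned alongside, for generator-classifier round-trip checks.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    rng = np.random.default_rng(seed)
    cats = [c for c in _SIZE_CHOICES if length_distribution.get(c, 0) > 0]
    probs = np.array([length_distribution[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    lengths = {c: len(index.genome.contigs[c]) for c in index.genome.contigs}
    contig_names = list(lengths)
    contig_p = np.array([lengths[c] for c in contig_names], dtype=float)
    contig_p = contig_p / contig_p.sum()
    composition = np.array([0.25] * 4)

    records, truth = [], []
    for _ in range(n):
        category = cats[rng.choice(len(cats), p=probs)]
        size = int(category) if category != "5plus" else int(rng.integers(5, 201))
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        contig = contig_names[rng.choice(len(contig_names), p=contig_p)]
        L = lengths[contig]
        if kind == "deletion":
            if L < size + 1:
                raise ValueError(f"contig {contig} too short for a {size} bp deletion")
            pos = int(rng.integers(1, L - size + 1))  # anchor; deletion fits
            ref = index.genome.slice(contig, pos, pos + size)
            alt = ref[0]
        else:
            pos = int(rng.integers(1, L + 1))
            ref = index.genome.base(contig, pos)
            inserted = rng.choice(_BASES, size=size, p=composition).tobytes().decode()
            alt = ref + inserted
        alt_depth, total, vaf = _synthesize_support(rng)
        records.append(
            MutationRecord(sample_id, contig, pos, ref, alt, alt_depth, total, vaf)
        )
        truth.append((kind, category))
    if return_truth:
        return records, truth
    return records


def generate_timing_track(
    genome: GenomeSequence,
    window: int,
    bias_ratio: float,
    seed: int,
) -> TimingTrack:
    """Tile the genome and assign timing values inducing equal-coverage
    quintiles with planted attraction weights (1, r, r^2, r^3, r^4).

    The returned track carries continuous values (smaller = earlier);
    :func:`sigscan.timing.quintilize` recovers the planted quintiles.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rng = np.random.default_rng(seed)
    tiles = []
    for contig, seq in genome.contigs.items():
        for start in range(0, len(seq), window):
            tiles.append((contig, start, min(start + window, len(seq))))
    n = len(tiles)
    order = rng.permutation(n)
    intervals = []
    for rank, tile_i in enumerate(order):
        quintile = (rank * 5) // n + 1
        contig, start, end = tiles[tile_i]
        value = (quintile - 1) + rng.uniform(0.05, 0.95)
        intervals.append(TimingInterval(contig, start, end, value))
    return TimingTrack(sorted(intervals, key=lambda iv: (iv.contig, iv.start)))


def timing_site_weights(
    index: GenomeIndex, labeled_track: TimingTrack, bias_ratio: float
) -> np.ndarray:
    """Per-global-position attraction weights r^(quintile - 1)."""
    weights = np.ones(index.total_length)
    for iv in labeled_track.intervals:
        base = index.offsets[iv.contig]
        weights[base + iv.start : base + iv.end] = bias_ratio ** (iv.value - 1)
    return weights


@dataclass
class SyntheticCohort:
    """A complete synthetic study with its planted truth."""

    config: SyntheticCohortConfig
    genome: GenomeSequence
    track: TimingTrack
    sbs_by_sample: dict[str, list[MutationRecord]]
    indels_by_sample: dict[str, list[MutationRecord]]
    truth: pd.DataFrame
    paths: dict[str, str] = field(default_factory=dict)

    def records_by_sample(self) -> dict[str, list[MutationRecord]]:
        return {
            sid: self.sbs_by_sample[sid] + self.indels_by_sample[sid]
            for sid in self.sbs_by_sample
        }


def _derive_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(
    config: SyntheticCohortConfig, out_dir: str | None = None
) -> SyntheticCohort:
    """Emit a complete synthetic study: genome, per-sample mutation sets,
    timing track, and a truth table of planted parameters.

    With ``out_dir`` the study is also written as FASTA + one VCF per
    sample + BED + truth TSV, so the shell pipeline runs end to end with
    no external data; outputs are byte-stable under a fixed seed.
    """
    root = np.random.SeedSequence(config.seed)
    track_seq, *sample_seqs = root.spawn(1 + config.n_samples)
    genome = generate_genome(config)
    index = GenomeIndex(genome)
    track = generate_timing_track(
        genome,
        window=max(1, config.contig_length // 100),
        bias_ratio=config.timing_bias_ratio,
        seed=_derive_seed(track_seq),
    )
    weights = None
    if config.timing_bias_ratio != 1.0:
        weights = timing_site_weights(index, quintilize(track), config.timing_bias_ratio)

    fractions = config.sample_fractions()
    sbs_by_sample: dict[str, list[MutationRecord]] = {}
    indels_by_sample: dict[str, list[MutationRecord]] = {}
    rows = []
    for i, (fraction, seq) in enumerate(zip(fractions, sample_seqs)):
        sample_id = f"S{i + 1:02d}"
        sbs_seed_seq, indel_seed_seq = seq.spawn(2)
        sbs_by_sample[sample_id] = spawn_sbs(
            index,
            config.sbs_per_sample,
            fraction,
            config.apobec_ct_cg_split,
            seed=_derive_seed(sbs_seed_seq),
            sample_id=sample_id,
            site_weights=weights,
        )
        n_indels = config.indels_per_sample
        if config.indel_rate_couples_to_apobec:
            n_indels = int(round(n_indels * (1 + 2 * fraction)))
        indels_by_sample[sample_id] = spawn_indels(
            index,
            n_indels,
            config.indel_length_distribution,
            seed=_derive_seed(indel_seed_seq),
            sample_id=sample_id,
        )
        rows.append(
            {
                "sample": sample_id,
                "group": "apobec" if fraction > 0 else "background",
                "apobec_fraction": fraction,
                "ct_cg_split": config.apobec_ct_cg_split,
                "n_sbs": config.sbs_per_sample,
                "n_indels": n_indels,
                "timing_bias_ratio": config.timing_bias_ratio,
            }
        )
    truth = pd.DataFrame(rows)

    cohort = SyntheticCohort(
        config=config,
        genome=genome,
        track=track,
        sbs_by_sample=sbs_by_sample,
        indels_by_sample=indels_by_sample,
        truth=truth,
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "genome": os.path.join(out_dir, "genome.fa"),
            "track": os.path.join(out_dir, "timing.bed"),
            "truth": os.path.join(out_dir, "truth.tsv"),
            "manifest": os.path.join(out_dir, "manifest.tsv"),
        }
        write_fasta(genome, paths["genome"])
        write_timing_bed(track, paths["track"])
        truth.to_csv(paths["truth"], sep="\t", index=False)
        manifest_rows = []
        for sample_id in sbs_by_sample:
            vcf_path = os.path.join(out_dir, f"{sample_id}.vcf")
            write_vcf(
                sbs_by_sample[sample_id] + indels_by_sample[sample_id],
                vcf_path,
                genome=genome,
            )
            paths[sample_id] = vcf_path
            group = truth.loc[truth["sample"] == sample_id, "group"].iloc[0]
            manifest_rows.append(
                {"sample": sample_id, "group": group, "vcf": vcf_path}
            )
        pd.DataFrame(manifest_rows).to_csv(paths["manifest"], sep="\t", index=False)
        cohort.paths = paths
    return cohort


def expected_enrichment_score(
    index: GenomeIndex,
    apobec_fraction: float,
    n: int,
    half_width: int = 20,
) -> float:
    """Closed-form expectation of the enrichment score for a planted sample.

    Computed by exhaustive site enumeration over the genome, independently
    of the per-record window machinery: window motif/cytosine counts come
    from cumulative-sum arrays over every cytosine-presenting site.  For a
    sample of ``n`` substitutions with planted fraction ``f``, the
    ``round(n f)`` APOBEC events sit at TCW sites (always motif-mutated);
    background events are uniform over all sites, survive the organizing
    rules iff they hit a C:G base with a non-C>A alternate (probability
    2/3 given a C:G site), and are then uniform over C:G sites.  The
    expectation composes the per-class mean window counts with these
    weights and evaluates the ratio of ratios on the expected aggregates.
    """
    hw = half_width
    n_apobec = int(round(n * apobec_fraction))
    n_background = n - n_apobec

    # accumulated over site classes: [0] = TCW sites, [1] = all C:G sites
    win_motif = [0.0, 0.0]
    win_cyt = [0.0, 0.0]
    n_sites = [0, 0]
    n_tcw_total = 0
    n_cg_total = 0

    for name in index.names:
        seq = index.genome.contigs[name]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        L = len(arr)
        is_c = arr == _C
        is_g = arr == _G
        plus_center = np.zeros(L, dtype=bool)
        minus_center = np.zeros(L, dtype=bool)
        if L >= 3:
            left, center, right = arr[:-2], arr[1:-1], arr[2:]
            plus = (center == _C) & (left == _T) & ((right == _A) | (right == _T))
            minus = (center == _G) & (right == _A) & ((left == _T) | (left == _A))
            plus_center[1:-1] = plus
            minus_center[1:-1] = minus
        cum = {
            "c": np.concatenate(([0], np.cumsum(is_c))),
            "g": np.concatenate(([0], np.cumsum(is_g))),
            "p": np.concatenate(([0], np.cumsum(plus_center))),
            "m": np.concatenate(([0], np.cumsum(minus_center))),
        }

        def window_sums(sites: np.ndarray, base_key: str, motif_key: str):
            """Per-site window (cytosine, motif) counts on the presented
            strand, truncated at contig edges like the real windows."""
            start = np.maximum(sites - hw, 0)
            end = np.minimum(sites + hw, L - 1)
            cyt = cum[base_key][end + 1] - cum[base_key][start]
            # a motif counts iff it lies fully inside the window
            mstart = np.maximum(sites - (hw - 1), 0)
            mend = np.minimum(sites + (hw - 1), L - 1)
            motif = cum[motif_key][mend + 1] - cum[motif_key][mstart]
            return cyt, motif

        for mask, base_key, motif_key in (
            (is_c, "c", "p"),  # C-reference sites: plus-strand window
            (is_g, "g", "m"),  # G-reference sites: reverse-complement window
        ):
            sites = np.nonzero(mask)[0]
            if len(sites) == 0:
                continue
            cyt, motif = window_sums(sites, base_key, motif_key)
            tcw_mask = (plus_center | minus_center)[sites]
            win_cyt[0] += float(cyt[tcw_mask].sum())
            win_motif[0] += float(motif[tcw_mask].sum())
            n_sites[0] += int(tcw_mask.sum())
            win_cyt[1] += float(cyt.sum())
            win_motif[1] += float(motif.sum())
            n_sites[1] += len(sites)
            n_tcw_total += int(tcw_mask.sum())
            n_cg_total += len(sites)

    L_total = index.total_length
    # expected retained background events and their class composition
    bg_retained = n_background * (n_cg_total / L_total) * (2 / 3)
    bg_tcw = n_background * (n_tcw_total / L_total) * (2 / 3)
    e_mut_c = n_apobec + bg_retained
    e_mut_tcw = n_apobec + bg_tcw
    e_con_c = (
        n_apobec * (win_cyt[0] / n_sites[0]) + bg_retained * (win_cyt[1] / n_sites[1])
    )
    e_con_tcw = (
        n_apobec * (win_motif[0] / n_sites[0])
        + bg_retained * (win_motif[1] / n_sites[1])
    )
    return (e_mut_tcw / e_con_tcw) / (e_mut_c / e_con_c)


def toy_signature_catalog() -> SignatureCatalog:
    """Small deterministic catalog for tests and worked examples.

    Five synthetic signatures: an APOBEC C>T signature concentrated at
    T[C>T]W ("SBS2"), its C>G counterpart ("SBS13"), a CpG deamination
    C>T signature ("SBS1"), a flat clock-like signature ("SBS5"), and a
    T>G/T>C signature at TTT ("SBS17").  These mimic the shapes of the
    correspondingly named catalog signatures but are synthetic.
    """
    def vector(masses: dict[str, float]) -> np.ndarray:
        v = np.zeros(96)
        for label, mass in masses.items():
            v[SBS96_LABELS.index(label)] = mass
        return v / v.sum()

    signatures = {
        "SBS1": vector(
            {"A[C>T]G": 0.25, "C[C>T]G": 0.25, "G[C>T]G": 0.25, "T[C>T]G": 0.25}
        ),
        "SBS2": vector(
            {"T[C>T]A": 0.38, "T[C>T]T": 0.38, "T[C>T]C": 0.12, "T[C>T]G": 0.12}
        ),
        "SBS5": vector({label: 1.0 for label in SBS96_LABELS}),
        "SBS13": vector(
            {"T[C>G]A": 0.40, "T[C>G]T": 0.40, "T[C>G]C": 0.10, "T[C>G]G": 0.10}
        ),
        "SBS17": vector({"T[T>G]T": 0.55, "T[T>C]T": 0.30, "C[T>G]T": 0.15}),
    }
    names = list(signatures)
    return SignatureCatalog(names, np.column_stack([signatures[n] for n in names]))
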