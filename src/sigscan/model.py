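"""Model/Results interface over the enrichment and refitting cores.

Mirrors the fit-then-inspect convention of statistical modelling packages:
a model object is built from data, ``fit()`` performs the estimation, and
the returned results object carries estimates, uncertainties, and a
``summary()`` table.

``ApobecEnrichment`` estimates per-sample TCW fold-enrichment with
one-sided Fisher p-values, cohort-wide BH q-values, and the
enrichment-high/low call.  ``SignatureRefit`` estimates per-sample
signature exposures by constrained forward selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .enrichment import (
    EnrichmentResult,
    Motif,
    attach_q_values,
    classify_es,
    enrichment_score,
    filter_for_enrichment,
)
from .genome import GenomeSequence
from .refit import (
    SignatureCatalog,
    SignatureExposure,
    exposures_to_frame,
    percent_sbs2,
    refit,
)
from .spectrum import Spectrum96
from .variants import MutationRecord


class ApobecEnrichment:
    """Per-sample APOBEC TCW enrichment model for a cohort.

    Parameters
    ----------
    records_by_sample
        Mapping of sample id to that sample's read-support-filtered
        mutation records.  The four organizing rules (SBS only, C:G
        reference, no mitochondrial sites, no C>A) are applied during
        ``fit`` unless ``prefiltered``.
    genome
        Reference genome providing trinucleotide contexts and windows.
    half_width
        Bases extracted either side of each mutation (window length
        ``2 * half_width + 1``; default the standard 41-base window).
    motif
        "TCW" counts TCA+TCT (default); "TCA" is the strict variant.
    """

    def __init__(
        self,
        records_by_sample: dict[str, Sequence[MutationRecord]],
        genome: GenomeSequence,
        half_width: int = 20,
        motif: Motif = "TCW",
        prefiltered: bool = False,
    ):
        self.records_by_sample = records_by_sample
        self.genome = genome
        self.half_width = half_width
        self.motif = motif
        self.prefiltered = prefiltered

    @classmethod
    def from_records(
        cls, records: Sequence[MutationRecord], genome: GenomeSequence, **kwargs
    ) -> "ApobecEnrichment":
        """Build from a flat record list, grouping by ``sample_id``."""
        by_sample: dict[str, list[MutationRecord]] = {}
        for rec in records:
            by_sample.setdefault(rec.sample_id, []).append(rec)
        return cls(by_sample, genome, **kwargs)

    def fit(self, q_threshold: float = 0.1) -> "ApobecEnrichmentResults":
        results = []
        for sample_id, records in self.records_by_sample.items():
            recs = list(records)
            if not self.prefiltered:
                recs = filter_for_enrichment(recs)
            results.append(
                enrichment_score(
                    recs, self.genome, self.half_width, self.motif, sample_id=sample_id
                )
            )
        results = classify_es(attach_q_values(results), q_threshold)
        return ApobecEnrichmentResults(self, results, q_threshold)


@dataclass
class ApobecEnrichmentResults:
    """Fitted per-sample enrichment scores with cohort-level inference."""

    model: ApobecEnrichment
    results: list[EnrichmentResult]
    q_threshold: float

    _COLUMNS = (
        "sample_id", "mut_tcw", "mut_c", "con_tcw", "con_c",
        "score", "p", "q", "es_class",
    )

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "mut_tcw": r.counts.mut_tcw,
                    "mut_c": r.counts.mut_c,
                    "con_tcw": r.counts.con_tcw,
                    "con_c": r.counts.con_c,
                    "score": r.score,
                    "p": r.p_value,
                    "q": r.q_value,
                    "es_class": r.es_class,
                }
            )
        return pd.DataFrame(rows, columns=list(self._COLUMNS))

    @property
    def scores(self) -> pd.Series:
        return self.frame.set_index("sample_id")["score"]

    def by_class(self) -> dict[str, list[str]]:
        """Sample ids per enrichment class."""
        out: dict[str, list[str]] = {"high": [], "low": []}
        for r in self.results:
            out[r.es_class].append(r.sample_id)
        return out

    def summary(self) -> str:
        df = self.frame
        n_high = int((df["es_class"] == "high").sum())
        lines = [
            "APOBEC TCW enrichment (one-sided Fisher, BH-corrected)",
            f"samples: {len(df)}   motif: {self.model.motif}   "
            f"window: {2 * self.model.half_width + 1} bases   "
            f"enrichment-high (q < {self.q_threshold:g}): {n_high}",
            "",
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
        ]
        return "\n".join(lines)


class SignatureRefit:
    """Signature-exposure model: spectra regressed on a catalog.

    ``fit`` runs forward selection with non-negative least-squares
    sub-solves per sample, zeroing weights under ``weight_floor``.
    """

    def __init__(
        self,
        spectra: Sequence[Spectrum96],
        catalog: SignatureCatalog,
        weight_floor: float = 0.06,
        tolerance: float = 1e-9,
    ):
        self.spectra = list(spectra)
        self.catalog = catalog
        self.weight_floor = weight_floor
        self.tolerance = tolerance

    def fit(self) -> "SignatureRefitResults":
        exposures = [
            refit(s, self.catalog, self.weight_floor, self.tolerance)
            for s in self.spectra
        ]
        return SignatureRefitResults(self, exposures)


@dataclass
class SignatureRefitResults:
    model: SignatureRefit
    exposures: list[SignatureExposure]

    @property
    def frame(self) -> pd.DataFrame:
        return exposures_to_frame(self.exposures)

    def percent(self, signature: str = "SBS2") -> pd.Series:
        """Percent contribution of one signature per sample."""
        return pd.Series(
            {e.sample_id: percent_sbs2(e, signature) for e in self.exposures},
            name=f"percent_{signature}",
        )

    def summary(self) -> str:
        df = self.frame
        lines = [
            "Signature refit (forward selection, NNLS sub-solves, "
            f"weight floor {self.model.weight_floor:g})",
            f"samples: {len(df)}   catalog: {len(self.model.catalog.names)} signatures",
            "",
            df.rename_axis("sample_id").to_string(
                float_format=lambda v: f"{v:.4f}"
            ),
        ]
        return "\n".join(lines)
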