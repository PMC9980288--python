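"""Cohort orchestration: ingest -> spectra -> enrichment -> refit ->
indels -> timing, with a machine-readable report bundle.

The run applies BH correction once, cohort-wide, to the per-sample
enrichment p-values — the correction family is all samples in the
manifest — and reconciles every per-sample total against the stage
outputs it came from.  All outputs are deterministic given fixed inputs
and configuration (no timestamps in the provenance block).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version

import pandas as pd
import yaml

from .enrichment import compare_groups
from .genome import GenomeSequence, read_fasta
from .indels import IndelSummary, indel_enrichment_association, summaries_to_frame, summarize_indels
from .model import ApobecEnrichment, ApobecEnrichmentResults, SignatureRefit
from .refit import SignatureCatalog
from .spectrum import Spectrum96, build_spectrum, spectra_to_frame
from .timing import assign_quintiles, quintile_profile, quintilize, read_timing_bed
from .variants import FilterPolicy, MutationRecord, apply_filters, read_records_tsv, read_vcf_somatic

logger = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return _pkg_version("sigscan")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class CohortManifest:
    """Input listing for one cohort run.

    ``entries`` rows: (sample_id, group label, variant file path); variant
    files may be VCF or the records-TSV fallback.  Optional tables supply
    per-sample covariates (e.g. expression) and structural-variation
    counts, both indexed by sample id.
    """

    entries: list[tuple[str, str, str]]
    reference: str
    timing_track: str | None = None
    covariates: str | None = None
    sv_counts: str | None = None

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")

    @classmethod
    def from_tsv(
        cls,
        path: str,
        reference: str,
        timing_track: str | None = None,
        covariates: str | None = None,
        sv_counts: str | None = None,
    ) -> "CohortManifest":
        df = pd.read_csv(path, sep="\t")
        required = {"sample", "group", "vcf"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
        entries = [
            (str(r.sample), str(r.group), str(r.vcf)) for r in df.itertuples()
        ]
        return cls(entries, reference, timing_track, covariates, sv_counts)


@dataclass
class RunConfig:
    """Flat run options mirroring the CLI flags."""

    min_alt_reads: int = 3
    min_total_reads: int = 10
    min_vaf: float = 0.05
    half_width: int = 20
    motif: str = "TCW"
    q_threshold: float = 0.1
    weight_floor: float = 0.06
    catalog: str | None = None
    mh_scan: int = 10
    group_profiles_by: str = "group"  # or "sample"
    pool_timing_groups: bool = True
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class CohortReport:
    """Bundle of all stage outputs for one cohort run."""

    records_by_sample: dict[str, list[MutationRecord]]
    spectra: list[Spectrum96]
    enrichment: ApobecEnrichmentResults
    exposures_frame: pd.DataFrame | None
    indel_summaries: list[IndelSummary]
    indel_associations: pd.DataFrame | None
    burden_association: tuple[float, float] | None
    covariate_associations: pd.DataFrame | None
    timing_profiles: dict[str, pd.DataFrame]
    group_comparisons: pd.DataFrame | None
    provenance: dict
    failures: dict[str, str] = field(default_factory=dict)


def _read_variants(path: str, sample_id: str) -> list[MutationRecord]:
    if path.endswith((".tsv", ".txt")):
        return [r for r in read_records_tsv(path) if r.sample_id == sample_id]
    return read_vcf_somatic(path, sample_id)


def run_cohort(
    manifest: CohortManifest,
    config: RunConfig | None = None,
    out_dir: str | None = None,
) -> CohortReport:
    """Run the full analysis over a cohort and optionally write TSV/JSON
    outputs under ``out_dir``."""
    config = config or RunConfig()
    genome = read_fasta(manifest.reference)
    policy = FilterPolicy(
        min_alt_reads=config.min_alt_reads,
        min_total_reads=config.min_total_reads,
        min_vaf=config.min_vaf,
    )

    groups: dict[str, str] = {}
    records_by_sample: dict[str, list[MutationRecord]] = {}
    failures: dict[str, str] = {}
    for sample_id, group, path in manifest.entries:
        try:
            records_by_sample[sample_id] = apply_filters(
                _read_variants(path, sample_id), policy
            )
            groups[sample_id] = group
        except Exception as exc:  # noqa: BLE001 - per-sample fault isolation
            if config.strict:
                raise
            logger.error("sample %s failed ingest: %s", sample_id, exc)
            failures[sample_id] = str(exc)

    spectra = [
        build_spectrum(recs, genome, sid) for sid, recs in records_by_sample.items()
    ]

    enrichment = ApobecEnrichment(
        records_by_sample,
        genome,
        half_width=config.half_width,
        motif=config.motif,  # type: ignore[arg-type]
    ).fit(q_threshold=config.q_threshold)
    enrichment_frame = enrichment.frame

    exposures_frame = None
    if config.catalog:
        catalog = SignatureCatalog.from_tsv(config.catalog)
        nonempty = [s for s in spectra if s.total > 0]
        if nonempty:
            exposures_frame = SignatureRefit(
                nonempty, catalog, weight_floor=config.weight_floor
            ).fit().frame

    indel_summaries = [
        summarize_indels(recs, genome, sid, mh_scan=config.mh_scan)
        for sid, recs in records_by_sample.items()
    ]
    indel_associations = None
    if len(indel_summaries) >= 3:
        indel_associations = indel_enrichment_association(
            indel_summaries, enrichment.results
        )

    burden_association = None
    if len(records_by_sample) >= 3:
        from .enrichment import associate

        burdens = [
            sum(1 for r in records_by_sample[sid] if r.is_sbs)
            for sid in records_by_sample
        ]
        burden_association = associate(
            [r.score for r in enrichment.results], burdens, method="spearman"
        )

    covariate_associations = None
    if manifest.covariates:
        cov = pd.read_csv(manifest.covariates, sep="\t", index_col=0)
        scores = enrichment_frame.set_index("sample_id")["score"]
        shared = [s for s in scores.index if s in cov.index]
        rows = []
        if len(shared) >= 3:
            from .enrichment import associate

            for column in cov.columns:
                r, p = associate(
                    scores.loc[shared], cov.loc[shared, column], method="pearson"
                )
                rows.append({"covariate": column, "pearson_r": r, "p_value": p})
        covariate_associations = pd.DataFrame(rows)

    timing_profiles: dict[str, pd.DataFrame] = {}
    if manifest.timing_track:
        track = quintilize(read_timing_bed(manifest.timing_track))
        if config.pool_timing_groups:
            pools: dict[str, list[MutationRecord]] = {}
            for sid, recs in records_by_sample.items():
                key = groups[sid] if config.group_profiles_by == "group" else sid
                pools.setdefault(key, []).extend(r for r in recs if r.is_sbs)
        else:
            pools = {
                sid: [r for r in recs if r.is_sbs]
                for sid, recs in records_by_sample.items()
            }
        for key, recs in pools.items():
            try:
                profile = quintile_profile(assign_quintiles(recs, track), genome, key)
                timing_profiles[key] = profile.as_frame()
            except ValueError as exc:
                logger.warning("timing profile %s skipped: %s", key, exc)

    group_comparisons = None
    per_sample: dict[str, pd.Series] = {
        "total_sbs": pd.Series(
            {sid: sum(1 for r in recs if r.is_sbs) for sid, recs in records_by_sample.items()}
        ),
        "total_indels_under_200": pd.Series(
            {s.sample_id: s.total_under_200 for s in indel_summaries}
        ),
    }
    if manifest.sv_counts:
        sv = pd.read_csv(manifest.sv_counts, sep="\t", index_col=0)
        per_sample["sv_count"] = sv.iloc[:, 0]
    es_class = enrichment_frame.set_index("sample_id")["es_class"]
    comparison_rows = []
    for name, values in per_sample.items():
        for split_name, labels in (("es_class", es_class), ("group", pd.Series(groups))):
            shared = [s for s in values.index if s in labels.index]
            split = {label: [] for label in labels.loc[shared].unique()}
            for s in shared:
                split[labels[s]].append(values[s])
            if len(split) == 2 and all(len(v) > 0 for v in split.values()):
                (label_a, a), (label_b, b) = sorted(split.items())
                u, p = compare_groups(a, b)
                comparison_rows.append(
                    {
                        "quantity": name,
                        "split": split_name,
                        "group_a": label_a,
                        "group_b": label_b,
                        "n_a": len(a),
                        "n_b": len(b),
                        "u_statistic": u,
                        "p_value": p,
                    }
                )
    if comparison_rows:
        group_comparisons = pd.DataFrame(comparison_rows)

    provenance = {
        "package": "sigscan",
        "version": _package_version(),
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "reference": manifest.reference,
        "n_samples": len(records_by_sample),
        "failed_samples": failures,
    }

    report = CohortReport(
        records_by_sample=records_by_sample,
        spectra=spectra,
        enrichment=enrichment,
        exposures_frame=exposures_frame,
        indel_summaries=indel_summaries,
        indel_associations=indel_associations,
        burden_association=burden_association,
        covariate_associations=covariate_associations,
        timing_profiles=timing_profiles,
        group_comparisons=group_comparisons,
        provenance=provenance,
        failures=failures,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: CohortReport, out_dir: str) -> None:
    """Write the report bundle as TSV tables plus a JSON summary."""
    os.makedirs(out_dir, exist_ok=True)
    spectra_to_frame(report.spectra).rename_axis("sample").to_csv(
        os.path.join(out_dir, "spectra.tsv"), sep="\t"
    )
    report.enrichment.frame.to_csv(
        os.path.join(out_dir, "enrichment.tsv"), sep="\t", index=False
    )
    summaries_to_frame(report.indel_summaries).rename_axis("sample").to_csv(
        os.path.join(out_dir, "indels.tsv"), sep="\t"
    )
    if report.exposures_frame is not None:
        report.exposures_frame.rename_axis("sample").to_csv(
            os.path.join(out_dir, "exposures.tsv"), sep="\t"
        )
    if report.indel_associations is not None:
        report.indel_associations.to_csv(
            os.path.join(out_dir, "indel_associations.tsv"), sep="\t", index=False
        )
    if report.covariate_associations is not None:
        report.covariate_associations.to_csv(
            os.path.join(out_dir, "covariate_associations.tsv"), sep="\t", index=False
        )
    for key, frame in report.timing_profiles.items():
        frame.to_csv(
            os.path.join(out_dir, f"timing_{key}.tsv"), sep="\t", index=False
        )
    if report.group_comparisons is not None:
        report.group_comparisons.to_csv(
            os.path.join(out_dir, "group_comparisons.tsv"), sep="\t", index=False
        )
    summary = {
        "provenance": report.provenance,
        "n_samples": len(report.records_by_sample),
        "enrichment_high": [
            r.sample_id for r in report.enrichment.results if r.es_class == "high"
        ],
        "burden_association": report.burden_association,
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
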