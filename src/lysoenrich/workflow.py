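"""End-to-end orchestration: configuration, stage sequencing, manifest.

``run_pipeline`` executes the full analysis on TSV inputs — read and
validate tables, orient/normalize/pool ratios, fit the per-line mixture and
call enrichment, build the V-ATPase-referenced abundance profile, and run
the cross-line frequency analysis — writing every result table plus a
machine-readable manifest (configuration, package version, per-stage row
counts, output checksums). Stage outputs are pure functions of inputs and
configuration; rerunning an identical configuration reproduces identical
bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance_profile import (
    AbundanceProfile,
    ReferenceSet,
    class_sums,
    compare_fractions,
    normalize_ibaq,
    summarize_profile,
)
from .cross_line import (
    candidate_list,
    category_frequency_profile,
    exact_frequency_counts,
    frequency_table,
    membership_from_enrichment,
    pearson_matrix,
    upset_counts,
)
from .errors import ConfigError, LysoEnrichError
from .mixture_model import EMConfig, fits_to_frame, score_all_lines
from .quant_io import (
    read_catalog,
    read_design,
    read_quant_table,
    records_to_frame,
    write_results,
)
from .ratio_pipeline import NONE, pooled_ratios_from_records

log = logging.getLogger("lysoenrich")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; every analysis constant lives here."""

    quant_table: str
    design_table: str
    catalog_table: str
    out_dir: str
    wcl_table: str | None = None
    column_map: dict[str, str] | None = None
    em: EMConfig = field(default_factory=EMConfig)
    alpha: float = 0.05
    weighted_posterior: bool = False
    p_mode: str = "one_minus_posterior"
    strict_cutoff: bool = False
    pooling_statistic: str = "median"
    min_valid_replicates: int = 3
    candidate_threshold: int = 5
    ibaq_min_reps: int = 3
    ibaq_min_lines: int = 2
    reference_subunits: tuple[str, ...] = ()
    ref_min_unique_peptides: int = 10
    pearson_min_overlap: int = 10
    join_key: str = "protein_id"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError(f"alpha={self.alpha} outside (0, 1]")
        if self.join_key not in ("protein_id", "gene_symbol"):
            raise ConfigError(f"join_key={self.join_key!r} unknown")
        if self.min_valid_replicates < 1 or self.candidate_threshold < 1:
            raise ConfigError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        em = EMConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("em", {}).items()
        })
        if "reference_subunits" in raw:
            raw["reference_subunits"] = tuple(raw["reference_subunits"])
        return cls(em=em, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    tables: dict[str, pd.DataFrame]
    written: dict[str, Path]
    manifest: dict
    manifest_path: Path


@contextmanager
def _stage(name: str):
    try:
        yield
    except LysoEnrichError as exc:
        raise LysoEnrichError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see module docstring."""
    counts: dict[str, int] = {}

    with _stage("read_inputs"):
        design = read_design(
            config.design_table,
            min_valid_replicates=config.min_valid_replicates,
        )
        records = read_quant_table(config.quant_table, config.column_map)
        catalog = read_catalog(config.catalog_table)
    frame = records_to_frame(records)
    counts["quant_rows"] = len(frame)
    counts["proteins_in_quant"] = frame["protein_id"].nunique()
    log.info("read %d quant rows / %d proteins", counts["quant_rows"],
             counts["proteins_in_quant"])

    with _stage("ratio_pipeline"):
        ratio_frame = frame[frame["ratio_heavy_over_light"].notna()
                            | frame["reported_spions_over_control"].notna()]
        pooled = pooled_ratios_from_records(
            ratio_frame, design, statistic=config.pooling_statistic
        )
    counts["pooled_rows"] = len(pooled.table)
    counts["dropped_rows"] = len(pooled.drop_log)
    counts["extreme_rows"] = int((pooled.table["extreme"] != NONE).sum())
    log.info("pooled %d protein-line values (%d dropped, %d extreme)",
             counts["pooled_rows"], counts["dropped_rows"],
             counts["extreme_rows"])

    with _stage("mixture_model"):
        fits, enrichment = score_all_lines(
            pooled,
            config=config.em,
            alpha=config.alpha,
            weighted=config.weighted_posterior,
            p_mode=config.p_mode,
            strict_cutoff=config.strict_cutoff,
        )
    counts["enriched_calls"] = int(enrichment["enriched"].sum())
    log.info("called %d protein-line enrichments", counts["enriched_calls"])

    # optional join on gene symbol for cross-species protein spaces
    if config.join_key == "gene_symbol":
        symbol_of = dict(zip(frame["protein_id"], frame["gene_symbol"]))
        key = lambda p: symbol_of.get(p) or p  # noqa: E731
        enrichment = enrichment.assign(
            protein_id=[key(p) for p in enrichment["protein_id"]]
        )

    with _stage("cross_line"):
        identified = membership_from_enrichment(enrichment)
        enriched = membership_from_enrichment(enrichment, enriched_only=True)
        freq = frequency_table(
            identified, enriched, catalog,
            candidate_threshold=config.candidate_threshold,
        )
        symbols = dict(zip(frame["protein_id"], frame["gene_symbol"]))
        candidates = candidate_list(freq, enriched, gene_symbols=symbols)
        upset = upset_counts(identified)
        cat_profile = category_frequency_profile(identified, catalog)
        exact_counts = exact_frequency_counts(identified)
        nonextreme = pooled.table[pooled.table["extreme"] == NONE]
        vectors = {
            line: group.set_index("protein_id")["x_log2"]
            for line, group in nonextreme.groupby("cell_line")
        }
        pearson = pearson_matrix(vectors, min_overlap=config.pearson_min_overlap)
    counts["proteins_identified_any_line"] = len(identified.grid)
    counts["candidates"] = len(candidates)
    log.info("%d proteins identified in >=1 line; %d candidates",
             counts["proteins_identified_any_line"], counts["candidates"])

    tables: dict[str, pd.DataFrame] = {
        "pooled_ratios": pooled.table,
        "drop_log": pooled.drop_log,
        "mixture_fits": fits_to_frame(fits),
        "enrichment_table": enrichment,
        "frequency_table": freq,
        "candidates": candidates,
        "upset_counts": upset,
        "category_profile": cat_profile,
        "exact_frequency_counts": exact_counts,
        "pearson_matrix": pearson.reset_index(names="cell_line"),
    }

    with _stage("abundance_profile"):
        profile = None
        if config.reference_subunits:
            ref = ReferenceSet(
                subunit_ids=tuple(config.reference_subunits),
                min_unique_peptides=config.ref_min_unique_peptides,
            )
            normalized = normalize_ibaq(frame, ref)
            profile = summarize_profile(
                normalized,
                min_reps=config.ibaq_min_reps,
                min_lines=config.ibaq_min_lines,
            )
            sums, coverage = class_sums(profile, catalog)
            tables["abundance_profile"] = profile.per_line
            tables["class_sums"] = sums
            tables["class_coverage"] = coverage
            counts["profile_rows"] = len(profile.per_line)
            counts["profile_passing_proteins"] = int(profile.passes.sum())
            if config.wcl_table:
                wcl_records = read_quant_table(config.wcl_table,
                                               config.column_map)
                wcl_profile = summarize_profile(
                    normalize_ibaq(records_to_frame(wcl_records), ref),
                    min_reps=config.ibaq_min_reps,
                    min_lines=config.ibaq_min_lines,
                )
                comparison, corr = compare_fractions(profile, wcl_profile)
                tables["fraction_comparison"] = comparison
                tables["fraction_correlation"] = corr
                counts["fraction_comparison_rows"] = len(comparison)

    with _stage("write_results"):
        written = write_results(tables, config.out_dir)
        manifest = {
            "package": "lysoenrich",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "counts": counts,
            "outputs": {
                name: {
                    "file": path.name,
                    "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
                }
                for name, path in sorted(written.items())
            },
        }
        manifest_path = Path(config.out_dir) / "manifest.json"
        manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    return PipelineResult(
        config=config,
        tables=tables,
        written=written,
        manifest=manifest,
        manifest_path=manifest_path,
    )


def run_simulated(
    sim_config,
    out_dir: str | Path,
    **overrides,
) -> PipelineResult:
    """Simulate a study, write its tables, and run the pipeline on them.

    ``overrides`` are forwarded to :class:`PipelineConfig` (e.g. ``alpha``).
    The simulated V-ATPase subunits are wired in as the reference set.
    """
    from .synthetic_data import reference_ids, simulate_study, write_study

    out = Path(out_dir)
    study = simulate_study(sim_config)
    paths = write_study(study, out / "inputs")
    config = PipelineConfig(
        quant_table=str(paths["quant_table"]),
        design_table=str(paths["design"]),
        catalog_table=str(paths["catalog"]),
        wcl_table=str(paths["wcl_table"]) if "wcl_table" in paths else None,
        out_dir=str(out / "results"),
        reference_subunits=reference_ids(sim_config),
        seed=sim_config.seed if sim_config is not None else 0,
        **overrides,
    )
    return run_pipeline(config)
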