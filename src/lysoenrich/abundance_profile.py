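"""V-ATPase-referenced iBAQ abundance profiles.

Lysosome yield varies between replicates and cell lines, so raw iBAQ
intensities are not comparable. Each replicate's intensities are divided by
the median iBAQ of a fixed set of V-ATPase complex subunits detected with at
least ``min_unique_peptides`` unique peptides in that replicate — the
V-ATPase is constitutive lysosomal machinery, making it a natural internal
scale. Per-protein medians across replicates then yield one normalized
abundance per protein per cell line, a protein-presence filter (>= min_reps
replicates in each of >= min_lines cell lines) marks profiles robust enough
for comparison, and functional-class sums and lysosome-enriched versus
whole-cell-lysate comparisons are derived from the filtered profile.

The reference subunit accessions are configuration, not code: they are
species- and annotation-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import ComparisonError, ReferenceSetError
from .quant_io import AnnotationCatalog, QuantRecord, records_to_frame


@dataclass(frozen=True)
class ReferenceSet:
    """V-ATPase reference subunits used as the per-replicate iBAQ scale."""

    subunit_ids: tuple[str, ...]
    min_unique_peptides: int = 10

    def __post_init__(self) -> None:
        if not self.subunit_ids:
            raise ValueError("reference set must name at least one subunit")
        if self.min_unique_peptides < 1:
            raise ValueError("min_unique_peptides must be >= 1")


@dataclass
class AbundanceProfile:
    """Median V-ATPase-normalized iBAQ per protein per cell line.

    ``per_line`` columns: protein_id, cell_line, median_norm_ibaq,
    n_replicates_observed, passes_filter. ``passes`` indexes the per-protein
    filter verdict (values in >= min_reps replicates in each of >= min_lines
    cell lines).
    """

    per_line: pd.DataFrame
    passes: pd.Series
    min_reps: int
    min_lines: int

    def passing(self) -> pd.DataFrame:
        return self.per_line[self.per_line["passes_filter"]].reset_index(drop=True)


def ibaq_frame(records: Sequence[QuantRecord] | pd.DataFrame) -> pd.DataFrame:
    """Long iBAQ view of quantification records (rows with an iBAQ value)."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    cols = ["protein_id", "cell_line", "replicate", "ibaq", "unique_peptides"]
    out = frame[cols].copy()
    return out[out["ibaq"].notna()].reset_index(drop=True)


def reference_median(replicate_frame: pd.DataFrame, ref: ReferenceSet) -> float:
    """Median iBAQ of qualifying reference subunits within one replicate."""
    sub = replicate_frame[
        replicate_frame["protein_id"].isin(ref.subunit_ids)
        & (replicate_frame["unique_peptides"] >= ref.min_unique_peptides)
        & (replicate_frame["ibaq"] > 0)
    ]
    if sub.empty:
        where = ""
        if {"cell_line", "replicate"} <= set(replicate_frame.columns) and len(
            replicate_frame
        ):
            first = replicate_frame.iloc[0]
            where = f" in ({first['cell_line']}, r{first['replicate']})"
        raise ReferenceSetError(
            f"no reference subunit with >= {ref.min_unique_peptides} unique "
            f"peptides and positive iBAQ{where}"
        )
    return float(sub["ibaq"].median())


def normalize_ibaq(
    records: Sequence[QuantRecord] | pd.DataFrame,
    ref: ReferenceSet,
) -> pd.DataFrame:
    """Divide every iBAQ by its replicate's reference median.

    Returns the long frame with an added ``norm_ibaq`` column. Reference
    subunits are normalized too, so their per-replicate median becomes 1.
    """
    frame = ibaq_frame(records)
    parts: list[pd.DataFrame] = []
    for (_, _), group in frame.groupby(["cell_line", "replicate"], sort=True):
        med = reference_median(group, ref)
        g = group.copy()
        g["norm_ibaq"] = g["ibaq"] / med
        parts.append(g)
    return pd.concat(parts, ignore_index=True)


def summarize_profile(
    normalized: pd.DataFrame,
    min_reps: int = 3,
    min_lines: int = 2,
) -> AbundanceProfile:
    """Median normalized iBAQ per (protein, cell line) plus the presence filter."""
    agg = (
        normalized.groupby(["protein_id", "cell_line"], sort=True)["norm_ibaq"]
        .agg(median_norm_ibaq="median", n_replicates_observed="count")
        .reset_index()
    )
    lines_ok = (
        agg[agg["n_replicates_observed"] >= min_reps]
        .groupby("protein_id")["cell_line"]
        .nunique()
    )
    all_proteins = pd.Index(agg["protein_id"].unique())
    passes = lines_ok.reindex(all_proteins, fill_value=0) >= min_lines
    passes.name = "passes_filter"
    agg["passes_filter"] = agg["protein_id"].map(passes).astype(bool)
    return AbundanceProfile(
        per_line=agg, passes=passes, min_reps=min_reps, min_lines=min_lines
    )


def class_sums(
    profile: AbundanceProfile,
    catalog: AnnotationCatalog,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summed normalized abundances per (cell line, functional class).

    Only putative-lysosomal proteins that pass the presence filter and
    carry a functional class contribute; classes declared in the catalog
    but matched by no contributing protein are reported with sum 0 and
    flagged empty. Returns (sums, coverage) where coverage counts the
    contributing proteins per class.
    """
    passing = profile.passing()
    keep = passing[
        passing["protein_id"].map(catalog.is_putative_lysosomal)
        & passing["protein_id"].map(
            lambda p: catalog.functional_class(p) is not None
        )
    ].copy()
    keep["functional_class"] = keep["protein_id"].map(catalog.functional_class)

    declared = sorted(
        {
            e.functional_class
            for e in catalog.entries.values()
            if e.functional_class is not None
        }
    )
    lines = sorted(profile.per_line["cell_line"].unique())
    grid = pd.MultiIndex.from_product(
        [lines, declared], names=["cell_line", "functional_class"]
    )
    sums = (
        keep.groupby(["cell_line", "functional_class"])["median_norm_ibaq"]
        .sum()
        .reindex(grid, fill_value=0.0)
        .rename("class_sum")
        .reset_index()
    )
    n_members = (
        keep.groupby(["cell_line", "functional_class"])["protein_id"]
        .nunique()
        .reindex(grid, fill_value=0)
        .rename("n_proteins")
        .reset_index(drop=True)
    )
    sums["n_proteins"] = n_members
    sums["empty"] = sums["n_proteins"] == 0

    coverage = (
        keep.groupby("functional_class")["protein_id"]
        .nunique()
        .reindex(declared, fill_value=0)
        .rename("n_proteins")
        .reset_index()
    )
    return sums, coverage


def compare_fractions(
    profile_enriched: AbundanceProfile,
    profile_wcl: AbundanceProfile,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lysosome-enriched versus whole-cell-lysate abundance comparison.

    Both profiles must be normalized against the same reference set. Per
    (protein, cell line) in the passing intersection: log2 of
    enriched/whole-cell-lysate normalized abundance, with proteins
    relatively more abundant in the whole cell lysate flagged
    (log2 ratio < 0). Per cell line, the Pearson correlation of log10
    abundances over the intersection is reported.
    """
    a = profile_enriched.passing()[
        ["protein_id", "cell_line", "median_norm_ibaq"]
    ].rename(columns={"median_norm_ibaq": "enriched"})
    b = profile_wcl.passing()[
        ["protein_id", "cell_line", "median_norm_ibaq"]
    ].rename(columns={"median_norm_ibaq": "wcl"})
    merged = a.merge(b, on=["protein_id", "cell_line"], how="inner")
    merged = merged[(merged["enriched"] > 0) & (merged["wcl"] > 0)]
    if merged.empty:
        raise ComparisonError(
            "no protein passes both profiles' filters; nothing to compare"
        )
    merged["log2_enriched_over_wcl"] = np.log2(merged["enriched"] / merged["wcl"])
    merged["wcl_higher"] = merged["log2_enriched_over_wcl"] < 0

    corr_rows = []
    for line, group in merged.groupby("cell_line", sort=True):
        a_log = np.log10(group["enriched"].to_numpy())
        b_log = np.log10(group["wcl"].to_numpy())
        if len(group) > 1 and np.ptp(a_log) > 0 and np.ptp(b_log) > 0:
            r = float(np.corrcoef(a_log, b_log)[0, 1])
        else:
            r = np.nan  # undefined for constant profiles

        corr_rows.append(
            {"cell_line": line, "pearson_log10": r, "n_proteins": len(group)}
        )
    return merged.reset_index(drop=True), pd.DataFrame(corr_rows)
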