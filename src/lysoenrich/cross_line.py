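"""Multi-cell-line overlap, frequency ranking and candidate selection.

A protein observed (or significantly enriched) in more of the study's cell
lines is more likely genuinely lysosomal than a sporadic interactor, so the
final ranking is by identification/enrichment frequency across lines.
Membership is coded 1/0 per (protein, cell line); exact-intersection counts
drive UpSet-style summaries; the candidate list keeps proteins enriched in
at least ``candidate_threshold`` lines that are not already reported as
lysosomal; and compartment-percentage profiles over increasing frequency
thresholds (normalized to the >= 1 line baseline) quantify how strongly
reproducibility selects for the lysosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .quant_io import AnnotationCatalog, COMPARTMENT_VOCAB

IDENTIFIED = "identified"
ENRICHED = "enriched"


@dataclass
class MembershipMatrix:
    """Protein x cell line boolean grid (1 = found / enriched in that line)."""

    grid: pd.DataFrame  # bool, index protein_id, columns cell lines
    mode: str = IDENTIFIED

    @property
    def cell_lines(self) -> list[str]:
        return list(self.grid.columns)

    def frequency(self) -> pd.Series:
        """Number of cell lines each protein is a member of."""
        return self.grid.sum(axis=1).astype(int)


def membership(
    proteins_by_line: Mapping[str, Iterable[str]],
    mode: str = IDENTIFIED,
) -> MembershipMatrix:
    """Boolean membership grid from per-line protein sets.

    Rows are the union of all proteins; a protein in no line never appears.
    """
    lines = list(proteins_by_line)
    sets = {line: set(proteins_by_line[line]) for line in lines}
    proteins = sorted(set().union(*sets.values())) if sets else []
    grid = pd.DataFrame(
        {line: [p in sets[line] for p in proteins] for line in lines},
        index=pd.Index(proteins, name="protein_id"),
        dtype=bool,
    )
    return MembershipMatrix(grid=grid, mode=mode)


def membership_from_enrichment(
    enrichment: pd.DataFrame,
    enriched_only: bool = False,
) -> MembershipMatrix:
    """Membership grid from a concatenated per-line enrichment table."""
    sub = enrichment[enrichment["enriched"]] if enriched_only else enrichment
    by_line = {
        line: group["protein_id"].tolist()
        for line, group in sub.groupby("cell_line")
    }
    # keep every line that appears in the full table, even if empty after filter
    for line in enrichment["cell_line"].unique():
        by_line.setdefault(line, [])
    by_line = {line: by_line[line] for line in sorted(by_line)}
    return membership(by_line, mode=ENRICHED if enriched_only else IDENTIFIED)


def upset_counts(matrix: MembershipMatrix) -> pd.DataFrame:
    """Exact-intersection counts: each protein counted once under its full
    membership pattern. Pattern strings join member lines with '+'."""
    grid = matrix.grid
    patterns = grid.apply(
        lambda row: "+".join(col for col in grid.columns if row[col]), axis=1
    )
    patterns = patterns[patterns != ""]
    counts = patterns.value_counts().rename("count")
    out = counts.reset_index().rename(columns={"index": "pattern"})
    out["degree"] = out["pattern"].str.count(r"\+") + 1
    return out.sort_values(["degree", "pattern"], kind="mergesort").reset_index(
        drop=True
    )[["pattern", "degree", "count"]]


def frequency_table(
    identified: MembershipMatrix,
    enriched: MembershipMatrix,
    catalog: AnnotationCatalog,
    candidate_threshold: int = 5,
) -> pd.DataFrame:
    """Per-protein identification/enrichment counts and the candidate flag.

    A candidate is a protein enriched in >= ``candidate_threshold`` cell
    lines that is not previously reported as lysosomal. Raises if a protein
    is enriched in a line where it was not identified.
    """
    proteins = identified.grid.index
    enr = enriched.grid.reindex(index=proteins, columns=identified.cell_lines,
                                fill_value=False)
    stray = set(enriched.grid.index) - set(proteins)
    if stray:
        raise ConsistencyError(
            f"enriched proteins absent from the identified matrix: "
            f"{sorted(stray)[:5]}"
        )
    if (enr & ~identified.grid).any().any():
        bad = (enr & ~identified.grid).any(axis=1)
        raise ConsistencyError(
            f"enriched without being identified: "
            f"{list(proteins[bad])[:5]}"
        )
    n_ident = identified.frequency()
    n_enr = enr.sum(axis=1).astype(int)
    prev = pd.Series(
        [catalog.previously_reported(p) for p in proteins], index=proteins
    )
    out = pd.DataFrame(
        {
            "protein_id": proteins,
            "n_identified": n_ident.values,
            "n_enriched": n_enr.values,
            "previously_reported": prev.values,
            "candidate": ((n_enr >= candidate_threshold) & ~prev).values,
        }
    ).reset_index(drop=True)
    return out


def candidate_list(
    freq: pd.DataFrame,
    enriched: MembershipMatrix,
    gene_symbols: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Candidates of :func:`frequency_table` with the lines they were enriched in."""
    cand = freq[freq["candidate"]].copy()
    lines = []
    for pid in cand["protein_id"]:
        if pid in enriched.grid.index:
            row = enriched.grid.loc[pid]
            lines.append("+".join(c for c in enriched.grid.columns if row[c]))
        else:
            lines.append("")
    cand["lines"] = lines
    cand["gene_symbol"] = [
        (gene_symbols or {}).get(p, "") for p in cand["protein_id"]
    ]
    cand = cand.sort_values(
        ["n_enriched", "protein_id"], ascending=[False, True], kind="mergesort"
    )
    return cand[
        ["protein_id", "gene_symbol", "n_enriched", "n_identified", "lines"]
    ].reset_index(drop=True)


def category_frequency_profile(
    matrix: MembershipMatrix,
    catalog: AnnotationCatalog,
    thresholds: Iterable[int] | None = None,
    categories: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Compartment percentages over increasing frequency thresholds.

    For every threshold k, among proteins present in >= k cell lines:
    percentage assigned to each compartment (a protein with several
    compartments counts once per compartment), plus the same value
    normalized to the k = 1 baseline (so the baseline row is exactly 1).
    Categories with a zero baseline get a missing normalized value.
    """
    freq = matrix.frequency()
    n_lines = len(matrix.cell_lines)
    ks = list(thresholds) if thresholds is not None else list(range(1, n_lines + 1))
    cats = sorted(categories) if categories is not None else sorted(COMPARTMENT_VOCAB)

    comp = {p: catalog.compartments(p) for p in matrix.grid.index}
    rows = []
    baseline: dict[str, float] = {}
    for k in sorted(ks):
        selected = [p for p, f in freq.items() if f >= k]
        n_sel = len(selected)
        for cat in cats:
            n_cat = sum(1 for p in selected if cat in comp[p])
            pct = 100.0 * n_cat / n_sel if n_sel else np.nan
            if k == min(ks):
                baseline[cat] = pct
            base = baseline.get(cat, np.nan)
            norm = (
                pct / base
                if base is not None and np.isfinite(base) and base > 0
                else np.nan
            )
            rows.append(
                {
                    "category": cat,
                    "k": k,
                    "n_proteins": n_sel,
                    "percent": pct,
                    "normalized": norm,
                }
            )
    return pd.DataFrame(rows)


def exact_frequency_counts(matrix: MembershipMatrix) -> pd.DataFrame:
    """Number of proteins present in exactly k cell lines, k = 1..L."""
    freq = matrix.frequency()
    n_lines = len(matrix.cell_lines)
    counts = freq.value_counts().reindex(range(1, n_lines + 1), fill_value=0)
    return pd.DataFrame({"k": counts.index, "n_proteins": counts.values})


def pearson_matrix(
    vectors: Mapping[str, pd.Series],
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of per-line pooled log2 ratios.

    Pairs with fewer than ``min_overlap`` shared proteins are reported
    missing (NaN). Diagonal is 1 for any non-empty vector.
    """
    lines = list(vectors)
    frame = pd.DataFrame({line: vectors[line] for line in lines})
    corr = frame.corr(method="pearson", min_periods=min_overlap)
    for line in lines:
        if frame[line].notna().any():
            corr.loc[line, line] = 1.0
    return corr
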