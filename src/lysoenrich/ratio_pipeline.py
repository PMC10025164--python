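"""From per-replicate SILAC ratios to one pooled log2 value per protein per line.

The chain is: orient heavy/light ratios to SPIONs/control using the design's
label-switch assignment, log2-transform and median-normalize each replicate
(so within every replicate the median of valid log2 ratios is exactly 0),
pool replicates per protein (median by default), apply the minimum-valid-
replicates filter, and finally substitute sentinel-coded one-channel
detections with the most extreme finite pooled value of their cell line.

Sentinel ratios are arbitrary codes, not measurements: they are excluded
from normalization medians and carried through as EXTREME_HIGH/EXTREME_LOW
status for the mixture stage to force posteriors to 1 or 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DesignError, LysoEnrichError
from .quant_io import HEAVY, LIGHT, QuantRecord, StudyDesign, records_to_frame

# cell status codes
VALID = "valid"
MISSING = "missing"
EXTREME_HIGH = "extreme_high"
EXTREME_LOW = "extreme_low"

# pooled extreme tags
NONE = "none"
HIGH = "high"
LOW = "low"


@dataclass
class RatioMatrix:
    """Per-cell-line protein x replicate grid of normalized log2 ratios.

    ``cells`` is long-format with columns (cell_line, protein_id, replicate,
    status, log2_value); log2_value is NaN except for VALID cells.
    """

    cells: pd.DataFrame
    design: StudyDesign

    def pivot(self, cell_line: str) -> pd.DataFrame:
        sub = self.cells[self.cells["cell_line"] == cell_line]
        return sub.pivot(index="protein_id", columns="replicate",
                         values="log2_value")


@dataclass
class PooledRatios:
    """One pooled log2 SPIONs/control value per protein per cell line.

    ``table`` columns: cell_line, protein_id, x_log2, n_valid, extreme
    (none/high/low). ``drop_log`` records proteins removed by the
    minimum-valid-replicates filter, with the reason.
    """

    table: pd.DataFrame
    drop_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cell_line", "protein_id", "reason"]
        )
    )

    def for_line(self, cell_line: str) -> pd.DataFrame:
        return self.table[self.table["cell_line"] == cell_line].reset_index(
            drop=True
        )


def orient_ratios(
    records: Sequence[QuantRecord] | pd.DataFrame,
    design: StudyDesign,
) -> pd.DataFrame:
    """Orient each record's ratio to SPIONs/control.

    Heavy-SPIONs replicates use H/L directly; light-SPIONs replicates use
    1/(H/L). Records already carrying a reported SPIONs/control ratio pass
    through unchanged. Sentinel codes are preserved as codes: in a
    light-SPIONs replicate a heavy/light sentinel swaps direction
    (high <-> low), which for the default reciprocal sentinel pair
    (100, 0.01) coincides with exact reciprocal arithmetic.

    Returns a long DataFrame (protein_id, gene_symbol, cell_line, replicate,
    sc_ratio) with NaN where no ratio was observed.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    known = set(design.channel_of_spions)
    pairs = set(zip(frame["cell_line"], frame["replicate"]))
    unknown = pairs - known
    if unknown:
        raise DesignError(
            f"records reference (cell_line, replicate) pairs outside the "
            f"design: {sorted(unknown)[:5]}"
        )

    hi, lo = design.sentinel_high, design.sentinel_low
    channels = frame.apply(
        lambda r: design.spions_channel(r["cell_line"], r["replicate"]), axis=1
    ) if len(frame) else pd.Series(dtype=object)

    sc = np.full(len(frame), np.nan)
    reported = frame["reported_spions_over_control"].to_numpy(dtype=float)
    hl = frame["ratio_heavy_over_light"].to_numpy(dtype=float)
    is_light = (channels == LIGHT).to_numpy() if len(frame) else np.array([], bool)

    has_reported = ~np.isnan(reported)
    sc[has_reported] = reported[has_reported]

    use_hl = ~has_reported & ~np.isnan(hl)
    # sentinels in the H/L column: keep the code, flip direction on light
    sent_hi = use_hl & (hl == hi)
    sent_lo = use_hl & (hl == lo)
    plain = use_hl & ~sent_hi & ~sent_lo
    sc[sent_hi] = np.where(is_light[sent_hi], lo, hi)
    sc[sent_lo] = np.where(is_light[sent_lo], hi, lo)
    sc[plain] = np.where(is_light[plain], 1.0 / hl[plain], hl[plain])

    out = frame[["protein_id", "gene_symbol", "cell_line", "replicate"]].copy()
    out["sc_ratio"] = sc
    return out


def build_ratio_matrix(
    oriented: pd.DataFrame,
    design: StudyDesign,
) -> RatioMatrix:
    """Classify cells and median-normalize log2 ratios per replicate.

    Sentinels become EXTREME_HIGH / EXTREME_LOW, absent ratios MISSING;
    every other ratio must be positive and becomes VALID with
    ``log2(ratio) - median`` where the median is taken over the VALID log2
    values of the same (cell_line, replicate) column. After normalization
    the per-column median of VALID values is exactly 0.
    """
    hi, lo = design.sentinel_high, design.sentinel_low
    cells = oriented[["cell_line", "protein_id", "replicate"]].copy()
    ratio = oriented["sc_ratio"].to_numpy(dtype=float)

    status = np.where(
        np.isnan(ratio),
        MISSING,
        np.where(ratio == hi, EXTREME_HIGH, np.where(ratio == lo, EXTREME_LOW, VALID)),
    )
    bad = (status == VALID) & (ratio <= 0)
    if bad.any():
        first = oriented.iloc[int(np.flatnonzero(bad)[0])]
        raise LysoEnrichError(
            f"nonpositive non-sentinel ratio {first['sc_ratio']} for "
            f"{first['protein_id']} ({first['cell_line']} r{first['replicate']})"
        )
    log2 = np.where(status == VALID, np.log2(np.where(status == VALID, ratio, 1.0)),
                    np.nan)
    cells["status"] = status
    cells["log2_value"] = log2

    # median-normalize within each (cell_line, replicate) over VALID cells
    med = cells.groupby(["cell_line", "replicate"])["log2_value"].transform("median")
    cells["log2_value"] = cells["log2_value"] - med
    return RatioMatrix(cells=cells, design=design)


def pool_replicates(
    matrix: RatioMatrix,
    design: StudyDesign,
    statistic: str = "median",
) -> PooledRatios:
    """Pool replicate log2 values per protein per cell line.

    A protein is retained with a finite pooled value when it has at least
    ``design.min_valid_replicates`` VALID replicates; failing that, it is
    tagged extreme HIGH/LOW when it has that many same-direction sentinel
    observations; otherwise it is dropped (logged with the reason). Mixed
    finite/sentinel proteins fall back to their finite values when those
    alone satisfy the filter.
    """
    if statistic not in ("median", "mean"):
        raise ValueError(f"unknown pooling statistic {statistic!r}")
    k = design.min_valid_replicates

    grouped = matrix.cells.groupby(["cell_line", "protein_id"], sort=True)
    agg = grouped.agg(
        n_valid=("status", lambda s: int((s == VALID).sum())),
        n_high=("status", lambda s: int((s == EXTREME_HIGH).sum())),
        n_low=("status", lambda s: int((s == EXTREME_LOW).sum())),
        x_log2=("log2_value", statistic),
    ).reset_index()

    keep_valid = agg["n_valid"] >= k
    keep_high = ~keep_valid & (agg["n_high"] >= k)
    keep_low = ~keep_valid & ~keep_high & (agg["n_low"] >= k)
    dropped = ~(keep_valid | keep_high | keep_low)

    table = agg[keep_valid | keep_high | keep_low].copy()
    table["extreme"] = np.select(
        [keep_high[table.index], keep_low[table.index]], [HIGH, LOW], NONE
    )
    table.loc[table["extreme"] != NONE, "x_log2"] = np.nan
    table = table[["cell_line", "protein_id", "x_log2", "n_valid", "extreme"]]
    table = table.reset_index(drop=True)

    drops = agg[dropped]
    drop_log = pd.DataFrame(
        {
            "cell_line": drops["cell_line"],
            "protein_id": drops["protein_id"],
            "reason": [
                f"n_valid={nv} < {k} (extreme_high={nh}, extreme_low={nl})"
                for nv, nh, nl in zip(
                    drops["n_valid"], drops["n_high"], drops["n_low"]
                )
            ],
        }
    ).reset_index(drop=True)
    return PooledRatios(table=table, drop_log=drop_log)


def substitute_extremes(pooled: PooledRatios) -> PooledRatios:
    """Replace extreme-tagged proteins' x with the most extreme finite value.

    Per cell line, extreme HIGH proteins receive the maximum pooled x of the
    non-extreme proteins and extreme LOW the minimum, mirroring the
    replacement of sentinel codes by the most extreme ratios actually
    observed in the dataset. Tags are retained so the mixture stage can
    force posteriors.
    """
    table = pooled.table.copy()
    for line, sub in table.groupby("cell_line"):
        finite = sub.loc[sub["extreme"] == NONE, "x_log2"]
        is_high = (sub["extreme"] == HIGH)
        is_low = (sub["extreme"] == LOW)
        if (is_high.any() or is_low.any()) and finite.empty:
            raise DegenerateInputError(
                f"cell line {line!r}: every pooled protein is extreme; "
                f"no finite value to substitute"
            )
        if is_high.any():
            table.loc[sub.index[is_high], "x_log2"] = finite.max()
        if is_low.any():
            table.loc[sub.index[is_low], "x_log2"] = finite.min()
    return PooledRatios(table=table, drop_log=pooled.drop_log)


def pooled_ratios_from_records(
    records: Sequence[QuantRecord] | pd.DataFrame,
    design: StudyDesign,
    statistic: str = "median",
) -> PooledRatios:
    """Convenience chain: orient -> normalize -> pool -> substitute extremes."""
    oriented = orient_ratios(records, design)
    matrix = build_ratio_matrix(oriented, design)
    pooled = pool_replicates(matrix, design, statistic=statistic)
    return substitute_extremes(pooled)
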