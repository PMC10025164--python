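"""Tabular input/output for the lysosome-enrichment pipeline.

All on-disk formats are plain tab-separated text. Three inputs are read:

* a protein-level quantification table (one row per protein per cell line per
  replicate, carrying SILAC ratios, iBAQ intensities and peptide counts),
* a study-design table saying which SILAC channel received SPIONs in each
  replicate (label switching), and
* an annotation catalog flagging putative lysosomal proteins, subcellular
  compartments, functional class and whether a protein was previously
  reported as lysosomal.

Column names in quantification tables differ between search engines, so
:func:`read_quant_table` takes an explicit column map instead of hard-coding
an export layout. Missing values are empty cells on disk; "NA"/"NaN" tokens
are also accepted on read. Sentinel ratios (the arbitrary 100 / 0.01 codes a
search engine emits for one-channel-only detections) are parsed verbatim and
never coerced to missing — downstream stages treat them specially.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import (
    CatalogError,
    DesignError,
    FormatError,
    ParseError,
    VocabularyError,
)

#: tokens treated as missing when reading numeric cells
MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "NAN", "na", "N/A"})

#: closed vocabulary of subcellular compartment labels
COMPARTMENT_VOCAB = frozenset(
    {
        "lysosome",
        "endosome",
        "nucleus",
        "mitochondria",
        "er",
        "golgi",
        "cytoskeleton",
        "ribosome",
        "proteasome",
        "cytoplasm",
        "plasma_membrane",
        "peroxisome",
        "secreted",
    }
)

#: maximum number of distinct functional classes a catalog may declare
MAX_FUNCTIONAL_CLASSES = 32

#: default quant-table column map (field name -> column header)
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "protein_id": "protein_id",
    "gene_symbol": "gene_symbol",
    "cell_line": "cell_line",
    "replicate": "replicate",
    "ratio_heavy_over_light": "ratio_hl",
    "reported_spions_over_control": "ratio_sc",
    "ibaq": "ibaq",
    "unique_peptides": "unique_peptides",
}

LIGHT = "light"
HEAVY = "heavy"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Which SILAC channel received SPIONs in every (cell line, replicate).

    ``sentinel_high`` / ``sentinel_low`` are the arbitrary ratio codes used
    for proteins detected in only one channel; ``min_valid_replicates`` is
    the minimum number of valid replicate values required to retain a
    protein in a cell line.
    """

    cell_lines: tuple[str, ...]
    replicates_per_line: int
    channel_of_spions: Mapping[tuple[str, int], str]
    sentinel_high: float = 100.0
    sentinel_low: float = 0.01
    min_valid_replicates: int = 3

    def __post_init__(self) -> None:
        if not (self.sentinel_low < 1.0 < self.sentinel_high):
            raise DesignError(
                f"sentinels must satisfy low < 1 < high, got "
                f"({self.sentinel_low}, {self.sentinel_high})"
            )
        if self.min_valid_replicates > self.replicates_per_line:
            raise DesignError(
                f"min_valid_replicates={self.min_valid_replicates} exceeds "
                f"replicates_per_line={self.replicates_per_line}"
            )
        for line in self.cell_lines:
            for rep in self.replicates(line):
                ch = self.channel_of_spions.get((line, rep))
                if ch not in (LIGHT, HEAVY):
                    raise DesignError(
                        f"({line}, {rep}) has SPIONs channel {ch!r}; "
                        f"expected 'light' or 'heavy'"
                    )

    def replicates(self, cell_line: str) -> range:
        """Replicate numbers of one cell line (1-based)."""
        return range(1, self.replicates_per_line + 1)

    def spions_channel(self, cell_line: str, replicate: int) -> str:
        try:
            return self.channel_of_spions[(cell_line, replicate)]
        except KeyError:
            raise DesignError(
                f"({cell_line}, {replicate}) is not part of the study design"
            ) from None

    def flipped(self) -> "StudyDesign":
        """Design with every SPIONs channel swapped (light <-> heavy)."""
        swapped = {
            key: (HEAVY if ch == LIGHT else LIGHT)
            for key, ch in self.channel_of_spions.items()
        }
        return dataclasses.replace(self, channel_of_spions=swapped)


@dataclass(frozen=True)
class QuantRecord:
    """One protein x cell line x replicate quantification observation."""

    protein_id: str
    cell_line: str
    replicate: int
    gene_symbol: str = ""
    ratio_heavy_over_light: float | None = None
    reported_spions_over_control: float | None = None
    ibaq: float | None = None
    unique_peptides: int = 0


@dataclass(frozen=True)
class CatalogEntry:
    putative_lysosomal: bool
    compartments: frozenset[str]
    functional_class: str | None
    previously_reported_lysosomal: bool


@dataclass
class AnnotationCatalog:
    """Per-protein annotation; proteins absent from the catalog are unannotated."""

    entries: dict[str, CatalogEntry] = field(default_factory=dict)

    def is_putative_lysosomal(self, protein_id: str) -> bool:
        e = self.entries.get(protein_id)
        return e.putative_lysosomal if e else False

    def compartments(self, protein_id: str) -> frozenset[str]:
        e = self.entries.get(protein_id)
        return e.compartments if e else frozenset()

    def functional_class(self, protein_id: str) -> str | None:
        e = self.entries.get(protein_id)
        return e.functional_class if e else None

    def previously_reported(self, protein_id: str) -> bool:
        e = self.entries.get(protein_id)
        return e.previously_reported_lysosomal if e else False

    def add(self, protein_id: str, entry: CatalogEntry) -> None:
        if entry.putative_lysosomal and "lysosome" not in entry.compartments:
            raise CatalogError(
                f"{protein_id}: putative_lysosomal requires 'lysosome' "
                f"among its compartments"
            )
        unknown = entry.compartments - COMPARTMENT_VOCAB
        if unknown:
            raise VocabularyError(
                f"{protein_id}: unknown compartment label(s) {sorted(unknown)}"
            )
        self.entries[protein_id] = entry


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _parse_float(token: str, column: str, row: int) -> float | None:
    token = token.strip()
    if token in MISSING_TOKENS:
        return None
    try:
        value = float(token)
    except ValueError:
        raise ParseError(
            f"row {row}: non-numeric value {token!r} in column {column!r}"
        ) from None
    if math.isnan(value):
        return None
    return value


def _parse_int(token: str, column: str, row: int, default: int = 0) -> int:
    token = token.strip()
    if token in MISSING_TOKENS:
        return default
    try:
        return int(float(token))
    except ValueError:
        raise ParseError(
            f"row {row}: non-integer value {token!r} in column {column!r}"
        ) from None


def _parse_bool(token: str, column: str, row: int) -> bool:
    t = token.strip().lower()
    if t in {"1", "true", "yes", "y"}:
        return True
    if t in {"0", "false", "no", "n", ""}:
        return False
    raise ParseError(f"row {row}: non-boolean value {token!r} in column {column!r}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_quant_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[QuantRecord]:
    """Read a protein-level quantification table.

    ``column_map`` maps :class:`QuantRecord` field names to the column
    headers of the file at hand; fields left out of the map (other than
    ``protein_id``, ``cell_line`` and ``replicate``) are simply absent from
    every record. Empty cells become missing values; sentinel ratios are
    kept verbatim.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    frame = _read_tsv(path)
    required = ("protein_id", "cell_line", "replicate")
    for fieldname in required:
        if fieldname not in cmap:
            raise FormatError(f"column map lacks required field {fieldname!r}")
    for fieldname, colname in cmap.items():
        if colname not in frame.columns:
            raise FormatError(
                f"mapped column {colname!r} (field {fieldname!r}) "
                f"not found in {path}"
            )

    records: list[QuantRecord] = []
    seen: set[tuple[str, str, int]] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1 = header
        get = lambda f: getattr(row, cmap[f]) if f in cmap else ""  # noqa: E731
        protein_id = str(get("protein_id")).strip()
        if not protein_id:
            raise ParseError(f"row {i}: empty protein_id")
        cell_line = str(get("cell_line")).strip()
        replicate = _parse_int(str(get("replicate")), cmap["replicate"], i)
        key = (protein_id, cell_line, replicate)
        if key in seen:
            raise FormatError(
                f"row {i}: duplicate (protein_id, cell_line, replicate) {key}"
            )
        seen.add(key)
        records.append(
            QuantRecord(
                protein_id=protein_id,
                cell_line=cell_line,
                replicate=replicate,
                gene_symbol=str(get("gene_symbol")).strip(),
                ratio_heavy_over_light=(
                    _parse_float(str(get("ratio_heavy_over_light")),
                                 cmap.get("ratio_heavy_over_light", ""), i)
                    if "ratio_heavy_over_light" in cmap
                    else None
                ),
                reported_spions_over_control=(
                    _parse_float(str(get("reported_spions_over_control")),
                                 cmap.get("reported_spions_over_control", ""), i)
                    if "reported_spions_over_control" in cmap
                    else None
                ),
                ibaq=(
                    _parse_float(str(get("ibaq")), cmap.get("ibaq", ""), i)
                    if "ibaq" in cmap
                    else None
                ),
                unique_peptides=(
                    _parse_int(str(get("unique_peptides")),
                               cmap.get("unique_peptides", ""), i)
                    if "unique_peptides" in cmap
                    else 0
                ),
            )
        )
    return records


def read_design(path: str | Path, **overrides) -> StudyDesign:
    """Read a study-design table (columns cell_line, replicate, spions_channel).

    Keyword overrides (``sentinel_high``, ``sentinel_low``,
    ``min_valid_replicates``) are passed to :class:`StudyDesign`.
    """
    frame = _read_tsv(path)
    for col in ("cell_line", "replicate", "spions_channel"):
        if col not in frame.columns:
            raise FormatError(f"design table lacks column {col!r}")
    channel: dict[tuple[str, int], str] = {}
    lines: list[str] = []
    reps_per_line: dict[str, set[int]] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        line = str(row.cell_line).strip()
        rep = _parse_int(str(row.replicate), "replicate", i)
        ch = str(row.spions_channel).strip().lower()
        if ch not in (LIGHT, HEAVY):
            raise DesignError(
                f"row {i}: spions_channel {ch!r} outside {{light, heavy}}"
            )
        if (line, rep) in channel:
            raise DesignError(f"row {i}: duplicate design entry ({line}, {rep})")
        channel[(line, rep)] = ch
        if line not in reps_per_line:
            lines.append(line)
            reps_per_line[line] = set()
        reps_per_line[line].add(rep)

    counts = {line: len(reps) for line, reps in reps_per_line.items()}
    n_reps = max(counts.values(), default=0)
    for line, reps in reps_per_line.items():
        if reps != set(range(1, n_reps + 1)):
            raise DesignError(
                f"cell line {line!r} has replicates {sorted(reps)}; "
                f"expected 1..{n_reps} in every line"
            )
    return StudyDesign(
        cell_lines=tuple(lines),
        replicates_per_line=n_reps,
        channel_of_spions=channel,
        **overrides,
    )


def read_catalog(path: str | Path) -> AnnotationCatalog:
    """Read an annotation catalog table.

    Expected columns: protein_id, putative_lysosomal, compartments
    (semicolon-separated), functional_class (may be empty),
    previously_reported. Compartment labels must come from
    :data:`COMPARTMENT_VOCAB`; a protein has at most one functional class.
    """
    frame = _read_tsv(path)
    for col in ("protein_id", "putative_lysosomal", "compartments"):
        if col not in frame.columns:
            raise FormatError(f"catalog table lacks column {col!r}")
    has_class = "functional_class" in frame.columns
    has_prev = "previously_reported" in frame.columns

    catalog = AnnotationCatalog()
    classes_seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        pid = str(row.protein_id).strip()
        if not pid:
            raise ParseError(f"row {i}: empty protein_id")
        compartments = frozenset(
            tok.strip()
            for tok in str(row.compartments).split(";")
            if tok.strip()
        )
        fclass: str | None = None
        if has_class:
            raw = str(row.functional_class).strip()
            if ";" in raw:
                raise CatalogError(
                    f"row {i}: {pid} maps to multiple functional classes {raw!r}; "
                    f"classes form a partition"
                )
            fclass = raw or None
        if fclass is not None:
            classes_seen.add(fclass)
            if len(classes_seen) > MAX_FUNCTIONAL_CLASSES:
                raise CatalogError(
                    f"catalog declares more than {MAX_FUNCTIONAL_CLASSES} "
                    f"functional classes"
                )
        entry = CatalogEntry(
            putative_lysosomal=_parse_bool(
                str(row.putative_lysosomal), "putative_lysosomal", i
            ),
            compartments=compartments,
            functional_class=fclass,
            previously_reported_lysosomal=(
                _parse_bool(str(row.previously_reported), "previously_reported", i)
                if has_prev
                else False
            ),
        )
        catalog.add(pid, entry)
    return catalog


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_SORT_PREFERENCE: tuple[str, ...] = ("protein_id", "cell_line", "replicate",
                                     "functional_class", "category", "pattern", "k")


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    float_format: str = "%.10g",
) -> dict[str, Path]:
    """Write result tables as byte-stable TSV files.

    Rows are sorted by protein_id then cell_line (when those columns exist,
    falling back to other identifier columns), floats are formatted with a
    fixed format string and missing values become empty cells, so writing
    the same tables twice produces identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        sort_cols = [c for c in _SORT_PREFERENCE if c in table.columns]
        if sort_cols:
            table = table.sort_values(sort_cols, kind="mergesort")
        path = out / f"{name}.tsv"
        table.to_csv(
            path,
            sep="\t",
            index=False,
            na_rep="",
            float_format=float_format,
            lineterminator="\n",
        )
        written[name] = path
    return written


# ---------------------------------------------------------------------------
# frame conversion
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = [
    "protein_id",
    "gene_symbol",
    "cell_line",
    "replicate",
    "ratio_heavy_over_light",
    "reported_spions_over_control",
    "ibaq",
    "unique_peptides",
]


def records_to_frame(records: Iterable[QuantRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of quantification records."""
    rows = [dataclasses.asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    for col in ("ratio_heavy_over_light", "reported_spions_over_control", "ibaq"):
        frame[col] = pd.to_numeric(frame[col])
    return frame


def write_records(
    records: Sequence[QuantRecord],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> Path:
    """Write records in the TSV layout that :func:`read_quant_table` reads."""
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    frame = records_to_frame(records).rename(columns=cmap)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, na_rep="",
                 float_format="%.10g", lineterminator="\n")
    return path
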