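"""Ground-truthed synthetic SILAC SPIONs lysosome-enrichment studies.

The generator emulates the statistical structure the analysis assumes: six
cell lines with four replicates each and SILAC label switching (two
replicates receive SPIONs in the light channel, two in the heavy), per-line
log2 SPIONs/control ratios drawn from a background component centred near 0
and a right-shifted enriched (lysosomal) component, replicate-level noise,
missing values, sentinel-coded one-channel detections, lognormal iBAQ
intensities with a high-peptide-count V-ATPase reference set, and a
lysosomal membership with a core shared by all lines plus line-specific
proteins. A whole-cell-lysate companion table re-noises the same latent
abundances with a fraction-specific offset so that background proteins are
relatively more abundant in the lysate than in the lysosome-enriched
fraction.

All randomness flows through a single generator seeded once and consumed in
a fixed, documented order (protein universe, line membership, latent
ratios, sentinels, replicate noise, missing mask, iBAQ, peptide counts,
catalog annotations, whole cell lysate), so identical configurations give
byte-identical output tables.

Reference subunit accessions and all other identifiers are synthetic
stand-ins, not real database accessions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .quant_io import (
    HEAVY,
    LIGHT,
    AnnotationCatalog,
    CatalogEntry,
    QuantRecord,
    StudyDesign,
    write_records,
)

_DEFAULT_LINE_NAMES = ("HEK293", "HeLa", "HuH7", "SHSY5Y", "MEF", "NIH3T3")

#: synthetic gene symbols for the V-ATPase reference subunits
_REFERENCE_SYMBOLS = (
    "ATP6V1A", "ATP6V1B2", "ATP6V1D", "ATP6V1E1",
    "ATP6V1F", "ATP6V1G1", "ATP6V1H", "ATP6V0D1",
)

_LYSO_CLASSES = (
    "hydrolase", "transporter", "channel", "mtorc1",
    "membrane_trafficking", "lipid_metabolism", "glycosidase", "accessory",
)
_BG_CLASSES = ("ribosomal_protein", "proteasome_subunit", "metabolic_enzyme")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generation settings.

    Defaults reproduce the structure of a six-line, four-replicate screen:
    ~2000 proteins of which 15% are lysosomal, background log2 ratios
    N(0, 0.6) and lysosomal N(2.2, 0.7), 10% missing cells and 5% of
    lysosomal proteins detected only in the SPIONs channel (sentinels).
    """

    n_lines: int = 6
    n_replicates: int = 4
    n_background: int = 1700
    n_lysosomal: int = 300
    core_fraction: float = 0.5
    mu_bg: float = 0.0
    sigma_bg: float = 0.6
    mu_lyso: float = 2.2
    sigma_lyso: float = 0.7
    missing_rate: float = 0.10
    sentinel_rate: float = 0.05
    replicate_noise_sd: float = 0.30
    ibaq_log_mean: float = 16.0
    ibaq_log_sd: float = 2.0
    ibaq_replicate_log_sd: float = 0.20
    n_reference_subunits: int = 8
    previously_reported_fraction: float = 0.6
    wcl_background_log_boost: float = 1.5
    sentinel_high: float = 100.0
    sentinel_low: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("core_fraction", "missing_rate", "sentinel_rate",
                     "previously_reported_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("sigma_bg", "sigma_lyso", "replicate_noise_sd",
                     "ibaq_log_sd", "ibaq_replicate_log_sd"):
            if getattr(self, name) < 0 or (
                name in ("sigma_bg", "sigma_lyso") and getattr(self, name) == 0
            ):
                raise ConfigError(f"{name} must be positive")
        if self.mu_lyso <= self.mu_bg:
            raise ConfigError("mu_lyso must exceed mu_bg")
        if self.n_lines < 1 or self.n_replicates < 1:
            raise ConfigError("need at least one line and one replicate")

    @property
    def cell_lines(self) -> tuple[str, ...]:
        if self.n_lines == len(_DEFAULT_LINE_NAMES):
            return _DEFAULT_LINE_NAMES
        return tuple(f"line{i + 1}" for i in range(self.n_lines))


@dataclass
class GroundTruth:
    """What the generator actually simulated.

    ``proteins``: per protein — is_lysosomal, is_reference, is_sentinel,
    previously_reported, lines_present (joined with '+'), n_lines_present.
    ``latent``: per (protein, cell line) — the true log2 SPIONs/control
    ratio before replicate noise.
    """

    proteins: pd.DataFrame
    latent: pd.DataFrame

    def lysosomal_ids(self, include_sentinels: bool = True) -> list[str]:
        sub = self.proteins[self.proteins["is_lysosomal"]]
        if not include_sentinels:
            sub = sub[~sub["is_sentinel"]]
        return sub["protein_id"].tolist()

    def background_ids(self) -> list[str]:
        return self.proteins[~self.proteins["is_lysosomal"]][
            "protein_id"
        ].tolist()


@dataclass
class SimulatedStudy:
    records: list[QuantRecord]
    design: StudyDesign
    catalog: AnnotationCatalog
    truth: GroundTruth
    wcl_records: list[QuantRecord] = field(default_factory=list)


def _default_design(config: SimulationConfig) -> StudyDesign:
    """First half of the replicates receive SPIONs in the light channel."""
    channel: dict[tuple[str, int], str] = {}
    half = config.n_replicates // 2
    for line in config.cell_lines:
        for rep in range(1, config.n_replicates + 1):
            channel[(line, rep)] = LIGHT if rep <= half else HEAVY
    return StudyDesign(
        cell_lines=config.cell_lines,
        replicates_per_line=config.n_replicates,
        channel_of_spions=channel,
        sentinel_high=config.sentinel_high,
        sentinel_low=config.sentinel_low,
    )


def simulate_mixture_sample(
    n: int,
    lambda_lyso: float,
    mu_bg: float,
    sigma_bg: float,
    mu_lyso: float,
    sigma_lyso: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n values from the two-component normal mixture with true labels."""
    if n < 0:
        raise ValueError(f"n must be nonnegative, got {n}")
    rng = np.random.default_rng(seed)
    labels = rng.random(n) < lambda_lyso
    values = np.where(
        labels,
        rng.normal(mu_lyso, sigma_lyso, n),
        rng.normal(mu_bg, sigma_bg, n),
    )
    return values, labels


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a complete ground-truthed study (see module docstring)."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    design = _default_design(cfg)
    lines = list(cfg.cell_lines)
    n_lines = cfg.n_lines

    # 1) protein universe -------------------------------------------------
    width = max(4, len(str(cfg.n_background + cfg.n_lysosomal)))
    ref_ids = [f"REF{i + 1:03d}" for i in range(cfg.n_reference_subunits)]
    lyso_ids = [f"LYSO{i + 1:0{width}d}" for i in range(cfg.n_lysosomal)]
    bg_ids = [f"BG{i + 1:0{width}d}" for i in range(cfg.n_background)]
    n_core = int(round(cfg.core_fraction * cfg.n_lysosomal))

    # 2) line membership ---------------------------------------------------
    lines_present: dict[str, tuple[str, ...]] = {}
    for pid in ref_ids:
        lines_present[pid] = tuple(lines)
    for i, pid in enumerate(lyso_ids):
        if i < n_core or n_lines < 3:
            lines_present[pid] = tuple(lines)
        else:
            k = int(rng.integers(2, n_lines))  # 2..n_lines-1 lines
            chosen = rng.choice(n_lines, size=k, replace=False)
            lines_present[pid] = tuple(lines[j] for j in sorted(chosen))
    for pid in bg_ids:
        k = int(rng.integers(1, n_lines + 1))  # 1..n_lines lines
        chosen = rng.choice(n_lines, size=k, replace=False)
        lines_present[pid] = tuple(lines[j] for j in sorted(chosen))

    all_ids = ref_ids + lyso_ids + bg_ids
    is_lyso = {pid: pid not in set(bg_ids) for pid in all_ids}

    # 3) latent per-line log2 ratios --------------------------------------
    latent_rows = []
    latent: dict[tuple[str, str], float] = {}
    for pid in all_ids:
        for line in lines_present[pid]:
            if is_lyso[pid]:
                value = rng.normal(cfg.mu_lyso, cfg.sigma_lyso)
            else:
                value = rng.normal(cfg.mu_bg, cfg.sigma_bg)
            latent[(pid, line)] = value
            latent_rows.append(
                {"protein_id": pid, "cell_line": line, "true_log2_ratio": value}
            )

    # 4) sentinel proteins (SPIONs-channel-only detections) ----------------
    is_sentinel = {pid: False for pid in all_ids}
    for pid in lyso_ids:
        if rng.random() < cfg.sentinel_rate:
            is_sentinel[pid] = True

    # 5-7) replicate observations, missingness, iBAQ, peptide counts -------
    ibaq_base = {pid: rng.normal(cfg.ibaq_log_mean, cfg.ibaq_log_sd)
                 for pid in all_ids}
    peptides = {
        pid: int(rng.integers(10, 41)) if pid in set(ref_ids)
        else int(rng.integers(1, 10))
        for pid in all_ids
    }
    symbols = {pid: f"G{pid}" for pid in all_ids}
    for pid, sym in zip(ref_ids, _REFERENCE_SYMBOLS):
        symbols[pid] = sym

    records: list[QuantRecord] = []
    for pid in all_ids:
        for line in lines_present[pid]:
            for rep in range(1, cfg.n_replicates + 1):
                if rng.random() < cfg.missing_rate:
                    continue  # cell not detected in this replicate at all
                obs = latent[(pid, line)] + rng.normal(0, cfg.replicate_noise_sd)
                ibaq = float(
                    np.exp(ibaq_base[pid]
                           + rng.normal(0, cfg.ibaq_replicate_log_sd))
                )
                if is_sentinel[pid]:
                    records.append(
                        QuantRecord(
                            protein_id=pid,
                            gene_symbol=symbols[pid],
                            cell_line=line,
                            replicate=rep,
                            reported_spions_over_control=cfg.sentinel_high,
                            ibaq=ibaq,
                            unique_peptides=peptides[pid],
                        )
                    )
                    continue
                channel = design.spions_channel(line, rep)
                hl = float(2.0 ** obs) if channel == HEAVY else float(2.0 ** -obs)
                records.append(
                    QuantRecord(
                        protein_id=pid,
                        gene_symbol=symbols[pid],
                        cell_line=line,
                        replicate=rep,
                        ratio_heavy_over_light=hl,
                        ibaq=ibaq,
                        unique_peptides=peptides[pid],
                    )
                )

    # 8) annotation catalog -------------------------------------------------
    catalog = AnnotationCatalog()
    prev_reported: dict[str, bool] = {}
    for pid in all_ids:
        if is_lyso[pid]:
            compartments = {"lysosome"}
            if rng.random() < 0.3:
                compartments.add("endosome")
            if pid in set(ref_ids):
                fclass = "v-atpase"
                prev = True
            else:
                fclass = _LYSO_CLASSES[int(rng.integers(len(_LYSO_CLASSES)))]
                prev = bool(rng.random() < cfg.previously_reported_fraction)
            catalog.add(
                pid,
                CatalogEntry(
                    putative_lysosomal=True,
                    compartments=frozenset(compartments),
                    functional_class=fclass,
                    previously_reported_lysosomal=prev,
                ),
            )
            prev_reported[pid] = prev
        else:
            pool = sorted({"nucleus", "mitochondria", "er", "golgi",
                           "cytoskeleton", "ribosome", "proteasome",
                           "cytoplasm", "plasma_membrane"})
            k = int(rng.integers(1, 3))
            comp = frozenset(
                pool[j] for j in rng.choice(len(pool), size=k, replace=False)
            )
            fclass = (
                _BG_CLASSES[int(rng.integers(len(_BG_CLASSES)))]
                if rng.random() < 0.2
                else None
            )
            catalog.add(
                pid,
                CatalogEntry(
                    putative_lysosomal=False,
                    compartments=comp,
                    functional_class=fclass,
                    previously_reported_lysosomal=False,
                ),
            )
            prev_reported[pid] = False

    # 9) whole-cell-lysate companion (iBAQ only) ---------------------------
    wcl_records: list[QuantRecord] = []
    for pid in all_ids:
        boost = 0.0 if is_lyso[pid] else cfg.wcl_background_log_boost
        for line in lines_present[pid]:
            for rep in range(1, cfg.n_replicates + 1):
                if rng.random() < cfg.missing_rate:
                    continue
                ibaq = float(
                    np.exp(ibaq_base[pid] + boost
                           + rng.normal(0, cfg.ibaq_replicate_log_sd))
                )
                wcl_records.append(
                    QuantRecord(
                        protein_id=pid,
                        gene_symbol=symbols[pid],
                        cell_line=line,
                        replicate=rep,
                        ibaq=ibaq,
                        unique_peptides=peptides[pid],
                    )
                )

    proteins = pd.DataFrame(
        {
            "protein_id": all_ids,
            "gene_symbol": [symbols[p] for p in all_ids],
            "is_lysosomal": [is_lyso[p] for p in all_ids],
            "is_reference": [p in set(ref_ids) for p in all_ids],
            "is_sentinel": [is_sentinel[p] for p in all_ids],
            "previously_reported": [prev_reported[p] for p in all_ids],
            "lines_present": ["+".join(lines_present[p]) for p in all_ids],
            "n_lines_present": [len(lines_present[p]) for p in all_ids],
        }
    )
    truth = GroundTruth(proteins=proteins, latent=pd.DataFrame(latent_rows))
    return SimulatedStudy(
        records=records,
        design=design,
        catalog=catalog,
        truth=truth,
        wcl_records=wcl_records,
    )


def reference_ids(config: SimulationConfig | None = None) -> tuple[str, ...]:
    """Identifiers of the simulated V-ATPase reference subunits."""
    cfg = config or SimulationConfig()
    return tuple(f"REF{i + 1:03d}" for i in range(cfg.n_reference_subunits))


# ---------------------------------------------------------------------------
# writing a study to disk in the formats quant_io reads
# ---------------------------------------------------------------------------


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write quant/design/catalog/ground-truth tables for a simulated study."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["quant_table"] = write_records(study.records, out / "quant_table.tsv")
    if study.wcl_records:
        paths["wcl_table"] = write_records(study.wcl_records,
                                           out / "wcl_table.tsv")

    design_rows = [
        {"cell_line": line, "replicate": rep, "spions_channel": ch}
        for (line, rep), ch in sorted(study.design.channel_of_spions.items())
    ]
    p = out / "design.tsv"
    pd.DataFrame(design_rows).to_csv(p, sep="\t", index=False,
                                     lineterminator="\n")
    paths["design"] = p

    cat_rows = [
        {
            "protein_id": pid,
            "putative_lysosomal": int(e.putative_lysosomal),
            "compartments": ";".join(sorted(e.compartments)),
            "functional_class": e.functional_class or "",
            "previously_reported": int(e.previously_reported_lysosomal),
        }
        for pid, e in sorted(study.catalog.entries.items())
    ]
    p = out / "catalog.tsv"
    pd.DataFrame(cat_rows).to_csv(p, sep="\t", index=False, lineterminator="\n")
    paths["catalog"] = p

    p = out / "truth_proteins.tsv"
    study.truth.proteins.to_csv(p, sep="\t", index=False, lineterminator="\n")
    paths["truth_proteins"] = p
    p = out / "truth_latent.tsv"
    study.truth.latent.to_csv(p, sep="\t", index=False, float_format="%.10g",
                              lineterminator="\n")
    paths["truth_latent"] = p
    return paths


# ---------------------------------------------------------------------------
# small hand-checkable fixtures with expected-output companions
# ---------------------------------------------------------------------------


def emit_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the hand-computed unit fixtures and their expected outputs.

    * pooling: 5 proteins x 4 heavy-SPIONs replicates in one line,
      exercising median normalization, the >=3-valid-replicates filter and
      sentinel substitution;
    * upset: 8 proteins x 3 lines covering all 7 nonempty patterns;
    * class sums: 10 proteins across 2 lines and 4 declared classes, one of
      which stays empty.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, frame: pd.DataFrame) -> None:
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False, lineterminator="\n")
        paths[name] = p

    # ---- pooling fixture -------------------------------------------------
    # heavy-SPIONs in all replicates, so S/C = H/L. Hand computation:
    # valid log2 per replicate, median-centred per replicate, then median
    # across replicates; P3 has 2 valid < 3 -> dropped; P4 all-sentinel ->
    # extreme high, substituted with max finite pooled x (1.25).
    pooling_rows = []
    ratios = {
        "P1": [2, 2, 2, 2],
        "P2": [1, 1, 1, None],
        "P3": [0.5, 0.5, None, None],
        "P4": [100, 100, 100, 100],
        "P5": [4, 4, 4, 4],
    }
    for pid, values in ratios.items():
        for rep, v in enumerate(values, start=1):
            pooling_rows.append(
                {
                    "protein_id": pid,
                    "gene_symbol": f"G{pid}",
                    "cell_line": "L1",
                    "replicate": rep,
                    "ratio_hl": "" if v is None else v,
                    "ratio_sc": "",
                    "ibaq": "",
                    "unique_peptides": 1,
                }
            )
    _write("pooling_quant", pd.DataFrame(pooling_rows))
    _write(
        "pooling_design",
        pd.DataFrame(
            {
                "cell_line": ["L1"] * 4,
                "replicate": [1, 2, 3, 4],
                "spions_channel": ["heavy"] * 4,
            }
        ),
    )
    _write(
        "pooling_expected_pooled",
        pd.DataFrame(
            {
                "protein_id": ["P1", "P2", "P4", "P5"],
                "x_log2": [0.25, -0.5, 1.25, 1.25],
                "n_valid": [4, 3, 0, 4],
                "extreme": ["none", "none", "high", "none"],
            }
        ),
    )
    _write(
        "pooling_expected_drops",
        pd.DataFrame({"protein_id": ["P3"]}),
    )

    # ---- upset fixture ---------------------------------------------------
    grid = pd.DataFrame(
        {
            "protein_id": [f"Q{i}" for i in range(1, 9)],
            "A": [1, 0, 0, 1, 1, 0, 1, 1],
            "B": [0, 1, 0, 1, 0, 1, 1, 1],
            "C": [0, 0, 1, 0, 1, 1, 1, 1],
        }
    )
    _write("upset_membership", grid)
    _write(
        "upset_expected_counts",
        pd.DataFrame(
            {
                "pattern": ["A", "B", "C", "A+B", "A+C", "B+C", "A+B+C"],
                "count": [1, 1, 1, 1, 1, 1, 2],
            }
        ),
    )

    # ---- class-sum fixture ----------------------------------------------
    # Reference subunit REF1 (iBAQ 10, 12 peptides) gives replicate medians
    # of 10, so normalized values are ibaq/10; constant across replicates,
    # so line medians equal the per-replicate values. Expected sums per
    # line: hydrolase 0.2+0.3 = 0.5, transporter 1.0+0.5+0.25 = 1.75,
    # v-atpase 1.0; metabolic_enzyme declared only by a non-lysosomal
    # protein -> empty (sum 0). P_F1 exists in one line only -> filtered.
    ibaqs = {
        "REF1": 10.0, "P_H1": 2.0, "P_H2": 3.0, "P_T1": 10.0, "P_T2": 5.0,
        "P_T3": 2.5, "P_N1": 4.0, "P_N2": 6.0, "P_F1": 8.0, "P_X1": 9.0,
    }
    class_rows = []
    for pid, val in ibaqs.items():
        lines = ["L1"] if pid == "P_F1" else ["L1", "L2"]
        for line in lines:
            for rep in (1, 2, 3):
                class_rows.append(
                    {
                        "protein_id": pid,
                        "gene_symbol": f"G{pid}",
                        "cell_line": line,
                        "replicate": rep,
                        "ratio_hl": "",
                        "ratio_sc": "",
                        "ibaq": val,
                        "unique_peptides": 12 if pid == "REF1" else 5,
                    }
                )
    _write("classsum_quant", pd.DataFrame(class_rows))
    _write(
        "classsum_catalog",
        pd.DataFrame(
            {
                "protein_id": ["REF1", "P_H1", "P_H2", "P_T1", "P_T2", "P_T3",
                               "P_N1", "P_N2", "P_F1", "P_X1"],
                "putative_lysosomal": [1, 1, 1, 1, 1, 1, 1, 0, 1, 0],
                "compartments": ["lysosome"] * 7 + ["nucleus", "lysosome",
                                                    "cytoplasm"],
                "functional_class": ["v-atpase", "hydrolase", "hydrolase",
                                     "transporter", "transporter",
                                     "transporter", "", "", "hydrolase",
                                     "metabolic_enzyme"],
                "previously_reported": [1, 1, 0, 1, 0, 0, 0, 0, 0, 0],
            }
        ),
    )
    expected_sums = []
    for line in ("L1", "L2"):
        for fclass, total in (
            ("hydrolase", 0.5),
            ("metabolic_enzyme", 0.0),
            ("transporter", 1.75),
            ("v-atpase", 1.0),
        ):
            expected_sums.append(
                {"cell_line": line, "functional_class": fclass,
                 "class_sum": total}
            )
    _write("classsum_expected", pd.DataFrame(expected_sums))
    return paths


def study_to_config_dict(cfg: SimulationConfig) -> dict:
    """Plain-dict view of a simulation config (for manifests and YAML)."""
    return dataclasses.asdict(cfg)
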