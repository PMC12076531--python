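"""From MS-scale fmol to absolute units via the experimental parameters.

The experimental-parameters table carries, per condition, the wet-lab
numbers that connect what the mass spectrometer saw to the culture it came
from: volume and protein concentration of the digested extract, amount
injected, cell density and harvested culture volume, and — for subproteome
workflows — the enrichment settings.  Expected column names (matched
case-insensitively): Condition, SampleVolume, ProteinConcentration,
AmountMS, CellsPerML, TotalCultureVolume, ProteinSRM, fmolSRM, Enrichment,
EnrichmentMode, StdDilution, StdVolume.

Unit conventions: SampleVolume and StdVolume in µL, ProteinConcentration in
µg/µL, AmountMS in µg, CellsPerML in cells/mL, TotalCultureVolume in µL by
default (``culture_volume_unit='mL'`` switches to the other common
convention).

Three absolute units are produced per protein and sample:

- ``fmol_total``  = fmol_ms x (SampleVolume x ProteinConcentration) / AmountMS
- ``ng_per_ug``   = fmol_ms x MW[kDa] x 1e-3 / AmountMS
- ``molecules_per_cell`` = fmol_total_corrected x 1e-15 x N_A / cells_total

where ``fmol_total_corrected`` divides by the enrichment factor when an
enrichment or concentration step applies, and N_A is Avogadro's constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import AbsoluteQuantResult

__all__ = [
    "ExperimentalParams",
    "EnrichmentStandards",
    "EnrichmentFactor",
    "read_params",
    "read_standards",
    "compute_enrichment",
    "srm_enrichment",
    "to_absolute",
    "mol_weights_from_fasta",
    "samples_for_condition",
]

AVOGADRO = 6.02214076e23  # mol^-1, SI exact

_COLUMN_ALIASES = {
    "condition": "condition",
    "samplevolume": "sample_volume_ul",
    "proteinconcentration": "protein_conc_ug_per_ul",
    "amountms": "amount_ms_ug",
    "cellsperml": "cells_per_ml",
    "totalculturevolume": "total_culture_volume",
    "proteinsrm": "protein_srm",
    "fmolsrm": "fmol_srm",
    "enrichment": "enrichment",
    "enrichmentmode": "enrichment_mode",
    "stddilution": "std_dilution",
    "stdvolume": "std_volume_ul",
}

MANDATORY_COLUMNS = ("Condition", "SampleVolume", "ProteinConcentration", "AmountMS")


@dataclass
class ExperimentalParams:
    """One condition's sample-preparation record."""

    condition: str
    sample_volume_ul: float
    protein_conc_ug_per_ul: float
    amount_ms_ug: float
    cells_per_ml: float | None = None
    total_culture_volume: float | None = None
    protein_srm: list[str] | None = None
    fmol_srm: list[float] | None = None
    enrichment: bool = False
    enrichment_mode: str | None = None
    std_dilution: float | None = None
    std_volume_ul: float | None = None
    culture_volume_unit: str = "uL"

    def __post_init__(self) -> None:
        for name in ("sample_volume_ul", "protein_conc_ug_per_ul", "amount_ms_ug"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{self.condition}: {name} must be > 0, got {v!r}")
        for name in ("cells_per_ml", "total_culture_volume", "std_dilution", "std_volume_ul"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"{self.condition}: {name} must be > 0, got {v!r}")
        if (self.protein_srm is None) != (self.fmol_srm is None):
            raise ValueError(f"{self.condition}: ProteinSRM and fmolSRM must come together")
        if self.protein_srm is not None and len(self.protein_srm) != len(self.fmol_srm):
            raise ValueError(
                f"{self.condition}: ProteinSRM and fmolSRM lists differ in length"
            )
        if self.enrichment and not self.has_srm and not (
            self.enrichment_mode and self.std_dilution and self.std_volume_ul
        ):
            raise ValueError(
                f"{self.condition}: Enrichment is TRUE but neither "
                "EnrichmentMode/StdDilution/StdVolume nor SRM columns are given"
            )
        if self.enrichment_mode is not None:
            mode = self.enrichment_mode.strip().lower()
            if mode not in ("enrichment", "concentration"):
                raise ValueError(
                    f"{self.condition}: EnrichmentMode must be Enrichment or "
                    f"Concentration, got {self.enrichment_mode!r}"
                )
            self.enrichment_mode = mode.capitalize()
        if self.culture_volume_unit not in ("uL", "mL"):
            raise ValueError("culture_volume_unit must be 'uL' or 'mL'")

    @property
    def has_srm(self) -> bool:
        return bool(self.protein_srm)

    @property
    def total_protein_ug(self) -> float:
        return self.sample_volume_ul * self.protein_conc_ug_per_ul

    @property
    def cells_total(self) -> float | None:
        if self.cells_per_ml is None or self.total_culture_volume is None:
            return None
        ml = (
            self.total_culture_volume / 1000.0
            if self.culture_volume_unit == "uL"
            else self.total_culture_volume
        )
        return self.cells_per_ml * ml


@dataclass
class EnrichmentStandards:
    """Spiked enrichment standards: accession -> stock concentration (fmol/µL)."""

    entries: dict[str, float]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("enrichment-standards table is empty")
        for acc, conc in self.entries.items():
            if not (np.isfinite(conc) and conc > 0):
                raise ValueError(f"standard {acc!r} has non-positive stock {conc!r}")


@dataclass
class EnrichmentFactor:
    """Multiplicative abundance change introduced by an enrichment step."""

    condition: str
    factor: float
    n_standards: int
    basis: str  # 'spiked_standards' or 'srm_supplied'

    def __post_init__(self) -> None:
        if not (np.isfinite(self.factor) and self.factor > 0):
            raise ValueError(f"enrichment factor must be > 0, got {self.factor!r}")


# ---------------------------------------------------------------------------
# table input
# ---------------------------------------------------------------------------

def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if pd.isna(value) or str(value).strip() == "":
        return False
    text = str(value).strip().lower()
    if text in ("true", "1", "1.0"):
        return True
    if text in ("false", "0", "0.0"):
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def _split_list(value) -> list[str] | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return None
    return [t.strip() for t in text.split(",") if t.strip()]


def _opt_float(value) -> float | None:
    if value is None:
        return None
    v = pd.to_numeric(value, errors="coerce")
    return None if pd.isna(v) else float(v)


def read_params(path, culture_volume_unit: str = "uL") -> list[ExperimentalParams]:
    """Read the experimental-parameters table (TSV or xlsx).

    Column names are matched case-insensitively; optional columns may be
    absent entirely or left blank per row.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t")
    canonical = {}
    for col in df.columns:
        key = str(col).strip().lower().replace(" ", "").replace("_", "")
        if key in _COLUMN_ALIASES:
            canonical[_COLUMN_ALIASES[key]] = col
    for col in MANDATORY_COLUMNS:
        if _COLUMN_ALIASES[col.lower()] not in canonical:
            raise ValueError(f"{path}: mandatory column {col!r} is missing")

    def get(row, name):
        return row[canonical[name]] if name in canonical else None

    records = []
    for _, row in df.iterrows():
        srm_proteins = _split_list(get(row, "protein_srm"))
        srm_fmol_raw = _split_list(get(row, "fmol_srm"))
        srm_fmol = [float(v) for v in srm_fmol_raw] if srm_fmol_raw else None
        records.append(
            ExperimentalParams(
                condition=str(get(row, "condition")).strip(),
                sample_volume_ul=float(get(row, "sample_volume_ul")),
                protein_conc_ug_per_ul=float(get(row, "protein_conc_ug_per_ul")),
                amount_ms_ug=float(get(row, "amount_ms_ug")),
                cells_per_ml=_opt_float(get(row, "cells_per_ml")),
                total_culture_volume=_opt_float(get(row, "total_culture_volume")),
                protein_srm=srm_proteins,
                fmol_srm=srm_fmol,
                enrichment=_parse_bool(get(row, "enrichment")),
                enrichment_mode=(
                    str(get(row, "enrichment_mode")).strip()
                    if _split_list(get(row, "enrichment_mode"))
                    else None
                ),
                std_dilution=_opt_float(get(row, "std_dilution")),
                std_volume_ul=_opt_float(get(row, "std_volume_ul")),
                culture_volume_unit=culture_volume_unit,
            )
        )
    if not records:
        raise ValueError(f"{path}: no parameter rows found")
    return records


def read_standards(path) -> EnrichmentStandards:
    """Read an enrichment-standards table (accession, stock fmol/µL)."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, header=None)
    else:
        df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :2]
    df.columns = ["accession", "stock"]
    if pd.isna(pd.to_numeric(df["stock"].iloc[0], errors="coerce")):
        df = df.iloc[1:]
    entries: dict[str, float] = {}
    for row in df.itertuples(index=False):
        acc = str(row.accession).strip()
        if acc in entries:
            raise ValueError(f"{path}: duplicate standard accession {acc!r}")
        entries[acc] = float(row.stock)
    return EnrichmentStandards(entries=entries)


# ---------------------------------------------------------------------------
# condition <-> sample matching
# ---------------------------------------------------------------------------

def samples_for_condition(samples: list[str], condition: str) -> list[str]:
    """Samples belonging to a condition, by exact or prefix match.

    A sample matches when its replicate-group label equals the condition,
    or one is a prefix of the other (e.g., group 'Cond1' vs condition
    'Cond1_t0').
    """
    from .preprocess import infer_groups

    grouping = infer_groups(list(samples))
    matched = []
    for group_label, members in grouping.groups.items():
        if (
            group_label == condition
            or group_label.startswith(condition)
            or condition.startswith(group_label)
        ):
            matched.extend(m for m in members if m in samples)
    return sorted(matched)


def _map_samples_to_conditions(
    samples: list[str], params: list[ExperimentalParams]
) -> dict[str, ExperimentalParams]:
    mapping: dict[str, ExperimentalParams] = {}
    for p in params:
        for s in samples_for_condition(samples, p.condition):
            if s in mapping and mapping[s].condition != p.condition:
                raise ValueError(
                    f"sample {s!r} matches both condition "
                    f"{mapping[s].condition!r} and {p.condition!r}"
                )
            mapping[s] = p
    unmapped = [s for s in samples if s not in mapping]
    if unmapped:
        raise ValueError(
            f"no parameter row matches sample(s) {unmapped}; "
            f"conditions available: {[p.condition for p in params]}"
        )
    return mapping


# ---------------------------------------------------------------------------
# enrichment factors
# ---------------------------------------------------------------------------

def expected_ms_share_fmol(params: ExperimentalParams, stock_fmol_per_ul: float) -> float:
    """fmol of a spiked standard expected in the MS injection.

    The standard stock is diluted by StdDilution, StdVolume µL of it added
    to the sample, and the injection carries AmountMS of the sample's
    TotalProtein µg.
    """
    added = (stock_fmol_per_ul / params.std_dilution) * params.std_volume_ul
    return added * params.amount_ms_ug / params.total_protein_ug


def compute_enrichment(
    result: AbsoluteQuantResult,
    params: ExperimentalParams,
    standards: EnrichmentStandards,
) -> EnrichmentFactor:
    """Estimate the enrichment factor from spiked standards.

    Per replicate sample of the condition, the ratio measured/expected fmol
    at MS scale is taken per standard and the median over standards formed;
    the factor is the mean of these medians over replicates.
    """
    if not params.enrichment:
        raise ValueError(f"{params.condition}: enrichment is not enabled")
    if params.std_dilution is None or params.std_volume_ul is None:
        raise ValueError(f"{params.condition}: StdDilution/StdVolume required")
    samples = samples_for_condition(result.samples, params.condition)
    if not samples:
        raise ValueError(f"no samples found for condition {params.condition!r}")

    per_sample_medians = []
    used: set[str] = set()
    for s in samples:
        sub = result.for_sample(s)
        first_acc = sub["protein_id"].astype(str).str.split(";").str[0].str.strip()
        ratios = []
        for acc, stock in standards.entries.items():
            rows = sub.loc[first_acc.to_numpy() == acc]
            if rows.empty:
                warnings.warn(
                    f"standard {acc!r} not quantified in sample {s!r}; skipped",
                    stacklevel=2,
                )
                continue
            measured = float(rows["fmol_ms"].iloc[0])
            ratios.append(measured / expected_ms_share_fmol(params, stock))
            used.add(acc)
        if ratios:
            per_sample_medians.append(float(np.median(ratios)))
    if not per_sample_medians:
        raise ValueError(
            f"{params.condition}: no usable enrichment standard in any sample"
        )
    return EnrichmentFactor(
        condition=params.condition,
        factor=float(np.mean(per_sample_medians)),
        n_standards=len(used),
        basis="spiked_standards",
    )


def srm_enrichment(
    result: AbsoluteQuantResult, params: ExperimentalParams
) -> EnrichmentFactor:
    """Enrichment factor from externally supplied (targeted-MS) amounts.

    The supplied fmol are taken to be on the MS-injection basis; per listed
    protein, the ratio of the calibration-estimated fmol (mean over the
    condition's replicates) to the supplied fmol is formed and the factor is
    the median of these ratios.
    """
    if not params.has_srm:
        raise ValueError(f"{params.condition}: no SRM columns supplied")
    samples = samples_for_condition(result.samples, params.condition)
    sub = result.data[result.data["sample"].isin(samples)]
    first_acc = sub["protein_id"].astype(str).str.split(";").str[0].str.strip()
    ratios = []
    for acc, fmol_ref in zip(params.protein_srm, params.fmol_srm):
        rows = sub.loc[first_acc.to_numpy() == acc]
        if rows.empty:
            warnings.warn(
                f"SRM protein {acc!r} absent from the quantified result; skipped",
                stacklevel=2,
            )
            continue
        ratios.append(float(rows["fmol_ms"].mean()) / fmol_ref)
    if not ratios:
        raise ValueError(f"{params.condition}: no usable SRM protein")
    return EnrichmentFactor(
        condition=params.condition,
        factor=float(np.median(ratios)),
        n_standards=len(ratios),
        basis="srm_supplied",
    )


# ---------------------------------------------------------------------------
# absolute units
# ---------------------------------------------------------------------------

def to_absolute(
    result: AbsoluteQuantResult,
    params: list[ExperimentalParams] | ExperimentalParams,
    factors: dict[str, EnrichmentFactor] | None = None,
    mol_weights: dict[str, float] | None = None,
) -> AbsoluteQuantResult:
    """Convert MS-scale fmol into total fmol, ng/µg protein and copies/cell.

    ``mol_weights`` maps first accessions to kDa; proteins without a weight
    get ``ng_per_ug`` unset.  ``factors`` maps condition labels to
    enrichment factors; where a condition is enriched its per-cell copy
    numbers are corrected by dividing the total amount by the factor
    (identically for the Enrichment and Concentration modes).
    """
    if isinstance(params, ExperimentalParams):
        params = [params]
    factors = factors or {}
    df = result.data.copy()
    mapping = _map_samples_to_conditions(result.samples, params)

    conditions, fmol_total, ng_per_ug, mol_per_cell, corrected = [], [], [], [], []
    missing_mw: set[str] = set()
    for row in df.itertuples(index=False):
        p = mapping[row.sample]
        conditions.append(p.condition)
        total = row.fmol_ms * p.total_protein_ug / p.amount_ms_ug
        fmol_total.append(total)

        acc = str(row.protein_id).split(";")[0].strip()
        mw = (mol_weights or {}).get(acc)
        if mw is not None and np.isfinite(mw) and mw > 0:
            ng_per_ug.append(row.fmol_ms * mw * 1e-3 / p.amount_ms_ug)
        else:
            ng_per_ug.append(np.nan)
            missing_mw.add(acc)

        factor = factors.get(p.condition)
        apply_corr = p.enrichment and factor is not None
        total_corr = total / factor.factor if apply_corr else total
        corrected.append(bool(apply_corr))
        cells = p.cells_total
        if cells is not None:
            mol_per_cell.append(total_corr * 1e-15 * AVOGADRO / cells)
        else:
            mol_per_cell.append(np.nan)

    if missing_mw and mol_weights is not None:
        warnings.warn(
            f"no molecular weight for {len(missing_mw)} protein(s); "
            "ng_per_ug left unset for them",
            stacklevel=2,
        )
    df["condition"] = conditions
    df["fmol_total"] = fmol_total
    df["ng_per_ug"] = ng_per_ug
    df["molecules_per_cell"] = mol_per_cell
    df["enrichment_corrected"] = corrected
    return AbsoluteQuantResult(data=df, models=result.models)


def mol_weights_from_fasta(path) -> dict[str, float]:
    """Average molecular weights (kDa) per accession from a protein FASTA.

    Accessions are taken from UniProt-style headers (``sp|ACC|NAME``) or the
    first whitespace-delimited token.  Non-standard residues are skipped.
    """
    from Bio import SeqIO
    from Bio.SeqUtils import molecular_weight

    weights: dict[str, float] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        acc = parts[1] if len(parts) >= 2 else parts[0]
        seq = "".join(c for c in str(rec.seq).upper() if c in "ACDEFGHIKLMNPQRSTVWY")
        if seq:
            weights[acc] = molecular_weight(seq, seq_type="protein") / 1000.0
    return weights
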