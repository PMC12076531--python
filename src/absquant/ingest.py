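"""Reading protein-groups reports from label-free proteomics search engines.

Supported dialects: MaxQuant ``proteinGroups.txt``, MSFragger/FragPipe
``combined_protein.tsv``, DIA-NN ``pg_matrix`` reports and Spectronaut pivot
reports.  The reader normalises them into a single :class:`QuantReport`
container: one row per protein group, a (method, sample) intensity matrix,
and boolean quality flags (contaminant / decoy / site-only).

Zero intensities are coerced to missing on ingestion: label-free engines
write 0 for "not quantified", and a true zero would be undefined under the
log transforms used downstream.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QuantReport",
    "IntensityCatalog",
    "ReportFormatError",
    "read_report",
    "inspect",
]

ENGINES = ("maxquant", "msfragger", "diann", "spectronaut")

#: Known protein-level intensity measures, most specific first.
KNOWN_METHODS = (
    "LFQ intensity",
    "MaxLFQ Intensity",
    "iBAQ",
    "Top3",
    "Intensity",
    "PG.MaxLFQ",
    "PG.Quantity",
)

#: ID-column preference when several coexist in one report.
ID_COLUMN_PRECEDENCE = (
    "Protein IDs",
    "Majority protein IDs",
    "Protein.Group",
    "Protein ID",
    "PG.ProteinGroups",
)

_FLAG_COLUMNS = {
    "is_contaminant": ("Potential contaminant", "Contaminant"),
    "is_reverse": ("Reverse",),
    "is_site_only": ("Only identified by site",),
}

_CONTAMINANT_PREFIXES = ("CON__", "contam_", "Cont_")
_REVERSE_PREFIXES = ("REV__", "rev_")

_MQ_AGGREGATE_COLUMNS = {"iBAQ peptides", "Intensity L", "Intensity H", "Intensity M"}

_METADATA_COLUMNS = {
    "Protein IDs", "Majority protein IDs", "Protein ID", "Protein",
    "Protein.Group", "Protein.Ids", "Protein.Names", "PG.ProteinGroups",
    "Gene names", "Gene", "Genes", "PG.Genes", "First.Protein.Description",
    "Mol. weight [kDa]", "PG.MolecularWeight", "Fasta headers",
    "Protein Probability", "Top Peptide Probability", "Combined Total Peptides",
    "Combined Spectral Count", "Combined Unique Spectral Count",
    "Protein Length", "Organism", "Protein Existence", "Description",
    "Indistinguishable Proteins", "Entry Name",
    "Peptides", "Razor + unique peptides", "Unique peptides",
    "Sequence coverage [%]", "Score", "id",
    "Reverse", "Potential contaminant", "Contaminant",
    "Only identified by site",
}

_SPECTRONAUT_RE = re.compile(r"^(?:\[\d+\]\s*)?(?P<sample>.+?)\.(?P<method>PG\.[A-Za-z]+)$")


class ReportFormatError(ValueError):
    """The file does not look like a supported protein-groups report."""


@dataclass
class QuantReport:
    """A protein-groups report in canonical form.

    Attributes
    ----------
    meta:
        One row per protein group with columns ``protein_id`` and, where the
        dialect provides them, ``gene_name`` and ``mol_weight_kda``.
    intensities:
        Float matrix with MultiIndex columns ``(method, sample)``; ``NaN``
        marks a missing (not-quantified) value.
    imputed:
        Boolean matrix aligned with ``intensities``; ``True`` where a value
        was filled in by imputation rather than measured.
    flags:
        Boolean columns ``is_contaminant``, ``is_reverse``, ``is_site_only``.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame
    flags: pd.DataFrame
    imputed: pd.DataFrame = None  # type: ignore[assignment]
    engine: str = "unknown"
    id_column: str = "protein_id"
    source_path: str | None = None

    def __post_init__(self) -> None:
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.intensities.index, columns=self.intensities.columns
            )
        ids = self.meta["protein_id"]
        if ids.isna().any() or (ids.astype(str).str.strip() == "").any():
            raise ReportFormatError("every row must carry a non-empty protein_id")
        if self.intensities.shape[1] == 0:
            raise ReportFormatError("report contains no intensity columns")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ReportFormatError("negative intensity values are not allowed")

    # -- structure -----------------------------------------------------
    @property
    def methods(self) -> dict[str, list[str]]:
        """Mapping of intensity-method name to its ordered sample labels."""
        out: dict[str, list[str]] = {}
        for method, sample in self.intensities.columns:
            out.setdefault(method, []).append(sample)
        return out

    @property
    def n_proteins(self) -> int:
        return len(self.meta)

    def matrix(self, method: str) -> pd.DataFrame:
        """Proteins x samples intensity matrix for one method."""
        if method not in self.methods:
            raise KeyError(
                f"method {method!r} not in report (have {sorted(self.methods)})"
            )
        block = self.intensities[method]
        return block.copy()

    def imputed_matrix(self, method: str) -> pd.DataFrame:
        return self.imputed[method].copy()

    def first_accessions(self) -> pd.Series:
        """First accession of each (possibly semicolon-separated) group."""
        return self.meta["protein_id"].astype(str).str.split(";").str[0].str.strip()

    # -- functional updates -------------------------------------------
    def subset(self, mask) -> "QuantReport":
        """New report keeping the rows where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            meta=self.meta.loc[mask].reset_index(drop=True),
            intensities=self.intensities.loc[mask].reset_index(drop=True),
            flags=self.flags.loc[mask].reset_index(drop=True),
            imputed=self.imputed.loc[mask].reset_index(drop=True),
        )

    def with_matrix(
        self,
        method: str,
        values: pd.DataFrame,
        imputed: pd.DataFrame | None = None,
    ) -> "QuantReport":
        """New report with one method's intensity block replaced."""
        intens = self.intensities.copy()
        imp = self.imputed.copy()
        for sample in values.columns:
            intens[(method, sample)] = values[sample].to_numpy()
            if imputed is not None:
                imp[(method, sample)] = imputed[sample].to_numpy()
        return replace(self, intensities=intens, imputed=imp)

    def copy(self) -> "QuantReport":
        return replace(
            self,
            meta=self.meta.copy(),
            intensities=self.intensities.copy(),
            flags=self.flags.copy(),
            imputed=self.imputed.copy(),
        )


@dataclass
class IntensityCatalog:
    """What :func:`inspect` found in a report."""

    methods: dict[str, list[str]]
    suggested_id_column: str
    engine: str = "unknown"

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "suggested_id_column": self.suggested_id_column,
            "methods": {m: list(s) for m, s in self.methods.items()},
        }


# ---------------------------------------------------------------------------
# dialect detection
# ---------------------------------------------------------------------------

def detect_engine(columns: list[str]) -> str:
    """Resolve the search-engine dialect from header signatures."""
    colset = set(columns)
    if "Majority protein IDs" in colset:
        return "maxquant"
    if "Protein Probability" in colset or "Combined Total Peptides" in colset:
        return "msfragger"
    if "Protein.Group" in colset:
        return "diann"
    if any("PG.Quantity" in c or "PG.MaxLFQ" in c for c in columns):
        return "spectronaut"
    raise ReportFormatError(
        "could not recognise the report dialect from its headers: "
        + ", ".join(map(str, columns[:25]))
    )


def _suggest_id_column(columns: list[str]) -> str:
    for cand in ID_COLUMN_PRECEDENCE:
        if cand in columns:
            return cand
    return columns[0]


def _detect_prefix_methods(columns: list[str]) -> dict[str, dict[str, str]]:
    """MaxQuant-style ``<method> <sample>`` columns.

    Returns ``{method: {sample: source_column}}``.  Columns equal to the bare
    method name are MaxQuant's experiment-wide sums and are excluded.
    """
    found: dict[str, dict[str, str]] = {}
    for col in columns:
        if col in _MQ_AGGREGATE_COLUMNS or col in _METADATA_COLUMNS:
            continue
        for method in KNOWN_METHODS:
            if col == method:  # summed-across-samples column
                break
            if col.startswith(method + " "):
                sample = col[len(method) + 1:].strip()
                if sample:
                    found.setdefault(method, {})[sample] = col
                break
    return found


def _detect_suffix_methods(columns: list[str]) -> dict[str, dict[str, str]]:
    """MSFragger-style ``<sample> <method>`` columns."""
    found: dict[str, dict[str, str]] = {}
    for col in columns:
        if col in _METADATA_COLUMNS:
            continue
        for method in ("MaxLFQ Intensity", "Intensity", "iBAQ", "Top3"):
            if col.endswith(" " + method):
                sample = col[: -(len(method) + 1)].strip()
                if sample and not sample.startswith("Combined"):
                    found.setdefault(method, {})[sample] = col
                break
    return found


def _detect_spectronaut_methods(columns: list[str]) -> dict[str, dict[str, str]]:
    found: dict[str, dict[str, str]] = {}
    for col in columns:
        m = _SPECTRONAUT_RE.match(col)
        if m:
            found.setdefault(m.group("method"), {})[m.group("sample")] = col
    return found


def _fallback_methods(df: pd.DataFrame) -> dict[str, dict[str, str]]:
    """All numeric non-metadata columns as a single method ``Intensity``."""
    samples: dict[str, str] = {}
    for col in df.columns:
        if col in _METADATA_COLUMNS:
            continue
        series = pd.to_numeric(df[col], errors="coerce")
        if series.notna().any():
            samples[col] = col
    return {"Intensity": samples} if samples else {}


def _detect_methods(df: pd.DataFrame, engine: str) -> dict[str, dict[str, str]]:
    columns = list(df.columns)
    if engine == "msfragger":
        found = _detect_suffix_methods(columns)
    elif engine == "spectronaut":
        found = _detect_spectronaut_methods(columns)
    else:
        found = _detect_prefix_methods(columns)
    if not found:
        found = _fallback_methods(df)
    return found


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ("Gene names", "Gene", "Genes", "PG.Genes")
_MW_COLUMNS = ("Mol. weight [kDa]", "PG.MolecularWeight")


def _plus_flag(df: pd.DataFrame, names: tuple[str, ...]) -> pd.Series:
    for name in names:
        if name in df.columns:
            return df[name].astype(str).str.strip().eq("+")
    return pd.Series(False, index=df.index)


def read_report(path, engine: str = "auto") -> QuantReport:
    """Read a protein-groups report into a :class:`QuantReport`.

    Parameters
    ----------
    path:
        Tab-separated protein-level report of one of the supported engines.
    engine:
        ``maxquant``, ``msfragger``, ``diann``, ``spectronaut`` or ``auto``
        (resolve from header signatures).
    """
    path = Path(path)
    if engine not in ENGINES + ("auto",):
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES + ('auto',)}")
    try:
        df = pd.read_csv(path, sep="\t", low_memory=False)
    except OSError:
        raise
    except Exception as exc:  # malformed text
        raise ReportFormatError(f"could not parse {path} as a tab-separated table: {exc}")
    if df.shape[1] < 2:
        raise ReportFormatError(
            f"{path} has {df.shape[1]} column(s); not a protein-groups report"
        )
    columns = [str(c) for c in df.columns]
    df.columns = columns

    if engine == "auto":
        try:
            engine = detect_engine(columns)
        except ReportFormatError:
            engine = "generic"

    id_column = _suggest_id_column(columns)
    methods = _detect_methods(df, engine)
    if not methods:
        raise ReportFormatError(
            f"no intensity columns recognised in {path}; headers seen: "
            + ", ".join(columns[:25])
        )

    meta = pd.DataFrame({"protein_id": df[id_column].astype(str).str.strip()})
    for col in _GENE_COLUMNS:
        if col in df.columns:
            meta["gene_name"] = df[col].astype(str)
            break
    for col in _MW_COLUMNS:
        if col in df.columns:
            meta["mol_weight_kda"] = pd.to_numeric(df[col], errors="coerce")
            break

    empty_id = meta["protein_id"].isin(("", "nan"))
    if empty_id.any():
        df = df.loc[~empty_id].reset_index(drop=True)
        meta = meta.loc[~empty_id].reset_index(drop=True)

    blocks = {}
    for method, samples in methods.items():
        for sample, col in samples.items():
            vals = pd.to_numeric(df[col], errors="coerce").astype(float)
            vals = vals.mask(vals == 0)  # 0 means "not quantified"
            blocks[(method, sample)] = vals
    intensities = pd.DataFrame(blocks)
    intensities.columns = pd.MultiIndex.from_tuples(
        intensities.columns, names=["method", "sample"]
    )

    first_acc = meta["protein_id"].str.split(";").str[0].str.strip()
    flags = pd.DataFrame(
        {
            "is_contaminant": _plus_flag(df, _FLAG_COLUMNS["is_contaminant"])
            | first_acc.str.startswith(_CONTAMINANT_PREFIXES),
            "is_reverse": _plus_flag(df, _FLAG_COLUMNS["is_reverse"])
            | first_acc.str.startswith(_REVERSE_PREFIXES),
            "is_site_only": _plus_flag(df, _FLAG_COLUMNS["is_site_only"]),
        }
    )

    return QuantReport(
        meta=meta,
        intensities=intensities,
        flags=flags,
        engine=engine,
        id_column=id_column,
        source_path=str(path),
    )


def inspect(report: QuantReport) -> IntensityCatalog:
    """Catalogue the intensity methods and suggest the protein-ID column."""
    return IntensityCatalog(
        methods=report.methods,
        suggested_id_column=report.id_column,
        engine=report.engine,
    )
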