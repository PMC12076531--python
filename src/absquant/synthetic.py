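"""Synthetic datasets with known ground truth.

Everything the pipeline consumes can be generated here: dialect-faithful
protein-groups reports (with planted contaminant/decoy rows, anchor
spike-ins, left-censored missingness), anchor tables, experimental-parameter
tables, enrichment scenarios, and benchmarks of replicate sample names.
Under a fixed seed every generator is fully deterministic, down to the bytes
of the files it writes.

The anchor design mimics a staggered-decade dynamic-range standard (UPS2
style): groups of equal-amount proteins across several orders of magnitude,
by default 6 levels x 8 proteins spanning 0.5-50,000 fmol.  The detector
response is a log-linear model: ``intensity = 10^(a + b*log10(fmol))`` times
multiplicative lognormal noise whose sigma is the standard deviation of the
base-10 log.  Missingness combines an intensity censoring threshold (values
below it are written as 0/blank, mirroring left censoring in label-free
data) with Bernoulli dropout.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "GroupingCase",
    "make_report",
    "make_grouping_benchmark",
    "make_enrichment_scenario",
]

DIALECTS = ("maxquant", "msfragger", "diann", "spectronaut")

#: Default separator styles of the sample-name benchmark.
GROUPING_SEPARATORS = ("_", "-", ".", " ", "")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic label-free experiment.

    ``amount_range`` is the log-uniform dynamic range of true per-protein
    amounts (fmol at MS scale); the response is
    ``10^(intercept + slope*log10(fmol))`` with lognormal noise of
    log10-standard-deviation ``noise_sigma``.
    """

    n_proteins: int = 200
    n_conditions: int = 2
    n_replicates: int = 3
    amount_range: tuple[float, float] = (1e-2, 1e3)
    anchor_levels: int = 6
    anchors_per_level: int = 8
    anchor_top_fmol: float = 50_000.0
    response_intercept: float = 5.0
    response_slope: float = 1.0
    noise_sigma: float = 0.0
    censor_threshold: float | None = None
    dropout_rate: float = 0.0
    n_contaminants: int = 5
    n_reverse: int = 3
    enrichment_factor: float | None = None
    n_enrichment_standards: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_conditions, self.n_replicates) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.anchor_levels < 3:
            raise ValueError("anchors must span >= 2 decades (>= 3 levels)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def n_anchors(self) -> int:
        return self.anchor_levels * self.anchors_per_level

    @property
    def samples(self) -> list[str]:
        return [
            f"Cond{c + 1}_{r + 1}"
            for c in range(self.n_conditions)
            for r in range(self.n_replicates)
        ]

    def anchor_amounts(self) -> dict[str, float]:
        """Staggered-decade anchor design: accession -> fmol."""
        amounts = {}
        for level in range(self.anchor_levels):
            fmol = self.anchor_top_fmol / 10**level
            for j in range(self.anchors_per_level):
                amounts[f"ANC{level * self.anchors_per_level + j + 1:03d}"] = fmol
        return amounts


@dataclass
class SyntheticDataset:
    """Paths and ground truth of one generated scenario."""

    report_path: Path
    truth_path: Path
    anchors_path: Path
    dialect: str
    truth: pd.DataFrame  # protein_id, mol_weight_kda, is_anchor + fmol per sample
    params_path: Path | None = None
    standards_path: Path | None = None
    enrichment_factor: float | None = None


# ---------------------------------------------------------------------------
# protein-groups reports
# ---------------------------------------------------------------------------

def _true_amount_table(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = np.log10(spec.amount_range[0]), np.log10(spec.amount_range[1])
    base = 10 ** rng.uniform(lo, hi, spec.n_proteins)
    ids = [f"PROT{i + 1:05d}" for i in range(spec.n_proteins)]
    mw = np.round(rng.uniform(10.0, 150.0, spec.n_proteins), 3)
    rows = {"protein_id": ids, "mol_weight_kda": mw, "is_anchor": False}
    truth = pd.DataFrame(rows)
    for s in spec.samples:
        truth[s] = base
    anchors = spec.anchor_amounts()
    anc = pd.DataFrame(
        {
            "protein_id": list(anchors),
            "mol_weight_kda": np.round(rng.uniform(10.0, 150.0, len(anchors)), 3),
            "is_anchor": True,
        }
    )
    for s in spec.samples:
        anc[s] = list(anchors.values())
    return pd.concat([truth, anc], ignore_index=True)


def _intensities(
    spec: SyntheticSpec, truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    return _intensities_for(truth, spec.samples, spec, rng)


def _decoy_rows(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Planted contaminant and reverse-decoy rows."""
    rows = []
    for i in range(spec.n_contaminants):
        rows.append((f"CON__CONT{i + 1:02d}", "contaminant", False))
    for i in range(spec.n_reverse):
        rows.append((f"REV__DECOY{i + 1:02d}", "reverse", False))
    df = pd.DataFrame(rows, columns=["protein_id", "flag", "is_anchor"])
    for s in spec.samples:
        df[s] = 10 ** rng.uniform(4.0, 7.0, len(df))
    return df


def _write_dialect(
    body: pd.DataFrame,
    flags: pd.Series,
    mw: pd.Series,
    samples: list[str],
    dialect: str,
    path: Path,
    method: str | None = None,
) -> None:
    """Write a protein-groups file faithful to one engine's headers."""
    ids = body["protein_id"]
    genes = ["G" + i[-4:] for i in ids]
    if dialect == "maxquant":
        method = method or "iBAQ"
        out = pd.DataFrame(
            {
                "Protein IDs": ids,
                "Majority protein IDs": ids,
                "Gene names": genes,
                "Mol. weight [kDa]": mw,
            }
        )
        for s in samples:
            out[f"{method} {s}"] = body[s]
        out[method] = body[samples].sum(axis=1)  # experiment-wide sum column
        out["Reverse"] = np.where(flags == "reverse", "+", "")
        out["Potential contaminant"] = np.where(flags == "contaminant", "+", "")
        out["Only identified by site"] = ""
    elif dialect == "msfragger":
        out = pd.DataFrame(
            {
                "Protein": ids,
                "Protein ID": ids,
                "Gene": genes,
                "Protein Probability": 0.99,
                "Combined Total Peptides": 10,
            }
        )
        # MSFragger carries no flag columns; contaminants keep their prefix
        for s in samples:
            out[f"{s} Intensity"] = body[s]
        for s in samples:
            out[f"{s} MaxLFQ Intensity"] = body[s]
    elif dialect == "diann":
        out = pd.DataFrame(
            {
                "Protein.Group": ids,
                "Protein.Ids": ids,
                "Protein.Names": ids,
                "Genes": genes,
                "First.Protein.Description": "synthetic protein",
            }
        )
        for s in samples:
            out[s] = body[s].replace(0.0, np.nan)
    elif dialect == "spectronaut":
        out = pd.DataFrame(
            {
                "PG.ProteinGroups": ids,
                "PG.Genes": genes,
                "PG.MolecularWeight": mw,
            }
        )
        for k, s in enumerate(samples, start=1):
            out[f"[{k}] {s}.PG.Quantity"] = body[s].replace(0.0, np.nan)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    out.to_csv(path, sep="\t", index=False)


def make_report(
    spec: SyntheticSpec,
    out_dir,
    dialect: str = "maxquant",
    method: str | None = None,
) -> SyntheticDataset:
    """Generate a dialect-faithful report plus its ground truth on disk.

    Writes ``report.tsv`` (engine headers, planted CON__/REV__ rows, anchor
    spike-ins), ``anchors.tsv`` (accession, fmol) and ``truth.tsv``
    (per-protein true fmol per sample).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    truth = _true_amount_table(spec, rng)
    intens = _intensities(spec, truth, rng)
    body = pd.concat([truth[["protein_id", "is_anchor"]], intens], axis=1)
    body_flags = pd.Series("", index=body.index)

    decoys = _decoy_rows(spec, rng)
    body_all = pd.concat(
        [body, decoys.drop(columns="flag")], ignore_index=True
    )
    flags_all = pd.concat([body_flags, decoys["flag"]], ignore_index=True)
    mw_all = pd.concat(
        [truth["mol_weight_kda"], pd.Series([55.0] * len(decoys), dtype=float)],
        ignore_index=True,
    )

    report_path = out_dir / "report.tsv"
    _write_dialect(
        body_all, flags_all, mw_all, spec.samples, dialect, report_path, method=method
    )

    anchors_path = out_dir / "anchors.tsv"
    anchors = spec.anchor_amounts()
    pd.DataFrame(
        {"accession": list(anchors), "fmol": list(anchors.values())}
    ).to_csv(anchors_path, sep="\t", index=False, header=False)

    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    return SyntheticDataset(
        report_path=report_path,
        truth_path=truth_path,
        anchors_path=anchors_path,
        dialect=dialect,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# sample-name grouping benchmark
# ---------------------------------------------------------------------------

@dataclass
class GroupingCase:
    """One benchmark instance: labels plus the planted partition."""

    labels: list[str]
    partition: set[frozenset]


_LETTERS = string.ascii_lowercase


def _random_word(rng: np.random.Generator, with_digit_prob: float = 0.3) -> str:
    length = int(rng.integers(3, 9))
    word = "".join(rng.choice(list(_LETTERS), length))
    if rng.random() < with_digit_prob:
        digits = str(rng.integers(1, 100))
        pos = int(rng.integers(0, length + 1))
        word = word[:pos] + digits + word[pos:]
    return word


def _replicate_suffix(style: str, r: int) -> str:
    if style == "integer":
        return str(r + 1)
    if style == "letter":
        return string.ascii_uppercase[r]
    if style == "repN":
        return f"rep{r + 1}"
    raise ValueError(style)


def make_grouping_benchmark(
    n_sets: int,
    seed: int = 0,
    separators: tuple[str, ...] = GROUPING_SEPARATORS,
    n_conditions_range: tuple[int, int] = (2, 6),
    n_replicates_range: tuple[int, int] = (2, 5),
) -> list[GroupingCase]:
    """Generate label sets with a planted replicate partition.

    Each set draws 2-6 condition names (random lowercase words, ~30% of
    which contain digits), 2-5 replicates encoded as an integer, letter or
    ``repN`` suffix, and one separator shared within the set.  The truth
    partition groups labels by condition.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    styles = ("integer", "letter", "repN")
    cases: list[GroupingCase] = []
    while len(cases) < n_sets:
        n_cond = int(rng.integers(n_conditions_range[0], n_conditions_range[1] + 1))
        n_rep = int(rng.integers(n_replicates_range[0], n_replicates_range[1] + 1))
        sep = separators[int(rng.integers(0, len(separators)))]
        style = styles[int(rng.integers(0, len(styles)))]
        conditions: list[str] = []
        while len(conditions) < n_cond:
            w = _random_word(rng)
            if w not in conditions:
                conditions.append(w)
        labels, partition = [], set()
        for cond in conditions:
            members = [
                f"{cond}{sep}{_replicate_suffix(style, r)}" for r in range(n_rep)
            ]
            labels.extend(members)
            partition.add(frozenset(members))
        if len(set(labels)) != len(labels):  # rare collision; redraw the set
            continue
        cases.append(GroupingCase(labels=labels, partition=partition))
    return cases


def score_grouping(cases: list[GroupingCase]) -> float:
    """Fraction of benchmark sets grouped exactly as planted."""
    from .preprocess import infer_groups

    correct = sum(
        1 for c in cases if infer_groups(c.labels).as_partition() == c.partition
    )
    return correct / len(cases)


# ---------------------------------------------------------------------------
# enrichment scenarios
# ---------------------------------------------------------------------------

def make_enrichment_scenario(
    spec: SyntheticSpec,
    out_dir,
    dialect: str = "maxquant",
    std_stock_fmol_per_ul: float = 1000.0,
    std_dilution: float = 10.0,
    std_volume_ul: float = 10.0,
    sample_volume_ul: float = 20.0,
    protein_conc_ug_per_ul: float = 2.5,
    amount_ms_ug: float = 5.0,
    cells_per_ml: float = 5e8,
    total_culture_volume_ul: float = 10_000.0,
) -> SyntheticDataset:
    """Generate an enriched-fraction experiment with planted factor f.

    Two conditions are produced: ``Base`` (no enrichment) and ``Enr``
    (enrichment TRUE, mode Enrichment).  In the enriched condition every
    native protein's MS-scale amount, and every spiked standard's expected
    MS share, is multiplied by ``spec.enrichment_factor``.  The Table-1-style
    parameters file and the standards table are written alongside.
    """
    if spec.enrichment_factor is None:
        raise ValueError("spec.enrichment_factor must be set")
    f = spec.enrichment_factor
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    base_spec = SyntheticSpec(
        **{**spec.__dict__, "n_conditions": 2, "enrichment_factor": None}
    )
    samples = base_spec.samples  # Cond1_* = Base, Cond2_* = Enr
    truth = _true_amount_table(base_spec, rng)

    # enrichment standards: spiked into both conditions at known amounts;
    # the enriched condition multiplies their MS share by f, like any protein
    total_protein_ug = sample_volume_ul * protein_conc_ug_per_ul
    expected_ms = (
        (std_stock_fmol_per_ul / std_dilution)
        * std_volume_ul
        * amount_ms_ug
        / total_protein_ug
    )
    std_ids = [f"ESTD{i + 1:02d}" for i in range(spec.n_enrichment_standards)]
    std_rows = pd.DataFrame(
        {
            "protein_id": std_ids,
            "mol_weight_kda": np.round(rng.uniform(10.0, 150.0, len(std_ids)), 3),
            "is_anchor": False,
        }
    )
    for s in samples:
        std_rows[s] = expected_ms
    truth = pd.concat([truth, std_rows], ignore_index=True)

    # apply the factor to native proteins and standards of the enriched
    # condition, not to the anchors (those are spiked after enrichment,
    # right before the MS measurement)
    enr_samples = [s for s in samples if s.startswith("Cond2")]
    native = ~truth["is_anchor"]
    for s in enr_samples:
        truth.loc[native, s] = truth.loc[native, s] * f

    renamed = {s: s.replace("Cond1", "Base").replace("Cond2", "Enr") for s in samples}
    truth = truth.rename(columns=renamed)
    sample_labels = [renamed[s] for s in samples]

    spec_for_files = SyntheticSpec(
        **{**base_spec.__dict__, "n_proteins": len(truth)}
    )
    intens = _intensities_for(truth, sample_labels, spec_for_files, rng)
    body = pd.concat([truth[["protein_id", "is_anchor"]], intens], axis=1)
    flags = pd.Series("", index=body.index)

    report_path = out_dir / "report.tsv"
    _write_dialect(
        body, flags, truth["mol_weight_kda"], sample_labels, dialect, report_path
    )

    anchors_path = out_dir / "anchors.tsv"
    anchors = spec.anchor_amounts()
    pd.DataFrame(
        {"accession": list(anchors), "fmol": list(anchors.values())}
    ).to_csv(anchors_path, sep="\t", index=False, header=False)

    standards_path = out_dir / "standards.tsv"
    pd.DataFrame(
        {"accession": std_ids, "stock": std_stock_fmol_per_ul}
    ).to_csv(standards_path, sep="\t", index=False, header=False)

    params_path = out_dir / "params.tsv"
    pd.DataFrame(
        {
            "Condition": ["Base", "Enr"],
            "SampleVolume": sample_volume_ul,
            "ProteinConcentration": protein_conc_ug_per_ul,
            "AmountMS": amount_ms_ug,
            "CellsPerML": cells_per_ml,
            "TotalCultureVolume": total_culture_volume_ul,
            "Enrichment": ["FALSE", "TRUE"],
            "EnrichmentMode": ["", "Enrichment"],
            "StdDilution": ["", str(std_dilution)],
            "StdVolume": ["", str(std_volume_ul)],
        }
    ).to_csv(params_path, sep="\t", index=False)

    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    return SyntheticDataset(
        report_path=report_path,
        truth_path=truth_path,
        anchors_path=anchors_path,
        dialect=dialect,
        truth=truth,
        params_path=params_path,
        standards_path=standards_path,
        enrichment_factor=f,
    )


def _intensities_for(
    truth: pd.DataFrame,
    samples: list[str],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    out = {}
    for s in samples:
        fmol = truth[s].to_numpy(dtype=float)
        log_i = spec.response_intercept + spec.response_slope * np.log10(fmol)
        if spec.noise_sigma > 0:
            log_i = log_i + rng.normal(0.0, spec.noise_sigma, fmol.size)
        vals = 10**log_i
        if spec.censor_threshold is not None:
            vals = np.where(vals < spec.censor_threshold, 0.0, vals)
        if spec.dropout_rate > 0:
            vals = np.where(rng.random(fmol.size) < spec.dropout_rate, 0.0, vals)
        out[s] = vals
    return pd.DataFrame(out)
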