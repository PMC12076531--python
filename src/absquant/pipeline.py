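"""End-to-end orchestration: ingest -> preprocess -> calibrate -> integrate.

:func:`run_pipeline` chains the whole analysis from one declarative config
and writes four artifacts into the output directory:

- ``preprocessed.tsv``  — filtered/normalized/imputed intensity table with
  an ``imputed_<sample>`` boolean block;
- ``calibration.json``  — every fitted calibration model plus the chosen
  intensity method and normalization;
- ``absolute.tsv``      — per protein and sample, the estimated amounts
  (MS-scale fmol and, when experimental parameters are given, total fmol,
  ng/µg and molecules per cell);
- ``run.log``           — every decision taken (method chosen, anchors
  dropped, enrichment factors, seeds), without timestamps so reruns are
  byte-identical.

Without a parameters table the pipeline stops after calibration and emits
MS-scale fmol only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ingest, integrate, preprocess, quantify

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    report: str
    anchors: str
    out_dir: str = "absquant_out"
    params: str | None = None
    standards: str | None = None
    fasta: str | None = None
    engine: str = "auto"
    method: str | None = None  # None = consult
    normalization: str | None = None  # None = consult
    imputation: bool = True
    remove_contaminants: bool = True
    min_valid_fraction: float = 2 / 3
    sample_scope: str = "per_sample"
    culture_volume_unit: str = "uL"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "report" not in raw or "anchors" not in raw:
            raise ValueError("config must set 'report' and 'anchors'")
        return cls(**raw)


def _write_preprocessed(report, method: str, path: Path) -> None:
    mat = report.matrix(method)
    imp = report.imputed_matrix(method)
    out = pd.DataFrame({"protein_id": report.meta["protein_id"]})
    if "mol_weight_kda" in report.meta:
        out["mol_weight_kda"] = report.meta["mol_weight_kda"]
    for s in mat.columns:
        out[s] = mat[s]
    for s in mat.columns:
        out[f"imputed_{s}"] = imp[s]
    out.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns a summary dict of what was produced."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed: {config.seed}"]

    report = ingest.read_report(config.report, engine=config.engine)
    log.append(f"ingested {report.n_proteins} protein groups ({report.engine})")
    log.append(f"intensity methods: {sorted(report.methods)}")

    if config.remove_contaminants:
        before = report.n_proteins
        report = preprocess.remove_flagged(report)
        log.append(f"removed {before - report.n_proteins} flagged rows")

    anchors = quantify.read_anchors(config.anchors)
    log.append(f"anchors: {len(anchors)} from {config.anchors}")

    # choose method/normalization, consulting the anchors when unspecified
    method, normalization = config.method, config.normalization
    if method is None or normalization is None:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ranking = quantify.consult(
                report,
                anchors,
                candidate_methods=[method] if method else None,
                candidate_normalizations=[normalization] if normalization else None,
            )
        for w in caught:
            log.append(f"consult: {w.message}")
        best = ranking[0]
        method = best["method"]
        normalization = best["normalization"]
        log.append(
            "consult chose method=%s normalization=%s (mean R^2 %.4f)"
            % (method, normalization, best["mean_r_squared"])
        )
    else:
        log.append(f"method={method} normalization={normalization} (user-set)")

    grouping = preprocess.infer_groups(report.methods[method])
    log.append(f"sample groups: { {g: m for g, m in grouping.groups.items()} }")

    pp_config = preprocess.PreprocessConfig(
        remove_contaminants=config.remove_contaminants,
        min_valid_fraction=config.min_valid_fraction,
        normalization=normalization,
        imputation="gaussian_downshift" if config.imputation else "none",
        rng_seed=config.seed,
    )
    before = report.n_proteins
    report = preprocess.filter_valid(report, grouping, pp_config, method=method)
    log.append(f"validity filter: {before} -> {report.n_proteins} proteins")
    report = preprocess.normalize(report, normalization=normalization, method=method)
    if config.imputation:
        report = preprocess.impute(report, pp_config, method=method)
        n_imp = int(report.imputed_matrix(method).to_numpy().sum())
        log.append(f"imputed {n_imp} missing values (gaussian downshift)")

    _write_preprocessed(report, method, out_dir / "preprocessed.tsv")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = quantify.quantify_samples(
            report, anchors, method,
            normalization=normalization, sample_scope=config.sample_scope,
        )
    for w in caught:
        log.append(f"quantify: {w.message}")
    for m in result.models:
        log.append(
            "calibration %s: slope %.6g intercept %.6g R^2 %.6g (n=%d)"
            % (m.sample, m.slope, m.intercept, m.r_squared, m.n_anchors_used)
        )
    with open(out_dir / "calibration.json", "w") as fh:
        json.dump(
            {
                "method": method,
                "normalization": normalization,
                "models": [m.to_dict() for m in result.models],
            },
            fh,
            indent=2,
        )

    summary = {
        "method": method,
        "normalization": normalization,
        "n_proteins": report.n_proteins,
        "models": result.models,
    }

    if config.params is None:
        result.data.to_csv(out_dir / "absolute.tsv", sep="\t", index=False)
        log.append("no experimental parameters given; stopping at MS-scale fmol")
        (out_dir / "run.log").write_text("\n".join(log) + "\n")
        summary["result"] = result
        return summary

    params = integrate.read_params(
        config.params, culture_volume_unit=config.culture_volume_unit
    )
    log.append(f"experimental parameters: {[p.condition for p in params]}")

    factors: dict[str, integrate.EnrichmentFactor] = {}
    standards = (
        integrate.read_standards(config.standards) if config.standards else None
    )
    for p in params:
        if not p.enrichment:
            continue
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if p.has_srm:
                factor = integrate.srm_enrichment(result, p)
            elif standards is not None:
                factor = integrate.compute_enrichment(result, p, standards)
            else:
                raise ValueError(
                    f"condition {p.condition!r} is enriched but neither SRM "
                    "columns nor an enrichment-standards table were given"
                )
        for w in caught:
            log.append(f"enrichment: {w.message}")
        factors[p.condition] = factor
        log.append(
            "enrichment factor %s: %.6g (basis %s, n=%d)"
            % (p.condition, factor.factor, factor.basis, factor.n_standards)
        )

    mol_weights: dict[str, float] = {}
    if "mol_weight_kda" in report.meta:
        mol_weights.update(
            dict(zip(report.first_accessions(), report.meta["mol_weight_kda"]))
        )
    if config.fasta:
        mol_weights.update(integrate.mol_weights_from_fasta(config.fasta))
        log.append(f"molecular weights from FASTA: {config.fasta}")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        final = integrate.to_absolute(
            result, params, factors=factors, mol_weights=mol_weights or None
        )
    for w in caught:
        log.append(f"integrate: {w.message}")
    final.data.to_csv(out_dir / "absolute.tsv", sep="\t", index=False)
    log.append(f"wrote {len(final.data)} absolute quantifications")
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    summary["result"] = final
    summary["factors"] = factors
    return summary
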