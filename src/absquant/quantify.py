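"""Anchor-protein calibration and proteome-wide absolute estimation.

Proteome-scale absolute quantification rests on proteins spiked into the
sample at known amounts (e.g., the UPS2 dynamic-range standard).  A linear
regression of log10(intensity) on log10(spiked fmol) — the calibration
curve — is fitted per sample and inverted to convert every protein's
intensity into an estimated amount (fmol) at MS-injection scale.

:class:`AnchorCalibrator` is the sklearn-style core (``fit`` on amounts and
intensities, ``predict``/``estimate_amount`` to move between the two
scales); :func:`fit_anchors` / :func:`estimate_amounts` wrap it at the
report level, and :func:`consult` ranks candidate intensity-method /
normalization combinations by how well the anchors fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from . import preprocess
from .ingest import QuantReport

__all__ = [
    "AnchorSet",
    "CalibrationModel",
    "AbsoluteQuantResult",
    "AnchorCalibrator",
    "InsufficientAnchorsError",
    "read_anchors",
    "fit_anchors",
    "estimate_amounts",
    "quantify_samples",
    "consult",
]

MIN_ANCHORS = 3


class InsufficientAnchorsError(ValueError):
    """Fewer than the minimum number of anchors could be matched and fitted."""


@dataclass
class AnchorSet:
    """Spiked anchor proteins: accession -> amount (fmol at MS injection)."""

    entries: dict[str, float]
    source_path: str | None = None

    def __post_init__(self) -> None:
        if len(self.entries) < MIN_ANCHORS:
            raise ValueError(
                f"need at least {MIN_ANCHORS} anchor proteins, got {len(self.entries)}"
            )
        for acc, fmol in self.entries.items():
            if not np.isfinite(fmol) or fmol <= 0:
                raise ValueError(f"anchor {acc!r} has non-positive amount {fmol!r}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CalibrationModel:
    """A fitted log10-log10 calibration line for one sample (or pooled)."""

    slope: float
    intercept: float
    r_squared: float
    n_anchors_used: int
    method: str
    normalization: str = "none"
    sample_scope: str = "per_sample"
    sample: str | None = None
    anchors_excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero (model not invertible)")

    def estimate_fmol(self, intensity) -> np.ndarray:
        """Invert the curve: intensity -> fmol at MS scale."""
        return 10 ** ((np.log10(intensity) - self.intercept) / self.slope)

    def predict_intensity(self, fmol) -> np.ndarray:
        return 10 ** (self.intercept + self.slope * np.log10(fmol))

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "method": self.method,
            "normalization": self.normalization,
            "sample_scope": self.sample_scope,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_anchors_used": self.n_anchors_used,
            "anchors_excluded": list(self.anchors_excluded),
        }


@dataclass
class AbsoluteQuantResult:
    """Tidy per-protein per-sample quantification result.

    ``data`` columns: protein_id, sample, intensity, fmol_ms, provenance
    ('observed' or 'imputed'); after integration also condition, fmol_total,
    ng_per_ug, molecules_per_cell, enrichment_corrected.
    """

    data: pd.DataFrame
    models: list[CalibrationModel] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.data[self.data["sample"] == sample]


class AnchorCalibrator(RegressorMixin, BaseEstimator):
    """Ordinary least-squares calibration in log10-log10 space.

    ``fit(X, y)`` takes spiked amounts (fmol) as X and measured intensities
    as y, both strictly positive; non-finite pairs are dropped.  Fitted
    attributes: ``slope_``, ``intercept_``, ``r_squared_``,
    ``n_anchors_used_``.  ``predict`` maps amounts to intensities on the
    fitted line; ``estimate_amount`` inverts it.
    """

    def __init__(self, min_anchors: int = MIN_ANCHORS):
        self.min_anchors = min_anchors

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("amounts and intensities must have equal length")
        ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
        x, y = x[ok], y[ok]
        if x.size < self.min_anchors:
            raise InsufficientAnchorsError(
                f"insufficient anchors: {x.size} usable, need {self.min_anchors}"
            )
        lx, ly = np.log10(x), np.log10(y)
        if np.ptp(lx) == 0:
            raise ValueError("zero variance in log10(fmol); cannot fit a line")
        res = stats.linregress(lx, ly)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.stderr_slope_ = float(res.stderr)
        self.stderr_intercept_ = float(res.intercept_stderr)
        self.n_anchors_used_ = int(x.size)
        if self.slope_ == 0:
            raise ValueError("degenerate fit: zero slope")
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return 10 ** (self.intercept_ + self.slope_ * np.log10(x))

    def estimate_amount(self, intensity):
        i = np.asarray(intensity, dtype=float)
        return 10 ** ((np.log10(i) - self.intercept_) / self.slope_)

    def to_model(self, **meta) -> CalibrationModel:
        return CalibrationModel(
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            n_anchors_used=self.n_anchors_used_,
            **meta,
        )


# ---------------------------------------------------------------------------
# anchor-table input
# ---------------------------------------------------------------------------

def read_anchors(path) -> AnchorSet:
    """Read an anchor table (accession, spiked fmol) from TSV or xlsx.

    A header row is accepted and detected by the second field not parsing
    as a number.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, header=None)
    else:
        df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: anchor table needs two columns (accession, fmol)")
    df = df.iloc[:, :2]
    df.columns = ["accession", "fmol"]
    first = pd.to_numeric(df["fmol"].iloc[0], errors="coerce")
    if pd.isna(first):  # header row
        df = df.iloc[1:]
    entries: dict[str, float] = {}
    for row in df.itertuples(index=False):
        acc = str(row.accession).strip()
        fmol = pd.to_numeric(row.fmol, errors="coerce")
        if pd.isna(fmol) or fmol <= 0:
            raise ValueError(f"{path}: anchor {acc!r} has invalid amount {row.fmol!r}")
        if acc in entries:
            raise ValueError(f"{path}: duplicate anchor accession {acc!r}")
        entries[acc] = float(fmol)
    return AnchorSet(entries=entries, source_path=str(path))


# ---------------------------------------------------------------------------
# report-level fitting
# ---------------------------------------------------------------------------

def _match_anchors(report: QuantReport, anchors: AnchorSet) -> pd.Series:
    """Row index per anchor accession, matching on the first accession.

    Anchors matched by more than one protein group are dropped (the curve
    point would be ambiguous).
    """
    first = report.first_accessions()
    hits: dict[str, int] = {}
    for acc in anchors.entries:
        rows = np.flatnonzero(first.to_numpy() == acc)
        if rows.size == 0:
            continue
        if rows.size > 1:
            warnings.warn(
                f"anchor {acc!r} matches {rows.size} protein groups; dropped",
                stacklevel=3,
            )
            continue
        hits[acc] = int(rows[0])
    return pd.Series(hits, dtype=int)


def fit_anchors(
    report: QuantReport,
    anchors: AnchorSet,
    method: str,
    sample: str | None = None,
    normalization: str = "none",
    include_imputed: bool = False,
) -> CalibrationModel:
    """Fit the calibration curve for one sample (or pooled across samples).

    Anchors missing in the sample are excluded and listed in the returned
    model; anchors whose intensity was imputed are excluded unless
    ``include_imputed`` (an imputed value is not a measurement).
    """
    mat = report.matrix(method)
    imputed = report.imputed_matrix(method)
    hits = _match_anchors(report, anchors)
    samples = [sample] if sample is not None else list(mat.columns)
    for s in samples:
        if s not in mat.columns:
            raise KeyError(f"sample {s!r} not in method {method!r}")

    amounts, intens, used = [], [], set()
    for acc, row in hits.items():
        for s in samples:
            val = mat.at[row, s]
            if not np.isfinite(val):
                continue
            if not include_imputed and bool(imputed.at[row, s]):
                continue
            amounts.append(anchors.entries[acc])
            intens.append(float(val))
            used.add(acc)
    excluded = sorted(set(anchors.entries) - used)

    calib = AnchorCalibrator().fit(amounts, intens)
    return calib.to_model(
        method=method,
        normalization=normalization,
        sample_scope="per_sample" if sample is not None else "pooled",
        sample=sample,
        anchors_excluded=excluded,
    )


def estimate_amounts(report: QuantReport, model: CalibrationModel) -> AbsoluteQuantResult:
    """Invert a calibration model into per-protein fmol at MS scale."""
    mat = report.matrix(model.method)
    imputed = report.imputed_matrix(model.method)
    samples = [model.sample] if model.sample is not None else list(mat.columns)
    frames = []
    for s in samples:
        vals = mat[s].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": report.meta["protein_id"].to_numpy()[finite],
                    "sample": s,
                    "intensity": vals[finite],
                    "fmol_ms": model.estimate_fmol(vals[finite]),
                    "provenance": np.where(
                        imputed[s].to_numpy()[finite], "imputed", "observed"
                    ),
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    return AbsoluteQuantResult(data=data, models=[model])


def quantify_samples(
    report: QuantReport,
    anchors: AnchorSet,
    method: str,
    normalization: str = "none",
    sample_scope: str = "per_sample",
    include_imputed: bool = False,
) -> AbsoluteQuantResult:
    """Calibrate and estimate amounts for every sample of a method.

    ``sample_scope='per_sample'`` fits one curve per sample (default; spike-in
    response drifts run to run); ``'pooled'`` fits all samples' anchor points
    jointly, as a single experiment-wide curve.
    """
    samples = report.methods[method]
    if sample_scope == "pooled":
        model = fit_anchors(
            report, anchors, method, sample=None,
            normalization=normalization, include_imputed=include_imputed,
        )
        return estimate_amounts(report, model)
    if sample_scope != "per_sample":
        raise ValueError("sample_scope must be 'per_sample' or 'pooled'")
    parts, models = [], []
    for s in samples:
        model = fit_anchors(
            report, anchors, method, sample=s,
            normalization=normalization, include_imputed=include_imputed,
        )
        part = estimate_amounts(report, model)
        parts.append(part.data)
        models.append(model)
    return AbsoluteQuantResult(data=pd.concat(parts, ignore_index=True), models=models)


# ---------------------------------------------------------------------------
# the consultant
# ---------------------------------------------------------------------------

def consult(
    report: QuantReport,
    anchors: AnchorSet,
    candidate_methods: list[str] | None = None,
    candidate_normalizations: list[str] | None = None,
    sample_scope: str = "per_sample",
) -> list[dict]:
    """Rank (intensity method, normalization) pairs by anchor fit quality.

    The raw report is normalized with each candidate, the calibration curve
    fitted per sample (or once on all samples' anchor points with
    ``sample_scope='pooled'``, where run-to-run scale distortions count
    against a candidate), and candidates ranked by mean R^2 (descending);
    ties broken by larger n_anchors_used, then lexicographically.  The
    first entry is the recommendation.
    """
    methods = candidate_methods or list(report.methods)
    norms = candidate_normalizations or list(preprocess.NORMALIZATIONS)
    rows = []
    for m in methods:
        for norm in norms:
            try:
                prepped = preprocess.normalize(report, normalization=norm, method=m)
                scopes = (
                    [None] if sample_scope == "pooled" else report.methods[m]
                )
                models = [
                    fit_anchors(prepped, anchors, m, sample=s, normalization=norm)
                    for s in scopes
                ]
            except (InsufficientAnchorsError, ValueError, KeyError) as exc:
                warnings.warn(f"candidate ({m}, {norm}) failed: {exc}", stacklevel=2)
                continue
            rows.append(
                {
                    "method": m,
                    "normalization": norm,
                    "mean_r_squared": float(np.mean([c.r_squared for c in models])),
                    "mean_n_anchors": float(np.mean([c.n_anchors_used for c in models])),
                }
            )
    if not rows:
        raise InsufficientAnchorsError("no candidate produced a usable calibration")
    # R^2 compared at 1e-12 so numerically identical fits tie cleanly
    rows.sort(
        key=lambda r: (
            -round(r["mean_r_squared"], 12),
            -r["mean_n_anchors"],
            r["method"],
            r["normalization"],
        )
    )
    return rows
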