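"""Routine processing of label-free intensity matrices.

Covers the steps a proteomics analysis needs before calibration: removal of
flagged rows (contaminants, decoys, site-only identifications), automatic
inference of the replicate structure from sample names, validity filtering,
per-sample normalization, and left-censored missing-value imputation by
Gaussian downshift.

Normalization and imputation are exposed both as sklearn-style transformers
(:class:`IntensityNormalizer`, :class:`GaussianDownshiftImputer`) operating
on plain ``(n_samples, n_features)`` arrays, and as report-level functions
(:func:`normalize`, :func:`impute`) that keep the :class:`~absquant.ingest.QuantReport`
on its raw intensity scale: internally the report functions work in log2 and
transform back, so a report always holds raw-scale positive intensities.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .ingest import QuantReport

__all__ = [
    "PreprocessConfig",
    "SampleGrouping",
    "IntensityNormalizer",
    "GaussianDownshiftImputer",
    "remove_flagged",
    "infer_groups",
    "filter_valid",
    "normalize",
    "impute",
]

NORMALIZATIONS = ("none", "median", "quantile", "total_sum")
IMPUTATIONS = ("none", "gaussian_downshift")


@dataclass
class PreprocessConfig:
    """Settings for the preprocessing stage.

    ``downshift_sd`` and ``downshift_width`` are in units of each sample's
    observed log2 standard deviation: missing values are drawn from
    ``Normal(mean - downshift_sd * sd, downshift_width * sd)``.
    """

    remove_contaminants: bool = True
    min_valid_fraction: float = 2 / 3
    normalization: str = "median"
    imputation: str = "gaussian_downshift"
    downshift_sd: float = 1.8
    downshift_width: float = 0.3
    log_base: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in (0, 1]")
        if self.downshift_width <= 0:
            raise ValueError("downshift_width must be > 0")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
        if self.imputation not in IMPUTATIONS:
            raise ValueError(f"imputation must be one of {IMPUTATIONS}")


@dataclass
class SampleGrouping:
    """A partition of sample labels into replicate groups."""

    groups: dict[str, list[str]]
    singleton_policy_applied: bool = False

    @property
    def samples(self) -> list[str]:
        return [s for members in self.groups.values() for s in members]

    def group_of(self, sample: str) -> str:
        for label, members in self.groups.items():
            if sample in members:
                return label
        raise KeyError(sample)

    def as_partition(self) -> set[frozenset]:
        return {frozenset(members) for members in self.groups.values()}


# ---------------------------------------------------------------------------
# flagged-row removal
# ---------------------------------------------------------------------------

def remove_flagged(report: QuantReport) -> QuantReport:
    """Drop contaminant, decoy (reverse) and site-only rows."""
    bad = report.flags[["is_contaminant", "is_reverse", "is_site_only"]].any(axis=1)
    return report.subset(~bad.to_numpy())


# ---------------------------------------------------------------------------
# replicate-group inference
# ---------------------------------------------------------------------------

_SEPARATORS = re.compile(r"[_\-\. ]+")
_CAMEL = re.compile(r"\d+|[A-Z]+(?![a-z])|[A-Z][a-z]*|[a-z]+")
_ROMAN = {"I", "II", "III", "IV"}


def _tokenize(label: str) -> list[str]:
    """Split on separators, letter/digit boundaries and case changes."""
    tokens: list[str] = []
    for part in _SEPARATORS.split(label):
        if part:
            tokens.extend(_CAMEL.findall(part))
    return tokens


def _is_replicate_token(token: str) -> bool:
    return (
        token.isdigit()
        or (len(token) == 1 and token.isalpha())
        or token.upper() in _ROMAN
    )


def _group_key(label: str) -> tuple[tuple[str, ...], str] | None:
    """Key of the group a label belongs to, or None for a singleton.

    Returns ``(shared_tokens, replicate_token)``.
    """
    tokens = _tokenize(label)
    if len(tokens) < 2 or not _is_replicate_token(tokens[-1]):
        return None
    return tuple(tokens[:-1]), tokens[-1]


def _strip_replicate(label: str, replicate: str) -> str:
    stem = label[: len(label) - len(replicate)] if label.endswith(replicate) else label
    return stem.rstrip("_-. ")


def infer_groups(sample_labels: list[str]) -> SampleGrouping:
    """Infer replicate groups from sample names.

    Labels sharing every name token except a trailing replicate token (an
    integer, a single letter, or a roman numeral up to IV, set off by a
    separator, a case change or a letter/digit boundary) form one group;
    anything else becomes a singleton group.  The result is deterministic
    and invariant to the input order.
    """
    if not sample_labels:
        raise ValueError("need at least one sample label")
    labels = sorted(set(sample_labels))
    keyed: dict[tuple[str, ...], list[tuple[str, str]]] = {}
    singletons: list[str] = []
    for label in labels:
        key = _group_key(label)
        if key is None:
            singletons.append(label)
        else:
            keyed.setdefault(key[0], []).append((label, key[1]))

    groups: dict[str, list[str]] = {}

    def _add(name: str, members: list[str]) -> None:
        final = name
        n = 2
        while final in groups:  # two keys collapsing to one display label
            final = f"{name}~{n}"
            n += 1
        groups[final] = members

    for key in sorted(keyed):
        members = keyed[key]
        if len(members) == 1:
            singletons.append(members[0][0])
            continue
        label0, rep0 = members[0]
        name = _strip_replicate(label0, rep0) or "_".join(key)
        _add(name, [m[0] for m in members])
    for label in sorted(singletons):
        _add(label, [label])

    ordered = dict(sorted(groups.items()))
    return SampleGrouping(groups=ordered, singleton_policy_applied=bool(singletons))


# ---------------------------------------------------------------------------
# validity filtering
# ---------------------------------------------------------------------------

def filter_valid(
    report: QuantReport,
    grouping: SampleGrouping,
    config: PreprocessConfig | None = None,
    method: str | None = None,
) -> QuantReport:
    """Keep proteins quantified in enough replicates of at least one group.

    A protein survives iff in >= 1 group the fraction of non-missing values
    reaches ``config.min_valid_fraction`` for the chosen intensity method.
    """
    config = config or PreprocessConfig()
    method = _resolve_method(report, method)
    mat = report.matrix(method)
    missing_groups = [s for s in grouping.samples if s not in mat.columns]
    if missing_groups:
        raise ValueError(f"grouping mentions unknown samples: {missing_groups}")
    keep = np.zeros(len(mat), dtype=bool)
    for members in grouping.groups.values():
        cols = [s for s in members if s in mat.columns]
        if not cols:
            continue
        frac = mat[cols].notna().sum(axis=1) / len(cols)
        keep |= (frac >= config.min_valid_fraction).to_numpy()
    if not keep.any():
        warnings.warn("validity filter removed every protein", stacklevel=2)
    return report.subset(keep)


def _resolve_method(report: QuantReport, method: str | None) -> str:
    if method is not None:
        if method not in report.methods:
            raise KeyError(f"method {method!r} not in report")
        return method
    methods = list(report.methods)
    if len(methods) == 1:
        return methods[0]
    raise ValueError(
        f"report has several intensity methods {methods}; specify one"
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class IntensityNormalizer(TransformerMixin, BaseEstimator):
    """Per-sample normalization of a log2 (or raw, for total_sum) matrix.

    Parameters
    ----------
    method:
        ``median`` — shift each sample so its median equals the global
        median of sample medians (expects log-scale input).
        ``quantile`` — replace each value by the cross-sample mean of its
        rank's value, ties averaged (expects log-scale input).
        ``total_sum`` — divide by the sample total and rescale by the mean
        total (expects raw-scale input).
        ``none`` — identity.

    X is ``(n_samples, n_features)``: one row per MS run.  NaNs are ignored
    when fitting and preserved by transform.
    """

    def __init__(self, method: str = "median"):
        self.method = method

    def fit(self, X, y=None):
        X = self._check(X)
        if self.method == "median":
            medians = np.nanmedian(X, axis=1)
            self.target_median_ = float(np.nanmedian(medians))
        elif self.method == "quantile":
            n = X.shape[1]
            self.grid_ = (np.arange(n) + 0.5) / n
            curves = []
            for row in X:
                obs = row[np.isfinite(row)]
                if obs.size >= 2:
                    curves.append(np.quantile(obs, self.grid_))
            if not curves:
                raise ValueError("no sample with >= 2 finite values to fit on")
            self.reference_ = np.mean(curves, axis=0)
        elif self.method == "total_sum":
            totals = np.nansum(X, axis=1)
            self.mean_total_ = float(np.mean(totals[totals > 0]))
        elif self.method != "none":
            raise ValueError(f"unknown normalization {self.method!r}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = self._check(X).copy()
        if self.method == "none":
            return X
        for i, row in enumerate(X):
            finite = np.isfinite(row)
            if finite.sum() < 2:
                warnings.warn(
                    f"sample {i} has < 2 finite values; left unnormalized",
                    stacklevel=2,
                )
                continue
            if self.method == "median":
                row[finite] += self.target_median_ - np.nanmedian(row)
            elif self.method == "quantile":
                obs = row[finite]
                q = (rankdata(obs, method="average") - 0.5) / obs.size
                row[finite] = np.interp(q, self.grid_, self.reference_)
            elif self.method == "total_sum":
                total = np.nansum(row)
                row[finite] *= self.mean_total_ / total
        return X

    @staticmethod
    def _check(X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D (n_samples, n_features) matrix")
        return X


def normalize(
    report: QuantReport,
    normalization: str = "median",
    method: str | None = None,
) -> QuantReport:
    """Normalize a report's intensities per sample, raw scale in and out.

    ``median`` and ``quantile`` act on log2 intensities internally and are
    transformed back; ``total_sum`` acts on the raw scale directly.
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    if normalization == "none":
        return report
    methods = [method] if method else list(report.methods)
    out = report
    for m in methods:
        mat = out.matrix(m)  # proteins x samples
        X = mat.to_numpy(dtype=float).T  # runs x proteins
        log_space = normalization in ("median", "quantile")
        if log_space:
            X = np.log2(X)
        norm = IntensityNormalizer(method=normalization).fit(X)
        Xn = norm.transform(X)
        if log_space:
            Xn = np.exp2(Xn)
        out = out.with_matrix(m, pd.DataFrame(Xn.T, index=mat.index, columns=mat.columns))
    return out


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

class GaussianDownshiftImputer(TransformerMixin, BaseEstimator):
    """Left-censored imputation from a down-shifted, narrowed normal.

    For each run (row of X, log-scale values) the observed mean m and
    standard deviation s are estimated and every missing value is drawn from
    ``Normal(m - shift * s, width * s)``.  Rows with fewer than 3 observed
    values are left untouched with a warning.
    """

    def __init__(self, shift: float = 1.8, width: float = 0.3, random_state=None):
        self.shift = shift
        self.width = width
        self.random_state = random_state

    def fit(self, X, y=None):
        X = IntensityNormalizer._check(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = IntensityNormalizer._check(X).copy()
        rng = np.random.default_rng(self.random_state)
        self.imputed_mask_ = np.zeros_like(X, dtype=bool)
        for i, row in enumerate(X):
            missing = ~np.isfinite(row)
            obs = row[~missing]
            if not missing.any():
                continue
            if obs.size < 3:
                warnings.warn(
                    f"sample {i} has < 3 observed values; left unimputed",
                    stacklevel=2,
                )
                continue
            m, s = float(np.mean(obs)), float(np.std(obs, ddof=1))
            row[missing] = rng.normal(m - self.shift * s, self.width * s, missing.sum())
            self.imputed_mask_[i, missing] = True
        return X


def impute(
    report: QuantReport,
    config: PreprocessConfig | None = None,
    method: str | None = None,
) -> QuantReport:
    """Fill missing values by Gaussian downshift in log2 space.

    Observed values are unchanged; imputed cells are marked in the report's
    ``imputed`` mask so downstream absolute estimates can be flagged as
    imputation-derived.
    """
    config = config or PreprocessConfig()
    if config.imputation == "none":
        return report
    methods = [method] if method else list(report.methods)
    out = report
    for k, m in enumerate(methods):
        mat = out.matrix(m)
        X = np.log2(mat.to_numpy(dtype=float).T)
        imputer = GaussianDownshiftImputer(
            shift=config.downshift_sd,
            width=config.downshift_width,
            random_state=np.random.SeedSequence([config.rng_seed, k]).generate_state(1)[0],
        )
        Xi = imputer.fit(X).transform(X)
        # write back only the imputed cells; observed values stay bit-identical
        filled = np.where(imputer.imputed_mask_.T, np.exp2(Xi).T, mat.to_numpy())
        values = pd.DataFrame(filled, index=mat.index, columns=mat.columns)
        mask = pd.DataFrame(
            imputer.imputed_mask_.T | out.imputed_matrix(m).to_numpy(),
            index=mat.index,
            columns=mat.columns,
        )
        out = out.with_matrix(m, values, imputed=mask)
    return out
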