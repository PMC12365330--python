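"""Clinical tabular data: CSV/ARFF readers, preprocessing, synthetic generator.

All three entry points — :func:`read_csv_dataset`, :func:`read_arff_dataset`
and :func:`generate_synthetic` — emit a :class:`Dataset` validated by the
same single path: an encoded numeric feature matrix with no remaining
missing values (median/mode imputation, counts logged), at least two
rows, two features and two target classes.

The synthetic generator stands in for clinical screening panels of the
thyroid-function kind: a small set of *informative* features whose class
means differ by a standardized effect size, *redundant* features
correlated with informative ones, and label-independent *noise*
features, optionally with missing entries planted before imputation.
Ground-truth feature roles are kept so a selector's output can be scored
with :func:`recovery_score`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "SyntheticSpec",
    "read_csv_dataset",
    "read_arff_dataset",
    "generate_synthetic",
    "recovery_score",
    "write_csv_dataset",
]

FEATURE_KINDS = ("numeric", "boolean", "categorical")
DEFAULT_NA_TOKENS = ("?",)
_TRUE_TOKENS = {"t", "true", "y", "yes"}
_FALSE_TOKENS = {"f", "false", "n", "no"}


@dataclass
class Dataset:
    """Encoded feature matrix + target labels ready for the wrapper objective.

    ``features`` is the n x d float matrix after encoding and imputation;
    ``missing_mask`` marks cells that were imputed; ``meta`` carries
    reader/generator bookkeeping (encodings, imputation counts, synthetic
    ground truth).
    """

    features: np.ndarray
    feature_names: List[str]
    feature_kinds: List[str]
    target: np.ndarray
    missing_mask: np.ndarray
    provenance: str = "file"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.target = np.asarray(self.target)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, d = self.features.shape
        if n < 2 or d < 2:
            raise ValueError(f"dataset needs n >= 2 rows and d >= 2 features (got {n}x{d})")
        if len(self.feature_names) != d or len(self.feature_kinds) != d:
            raise ValueError("feature_names/feature_kinds length must equal d")
        if any(k not in FEATURE_KINDS for k in self.feature_kinds):
            raise ValueError(f"feature kinds must be in {FEATURE_KINDS}")
        if self.target.shape != (n,):
            raise ValueError("target length must equal number of rows")
        if self.missing_mask.shape != (n, d):
            raise ValueError("missing_mask must be n x d")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite values after preprocessing")
        if np.unique(self.target).size < 2:
            raise ValueError("target must have at least 2 distinct labels")
        if self.provenance not in ("file", "synthetic"):
            raise ValueError("provenance must be 'file' or 'synthetic'")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.target)

    @property
    def target_encoded(self) -> np.ndarray:
        """Integer-coded target (sorted label order), cached."""
        enc = self.meta.get("_target_encoded")
        if enc is None:
            classes, enc = np.unique(self.target, return_inverse=True)
            self.meta["_target_encoded"] = enc
            self.meta["_target_classes"] = classes
        return self.meta["_target_encoded"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df["target"] = self.target
        return df


@dataclass(frozen=True)
class SyntheticSpec:
    """Blueprint of a synthetic classification problem with known truth.

    ``informative``, ``redundant`` (pairs of source index and correlation
    rho) and the remaining ``noise`` indices partition the d features.
    ``effect_size`` is the standardized between-class mean shift of each
    informative feature; ``class_balance`` is the positive-class rate
    (minority-positive by default, as in clinical screening data).
    """

    n: int = 500
    d: int = 20
    informative: Tuple[int, ...] = (0, 1, 2, 3, 4)
    redundant: Tuple[Tuple[int, float], ...] = ()
    effect_size: float = 2.0
    class_balance: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.d < 2:
            raise ValueError("need n >= 2 and d >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        inf = set(self.informative)
        if not inf or not inf <= set(range(self.d)):
            raise ValueError("informative indices must be a non-empty subset of 0..d-1")
        for src, rho in self.redundant:
            if src not in inf:
                raise ValueError("redundant sources must be informative indices")
            if not -1 < rho < 1:
                raise ValueError("redundant correlation must lie in (-1, 1)")
        if len(self.redundant) + len(inf) > self.d:
            raise ValueError("too many informative+redundant features for d")

    @property
    def redundant_indices(self) -> Tuple[int, ...]:
        """Redundant features occupy the indices right after the largest informative."""
        taken = sorted(self.informative)
        free = [j for j in range(self.d) if j not in set(taken)]
        return tuple(free[: len(self.redundant)])

    @property
    def noise_indices(self) -> Tuple[int, ...]:
        used = set(self.informative) | set(self.redundant_indices)
        return tuple(j for j in range(self.d) if j not in used)


def _impute(values: pd.Series, kind: str) -> Tuple[pd.Series, float]:
    """Median (numeric) or mode (boolean/categorical) imputation."""
    if values.notna().sum() == 0:
        raise ValueError(f"column {values.name!r} is entirely missing")
    if kind == "numeric":
        fill = float(values.median())
    else:
        fill = float(values.mode().iloc[0])  # ties -> smallest encoded value
    return values.fillna(fill), fill


def _encode_frame(
    df: pd.DataFrame, target_column: str
) -> Tuple[np.ndarray, List[str], List[str], np.ndarray, np.ndarray, dict]:
    """Shared CSV/ARFF encoding path.

    Numeric columns stay numeric; t/f-style columns become 0/1 booleans;
    everything else is label-encoded in sorted order (mapping logged).
    Missing cells are recorded, then imputed (median / mode).
    """
    target = df[target_column].to_numpy()
    feats = df.drop(columns=[target_column])
    names = list(feats.columns)
    kinds: List[str] = []
    encodings: Dict[str, dict] = {}
    encoded = pd.DataFrame(index=feats.index)

    for col in names:
        raw = feats[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        non_missing = raw.notna()
        if (numeric.notna() | ~non_missing).all():
            encoded[col] = numeric
            kinds.append("numeric")
            continue
        lowered = raw.astype("string").str.strip().str.lower()
        observed = set(lowered.dropna().unique())
        if observed <= (_TRUE_TOKENS | _FALSE_TOKENS):
            encoded[col] = pd.to_numeric(
                lowered.map(lambda v: 1.0 if v in _TRUE_TOKENS else 0.0, na_action="ignore"),
                errors="coerce",
            )
            kinds.append("boolean")
            continue
        levels = sorted(lowered.dropna().unique())
        mapping = {lev: float(i) for i, lev in enumerate(levels)}
        encodings[col] = mapping
        logger.info("label-encoded column %r: %s", col, mapping)
        encoded[col] = pd.to_numeric(lowered.map(mapping), errors="coerce")
        kinds.append("categorical")

    missing = encoded.isna().to_numpy()
    n_missing = int(missing.sum())
    fills: Dict[str, float] = {}
    for col, kind in zip(names, kinds):
        encoded[col], fills[col] = _impute(encoded[col], kind)
    if n_missing:
        logger.info("imputed %d missing cells across %d columns", n_missing, len(names))

    meta = {"encodings": encodings, "imputed_cells": n_missing, "fill_values": fills}
    return encoded.to_numpy(dtype=float), names, kinds, target, missing, meta


def read_csv_dataset(
    path,
    target_column: str,
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
) -> Dataset:
    """Read a header-bearing CSV into a validated, fully imputed Dataset."""
    path = Path(path)
    df = pd.read_csv(path, na_values=list(na_tokens), keep_default_na=True, dtype=object)
    if target_column not in df.columns:
        raise ValueError(
            f"target column {target_column!r} not found; available: {list(df.columns)}"
        )
    if df[target_column].isna().any():
        raise ValueError("target column contains missing values")
    features, names, kinds, target, missing, meta = _encode_frame(df, target_column)
    return Dataset(features, names, kinds, target, missing, provenance="file", meta=meta)


def read_arff_dataset(path, target_attribute: str) -> Dataset:
    """Read a Weka-dialect ARFF file ('?' missing values) into a Dataset."""
    from scipy.io import arff as scipy_arff

    path = Path(path)
    try:
        data, arff_meta = scipy_arff.loadarff(str(path))
    except Exception as exc:
        raise ValueError(f"malformed ARFF file {path}: {exc}") from exc
    df = pd.DataFrame(data)
    # scipy returns nominal attributes as bytes and missing nominals as b'?'
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].str.decode("utf-8").replace({"?": None})
    if target_attribute not in df.columns:
        raise ValueError(
            f"target attribute {target_attribute!r} not found; "
            f"available: {list(df.columns)}"
        )
    if df[target_attribute].isna().any():
        raise ValueError("target attribute contains missing values")
    features, names, kinds, target, missing, meta = _encode_frame(df, target_attribute)
    # keep the declared nominal domains for reference
    meta["arff_attributes"] = {
        name: str(arff_meta[name][0]) for name in arff_meta.names()
    }
    return Dataset(features, names, kinds, target, missing, provenance="file", meta=meta)


def write_csv_dataset(dataset: Dataset, path) -> None:
    """Write the encoded matrix + target to CSV (round-trips exactly)."""
    dataset.to_frame().to_csv(path, index=False)


def generate_synthetic(spec: SyntheticSpec) -> Dataset:
    """Draw a synthetic dataset with known informative/redundant/noise roles.

    Labels ~ Bernoulli(class_balance).  Informative feature j is N(0,1)
    under class 0 and N(effect_size, 1) under class 1; redundant
    features are rho * source + sqrt(1-rho^2) * N(0,1); noise features
    are N(0,1) independent of the label.  Missing entries are planted at
    ``missing_rate`` and imputed through the standard path.
    """
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n) < spec.class_balance).astype(int)
    # guarantee both classes appear (tiny-n edge)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    X = rng.standard_normal((spec.n, spec.d))
    for j in spec.informative:
        X[:, j] += spec.effect_size * y
    for (src, rho), j in zip(spec.redundant, spec.redundant_indices):
        X[:, j] = rho * X[:, src] + np.sqrt(1.0 - rho**2) * X[:, j]

    missing = np.zeros((spec.n, spec.d), dtype=bool)
    if spec.missing_rate > 0:
        missing = rng.random((spec.n, spec.d)) < spec.missing_rate
        # never blank out a full column
        full = missing.all(axis=0)
        missing[0, full] = False

    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(spec.d)])
    df = df.mask(missing)
    n_imputed = int(missing.sum())
    for col in df.columns:
        df[col], _ = _impute(df[col], "numeric")

    meta = {
        "synthetic_spec": spec,
        "informative": tuple(spec.informative),
        "redundant": spec.redundant_indices,
        "noise": spec.noise_indices,
        "imputed_cells": n_imputed,
    }
    return Dataset(
        features=df.to_numpy(dtype=float),
        feature_names=list(df.columns),
        feature_kinds=["numeric"] * spec.d,
        target=y,
        missing_mask=missing,
        provenance="synthetic",
        meta=meta,
    )


def recovery_score(selected_mask: np.ndarray, spec: SyntheticSpec) -> Tuple[float, float]:
    """Score a selected mask against the generator's ground truth.

    Returns ``(recall_informative, fp_noise_rate)``: the fraction of
    informative features selected, and the fraction of pure-noise
    features selected.  The noise rate is 0 when there are no noise
    features.
    """
    mask = np.asarray(selected_mask, dtype=bool)
    if mask.size != spec.d:
        raise ValueError(f"mask length {mask.size} does not match spec.d={spec.d}")
    informative = np.asarray(spec.informative, dtype=int)
    noise = np.asarray(spec.noise_indices, dtype=int)
    recall = float(mask[informative].mean()) if informative.size else 0.0
    fp_rate = float(mask[noise].mean()) if noise.size else 0.0
    return recall, fp_rate
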