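"""Foldability statistics: RMSD thresholding, aggregation maps, a
gradient-boosted foldability classifier and exact Shapley attribution.

A conformation counts as "foldable" when the RMSD of its guanine core to
the unique core reference falls strictly below a per-class threshold, the
99th percentile of the core-fluctuation RMSD distribution of stably
folded references.  Foldability fractions are then aggregated by
topology, total loop length, per-position loop features and two-loop
combinations, and a classifier over the conformational features is
interrogated with exact (coalition-enumeration) Shapley values.

Records travel as pandas DataFrames in the conformational-grid TSV
schema plus ``rmsd_nm`` and ``foldable`` columns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.metrics import precision_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder

__all__ = [
    "ThresholdSet",
    "DEFAULT_THRESHOLDS",
    "rmsd_threshold",
    "label_foldable",
    "foldability_map",
    "foldability_by_feature",
    "two_loop_combination_table",
    "FEATURE_COLUMNS",
    "featurize",
    "ClassifierResult",
    "fit_foldability_classifier",
    "shapley_values",
    "ShapleyAttribution",
    "exact_shapley_attribution",
    "attribution_by_level",
]

DEFAULT_SEED = 20250911


@dataclass(frozen=True)
class ThresholdSet:
    """Per-class RMSD thresholds (nm) for fold classification.

    Classes are keyed ``"<n>T-<helicity>"``.  The defaults are the
    reference thresholds for three-tetrad right-handed, two-tetrad
    right-handed and two-tetrad left-handed cores at the 99th percentile
    of the folded-state fluctuation distributions; they apply only to
    data generated against those references (synthetic or ingested).
    """

    thresholds_nm: Mapping[str, float] = field(
        default_factory=lambda: {"3T-RH": 0.104, "2T-RH": 0.079, "2T-LH": 0.083}
    )
    percentile: float = 99.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds_nm", dict(self.thresholds_nm))
        if any(t <= 0 for t in self.thresholds_nm.values()):
            raise ValueError(f"thresholds must be positive: {self.thresholds_nm}")
        if not 0 < self.percentile <= 100:
            raise ValueError(f"percentile must be in (0, 100]: {self.percentile}")

    def for_class(self, n_tetrads: int, helicity: str) -> float:
        key = f"{n_tetrads}T-{helicity}"
        try:
            return self.thresholds_nm[key]
        except KeyError:
            raise KeyError(
                f"no RMSD threshold for class {key!r}; available: "
                f"{sorted(self.thresholds_nm)}"
            ) from None

    def with_threshold(self, key: str, value: float) -> "ThresholdSet":
        merged = {**self.thresholds_nm, key: value}
        return ThresholdSet(thresholds_nm=merged, percentile=self.percentile)


DEFAULT_THRESHOLDS = ThresholdSet()


def rmsd_threshold(folded_samples: Sequence[float], percentile: float = 99.0) -> float:
    """Empirical percentile of a folded-state RMSD series.

    Uses linear interpolation between order statistics (numpy's default
    ``linear`` method), e.g. the 99th percentile of 1..100 is 99.01.
    """
    samples = np.asarray(folded_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("folded_samples must be nonempty")
    if not 0 < percentile <= 100:
        raise ValueError(f"percentile must be in (0, 100]: {percentile}")
    return float(np.percentile(samples, percentile, method="linear"))


def label_foldable(
    records: pd.DataFrame, thresholds: ThresholdSet = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Assign ``foldable = (rmsd_nm < class threshold)`` (strict).

    Returns a copy; requires ``n_tetrads``, ``helicity`` and ``rmsd_nm``
    columns and a threshold for every class present.
    """
    out = records.copy()
    classes = out[["n_tetrads", "helicity"]].drop_duplicates()
    thr = {
        (int(n), h): thresholds.for_class(int(n), h)
        for n, h in classes.itertuples(index=False)
    }
    per_row = [
        thr[(int(n), h)]
        for n, h in zip(out["n_tetrads"], out["helicity"])
    ]
    out["foldable"] = out["rmsd_nm"].to_numpy() < np.asarray(per_row)
    return out


def foldability_map(records: pd.DataFrame) -> pd.DataFrame:
    """Fraction of foldable structures per (topology, total loop length).

    Averages over polarity patterns (and anything else sharing the cell);
    rows are ordered by decreasing mean foldability of the topology;
    empty cells are NaN (missing), never zero.
    """
    df = records.copy()
    df["total_loop_len"] = df[["len_I", "len_II", "len_III"]].sum(axis=1)
    table = df.pivot_table(
        index="topology", columns="total_loop_len", values="foldable", aggfunc="mean"
    )
    order = (
        df.groupby("topology")["foldable"].mean().sort_values(ascending=False).index
    )
    return table.loc[order]


def foldability_by_feature(records: pd.DataFrame, feature: str = "type") -> pd.DataFrame:
    """Mean foldability grouped by (loop type | loop length, position).

    ``feature`` is ``"type"`` (loop token at each position) or
    ``"length"``.  Tidy output: position, value, foldability, n.
    """
    if feature == "type":
        cols = {"I": None, "II": None, "III": None}
        extract = lambda df, pos: df["topology"].map(
            lambda t: _split_tokens(t)[("I", "II", "III").index(pos)]
        )
    elif feature == "length":
        extract = lambda df, pos: df[f"len_{pos}"]
    else:
        raise ValueError(f"feature must be 'type' or 'length': {feature!r}")
    rows = []
    for pos in ("I", "II", "III"):
        values = extract(records, pos)
        grouped = records.groupby(values)["foldable"]
        for value, sub in grouped:
            rows.append(
                {
                    "position": pos,
                    "value": value,
                    "foldability": sub.mean(),
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows)


def _split_tokens(notation: str) -> tuple[str, str, str]:
    from .topology import parse_topology

    return tuple(str(lt) for lt in parse_topology(notation).loops)  # type: ignore


def two_loop_combination_table(records: pd.DataFrame) -> pd.DataFrame:
    """Mean foldability for every ordered pair of loop types at two
    distinct positions, with the topologies containing each combination.

    A combination present in a single topology simply reports that
    topology's foldability.
    """
    tokens = records["topology"].map(_split_tokens)
    df = records.assign(
        type_I=tokens.str[0], type_II=tokens.str[1], type_III=tokens.str[2]
    )
    rows = []
    for pos_a, pos_b in itertools.combinations(("I", "II", "III"), 2):
        grouped = df.groupby([f"type_{pos_a}", f"type_{pos_b}"])
        for (ta, tb), sub in grouped:
            rows.append(
                {
                    "position_a": pos_a,
                    "type_a": ta,
                    "position_b": pos_b,
                    "type_b": tb,
                    "foldability": sub["foldable"].mean(),
                    "n": len(sub),
                    "topologies": ",".join(sorted(sub["topology"].unique())),
                }
            )
    return pd.DataFrame(rows).sort_values("foldability").reset_index(drop=True)


# --------------------------------------------------------------------------
# classifier + Shapley attribution

#: Conformational features fed to the classifier: loop type and length at
#: each position plus the tetrad-polarity pattern as one categorical.
FEATURE_COLUMNS = [
    "type_I",
    "type_II",
    "type_III",
    "len_I",
    "len_II",
    "len_III",
    "polarity",
]

_CATEGORICAL = ["type_I", "type_II", "type_III", "polarity"]


def featurize(records: pd.DataFrame) -> pd.DataFrame:
    """Derive the feature matrix (and copy the label if present)."""
    tokens = records["topology"].map(_split_tokens)
    out = pd.DataFrame(
        {
            "type_I": tokens.str[0],
            "type_II": tokens.str[1],
            "type_III": tokens.str[2],
            "len_I": records["len_I"].astype(int),
            "len_II": records["len_II"].astype(int),
            "len_III": records["len_III"].astype(int),
            "polarity": records["polarity"],
        }
    )
    if "foldable" in records:
        out["foldable"] = records["foldable"].astype(bool).to_numpy()
    return out


def _make_pipeline(columns: Sequence[str], model) -> Pipeline:
    cats = [c for c in columns if c in _CATEGORICAL]
    nums = [c for c in columns if c not in _CATEGORICAL]
    pre = ColumnTransformer(
        [
            ("onehot", OneHotEncoder(handle_unknown="ignore"), cats),
            ("passthrough", "passthrough", nums),
        ]
    )
    return Pipeline([("features", pre), ("model", model)])


def _default_model(seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=150,
        max_depth=4,
        learning_rate=0.2,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )


@dataclass
class ClassifierResult:
    pipeline: Pipeline
    precision_mean: float
    precision_folds: np.ndarray
    prevalence: float
    n_folds: int
    seed: int


def fit_foldability_classifier(
    records: pd.DataFrame,
    n_folds: int = 10,
    seed: int = DEFAULT_SEED,
    model_factory: Callable[[int], object] | None = None,
) -> ClassifierResult:
    """Fit a gradient-boosted foldability classifier on the
    conformational features and report stratified cross-validated
    precision (positive class: foldable).

    Deterministic given ``seed``; raises on single-class input.
    """
    feats = featurize(records)
    y = feats.pop("foldable").to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both foldable and unfoldable records are required")
    factory = model_factory or _default_model
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    precisions = []
    for train_idx, test_idx in skf.split(feats, y):
        pipe = _make_pipeline(FEATURE_COLUMNS, factory(seed))
        pipe.fit(feats.iloc[train_idx], y[train_idx])
        pred = pipe.predict(feats.iloc[test_idx])
        precisions.append(precision_score(y[test_idx], pred, zero_division=0))
    final = _make_pipeline(FEATURE_COLUMNS, factory(seed))
    final.fit(feats, y)
    return ClassifierResult(
        pipeline=final,
        precision_mean=float(np.mean(precisions)),
        precision_folds=np.asarray(precisions),
        prevalence=float(y.mean()),
        n_folds=n_folds,
        seed=seed,
    )


MAX_EXACT_FEATURES = 12


def shapley_values(
    value_fn: Callable[[frozenset[int]], np.ndarray | float], n_features: int
) -> np.ndarray:
    """Exact Shapley values by full coalition enumeration.

    ``value_fn(S)`` returns the characteristic value of coalition ``S``
    (a scalar, or a per-record vector -- the output then has one row of
    attributions per record).  Enumeration covers all 2**m coalitions;
    ``n_features`` above 12 is refused (use a sampling approximation for
    larger feature sets).
    """
    m = int(n_features)
    if m < 1:
        raise ValueError("n_features must be >= 1")
    if m > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{m} features exceed the exact-enumeration limit of "
            f"{MAX_EXACT_FEATURES}; use a sampled (Monte Carlo permutation) "
            "approximation instead"
        )
    values = {
        frozenset(S): np.asarray(value_fn(frozenset(S)), dtype=float)
        for r in range(m + 1)
        for S in itertools.combinations(range(m), r)
    }
    fact = [math.factorial(i) for i in range(m + 1)]
    shape = values[frozenset()].shape
    phi = np.zeros((m, *shape))
    for S, v_s in values.items():
        for i in range(m):
            if i in S:
                continue
            weight = fact[len(S)] * fact[m - len(S) - 1] / fact[m]
            phi[i] += weight * (values[S | {i}] - v_s)
    return phi


@dataclass
class ShapleyAttribution:
    """Exact Shapley attribution of predicted foldability to features.

    ``per_record`` holds one row of signed attributions per record and
    one column per feature; ``mean_signed`` is the per-feature average.
    Efficiency: per record the attributions sum to (full-coalition
    prediction - base rate).
    """

    features: list[str]
    per_record: np.ndarray  # (n_records, n_features)
    mean_signed: pd.Series
    base_value: float
    full_prediction: np.ndarray  # (n_records,)


def exact_shapley_attribution(
    records: pd.DataFrame,
    model_factory: Callable[[int], object] | None = None,
    seed: int = DEFAULT_SEED,
    features: Sequence[str] | None = None,
) -> ShapleyAttribution:
    """Retrain-per-coalition Shapley attribution of foldability.

    The characteristic value of coalition S is the per-record predicted
    probability of foldability from a model retrained on the feature
    subset S (the empty coalition predicts the base rate).  Exact
    enumeration over all 2**m coalitions; deterministic given ``seed``.
    """
    cols = list(features) if features is not None else list(FEATURE_COLUMNS)
    feats = featurize(records)
    y = feats["foldable"].to_numpy().astype(float)
    X = feats[cols]
    factory = model_factory or _default_model

    cache: dict[frozenset[int], np.ndarray] = {}

    def value_fn(S: frozenset[int]) -> np.ndarray:
        if S in cache:
            return cache[S]
        if not S:
            v = np.full(len(X), y.mean())
        else:
            sub = [cols[i] for i in sorted(S)]
            pipe = _make_pipeline(sub, factory(seed))
            pipe.fit(X[sub], y.astype(bool))
            v = pipe.predict_proba(X[sub])[:, 1]
        cache[S] = v
        return v

    phi = shapley_values(value_fn, len(cols))  # (m, n_records)
    per_record = phi.T
    return ShapleyAttribution(
        features=cols,
        per_record=per_record,
        mean_signed=pd.Series(per_record.mean(axis=0), index=cols),
        base_value=float(y.mean()),
        full_prediction=cache[frozenset(range(len(cols)))],
    )


def attribution_by_level(
    records: pd.DataFrame, attribution: ShapleyAttribution
) -> pd.DataFrame:
    """Mean signed attribution per (feature, level), e.g. the average
    Shapley contribution of ``type_I`` among records where it equals
    ``-p`` -- the per-level reading of a Shapley summary.
    """
    feats = featurize(records)
    rows = []
    for j, col in enumerate(attribution.features):
        for value, idx in feats.groupby(col).groups.items():
            pos = feats.index.get_indexer(idx)
            rows.append(
                {
                    "feature": col,
                    "value": value,
                    "mean_attribution": float(attribution.per_record[pos, j].mean()),
                    "n": len(pos),
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values("mean_attribution", ascending=False)
        .reset_index(drop=True)
    )
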