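"""Ensemble consensus subtype classification.

A roster of heterogeneous classifiers — spanning the six classical
families *bayesian, functions, lazy, meta, rules, trees* — is trained on
an expression matrix restricted to a probe list, either under stratified
k-fold cross-validation or in a train/test transfer setting (optionally
across platforms via a probe mapping and per-probe min-max
normalisation).  Each classifier votes one of the five subtypes for every
sample; the consensus label is the subtype with a *strict* majority
(> 50 % of the votes), and samples where no subtype reaches that bar are
marked inconsistent (``INC``).

The default roster holds 24 models, a scikit-learn analogue of a classic
Weka panel; family coverage rather than classifier identity is what the
consensus mechanism relies on, and any roster can be substituted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from cm1subtype.cm1 import ProbeSelection
from cm1subtype.types import ConfigurationError, DomainError, INC, validate_labels

FAMILIES = ("bayesian", "functions", "lazy", "meta", "rules", "trees")


@dataclass(frozen=True)
class ClassifierSpec:
    """One voter in the ensemble: a named, seeded model of a known family."""

    name: str
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )


#: name -> (family, hyperparameters) of the 24-model default roster.
DEFAULT_ROSTER: tuple[tuple[str, str, dict], ...] = (
    # bayesian
    ("gaussian_nb", "bayesian", {}),
    ("gaussian_nb_smoothed", "bayesian", {"var_smoothing": 1e-3}),
    ("bernoulli_nb", "bayesian", {}),
    # functions
    ("logistic", "functions", {"C": 1.0, "max_iter": 2000}),
    ("ridge", "functions", {"alpha": 1.0}),
    ("linear_svm", "functions", {"C": 1.0, "max_iter": 5000}),
    ("rbf_svm", "functions", {"C": 1.0, "gamma": "scale"}),
    ("mlp", "functions", {"hidden_layer_sizes": (32,), "max_iter": 500}),
    # lazy
    ("knn_1", "lazy", {"n_neighbors": 1}),
    ("knn_5", "lazy", {"n_neighbors": 5}),
    ("knn_10_distance", "lazy", {"n_neighbors": 10, "weights": "distance"}),
    ("nearest_centroid", "lazy", {}),
    # meta
    ("random_forest", "meta", {"n_estimators": 100}),
    ("extra_trees", "meta", {"n_estimators": 100}),
    ("bagging_tree", "meta", {"n_estimators": 25}),
    ("adaboost_tree", "meta", {"n_estimators": 50}),
    ("gradient_boosting", "meta", {"n_estimators": 50}),
    ("lda_bagging", "meta", {"n_estimators": 15}),
    # rules
    ("zero_rule", "rules", {}),
    ("one_rule", "rules", {}),
    ("decision_table", "rules", {"max_depth": 3, "min_samples_leaf": 5}),
    # trees
    ("cart_gini", "trees", {"criterion": "gini"}),
    ("cart_entropy", "trees", {"criterion": "entropy"}),
    ("random_tree", "trees", {"splitter": "random", "max_features": "sqrt"}),
)


def build_roster(
    names: list[str] | None = None, seed: int = 0
) -> list[ClassifierSpec]:
    """Build the classifier roster (default: all 24 models, six families).

    Each spec gets a distinct deterministic seed derived from *seed*.
    Passing *names* restricts the roster to those models (>= 2 models over
    >= 2 families required).
    """
    catalogue = {name: (family, hp) for name, family, hp in DEFAULT_ROSTER}
    if names is None:
        chosen = [name for name, _, _ in DEFAULT_ROSTER]
    else:
        unknown = [n for n in names if n not in catalogue]
        if unknown:
            raise ConfigurationError(f"unknown classifiers: {unknown}")
        chosen = list(names)
    specs = [
        ClassifierSpec(
            name=name,
            family=catalogue[name][0],
            hyperparameters=dict(catalogue[name][1]),
            seed=seed + 1000 * i,
        )
        for i, name in enumerate(chosen)
    ]
    if names is not None and len(specs) >= 2:
        if len({s.family for s in specs}) < 2:
            raise ConfigurationError(
                "a custom roster must span at least two families"
            )
    return specs


def make_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator behind a spec.

    Scale-sensitive models are wrapped in a standardising pipeline.
    """
    hp = dict(spec.hyperparameters)
    seed = spec.seed

    def scaled(model):
        return Pipeline([("scale", StandardScaler()), ("model", model)])

    builders = {
        "gaussian_nb": lambda: GaussianNB(**hp),
        "gaussian_nb_smoothed": lambda: GaussianNB(**hp),
        # standardising first makes binarize=0 a per-feature mean split
        "bernoulli_nb": lambda: scaled(BernoulliNB(binarize=0.0, **hp)),
        "logistic": lambda: scaled(LogisticRegression(random_state=seed, **hp)),
        "ridge": lambda: scaled(RidgeClassifier(**hp)),
        "linear_svm": lambda: scaled(LinearSVC(random_state=seed, **hp)),
        "rbf_svm": lambda: scaled(SVC(random_state=seed, **hp)),
        "mlp": lambda: scaled(MLPClassifier(random_state=seed, **hp)),
        "knn_1": lambda: scaled(KNeighborsClassifier(**hp)),
        "knn_5": lambda: scaled(KNeighborsClassifier(**hp)),
        "knn_10_distance": lambda: scaled(KNeighborsClassifier(**hp)),
        "nearest_centroid": lambda: scaled(NearestCentroid(**hp)),
        "random_forest": lambda: RandomForestClassifier(random_state=seed, **hp),
        "extra_trees": lambda: ExtraTreesClassifier(random_state=seed, **hp),
        "bagging_tree": lambda: BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            random_state=seed,
            **hp,
        ),
        "adaboost_tree": lambda: AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=3, random_state=seed),
            random_state=seed,
            **hp,
        ),
        "gradient_boosting": lambda: GradientBoostingClassifier(
            random_state=seed, **hp
        ),
        "lda_bagging": lambda: BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(), random_state=seed, **hp
        ),
        "zero_rule": lambda: DummyClassifier(strategy="most_frequent", **hp),
        "one_rule": lambda: DecisionTreeClassifier(max_depth=1, random_state=seed, **hp),
        "decision_table": lambda: DecisionTreeClassifier(random_state=seed, **hp),
        "cart_gini": lambda: DecisionTreeClassifier(random_state=seed, **hp),
        "cart_entropy": lambda: DecisionTreeClassifier(random_state=seed, **hp),
        "random_tree": lambda: DecisionTreeClassifier(random_state=seed, **hp),
    }
    if spec.name not in builders:
        raise ConfigurationError(f"no estimator builder for {spec.name!r}")
    return builders[spec.name]()


def majority_vote(votes) -> str:
    """Strict-majority reduction of one sample's votes.

    Returns the unique label held by *more than half* of the voters, or
    ``INC`` when no label clears that bar (including exact ties at k/2).
    """
    votes = list(votes)
    if not votes:
        raise DomainError("majority_vote requires at least one vote")
    label, count = Counter(votes).most_common(1)[0]
    return label if count * 2 > len(votes) else INC


def consensus_from_predictions(predictions: pd.DataFrame) -> pd.DataFrame:
    """Reduce a samples x classifiers prediction matrix to consensus labels.

    Returns a DataFrame indexed by sample id with columns
    ``consensus, votes, k``.
    """
    k = predictions.shape[1]
    rows = []
    for sample, row in predictions.iterrows():
        counts = Counter(row.tolist())
        label, top = counts.most_common(1)[0]
        if top * 2 > k:
            rows.append((sample, label, top, k))
        else:
            rows.append((sample, INC, top, k))
    return pd.DataFrame(
        rows, columns=["sample_id", "consensus", "votes", "k"]
    ).set_index("sample_id")


def _probe_list(probes) -> list[str]:
    if isinstance(probes, ProbeSelection):
        return list(probes.union)
    return list(probes)


def cross_validate_consensus(
    matrix: pd.DataFrame,
    labels: pd.Series,
    probes,
    roster: list[ClassifierSpec] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified k-fold cross-validated ensemble consensus.

    Samples are partitioned into *folds* stratified folds; every
    classifier is trained on the out-of-fold 90 % and predicts the held
    out 10 %, so no sample is ever predicted by a model that saw it in
    training.  Returns the samples x classifiers prediction matrix (with
    the fold assignment in ``attrs["fold"]``) and the consensus table.
    """
    if roster is None:
        roster = build_roster(seed=seed)
    probe_ids = _probe_list(probes)
    missing = [p for p in probe_ids if p not in matrix.index]
    if missing:
        raise DomainError(f"probes absent from matrix: {missing[:5]}")
    validate_labels(labels, samples=matrix.columns)
    labels = labels.reindex(matrix.columns)
    class_counts = labels.value_counts()
    too_small = class_counts[class_counts < folds]
    if len(too_small):
        raise DomainError(
            f"classes smaller than fold count {folds}: {too_small.to_dict()}"
        )

    X = matrix.loc[probe_ids].T.to_numpy(dtype=float)
    y = labels.to_numpy()
    sample_ids = matrix.columns

    predictions = pd.DataFrame(
        index=sample_ids.rename("sample_id"),
        columns=[s.name for s in roster],
        dtype=object,
    )
    fold_of_sample = pd.Series(-1, index=sample_ids, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold_no, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        fold_of_sample.iloc[test_idx] = fold_no
        for spec in roster:
            model = make_estimator(spec)
            model.fit(X[train_idx], y[train_idx])
            predictions.iloc[test_idx, predictions.columns.get_loc(spec.name)] = (
                model.predict(X[test_idx])
            )
    predictions.attrs["mode"] = "cross-validation"
    predictions.attrs["fold"] = fold_of_sample
    return predictions, consensus_from_predictions(predictions)


def minmax_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale each probe row to [0, 1] across the platform's samples.

    Constant rows (zero range) map to all zeros: a flat probe carries no
    signal and any constant placement is arbitrary.
    """
    if matrix.empty:
        raise DomainError("cannot normalise an empty matrix")
    values = matrix.to_numpy(dtype=float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(values)
    nonconstant = (span > 0).ravel()
    out[nonconstant] = (values[nonconstant] - lo[nonconstant]) / span[nonconstant]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def map_probes(
    probes, mapping: pd.DataFrame, test_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Resolve a source-platform probe list onto the test platform.

    *mapping* has columns ``source_probe, target_probe`` and may map one
    source probe to several targets; for those, the target with the
    largest variance across the test samples wins (ties broken by target
    identifier).  Targets absent from the test matrix are ignored.
    Returns matched ``(source_probe, target_probe)`` pairs, with the
    source probes that found no target listed in ``attrs["unmapped"]``.
    """
    probe_ids = _probe_list(probes)
    required = {"source_probe", "target_probe"}
    if not required <= set(mapping.columns):
        raise DomainError(f"mapping table needs columns {sorted(required)}")
    candidates = mapping[
        mapping["source_probe"].isin(probe_ids)
        & mapping["target_probe"].isin(test_matrix.index)
    ]
    variances = test_matrix.var(axis=1, ddof=1)
    pairs: list[tuple[str, str]] = []
    matched_sources: set[str] = set()
    for source in probe_ids:
        targets = candidates.loc[
            candidates["source_probe"] == source, "target_probe"
        ].tolist()
        if not targets:
            continue
        best = sorted(targets, key=lambda t: (-variances[t], t))[0]
        pairs.append((source, best))
        matched_sources.add(source)
    out = pd.DataFrame(pairs, columns=["source_probe", "target_probe"])
    out.attrs["unmapped"] = [p for p in probe_ids if p not in matched_sources]
    return out


def train_test_consensus(
    train_matrix: pd.DataFrame,
    train_labels: pd.Series,
    test_matrix: pd.DataFrame,
    probes,
    roster: list[ClassifierSpec] | None = None,
    mapping: pd.DataFrame | None = None,
    normalize: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train once on the full training set; predict the test set.

    With a cross-platform *mapping*, the probe list is first resolved via
    :func:`map_probes` and both sides are restricted to the matched pairs.
    With ``normalize=True`` each platform is min-max normalised per probe
    *separately* before fitting, making the two platforms' intensity
    scales commensurable.
    """
    if roster is None:
        roster = build_roster(seed=seed)
    probe_ids = _probe_list(probes)
    missing = [p for p in probe_ids if p not in train_matrix.index]
    if missing:
        raise DomainError(f"probes absent from training matrix: {missing[:5]}")

    if mapping is not None:
        pairs = map_probes(probe_ids, mapping, test_matrix)
        if pairs.empty:
            raise DomainError("no probes could be mapped onto the test platform")
        train_rows = pairs["source_probe"].tolist()
        test_sub = test_matrix.loc[pairs["target_probe"].tolist()]
        test_sub.index = pd.Index(train_rows, name="probe_id")
    else:
        shared = [p for p in probe_ids if p in test_matrix.index]
        if not shared:
            raise DomainError("no probes shared between train and test matrices")
        train_rows = shared
        test_sub = test_matrix.loc[shared]
    train_sub = train_matrix.loc[train_rows]

    if normalize:
        train_sub = minmax_normalize(train_sub)
        test_sub = minmax_normalize(test_sub)

    validate_labels(train_labels, samples=train_matrix.columns)
    y = train_labels.reindex(train_matrix.columns).to_numpy()
    X_train = train_sub.T.to_numpy(dtype=float)
    X_test = test_sub.T.to_numpy(dtype=float)

    predictions = pd.DataFrame(
        index=test_matrix.columns.rename("sample_id"),
        columns=[s.name for s in roster],
        dtype=object,
    )
    for spec in roster:
        model = make_estimator(spec)
        model.fit(X_train, y)
        predictions[spec.name] = model.predict(X_test)
    predictions.attrs["mode"] = "train-test"
    return predictions, consensus_from_predictions(predictions)
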