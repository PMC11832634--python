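"""Linear discriminant classification of spin systems into amino-acid types.

The model is classical LDA: each amino-acid type k is a Gaussian with its
own mean and a covariance pooled across types, so the log-posterior is
linear in the feature vector,

    delta_k(x) = x' S^-1 mu_k - 1/2 mu_k' S^-1 mu_k + log pi_k,

with posteriors the softmax of the delta_k.  Features (shifts in ppm,
temperature coefficients in ppb/K) are standardized before fitting, and
the pooled covariance is shrunk toward its diagonal,
S_lambda = (1-lambda) S + lambda diag(S), which keeps small same-protein
training sets (a handful of residues for the rarer types) well-posed.

Missing features are handled by refitting on the reduced feature subset
rather than by imputation, so every classification is an exact LDA on the
features actually observed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from numpy.linalg import LinAlgError
from scipy.linalg import cho_factor, cho_solve

from .spinsys import NUCLEI, SpinSystem, complete_feature_set

_PRESET_BASE4 = ("HN", "N", "C", "CA")
_PRESET_BASE5 = ("HN", "N", "C", "CA", "CB")


def _tc(nuclei: Sequence[str], interval: int) -> tuple[str, ...]:
    return tuple(f"TC{interval}_{n}" for n in nuclei)


@dataclass(frozen=True)
class FeatureSubset:
    """An ordered, duplicate-free list of feature ids with a name.

    Feature ids are nucleus names (shifts) or ``TC<k>_<nucleus>``
    (temperature coefficient of interval k).
    """

    name: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature subset is empty")
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"duplicate features in subset {self.name}")
        for f in self.features:
            if f not in NUCLEI and not (
                f.startswith("TC") and "_" in f and f.split("_", 1)[1] in NUCLEI
            ):
                raise ValueError(f"unknown feature id {f!r}")


#: The six canonical shift/TC combinations.  TC features are included for
#: exactly the nuclei whose shifts are in the subset.
PRESETS: dict[str, FeatureSubset] = {
    "i": FeatureSubset("i", _PRESET_BASE4),
    "ii": FeatureSubset("ii", _PRESET_BASE4 + _tc(_PRESET_BASE4, 1)),
    "iii": FeatureSubset("iii", _PRESET_BASE4 + _tc(_PRESET_BASE4, 1) + _tc(_PRESET_BASE4, 2)),
    "iv": FeatureSubset("iv", _PRESET_BASE5),
    "v": FeatureSubset("v", _PRESET_BASE5 + _tc(_PRESET_BASE5, 1)),
    "vi": FeatureSubset("vi", _PRESET_BASE5 + _tc(_PRESET_BASE5, 1) + _tc(_PRESET_BASE5, 2)),
}


class LDAError(ValueError):
    pass


@dataclass
class LDAModel:
    classes: tuple[str, ...]
    means: np.ndarray              # (K, d), standardized scale
    pooled_cov: np.ndarray         # (d, d), after shrinkage
    priors: np.ndarray             # (K,)
    center: np.ndarray             # (d,) raw-feature centering
    scale: np.ndarray              # (d,) raw-feature scaling
    lam: float
    n_per_class: dict[str, int]
    subset: FeatureSubset
    excluded_classes: dict[str, str] = field(default_factory=dict)
    _cho: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise LDAError("need at least two classes")
        if not np.isclose(self.priors.sum(), 1.0):
            raise LDAError("priors must sum to 1")
        try:
            self._cho = cho_factor(self.pooled_cov)
        except LinAlgError as exc:
            raise LDAError(
                "pooled covariance is singular; increase the shrinkage lambda"
            ) from exc

    @property
    def precision(self) -> np.ndarray:
        return cho_solve(self._cho, np.eye(len(self.center)))

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center) / self.scale


@dataclass
class ClassificationResult:
    """Posterior probabilities over amino-acid types for one spin system."""

    posteriors: dict[str, float]
    ranking: tuple[str, ...]
    subset: FeatureSubset
    excluded_classes: dict[str, str] = field(default_factory=dict)
    low_information: bool = False

    def top(self, m: int = 3) -> list[tuple[str, float]]:
        return [(c, self.posteriors[c]) for c in self.ranking[:m]]


def _features_matrix(systems: Sequence[SpinSystem], features: Sequence[str]) -> np.ndarray:
    return np.array([[s.feature(f) for f in features] for s in systems], dtype=float)


def _resolve_priors(
    priors: Union[str, Mapping[str, float]],
    classes: Sequence[str],
    counts: Mapping[str, int],
    sequence: Optional[str],
) -> np.ndarray:
    if isinstance(priors, Mapping):
        vec = np.array([priors[c] for c in classes], dtype=float)
    elif priors == "uniform":
        vec = np.ones(len(classes))
    elif priors == "training":
        vec = np.array([counts[c] for c in classes], dtype=float)
    elif priors == "sequence":
        if sequence is None:
            raise LDAError("priors mode 'sequence' needs a protein sequence")
        vec = np.array([sequence.count(c) for c in classes], dtype=float)
        if vec.sum() == 0:
            raise LDAError("no model class occurs in the sequence")
    else:
        raise LDAError(f"unknown priors mode {priors!r}")
    if np.any(vec < 0) or vec.sum() <= 0:
        raise LDAError("invalid priors")
    return vec / vec.sum()


def fit(
    train: Sequence[SpinSystem],
    subset: Union[str, FeatureSubset],
    priors: Union[str, Mapping[str, float]] = "uniform",
    lam: float = 0.05,
    min_class_size: int = 3,
    sequence: Optional[str] = None,
) -> LDAModel:
    """Fit an LDA model on labeled spin systems.

    Training items must be complete for ``subset``.  Classes with fewer
    than ``min_class_size`` members are dropped with a warning and listed
    in ``model.excluded_classes``.
    """
    subset = PRESETS[subset] if isinstance(subset, str) else subset
    labeled = [s for s in train if s.res_type is not None]
    for s in labeled:
        if not complete_feature_set(s, subset.features):
            raise LDAError(
                f"training spin system {s.id} is incomplete for subset {subset.name}; "
                "filter with complete_feature_set or use fit_subset_family"
            )
    counts: dict[str, int] = {}
    for s in labeled:
        counts[s.res_type] = counts.get(s.res_type, 0) + 1
    excluded = {
        c: f"only {n} training systems (< {min_class_size})"
        for c, n in counts.items()
        if n < min_class_size
    }
    if excluded:
        warnings.warn(f"dropping undersized classes: {sorted(excluded)}")
    classes = tuple(sorted(c for c in counts if c not in excluded))
    if len(classes) < 2:
        raise LDAError("fewer than two classes survive min_class_size")
    items = [s for s in labeled if s.res_type in classes]

    X = _features_matrix(items, subset.features)
    y = np.array([s.res_type for s in items])
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale

    d = Z.shape[1]
    means = np.vstack([Z[y == c].mean(axis=0) for c in classes])
    scatter = np.zeros((d, d))
    for k, c in enumerate(classes):
        dev = Z[y == c] - means[k]
        scatter += dev.T @ dev
    n, K = len(items), len(classes)
    pooled = scatter / (n - K)
    # shrink toward the diagonal; a zero within-class variance (possible in
    # degenerate training sets) is floored at the standardized total
    # variance 1 so that any lam > 0 yields a positive-definite matrix
    dvec = np.diag(pooled).copy()
    dvec[dvec <= 0] = 1.0
    cov = (1.0 - lam) * pooled + lam * np.diag(dvec)

    pri = _resolve_priors(priors, classes, counts, sequence)
    return LDAModel(
        classes=classes,
        means=means,
        pooled_cov=cov,
        priors=pri,
        center=center,
        scale=scale,
        lam=lam,
        n_per_class={c: counts[c] for c in classes},
        subset=subset,
        excluded_classes=excluded,
    )


def posterior(model: LDAModel, x: SpinSystem) -> ClassificationResult:
    """Amino-acid-type posteriors for a spin system complete for the model's subset."""
    missing = [f for f in model.subset.features if x.feature(f) is None]
    if missing:
        raise LDAError(
            f"spin system {x.id} lacks features {missing} for subset "
            f"{model.subset.name}; use posterior_auto for incomplete systems"
        )
    raw = np.array([x.feature(f) for f in model.subset.features], dtype=float)
    z = model.standardize(raw)
    sm = cho_solve(model._cho, model.means.T).T          # (K, d): S^-1 mu_k
    delta = sm @ z - 0.5 * np.sum(sm * model.means, axis=1) + np.log(model.priors)
    delta -= delta.max()
    p = np.exp(delta)
    p /= p.sum()
    post = dict(zip(model.classes, p))
    ranking = tuple(sorted(post, key=lambda c: (-post[c], c)))
    return ClassificationResult(
        posteriors=post,
        ranking=ranking,
        subset=model.subset,
        excluded_classes=dict(model.excluded_classes),
        low_information=len(model.subset.features) <= 1,
    )


class SubsetModelCache:
    """Lazily refit LDA models for reduced feature subsets.

    For each requested subset the model is refit on the training items
    complete for that subset, so incomplete query spin systems (e.g. only
    HN, N, CA observed) are classified by an exact LDA on their observed
    features.  Fits are cached per feature tuple; subsets leaving fewer
    than two trainable classes are marked unusable.
    """

    def __init__(
        self,
        train: Sequence[SpinSystem],
        base_subset: Union[str, FeatureSubset],
        priors: Union[str, Mapping[str, float]] = "uniform",
        lam: float = 0.05,
        min_class_size: int = 3,
        sequence: Optional[str] = None,
    ) -> None:
        self.train = list(train)
        self.base_subset = PRESETS[base_subset] if isinstance(base_subset, str) else base_subset
        self.priors = priors
        self.lam = lam
        self.min_class_size = min_class_size
        self.sequence = sequence
        self._models: dict[tuple[str, ...], Optional[LDAModel]] = {}

    def model_for(self, features: Sequence[str]) -> Optional[LDAModel]:
        key = tuple(features)
        if key not in self._models:
            usable = [s for s in self.train if complete_feature_set(s, key)]
            try:
                self._models[key] = fit(
                    usable,
                    FeatureSubset(name=f"{self.base_subset.name}|{len(key)}f", features=key),
                    priors=self.priors,
                    lam=self.lam,
                    min_class_size=self.min_class_size,
                    sequence=self.sequence,
                )
            except LDAError as exc:
                warnings.warn(f"subset {key} unusable: {exc}")
                self._models[key] = None
        return self._models[key]

    @property
    def full_model(self) -> Optional[LDAModel]:
        return self.model_for(self.base_subset.features)


def fit_subset_family(
    train: Sequence[SpinSystem],
    base_subset: Union[str, FeatureSubset],
    priors: Union[str, Mapping[str, float]] = "uniform",
    lam: float = 0.05,
    min_class_size: int = 3,
    sequence: Optional[str] = None,
) -> SubsetModelCache:
    """Build the on-demand cache of subset-refit models (see SubsetModelCache)."""
    return SubsetModelCache(train, base_subset, priors, lam, min_class_size, sequence)


def posterior_auto(cache: SubsetModelCache, x: SpinSystem) -> ClassificationResult:
    """Classify with the largest base-subset feature set present in ``x``."""
    available = x.features_present(cache.base_subset.features)
    if not available:
        raise LDAError(f"spin system {x.id} has no feature of the base subset")
    model = cache.model_for(available)
    if model is None:
        raise LDAError(f"no usable model for features {available}")
    result = posterior(model, x)
    result.low_information = len(available) <= 1
    return result


def fit_from_statistics(
    stats,
    subset: Union[str, FeatureSubset],
    priors: Union[str, Mapping[str, float]] = "uniform",
    sequence: Optional[str] = None,
) -> LDAModel:
    """Build an LDA model from a per-type mean/sd statistics table.

    Covariance is diagonal: each feature's variance is the squared sd
    averaged over classes (classes weighted equally).  Classes missing any
    subset feature are dropped with a warning.
    """
    subset = PRESETS[subset] if isinstance(subset, str) else subset
    classes_all = stats.types
    excluded: dict[str, str] = {}
    classes = []
    for c in classes_all:
        missing = [f for f in subset.features if not stats.has(c, f)]
        if missing:
            excluded[c] = f"missing statistics for {missing}"
        else:
            classes.append(c)
    if excluded:
        warnings.warn(f"dropping classes without full statistics: {sorted(excluded)}")
    if len(classes) < 2:
        raise LDAError("fewer than two classes have full statistics for the subset")
    classes = tuple(sorted(classes))
    raw_means = np.array(
        [[stats.get(c, f)[0] for f in subset.features] for c in classes]
    )
    raw_vars = np.array(
        [[stats.get(c, f)[1] ** 2 for f in subset.features] for c in classes]
    )
    var = raw_vars.mean(axis=0)
    center = raw_means.mean(axis=0)
    scale = np.sqrt(var)
    means = (raw_means - center) / scale
    cov = np.eye(len(subset.features))  # diagonal variances absorbed by the scale
    counts = {c: 1 for c in classes}
    pri = _resolve_priors(priors, classes, counts, sequence)
    return LDAModel(
        classes=classes,
        means=means,
        pooled_cov=cov,
        priors=pri,
        center=center,
        scale=scale,
        lam=0.0,
        n_per_class=counts,
        subset=subset,
        excluded_classes=excluded,
    )


def exclude_classes(obj, types: Sequence[str]):
    """Remove amino-acid types from a model or a training list.

    Typical use: drop glycines (assignment usually obvious from their N/CA
    shifts) and prolines (no amide proton, invisible in HN-rooted data).
    On a model, priors are renormalized; on a training list, systems of
    the listed types are filtered out.
    """
    types = set(types)
    if isinstance(obj, LDAModel):
        keep = [i for i, c in enumerate(obj.classes) if c not in types]
        if len(keep) < 2:
            raise LDAError("exclusion leaves fewer than two classes")
        if len(keep) == len(obj.classes):
            return obj
        pri = obj.priors[keep]
        return LDAModel(
            classes=tuple(obj.classes[i] for i in keep),
            means=obj.means[keep],
            pooled_cov=obj.pooled_cov,
            priors=pri / pri.sum(),
            center=obj.center,
            scale=obj.scale,
            lam=obj.lam,
            n_per_class={c: n for c, n in obj.n_per_class.items() if c not in types},
            subset=obj.subset,
            excluded_classes={**obj.excluded_classes, **{t: "excluded by user" for t in types}},
        )
    return [s for s in obj if s.res_type not in types]


def model_to_json(model: LDAModel) -> dict:
    return {
        "classes": list(model.classes),
        "means": model.means.tolist(),
        "pooled_cov": model.pooled_cov.tolist(),
        "priors": model.priors.tolist(),
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "lambda": model.lam,
        "n_per_class": model.n_per_class,
        "subset": {"name": model.subset.name, "features": list(model.subset.features)},
        "excluded_classes": model.excluded_classes,
    }


def model_from_json(data: Mapping) -> LDAModel:
    return LDAModel(
        classes=tuple(data["classes"]),
        means=np.array(data["means"], dtype=float),
        pooled_cov=np.array(data["pooled_cov"], dtype=float),
        priors=np.array(data["priors"], dtype=float),
        center=np.array(data["center"], dtype=float),
        scale=np.array(data["scale"], dtype=float),
        lam=float(data["lambda"]),
        n_per_class={k: int(v) for k, v in data["n_per_class"].items()},
        subset=FeatureSubset(data["subset"]["name"], tuple(data["subset"]["features"])),
        excluded_classes=dict(data.get("excluded_classes", {})),
    )


def save_model(model: LDAModel, path, provenance: Optional[Mapping] = None) -> None:
    payload = model_to_json(model)
    if provenance:
        payload["_provenance"] = dict(provenance)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> LDAModel:
    with open(path) as fh:
        return model_from_json(json.load(fh))
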