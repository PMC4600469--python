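"""Subject-level inference: leave-one-subject-out GP classification,
permutation significance, Bonferroni correction, discriminative weight maps
(g-maps), ordinal GP confusion matrices and supplementary univariate tests.

Cross-validation folds are whole participants: the classifier is trained on
every other subject's windowed samples and the held-out subject's windows
are aggregated into one posterior probability per condition (mean over
windows, thresholded at 0.5), so a 16-subject two-condition contrast yields
32 test items. Significance uses within-subject permutation of the two
condition labels — the exchangeable unit of the repeated-measures design —
with the add-one p estimator (1 + #{perm >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import CentralityFeatureSet
from .gp import GPClassification, GPClassificationResults, OrdinalGP

__all__ = [
    "ClassificationResult",
    "OrdinalResult",
    "GMap",
    "ContrastAnalysis",
    "ContrastResults",
    "loso_classify",
    "permutation_pvalue",
    "bonferroni_adjust",
    "compute_gmap",
    "orgp_fit_predict",
    "cross_model_confusion",
    "paired_node_ttests",
    "correlate_covariate",
]


@dataclass
class ClassificationResult:
    """LOSO outcome of one binary contrast."""

    contrast: tuple
    per_subject_probabilities: pd.DataFrame
    per_item_predictions: np.ndarray
    per_item_truth: np.ndarray
    accuracy: float
    n_test_items: int
    permutation_p: float | None = None
    n_perm: int | None = None
    fold_models: list = field(default_factory=list, repr=False)


@dataclass
class OrdinalResult:
    """LOSO outcome of one ordinal analysis over C rank-ordered conditions."""

    conditions: tuple
    thresholds: np.ndarray
    theta: float
    confusion_matrix: np.ndarray  # (C, C), rows true class, row-normalised
    counts: np.ndarray
    accuracy: float
    per_subject_probabilities: pd.DataFrame


@dataclass
class GMap:
    """Per-node discriminative weights with MNI centroids for export."""

    node_weights: np.ndarray
    node_labels: list[str]
    mni_centroids: np.ndarray | None = None
    contrast: tuple | None = None

    @property
    def radius(self) -> np.ndarray:
        """Sphere radius proportional to |weight| (max-normalised)."""
        aw = np.abs(self.node_weights)
        top = aw.max()
        return aw / top if top > 0 else aw

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "label": self.node_labels,
                "weight": self.node_weights,
                "sign": np.sign(self.node_weights).astype(int),
                "radius": self.radius,
            }
        )
        if self.mni_centroids is not None:
            df.insert(1, "mni_x", self.mni_centroids[:, 0])
            df.insert(2, "mni_y", self.mni_centroids[:, 1])
            df.insert(3, "mni_z", self.mni_centroids[:, 2])
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.8g")


def _check_two_class(fs: CentralityFeatureSet):
    labs = np.unique(fs.labels)
    if not np.array_equal(np.sort(labs), [-1, 1]):
        raise ValueError(f"feature set labels must be exactly -1/+1, got {labs}")


def _loso_folds(subject_ids):
    subjects = []
    for s in subject_ids:
        if s not in subjects:
            subjects.append(s)
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    return subjects


def _fit_gpc(X, y, theta=None, start_weights=None):
    return GPClassification(y, X).fit(theta=theta, start_weights=start_weights)


def loso_classify(
    fs: CentralityFeatureSet,
    theta_mode: str = "per_fold",
    keep_models: bool = True,
) -> ClassificationResult:
    """Leave-one-subject-out GP classification of a binary feature set.

    ``theta_mode`` — "per_fold": the kernel scale is re-optimised on every
    training fold (default); "shared": optimised once on the full data and
    held fixed across folds (used by the permutation engine, where the same
    scheme is applied to observed and permuted labels alike).

    Per fold, the held-out subject's window probabilities are averaged
    within each condition and thresholded at 0.5 (ties predict -1); accuracy
    is the fraction of correct subject x condition items.
    """
    _check_two_class(fs)
    if theta_mode not in ("per_fold", "shared"):
        raise ValueError(f"unknown theta_mode {theta_mode!r}")
    subjects = _loso_folds(fs.subject_ids)
    y = fs.labels.astype(int)
    X = fs.features

    shared_theta = None
    if theta_mode == "shared":
        shared_theta = _fit_gpc(X, y).theta

    rows = []
    preds, truths = [], []
    models = []
    for s in subjects:
        test = fs.subject_ids == s
        y_tr = y[~test]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"training fold without subject {s!r} lacks a class")
        res = _fit_gpc(X[~test], y_tr, theta=shared_theta)
        if keep_models:
            models.append(res)
        for lab in (1, -1):
            items = test & (y == lab)
            if not items.any():
                raise ValueError(
                    f"subject {s!r} has no samples with label {lab:+d}"
                )
            p = float(res.predict_prob(X[items]).mean())
            pred = 1 if p > 0.5 else -1
            cond = fs.conditions[items][0]
            rows.append(
                {
                    "subject_id": s,
                    "condition": cond,
                    "label": lab,
                    "probability": p,
                    "prediction": pred,
                }
            )
            preds.append(pred)
            truths.append(lab)
    preds = np.array(preds)
    truths = np.array(truths)
    acc = float(np.mean(preds == truths))
    return ClassificationResult(
        contrast=fs.contrast,
        per_subject_probabilities=pd.DataFrame(rows),
        per_item_predictions=preds,
        per_item_truth=truths,
        accuracy=acc,
        n_test_items=len(preds),
        fold_models=models,
    )


def _loso_accuracy_fast(X, y, subject_ids, subjects, theta, w0=None):
    """Accuracy-only LOSO pass with a fixed kernel scale (permutation path)."""
    correct = 0
    total = 0
    for s in subjects:
        test = subject_ids == s
        res = _fit_gpc(X[~test], y[~test], theta=theta, start_weights=w0)
        for lab in (1, -1):
            items = test & (y == lab)
            p = res.predict_prob(X[items]).mean()
            pred = 1 if p > 0.5 else -1
            correct += pred == lab
            total += 1
    return correct / total


def permutation_pvalue(
    fs: CentralityFeatureSet,
    true_accuracy: float | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    return_null: bool = False,
):
    """Permutation p-value for a LOSO classification accuracy.

    Labels are permuted within subject: each subject's two condition labels
    are swapped or not, independently and equiprobably. The full LOSO
    accuracy is recomputed for every permutation under the shared-theta
    scheme; the observed accuracy is computed the same way when
    ``true_accuracy`` is not supplied. p = (1 + #{perm >= true}) / (n_perm + 1).
    """
    _check_two_class(fs)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = _loso_folds(fs.subject_ids)
    X = fs.features
    y = fs.labels.astype(int)
    subj = fs.subject_ids

    if true_accuracy is None:
        true_accuracy = loso_classify(
            fs, theta_mode="shared", keep_models=False
        ).accuracy

    subj_index = {s: i for i, s in enumerate(subjects)}
    subj_codes = np.array([subj_index[s] for s in subj])
    null = np.empty(n_perm)
    for i in range(n_perm):
        flips = np.where(rng.random(len(subjects)) < 0.5, -1, 1)
        y_perm = y * flips[subj_codes]
        full = _fit_gpc(X, y_perm)
        null[i] = _loso_accuracy_fast(
            X, y_perm, subj, subjects, full.theta, w0=full.weights
        )
    p = (1.0 + np.sum(null >= true_accuracy - 1e-12)) / (n_perm + 1.0)
    if return_null:
        return float(p), null
    return float(p)


def bonferroni_adjust(p_values, family_size: int | None = None):
    """Bonferroni correction: adjusted p = min(1, p * family); significant
    when the adjusted value is <= 0.05."""
    p_values = np.asarray(p_values, dtype=float)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p_values) if family_size is None else int(family_size)
    if m < len(p_values):
        raise ValueError(
            f"family size {m} smaller than number of p-values {len(p_values)}"
        )
    adjusted = np.minimum(1.0, p_values * m)
    return adjusted, adjusted <= 0.05


def compute_gmap(
    models: list[GPClassificationResults],
    node_labels,
    mni_centroids=None,
    contrast=None,
) -> GMap:
    """Discriminative weight map from per-fold linear-kernel GPC models.

    Each fold's weight vector w = theta X^T alpha (dual coefficients times
    training samples) reproduces that fold's latent mean exactly; the g-map
    is the mean of the fold weight vectors. Positive weights mark nodes whose
    weighted-average density-normalised DC is higher in the +1 class.
    """
    if not models:
        raise ValueError("need at least one fold model")
    node_labels = list(node_labels)
    ws = []
    for m in models:
        if not isinstance(m, GPClassificationResults):
            raise ValueError(
                "g-maps are defined only for linear-kernel GPC fold models"
            )
        if len(m.weights) != len(node_labels):
            raise ValueError("model weight length does not match node count")
        ws.append(m.weights)
    mean_w = np.mean(ws, axis=0)
    cent = None
    if mni_centroids is not None:
        cent = np.asarray(mni_centroids, dtype=float)
        if cent.shape != (len(node_labels), 3):
            raise ValueError("mni_centroids must be (n_nodes, 3)")
    return GMap(
        node_weights=mean_w,
        node_labels=node_labels,
        mni_centroids=cent,
        contrast=contrast,
    )


def orgp_fit_predict(
    fs: CentralityFeatureSet,
    optimize_hyperparams: bool = True,
    maxfev: int = 200,
) -> OrdinalResult:
    """LOSO ordinal GP over a rank-ordered multi-class feature set.

    Per fold an ordinal GP is fitted to all other subjects' samples
    (thresholds and kernel scale optimised on the training fold); the
    held-out subject's class-probability vectors are averaged over windows
    within each condition and the arg-max taken. Returns the row-normalised
    C x C confusion matrix.
    """
    if fs.class_index is None:
        raise ValueError(
            "ordinal analysis needs a feature set with class_index "
            "(see assemble_ordinal_features)"
        )
    y = fs.class_index.astype(int)
    C = int(y.max() + 1)
    if C < 2:
        raise ValueError("need at least 2 ordered classes")
    subjects = _loso_folds(fs.subject_ids)
    X = fs.features

    counts = np.zeros((C, C))
    rows = []
    thetas, cut_list = [], []
    for s in subjects:
        test = fs.subject_ids == s
        if np.unique(y[~test]).size < C:
            raise ValueError(f"training fold without subject {s!r} lacks a class")
        res = OrdinalGP(y[~test], X[~test], n_classes=C).fit(
            optimize_hyperparams=optimize_hyperparams, maxfev=maxfev
        )
        thetas.append(res.theta)
        cut_list.append(res.thresholds)
        for c in range(C):
            items = test & (y == c)
            if not items.any():
                raise ValueError(f"subject {s!r} has no class-{c} samples")
            probs = res.predict_class_prob(X[items]).mean(axis=0)
            pred = int(np.argmax(probs))
            counts[c, pred] += 1
            rows.append(
                {
                    "subject_id": s,
                    "condition": fs.conditions[items][0],
                    "true_class": c,
                    "predicted_class": pred,
                    **{f"p_class_{j}": probs[j] for j in range(C)},
                }
            )
    confusion = counts / counts.sum(axis=1, keepdims=True)
    acc = float(np.trace(counts) / counts.sum())
    return OrdinalResult(
        conditions=fs.contrast if fs.contrast else tuple(range(C)),
        thresholds=np.mean(cut_list, axis=0),
        theta=float(np.mean(thetas)),
        confusion_matrix=confusion,
        counts=counts,
        accuracy=acc,
        per_subject_probabilities=pd.DataFrame(rows),
    )


def cross_model_confusion(
    train_fs: CentralityFeatureSet,
    test_fs: CentralityFeatureSet,
    theta_mode: str = "per_fold",
) -> pd.DataFrame:
    """Assign a held-out third condition to the two classes of a trained
    contrast.

    For each LOSO fold of the (a, b) training contrast, the held-out
    subject's ``test_fs`` samples (a condition outside the contrast, centred
    in the same subject-referenced space) are averaged into one posterior
    probability and assigned to class a (p > 0.5) or class b. Returns the
    per-class assignment proportions plus per-subject probabilities.
    """
    _check_two_class(train_fs)
    cond_a, cond_b = train_fs.contrast
    test_conditions = set(np.unique(test_fs.conditions))
    if test_conditions & {cond_a, cond_b}:
        raise ValueError(
            f"test condition(s) {sorted(test_conditions)} overlap the "
            f"training contrast {train_fs.contrast}"
        )
    if test_fs.features.shape[1] != train_fs.features.shape[1]:
        raise ValueError("train and test feature dimensions differ")
    subjects = _loso_folds(train_fs.subject_ids)
    y = train_fs.labels.astype(int)
    X = train_fs.features
    shared_theta = None
    if theta_mode == "shared":
        shared_theta = _fit_gpc(X, y).theta

    rows = []
    for s in subjects:
        tr = train_fs.subject_ids != s
        te = test_fs.subject_ids == s
        if not te.any():
            raise ValueError(f"subject {s!r} has no test-condition samples")
        res = _fit_gpc(X[tr], y[tr], theta=shared_theta)
        p = float(res.predict_prob(test_fs.features[te]).mean())
        rows.append(
            {
                "subject_id": s,
                "probability_class_a": p,
                "assigned": cond_a if p > 0.5 else cond_b,
            }
        )
    df = pd.DataFrame(rows)
    frac_a = float(np.mean(df["assigned"] == cond_a))
    df.attrs["proportions"] = {cond_a: frac_a, cond_b: 1.0 - frac_a}
    return df


def paired_node_ttests(dc_a, dc_b, node_labels=None) -> pd.DataFrame:
    """Per-node paired t-tests on subject-mean DC values.

    ``dc_a`` and ``dc_b`` are subjects x nodes matrices of per-subject mean
    (density-normalised) DC for the two conditions, matched by row. The test
    is a one-sample t on the per-subject deltas, two-sided, uncorrected;
    ``significant`` flags p < 0.05. Zero-variance nonzero deltas are flagged
    degenerate with t = +/-inf and p = 0 rather than silently dropped.
    """
    a = np.asarray(dc_a, dtype=float)
    b = np.asarray(dc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dc_a and dc_b must have matching shapes")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    delta = a - b
    n = delta.shape[0]
    mean = delta.mean(axis=0)
    sd = delta.std(axis=0, ddof=1)
    t = np.zeros(delta.shape[1])
    p = np.ones(delta.shape[1])
    zero_sd = sd == 0
    degenerate = zero_sd & (mean != 0)
    ok = ~zero_sd
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    t[degenerate] = np.sign(mean[degenerate]) * np.inf
    p[degenerate] = 0.0
    if node_labels is None:
        node_labels = [f"node_{i}" for i in range(delta.shape[1])]
    return pd.DataFrame(
        {
            "label": list(node_labels),
            "delta": mean,
            "t": t,
            "p": p,
            "significant": p < 0.05,
            "degenerate": degenerate,
        }
    )


def correlate_covariate(per_subject_probabilities, covariate):
    """Pearson correlation between per-subject posterior probabilities and a
    subject covariate (e.g. drug plasma concentration)."""
    x = np.asarray(per_subject_probabilities, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if x.shape != c.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(c) == 0:
        raise ValueError("covariate is constant")
    r, p = stats.pearsonr(x, c)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Model/Results wrapper around one binary contrast
# ---------------------------------------------------------------------------


class ContrastAnalysis:
    """LOSO classification analysis of one binary condition contrast.

    Statsmodels-style: built from a :class:`CentralityFeatureSet`, ``fit()``
    runs the leave-one-subject-out classification and returns a
    :class:`ContrastResults` carrying accuracy, per-subject posterior
    probabilities, fold models and follow-up methods (permutation test,
    g-map, summary).
    """

    def __init__(self, features: CentralityFeatureSet):
        _check_two_class(features)
        self.features = features

    def fit(self, theta_mode: str = "per_fold") -> "ContrastResults":
        res = loso_classify(self.features, theta_mode=theta_mode)
        return ContrastResults(self, res)


class ContrastResults:
    def __init__(self, model: ContrastAnalysis, result: ClassificationResult):
        self.model = model
        self.result = result

    @property
    def accuracy(self) -> float:
        return self.result.accuracy

    @property
    def per_subject_probabilities(self) -> pd.DataFrame:
        return self.result.per_subject_probabilities

    def permutation_test(self, n_perm: int = 1000, seed: int | None = None):
        p = permutation_pvalue(self.model.features, n_perm=n_perm, seed=seed)
        self.result.permutation_p = p
        self.result.n_perm = n_perm
        return p

    def gmap(self, node_labels=None, mni_centroids=None) -> GMap:
        labels = (
            node_labels
            if node_labels is not None
            else self.model.features.node_labels
        )
        return compute_gmap(
            self.result.fold_models,
            labels,
            mni_centroids=mni_centroids,
            contrast=self.result.contrast,
        )

    def summary(self) -> str:
        r = self.result
        lines = [
            f"LOSO GP classification: {r.contrast[0]} (+1) vs {r.contrast[1]} (-1)",
            f"  subjects            : {r.n_test_items // 2}",
            f"  test items          : {r.n_test_items}",
            f"  accuracy            : {100 * r.accuracy:.2f} %",
        ]
        if r.permutation_p is not None:
            lines.append(
                f"  permutation p       : {r.permutation_p:.4g} "
                f"({r.n_perm} permutations)"
            )
        return "\n".join(lines)
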