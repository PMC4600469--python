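"""Reference validation scenarios for the full-size analysis pipeline.

These functions re-run the package end to end under the emulated study
geometry (16 subjects, 116 nodes, 150 volumes per condition, TR = 2 s,
eight windows) and measure recovery of planted effects, calibration under
the null, weight-map fidelity and agreement of the core numerical routines
with independent brute-force oracles. They are shared by the test suite and
the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from .features import (
    assemble_features,
    assemble_ordinal_features,
    degree_centrality,
    weighted_correlation_matrix,
)
from .gp import GPClassification
from .inference import (
    compute_gmap,
    loso_classify,
    orgp_fit_predict,
    permutation_pvalue,
)
from .pipeline import _preprocess_runs, compute_dc_map
from .synthetic import CohortConfig, generate_cohort, planted_dc_delta

STUDY_GEOMETRY = dict(n_subjects=16, n_nodes=116, n_volumes=150)


def build_contrast_features(
    effect_size: float,
    seed: int,
    conditions=("saline", "ketamine"),
    condition_effects=None,
    **config_overrides,
):
    """Generate, preprocess and window one two-condition cohort; return the
    assembled (ketamine = +1) feature set plus ground truth."""
    cfg = CohortConfig(
        conditions=conditions,
        condition_effects=(
            condition_effects
            if condition_effects is not None
            else {"ketamine": 1.0}
        ),
        effect_size=effect_size,
        seed=seed,
        **{**STUDY_GEOMETRY, **config_overrides},
    )
    cohort, truth = generate_cohort(cfg)
    runs = _preprocess_runs(cohort.runs, cohort.nuisance, 0.01, 0.1)
    dc_map = compute_dc_map(runs)
    fs = assemble_features(dc_map, conditions[1], conditions[0],
                           truth.node_labels)
    return fs, truth, dc_map


def null_calibration(n_seeds: int = 50, n_perm: int = 99, base_seed: int = 0):
    """Accuracy and permutation-p behaviour with no planted effect.

    Returns per-seed LOSO accuracies and permutation p-values (shared-theta
    scheme applied identically to observed and permuted labels).
    """
    accuracies = np.empty(n_seeds)
    pvalues = np.empty(n_seeds)
    for i in range(n_seeds):
        seed = base_seed + i
        fs, *_ = build_contrast_features(0.0, seed)
        acc = loso_classify(fs, theta_mode="shared", keep_models=False).accuracy
        accuracies[i] = acc
        pvalues[i] = permutation_pvalue(
            fs, true_accuracy=acc, n_perm=n_perm, seed=seed + 1_000_000
        )
    return {
        "accuracies": accuracies,
        "pvalues": pvalues,
        "mean_accuracy": float(accuracies.mean()),
        "frac_p_le_05": float(np.mean(pvalues <= 0.05)),
    }


def effect_recovery_curve(
    deltas=(0.0, 0.5, 1.0, 2.0), n_seeds: int = 20, base_seed: int = 100
):
    """Mean LOSO accuracy (shared-theta) as a function of planted effect size."""
    means = {}
    for delta in deltas:
        accs = []
        for i in range(n_seeds):
            fs, *_ = build_contrast_features(delta, base_seed + i)
            accs.append(
                loso_classify(fs, theta_mode="shared",
                              keep_models=False).accuracy
            )
        means[delta] = float(np.mean(accs))
    return means


def strong_effect_accuracy(seed: int = 0, effect_size: float = 2.0) -> float:
    """Headline LOSO accuracy with per-fold hyperparameter optimisation."""
    fs, *_ = build_contrast_features(effect_size, seed)
    return loso_classify(fs, keep_models=False).accuracy


def gmap_recovery(seed: int = 0, effect_size: float = 2.0, top_k: int = 20):
    """Weight-map fidelity against planted per-node centrality changes.

    Returns (sign agreement on the top_k strongest ground-truth nodes,
    maximum |w_ab + w_ba| under exact label swap).
    """
    fs, truth, dc_map = build_contrast_features(effect_size, seed)
    res = loso_classify(fs, theta_mode="shared")
    gm = compute_gmap(res.fold_models, truth.node_labels)
    dd = planted_dc_delta(truth, "ketamine")
    top = np.argsort(-np.abs(dd))[:top_k]
    agreement = float(
        np.mean(np.sign(gm.node_weights[top]) == np.sign(dd[top]))
    )

    fs_swapped = assemble_features(
        dc_map, "saline", "ketamine", truth.node_labels
    )
    res_sw = loso_classify(fs_swapped, theta_mode="shared")
    gm_sw = compute_gmap(res_sw.fold_models, truth.node_labels)
    scale = np.abs(gm.node_weights).max()
    antisym = float(np.abs(gm.node_weights + gm_sw.node_weights).max() / scale)
    return agreement, antisym


def _ordinal_confusion(condition_effects, seed, effect_size):
    cfg = CohortConfig(
        conditions=("saline", "mid", "high"),
        condition_effects=condition_effects,
        effect_size=effect_size,
        seed=seed,
        **STUDY_GEOMETRY,
    )
    cohort, truth = generate_cohort(cfg)
    runs = _preprocess_runs(cohort.runs, cohort.nuisance, 0.01, 0.1)
    dc_map = compute_dc_map(runs)
    fs = assemble_ordinal_features(
        dc_map, ["saline", "mid", "high"], truth.node_labels
    )
    return orgp_fit_predict(fs).confusion_matrix


def ordinal_graded_confusion(seed: int = 0, effect_size: float = 2.0):
    """Three rank-ordered classes with a graded planted effect (0, d, 2d)."""
    return _ordinal_confusion({"mid": 0.5, "high": 1.0}, seed, effect_size)


def ordinal_nonintermediate_confusion(seeds=(0, 1, 2), effect_size: float = 2.0):
    """Middle class drawn from the same distribution as the upper extreme
    (no intermediate structure); mean confusion over the given seeds."""
    cms = [
        _ordinal_confusion({"mid": 1.0, "high": 1.0}, s, effect_size)
        for s in seeds
    ]
    return np.mean(cms, axis=0)


# ---------------------------------------------------------------------------
# Independent oracles for the numerical core
# ---------------------------------------------------------------------------

#: Frozen non-separable toys for the Laplace-vs-quadrature comparison.
GPC_ORACLE_TOYS = (
    (
        np.array([-2.0, -1.0, 0.3, -0.4, 1.0, 2.0]),
        np.array([-1, -1, -1, 1, 1, 1]),
        0.05,
    ),
    (
        np.array([-1.5, -0.8, 0.6, -0.2, 0.9, 1.7, 0.1, -1.1]),
        np.array([-1, -1, -1, 1, 1, 1, -1, 1]),
        0.1,
    ),
)
GPC_ORACLE_TEST_POINTS = (-1.5, -0.5, 0.0, 0.7, 1.8)


def quadrature_predictive(x, y, theta, x_star, half_width=25.0, n=100001):
    """Dense numeric integration of the probit predictive over the scalar
    weight posterior of the 1-D linear-kernel model (independent oracle)."""
    w = np.linspace(-half_width, half_width, n)
    with np.errstate(divide="ignore"):
        logpost = -0.5 * w**2 / theta + np.sum(
            np.log(ndtr(y[:, None] * np.outer(x, w))), axis=0
        )
    post = np.exp(logpost - logpost.max())
    post /= np.trapezoid(post, w)
    return float(np.trapezoid(ndtr(w * x_star) * post, w))


def laplace_oracle_error() -> float:
    """Max |Laplace - quadrature| predictive probability over frozen toys."""
    worst = 0.0
    for x, y, theta in GPC_ORACLE_TOYS:
        res = GPClassification(y, x[:, None]).fit(theta=theta)
        for xs in GPC_ORACLE_TEST_POINTS:
            lap = float(res.predict_prob(np.array([[xs]]))[0])
            ora = quadrature_predictive(x, y, theta, xs)
            worst = max(worst, abs(lap - ora))
    return worst


def primitive_oracle_errors(seed: int = 0) -> dict:
    """Brute-force agreement of DC, weighted correlation and nuisance
    regression on random small instances."""
    rng = np.random.default_rng(seed)

    A = rng.standard_normal((10, 10))
    A = 0.5 * (A + A.T)
    dc = degree_centrality(A)
    dc_brute = np.array(
        [sum(A[i, j] for j in range(10) if j != i) for i in range(10)]
    )
    dc_err = float(np.abs(dc - dc_brute).max())

    seg = rng.standard_normal((30, 5))
    w = rng.uniform(0.1, 1.0, 30)
    C = weighted_correlation_matrix(seg, w)
    mean = (w @ seg) / w.sum()
    cen = seg - mean
    cov = (cen * w[:, None]).T @ cen / w.sum()
    sd = np.sqrt(np.diag(cov))
    C_brute = cov / np.outer(sd, sd)
    corr_err = float(np.abs(C - C_brute).max())

    from .preprocess import NuisanceTable, ParcellatedTimeSeries, regress_nuisance

    X = rng.standard_normal((50, 3))
    R = rng.standard_normal((50, 2))
    ts = ParcellatedTimeSeries(
        data=X, tr=2.0, node_labels=["a", "b", "c"]
    )
    out = regress_nuisance(ts, NuisanceTable(regressors=R))
    D = np.column_stack([np.ones(50), R])
    beta = np.linalg.solve(D.T @ D, D.T @ X)
    reg_err = float(np.abs(out.data - (X - D @ beta)).max())

    return {
        "dc_bruteforce_max_abs_err": dc_err,
        "weighted_corr_oracle_max_abs_err": corr_err,
        "nuisance_regression_oracle_max_abs_err": reg_err,
    }
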