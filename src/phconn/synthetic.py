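"""Synthetic multi-subject phMRI-like cohort with planted connectivity effects.

The generator emulates a repeated-measures pharmacological fMRI design:
16 subjects, eight drug conditions, 150 volumes per condition at TR = 2 s and
116 parcellated nodes. Each condition's node series is an AR(1)-coloured
multivariate normal draw whose covariance is a subject-perturbed version of a
condition covariance. "Active" (drug-like) conditions shift the covariance by
attenuating inter-cortical couplings and amplifying couplings among
subcortical and cerebellar nodes, reproducing the qualitative cortical-to-
subcortical shift the analysis is designed to detect, with known per-node
ground-truth centrality changes. Drift, nuisance signals and white noise are
added on top so the preprocessing stages have work to do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import degree_centrality, density_normalize
from .nodes import (
    CEREBELLAR,
    CORTICAL,
    SUBCORTICAL,
    load_node_fixture,
    node_roles,
)
from .preprocess import (
    NuisanceTable,
    ParcellatedTimeSeries,
    write_nuisance_tsv,
    write_timeseries_tsv,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "build_condition_covariance",
    "generate_cohort",
    "planted_dc_delta",
    "write_cohort",
]

#: Table-1 style condition vocabulary (pre/post infusion of each session).
DEFAULT_CONDITIONS = (
    "placebo_pre_sal",
    "placebo_pre_ket",
    "risperidone",
    "lamotrigine",
    "saline",
    "ketamine",
    "ris_ketamine",
    "lam_ketamine",
)

#: Per-condition multiplier on the planted effect size. The NMDAR-blockade
#: shift is fully expressed after ketamine, unchanged by lamotrigine
#: pre-treatment and strongly attenuated by risperidone pre-treatment.
DEFAULT_CONDITION_EFFECTS = {
    "ketamine": 1.0,
    "lam_ketamine": 1.0,
    "ris_ketamine": 0.4,
}

# Fractional coupling change per unit of planted effect delta.
_COUPLING_SHIFT = 0.25
# Eigenvalue floor for SPD repair, relative to the largest eigenvalue.
_SPD_FLOOR = 1e-6

_ROLES = (CORTICAL, SUBCORTICAL, CEREBELLAR)


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated design: 16 subjects, 116 nodes, 150 volumes
    per condition at TR = 2 s, and the eight-condition vocabulary.
    """

    n_subjects: int = 16
    n_nodes: int = 116
    n_volumes: int = 150
    tr: float = 2.0
    conditions: tuple = DEFAULT_CONDITIONS
    condition_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_EFFECTS)
    )
    condition_pattern: dict = field(default_factory=dict)
    effect_size: float = 1.0
    subject_sd: float = 0.1
    ar_coeff: float = 0.4
    nuisance_amp: float = 1.0
    drift_amp: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0
    node_labels: tuple | None = None

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_nodes", "n_volumes"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 2):
                raise ValueError(f"{name} must be an integer >= 2, got {v!r}")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError(f"ar_coeff must be in [0, 1), got {self.ar_coeff}")
        if self.effect_size < 0:
            raise ValueError(
                f"effect_size must be >= 0, got {self.effect_size}"
            )
        for name in ("subject_sd", "nuisance_amp", "drift_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        self.conditions = tuple(self.conditions)
        if len(self.conditions) < 2:
            raise ValueError("conditions must list at least two labels")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions contains duplicates")
        unknown = set(self.condition_effects) - set(self.conditions)
        # Effects for conditions not generated are simply ignored so the
        # default mapping can be used with a reduced condition list.
        for k in unknown:
            self.condition_effects = {
                c: m for c, m in self.condition_effects.items()
                if c in self.conditions
            }
            break
        for cond, pat in self.condition_pattern.items():
            if pat not in ("shift", "distinct", "opposing", "mixture"):
                raise ValueError(
                    f"condition_pattern[{cond!r}] must be one of 'shift', "
                    f"'distinct', 'opposing', 'mixture'; got {pat!r}"
                )
        if self.node_labels is not None:
            self.node_labels = tuple(str(l) for l in self.node_labels)
            if len(self.node_labels) != self.n_nodes:
                raise ValueError(
                    "node_labels length must equal n_nodes "
                    f"({len(self.node_labels)} != {self.n_nodes})"
                )


@dataclass
class GroundTruth:
    """Generating structure of a synthetic cohort.

    ``dc_delta`` maps each condition to the expected change of every node's
    density-normalised degree centrality relative to baseline, computed from
    the generating correlation matrices with the same centrality rules the
    analysis applies.
    """

    baseline_cov: np.ndarray
    condition_cov: dict
    node_roles: list[str]
    node_labels: list[str]
    dc_delta: dict
    effect_size: float

    def __post_init__(self) -> None:
        for name, mat in [("baseline_cov", self.baseline_cov)] + [
            (f"condition_cov[{c!r}]", m) for c, m in self.condition_cov.items()
        ]:
            mat = np.asarray(mat)
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")
            if np.linalg.eigvalsh(mat)[0] <= 0:
                raise ValueError(f"{name} is not positive definite")
        for role in self.node_roles:
            if role not in _ROLES:
                raise ValueError(f"unknown node role {role!r}")


@dataclass
class Cohort:
    """Generated runs plus their nuisance tables, keyed by (subject, condition)."""

    runs: list
    nuisance: dict
    config: CohortConfig

    def get(self, subject_id: str, condition: str) -> ParcellatedTimeSeries:
        for ts in self.runs:
            if ts.subject_id == subject_id and ts.condition == condition:
                return ts
        raise KeyError((subject_id, condition))

    @property
    def subjects(self) -> list[str]:
        seen: dict = {}
        for ts in self.runs:
            seen.setdefault(ts.subject_id, None)
        return list(seen)


def _corr_from_cov(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _normalized_dc(corr: np.ndarray) -> np.ndarray:
    adj = corr.copy()
    np.fill_diagonal(adj, 0.0)
    return density_normalize(degree_centrality(adj), adj)


def _spd_repair(mat: np.ndarray) -> np.ndarray:
    """Floor eigenvalues at a small fraction of the largest one if needed."""
    vals, vecs = np.linalg.eigh(mat)
    floor = _SPD_FLOOR * vals[-1]
    if vals[0] > floor:
        return mat
    vals = np.maximum(vals, floor)
    out = (vecs * vals) @ vecs.T
    return 0.5 * (out + out.T)


def build_condition_covariance(
    baseline_cov: np.ndarray, roles, delta: float, invert: bool = False
) -> np.ndarray:
    """Shift a baseline covariance toward the planted drug-condition pattern.

    Off-diagonal couplings between two cortical nodes are attenuated by a
    factor ``1 - 0.25*delta`` (floored just above zero); couplings between
    two non-cortical (subcortical or cerebellar) nodes are amplified by
    ``1 + 0.25*delta``; cortical-to-noncortical couplings and all variances
    are untouched. ``invert=True`` swaps the attenuated and amplified blocks,
    producing a shift opposing the canonical pattern. The result is projected
    back to the SPD cone by eigenvalue flooring when the scaling breaks
    positive definiteness.
    """
    baseline_cov = np.asarray(baseline_cov, dtype=float)
    if baseline_cov.ndim != 2 or baseline_cov.shape[0] != baseline_cov.shape[1]:
        raise ValueError("baseline_cov must be square")
    if not np.allclose(baseline_cov, baseline_cov.T, atol=1e-10):
        raise ValueError("baseline_cov must be symmetric")
    if np.linalg.eigvalsh(baseline_cov)[0] <= 0:
        raise ValueError("baseline_cov must be positive definite")
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    roles = list(roles)
    if len(roles) != baseline_cov.shape[0]:
        raise ValueError("one role per node required")
    for role in roles:
        if role not in _ROLES:
            raise ValueError(f"unknown role label {role!r}")
    if delta == 0:
        return baseline_cov.copy()

    cortical = np.array([r == CORTICAL for r in roles])
    atten = max(1.0 - _COUPLING_SHIFT * delta, 0.02)
    amp = 1.0 + _COUPLING_SHIFT * delta
    if invert:
        atten, amp = amp, max(1.0 - _COUPLING_SHIFT * delta, 0.02)
    factor = np.ones_like(baseline_cov)
    factor[np.ix_(cortical, cortical)] = atten
    factor[np.ix_(~cortical, ~cortical)] = amp
    np.fill_diagonal(factor, 1.0)
    return _spd_repair(baseline_cov * factor)


def _baseline_covariance(rng: np.random.Generator, roles) -> np.ndarray:
    """Factor-model correlation matrix: one global factor shared by all nodes
    plus one factor per role, uniqueness chosen for unit variances."""
    n = len(roles)
    u = rng.uniform(0.35, 0.65, size=n)
    cov = np.outer(u, u)
    for role in _ROLES:
        mask = np.array([r == role for r in roles], dtype=float)
        v = rng.uniform(0.2, 0.5, size=n) * mask
        cov += np.outer(v, v)
    np.fill_diagonal(cov, 1.0)
    return _spd_repair(cov)


def _default_labels_roles(config: CohortConfig):
    if config.node_labels is not None:
        labels = list(config.node_labels)
        return labels, node_roles(labels)
    if config.n_nodes == 116:
        fixture = load_node_fixture()
        return list(fixture["label"]), list(fixture["role"])
    # Reduced-size cohorts keep the AAL role proportions (78/12/26 of 116).
    n = config.n_nodes
    n_sub = max(1, round(n * 12 / 116))
    n_cer = max(1, round(n * 26 / 116))
    n_cor = n - n_sub - n_cer
    labels, roles = [], []
    for role, count, stem in (
        (CORTICAL, n_cor, "CorticalNode"),
        (SUBCORTICAL, n_sub, "Thalamus_Syn"),
        (CEREBELLAR, n_cer, "Cerebelum_Syn"),
    ):
        for i in range(count):
            labels.append(f"{stem}_{i + 1:03d}")
            roles.append(role)
    return labels, roles


def _ar1_mvn(
    rng: np.random.Generator, chol: np.ndarray, n_volumes: int, phi: float
) -> np.ndarray:
    """AR(1)-coloured draw with stationary covariance chol @ chol.T."""
    innov = rng.standard_normal((n_volumes, chol.shape[0])) @ chol.T
    out = np.empty_like(innov)
    out[0] = innov[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, n_volumes):
        out[t] = phi * out[t - 1] + scale * innov[t]
    return out


def _nuisance_signals(
    rng: np.random.Generator, n_volumes: int
) -> NuisanceTable:
    """Eight smooth nuisance series: six motion-like plus CSF and WM means."""
    names = [f"motion_{i + 1}" for i in range(6)] + ["csf_mean", "wm_mean"]
    phi = 0.9
    innov = rng.standard_normal((n_volumes, len(names)))
    sig = np.empty_like(innov)
    sig[0] = innov[0]
    for t in range(1, n_volumes):
        sig[t] = phi * sig[t - 1] + np.sqrt(1 - phi**2) * innov[t]
    sig = (sig - sig.mean(axis=0)) / sig.std(axis=0)
    return NuisanceTable(regressors=sig, names=names)


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Generate every subject x condition run plus the generating truth.

    Deterministic: the same config (including seed) reproduces the cohort
    bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    labels, roles = _default_labels_roles(config)
    baseline = _baseline_covariance(rng, roles)

    condition_cov = {}
    for cond in config.conditions:
        delta = config.effect_size * config.condition_effects.get(cond, 0.0)
        cond_roles = roles
        pat = config.condition_pattern.get(cond, "shift")
        if pat == "distinct":
            # A drug state off the ordinal axis: the same coupling shift
            # applied to a randomly permuted role assignment, giving a
            # recoverable pattern unrelated to the cortical/subcortical one.
            cond_roles = [roles[i] for i in rng.permutation(len(roles))]
        condition_cov[cond] = build_condition_covariance(
            baseline, cond_roles, delta, invert=(pat == "opposing")
        )

    base_dc = _normalized_dc(_corr_from_cov(baseline))
    dc_delta = {
        cond: _normalized_dc(_corr_from_cov(cov)) - base_dc
        for cond, cov in condition_cov.items()
    }
    truth = GroundTruth(
        baseline_cov=baseline,
        condition_cov=condition_cov,
        node_roles=roles,
        node_labels=labels,
        dc_delta=dc_delta,
        effect_size=config.effect_size,
    )

    n = config.n_nodes
    subject_tf = [
        np.eye(n) + (config.subject_sd / np.sqrt(n)) * rng.standard_normal((n, n))
        for _ in range(config.n_subjects)
    ]
    # "mixture" conditions have no location of their own: each subject's run
    # is drawn from the baseline or the fully shifted covariance at random,
    # so no latent direction orders the class between the extremes.
    mixture_flags = {
        cond: rng.random(config.n_subjects) < 0.5
        for cond in config.conditions
        if config.condition_pattern.get(cond) == "mixture"
    }

    runs: list[ParcellatedTimeSeries] = []
    nuisance: dict = {}
    t_ax = np.arange(config.n_volumes) / config.n_volumes
    for s in range(config.n_subjects):
        subject_id = f"sub-{s + 1:02d}"
        for cond in config.conditions:
            cond_c = condition_cov[cond]
            if cond in mixture_flags and not mixture_flags[cond][s]:
                cond_c = baseline
            cov = subject_tf[s] @ cond_c @ subject_tf[s].T
            chol = np.linalg.cholesky(_spd_repair(cov))
            data = _ar1_mvn(rng, chol, config.n_volumes, config.ar_coeff)

            nuis = _nuisance_signals(rng, config.n_volumes)
            loading = rng.standard_normal((nuis.regressors.shape[1], n))
            data = data + config.nuisance_amp * (
                nuis.regressors @ loading
            ) / np.sqrt(loading.shape[0])

            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            drift = np.outer(2.0 * (t_ax - 0.5), a) + np.outer(
                np.cos(np.pi * t_ax), b
            )
            data = data + config.drift_amp * drift
            data = data + config.noise_sd * rng.standard_normal(data.shape)

            runs.append(
                ParcellatedTimeSeries(
                    data=data,
                    tr=config.tr,
                    node_labels=labels,
                    subject_id=subject_id,
                    condition=cond,
                )
            )
            nuisance[(subject_id, cond)] = nuis
    return Cohort(runs=runs, nuisance=nuisance, config=config), truth


def planted_dc_delta(truth: GroundTruth, condition: str) -> np.ndarray:
    """Expected per-node change in density-normalised degree centrality for
    ``condition`` relative to baseline, from the generating correlations."""
    if condition not in truth.dc_delta:
        raise KeyError(
            f"condition {condition!r} not in ground truth "
            f"({sorted(truth.dc_delta)})"
        )
    return np.asarray(truth.dc_delta[condition]).copy()


def write_cohort(cohort: Cohort, truth: GroundTruth, outdir) -> Path:
    """Write one TSV per run plus nuisance tables, a JSON manifest and a
    ground-truth summary. Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for ts in cohort.runs:
        stem = f"{ts.subject_id}_{ts.condition}"
        ts_file = f"{stem}.tsv"
        nuis_file = f"{stem}_nuisance.tsv"
        write_timeseries_tsv(ts, outdir / ts_file)
        write_nuisance_tsv(cohort.nuisance[(ts.subject_id, ts.condition)],
                           outdir / nuis_file)
        entries.append(
            {
                "subject": ts.subject_id,
                "condition": ts.condition,
                "file": ts_file,
                "nuisance_file": nuis_file,
                "tr": ts.tr,
            }
        )
    manifest = {
        "seed": cohort.config.seed,
        "n_subjects": cohort.config.n_subjects,
        "n_nodes": cohort.config.n_nodes,
        "n_volumes": cohort.config.n_volumes,
        "conditions": list(cohort.config.conditions),
        "runs": entries,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    gt = {
        "node_labels": truth.node_labels,
        "node_roles": truth.node_roles,
        "effect_size": truth.effect_size,
        "dc_delta": {c: list(map(float, v)) for c, v in truth.dc_delta.items()},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return manifest_path


def write_phantom_nifti(
    ts: ParcellatedTimeSeries, image_path, atlas_path, voxels_per_node: int = 2
) -> list[int]:
    """Write a 4D NIfTI phantom plus integer-labelled atlas that reproduce
    ``ts`` through the parcellation path. Returns the region ids in node
    order."""
    import nibabel as nib

    img, atlas, labels = make_phantom(ts, voxels_per_node=voxels_per_node)
    nib.save(nib.Nifti1Image(img.astype(np.float32), np.eye(4)),
             str(image_path))
    nib.save(nib.Nifti1Image(atlas.astype(np.int16), np.eye(4)),
             str(atlas_path))
    return labels


def make_phantom(
    ts: ParcellatedTimeSeries, voxels_per_node: int = 2
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Build a 4D phantom image plus integer atlas reproducing ``ts`` through
    the parcellation path: each region is filled with its node value at every
    volume. Returns (image, atlas, region ids in node order)."""
    n = ts.n_nodes
    vx = n * voxels_per_node
    atlas = np.zeros((vx, 1, 2), dtype=int)
    img = np.zeros((vx, 1, 2, ts.n_volumes))
    labels = list(range(1, n + 1))
    for j, lab in enumerate(labels):
        sl = slice(j * voxels_per_node, (j + 1) * voxels_per_node)
        atlas[sl, 0, 0] = lab
        img[sl, 0, 0, :] = ts.data[:, j]
    return img, atlas, labels
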