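"""End-to-end study orchestration from a single config.

``run_study`` drives preprocess -> windowed connectivity features -> GP
inference for every configured contrast and ordinal triple, on either a
synthetic cohort or a user-supplied data manifest, and writes the analysis
surface as files: a contrasts table (accuracy, permutation p, Bonferroni),
g-map node tables for significant contrasts, univariate t-tables, ordinal
confusion matrices and a JSON run log with provenance. Runs are
deterministic given the config seed. Node-label order is strict across all
input files: a mismatch is an error, never a silent reorder.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import (
    assemble_features,
    assemble_ordinal_features,
    compute_adjacency_stack,
    dc_feature_stack,
)
from .inference import (
    bonferroni_adjust,
    compute_gmap,
    loso_classify,
    orgp_fit_predict,
    paired_node_ttests,
    permutation_pvalue,
)
from .nodes import load_node_fixture
from .preprocess import (
    bandpass_filter,
    read_nuisance_tsv,
    read_timeseries_tsv,
    regress_nuisance,
)
from .synthetic import Cohort, CohortConfig, generate_cohort

__all__ = ["StudyConfig", "RunReport", "run_study", "validate_manifest"]


@dataclass
class StudyConfig:
    """Everything one analysis run needs.

    Exactly one of ``synthetic`` (a CohortConfig) or ``manifest`` (path to a
    cohort manifest JSON) provides the input data.
    """

    synthetic: CohortConfig | None = None
    manifest: str | None = None
    window_length: int = 120
    window_step: float | None = None  # defaults to window_length / 6
    contrasts: tuple = (("ketamine", "saline"),)
    ordinal_triples: tuple = ()
    n_perm: int = 1000
    bonferroni_family: int | None = None
    theta_mode: str = "per_fold"
    low_hz: float = 0.01
    high_hz: float = 0.1
    seed: int = 0
    output_dir: str = "phconn_out"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.manifest is None):
            raise ValueError(
                "exactly one of 'synthetic' or 'manifest' must be set"
            )
        self.contrasts = tuple(tuple(c) for c in self.contrasts)
        if not self.contrasts and not self.ordinal_triples:
            raise ValueError("no contrasts or ordinal triples configured")
        for c in self.contrasts:
            if len(c) != 2 or c[0] == c[1]:
                raise ValueError(f"bad contrast {c!r}")
        self.ordinal_triples = tuple(tuple(t) for t in self.ordinal_triples)
        for t in self.ordinal_triples:
            if len(t) < 3 or len(set(t)) != len(t):
                raise ValueError(f"bad ordinal triple {t!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        if syn is not None:
            syn = CohortConfig(**syn)
        return cls(synthetic=syn, **d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_jsonable(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("synthetic",)
        }
        if self.synthetic is not None:
            syn = dict(self.synthetic.__dict__)
            syn["conditions"] = list(syn["conditions"])
            if syn.get("node_labels"):
                syn["node_labels"] = list(syn["node_labels"])
            d["synthetic"] = syn
        d["contrasts"] = [list(c) for c in self.contrasts]
        d["ordinal_triples"] = [list(t) for t in self.ordinal_triples]
        return d


@dataclass
class RunReport:
    """Collected outputs of one study run."""

    contrast_table: pd.DataFrame
    classification: dict
    gmaps: dict
    ttests: dict
    ordinal: dict
    provenance: dict
    output_dir: Path


def validate_manifest(manifest_path) -> dict:
    """Validate a cohort manifest and return the normalised listing.

    Checks that every subject x condition file exists, every matrix is
    rectangular and numeric, and all files share the same node labels in the
    same order. All problems are collected and reported together.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    problems = []
    labels_ref = None
    entries = []
    for entry in manifest.get("runs", []):
        subj = entry.get("subject")
        cond = entry.get("condition")
        fpath = root / entry.get("file", "")
        if not fpath.exists():
            problems.append(
                f"missing file for subject {subj!r} condition {cond!r}: {fpath}"
            )
            continue
        try:
            df = pd.read_csv(fpath, sep="\t")
            data = df.to_numpy(dtype=float)
        except Exception as exc:  # ragged / non-numeric
            problems.append(
                f"unreadable matrix for subject {subj!r} condition {cond!r}: {exc}"
            )
            continue
        labels = [str(c) for c in df.columns]
        if labels_ref is None:
            labels_ref = labels
        elif labels != labels_ref:
            problems.append(
                f"node-label mismatch in {fpath.name} (order must be "
                "identical across all files; reordering is not performed)"
            )
            continue
        nuis = entry.get("nuisance_file")
        if nuis is not None and not (root / nuis).exists():
            problems.append(
                f"missing nuisance file for subject {subj!r} condition "
                f"{cond!r}: {root / nuis}"
            )
            continue
        entries.append(
            {
                "subject": subj,
                "condition": cond,
                "file": str(fpath),
                "nuisance_file": str(root / nuis) if nuis else None,
                "n_volumes": data.shape[0],
                "tr": float(entry.get("tr", manifest.get("tr", 2.0))),
            }
        )
    if problems:
        raise ValueError(
            "manifest validation failed:\n  " + "\n  ".join(problems)
        )
    return {
        "node_labels": labels_ref,
        "runs": entries,
        "conditions": manifest.get("conditions"),
        "seed": manifest.get("seed"),
    }


def _load_manifest_cohort(manifest: dict):
    runs = []
    nuisance = {}
    for entry in manifest["runs"]:
        ts = read_timeseries_tsv(
            entry["file"],
            tr=entry["tr"],
            subject_id=str(entry["subject"]),
            condition=str(entry["condition"]),
        )
        runs.append(ts)
        if entry["nuisance_file"]:
            nuisance[(ts.subject_id, ts.condition)] = read_nuisance_tsv(
                entry["nuisance_file"]
            )
    return runs, nuisance


def _preprocess_runs(runs, nuisance, low_hz, high_hz):
    out = []
    for ts in runs:
        nuis = nuisance.get((ts.subject_id, ts.condition))
        if nuis is not None:
            ts = regress_nuisance(ts, nuis)
        out.append(bandpass_filter(ts, low_hz=low_hz, high_hz=high_hz))
    return out


def compute_dc_map(runs, window_length=120, window_step=None):
    """{(subject, condition): (K, N) normalised-DC stack} for all runs."""
    return {
        (ts.subject_id, ts.condition): dc_feature_stack(
            compute_adjacency_stack(ts, length_T=window_length, s=window_step)
        )
        for ts in runs
    }


#: Minimum level printed by :func:`_log`; set via the CLI --log-level flag.
LOG_LEVEL = "info"
_LEVELS = {"debug": 0, "info": 1, "warning": 2, "error": 3, "quiet": 4}


def _log(msg: str, level: str = "info") -> None:
    if _LEVELS.get(level, 1) >= _LEVELS.get(LOG_LEVEL, 1):
        print(f"[phconn:{level}] {msg}", file=sys.stderr)


def run_study(config: StudyConfig) -> RunReport:
    """Execute the full analysis for every configured contrast and triple."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        _log("generating synthetic cohort")
        cohort, truth = generate_cohort(config.synthetic)
        runs, nuisance = cohort.runs, cohort.nuisance
        node_labels = truth.node_labels
    else:
        _log(f"validating manifest {config.manifest}")
        manifest = validate_manifest(config.manifest)
        runs, nuisance = _load_manifest_cohort(manifest)
        node_labels = manifest["node_labels"]
        truth = None

    available = {ts.condition for ts in runs}
    wanted = {c for pair in config.contrasts for c in pair}
    wanted |= {c for t in config.ordinal_triples for c in t}
    missing = sorted(wanted - available)
    if missing:
        raise ValueError(f"conditions not present in input data: {missing}")

    _log("preprocessing (nuisance regression + band-pass)")
    runs = _preprocess_runs(runs, nuisance, config.low_hz, config.high_hz)
    _log("computing windowed centrality features")
    dc_map = compute_dc_map(runs, config.window_length, config.window_step)

    centroids = None
    fixture = load_node_fixture()
    if list(fixture["label"]) == list(node_labels):
        centroids = fixture[["mni_x", "mni_y", "mni_z"]].to_numpy(float)

    classification = {}
    p_values = []
    rows = []
    rng = np.random.default_rng(config.seed)
    for contrast in config.contrasts:
        a, b = contrast
        _log(f"contrast {a} vs {b}: LOSO classification")
        fs = assemble_features(dc_map, a, b, node_labels)
        res = loso_classify(fs, theta_mode=config.theta_mode)
        perm_seed = int(rng.integers(2**31 - 1))
        res.permutation_p = permutation_pvalue(
            fs, n_perm=config.n_perm, seed=perm_seed
        )
        res.n_perm = config.n_perm
        classification[contrast] = res
        p_values.append(res.permutation_p)
        rows.append(
            {
                "condition_a": a,
                "condition_b": b,
                "accuracy_percent": 100.0 * res.accuracy,
                "n_test_items": res.n_test_items,
                "n_perm": config.n_perm,
                "p": res.permutation_p,
            }
        )

    table = pd.DataFrame(rows)
    gmaps = {}
    ttests = {}
    if len(table):
        adjusted, flags = bonferroni_adjust(
            table["p"].to_numpy(), family_size=config.bonferroni_family
        )
        table["p_adjusted"] = adjusted
        table["significant"] = flags
        table.to_csv(outdir / "contrasts.csv", index=False,
                     float_format="%.6g")

        for contrast, sig in zip(config.contrasts, flags):
            a, b = contrast
            res = classification[contrast]
            # Univariate follow-up on subject-mean DC values (uncentred).
            subjects = sorted({s for s, _ in dc_map})
            dc_a = np.stack([dc_map[(s, a)].mean(axis=0) for s in subjects])
            dc_b = np.stack([dc_map[(s, b)].mean(axis=0) for s in subjects])
            tt = paired_node_ttests(dc_a, dc_b, node_labels)
            ttests[contrast] = tt
            tt.to_csv(outdir / f"ttests_{a}_vs_{b}.csv", index=False,
                      float_format="%.6g")
            if sig:
                gm = compute_gmap(
                    res.fold_models, node_labels,
                    mni_centroids=centroids, contrast=contrast,
                )
                gmaps[contrast] = gm
                gm.to_csv(outdir / f"gmap_{a}_vs_{b}.csv")

    ordinal = {}
    for triple in config.ordinal_triples:
        _log(f"ordinal analysis {' < '.join(triple)}")
        fs = assemble_ordinal_features(dc_map, triple, node_labels)
        o = orgp_fit_predict(fs)
        ordinal[triple] = o
        pd.DataFrame(
            o.confusion_matrix,
            index=list(triple),
            columns=list(triple),
        ).to_csv(outdir / ("confusion_" + "_".join(triple) + ".csv"),
                 float_format="%.6g")

    cfg_json = json.dumps(config.to_jsonable(), sort_keys=True, default=str)
    provenance = {
        "phconn_version": __version__,
        "numpy_version": np.__version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "n_runs": len(runs),
        "n_nodes": len(node_labels),
        "config": config.to_jsonable(),
    }
    (outdir / "run_log.json").write_text(json.dumps(provenance, indent=1,
                                                    default=str))
    return RunReport(
        contrast_table=table,
        classification=classification,
        gmaps=gmaps,
        ttests=ttests,
        ordinal=ordinal,
        provenance=provenance,
        output_dir=outdir,
    )
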