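"""File-level orchestration of the two-stage screening pipeline.

Each stage consumes and produces plain files (CSV / PDB / JSON) plus a JSON
run manifest recording inputs, seeds and thresholds, so stages are
restartable and every artifact is reproducible from its manifest.  The CLI
module is a thin wrapper over these functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from . import cs_stack, fingerprints, interactions, io_prep, ps_rank
from .cs_stack import classification_metrics, ensemble_entropy, make_folds
from .io_prep import FilterConfig


@dataclass
class RunConfig:
    """Declarative run configuration; defaults follow the published protocol."""

    ic50_cutoff_um: float = 0.05
    max_zero_frac: float = 0.85
    min_sd: float = 0.03
    max_abs_rho: float = 0.90
    cs_folds: int = 10
    ps_folds: int = 5
    epochs: int = 50
    split_mode: str = "holdout10"        # or "70:30"
    base_learners: tuple[str, ...] = ("random_forest", "xgboost")
    super_arch: tuple[int, ...] = (200, 400, 2)
    ps_arch: tuple[int, ...] = (400, 200, 400, 2)
    momentum_grid: tuple[float, ...] = (0.9,)
    rate_annealing_grid: tuple[float, ...] = (1e-6,)
    input_dropout_grid: tuple[float, ...] = (0.0,)
    window: tuple[int, int] = (9, 12)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("base_learners", "super_arch", "ps_arch", "window",
                    "momentum_grid", "rate_annealing_grid", "input_dropout_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(max_zero_frac=self.max_zero_frac, min_sd=self.min_sd,
                            max_abs_rho=self.max_abs_rho)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, stage: str, cfg: RunConfig,
                   inputs: Sequence[Path], extras: dict | None = None) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config": dataclasses.asdict(cfg),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()},
        **(extras or {}),
    }
    path = out_dir / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def _split_holdout(n: int, labels: np.ndarray, mode: str, seed: int):
    """Internal-evaluation split: 10% random holdout or a 70:30 partition."""
    frac = 0.1 if mode == "holdout10" else 0.3
    rng = np.random.default_rng(seed)
    holdout_idx: list[int] = []
    for cls in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == cls))
        k = max(1, int(round(frac * len(members))))
        holdout_idx.extend(members[:k].tolist())
    holdout = np.sort(np.array(holdout_idx))
    train = np.setdiff1d(np.arange(n), holdout)
    return train, holdout


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_preprocess(descriptor_csv: Path, out_dir: Path, cfg: RunConfig,
                     label_column: str | None = "label") -> Path:
    out_dir = Path(out_dir)
    m = io_prep.read_descriptor_csv(descriptor_csv, label_column=label_column)
    filtered, reports = io_prep.preprocess(m, cfg.filter_config())
    out = out_dir / "descriptors_filtered.csv"
    out_dir.mkdir(parents=True, exist_ok=True)
    io_prep.write_descriptor_csv(filtered, out)
    report_json = [dataclasses.asdict(r) for r in reports]
    (out_dir / "filter_reports.json").write_text(json.dumps(report_json, indent=2))
    write_manifest(out_dir, "preprocess", cfg, [Path(descriptor_csv)],
                   {"kept": filtered.d, "removed": sum(len(r.removed) for r in reports)})
    return out


def stage_train_cs(filtered_csv: Path, out_dir: Path, cfg: RunConfig) -> Path:
    out_dir = Path(out_dir)
    m = io_prep.read_descriptor_csv(filtered_csv, label_column="label")
    if m.labels is None:
        raise ValueError("training requires a label column")
    train_idx, hold_idx = _split_holdout(m.n, m.labels, cfg.split_mode, cfg.seed)

    def subset(idx):
        return io_prep.DescriptorMatrix(
            ids=[m.ids[i] for i in idx], feature_names=list(m.feature_names),
            values=m.values[idx], labels=m.labels[idx])

    m_train, m_hold = subset(train_idx), subset(hold_idx)
    model, l1 = cs_stack.train_stacked(
        m_train, learners=cfg.base_learners, J=cfg.cs_folds, seed=cfg.seed,
        arch=cfg.super_arch, epochs=cfg.epochs)
    proba, pred = cs_stack.predict_stacked(model, m_hold)
    metrics = classification_metrics(m_hold.labels, proba)
    base_preds = (l1.z >= 0.5).astype(int)
    diversity = ensemble_entropy(base_preds, l1.y)

    out_dir.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, out_dir / "cs_model.joblib")
    payload = {"holdout": metrics.as_dict(), "oof_entropy": diversity,
               "n_train": int(len(train_idx)), "n_holdout": int(len(hold_idx))}
    (out_dir / "cs_metrics.json").write_text(json.dumps(payload, indent=2))
    write_manifest(out_dir, "train_cs", cfg, [Path(filtered_csv)], payload)
    return out_dir / "cs_model.joblib"


def stage_predict_cs(model_path: Path, descriptor_csv: Path, out_dir: Path,
                     cfg: RunConfig) -> Path:
    out_dir = Path(out_dir)
    model = joblib.load(model_path)
    m = io_prep.read_descriptor_csv(descriptor_csv, label_column="label")
    proba, pred = cs_stack.predict_stacked(model, m)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"id": m.ids, "proba": proba, "pred": pred})
    out = out_dir / "cs_predictions.csv"
    df.to_csv(out, index=False)
    write_manifest(out_dir, "predict_cs", cfg, [Path(model_path), Path(descriptor_csv)],
                   {"n_scored": len(df), "n_positive": int(pred.sum())})
    return out


def stage_fingerprint(molecules_csv: Path, out_dir: Path, cfg: RunConfig) -> Path:
    out_dir = Path(out_dir)
    records, failures = io_prep.read_molecules(molecules_csv, "smiles_table")
    lib = fingerprints.load_library()
    df = fingerprints.fingerprint_matrix(records, lib)
    out_dir.mkdir(parents=True, exist_ok=True)
    out = out_dir / "fingerprints.csv"
    fingerprints.write_fingerprints(df, out, sparse=True)
    write_manifest(out_dir, "fingerprint", cfg, [Path(molecules_csv)],
                   {"n_molecules": len(df), "n_failures": len(failures),
                    "library": lib.version, "library_size": lib.size})
    return out


def stage_profile(complex_paths: Sequence[Path], out_dir: Path, cfg: RunConfig,
                  ligand_selector: str | None = None) -> Path:
    out_dir = Path(out_dir)
    profiles = []
    for p in complex_paths:
        c = interactions.parse_complex(p, ligand_selector=ligand_selector)
        profiles.append(interactions.profile(c))
    out_dir.mkdir(parents=True, exist_ok=True)
    df = interactions.profiles_to_frame(profiles)
    out = out_dir / "interaction_profiles.csv"
    df.to_csv(out, index=False)
    counts = {p.complex_id: p.d_i for p in profiles}
    (out_dir / "interaction_counts.json").write_text(json.dumps(counts, indent=2))
    write_manifest(out_dir, "profile", cfg, list(complex_paths), {"n_complexes": len(profiles)})
    return out


def stage_train_ps(fingerprint_csv: Path, labels_csv: Path, out_dir: Path,
                   cfg: RunConfig) -> Path:
    out_dir = Path(out_dir)
    X = fingerprints.read_fingerprints(fingerprint_csv)
    labels = pd.read_csv(labels_csv).set_index("id")["label"]
    y = labels.loc[X.index].to_numpy()
    ps_cfg = ps_rank.PSModelConfig(
        layers=cfg.ps_arch, epochs=cfg.epochs, folds=cfg.ps_folds,
        momentum_grid=cfg.momentum_grid, rate_annealing_grid=cfg.rate_annealing_grid,
        input_dropout_grid=cfg.input_dropout_grid, seed=cfg.seed)
    model = ps_rank.fit_ps_model(X.to_numpy(), y, ps_cfg)
    out_dir.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, out_dir / "ps_model.joblib")
    model.cv_results.to_csv(out_dir / "ps_grid_results.csv", index=False)
    write_manifest(out_dir, "train_ps", cfg, [Path(fingerprint_csv), Path(labels_csv)],
                   {"best_point": model.best_point,
                    "cv_auc": float(model.cv_results["cv_auc"].max())})
    return out_dir / "ps_model.joblib"


def stage_rank(predictions_csv: Path, counts_json: Path, out_dir: Path,
               cfg: RunConfig, truth_csv: Path | None = None) -> Path:
    out_dir = Path(out_dir)
    preds = pd.read_csv(predictions_csv)
    col = "f_alpha" if "f_alpha" in preds.columns else "proba"
    predictions = dict(zip(preds["id"].astype(str), preds[col]))
    counts = json.loads(Path(counts_json).read_text())
    truth = None
    if truth_csv is not None:
        tdf = pd.read_csv(truth_csv)
        truth = dict(zip(tdf["id"].astype(str), tdf["label"].astype(int)))
    window = ps_rank.ThresholdWindow(*cfg.window)
    hits = ps_rank.rank_hits(predictions, counts, window, truth=truth)
    out_dir.mkdir(parents=True, exist_ok=True)
    out = out_dir / "ranked_hits.csv"
    ps_rank.ranked_hits_frame(hits).to_csv(out, index=False)
    write_manifest(out_dir, "rank", cfg,
                   [Path(predictions_csv), Path(counts_json)],
                   {"mode": "true_positives" if truth else "predicted_positives",
                    "window": list(cfg.window),
                    "n_ranked": sum(1 for h in hits if h.rank is not None)})
    return out


def stage_baselines(filtered_csv: Path, out_dir: Path, cfg: RunConfig) -> Path:
    """Each base learner (plus a plain network) standalone, same metrics."""
    out_dir = Path(out_dir)
    m = io_prep.read_descriptor_csv(filtered_csv, label_column="label")
    train_idx, hold_idx = _split_holdout(m.n, m.labels, cfg.split_mode, cfg.seed)
    results = {}
    specs = list(cfg.base_learners) + ["dnn"]
    for spec in specs:
        if spec == "dnn":
            from sklearn.neural_network import MLPClassifier

            model = MLPClassifier(hidden_layer_sizes=(200, 400), activation="tanh",
                                  max_iter=cfg.epochs, random_state=cfg.seed)
        else:
            model = cs_stack.make_base_learner(spec, seed=cfg.seed)
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(m.values[train_idx], m.labels[train_idx])
        proba = cs_stack._positive_proba(model, m.values[hold_idx])
        results[spec] = classification_metrics(m.labels[hold_idx], proba).as_dict()
    out_dir.mkdir(parents=True, exist_ok=True)
    out = out_dir / "baseline_metrics.json"
    out.write_text(json.dumps(results, indent=2))
    write_manifest(out_dir, "baselines", cfg, [Path(filtered_csv)], {"models": specs})
    return out


# --------------------------------------------------------------------------
# In-memory end-to-end on a synthetic study (also used by the CLI demo)
# --------------------------------------------------------------------------

def run_study(study, cfg: RunConfig | None = None, mode: str = "truth") -> dict:
    """Run the full two-stage pipeline on a :class:`synthetic.StudyData`.

    Chemical space: filter chain + stacked ensemble trained on the training
    descriptors, scored on the screening set.  Protein space: fingerprint
    network trained on the training fingerprints; screening complexes are
    profiled geometrically; hits are window-filtered and beta-ranked.
    Returns metrics, the ranked table and the recovery of planted actives.
    """
    from .interactions import parse_complex
    import tempfile

    cfg = cfg or RunConfig(window=study.window)
    filtered, reports = io_prep.preprocess(study.train_descriptors, cfg.filter_config())
    model, l1 = cs_stack.train_stacked(
        filtered, learners=cfg.base_learners, J=cfg.cs_folds, seed=cfg.seed,
        arch=cfg.super_arch, epochs=cfg.epochs)
    screen_filtered = study.screen_descriptors.select_features(filtered.feature_names)
    screen_filtered.labels = study.screen_labels
    cs_proba, cs_pred = cs_stack.predict_stacked(model, screen_filtered)
    cs_metrics = classification_metrics(study.screen_labels, cs_proba)

    ps_cfg = ps_rank.PSModelConfig(
        layers=cfg.ps_arch, epochs=cfg.epochs, folds=cfg.ps_folds,
        momentum_grid=cfg.momentum_grid, rate_annealing_grid=cfg.rate_annealing_grid,
        input_dropout_grid=cfg.input_dropout_grid, seed=cfg.seed)
    ps_model = ps_rank.fit_ps_model(study.train_fingerprints, study.train_labels, ps_cfg)
    f_alpha = ps_model.predict_f_alpha(study.screen_fingerprints)
    ps_metrics = classification_metrics(study.screen_labels, f_alpha)

    d_counts = {}
    with tempfile.TemporaryDirectory() as td:
        for mol_id, pdb_text in study.complexes.items():
            p = Path(td) / f"{mol_id}.pdb"
            p.write_text(pdb_text)
            c = parse_complex(p, ligand_selector="LIG", complex_id=mol_id)
            d_counts[mol_id] = interactions.profile(c).d_i

    window = ps_rank.ThresholdWindow(*study.window)
    truth = dict(zip(study.screen_ids, study.screen_labels)) if mode == "truth" else None
    predictions = dict(zip(study.screen_ids, f_alpha))
    hits = ps_rank.rank_hits(predictions, d_counts, window, truth=truth)
    ranked_ids = [h.molecule_id for h in hits if h.rank is not None]
    planted = set(study.manifest["planted_actives"])
    recovery_precision = (
        sum(1 for i in ranked_ids if i in planted) / len(ranked_ids) if ranked_ids else 0.0
    )
    recovery_recall = sum(1 for i in ranked_ids if i in planted) / len(planted)
    return {
        "cs_metrics": cs_metrics.as_dict(),
        "ps_metrics": ps_metrics.as_dict(),
        "oof_entropy": ensemble_entropy((l1.z >= 0.5).astype(int), l1.y),
        "filter_reports": reports,
        "d_counts": d_counts,
        "ranked": ps_rank.ranked_hits_frame(hits),
        "recovery_precision": recovery_precision,
        "recovery_recall": recovery_recall,
    }
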