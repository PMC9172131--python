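"""End-to-end experiment orchestration.

The workhorse is :func:`evaluate_methods`: given a panel, a split mask and
a base learner spec, it trains each requested method under each training
seed (the split stays fixed; only model training is re-seeded) and scores
every assay's test cells, returning a tidy results table that
:func:`toximpute.evaluation.multi_seed_summary` aggregates the way the
study protocol prescribes (assay-mean per seed, then median/IQR across
seeds).

Higher-level studies reuse it: the pairwise Feature-Net heatmap (median
MCC of each (target, auxiliary) pairwise model minus the target's
single-task median, full-Feature-Net difference on the diagonal) and the
auxiliary-selection study (MI-entropy-ratio-ranked vs random-additive
auxiliary sets at increasing k).

``run_experiment`` drives everything from a validated config and writes
CSV outputs plus a JSON manifest; stages whose outputs already exist are
skipped, so interrupted runs are resumable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data as _data
from . import evaluation, relatedness, splitting, synthetic
from .feature_net import (EXPERIMENTAL, PREDICTED, FeatureNetClassifier,
                          fn_step1_fill)
from .learners import (DEFAULT_THRESHOLD, LearnerSpec, fit_multitask_masked,
                       fit_single_task, predict_proba_toxic)

METHODS = ("single_task", "multitask", "fn_experimental", "fn_predicted")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any compute)."""


def _training_seeds(master_seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(master_seed).spawn(n)]


def _score_row(y_true, proba, threshold):
    preds = (np.asarray(proba) >= threshold).astype(int)
    f1, auc = evaluation.f1_and_auc(proba, y_true, threshold)
    return {"mcc": evaluation.mcc_from_predictions(y_true, preds),
            "f1": f1, "auc": auc}


def single_task_models(features, labels, mask, base_spec, seed):
    """One fitted single-task model per assay, trained on train cells."""
    train = labels.where(_data.train_mask(mask))
    seeds = _training_seeds(seed, len(labels.columns))
    models = {}
    for s, assay in zip(seeds, labels.columns):
        col = train[assay]
        obs = col.notna().to_numpy()
        models[assay] = fit_single_task(base_spec.with_seed(s),
                                        features[obs], col.to_numpy()[obs])
    return models


def evaluate_methods(features: pd.DataFrame, labels: pd.DataFrame,
                     mask: pd.DataFrame, base_spec: LearnerSpec,
                     methods=("single_task", "fn_experimental"),
                     seeds=(0,), aux_labels: pd.DataFrame | None = None,
                     threshold: float = DEFAULT_THRESHOLD,
                     ghost: bool = False) -> pd.DataFrame:
    """Tidy per-(method, assay, seed) metrics on the test cells.

    ``aux_labels`` feeds the Feature Net's experimental mode; by default it
    is the train-cell labels (the assay-split imputation scenario).  For
    the compound-split "known test labels" scenario pass the full observed
    label matrix.  ``ghost=True`` replaces the fixed threshold with a
    per-assay GHOST threshold derived from training scores.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ConfigError(f"unknown methods: {unknown}")
    train_bool = _data.train_mask(mask)
    test_bool = _data.test_mask(mask)
    train_labels = labels.where(train_bool)
    if aux_labels is None:
        aux_labels = train_labels
    rows = []
    for seed in seeds:
        st = (single_task_models(features, labels, mask, base_spec, seed)
              if "single_task" in methods or ghost else None)
        fn = None
        if "fn_experimental" in methods or "fn_predicted" in methods:
            fn = FeatureNetClassifier(base_spec=base_spec,
                                      threshold=threshold,
                                      random_state=seed)
            fn.fit(features, labels, split=mask)
        mt = None
        if "multitask" in methods:
            mt = fit_multitask_masked(LearnerSpec.make("multitask_net", seed=seed),
                                      features, train_labels)
        for j, assay in enumerate(labels.columns):
            sel = test_bool[assay].to_numpy()
            if sel.sum() == 0:
                continue
            y_true = labels[assay].to_numpy()[sel].astype(int)
            X_test = features[sel]
            thr = threshold
            if ghost and st is not None:
                tr_sel = train_bool[assay].to_numpy()
                tr_scores = predict_proba_toxic(st[assay], features[tr_sel])
                thr = evaluation.ghost_threshold(
                    tr_scores, labels[assay].to_numpy()[tr_sel].astype(int),
                    seed=seed)
            for method in methods:
                if method == "single_task":
                    proba = predict_proba_toxic(st[assay], X_test)
                elif method == "multitask":
                    proba = mt.predict_proba(X_test)[:, j]
                elif method == "fn_experimental":
                    aux = aux_labels[sel].drop(columns=[assay])
                    proba = fn.predict_proba_assay(assay, X_test, aux,
                                                   mode=EXPERIMENTAL)
                else:  # fn_predicted
                    proba = fn.predict_proba_assay(assay, X_test, None,
                                                   mode=PREDICTED)
                row = {"method": method, "assay": assay, "seed": seed,
                       "threshold": thr, "n_test": int(sel.sum())}
                row.update(_score_row(y_true, proba, thr))
                rows.append(row)
    return pd.DataFrame(rows)


def pairwise_fn_heatmap(features: pd.DataFrame, labels: pd.DataFrame,
                        mask: pd.DataFrame, base_spec: LearnerSpec,
                        seeds=(0,), aux_labels: pd.DataFrame | None = None,
                        mode: str = EXPERIMENTAL,
                        threshold: float = DEFAULT_THRESHOLD,
                        return_tidy: bool = False):
    """Median-over-seeds MCC difference matrix of pairwise Feature Nets.

    Off-diagonal cell (target, auxiliary) = median MCC of the pairwise
    model minus the target's single-task median; the diagonal holds the
    full-Feature-Net difference.  Step 1 is fitted once per seed and shared
    by every step-2 variant.
    """
    if len(labels.columns) < 2:
        raise ConfigError("pairwise heatmap needs at least 2 assays")
    assays = list(labels.columns)
    train_labels = labels.where(_data.train_mask(mask))
    test_bool = _data.test_mask(mask)
    if aux_labels is None:
        aux_labels = train_labels
    records = []
    for seed in seeds:
        st = single_task_models(features, labels, mask, base_spec, seed)
        filled, step1 = fn_step1_fill(train_labels, features, base_spec,
                                      seed=seed, threshold=threshold)
        full = FeatureNetClassifier.from_step1(
            filled, step1, features, train_labels, base_spec=base_spec,
            threshold=threshold, random_state=seed)
        for t in assays:
            sel = test_bool[t].to_numpy()
            y_true = labels[t].to_numpy()[sel].astype(int)
            X_test = features[sel]
            aux = aux_labels[sel].drop(columns=[t])
            st_proba = predict_proba_toxic(st[t], X_test)
            records.append({"seed": seed, "target": t, "auxiliary": "single_task",
                            "mcc": _score_row(y_true, st_proba, threshold)["mcc"]})
            full_proba = full.predict_proba_assay(t, X_test, aux, mode=mode)
            records.append({"seed": seed, "target": t, "auxiliary": "__full__",
                            "mcc": _score_row(y_true, full_proba, threshold)["mcc"]})
            for a in assays:
                if a == t:
                    continue
                pw = FeatureNetClassifier.from_step1(
                    filled, step1, features, train_labels, base_spec=base_spec,
                    auxiliary_sets={t: [a]}, targets=[t],
                    threshold=threshold, random_state=seed)
                proba = pw.predict_proba_assay(t, X_test, aux[[a]], mode=mode)
                records.append({"seed": seed, "target": t, "auxiliary": a,
                                "mcc": _score_row(y_true, proba, threshold)["mcc"]})
    tidy = pd.DataFrame(records)
    med = tidy.groupby(["target", "auxiliary"])["mcc"].median()
    diff = pd.DataFrame(np.nan, index=assays, columns=assays)
    for t in assays:
        base = med[(t, "single_task")]
        diff.loc[t, t] = med[(t, "__full__")] - base
        for a in assays:
            if a != t:
                diff.loc[t, a] = med[(t, a)] - base
    diff.index.name = "target"
    diff.columns.name = "auxiliary"
    if return_tidy:
        return diff, tidy
    return diff


def auxiliary_selection_study(features: pd.DataFrame, labels: pd.DataFrame,
                              mask: pd.DataFrame, target: str,
                              base_spec: LearnerSpec,
                              k_values=(1, 3, 5, 10, 20),
                              strategies=("mi_ratio", "random_additive"),
                              seeds=(0,),
                              threshold: float = DEFAULT_THRESHOLD
                              ) -> pd.DataFrame:
    """Feature-Net performance for a target with selected auxiliary subsets.

    For each (strategy, k, seed) an FN model for ``target`` is trained with
    the k auxiliaries the strategy selects (MI-entropy-ratio descending on
    training labels, or a seeded random-additive draw whose sets are nested
    across k) and evaluated on the fixed test split.
    """
    if target not in labels.columns:
        raise ConfigError(f"unknown target assay: {target}")
    if max(k_values) >= len(labels.columns):
        raise ConfigError("k must be below the number of assays")
    train_labels = labels.where(_data.train_mask(mask))
    test_bool = _data.test_mask(mask)
    sel = test_bool[target].to_numpy()
    y_true = labels[target].to_numpy()[sel].astype(int)
    X_test = features[sel]
    aux_labels = train_labels[sel]
    rows = []
    for seed in seeds:
        filled, step1 = fn_step1_fill(train_labels, features, base_spec,
                                      seed=seed, threshold=threshold)
        for strategy in strategies:
            for k in k_values:
                chosen = relatedness.rank_auxiliaries(
                    labels, target, k, strategy=strategy, seed=seed,
                    split=mask, label_scope="train")
                model = FeatureNetClassifier.from_step1(
                    filled, step1, features, train_labels, base_spec=base_spec,
                    auxiliary_sets={target: chosen}, targets=[target],
                    threshold=threshold, random_state=seed)
                proba = model.predict_proba_assay(
                    target, X_test, aux_labels[chosen], mode=EXPERIMENTAL)
                row = {"strategy": strategy, "k": k, "seed": seed,
                       "auxiliaries": ",".join(chosen)}
                row.update(_score_row(y_true, proba, threshold))
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config-driven runs

_REQUIRED_SPLIT_KEYS = {"kind", "fraction", "seed"}


@dataclass
class RunConfig:
    """Validated experiment configuration.

    ``dataset`` is either ``{"synthetic": {...SyntheticConfig fields...}}``
    or ``{"labels_csv": path, "features_csv": path}``; ``split`` needs
    ``kind`` ('compound'|'assay'), ``fraction`` and ``seed`` (optional
    ``stratified``, ``cap``); ``learner`` is ``{"algorithm": ..., "params":
    {...}}``; ``methods``, ``seeds``, ``threshold``, ``ghost`` control
    evaluation; ``outdir`` receives the outputs.
    """

    dataset: dict
    split: dict
    outdir: str
    learner: dict = field(default_factory=lambda: {"algorithm": "boosting"})
    methods: tuple = ("single_task", "fn_experimental")
    seeds: tuple = (0, 1, 2)
    threshold: float = DEFAULT_THRESHOLD
    ghost: bool = False

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        unknown = set(cfg) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dataset", "split", "outdir"):
            if key not in cfg:
                raise ConfigError(f"missing config key: {key}")
        missing = _REQUIRED_SPLIT_KEYS - set(cfg["split"])
        if missing:
            raise ConfigError(f"missing split keys: {sorted(missing)}")
        ds = cfg["dataset"]
        if not ({"synthetic"} <= set(ds) or {"labels_csv", "features_csv"} <= set(ds)):
            raise ConfigError(
                "dataset needs either 'synthetic' or 'labels_csv'+'features_csv'")
        out = cls(**cfg)
        out.methods = tuple(out.methods)
        out.seeds = tuple(out.seeds)
        bad = set(out.methods) - set(METHODS)
        if bad:
            raise ConfigError(f"unknown methods: {sorted(bad)}")
        return out

    def hash(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_dataset(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    ds = cfg.dataset
    if "synthetic" in ds:
        sconf = synthetic.SyntheticConfig(**ds["synthetic"])
        features, labels, _ = synthetic.generate_panel(sconf)
        return features, labels
    labels, _ = _data.read_label_csv(ds["labels_csv"])
    features = _data.read_feature_csv(ds["features_csv"])
    _data.validate_alignment(features, labels)
    return features, labels


def run_experiment(config: dict | RunConfig) -> dict:
    """Execute a configured run; returns the manifest (also written to disk).

    Stage outputs (split CSV, results CSV, summary CSV) are written under
    ``outdir``; a stage whose output file already exists under the same
    config hash is skipped, making interrupted runs resumable.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.hash(), "stages": {}, "warnings": []}
    t0 = time.time()

    features, labels = load_dataset(cfg)
    manifest["n_compounds"], manifest["n_assays"] = labels.shape

    split_path = outdir / f"split_{cfg.hash()}.csv"
    if split_path.exists():
        mask = _data.read_split_csv(split_path, labels)
        manifest["stages"]["split"] = {"path": str(split_path), "cached": True}
    else:
        mask = splitting.split(labels, kind=cfg.split["kind"],
                               test_fraction=cfg.split["fraction"],
                               seed=cfg.split["seed"],
                               stratified=cfg.split.get("stratified", False),
                               cap=cfg.split.get("cap"))
        _data.write_split_csv(mask, split_path)
        manifest["stages"]["split"] = {"path": str(split_path), "cached": False}

    results_path = outdir / f"results_{cfg.hash()}.csv"
    if results_path.exists():
        results = pd.read_csv(results_path)
        manifest["stages"]["evaluate"] = {"path": str(results_path), "cached": True}
    else:
        spec = LearnerSpec.make(cfg.learner.get("algorithm", "boosting"),
                                **cfg.learner.get("params", {}))
        aux = labels if cfg.split["kind"] == "compound" else None
        results = evaluate_methods(features, labels, mask, spec,
                                   methods=cfg.methods, seeds=cfg.seeds,
                                   aux_labels=aux, threshold=cfg.threshold,
                                   ghost=cfg.ghost)
        results.to_csv(results_path, index=False)
        manifest["stages"]["evaluate"] = {"path": str(results_path), "cached": False}

    summary = evaluation.multi_seed_summary(results, metric="mcc")
    summary_path = outdir / f"summary_{cfg.hash()}.csv"
    summary.to_csv(summary_path, index=False)
    manifest["stages"]["summary"] = {"path": str(summary_path)}
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(outdir / f"manifest_{cfg.hash()}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
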