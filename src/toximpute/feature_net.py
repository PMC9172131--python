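"""Two-stage Feature-Net imputation.

Step 1 trains a single-task model per assay on the training labels and
uses it to fill every unknown cell of the matrix with a binary call,
yielding a dense ``FilledMatrix`` whose cells are tagged *experimental*
(kept verbatim from the training labels) or *predicted*.

Step 2 retrains one model per *target* assay on the compounds that have an
experimental training label for that target, using the chemical
fingerprint plus the other (auxiliary) assays' filled labels as features.
The auxiliary set defaults to all other assays; a singleton set gives the
pairwise variant used to attribute the benefit to individual assays.

At prediction time auxiliary features come either from step-1 predictions
only (*predicted* mode -- the virtual-compound scenario) or from the test
compounds' known labels where available with step-1 predictions as
fallback (*experimental* mode -- the imputation scenario).  A target
assay's own label is never an input to its own prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import data as _data
from .learners import (DEFAULT_THRESHOLD, LearnerSpec, SingleClassError,
                       fit_single_task, predict_proba_toxic)

EXPERIMENTAL = "experimental"
PREDICTED = "predicted"


class LeakageError(ValueError):
    """A target assay's own held-out label was offered as an input."""


@dataclass
class FilledMatrix:
    """Dense label matrix with per-cell provenance."""

    values: pd.DataFrame  # 0/1 everywhere
    provenance: pd.DataFrame  # "experimental" / "predicted"

    def n_predicted(self) -> int:
        return int((self.provenance == PREDICTED).to_numpy().sum())


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def fn_step1_fill(train_labels: pd.DataFrame, features: pd.DataFrame,
                  base_spec: LearnerSpec, seed: int = 0,
                  threshold: float = DEFAULT_THRESHOLD
                  ) -> tuple[FilledMatrix, dict]:
    """Fill every unknown cell with a step-1 single-task binary call.

    ``train_labels`` holds only the labels available for training (held-out
    cells already NaN).  Experimental training labels are kept verbatim.
    Returns the filled matrix and the fitted per-assay step-1 models.
    """
    _data.validate_alignment(features, train_labels)
    seeds = _child_seeds(seed, len(train_labels.columns))
    values = train_labels.copy()
    prov = pd.DataFrame(np.where(train_labels.notna(), EXPERIMENTAL, PREDICTED),
                        index=train_labels.index, columns=train_labels.columns)
    models: dict = {}
    for s, assay in zip(seeds, train_labels.columns):
        col = train_labels[assay]
        obs = col.notna()
        try:
            model = fit_single_task(base_spec.with_seed(s), features[obs.to_numpy()],
                                    col[obs].to_numpy())
        except SingleClassError as err:
            raise SingleClassError(f"assay {assay} is untrainable: {err}") from err
        models[assay] = model
        gaps = ~obs
        if gaps.any():
            proba = predict_proba_toxic(model, features[gaps.to_numpy()])
            values.loc[gaps, assay] = (proba >= threshold).astype(float)
    return FilledMatrix(values=values.astype(float), provenance=prov), models


class FeatureNetClassifier(BaseEstimator):
    """Two-stage Feature-Net imputation model (scikit-learn style).

    Parameters
    ----------
    base_spec : LearnerSpec for both stages (step 2 reuses step 1's
        hyperparameters; no extra optimisation).
    auxiliary_sets : None (each target uses all other assays) or a mapping
        ``{target: [auxiliary, ...]}``; a singleton list gives a pairwise
        Feature Net.  A set containing its own target is an error.
    threshold : binary-call threshold used for step-1 fills.
    random_state : master seed; the two stages use distinct child seeds.

    Fitted attributes: ``step1_models_``, ``filled_``, ``models_``,
    ``aux_sets_``, ``assays_``.
    """

    def __init__(self, base_spec=None, auxiliary_sets=None, targets=None,
                 threshold=DEFAULT_THRESHOLD, random_state=0):
        self.base_spec = base_spec
        self.auxiliary_sets = auxiliary_sets
        self.targets = targets
        self.threshold = threshold
        self.random_state = random_state

    def _spec(self) -> LearnerSpec:
        return self.base_spec or LearnerSpec.make("boosting")

    def fit(self, features: pd.DataFrame, labels: pd.DataFrame,
            split=None):
        """Fit both stages on training labels.

        ``labels`` is the sparse label matrix; if ``split`` is given, only
        its train cells are used (test cells are invisible to both stages).
        """
        train_labels = labels.where(_data.train_mask(split)) if split is not None else labels
        _data.validate_alignment(features, train_labels)
        self.assays_ = list(train_labels.columns)
        seed1, seed2 = _child_seeds(self.random_state, 2)
        self.filled_, self.step1_models_ = fn_step1_fill(
            train_labels, features, self._spec(), seed=seed1,
            threshold=self.threshold)
        self._fit_step2(features, train_labels, seed2)
        return self

    @classmethod
    def from_step1(cls, filled: FilledMatrix, step1_models: dict,
                   features: pd.DataFrame, train_labels: pd.DataFrame,
                   base_spec=None, auxiliary_sets=None, targets=None,
                   threshold=DEFAULT_THRESHOLD, random_state=0
                   ) -> "FeatureNetClassifier":
        """Build step-2 models over an existing step-1 fill.

        Lets many step-2 variants (pairwise sets, ranked auxiliary subsets)
        share one step-1 fill instead of refitting it per variant.
        """
        model = cls(base_spec=base_spec, auxiliary_sets=auxiliary_sets,
                    targets=targets, threshold=threshold,
                    random_state=random_state)
        model.assays_ = list(train_labels.columns)
        model.filled_ = filled
        model.step1_models_ = step1_models
        _, seed2 = _child_seeds(random_state, 2)
        model._fit_step2(features, train_labels, seed2)
        return model

    def _fit_step2(self, features, train_labels, seed2):
        self.aux_sets_ = self._resolve_aux_sets()
        targets = list(self.targets) if self.targets is not None else self.assays_
        self.models_ = {}
        step2_seeds = dict(zip(self.assays_, _child_seeds(seed2, len(self.assays_))))
        for target in targets:
            col = train_labels[target]
            obs = col.notna().to_numpy()
            aux = self.aux_sets_[target]
            X2 = self._stack(features, self.filled_.values[aux])
            self.models_[target] = fit_single_task(
                self._spec().with_seed(step2_seeds[target]),
                X2[obs], col.to_numpy(dtype=float)[obs])

    def _resolve_aux_sets(self) -> dict:
        if self.auxiliary_sets is None:
            return {t: [a for a in self.assays_ if a != t] for t in self.assays_}
        out = {}
        for t in self.assays_:
            aux = list(self.auxiliary_sets.get(t, [a for a in self.assays_ if a != t]))
            if t in aux:
                raise ValueError(f"auxiliary set for {t} contains the target itself")
            unknown = set(aux) - set(self.assays_)
            if unknown:
                raise ValueError(f"unknown auxiliary assays for {t}: {unknown}")
            out[t] = aux
        return out

    @staticmethod
    def _stack(features: pd.DataFrame, aux: pd.DataFrame) -> np.ndarray:
        if aux.shape[1] == 0:
            return features.to_numpy(dtype=np.float32)
        return np.hstack([features.to_numpy(dtype=np.float32),
                          aux.to_numpy(dtype=np.float32)])

    def _step1_calls(self, features: pd.DataFrame) -> pd.DataFrame:
        calls = {}
        for assay in self.assays_:
            proba = predict_proba_toxic(self.step1_models_[assay], features)
            calls[assay] = (proba >= self.threshold).astype(float)
        return pd.DataFrame(calls, index=features.index)[self.assays_]

    def predict_proba_assay(self, target: str, features: pd.DataFrame,
                            aux_labels: pd.DataFrame | None = None,
                            mode: str = EXPERIMENTAL) -> np.ndarray:
        """Probability of toxicity in ``target`` for the given compounds.

        ``aux_labels`` carries the compounds' known labels for *other*
        assays (NaN where unknown); offering a label for the target itself
        raises ``LeakageError``.  In ``predicted`` mode any supplied labels
        are ignored entirely.
        """
        if mode not in (EXPERIMENTAL, PREDICTED):
            raise ValueError(f"unknown mode: {mode}")
        step1 = self._step1_calls(features)
        if mode == EXPERIMENTAL and aux_labels is not None:
            if target in aux_labels.columns and aux_labels[target].notna().any():
                raise LeakageError(
                    f"experimental labels supplied for target assay {target} itself")
            known = aux_labels.reindex(index=features.index,
                                       columns=self.assays_)
            base = known.combine_first(step1)
        else:
            base = step1
        aux = self.aux_sets_[target]
        X2 = self._stack(features, base[aux])
        return predict_proba_toxic(self.models_[target], X2)

    def predict_proba(self, features: pd.DataFrame,
                      aux_labels: pd.DataFrame | None = None,
                      mode: str = EXPERIMENTAL) -> pd.DataFrame:
        """Score matrix over all targets; per target, its own column of
        ``aux_labels`` is withheld before prediction."""
        out = {}
        trained = [a for a in self.assays_ if a in self.models_]
        for target in trained:
            if aux_labels is not None:
                masked = aux_labels.drop(columns=[target], errors="ignore")
            else:
                masked = None
            out[target] = self.predict_proba_assay(target, features, masked, mode)
        return pd.DataFrame(out, index=features.index)[trained]

    def predict(self, features: pd.DataFrame,
                aux_labels: pd.DataFrame | None = None,
                mode: str = EXPERIMENTAL,
                threshold: float | dict | None = None) -> pd.DataFrame:
        """Binary calls; ``threshold`` may be global or per-assay."""
        proba = self.predict_proba(features, aux_labels, mode)
        if threshold is None:
            threshold = self.threshold
        if isinstance(threshold, dict):
            return pd.DataFrame({a: (proba[a] >= threshold[a]).astype(int)
                                 for a in proba.columns}, index=proba.index)
        return (proba >= threshold).astype(int)


def fn_train(labels: pd.DataFrame, features: pd.DataFrame,
             base_spec: LearnerSpec, auxiliary_sets=None, split=None,
             seed: int = 0) -> FeatureNetClassifier:
    """Functional wrapper over ``FeatureNetClassifier.fit``."""
    model = FeatureNetClassifier(base_spec=base_spec,
                                 auxiliary_sets=auxiliary_sets,
                                 random_state=seed)
    return model.fit(features, labels, split=split)


def fn_predict(model: FeatureNetClassifier, features: pd.DataFrame,
               aux_labels: pd.DataFrame | None = None,
               mode: str = EXPERIMENTAL) -> pd.DataFrame:
    """Functional wrapper over ``FeatureNetClassifier.predict_proba``."""
    return model.predict_proba(features, aux_labels, mode)
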