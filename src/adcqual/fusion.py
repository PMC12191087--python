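"""Hierarchical logistic fusion of network / region / modality scores.

Three stacked levels of L2-regularized binary logistic regression:

* level 1 - per (modality, region): combines the complementary networks'
  non-diagnostic probabilities;
* level 2 - per modality: combines the three region scores into a modality
  score (the T2 level-2 score is the early, pre-DWI prediction);
* level 3 - combines the T2 and ADC modality scores into the final quality
  score for the visit.

Each stage uses balanced class weights and picks its penalty strength from
a fixed grid by 5-fold cross-validated AUC. Scores of 0.5 or above are
called non-diagnostic (fail-safe tie direction for a screening tool).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .metrics import binary_auc

C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
MODALITIES = ("t2", "adc")
REGIONS = ("bladder", "prostate", "rectum")
NON_DIAGNOSTIC, DIAGNOSTIC = 1, 0


def collapse_to_binary(label: int) -> int:
    """Ordinal 1-3 quality -> binary: 1 = non-diagnostic (positive),
    2-3 = diagnostic."""
    if label not in (1, 2, 3):
        raise ValueError(f"quality label must be in {{1,2,3}}, got {label}")
    return NON_DIAGNOSTIC if label == 1 else DIAGNOSTIC


@dataclass
class StageModel:
    """One fitted logistic stage (features are z-scored internally so the
    penalty acts on a common scale)."""

    coef: np.ndarray
    intercept: float
    C: float
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if self.mu is not None:
            X = (X - self.mu) / self.sd
        z = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def fit_stage(features, labels, folds: int = 5, seed: int = 0) -> StageModel:
    """L2 logistic regression with balanced class weights; C selected from
    a fixed log grid by stratified k-fold cross-validated AUC."""
    X = np.atleast_2d(np.asarray(features, float))
    if X.shape[0] == len(np.ravel(labels)) or X.ndim == 1:
        X = X.reshape(len(np.ravel(labels)), -1)
    y = np.ravel(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("fit_stage needs both classes present")
    if counts.min() < 2:
        raise ValueError("fit_stage needs >= 2 examples per class")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    k = int(min(folds, counts.min()))
    best_C, best_auc = 1.0, -np.inf
    if k >= 2:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = list(skf.split(Xs, y))
        for C in C_GRID:
            aucs = []
            for tr, te in split:
                m = LogisticRegression(C=C, solver="liblinear",
                                       class_weight="balanced")
                m.fit(Xs[tr], y[tr])
                s = m.predict_proba(Xs[te])[:, 1]
                if len(np.unique(y[te])) > 1:
                    aucs.append(binary_auc(s, y[te]))
            mean_auc = np.nanmean(aucs) if aucs else np.nan
            # strict improvement keeps the strongest-regularized winner on ties
            if np.isfinite(mean_auc) and mean_auc > best_auc + 1e-12:
                best_auc, best_C = mean_auc, C
    final = LogisticRegression(C=best_C, solver="liblinear",
                               class_weight="balanced")
    final.fit(Xs, y)
    return StageModel(coef=final.coef_.ravel().copy(),
                      intercept=float(final.intercept_[0]), C=best_C,
                      mu=mu, sd=sd)


@dataclass
class FusionCascade:
    """Fitted three-level stack. ``networks`` names the level-1 feature
    columns; stages are keyed ``(modality, region)``, ``modality``, and
    ``"final"``."""

    modalities: tuple = MODALITIES
    regions: tuple = REGIONS
    networks: tuple = ("small_cnn", "wide_cnn")
    threshold: float = 0.5
    level1: dict = field(default_factory=dict)
    level2: dict = field(default_factory=dict)
    level3: StageModel | None = None

    @property
    def fitted(self) -> bool:
        return self.level3 is not None or (
            len(self.modalities) == 1 and len(self.level2) > 0
        )

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        def enc(sm):
            return {"coef": sm.coef.tolist(), "intercept": sm.intercept,
                    "C": sm.C,
                    "mu": None if sm.mu is None else sm.mu.tolist(),
                    "sd": None if sm.sd is None else sm.sd.tolist()}
        return json.dumps({
            "modalities": list(self.modalities),
            "regions": list(self.regions),
            "networks": list(self.networks),
            "threshold": self.threshold,
            "level1": {f"{m}|{r}": enc(s) for (m, r), s in self.level1.items()},
            "level2": {m: enc(s) for m, s in self.level2.items()},
            "level3": enc(self.level3) if self.level3 else None,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FusionCascade":
        d = json.loads(text)
        def dec(e):
            return StageModel(
                np.asarray(e["coef"]), e["intercept"], e["C"],
                mu=None if e.get("mu") is None else np.asarray(e["mu"]),
                sd=None if e.get("sd") is None else np.asarray(e["sd"]),
            )
        c = cls(modalities=tuple(d["modalities"]), regions=tuple(d["regions"]),
                networks=tuple(d["networks"]), threshold=d["threshold"])
        c.level1 = {tuple(k.split("|")): dec(v) for k, v in d["level1"].items()}
        c.level2 = {m: dec(v) for m, v in d["level2"].items()}
        c.level3 = dec(d["level3"]) if d["level3"] else None
        return c


def _level2_scores(cascade: FusionCascade, predictions: dict, modality: str):
    feats = np.column_stack([
        cascade.level1[(modality, r)].predict_proba(
            np.column_stack([predictions[modality][r][nw] for nw in cascade.networks])
        )
        for r in cascade.regions
    ])
    return cascade.level2[modality].predict_proba(feats)


def fit_cascade(predictions: dict, labels: dict, *,
                modalities=MODALITIES, regions=REGIONS,
                networks=("small_cnn", "wide_cnn"),
                trained_patient_ids=None, stacking_patient_ids=None,
                seed: int = 0) -> FusionCascade:
    """Fit the three-level stack on a stacking set.

    ``predictions[modality][region][network]`` is the per-visit
    non-diagnostic probability vector from that network.
    ``labels[modality]`` is the binary collapse of that modality's quality;
    ``labels["final"]`` is the endpoint (ADC binary quality). If both
    ``trained_patient_ids`` and ``stacking_patient_ids`` are given, any
    overlap is rejected as leakage.
    """
    if trained_patient_ids is not None and stacking_patient_ids is not None:
        leak = set(trained_patient_ids) & set(stacking_patient_ids)
        if leak:
            raise ValueError(
                f"stacking set shares patients with network training: {sorted(leak)[:5]}"
            )
    cascade = FusionCascade(modalities=tuple(modalities), regions=tuple(regions),
                            networks=tuple(networks))
    for m in cascade.modalities:
        y_m = np.asarray(labels[m]).astype(int)
        for r in cascade.regions:
            X = np.column_stack([predictions[m][r][nw] for nw in cascade.networks])
            cascade.level1[(m, r)] = fit_stage(X, y_m, seed=seed)
        feats = np.column_stack([
            cascade.level1[(m, r)].predict_proba(
                np.column_stack([predictions[m][r][nw] for nw in cascade.networks])
            ) for r in cascade.regions
        ])
        cascade.level2[m] = fit_stage(feats, y_m, seed=seed)
    if len(cascade.modalities) > 1:
        y_final = np.asarray(labels["final"]).astype(int)
        feats3 = np.column_stack([
            _level2_scores(cascade, predictions, m) for m in cascade.modalities
        ])
        cascade.level3 = fit_stage(feats3, y_final, seed=seed)
    return cascade


def predict(cascade: FusionCascade, predictions: dict) -> dict:
    """Scores and labels for new visits.

    Returns modality-level scores (``"t2"`` is computable without any ADC
    input), the combined ``"final"`` score where fitted, and thresholded
    labels (score >= threshold -> non-diagnostic).
    """
    if not cascade.fitted:
        raise ValueError("cascade is not fitted")
    out = {}
    for m in cascade.modalities:
        if m in predictions:
            out[m] = _level2_scores(cascade, predictions, m)
    if cascade.level3 is not None and all(m in out for m in cascade.modalities):
        feats3 = np.column_stack([out[m] for m in cascade.modalities])
        out["final"] = cascade.level3.predict_proba(feats3)
    elif len(cascade.modalities) == 1:
        out["final"] = out[cascade.modalities[0]]
    out["labels"] = {
        k: (v >= cascade.threshold).astype(int)
        for k, v in out.items() if k != "labels"
    }
    return out
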