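"""Patient-level nested validation protocol.

The study design: 20% of patient IDs are held out as the final validation
set; the remaining 80% undergo stratified 5-fold cross-validation. Within
each fold the ordinal networks train on the fold's training patients, the
fusion cascade is fitted on the fold's *test* patients' network predictions
(by default restricted to external-site visits, emulating a multicenter
test set), and everything is finally evaluated on the untouched holdout.
All partitioning is by patient ID - a patient's slices and regions never
straddle splits.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import fusion
from .fusion import FusionCascade, collapse_to_binary, fit_cascade
from .metrics import MetricReport, compute_metrics
from .ordinal import Dataset, TrainConfig, build_backbone, predict_cum_probs, train
from .preprocess import REGIONS, PreprocessConfig, prepare_stack

log = logging.getLogger(__name__)

MODALITIES = ("t2", "adc")


class LeakageError(RuntimeError):
    """A patient ID crossed a partition boundary."""


@dataclass
class SplitPlan:
    holdout_ids: list
    folds: list  # k disjoint ID lists covering the non-holdout IDs
    stratify_labels: dict  # id -> binary label used for stratification
    seed: int

    def audit(self) -> None:
        hold = set(self.holdout_ids)
        seen = set()
        for i, f in enumerate(self.folds):
            fs = set(f)
            if fs & hold:
                raise LeakageError(f"fold {i} overlaps the holdout set")
            if fs & seen:
                raise LeakageError(f"fold {i} overlaps an earlier fold")
            seen |= fs
        # per-fold class proportions within one sample of the global ones
        ids = sorted(seen)
        y = np.array([self.stratify_labels[i] for i in ids])
        global_frac = y.mean() if len(y) else 0.0
        for i, f in enumerate(self.folds):
            yf = np.array([self.stratify_labels[j] for j in f])
            if abs(yf.sum() - global_frac * len(yf)) > 1.0 + 1e-9:
                raise LeakageError(f"fold {i} is not stratified")


def make_split(ids, labels, holdout_frac: float = 0.2, k: int = 5,
               seed: int = 0) -> SplitPlan:
    """Stratified holdout + stratified k folds over patient IDs."""
    ids = list(ids)
    y = np.asarray(labels).astype(int)
    if len(ids) != len(y):
        raise ValueError("ids and labels length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < k:
        raise ValueError(f"need at least {k} patients per class for {k} folds")
    rng = np.random.default_rng(seed)

    # stratified holdout: proportional per-class draw
    n_hold = int(round(holdout_frac * len(ids)))
    holdout = []
    order = rng.permutation(len(ids))
    per_class_target = {c: int(round(holdout_frac * cnt)) for c, cnt in zip(classes, counts)}
    taken = {c: 0 for c in classes}
    for i in order:
        c = y[i]
        if taken[c] < per_class_target[c] and len(holdout) < n_hold:
            holdout.append(i)
            taken[c] += 1
    rest = [i for i in range(len(ids)) if i not in set(holdout)]

    # stratified k folds by round-robin within each class
    folds = [[] for _ in range(k)]
    for c in classes:
        members = [i for i in rest if y[i] == c]
        rng.shuffle(members)
        for j, i in enumerate(members):
            folds[j % k].append(i)
    plan = SplitPlan(
        holdout_ids=[ids[i] for i in holdout],
        folds=[[ids[i] for i in f] for f in folds],
        stratify_labels={ids[i]: int(y[i]) for i in range(len(ids))},
        seed=seed,
    )
    plan.audit()
    return plan


@dataclass
class ProtocolConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    networks: tuple = ("small_cnn", "wide_cnn")
    regions: tuple = REGIONS
    modalities: tuple = MODALITIES
    holdout_frac: float = 0.2
    k: int = 5
    external_test_only: bool = True  # stacking set uses non-first-site visits
    seed: int = 0


@dataclass
class ProtocolResult:
    split: SplitPlan
    fold_reports: list  # per fold: {score_name: MetricReport} on the holdout
    aggregate: dict  # score_name -> {metric: (mean, sd)}
    selected_fold: int
    selected_reports: dict  # holdout reports of the best-test-AUC fold
    fold_test_auc: list  # cascade final-score AUC on each fold's stacking set
    training_logs: dict


def _patient_strat_labels(visits):
    """Patient-level stratification label: any ADC-non-diagnostic visit."""
    lab = {}
    for v in visits:
        b = collapse_to_binary(v.quality_adc)
        lab[v.patient_id] = max(lab.get(v.patient_id, 0), b)
    return lab


def prepare_visit_crops(visits, cfg: PreprocessConfig, modalities=MODALITIES):
    """Deterministic preprocessing of every visit.

    Returns ``crops[modality][region]`` of shape (n_visits, n_slices, px, px).
    """
    out = {m: {r: [] for r in REGIONS} for m in modalities}
    for v in visits:
        for m in modalities:
            stack = v.t2_stack if m == "t2" else v.adc_stack
            if stack is None:
                raise ValueError(f"visit {v.patient_id}/{v.site_id} has no {m} images")
            per_region = prepare_stack(stack, cfg)
            for r in REGIONS:
                out[m][r].append(per_region[r])
    return {m: {r: np.asarray(a, np.float32) for r, a in d.items()}
            for m, d in out.items()}


def _slice_dataset(crops_mr, visit_idx, labels, pids):
    X = crops_mr[visit_idx]  # (n, s, h, w)
    n, s, h, w = X.shape
    return Dataset(
        X=X.reshape(n * s, h, w),
        y=np.repeat(labels[visit_idx], s),
        patient_ids=np.repeat(pids[visit_idx], s),
    )


def _visit_probs(model, crops_mr, visit_idx):
    """Visit-level non-diagnostic probability: slice exceedance probabilities
    averaged over the visit's slices."""
    X = crops_mr[visit_idx]
    n, s, h, w = X.shape
    cum = predict_cum_probs(model, X.reshape(n * s, h, w))
    cum_visit = cum.reshape(n, s, -1).mean(axis=1)
    return 1.0 - cum_visit[:, 0]


def run_protocol(visits, config: ProtocolConfig) -> ProtocolResult:
    """Execute the full nested protocol on a phantom cohort."""
    cfg = config
    pids = np.array([v.patient_id for v in visits])
    sites = np.array([v.site_id for v in visits])
    q = {"t2": np.array([v.quality_t2 for v in visits]),
         "adc": np.array([v.quality_adc for v in visits])}
    ybin = {m: np.array([collapse_to_binary(x) for x in q[m]]) for m in cfg.modalities}

    strat = _patient_strat_labels(visits)
    unique_ids = sorted(set(pids))
    plan = make_split(unique_ids, [strat[i] for i in unique_ids],
                      cfg.holdout_frac, cfg.k, cfg.seed)
    hold_set = set(plan.holdout_ids)
    hold_idx = np.flatnonzero(np.isin(pids, list(hold_set)))

    log.info("preprocessing %d visits", len(visits))
    crops = prepare_visit_crops(visits, cfg.preprocess, cfg.modalities)

    first_site = sorted(set(sites))[0] if len(set(sites)) > 1 else None
    fold_reports, fold_test_auc, logs = [], [], {}
    rng = np.random.default_rng(cfg.seed)

    for f in range(cfg.k):
        t0 = time.time()
        stack_ids = set(plan.folds[f])
        train_ids = set().union(*(plan.folds[j] for j in range(cfg.k) if j != f))
        if train_ids & hold_set or stack_ids & hold_set:
            raise LeakageError("holdout patients visible during fitting")
        tr_idx = np.flatnonzero(np.isin(pids, list(train_ids)))
        st_idx = np.flatnonzero(np.isin(pids, list(stack_ids)))
        if cfg.external_test_only and first_site is not None:
            ext = st_idx[sites[st_idx] != first_site]
            if len(ext) >= 10 and len(np.unique(ybin["adc"][ext])) > 1:
                st_idx = ext

        preds_stack = {m: {r: {} for r in cfg.regions} for m in cfg.modalities}
        preds_hold = {m: {r: {} for r in cfg.regions} for m in cfg.modalities}
        for m in cfg.modalities:
            for r in cfg.regions:
                train_ds = _slice_dataset(crops[m][r], tr_idx, q[m], pids)
                test_ds = _slice_dataset(crops[m][r], st_idx, q[m], pids)
                for nw in cfg.networks:
                    tcfg = TrainConfig(**{**cfg.train.__dict__,
                                          "backbone": nw,
                                          "seed": int(rng.integers(2**31))})
                    model = build_backbone(nw, crops[m][r].shape[-1], seed=tcfg.seed)
                    res = train(model, train_ds, test_ds, tcfg)
                    logs[(f, m, r, nw)] = res.log
                    preds_stack[m][r][nw] = _visit_probs(model, crops[m][r], st_idx)
                    preds_hold[m][r][nw] = _visit_probs(model, crops[m][r], hold_idx)

        labels_stack = {m: ybin[m][st_idx] for m in cfg.modalities}
        labels_stack["final"] = ybin["adc"][st_idx]
        cascade = fit_cascade(
            preds_stack, labels_stack,
            modalities=cfg.modalities, regions=cfg.regions, networks=cfg.networks,
            trained_patient_ids=train_ids, stacking_patient_ids=None,
            seed=cfg.seed,
        )
        stack_out = fusion.predict(cascade, preds_stack)
        fold_test_auc.append(float(
            compute_metrics(stack_out["final"], labels_stack["final"]).auc
        ))

        hold_out = fusion.predict(cascade, preds_hold)
        target = ybin["adc"][hold_idx]  # endpoint: ADC binary quality
        reports = {name: compute_metrics(hold_out[name], target)
                   for name in ("t2", "adc", "final") if name in hold_out}
        fold_reports.append(reports)
        log.info("fold %d done in %.1fs (stacking AUC %.3f)",
                 f, time.time() - t0, fold_test_auc[-1])

    names = fold_reports[0].keys()
    aggregate = {}
    for name in names:
        aggregate[name] = {}
        for metric in ("accuracy", "npv", "ppv", "specificity", "sensitivity", "auc"):
            vals = np.array([getattr(r[name], metric) for r in fold_reports])
            aggregate[name][metric] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    selected = int(np.nanargmax(fold_test_auc))
    return ProtocolResult(
        split=plan, fold_reports=fold_reports, aggregate=aggregate,
        selected_fold=selected, selected_reports=fold_reports[selected],
        fold_test_auc=fold_test_auc, training_logs=logs,
    )
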