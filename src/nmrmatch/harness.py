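"""Training, evaluation and accounting harness.

Implements the benchmark protocol: Adam (lr 1e-4), batch size 32, binary
cross-entropy on match probabilities, checkpoint selection by highest
validation accuracy (earliest epoch wins ties), and evaluation with
accuracy = (TP+TN)/(TP+TN+FP+FN), precision, recall, F1 and a
Mann-Whitney (tie-corrected) AUC.  Because the spectral backbone is
frozen, its feature maps are computed once per image and cached; training
touches only the trainable parameter groups.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .autodiff import Tensor, no_grad
from .graph_encoder import GraphBatch
from .model import MatchNet, ModelConfig, VariantSpec, build_variant
from .nn import Adam, bce_loss
from .synthetic import DatasetManifest, image_to_input


@dataclass
class TrainConfig:
    """Optimization protocol; defaults follow the benchmark settings."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    optimizer: str = "adam"
    loss: str = "bce"
    seed: int = 0
    checkpoint_rule: str = "best_val_accuracy"


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    auc: float | None
    split: str = ""

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def to_dict(self) -> dict:
        return {"split": self.split, "TP": self.tp, "TN": self.tn,
                "FP": self.fp, "FN": self.fn, "Accuracy": self.accuracy,
                "Precision": self.precision, "Recall": self.recall,
                "F1": self.f1, "AUC": self.auc, "n": self.n}


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float | None:
    """AUC via the Mann-Whitney rank statistic with midrank tie correction."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("single-class evaluation split: AUC undefined")
        return None
    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_counts(labels: np.ndarray, scores: np.ndarray,
                     threshold: float = 0.5) -> tuple[int, int, int, int]:
    pred = np.asarray(scores) >= threshold
    truth = np.asarray(labels).astype(bool)
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return tp, tn, fp, fn


# ------------------------------------------------------------------ dataset

class PairBatcher:
    """Caches frozen-backbone feature maps and serves pair minibatches."""

    def __init__(self, manifest: DatasetManifest, images: dict, graphs: dict,
                 model: MatchNet, splits: list[str] | None = None,
                 chunk: int = 32):
        self.manifest = manifest
        self.graphs = graphs
        pairs = manifest.pairs
        if splits is not None:
            pairs = pairs[pairs["split"].isin(splits)]
        self.pairs = {s: df.reset_index(drop=True)
                      for s, df in pairs.groupby("split")}
        needed = sorted(set(pairs["spec_mol_id"].astype(str)))
        self.features: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        enc = model.spectral_encoder
        for i in range(0, len(needed), chunk):
            ids = needed[i:i + chunk]
            h = np.stack([image_to_input(images[(m, "1H")]) for m in ids])
            c = np.stack([image_to_input(images[(m, "13C")]) for m in ids])
            fh = enc.backbone_features(h)
            fc = enc.backbone_features(c)
            for j, m in enumerate(ids):
                self.features[m] = (fh[j], fc[j])

    def split_size(self, split: str) -> int:
        return len(self.pairs.get(split, ()))

    def feature_stack(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (N,C,h,w) ¹H and ¹³C feature maps of one split's spectra."""
        df = self.pairs.get(split)
        if df is None or len(df) == 0:
            raise ValueError(f"empty split {split!r}")
        ids = sorted(set(df["spec_mol_id"].astype(str)))
        fh = np.stack([self.features[m][0] for m in ids])
        fc = np.stack([self.features[m][1] for m in ids])
        return fh, fc

    def batches(self, split: str, batch_size: int,
                rng: np.random.Generator | None = None):
        df = self.pairs.get(split)
        if df is None or len(df) == 0:
            raise ValueError(f"empty split {split!r}")
        order = np.arange(len(df))
        if rng is not None:
            order = rng.permutation(order)
        for i in range(0, len(order), batch_size):
            rows = df.iloc[order[i:i + batch_size]]
            gb = GraphBatch([self.graphs[m] for m in rows["mol_id"]])
            fh = Tensor(np.stack([self.features[m][0]
                                  for m in rows["spec_mol_id"]]))
            fc = Tensor(np.stack([self.features[m][1]
                                  for m in rows["spec_mol_id"]]))
            yield gb, fh, fc, rows["label"].to_numpy()


# ----------------------------------------------------------------- training

@dataclass
class TrainResult:
    model: MatchNet
    best_state: dict
    best_epoch: int
    best_val_accuracy: float
    log: list[dict] = field(default_factory=list)


def evaluate_scores(model: MatchNet, batcher: PairBatcher, split: str,
                    batch_size: int = 32) -> tuple[np.ndarray, np.ndarray]:
    model.eval()
    scores, labels = [], []
    with no_grad():
        for gb, fh, fc, y in batcher.batches(split, batch_size):
            scores.append(model(gb, fh, fc).data.ravel())
            labels.append(y)
    return np.concatenate(labels), np.concatenate(scores)


def evaluate(model: MatchNet, batcher: PairBatcher, split: str,
             threshold: float = 0.5, batch_size: int = 32) -> MetricsReport:
    labels, scores = evaluate_scores(model, batcher, split, batch_size)
    tp, tn, fp, fn = confusion_counts(labels, scores, threshold)
    return MetricsReport(tp, tn, fp, fn, auc_score(labels, scores), split)


def train_model(model: MatchNet, batcher: PairBatcher,
                cfg: TrainConfig | None = None,
                val_split: str = "val") -> TrainResult:
    """Adam/BCE training with best-validation-accuracy checkpointing."""
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    model.spectral_encoder.check_frozen()
    model.spectral_encoder.fit_feature_scaler(*batcher.feature_stack("train"))
    opt = Adam(model.trainable_parameters(), lr=cfg.learning_rate)
    best_state, best_acc, best_epoch = model.state_dict(), -1.0, -1
    log: list[dict] = []
    for epoch in range(cfg.epochs):
        model.train()
        losses = []
        for gb, fh, fc, y in batcher.batches("train", cfg.batch_size, rng):
            prob = model(gb, fh, fc)
            loss = bce_loss(prob, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val = evaluate(model, batcher, val_split, batch_size=cfg.batch_size)
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_accuracy": val.accuracy, "val_auc": val.auc})
        if val.accuracy > best_acc:      # earliest epoch wins ties
            best_acc = val.accuracy
            best_epoch = epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return TrainResult(model, best_state, best_epoch, best_acc, log)


def save_checkpoint(result: TrainResult, cfg: TrainConfig, path) -> None:
    meta = {"config": result.model.cfg.to_dict(),
            "train": {k: getattr(cfg, k) for k in
                      ("learning_rate", "batch_size", "epochs", "seed")},
            "best_epoch": result.best_epoch,
            "best_val_accuracy": result.best_val_accuracy}
    np.savez(path, __meta__=json.dumps(meta),
             **{k: v for k, v in result.best_state.items()})


# --------------------------------------------------------------- accounting

def count_parameters(model: MatchNet) -> dict:
    """Per-component and overall counts, with millions to two decimals."""
    comps = model.component_parameter_counts()
    out = {name: dict(c) for name, c in comps.items()}
    for c in out.values():
        c["total_M"] = round(c["total"] / 1e6, 2)
    return out


def parameter_report(variants: list[str] | None = None,
                     cfg: ModelConfig | None = None,
                     backbone: str = "tiny") -> pd.DataFrame:
    """Instantiated parameter counts per ablation variant (tiny backbone
    by default; add the real-trunk count separately for full totals)."""
    rows = []
    base = cfg or ModelConfig()
    base = ModelConfig(graph=base.graph,
                       spectral=replace(base.spectral, backbone=backbone),
                       fusion=base.fusion)
    for vid in variants or ["A", "B", "C", "D", "all"]:
        m = build_variant(vid, base, np.random.default_rng(0))
        c = m.count_parameters()
        rows.append({"variant": vid, "total": c["total"],
                     "trainable": c["trainable"], "frozen": c["frozen"]})
    return pd.DataFrame(rows)


def full_model_parameter_count(cfg: ModelConfig | None = None) -> dict:
    """Exact counts for the default full model with the real ResNet-101 trunk."""
    base = cfg or ModelConfig()
    base = ModelConfig(graph=base.graph,
                       spectral=replace(base.spectral, backbone="resnet101"),
                       fusion=base.fusion)
    model = MatchNet(base, np.random.default_rng(0))
    return count_parameters(model)


def search_budget(target_trainable: int, tolerance: int = 500,
                  fused_widths=range(256, 513, 32),
                  gate_hiddens=range(16, 129, 16)) -> list[dict]:
    """Small integer search over free widths to meet a trainable budget."""
    hits = []
    for wf in fused_widths:
        for gh in gate_hiddens:
            cfg = ModelConfig()
            cfg.graph = replace(cfg.graph, fused_width=wf)
            cfg.spectral = replace(cfg.spectral, gate_hidden=gh, backbone="tiny")
            m = MatchNet(cfg, np.random.default_rng(0))
            t = m.count_parameters()["trainable"]
            if abs(t - target_trainable) <= tolerance:
                hits.append({"fused_width": wf, "gate_hidden": gh,
                             "trainable": t})
    return sorted(hits, key=lambda h: abs(h["trainable"] - target_trainable))
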