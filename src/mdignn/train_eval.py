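"""Full-batch semi-supervised training, cross-validation and ranking.

Training minimizes class-weighted binary cross-entropy on the labeled
nodes only (positive-class weight = N_neg / N_pos of the training mask),
with Adam (lr 1e-3, weight decay 5e-3), a 3000-epoch cap and early
stopping after 100 epochs without validation-loss improvement. Each epoch
independently drops a fraction of directed edges and rebuilds the shifted
magnetic Laplacian for that epoch (DropEdge-style regularization);
validation and test always use the full operator.

Evaluation follows repeated stratified 5-fold cross-validation: per
repeat, every labeled gene is tested exactly once; within each training
portion a stratified 10% split drives early stopping. Metrics (AUROC,
AUPR, accuracy, sensitivity, specificity, precision, MCC) are aggregated
as mean ± sd over folds × repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import autodiff as ad
from .autodiff import Adam, Tensor, concat, conv1d_width, spmatmul
from .core_io import FeatureMatrix, GeneGraph, LabelSet, RunConfig
from .magnetic_spectral import HermitianOperator, laplacian_from_edges, magnetic_laplacian
from .mdignn_model import ModelParams, forward, init_params

__all__ = [
    "MetricsReport",
    "forward_graph",
    "train",
    "compute_metrics",
    "cross_validate",
    "rank_candidates",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = (
    "auroc", "aupr", "accuracy", "sensitivity", "specificity", "precision", "mcc",
)


@dataclass
class MetricsReport:
    """Mean ± sd of each metric over folds × repeats."""

    rows: pd.DataFrame  # one row per fold×repeat, METRIC_COLUMNS

    @property
    def mean(self) -> pd.Series:
        return self.rows[list(METRIC_COLUMNS)].mean()

    @property
    def sd(self) -> pd.Series:
        metrics = self.rows[list(METRIC_COLUMNS)]
        return metrics.std(ddof=1) if len(metrics) > 1 else metrics.std(ddof=0)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


# ---------------------------------------------------------------------------
# Autodiff forward graph (training path)


def _complex_spmm(lr_mat, li_mat, xr: Tensor, xi: Tensor) -> tuple[Tensor, Tensor]:
    """(Lr + i·Li) @ (Xr + i·Xi) as a real tensor pair."""
    re = spmatmul(lr_mat, xr) - spmatmul(li_mat, xi)
    im = spmatmul(lr_mat, xi) + spmatmul(li_mat, xr)
    return re, im


def _complex_mm(xr: Tensor, xi: Tensor, wr: Tensor, wi: Tensor
                ) -> tuple[Tensor, Tensor]:
    return (xr @ wr - xi @ wi), (xr @ wi + xi @ wr)


def forward_graph(features: np.ndarray, op: HermitianOperator,
                  params: ModelParams, config: RunConfig,
                  training: bool = False,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Build the differentiable forward pass; returns the logits Tensor.

    Complex activations are carried as (re, im) tensor pairs so gradients
    stay in real arithmetic. Dropout is applied only when ``training``.
    """
    L = op.L_shifted
    lr_mat = L.real.tocsr()
    li_mat = L.imag.tocsr()
    xr = ad.constant(np.asarray(features, dtype=np.float64))
    xi = ad.constant(np.zeros_like(features, dtype=np.float64))
    for lp in params.layers:
        zr = ad.constant(0.0)
        zi = ad.constant(0.0)
        tr_prev = ti_prev = None
        tr_curr, ti_curr = xr, xi
        for k in range(len(lp.w_re)):
            mr, mi = _complex_mm(tr_curr, ti_curr, lp.w_re[k], lp.w_im[k])
            zr, zi = zr + mr, zi + mi
            if k + 1 < len(lp.w_re):
                ar, ai = _complex_spmm(lr_mat, li_mat, tr_curr, ti_curr)
                if tr_prev is not None:
                    ar = ar * 2.0 - tr_prev
                    ai = ai * 2.0 - ti_prev
                tr_prev, ti_prev = tr_curr, ti_curr
                tr_curr, ti_curr = ar, ai
        zr = zr + lp.b_re
        zi = zi + lp.b_im
        gate = (zr.value >= 0).astype(np.float64)  # complex ReLU on Re(z)
        xr, xi = zr.mask(gate), zi.mask(gate)
    h = concat([xr, xi], axis=1)
    if config.channel_attention:
        pool = h.mean(axis=0, keepdims=True)
        hidden = (pool @ params.att_w1 + params.att_b1).relu()
        mc = (hidden @ params.att_w2 + params.att_b2).sigmoid()
        h = h * mc
    if config.spatial_attention:
        avg = h.mean(axis=1, keepdims=True)
        mx = h.max(axis=1, keepdims=True)
        ms = conv1d_width(concat([avg, mx], axis=1),
                          params.conv_w, params.conv_b).sigmoid()
        h = h * ms.reshape(-1, 1)
    if training and config.dropout > 0:
        if rng is None:
            raise ValueError("training-mode forward needs an RNG for dropout")
        keep = 1.0 - config.dropout
        drop_mask = (rng.random(h.shape) < keep) / keep
        h = h.mask(drop_mask)
    logits = h @ params.head_w + params.head_b
    return logits.reshape(-1)


def _weighted_bce(logits: Tensor, y: np.ndarray, idx: np.ndarray,
                  pos_weight: float) -> Tensor:
    """Mean of w_i·[softplus(z_i) − y_i·z_i] over the ``idx`` nodes.

    Equals class-weighted binary cross-entropy with logits (positive class
    weighted by ``pos_weight``).
    """
    z = logits.take_rows(idx)
    yy = y[idx]
    w = np.where(yy == 1.0, pos_weight, 1.0)
    w = w / w.sum()
    per = z.softplus() - z.mask(yy)  # mask multiplies by the constant labels
    return per.mask(w).sum()


def _bce_value(logits: np.ndarray, y: np.ndarray, pos_weight: float) -> float:
    """Numpy mirror of :func:`_weighted_bce` for eval-mode monitoring."""
    w = np.where(y == 1.0, pos_weight, 1.0)
    w = w / w.sum()
    per = np.maximum(logits, 0.0) + np.log1p(np.exp(-np.abs(logits))) - y * logits
    return float((w * per).sum())


# ---------------------------------------------------------------------------
# Training


def train(graph: GeneGraph, features: FeatureMatrix, y: np.ndarray,
          train_idx: np.ndarray, val_idx: np.ndarray,
          config: RunConfig) -> tuple[ModelParams, dict]:
    """Full-batch training with early stopping on validation loss.

    ``y`` is the 0/1 label vector over all nodes; only ``train_idx`` rows
    enter the loss and only ``val_idx`` rows drive early stopping. Returns
    the best-validation-loss parameters and a history dict.
    """
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if len(np.intersect1d(train_idx, val_idx)):
        raise ValueError("train and validation masks overlap")
    n_pos = float(y[train_idx].sum())
    if n_pos == 0:
        raise ValueError("no positive labels in the training mask")
    pos_weight = (len(train_idx) - n_pos) / n_pos
    val_pos = float(y[val_idx].sum()) if len(val_idx) else 0.0
    val_weight = ((len(val_idx) - val_pos) / val_pos) if val_pos else 1.0

    rng = np.random.default_rng(config.seed)
    params = init_params(config, features.n_features, rng)
    opt = Adam(params.trainable(), lr=config.lr,
               weight_decay=config.weight_decay)
    full_op = magnetic_laplacian(graph, config.q)
    src, tgt = graph.edge_arrays()

    best_val = np.inf
    best_values = params.copy_values()
    best_epoch = 0
    history = {"train_loss": [], "val_loss": []}
    x = features.values
    for epoch in range(config.max_epochs):
        if config.edge_dropout > 0 and len(src):
            keep = rng.random(len(src)) >= config.edge_dropout
            op = laplacian_from_edges(src[keep], tgt[keep], graph.n_nodes,
                                      config.q)
        else:
            op = full_op
        opt.zero_grad()
        logits = forward_graph(x, op, params, config, training=True, rng=rng)
        loss = _weighted_bce(logits, y, train_idx, pos_weight)
        loss.backward()
        opt.step()
        history["train_loss"].append(float(loss.value))

        if len(val_idx):
            val_logits = forward(x, full_op.L_shifted, params, config,
                                 return_logits=True)
            val_loss = _bce_value(val_logits[val_idx], y[val_idx], val_weight)
        else:
            val_loss = history["train_loss"][-1]
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_values = params.copy_values()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break
    params.load_values(best_values)
    history["best_epoch"] = best_epoch
    history["stopped_epoch"] = epoch
    return params, history


# ---------------------------------------------------------------------------
# Metrics


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray,
                    threshold: float = 0.5) -> dict[str, float]:
    """One metrics row: ranking metrics plus confusion-matrix metrics at
    ``threshold``. MCC is 0 when any marginal factor is 0."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if len(y_true) != len(y_prob):
        raise ValueError("y_true and y_prob lengths differ")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUROC/AUPR undefined for single-class y_true")
    pred = (y_prob >= threshold).astype(np.float64)
    tp = float(np.sum((pred == 1) & (y_true == 1)))
    tn = float(np.sum((pred == 0) & (y_true == 0)))
    fp = float(np.sum((pred == 1) & (y_true == 0)))
    fn = float(np.sum((pred == 0) & (y_true == 1)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return {
        "auroc": float(roc_auc_score(y_true, y_prob)),
        "aupr": float(average_precision_score(y_true, y_prob)),
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "mcc": float(mcc),
    }


# ---------------------------------------------------------------------------
# Cross-validation


def _val_split(train_nodes: np.ndarray, y: np.ndarray, frac: float,
               seed: int) -> tuple[np.ndarray, np.ndarray]:
    tr, va = train_test_split(
        train_nodes, test_size=frac, stratify=y[train_nodes],
        random_state=seed,
    )
    return np.sort(tr), np.sort(va)


def cross_validate(graph: GeneGraph, features: FeatureMatrix,
                   labels: LabelSet, config: RunConfig,
                   n_folds: int = 5, n_repeats: int = 10,
                   val_fraction: float = 0.1) -> MetricsReport:
    """Repeated stratified k-fold CV over the labeled nodes.

    Fold assignment is seeded per repeat (seeds 0..n_repeats−1); every
    labeled gene is tested exactly once per repeat. Returns one metrics
    row per fold × repeat.
    """
    y, labeled = labels.masks(graph)
    labeled_idx = np.flatnonzero(labeled)
    n_pos = int(y[labeled_idx].sum())
    n_neg = len(labeled_idx) - n_pos
    if min(n_pos, n_neg) < n_folds:
        raise ValueError(
            f"each class needs >= {n_folds} members (got {n_pos} pos, {n_neg} neg)"
        )
    rows = []
    for repeat in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=repeat)
        for fold, (tr, te) in enumerate(
            skf.split(labeled_idx, y[labeled_idx])
        ):
            train_nodes = labeled_idx[tr]
            test_nodes = labeled_idx[te]
            tr_idx, va_idx = _val_split(
                train_nodes, y, val_fraction,
                seed=repeat * n_folds + fold,
            )
            fold_config = config.replace(
                seed=config.seed + 1009 * repeat + 31 * fold
            )
            params, _ = train(graph, features, y, tr_idx, va_idx, fold_config)
            op = magnetic_laplacian(graph, fold_config.q)
            probs = forward(features.values, op.L_shifted, params, fold_config)
            row = compute_metrics(y[test_nodes], probs[test_nodes])
            row.update({"repeat": repeat, "fold": fold})
            rows.append(row)
    df = pd.DataFrame(rows)
    return MetricsReport(rows=df[list(METRIC_COLUMNS)].assign(
        repeat=df["repeat"], fold=df["fold"]
    ))


# ---------------------------------------------------------------------------
# Ranking


def rank_candidates(params: ModelParams, graph: GeneGraph,
                    features: FeatureMatrix, labels: LabelSet,
                    config: RunConfig, threshold: float = 0.9
                    ) -> pd.DataFrame:
    """Score every node with a trained model and rank by probability.

    Candidates are the genes with probability strictly above ``threshold``;
    the novel set excludes known positives. Ties rank alphabetically.
    """
    op = magnetic_laplacian(graph, config.q)
    probs = forward(features.values, op.L_shifted, params, config)
    status = np.array([
        "positive" if g in labels.positives
        else "negative" if g in labels.negatives
        else "unknown"
        for g in graph.nodes
    ])
    table = pd.DataFrame({
        "gene": graph.nodes,
        "probability": probs,
        "label_status": status,
    }).sort_values(["probability", "gene"], ascending=[False, True])
    table["rank"] = np.arange(1, len(table) + 1)
    table["candidate"] = table["probability"] > threshold
    table["novel"] = table["candidate"] & (table["label_status"] != "positive")
    return table.reset_index(drop=True)


def train_full(graph: GeneGraph, features: FeatureMatrix, labels: LabelSet,
               config: RunConfig, val_fraction: float = 0.1
               ) -> tuple[ModelParams, dict]:
    """Train on the entire labeled set (for candidate ranking), holding out
    a stratified 10% of the labels for early stopping."""
    y, labeled = labels.masks(graph)
    labeled_idx = np.flatnonzero(labeled)
    tr_idx, va_idx = _val_split(labeled_idx, y, val_fraction, seed=config.seed)
    return train(graph, features, y, tr_idx, va_idx, config)
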