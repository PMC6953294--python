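"""Losses, the one-protein-per-batch training loop, and ensembling.

The total loss is the unweighted sum of three task losses:

    total = contact + secondary structure + accessible surface area

* contact: summed binary cross-entropy over unordered residue pairs
  i < j with sequence separation >= `min_separation` (default 6, the
  shortest evaluated range) whose label is not masked;
* secondary structure: summed 3-class cross-entropy over unmasked
  residues;
* ASA: root-mean-square error over unmasked residues (absolute area).

Masked labels (NaN contacts, SS code -1) contribute nothing — the loss
is invariant to predictions at masked entries.  Sums follow the printed
loss definitions; `normalize=True` switches to per-protein means for
cross-length comparability.

Training uses ADAM (lr 0.0005) with one optimizer step per protein;
depth sampling (30,000) and window cropping (200) are applied during
training only.  Contact and secondary-structure losses converge at
different epochs, so the best epoch is tracked per task on the
validation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features, msa, weighting
from .labels import SS_MASKED, LabelBundle
from .model import ContactNetwork, PredictionBundle
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.optim import Adam

PROB_EPS = 1e-7  # probability clamp inside the cross-entropy losses


@dataclass
class LossBreakdown:
    contact_loss: float = 0.0
    ss_loss: float = 0.0
    asa_loss: float = 0.0

    @property
    def total(self) -> float:
        return self.contact_loss + self.ss_loss + self.asa_loss


@dataclass
class TrainConfig:
    variant: str = "baseline"
    learning_rate: float = 0.0005
    epochs: int = 10
    seed: int = 0
    k_folds: int = 5
    max_depth: int = 30000  # training-time MSA depth cap
    max_len: int = 200  # training-time crop window
    min_separation: int = 6  # shortest pair separation entering the contact loss
    normalize_losses: bool = False  # False = the printed summed losses


def _pair_mask(y: np.ndarray, min_separation: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices (i, j) of unmasked unordered pairs with j - i >= separation."""
    L = y.shape[0]
    ii, jj = np.triu_indices(L, k=max(min_separation, 1))
    keep = np.isfinite(y[ii, jj])
    return ii[keep], jj[keep]


def contact_loss(y: np.ndarray, p, min_separation: int = 6, normalize: bool = False):
    """Masked binary cross-entropy between a contact map and probabilities.

    `p` may be a Tensor (training) or ndarray (reporting).  Returns a
    scalar of the same kind.  All-masked input gives 0 (empty sum).
    """
    y = np.asarray(y, dtype=float)
    p_shape = p.shape if isinstance(p, Tensor) else np.shape(p)
    if tuple(p_shape) != y.shape:
        raise ValueError(f"shape mismatch: labels {y.shape} vs predictions {p_shape}")
    ii, jj = _pair_mask(y, min_separation)
    if len(ii) == 0:
        return Tensor(0.0) if isinstance(p, Tensor) else 0.0
    y_sel = y[ii, jj]
    p_sel = ad.clip(p[ii, jj] if isinstance(p, Tensor) else np.asarray(p)[ii, jj],
                    PROB_EPS, 1.0 - PROB_EPS)
    terms = y_sel * ad.log(p_sel) + (1.0 - y_sel) * ad.log(1.0 - p_sel)
    loss = -terms.sum()
    return loss / len(ii) if normalize else loss


def ss_loss(ss3: np.ndarray, ss_prob, normalize: bool = False):
    """Masked 3-class cross-entropy; `ss3` uses -1 for masked residues."""
    ss3 = np.asarray(ss3)
    keep = np.flatnonzero(ss3 != SS_MASKED)
    if len(keep) == 0:
        return Tensor(0.0) if isinstance(ss_prob, Tensor) else 0.0
    onehot = np.zeros((len(keep), 3))
    onehot[np.arange(len(keep)), ss3[keep]] = 1.0
    p_sel = ad.clip(ss_prob[keep] if isinstance(ss_prob, Tensor)
                    else np.asarray(ss_prob)[keep], PROB_EPS, 1.0)
    loss = -(onehot * ad.log(p_sel)).sum()
    return loss / len(keep) if normalize else loss


def asa_loss(asa_true: np.ndarray, asa_pred):
    """RMSE over unmasked residues; N is the unmasked residue count."""
    asa_true = np.asarray(asa_true, dtype=float)
    keep = np.flatnonzero(np.isfinite(asa_true))
    if len(keep) == 0:
        return Tensor(0.0) if isinstance(asa_pred, Tensor) else 0.0
    pred_sel = asa_pred[keep] if isinstance(asa_pred, Tensor) else np.asarray(asa_pred)[keep]
    diff = pred_sel - asa_true[keep]
    return ad.sqrt((diff * diff).sum() / len(keep))


def total_loss(labels: LabelBundle, outputs: dict, config: TrainConfig):
    """Sum the task losses present in `outputs`; returns (Tensor, LossBreakdown)."""
    parts = {}
    parts["contact"] = contact_loss(
        labels.contact_map, outputs["contact"],
        min_separation=config.min_separation, normalize=config.normalize_losses,
    )
    if "ss" in outputs and labels.ss3 is not None:
        parts["ss"] = ss_loss(labels.ss3, outputs["ss"], normalize=config.normalize_losses)
    if "asa" in outputs and labels.asa is not None:
        parts["asa"] = asa_loss(labels.asa, outputs["asa"])
    total = None
    for term in parts.values():
        total = term if total is None else total + term
    breakdown = LossBreakdown(
        contact_loss=float(parts["contact"].data) if isinstance(parts["contact"], Tensor)
        else float(parts["contact"]),
        ss_loss=float(parts["ss"].data) if isinstance(parts.get("ss"), Tensor)
        else float(parts.get("ss", 0.0)),
        asa_loss=float(parts["asa"].data) if isinstance(parts.get("asa"), Tensor)
        else float(parts.get("asa", 0.0)),
    )
    return total, breakdown


# --------------------------------------------------------------------- data


@dataclass
class ProteinSample:
    """One training/validation example: an encoded MSA plus its labels."""

    enc: msa.EncodedAlignment
    labels: LabelBundle
    identifier: str = ""


def forward_sample(
    model: ContactNetwork,
    enc: msa.EncodedAlignment,
    weight_mlp: weighting.WeightMLP | None = None,
    weight_features: np.ndarray | None = None,
):
    """Featurize one protein and run the model.

    For the weighted variants the sequence weights come from `weight_mlp`
    (differentiably); otherwise unit weights are used.  Returns
    (outputs dict, weights Tensor or None).
    """
    w = None
    if weight_mlp is not None:
        if weight_features is None:
            weight_features = weighting.build_weight_features(enc)
        w = weight_mlp(weight_features)
    x = features.build_input_tensor(
        enc, weights=w, extra_features=model.config.uses_extra_features
    )
    return model(x), w


@dataclass
class TrainResult:
    """Loss traces and best-epoch snapshots from one training run."""

    train_trace: list[LossBreakdown] = field(default_factory=list)
    val_trace: list[LossBreakdown] = field(default_factory=list)
    best_epoch: dict = field(default_factory=dict)  # per task
    best_state: dict = field(default_factory=dict)  # per task: (model, mlp) states

    def log_tsv(self) -> str:
        lines = ["epoch\tsplit\tcontact\tss\tasa\ttotal"]
        for split, trace in (("train", self.train_trace), ("val", self.val_trace)):
            for epoch, lb in enumerate(trace):
                lines.append(
                    f"{epoch}\t{split}\t{lb.contact_loss:.6f}\t{lb.ss_loss:.6f}"
                    f"\t{lb.asa_loss:.6f}\t{lb.total:.6f}"
                )
        return "\n".join(lines) + "\n"


def _mean_breakdown(items: list[LossBreakdown]) -> LossBreakdown:
    n = max(len(items), 1)
    return LossBreakdown(
        contact_loss=sum(b.contact_loss for b in items) / n,
        ss_loss=sum(b.ss_loss for b in items) / n,
        asa_loss=sum(b.asa_loss for b in items) / n,
    )


def evaluate_losses(model, dataset, config, weight_mlp=None) -> LossBreakdown:
    """Mean per-protein validation losses (no cropping/sampling, eval mode)."""
    model.eval()
    if weight_mlp is not None:
        weight_mlp.eval()
    out = []
    for sample in dataset:
        outputs, _ = forward_sample(model, sample.enc, weight_mlp)
        _, breakdown = total_loss(sample.labels, outputs, config)
        out.append(breakdown)
    model.train()
    if weight_mlp is not None:
        weight_mlp.train()
    return _mean_breakdown(out)


def train(
    model: ContactNetwork,
    dataset: list[ProteinSample],
    config: TrainConfig,
    weight_mlp: weighting.WeightMLP | None = None,
    val_dataset: list[ProteinSample] | None = None,
) -> TrainResult:
    """ADAM training, one protein per optimizer step, deterministic in seed.

    Depth sampling and window cropping are re-drawn each epoch (training
    only).  If `val_dataset` is given, per-task best epochs and parameter
    snapshots are tracked (contact and SS may converge at different
    epochs).  Aborts on non-finite loss.
    """
    params = list(model.parameters())
    if weight_mlp is not None:
        params += weight_mlp.parameters()
    optimizer = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    result = TrainResult()
    tasks = ("contact", "ss", "asa") if model.config.is_multitask else ("contact",)
    best_val = {t: np.inf for t in tasks}
    for epoch in range(config.epochs):
        epoch_losses = []
        for idx in rng.permutation(len(dataset)):
            sample = dataset[idx]
            enc = msa.sample_sequences(sample.enc, config.max_depth, rng)
            enc, labels_cropped = msa.crop_window(enc, sample.labels, config.max_len, rng)
            outputs, _ = forward_sample(model, enc, weight_mlp)
            loss, breakdown = total_loss(labels_cropped, outputs, config)
            if not np.isfinite(breakdown.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, protein "
                    f"{sample.identifier or idx}: {breakdown}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(breakdown)
        result.train_trace.append(_mean_breakdown(epoch_losses))
        if val_dataset is not None:
            val = evaluate_losses(model, val_dataset, config, weight_mlp)
            result.val_trace.append(val)
            per_task = {"contact": val.contact_loss, "ss": val.ss_loss, "asa": val.asa_loss}
            for task in tasks:
                if per_task[task] < best_val[task]:
                    best_val[task] = per_task[task]
                    result.best_epoch[task] = epoch
                    result.best_state[task] = (
                        model.state_dict(),
                        weight_mlp.state_dict() if weight_mlp is not None else None,
                    )
    return result


# ------------------------------------------------------------------ ensemble


def ensemble_predict(models, x_or_enc, weight_mlps=None) -> PredictionBundle:
    """Arithmetic mean of the predictions of k fold models.

    `models` may be accompanied by per-fold weighting MLPs.  Accepts
    either a prebuilt input tensor or an EncodedAlignment (featurized
    per model, since weighted variants have model-specific weights).
    """
    models = list(models)
    if weight_mlps is None:
        weight_mlps = [None] * len(models)
    bundles = []
    for m, mlp in zip(models, weight_mlps):
        if isinstance(x_or_enc, msa.EncodedAlignment):
            m.eval()
            if mlp is not None:
                mlp.eval()
            outputs, _ = forward_sample(m, x_or_enc, mlp)
            bundles.append(PredictionBundle(
                contact_prob=outputs["contact"].data.copy(),
                ss_prob=outputs["ss"].data.copy() if "ss" in outputs else None,
                asa_pred=outputs["asa"].data.copy() if "asa" in outputs else None,
            ))
            m.train()
            if mlp is not None:
                mlp.train()
        else:
            bundles.append(m.predict(x_or_enc))
    k = len(bundles)
    mean = lambda arrs: None if arrs[0] is None else sum(arrs) / k  # noqa: E731
    return PredictionBundle(
        contact_prob=mean([b.contact_prob for b in bundles]),
        ss_prob=mean([b.ss_prob for b in bundles]),
        asa_pred=mean([b.asa_pred for b in bundles]),
    )
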