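"""High-level orchestration: the pipeline stages as plain functions.

The package is used from Python, so the pipeline surface is functional:
``simulate``, ``featurize``, ``train_folds``, ``predict``, ``evaluate``
and ``ensemble`` mirror the stages of a contact-prediction run.  Each
stage that writes to disk drops a ``manifest.json`` (config + seeds)
next to its outputs so any run can be reproduced exactly.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import features, metrics, msa, weighting
from .model import ContactNetwork, ModelConfig, PredictionBundle
from .synthetic import SyntheticSpec, SyntheticSuite, make_suite, write_suite
from .training import ProteinSample, TrainConfig, ensemble_predict, train


def _write_manifest(out_dir: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["python"] = sys.version.split()[0]
    payload["numpy"] = np.__version__
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def simulate(spec: SyntheticSpec, out_dir=None, n_folds: int = 5) -> SyntheticSuite:
    """Generate a synthetic suite; optionally write it to standard formats."""
    suite = make_suite(spec, n_folds=n_folds)
    if out_dir is not None:
        write_suite(suite, out_dir)
    return suite


def featurize(enc: msa.EncodedAlignment, variant: str = "baseline",
              weight_mlp=None, out_path=None):
    """Model-input tensor (C, L, L) for one alignment; optionally cached
    as .npz with the channel-order manifest."""
    config = ModelConfig(variant=variant)
    w = None
    if weight_mlp is not None:
        w = weight_mlp(weighting.build_weight_features(enc))
    x = features.build_input_tensor(enc, weights=w,
                                    extra_features=config.uses_extra_features)
    x_arr = x.data if hasattr(x, "data") else np.asarray(x)
    if out_path is not None:
        np.savez_compressed(
            out_path, input=x_arr,
            channels=json.dumps(features.channel_manifest()),
        )
    return x_arr


def samples_from_suite(proteins) -> list[ProteinSample]:
    return [
        ProteinSample(enc=p.enc, labels=p.labels, identifier=p.identifier)
        for p in proteins
    ]


def train_folds(
    suite: SyntheticSuite,
    model_config: ModelConfig,
    train_config: TrainConfig,
    folds=None,
    out_dir=None,
):
    """Train one model per cross-validation fold (fold f held out).

    Returns (models, weight_mlps, results) aligned by fold.  The weighted
    variants get a fresh weighting MLP per fold, trained jointly.
    """
    folds = range(len(suite.folds)) if folds is None else folds
    models, mlps, results = [], [], []
    for f in folds:
        train_set, val_set = suite.fold_split(f)
        model = ContactNetwork(model_config, seed=train_config.seed + 1000 + f)
        mlp = None
        if model_config.variant in ("weighted", "feature_added", "multitask"):
            mlp = weighting.WeightMLP(seed=train_config.seed + 2000 + f)
        fold_config = TrainConfig(**{**asdict(train_config), "seed": train_config.seed + f})
        result = train(
            model,
            samples_from_suite(train_set),
            fold_config,
            weight_mlp=mlp,
            val_dataset=samples_from_suite(val_set),
        )
        models.append(model)
        mlps.append(mlp)
        results.append(result)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            with open(out_dir / f"fold{f}_losses.tsv", "w") as fh:
                fh.write(result.log_tsv())
    if out_dir is not None:
        _write_manifest(Path(out_dir), {
            "model_config": asdict(model_config),
            "train_config": asdict(train_config),
            "synthetic_spec": asdict(suite.spec),
        })
    return models, mlps, results


def predict(model: ContactNetwork, enc: msa.EncodedAlignment,
            weight_mlp=None, target: str = "T0000"):
    """Full-alignment prediction (no cropping/sampling) plus RR text."""
    from .training import forward_sample

    model.eval()
    if weight_mlp is not None:
        weight_mlp.eval()
    outputs, _ = forward_sample(model, enc, weight_mlp)
    model.train()
    if weight_mlp is not None:
        weight_mlp.train()
    bundle = PredictionBundle(
        contact_prob=outputs["contact"].data.copy(),
        ss_prob=outputs["ss"].data.copy() if "ss" in outputs else None,
        asa_pred=outputs["asa"].data.copy() if "asa" in outputs else None,
    )
    pairs = metrics.select_top_contacts(bundle.contact_prob)
    sequence = msa.decode(enc).query
    rr_text = metrics.write_casp_rr(pairs, sequence, target=target)
    return bundle, rr_text


def ensemble(models, enc: msa.EncodedAlignment, weight_mlps=None) -> PredictionBundle:
    """Fold-averaged prediction for one alignment."""
    return ensemble_predict(models, enc, weight_mlps)


def evaluate(bundles, proteins, out_path=None) -> dict:
    """Per-protein MetricReports plus mean top-L/k precision per bin."""
    per_protein = {}
    for bundle, protein in zip(bundles, proteins):
        per_protein[protein.identifier] = metrics.full_report(
            bundle, protein.labels, restypes=protein.coords.restypes
        )
    summary: dict = {}
    for bin_name in metrics.RANGE_BINS:
        summary[bin_name] = {}
        for k in metrics.TOP_K_VALUES:
            vals = [
                rep["contact"][bin_name][f"L/{k}"]
                for rep in per_protein.values()
                if rep["contact"][bin_name][f"L/{k}"] is not None
            ]
            summary[bin_name][f"L/{k}"] = float(np.mean(vals)) if vals else None
    report = {"mean_precision": summary, "per_protein": per_protein}
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
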