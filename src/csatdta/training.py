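"""Seeded training and evaluation of the affinity regressor.

Training minimises the mean squared error with the configured optimizer
(Adadelta by default, initial learning rate and batch size from the model
configuration), monitors validation MSE for early stopping, and keeps the
best-validation weights.  Runs are reproducible: the shuffle order, the
dropout masks and the weight initialisation all derive from the configured
seed, and the whole pipeline is single-threaded numpy.

Checkpoints are single ``.npz`` archives holding every weight, the batch
normalisation statistics, the full model configuration and both
vocabularies, so prediction needs nothing but the checkpoint file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from .datasets import AffinityRecord, DatasetSplit
from .metrics import EvaluationReport, UndefinedConcordanceError, concordance_index
from .model import AffinityModel, ModelConfig, build_model
from .vocab import TokenVocabulary, build_protein_vocabulary, build_smiles_vocabulary
from .encoding import encode_protein, encode_smiles

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingRun",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# optimizers


class _Optimizer:
    def __init__(self, params: dict[str, Tensor]):
        self.params = params

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        raise NotImplementedError


class _SGD(_Optimizer):
    def __init__(self, params, lr: float):
        super().__init__(params)
        self.lr = lr

    def step(self) -> None:
        for p in self.params.values():
            if p.grad is not None:
                p.data -= self.lr * p.grad


class _Adadelta(_Optimizer):
    """Adaptive-delta optimizer (accumulated squared gradients and updates)."""

    def __init__(self, params, lr: float, rho: float = 0.95, eps: float = 1e-6):
        super().__init__(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.acc_g = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.acc_d = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.acc_g[k] = self.rho * self.acc_g[k] + (1 - self.rho) * g * g
            update = (
                np.sqrt(self.acc_d[k] + self.eps)
                / np.sqrt(self.acc_g[k] + self.eps)
            ) * g
            self.acc_d[k] = self.rho * self.acc_d[k] + (1 - self.rho) * update * update
            p.data -= self.lr * update


class _Adam(_Optimizer):
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _make_optimizer(name: str, params: dict[str, Tensor], lr: float) -> _Optimizer:
    if name == "adadelta":
        return _Adadelta(params, lr)
    if name == "adam":
        return _Adam(params, lr)
    if name == "sgd":
        return _SGD(params, lr)
    raise ValueError(f"unknown optimizer {name!r}")


# ---------------------------------------------------------------------------
# encoding cache: records usually repeat few unique drugs/proteins


def _encode_unique(records, drug_max_len: int, protein_max_len: int):
    smiles = sorted({r.smiles for r in records})
    seqs = sorted({r.sequence for r in records})
    d_map = {s: i for i, s in enumerate(smiles)}
    p_map = {s: i for i, s in enumerate(seqs)}
    d_mat = np.stack([encode_smiles(s, max_len=drug_max_len).tokens for s in smiles])
    p_mat = np.stack([encode_protein(s, max_len=protein_max_len).tokens for s in seqs])
    d_idx = np.array([d_map[r.smiles] for r in records])
    p_idx = np.array([p_map[r.sequence] for r in records])
    y = np.array([r.affinity for r in records], dtype=np.float64)
    return d_mat, p_mat, d_idx, p_idx, y


@dataclass
class TrainingRun:
    """History and outcome of one training run."""

    config: ModelConfig
    split: DatasetSplit
    history: dict[str, list[float]] = field(default_factory=dict)
    best_checkpoint: Path | None = None
    model: AffinityModel | None = None
    wall_seed: int = 0


def _predict_indexed(model, d_mat, p_mat, d_idx, p_idx, batch_size=256):
    out = np.empty(len(d_idx))
    for s in range(0, len(d_idx), batch_size):
        sl = slice(s, s + batch_size)
        out[sl] = model.predict_batch(d_mat[d_idx[sl]], p_mat[p_idx[sl]])
    return out


def train(
    records: list[AffinityRecord],
    config: ModelConfig,
    split: DatasetSplit,
    out_dir: str | Path | None = None,
    log_every: int = 1,
) -> TrainingRun:
    """Train a model on the train indices of ``split``.

    If the split has no validation indices, one sixth of the train indices
    (seeded) is carved out to monitor early stopping.  Returns the run with
    the best-validation model restored.
    """
    config.validate()
    if not split.train:
        raise ValueError("empty train split")
    train_idx = np.array(split.train)
    val_idx = np.array(split.validation, dtype=int)
    if val_idx.size == 0:
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(train_idx)
        n_val = max(1, len(train_idx) // 6)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        logger.info("carved %d validation pairs out of the train split", n_val)

    d_mat, p_mat, d_idx, p_idx, y = _encode_unique(
        records, config.drug_branch.max_len, config.protein_branch.max_len
    )
    model = build_model(config)
    # learn on standardised targets; predictions are de-standardised by the
    # stored affine so reports stay on the affinity scale
    model.target_center = float(np.mean(y[train_idx]))
    model.target_scale = float(np.std(y[train_idx])) or 1.0
    model.affinity_scale = records[0].scale
    y_std = (y - model.target_center) / model.target_scale
    opt = _make_optimizer(
        config.optimizer_name, model.parameters(), config.learning_rate
    )
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5F]).generate_state(1)[0]
    )

    history: dict[str, list[float]] = {
        "train_mse": [], "val_mse": [], "val_ci": []
    }
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    patience_left = config.early_stop_patience
    out_path = Path(out_dir) / "best.npz" if out_dir is not None else None
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)

    for epoch in range(1, config.epochs + 1):
        order = shuffle_rng.permutation(train_idx)
        epoch_losses = []
        for s in range(0, len(order), config.batch_size):
            batch = order[s : s + config.batch_size]
            pred = model.forward(
                d_mat[d_idx[batch]], p_mat[p_idx[batch]], training=True
            )
            target = Tensor(y_std[batch])
            loss = ((pred - target) ** 2.0).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            # record on the affinity scale, not the standardised one
            epoch_losses.append(float(loss.data) * model.target_scale**2)

        val_pred = _predict_indexed(model, d_mat, p_mat, d_idx[val_idx], p_idx[val_idx])
        val_mse = float(np.mean((val_pred - y[val_idx]) ** 2))
        try:
            val_ci = concordance_index(y[val_idx], val_pred)
        except UndefinedConcordanceError:
            val_ci = float("nan")
        history["train_mse"].append(float(np.mean(epoch_losses)))
        history["val_mse"].append(val_mse)
        history["val_ci"].append(val_ci)
        if epoch % log_every == 0:
            logger.info(
                "epoch %3d  train MSE %.4f  val MSE %.4f  val CI %.4f",
                epoch, history["train_mse"][-1], val_mse, val_ci,
            )
        if val_mse < best_val:
            best_val = val_mse
            best_state = model.state_dict()
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                logger.info("early stopping at epoch %d", epoch)
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.epochs_trained = len(history["train_mse"])
    model.best_validation_loss = float(best_val)
    if out_path is not None:
        save_checkpoint(model, out_path)
        (Path(out_dir) / "history.json").write_text(json.dumps(history))
    return TrainingRun(
        config=config,
        split=DatasetSplit(
            train=tuple(int(i) for i in train_idx),
            validation=tuple(int(i) for i in val_idx),
            test=split.test,
            fold_id=split.fold_id,
            seed=split.seed,
        ),
        history=history,
        best_checkpoint=out_path,
        model=model,
        wall_seed=config.seed,
    )


def evaluate(model: AffinityModel, records: list[AffinityRecord]) -> EvaluationReport:
    """CI, MSE and RMSE of the model on the given records."""
    if not records:
        raise ValueError("no records to evaluate")
    d_mat, p_mat, d_idx, p_idx, y = _encode_unique(
        records,
        model.config.drug_branch.max_len,
        model.config.protein_branch.max_len,
    )
    pred = _predict_indexed(model, d_mat, p_mat, d_idx, p_idx)
    return EvaluationReport.from_batch(pred, y)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: AffinityModel, path: str | Path) -> None:
    """Write a self-describing single-archive checkpoint (.npz)."""
    payload = {f"param:{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(model.config.to_dict()))
    payload["affinity_scale"] = np.array(model.affinity_scale)
    payload["smiles_vocab_json"] = np.array(build_smiles_vocabulary().to_json())
    payload["protein_vocab_json"] = np.array(build_protein_vocabulary().to_json())
    np.savez_compressed(path, **payload)


def load_checkpoint(
    path: str | Path,
) -> tuple[AffinityModel, TokenVocabulary, TokenVocabulary]:
    """Rebuild model and vocabularies from a checkpoint archive."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as archive:
        config = ModelConfig.from_dict(json.loads(str(archive["config_json"])))
        model = build_model(config)
        state = {
            k[len("param:"):]: archive[k]
            for k in archive.files
            if k.startswith("param:")
        }
        model.load_state_dict(state)
        if "affinity_scale" in archive.files:
            model.affinity_scale = str(archive["affinity_scale"])
        smiles_vocab = TokenVocabulary.from_json(str(archive["smiles_vocab_json"]))
        protein_vocab = TokenVocabulary.from_json(str(archive["protein_vocab_json"]))
    return model, smiles_vocab, protein_vocab
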