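"""Dual-branch convolutional affinity regressor and its training protocol.

Each branch — one for the 36x36 molecule signature image, one for the 97x97
protein image — is three (valid 3x3 convolution + ReLU, 2x2 max-pool) blocks
followed by a flatten.  The flattened branch outputs are concatenated (width
128 + 3200 = 3328 under the defaults) and fed to a dense head: dropout 0.4,
dense 512 ReLU, dropout 0.4, dense 1 linear.  Training minimizes MSE with
Adam (lr 1e-3, beta1 0.9, beta2 0.999, eps 1e-7) at batch size 256.

The per-fold protocol is two-phase: phase 1 trains on the fold's four
training parts with the fifth as validation and persists the weights; phase 2
evaluates the persisted model on the held-out test part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .dataset_io import ExperimentPlan, InteractionTable
from .encoder import MOLECULE_SPACE, PROTEIN_SPACE, count_kmers, normalize, to_image
from .metrics import evaluate_predictions

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["mse", "ci", "rm2", "aupr", "acc"]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of the dual-branch network.

    The defaults (3x3 valid convolutions, 2x2 pools, 32 filters per
    convolution) make the molecule branch flatten to 2*2*32 = 128 and the
    protein branch to 10*10*32 = 3200, so the concatenation is 3328 wide.
    ``strict_concat`` rejects any configuration whose concatenation width
    differs from that value.
    """

    mol_shape: tuple[int, int] = (36, 36)
    prot_shape: tuple[int, int] = (97, 97)
    kernel: int = 3
    filters: tuple[int, int, int] = (32, 32, 32)
    dense_width: int = 512
    dropout_rate: float = 0.4
    strict_concat: bool = False

    REFERENCE_CONCAT_WIDTH = 3328

    def branch_flat_width(self, side: int) -> int:
        """Flatten width of one branch: three conv(valid)+pool(2) blocks."""
        s = side
        for _ in self.filters:
            s = (s - self.kernel + 1) // 2
            if s < 1:
                raise ValueError(
                    f"input side {side} is too small for three conv+pool blocks"
                )
        return s * s * self.filters[-1]

    @property
    def concat_width(self) -> int:
        return self.branch_flat_width(self.mol_shape[0]) + self.branch_flat_width(
            self.prot_shape[0]
        )

    def validate(self) -> None:
        if self.mol_shape[0] != self.mol_shape[1] or self.prot_shape[0] != self.prot_shape[1]:
            raise ValueError("input images must be square")
        if self.strict_concat and self.concat_width != self.REFERENCE_CONCAT_WIDTH:
            raise ValueError(
                f"strict mode: computed concatenation width {self.concat_width} "
                f"!= required {self.REFERENCE_CONCAT_WIDTH}"
            )


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and schedule settings; defaults follow the training protocol
    except for the epoch count, which is overridable for desk-scale runs."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    batch_size: int = 256
    epochs: int = 1000
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")


class DualBranchCNN:
    """The two-branch regression network; built via :func:`build_model`."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.mol_branch = self._make_branch(rng)
        self.prot_branch = self._make_branch(rng)
        self.head = nn.Sequential(
            [
                nn.Dropout(spec.dropout_rate, rng),
                nn.Dense(spec.concat_width, spec.dense_width, rng),
                nn.ReLU(),
                nn.Dropout(spec.dropout_rate, rng),
                nn.Dense(spec.dense_width, 1, rng),
            ]
        )
        self._mol_flat = spec.branch_flat_width(spec.mol_shape[0])

    def _make_branch(self, rng: np.random.Generator) -> nn.Sequential:
        spec = self.spec
        layers: list[nn.Layer] = []
        c_in = 1
        for c_out in spec.filters:
            layers += [nn.Conv2D(c_in, c_out, spec.kernel, rng), nn.ReLU(), nn.MaxPool2D()]
            c_in = c_out
        layers.append(nn.Flatten())
        return nn.Sequential(layers)

    @property
    def concat_width(self) -> int:
        return self.spec.concat_width

    def forward(self, x_mol: np.ndarray, x_prot: np.ndarray, train: bool = False) -> np.ndarray:
        fm = self.mol_branch.forward(x_mol, train=train)
        fp = self.prot_branch.forward(x_prot, train=train)
        z = np.concatenate([fm, fp], axis=1)
        return self.head.forward(z, train=train)[:, 0]

    def backward(self, grad_out: np.ndarray) -> None:
        gz = self.head.backward(grad_out[:, None])
        self.mol_branch.backward(gz[:, : self._mol_flat])
        self.prot_branch.backward(gz[:, self._mol_flat :])

    def forward_indexed(
        self,
        mol_unique: np.ndarray,
        prot_unique: np.ndarray,
        mol_inv: np.ndarray,
        prot_inv: np.ndarray,
        train: bool = False,
    ) -> np.ndarray:
        """Forward pass over pairs that share entities: each unique image
        goes through its branch once and the flattened features are gathered
        per pair.  Mathematically identical to :meth:`forward` on the
        expanded batch, at a fraction of the convolution cost."""
        fm = self.mol_branch.forward(mol_unique, train=train)[mol_inv]
        fp = self.prot_branch.forward(prot_unique, train=train)[prot_inv]
        if train:
            self._inv = (mol_inv, prot_inv, mol_unique.shape[0], prot_unique.shape[0])
        z = np.concatenate([fm, fp], axis=1)
        return self.head.forward(z, train=train)[:, 0]

    def backward_indexed(self, grad_out: np.ndarray) -> None:
        """Backward companion of :meth:`forward_indexed`: per-pair feature
        gradients are scatter-added onto each unique entity before the
        branch backward pass."""
        mol_inv, prot_inv, n_mol, n_prot = self._inv
        gz = self.head.backward(grad_out[:, None])
        gm = np.zeros((n_mol, self._mol_flat), dtype=np.float32)
        np.add.at(gm, mol_inv, gz[:, : self._mol_flat])
        gp = np.zeros((n_prot, gz.shape[1] - self._mol_flat), dtype=np.float32)
        np.add.at(gp, prot_inv, gz[:, self._mol_flat :])
        self.mol_branch.backward(gm)
        self.prot_branch.backward(gp)

    def predict(self, x_mol: np.ndarray, x_prot: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference in batches (dropout inactive)."""
        out = np.empty(x_mol.shape[0], dtype=np.float64)
        for lo in range(0, x_mol.shape[0], batch_size):
            hi = lo + batch_size
            out[lo:hi] = self.forward(x_mol[lo:hi], x_prot[lo:hi], train=False)
        return out

    def predict_indexed(
        self,
        mol_images: np.ndarray,
        prot_images: np.ndarray,
        drug_idx: np.ndarray,
        target_idx: np.ndarray,
        batch_size: int = 256,
    ) -> np.ndarray:
        """Inference over (drug, target) index pairs with per-entity reuse."""
        out = np.empty(drug_idx.shape[0], dtype=np.float64)
        for lo in range(0, drug_idx.shape[0], batch_size):
            hi = lo + batch_size
            ud, mi = np.unique(drug_idx[lo:hi], return_inverse=True)
            ut, pi = np.unique(target_idx[lo:hi], return_inverse=True)
            out[lo:hi] = self.forward_indexed(
                mol_images[ud], prot_images[ut], mi, pi, train=False
            )
        return out

    def params(self) -> list[np.ndarray]:
        return self.mol_branch.params() + self.prot_branch.params() + self.head.params()

    def grads(self) -> list[np.ndarray]:
        return self.mol_branch.grads() + self.prot_branch.grads() + self.head.grads()

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w

    def save_weights(self, path: str) -> None:
        np.savez(path, *self.params())

    def load_weights(self, path: str) -> None:
        with np.load(path) as data:
            self.set_weights([data[k] for k in data.files])


def build_model(spec: ArchitectureSpec | None = None, seed: int = 0) -> DualBranchCNN:
    """Instantiate the dual-branch network with seeded initialization."""
    return DualBranchCNN(spec or ArchitectureSpec(), seed=seed)


@dataclass
class PairTensors:
    """Encoded dataset: per-entity image stacks plus interaction triples."""

    mol_images: np.ndarray  # (n_drugs, 36, 36, 1) float32
    prot_images: np.ndarray  # (n_targets, 97, 97, 1) float32
    drug_idx: np.ndarray  # (n_interactions,)
    target_idx: np.ndarray
    affinity: np.ndarray  # (n_interactions,) float64
    kind: str

    def gather(self, which: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            self.mol_images[self.drug_idx[which]],
            self.prot_images[self.target_idx[which]],
            self.affinity[which],
        )


def prepare_tensors(table: InteractionTable) -> PairTensors:
    """Encode every unique drug and target once and index interactions into
    the resulting image stacks."""

    def stack(records, space):
        images = np.empty((len(records), space.m, space.m, 1), dtype=np.float32)
        for i, rec in enumerate(records):
            img = to_image(normalize(count_kmers(rec, space)), space)
            images[i, :, :, 0] = img.pixels
        return images

    rows, cols = table.interaction_indices()
    return PairTensors(
        mol_images=stack(table.drugs, MOLECULE_SPACE),
        prot_images=stack(table.targets, PROTEIN_SPACE),
        drug_idx=rows,
        target_idx=cols,
        affinity=table.affinity[rows, cols].astype(np.float64),
        kind=table.kind,
    )


@dataclass
class FoldResult:
    model: DualBranchCNN
    history: pd.DataFrame  # per-epoch train/validation loss
    test_metrics: dict[str, float]
    predictions: np.ndarray  # on the held-out test part


def _epoch_minibatches(n: int, batch_size: int, rng: np.random.Generator, shuffle: bool):
    order = rng.permutation(n) if shuffle else np.arange(n)
    for lo in range(0, n, batch_size):
        yield order[lo : lo + batch_size]


def train_fold(
    model: DualBranchCNN,
    tensors: PairTensors,
    plan: ExperimentPlan,
    fold: int,
    config: TrainingConfig,
    checkpoint_path: str | None = None,
) -> FoldResult:
    """Run the two-phase per-fold protocol.

    Phase 1 trains on the four training parts of *fold* with the fifth part
    as validation, recording per-epoch losses, and persists the final
    weights.  Phase 2 evaluates the persisted model on the held-out test
    part and reports the full metric suite.
    """
    train_idx = plan.train_indices(fold)
    val_idx = plan.validation_indices(fold)
    test_idx = plan.test_indices()
    for name, idx in (("train", train_idx), ("validation", val_idx), ("test", test_idx)):
        if idx.size == 0:
            raise ValueError(f"{name} split of fold {fold} is empty")

    d_tr, t_tr, y_tr = tensors.drug_idx[train_idx], tensors.target_idx[train_idx], tensors.affinity[train_idx]
    d_va, t_va, y_va = tensors.drug_idx[val_idx], tensors.target_idx[val_idx], tensors.affinity[val_idx]
    d_te, t_te, y_te = tensors.drug_idx[test_idx], tensors.target_idx[test_idx], tensors.affinity[test_idx]

    # start the regression head at the training-target mean
    model.head.layers[-1].b[...] = np.float32(y_tr.mean())

    opt = nn.Adam(
        model.params(),
        model.grads(),
        lr=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        eps=config.eps,
    )
    rng = np.random.default_rng(config.seed)
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    n = train_idx.size
    for epoch in range(1, config.epochs + 1):
        sq_sum = 0.0
        for batch in _epoch_minibatches(n, config.batch_size, rng, config.shuffle):
            ud, mol_inv = np.unique(d_tr[batch], return_inverse=True)
            ut, prot_inv = np.unique(t_tr[batch], return_inverse=True)
            pred = model.forward_indexed(
                tensors.mol_images[ud], tensors.prot_images[ut],
                mol_inv, prot_inv, train=True,
            )
            resid = pred - y_tr[batch]
            sq_sum += float((resid**2).sum())
            model.backward_indexed((2.0 / batch.size * resid).astype(np.float32))
            opt.step()
        val_pred = model.predict_indexed(
            tensors.mol_images, tensors.prot_images, d_va, t_va,
            batch_size=config.batch_size,
        )
        tr_loss = sq_sum / n
        va_loss = float(np.mean((val_pred - y_va) ** 2))
        history["epoch"].append(epoch)
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(va_loss)
        logger.info("fold %d epoch %d: train %.5f val %.5f", fold, epoch, tr_loss, va_loss)

    if checkpoint_path is not None:
        model.save_weights(checkpoint_path)
        model.load_weights(checkpoint_path)

    test_pred = model.predict_indexed(
        tensors.mol_images, tensors.prot_images, d_te, t_te,
        batch_size=config.batch_size,
    )
    metrics = evaluate_predictions(y_te, test_pred, tensors.kind)
    return FoldResult(
        model=model,
        history=pd.DataFrame(history),
        test_metrics=metrics,
        predictions=test_pred,
    )


def cross_validate(
    table: InteractionTable,
    plan: ExperimentPlan,
    spec: ArchitectureSpec | None = None,
    config: TrainingConfig | None = None,
) -> pd.DataFrame:
    """Train one model per fold and tabulate held-out test metrics.

    Returns one row per fold plus ``mean`` and ``std`` summary rows, the
    shape of a cross-validated benchmark report.
    """
    spec = spec or ArchitectureSpec()
    config = config or TrainingConfig()
    tensors = prepare_tensors(table)
    rows = []
    for fold in range(plan.n_folds):
        model = build_model(spec, seed=config.seed + fold)
        result = train_fold(
            model, tensors, plan, fold, replace(config, seed=config.seed + fold)
        )
        rows.append({"fold": str(fold), **result.test_metrics})
    report = pd.DataFrame(rows).set_index("fold")[
        [c for c in METRIC_COLUMNS + ["r2"] if c in rows[0]]
    ]
    summary = pd.DataFrame(
        {"mean": report.mean(), "std": report.std(ddof=0)}
    ).T
    return pd.concat([report, summary])
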