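"""End-to-end composition: configuration, model, training, pretraining, prediction.

The full model runs each molecule through the 3D transformer branch (per-atom
features z1 from atom types + geometry) and the selective state-space sequence
branch (per-token features z2 from the SMILES string), gathers z2 at the atom
token positions (z2'), and feeds the fused per-atom features to the
mol-attention block for a bounded regression output that an affine label scaler
maps to log2 transfection-efficiency units.

Training minimizes the hybrid loss MSE + beta * triplet on the training split,
selects the best checkpoint by validation MSE, and reports MSE/MAE/R^2/PCC on
the test split.  All randomness (weight init, batch order, conformers,
corruption) derives from the config seed; repeated runs are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import chemio, encoder3d, fusion, losses, mambaseq
from .chemio import LipidRecord
from .minigrad import no_grad
from .nn import Adam, Module
from .splits import SplitAssignment

__all__ = ["RunConfig", "TransfectionModel", "TrainResult", "train", "pretrain", "predict",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class RunConfig:
    """All knobs of the model and training loop (serialized into every artifact).

    Defaults mirror the reference configuration (batch 4, 200 epochs, initial
    learning rate 1e-5, sequence branch width 512 x 2 layers, beta 6 for
    scaffold / 3 for cliff splitting).  ``desk()`` returns a reduced profile
    (width 128) for laptop-scale experiments and CI.
    """

    # model
    width: int = 512
    layers_3d: int = 6
    n_heads: int = 8
    n_kernels: int = 32
    mamba_layers: int = 2
    state_dim: int = 16
    conv_kernel: int = 4
    vocab_size: int = 100
    r: int = 2
    pool: str = "mean"
    # pretraining
    mask_rate: float = 0.15
    noise_halfwidth: float = 1.0
    pretrain_weights: tuple[float, float, float] = (1.0, 5.0, 10.0)
    # loss
    beta: float = 6.0
    margin: float = 1.0
    tau: float = 1.0
    eps: float = 1e-16
    # optimization
    batch_size: int = 4
    epochs: int = 200
    lr: float = 1e-5
    grad_clip: float = 1.0
    # provenance
    split_method: str = "scaffold"
    seed: int = 0

    @classmethod
    def desk(cls, **overrides) -> "RunConfig":
        """Reduced-width profile: same architecture, desk-scale budget."""
        base = dict(
            width=128, layers_3d=2, n_heads=4, n_kernels=16, state_dim=8,
            batch_size=8, epochs=40, lr=2e-3,
        )
        base.update(overrides)
        return cls(**base)

    def fused_width(self) -> int:
        return 2 * self.width

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=list)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def with_beta_for(self, split_method: str) -> "RunConfig":
        """beta = 6 under scaffold splitting, 3 under cliff splitting."""
        beta = 6.0 if split_method == "scaffold" else 3.0
        return replace(self, beta=beta, split_method=split_method)


class TransfectionModel(Module):
    """Two-branch encoder + mol-attention fusion head."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.encoder_3d = encoder3d.Encoder3D(
            width=config.width,
            n_layers=config.layers_3d,
            n_heads=config.n_heads,
            n_kernels=config.n_kernels,
            seed=config.seed,
        )
        self.encoder_seq = mambaseq.MambaEncoder(
            width=config.width,
            n_layers=config.mamba_layers,
            vocab_size=config.vocab_size,
            state_dim=config.state_dim,
            conv_kernel=config.conv_kernel,
            seed=config.seed,
        )
        self.head = fusion.MolAttentionBlock(
            fused_width=config.fused_width(),
            r=config.r,
            reg_hidden=config.width,
            pool=config.pool,
            seed=config.seed,
        )
        self.scaler: fusion.LabelScaler | None = None

    def forward(self, rec3d: chemio.Molecule3DRecord, tokens: chemio.TokenizedSMILES):
        """Returns (raw prediction in (-1,1), atom scores, pooled z1, pooled z2')."""
        z1 = self.encoder_3d(rec3d)
        z2 = self.encoder_seq(tokens)
        z2p = fusion.align(z2, tokens.atom_positions)
        if z2p.shape[0] != z1.shape[0]:
            raise chemio.AlignmentError(
                f"{z2p.shape[0]} aligned sequence rows vs {z1.shape[0]} atoms"
            )
        raw, scores = self.head.predict_raw(z1, z2p)
        return raw, scores, z1.mean(axis=0), z2p.mean(axis=0)

    def predict_label(self, rec3d, tokens) -> float:
        if self.scaler is None:
            raise ValueError("label scaler missing: model has not been fitted/loaded")
        with no_grad():
            raw, _, _, _ = self.forward(rec3d, tokens)
        return float(self.scaler.to_label(raw.data[0]))

    def explain(self, rec3d, tokens) -> pd.DataFrame:
        with no_grad():
            z1 = self.encoder_3d(rec3d)
            z2p = fusion.align(self.encoder_seq(tokens), tokens.atom_positions)
            return self.head.explain(z1, z2p, rec3d.atom_symbols)


@dataclass
class TrainResult:
    checkpoint: dict
    log: list[dict] = field(default_factory=list)
    test_metrics: dict = field(default_factory=dict)


def _featurize_all(records: list[LipidRecord], seed: int) -> dict[str, tuple]:
    feats = {}
    for rec in records:
        rec3d = chemio.featurize_3d(rec, seed=seed)
        tokens = chemio.tokenize(rec)
        feats[rec.id] = (rec3d, tokens)
    return feats


def train(
    config: RunConfig,
    records: list[LipidRecord],
    split: SplitAssignment,
    log_path=None,
    init_state: dict | None = None,
) -> TrainResult:
    """Fit on the train split, select by validation MSE, evaluate on test."""
    by_id = {r.id: r for r in records}
    missing = [i for i in split.assignment if i not in by_id]
    if missing:
        raise ValueError(f"split references unknown ids: {missing[:5]}")
    train_ids = split.ids("train")
    val_ids = split.ids("val")
    test_ids = split.ids("test")
    labelled = [i for i in train_ids if by_id[i].label is not None]
    if len(labelled) != len(train_ids):
        raise ValueError("all training molecules must be labelled")

    model = TransfectionModel(config)
    if init_state is not None:
        _load_encoder3d_state(model, init_state)
    model.scaler = fusion.LabelScaler.fit([by_id[i].label for i in train_ids])
    feats = _featurize_all(records, seed=config.seed)

    rng = np.random.default_rng(config.seed + 1)
    n_steps = max(len(train_ids) // config.batch_size, 1) * config.epochs
    opt = Adam(model.parameters(), lr=config.lr, grad_clip=config.grad_clip,
               total_steps=n_steps)
    cfg_trip = losses.TripletConfig(
        margin=config.margin, beta=config.beta, eps=config.eps, tau=config.tau
    )
    log: list[dict] = []
    best = (np.inf, None)
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_ids))
        epoch_losses = []
        for start in range(0, len(order) - 1, config.batch_size):
            batch = [train_ids[i] for i in order[start : start + config.batch_size]]
            if len(batch) < 2:
                continue
            raws, z1s, z2s, raw_targets = [], [], [], []
            for mol_id in batch:
                rec3d, tokens = feats[mol_id]
                raw, _, z1p, z2p = model.forward(rec3d, tokens)
                raws.append(raw)
                z1s.append(z1p.reshape(1, -1))
                z2s.append(z2p.reshape(1, -1))
                raw_targets.append(model.scaler.to_raw(by_id[mol_id].label))
            from .minigrad import concat

            pred = concat(raws, axis=0)
            bank = losses.EmbeddingBank(
                z1=concat(z1s, axis=0),
                z2=concat(z2s, axis=0),
                labels=np.array([by_id[i].label for i in batch]),
            )
            total, comp = losses.hybrid_loss(pred, np.array(raw_targets), bank, cfg_trip)
            if not np.isfinite(total.data):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_losses.append(comp)
        val_mse = _eval_mse(model, feats, by_id, val_ids) if val_ids else np.nan
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean([c["total"] for c in epoch_losses])),
            "train_mse": float(np.mean([c["mse"] for c in epoch_losses])),
            "train_triplet": float(np.mean([c["triplet"] for c in epoch_losses])),
            "val_mse": float(val_mse),
            "lr": opt.current_lr(),
            "config_hash": config.hash(),
            "seed": config.seed,
        }
        log.append(row)
        select_mse = val_mse if val_ids else row["train_mse"]
        if select_mse < best[0]:
            best = (select_mse, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])

    test_metrics = {}
    if test_ids:
        preds = [model.predict_label(*feats[i]) for i in test_ids]
        truths = [by_id[i].label for i in test_ids]
        test_metrics = losses.metrics(preds, truths)
    checkpoint = {
        "state": model.state_dict(),
        "config": asdict(config),
        "config_hash": config.hash(),
        "scaler": model.scaler.to_dict(),
        "split_method": split.method,
        "split_seed": split.seed,
    }
    if log_path is not None:
        with open(log_path, "w") as fh:
            for row in log:
                fh.write(json.dumps(row) + "\n")
    return TrainResult(checkpoint=checkpoint, log=log, test_metrics=test_metrics)


def _eval_mse(model: TransfectionModel, feats, by_id, ids) -> float:
    preds = [model.predict_label(*feats[i]) for i in ids]
    truths = [by_id[i].label for i in ids]
    return float(np.mean((np.asarray(preds) - np.asarray(truths)) ** 2))


def _load_encoder3d_state(model: TransfectionModel, state: dict) -> None:
    own = dict(model.named_parameters())
    n_loaded = 0
    for name, arr in state.items():
        if name.startswith("encoder_3d.") and name in own:
            own[name].data = np.asarray(arr, dtype=np.float64).copy()
            n_loaded += 1
    if n_loaded == 0:
        warnings.warn("pretrained state contained no matching 3D-encoder parameters")


def pretrain(
    config: RunConfig,
    smiles_corpus: list[str],
    n_steps: int = 100,
    batch_size: int | None = None,
) -> dict:
    """Masked-atom / noisy-coordinate pretraining of the 3D encoder.

    Returns a checkpoint dict whose encoder weights `train` can load as
    initialization.  The corpus can be any unlabelled molecule set.
    """
    batch_size = batch_size or config.batch_size
    enc = encoder3d.Encoder3D(
        width=config.width, n_layers=config.layers_3d, n_heads=config.n_heads,
        n_kernels=config.n_kernels, seed=config.seed,
    )
    heads = encoder3d.PretrainHeads(config.width, seed=config.seed)
    recs = [chemio.featurize_3d(s, seed=config.seed) for s in smiles_corpus]
    params = list(enc.parameters()) + list(heads.parameters())
    opt = Adam(params, lr=1e-3, grad_clip=config.grad_clip)
    rng = np.random.default_rng(config.seed + 2)
    log = []
    warned_zero_rate = False
    for step in range(n_steps):
        idx = rng.choice(len(recs), size=min(batch_size, len(recs)), replace=False)
        total_step = None
        comps = []
        for i in idx:
            rec = recs[i]
            plan = encoder3d.corrupt(
                rec, config.mask_rate, config.noise_halfwidth,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            if config.mask_rate == 0 and not warned_zero_rate:
                warnings.warn("mask rate 0: type loss term is identically zero")
                warned_zero_rate = True
            z = enc(rec, masked_atoms=plan.masked_atom_indices, coords=plan.noisy_coords)
            pt, pc, pdists, truth = heads(z, plan, rec)
            loss, comp = encoder3d.pretrain_losses(
                pt, pc, pdists, truth, weights=config.pretrain_weights
            )
            comps.append(comp)
            total_step = loss if total_step is None else total_step + loss
        if not np.isfinite(total_step.data):
            raise RuntimeError(f"pretraining diverged at step {step}")
        opt.zero_grad()
        total_step.backward()
        opt.step()
        log.append({"step": step, **{k: float(np.mean([c[k] for c in comps])) for k in comps[0]}})
    state = {f"encoder_3d.{k}": v for k, v in enc.state_dict().items()}
    state.update({f"heads.{k}": v for k, v in heads.state_dict().items()})
    return {"state": state, "config": asdict(config), "config_hash": config.hash(), "log": log}


def masked_type_accuracy(checkpoint: dict, smiles_list: list[str], seed: int = 0) -> float:
    """Held-out masked-atom type accuracy of a pretrained 3D encoder."""
    config = RunConfig(**checkpoint["config"])
    enc = encoder3d.Encoder3D(
        width=config.width, n_layers=config.layers_3d, n_heads=config.n_heads,
        n_kernels=config.n_kernels, seed=config.seed,
    )
    heads = encoder3d.PretrainHeads(config.width, seed=config.seed)
    enc.load_state_dict({k[len("encoder_3d."):]: v for k, v in checkpoint["state"].items()
                         if k.startswith("encoder_3d.")})
    heads.load_state_dict({k[len("heads."):]: v for k, v in checkpoint["state"].items()
                           if k.startswith("heads.")})
    hits = total = 0
    for j, smiles in enumerate(smiles_list):
        rec = chemio.featurize_3d(smiles, seed=seed)
        plan = encoder3d.corrupt(rec, config.mask_rate, config.noise_halfwidth, seed=seed + j)
        with no_grad():
            z = enc(rec, masked_atoms=plan.masked_atom_indices, coords=plan.noisy_coords)
            logits = heads.type_head(z.take_rows(plan.masked_atom_indices))
        pred = logits.data.argmax(axis=1)
        truth = rec.atom_type_ids()[plan.masked_atom_indices]
        hits += int((pred == truth).sum())
        total += len(truth)
    return hits / max(total, 1)


# --------------------------------------------------------------------------
# checkpoint I/O and batch prediction
# --------------------------------------------------------------------------


def save_checkpoint(checkpoint: dict, path) -> None:
    meta = {k: v for k, v in checkpoint.items() if k != "state"}
    arrays = {f"param::{k}": v for k, v in checkpoint["state"].items()}
    np.savez(path, __meta__=json.dumps(meta, default=list), **arrays)


def load_checkpoint(path) -> dict:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
    meta["state"] = state
    return meta


def model_from_checkpoint(checkpoint: dict) -> TransfectionModel:
    config = RunConfig(**{**checkpoint["config"],
                          "pretrain_weights": tuple(checkpoint["config"]["pretrain_weights"])})
    model = TransfectionModel(config)
    model.load_state_dict(checkpoint["state"])
    if checkpoint.get("scaler"):
        model.scaler = fusion.LabelScaler.from_dict(checkpoint["scaler"])
    return model


def predict(checkpoint: dict, records: list[LipidRecord], explain: bool = False) -> pd.DataFrame:
    """One prediction per molecule, input order; unparseable rows are flagged."""
    model = model_from_checkpoint(checkpoint)
    config = model.config
    rows = []
    for rec in records:
        try:
            rec3d = chemio.featurize_3d(rec, seed=config.seed)
            tokens = chemio.tokenize(rec)
            pred = model.predict_label(rec3d, tokens)
            rows.append({"id": rec.id, "smiles": rec.smiles, "prediction": pred, "flag": ""})
        except (ValueError, chemio.AlignmentError) as exc:
            rows.append({"id": rec.id, "smiles": rec.smiles, "prediction": np.nan,
                         "flag": str(exc)})
    return pd.DataFrame(rows)
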