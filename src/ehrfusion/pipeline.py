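"""End-to-end orchestration: splitting, training, evaluation, ablations.

The training loop optimizes all components jointly — text encoder, semantic
projection, time-series transformer and fusion MLP — with Adam on the
hybrid BCE + hinge objective, mirroring the mini-batch procedure of the
model: sample a batch of patients, assemble each patient's clinical text
and temporal features, forward through both streams, fuse, and step.  The
split is always at patient level, validated programmatically against
leakage, and every source of randomness derives from the two seeds in the
run configuration, so identical inputs give bit-identical metric reports.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import nn
from .ehr_data import (
    LabelSpace,
    PatientRecord,
    PredictionInstance,
    extract_temporal_features,
    filter_min_visits,
    make_prediction_instances,
)
from .fusion import DEFAULT_HF_CODE, FusionMLP, make_task_head, predict
from .metrics import MetricReport, full_report
from .objectives import LossConfig, combined_loss
from .synthetic import DEFAULT_CODES
from .text_assembly import AssemblyConfig, assemble_input_text
from .text_encoder import CompactTextEncoder, EncoderConfig, SemanticProjection, tokenize
from .tst_encoder import Scaler, TSTConfig, TSTEncoder, apply_scaler, fit_scaler

logger = logging.getLogger(__name__)

ABLATIONS = ("full", "no-text", "no-labtext", "no-temporal")


@dataclass
class RunConfig:
    task: str = "multilabel-10"
    ablation: str = "full"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    tst: TSTConfig = field(default_factory=TSTConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    lr: float = 1e-4
    epochs: int = 10
    batch_size: int = 8
    split_seed: int = 0
    init_seed: int = 0
    threshold: float = 0.5
    expanding_window: bool = False
    hf_code: str = DEFAULT_HF_CODE

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; expected one of {ABLATIONS}")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")

    @property
    def use_text(self) -> bool:
        return self.ablation != "no-text"

    @property
    def use_temporal(self) -> bool:
        return self.ablation != "no-temporal"

    def resolved_assembly(self) -> AssemblyConfig:
        if self.ablation == "no-labtext":
            return replace(self.assembly, include_lab_text=False)
        return self.assembly

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_config_to_dict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return _config_from_dict(yaml.safe_load(fh) or {})


def _config_to_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["assembly"]["section_order"] = list(d["assembly"]["section_order"])
    return d


def _config_from_dict(d: dict) -> RunConfig:
    kwargs = dict(d)
    if "encoder" in kwargs:
        kwargs["encoder"] = EncoderConfig(**kwargs["encoder"])
    if "tst" in kwargs:
        kwargs["tst"] = TSTConfig(**kwargs["tst"])
    if "assembly" in kwargs:
        a = dict(kwargs["assembly"])
        if "section_order" in a:
            a["section_order"] = tuple(a["section_order"])
        kwargs["assembly"] = AssemblyConfig(**a)
    if "loss" in kwargs:
        kwargs["loss"] = LossConfig(**kwargs["loss"])
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# Patient-level splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # patient_id -> "train" | "val" | "test"

    def ids(self, split: str) -> list[str]:
        return [pid for pid, s in self.assignment.items() if s == split]

    def subset(self, cohort: list[PatientRecord], split: str) -> list[PatientRecord]:
        return [p for p in cohort if self.assignment[p.patient_id] == split]


def split_cohort(cohort: list[PatientRecord], seed: int) -> SplitAssignment:
    """Random patient-level 80/20 train/test, train side re-split 4:1 into
    train/val (net 64/16/20).  Counts follow floor rounding: n_test =
    floor(0.2 n), n_train = floor(0.8 (n - n_test)), validation the rest."""
    n = len(cohort)
    if n < 5:
        raise ValueError(f"cohort has {n} patients; need at least 5 to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = math.floor(0.2 * n)
    n_train = math.floor(0.8 * (n - n_test))
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(order):
        pid = cohort[idx].patient_id
        if rank < n_train:
            assignment[pid] = "train"
        elif rank < n - n_test:
            assignment[pid] = "val"
        else:
            assignment[pid] = "test"
    return SplitAssignment(assignment)


def assert_no_leakage(split: SplitAssignment, cohort: list[PatientRecord]) -> None:
    ids = [p.patient_id for p in cohort]
    if set(ids) != set(split.assignment):
        raise AssertionError("split does not cover the cohort exactly")
    if len(ids) != len(set(ids)):
        raise AssertionError("duplicate patient ids in cohort")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class FusionModel(nn.Module):
    """Text encoder + projection and/or TST encoder, fused by an MLP head."""

    def __init__(self, run_config: RunConfig, d_out: int):
        self.run_config = run_config
        self.d_out = d_out
        rng = np.random.default_rng(run_config.init_seed)
        d_in = 0
        if run_config.use_text:
            self.encoder = CompactTextEncoder(
                replace(run_config.encoder, seed=run_config.init_seed)
            )
            self.projection = SemanticProjection(run_config.encoder.d_llm, d_out, rng)
            d_in += d_out
        if run_config.use_temporal:
            self.tst = TSTEncoder(run_config.tst, rng)
            d_in += run_config.tst.d_model
        self.mlp = FusionMLP(d_in, d_out, d_hidden=run_config.tst.d_model, rng=rng)

    def forward(
        self,
        batch: dict,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> nn.Tensor:
        parts: list[nn.Tensor] = []
        if self.run_config.use_text:
            h = self.encoder.forward_ids(
                batch["ids"], batch["token_mask"], training=training,
                dropout=self.run_config.tst.dropout, rng=rng,
            )
            parts.append(self.projection(h))
        if self.run_config.use_temporal:
            parts.append(
                self.tst.forward_batch(
                    batch["temporal"], batch["temporal_mask"], training=training, rng=rng
                )
            )
        z_in = parts[0] if len(parts) == 1 else nn.concat(parts, axis=-1)
        return self.mlp(z_in)


# ---------------------------------------------------------------------------
# Dataset preparation
# ---------------------------------------------------------------------------


@dataclass
class PreparedData:
    instances: list[PredictionInstance]
    token_ids: list[list[int]]
    temporal: np.ndarray        # (N, max_len, 2), unscaled
    temporal_mask: np.ndarray   # (N, max_len)
    targets: np.ndarray         # (N, d_out)


def _prepare(
    patients: list[PatientRecord],
    labels: LabelSpace,
    run_config: RunConfig,
    target_indices: list[int],
) -> PreparedData:
    assembly = run_config.resolved_assembly()
    instances: list[PredictionInstance] = []
    for p in patients:
        instances.extend(
            make_prediction_instances(p, labels, expanding_window=run_config.expanding_window)
        )
    token_ids: list[list[int]] = []
    if run_config.use_text:
        for inst in instances:
            doc = assemble_input_text(inst, assembly)
            token_ids.append(tokenize(doc.text, run_config.encoder))
    feats = [
        extract_temporal_features(
            PatientRecord(patient_id=i.patient_id + "#h", visits=list(i.history)),
            max_len=run_config.tst.max_len,
        )
        for i in instances
    ]
    temporal = np.stack([f.matrix for f in feats])
    temporal_mask = np.stack([f.mask for f in feats])
    targets = np.stack([i.target[target_indices] for i in instances])
    return PreparedData(instances, token_ids, temporal, temporal_mask, targets)


def _batch(data: PreparedData, idx: np.ndarray, scaler: Scaler | None) -> dict:
    out: dict = {"targets": data.targets[idx]}
    if data.token_ids:
        seqs = [data.token_ids[i] for i in idx]
        L = max(len(s) for s in seqs)
        ids = np.zeros((len(seqs), L), dtype=np.int64)
        mask = np.zeros((len(seqs), L), dtype=bool)
        for r, s in enumerate(seqs):
            ids[r, : len(s)] = s
            mask[r, : len(s)] = True
        out["ids"], out["token_mask"] = ids, mask
    if scaler is not None:
        mats = data.temporal[idx].copy()
        span = scaler.max - scaler.min
        safe = np.where(span == 0.0, 1.0, span)
        mats = np.clip((mats - scaler.min) / safe, 0.0, 1.0)
        mats[:, :, scaler.constant_features] = 0.0
        mats[~data.temporal_mask[idx]] = 0.0
        out["temporal"] = mats
        out["temporal_mask"] = data.temporal_mask[idx]
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class Checkpoint:
    state: dict[str, np.ndarray]
    scaler_min: np.ndarray | None
    scaler_max: np.ndarray | None
    run_config: RunConfig
    labels: LabelSpace
    log: list[dict] = field(default_factory=list)

    @property
    def scaler(self) -> Scaler | None:
        if self.scaler_min is None:
            return None
        return Scaler(min=self.scaler_min, max=self.scaler_max)

    def build_model(self) -> FusionModel:
        head = make_task_head(self.run_config.task, self.labels, self.run_config.hf_code)
        model = FusionModel(self.run_config, head["d_out"])
        model.load_state_dict(self.state)
        return model

    def save(self, path) -> None:
        arrays = {f"param::{k}": v for k, v in self.state.items()}
        if self.scaler_min is not None:
            arrays["scaler_min"] = self.scaler_min
            arrays["scaler_max"] = self.scaler_max
        meta = {
            "run_config": _config_to_dict(self.run_config),
            "labels": list(self.labels.codes),
            "log": self.log,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {
                k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")
            }
            smin = data["scaler_min"] if "scaler_min" in data.files else None
            smax = data["scaler_max"] if "scaler_max" in data.files else None
        return cls(
            state=state,
            scaler_min=smin,
            scaler_max=smax,
            run_config=_config_from_dict(meta["run_config"]),
            labels=LabelSpace(tuple(meta["labels"])),
            log=meta["log"],
        )


def _loss_on(
    model: FusionModel,
    data: PreparedData,
    idx: np.ndarray,
    scaler: Scaler | None,
    loss_config: LossConfig,
    batch_size: int,
) -> float:
    total, n = 0.0, 0
    for lo in range(0, len(idx), batch_size):
        sub = idx[lo: lo + batch_size]
        batch = _batch(data, sub, scaler)
        logits = model.forward(batch, training=False)
        probs = logits.sigmoid()
        loss = combined_loss(batch["targets"], probs, logits, loss_config)
        total += float(loss.data) * len(sub)
        n += len(sub)
    return total / max(n, 1)


def train(
    cohort: list[PatientRecord],
    run_config: RunConfig,
    labels: LabelSpace | None = None,
) -> Checkpoint:
    """Train the configured model; returns the best-validation checkpoint."""
    labels = labels or LabelSpace(DEFAULT_CODES)
    cohort = filter_min_visits(cohort, 2)
    split = split_cohort(cohort, run_config.split_seed)
    assert_no_leakage(split, cohort)
    head = make_task_head(run_config.task, labels, run_config.hf_code)

    train_patients = split.subset(cohort, "train")
    val_patients = split.subset(cohort, "val")
    train_data = _prepare(train_patients, labels, run_config, head["target_indices"])
    val_data = _prepare(val_patients, labels, run_config, head["target_indices"])

    scaler = None
    if run_config.use_temporal:
        from .ehr_data import TemporalFeatures

        scaler = fit_scaler(
            [
                TemporalFeatures(matrix=m, mask=k)
                for m, k in zip(train_data.temporal, train_data.temporal_mask)
            ]
        )

    model = FusionModel(run_config, head["d_out"])
    params = model.parameters()
    opt = nn.Adam(params, lr=run_config.lr)
    rng = np.random.default_rng(run_config.init_seed + 1)

    log: list[dict] = []
    best_state = model.state_dict()
    best_val = _loss_on(model, val_data, np.arange(len(val_data.instances)), scaler,
                        run_config.loss, run_config.batch_size) if val_data.instances else np.inf

    n_train = len(train_data.instances)
    for epoch in range(run_config.epochs):
        order = rng.permutation(n_train)
        epoch_loss, seen = 0.0, 0
        for lo in range(0, n_train, run_config.batch_size):
            idx = order[lo: lo + run_config.batch_size]
            batch = _batch(train_data, idx, scaler)
            logits = model.forward(batch, training=True, rng=rng)
            probs = logits.sigmoid()
            loss = combined_loss(batch["targets"], probs, logits, run_config.loss)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}; "
                    "lower the learning rate or inspect input scaling"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            seen += len(idx)
        train_loss = epoch_loss / max(seen, 1)
        val_loss = (
            _loss_on(model, val_data, np.arange(len(val_data.instances)), scaler,
                     run_config.loss, run_config.batch_size)
            if val_data.instances
            else train_loss
        )
        entry = {"epoch": epoch + 1, "train_loss": train_loss, "val_loss": val_loss}
        log.append(entry)
        logger.info("epoch %d: train %.4f val %.4f", epoch + 1, train_loss, val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()

    return Checkpoint(
        state=best_state,
        scaler_min=None if scaler is None else scaler.min,
        scaler_max=None if scaler is None else scaler.max,
        run_config=run_config,
        labels=labels,
        log=log,
    )


# ---------------------------------------------------------------------------
# Evaluation / prediction
# ---------------------------------------------------------------------------


def _forward_all(
    model: FusionModel,
    data: PreparedData,
    scaler: Scaler | None,
    batch_size: int,
) -> np.ndarray:
    chunks = []
    for lo in range(0, len(data.instances), batch_size):
        idx = np.arange(lo, min(lo + batch_size, len(data.instances)))
        logits = model.forward(_batch(data, idx, scaler), training=False)
        chunks.append(logits.data)
    return np.concatenate(chunks, axis=0)


def predict_cohort(
    checkpoint: Checkpoint, cohort: list[PatientRecord]
) -> tuple[list[PredictionInstance], np.ndarray, np.ndarray]:
    """Probabilities and decisions for every instance of a cohort."""
    rc = checkpoint.run_config
    head = make_task_head(rc.task, checkpoint.labels, rc.hf_code)
    data = _prepare(filter_min_visits(cohort, 2), checkpoint.labels, rc, head["target_indices"])
    model = checkpoint.build_model()
    logits = _forward_all(model, data, checkpoint.scaler, rc.batch_size)
    out = predict(logits, threshold=rc.threshold)
    return data.instances, out.probabilities, out.decisions


def evaluate(
    checkpoint: Checkpoint,
    cohort: list[PatientRecord],
    split: str = "test",
    ks: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> MetricReport:
    """Deterministic evaluation of a checkpoint on one split of a cohort."""
    rc = checkpoint.run_config
    cohort = filter_min_visits(cohort, 2)
    assignment = split_cohort(cohort, rc.split_seed)
    assert_no_leakage(assignment, cohort)
    patients = assignment.subset(cohort, split) if split != "all" else cohort
    if not patients:
        raise ValueError(f"split {split!r} is empty")
    head = make_task_head(rc.task, checkpoint.labels, rc.hf_code)
    data = _prepare(patients, checkpoint.labels, rc, head["target_indices"])
    model = checkpoint.build_model()
    logits = _forward_all(model, data, checkpoint.scaler, rc.batch_size)
    out = predict(logits, threshold=rc.threshold)
    ks = tuple(k for k in ks if k <= head["d_out"]) or (1,)
    return full_report(data.targets, out.probabilities, out.decisions, ks=ks)


def run_ablation(
    cohort: list[PatientRecord],
    run_config: RunConfig,
    ablations: tuple[str, ...] = ("full", "no-labtext", "no-text"),
    labels: LabelSpace | None = None,
) -> dict[str, MetricReport]:
    """Train and evaluate the listed ablations under shared seeds and splits."""
    reports: dict[str, MetricReport] = {}
    for ablation in ablations:
        rc = replace(run_config, ablation=ablation)
        ckpt = train(cohort, rc, labels=labels)
        reports[ablation] = evaluate(ckpt, cohort, "test")
    return reports
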