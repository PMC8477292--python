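"""Multitask training with cosine-gated auxiliary gradients.

The main task (30-day mortality or readmission) provides the gradient
``G``; each auxiliary task (three input reconstructions, current/future
cost regression, cardiac-arrest-record classification) provides a gradient
``V_i`` over the same shared parameters.  The update direction is

    G + sum_i max(0, cos(G, V_i)) * V_i

so an auxiliary gradient contributes in proportion to its alignment with
the main task and is gated out entirely when it conflicts (negative
cosine).  Two imbalance counter-measures are applied to the *training*
split only:

* **person upsampling** — patients with CA-positive records for the main
  task are replicated ``upsampling_rate`` times within each batch
  (replicas receive independent dropout);
* **CA record weighting** — every per-record loss is weighted ``w_pos`` on
  cardiac-arrest records and ``w_neg`` (fixed 1) elsewhere, normalized by
  the total weight.

Persons — never records — are the unit of the 70/15/15
train/validation/test split, and validation/test batches are never
upsampled or reweighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .data_model import Cohort, Person
from .featurization import (
    CodeEmbeddingTable,
    FeatureScaler,
    GROUP_SLICES,
    featurize_cohort_raw,
    make_table_for_cohort,
)
from .labeling import label_mortality, label_readmission
from .model import HVecModel, HVecParams

__all__ = [
    "TrainingConfig",
    "GradientBundle",
    "TrainedModel",
    "combine_gradients",
    "weighted_task_loss",
    "upsample_batch",
    "split_cohort",
    "train",
]

MAIN_TASKS = ("mortality", "readmission")
AUX_TASKS = ("recon_codes", "recon_context", "recon_history",
             "cur_cost", "fut_cost", "ihca")


@dataclass(frozen=True)
class TrainingConfig:
    multitask: bool = True
    upsampling_rate: int = 1
    event_weight_pos: float = 1.0
    event_weight_neg: float = 1.0
    batch_persons: int = 128
    max_epochs: int = 10
    early_stop_metric: str = "auroc_main"
    patience: int = 5
    seed: int = 0
    main_task: str = "mortality"

    def validate(self) -> None:
        if self.upsampling_rate < 1:
            raise ValueError("upsampling_rate must be >= 1 (1 = off)")
        if self.event_weight_pos <= 0 or self.event_weight_neg <= 0:
            raise ValueError("event weights must be positive")
        if self.batch_persons < 1 or self.max_epochs < 1:
            raise ValueError("batch_persons and max_epochs must be positive")
        if self.main_task not in MAIN_TASKS:
            raise ValueError(f"main_task must be one of {MAIN_TASKS}")


@dataclass
class GradientBundle:
    """Main-task gradient G, auxiliary gradients V_i, and the step size."""

    G: np.ndarray
    V_list: list[np.ndarray]
    alpha: float = 1e-3

    def validate(self) -> None:
        for v in self.V_list:
            if v.shape != self.G.shape:
                raise ValueError("all gradient vectors must have the same length")


def combine_gradients(G, V_list: Optional[Sequence[np.ndarray]] = None) -> np.ndarray:
    """Cosine-gated combination ``G + sum_i max(0, cos(G, V_i)) * V_i``.

    The cosine involving a zero vector is defined as 0, so zero gradients
    (and auxiliaries orthogonal or opposed to G) leave the direction at G.
    The caller applies ``theta <- theta - alpha * direction``.
    """
    if isinstance(G, GradientBundle):
        bundle = G
        bundle.validate()
        G, V_list = bundle.G, bundle.V_list
    G = np.asarray(G, dtype=float)
    direction = G.copy()
    norm_g = float(np.linalg.norm(G))
    for V in (V_list or []):
        V = np.asarray(V, dtype=float)
        if V.shape != G.shape:
            raise ValueError("gradient length mismatch")
        norm_v = float(np.linalg.norm(V))
        if norm_g == 0.0 or norm_v == 0.0:
            continue  # cos := 0 -> gate closed
        cos = float(G @ V) / (norm_g * norm_v)
        if cos > 0.0:
            direction += cos * V
    return direction


def weighted_task_loss(per_record_losses: Sequence[float], labels: Sequence[int],
                       is_ca: Sequence[int], w_pos: float, w_neg: float) -> float:
    """Weighted mean loss: weight ``w_pos`` on CA records, ``w_neg`` elsewhere.

    The indicator keys on cardiac-arrest record status (the emphasized
    class), not on label positivity.  Normalizing by the total weight keeps
    the scale comparable across weight settings.
    """
    losses = np.asarray(per_record_losses, dtype=float)
    if losses.size == 0:
        raise ValueError("weighted_task_loss requires a non-empty batch")
    ca = np.asarray(is_ca, dtype=bool)
    if ca.shape != losses.shape:
        raise ValueError("per_record_losses and is_ca must be aligned")
    w = np.where(ca, float(w_pos), float(w_neg))
    return float(np.sum(w * losses) / np.sum(w))


def upsample_batch(persons: Sequence[Person], positive_ids: set[str],
                   rate: int, seed: int) -> list[Person]:
    """Replicate CA-positive persons ``rate`` times within a batch, shuffled.

    Rate 1 returns a permutation of the input.  Replicas are the same Person
    object; downstream dropout randomness makes them independent samples.
    """
    if rate < 1:
        raise ValueError("rate must be >= 1")
    out: list[Person] = []
    for p in persons:
        out.extend([p] * (rate if p.person_id in positive_ids else 1))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


def split_cohort(cohort: Cohort, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                 seed: int = 0) -> tuple[list[Person], list[Person], list[Person]]:
    """Partition persons (never records) into train/validation/test."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(cohort.persons)
    if n < 3:
        raise ValueError("cohort must contain at least 3 persons to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(max(n_train, 1), n - 2)
    n_val = min(max(n_val, 1), n - n_train - 1)
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    ps = cohort.persons
    return ([ps[i] for i in idx_train], [ps[i] for i in idx_val], [ps[i] for i in idx_test])


# ---------------------------------------------------------------------------
# Per-person tensors

@dataclass
class _PersonData:
    X: np.ndarray            # (T, 707) scaled features
    y_mort: np.ndarray       # (T,)
    y_readm: np.ndarray      # (T,) with mask
    mask_readm: np.ndarray   # (T,) 1 where readmission label defined
    y_ca: np.ndarray         # (T,)
    cost_cur: np.ndarray     # (T,) standardized log1p total cost
    cost_fut: np.ndarray     # (T,)
    record_ids: list[str]


def _prepare_person(person: Person, raw: np.ndarray, scaler: FeatureScaler,
                    cost_mean: float, cost_std: float) -> _PersonData:
    X = scaler.transform(raw)
    y_m = np.asarray(label_mortality(person), dtype=float)
    readm = label_readmission(person)
    y_r = np.array([0.0 if v is None else float(v) for v in readm])
    m_r = np.array([0.0 if v is None else 1.0 for v in readm])
    y_ca = np.array([1.0 if r.is_ca else 0.0 for r in person.records])
    cost = np.array([math.log1p(sum(r.costs)) for r in person.records])
    cost = (cost - cost_mean) / cost_std
    fut = np.zeros_like(cost)
    fut[:-1] = cost[1:]
    return _PersonData(X, y_m, y_r, m_r, y_ca, cost, fut,
                       [r.record_id for r in person.records])


class _RunData:
    """Featurized cohort bound to one training run's scaler and table."""

    def __init__(self, cohort: Cohort, table: CodeEmbeddingTable,
                 scaler: FeatureScaler, cost_mean: float, cost_std: float,
                 raw: dict[str, np.ndarray]):
        self.cohort = cohort
        self.table = table
        self.scaler = scaler
        self.cost_mean = cost_mean
        self.cost_std = cost_std
        self._persons = {p.person_id: p for p in cohort.persons}
        self._cache: dict[str, _PersonData] = {}
        self._raw = raw

    def get(self, person_id: str) -> _PersonData:
        pd = self._cache.get(person_id)
        if pd is None:
            pd = _prepare_person(self._persons[person_id], self._raw[person_id],
                                 self.scaler, self.cost_mean, self.cost_std)
            self._cache[person_id] = pd
        return pd


def _pad_batch(datas: list[_PersonData]) -> dict[str, np.ndarray]:
    B = len(datas)
    T = max(d.X.shape[0] for d in datas)
    D = datas[0].X.shape[1]
    X = np.zeros((B, T, D))
    fields = {n: np.zeros((B, T)) for n in
              ("y_mort", "y_readm", "mask_readm", "y_ca", "cost_cur", "cost_fut")}
    lengths = np.zeros(B, dtype=int)
    for b, d in enumerate(datas):
        t = d.X.shape[0]
        lengths[b] = t
        X[b, :t] = d.X
        for n in fields:
            fields[n][b, :t] = getattr(d, n)
    mask = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
    return {"X": X, "lengths": lengths, "mask": mask, **fields}


# ---------------------------------------------------------------------------
# Losses

def _bce_with_logits(y_hat: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-element loss and dloss/dlogit (numerically stable)."""
    loss = np.maximum(y_hat, 0.0) - y_hat * y + np.log1p(np.exp(-np.abs(y_hat)))
    p = 1.0 / (1.0 + np.exp(-np.clip(y_hat, -60, 60)))
    return loss, p - y


def _task_targets(batch: dict, task: str) -> tuple[np.ndarray, np.ndarray, str]:
    """(target array, validity mask, kind) for one task on a padded batch."""
    mask = batch["mask"]
    if task == "mortality":
        return batch["y_mort"][..., None], mask, "bce"
    if task == "readmission":
        return batch["y_readm"][..., None], mask * batch["mask_readm"], "bce"
    if task == "ihca":
        return batch["y_ca"][..., None], mask, "bce"
    if task == "cur_cost":
        return batch["cost_cur"][..., None], mask, "mse"
    if task == "fut_cost":
        return batch["cost_fut"][..., None], mask, "mse"
    if task == "recon_codes":
        return batch["X"][..., GROUP_SLICES["codes"]], mask, "mse"
    if task == "recon_context":
        return batch["X"][..., GROUP_SLICES["context"]], mask, "mse"
    if task == "recon_history":
        return batch["X"][..., GROUP_SLICES["stats"]], mask, "mse"
    raise ValueError(f"unknown task {task!r}")


def _task_loss_and_grads(model: HVecModel, h: np.ndarray, batch: dict, task: str,
                         weights: np.ndarray) -> tuple[float, np.ndarray, dict]:
    """Scalar weighted loss, dL/dh (B,T,H), and head-parameter grads."""
    target, valid, kind = _task_targets(batch, task)
    f32 = np.float32
    W = model.weights[f"head_{task}_W"].astype(f32)
    b = model.weights[f"head_{task}_b"].astype(f32)
    h = h.astype(f32, copy=False)
    target = target.astype(f32, copy=False)
    B, T, H = h.shape
    y_hat = (h.reshape(B * T, H) @ W).reshape(B, T, -1) + b  # (B, T, out)
    if kind == "bce":
        loss_el, dldy = _bce_with_logits(y_hat, target)
        per_record = loss_el[..., 0]
        dY = dldy
    else:
        diff = y_hat - target
        per_record = np.mean(diff * diff, axis=-1)
        dY = (2.0 / y_hat.shape[-1]) * diff
    w = weights * valid
    total_w = w.sum()
    if total_w <= 0.0:
        return 0.0, np.zeros(h.shape), {f"head_{task}_W": np.zeros_like(W),
                                        f"head_{task}_b": np.zeros_like(b)}
    loss = float((w * per_record).sum() / total_w)
    dY = dY * (w / total_w)[..., None]
    dY_flat = dY.reshape(B * T, -1)
    dh = (dY_flat @ W.T).reshape(B, T, H)
    gW = h.reshape(B * T, H).T @ dY_flat
    gb = dY_flat.sum(axis=0)
    return loss, dh, {f"head_{task}_W": gW, f"head_{task}_b": gb}


# ---------------------------------------------------------------------------
# Trained model bundle

@dataclass
class TrainedModel:
    model: HVecModel
    table: CodeEmbeddingTable
    scaler: FeatureScaler
    cost_mean: float
    cost_std: float
    params: HVecParams
    config: TrainingConfig
    history: list[dict]
    split_ids: dict[str, list[str]]
    _run_data: Optional[_RunData] = None

    def predict_scores(self, persons: Sequence[Person], task: Optional[str] = None
                       ) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
        """Per-record probabilities for ``task`` over the given persons.

        Returns (record_ids, probabilities, labels, is_ca).  Readmission
        scores are restricted to eligible (inpatient) records.
        """
        task = task or self.config.main_task
        data = self._run_data
        ids: list[str] = []
        probs: list[np.ndarray] = []
        labels: list[np.ndarray] = []
        ca: list[np.ndarray] = []
        for chunk in _bucketed_batches(list(persons), self.config.batch_persons):
            datas = [data.get(p.person_id) for p in chunk]
            batch = _pad_batch(datas)
            cache = self.model.forward_batch(batch["X"], batch["lengths"], training=False)
            logits = self.model.head_outputs_batch(cache["h"], [task])[task][..., 0]
            p = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
            target, valid, _ = _task_targets(batch, task)
            for b, d in enumerate(datas):
                keep = valid[b].astype(bool)
                t_idx = np.nonzero(keep)[0]
                ids.extend(d.record_ids[t] for t in t_idx)
                probs.append(p[b, t_idx])
                labels.append(target[b, t_idx, 0])
                ca.append(d.y_ca[t_idx])
        return (ids, np.concatenate(probs) if probs else np.array([]),
                np.concatenate(labels) if labels else np.array([]),
                np.concatenate(ca) if ca else np.array([]))

    def save(self, path: str) -> None:
        """Write a single .npz checkpoint: format version, parameter vector,
        scaler/cost statistics, embedding-table seed and both configs."""
        import dataclasses
        import json

        meta = {
            "format_version": 1,
            "params": dataclasses.asdict(self.params),
            "config": dataclasses.asdict(self.config),
            "table_seed": self.table.seed,
            "table_dimension": self.table.dimension,
            "cost_mean": self.cost_mean,
            "cost_std": self.cost_std,
            "split_ids": self.split_ids,
        }
        np.savez_compressed(
            path, theta=self.model.param_vector(),
            scaler_mean=self.scaler.mean_, scaler_std=self.scaler.std_,
            meta=np.array(json.dumps(meta)))

    @staticmethod
    def load(path: str, cohort: Cohort) -> "TrainedModel":
        """Rebuild a trained bundle from a checkpoint plus its cohort."""
        import json

        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            if meta.get("format_version") != 1:
                raise ValueError(f"unsupported checkpoint format: "
                                 f"{meta.get('format_version')}")
            theta = archive["theta"]
            scaler = FeatureScaler()
            scaler.mean_ = archive["scaler_mean"]
            scaler.std_ = archive["scaler_std"]
            scaler.fitted = True
        params = HVecParams(**meta["params"])
        config = TrainingConfig(**meta["config"])
        model = HVecModel(params)
        model.set_param_vector(theta)
        table = make_table_for_cohort(cohort, dimension=meta["table_dimension"],
                                      seed=meta["table_seed"])
        raw = featurize_cohort_raw(cohort, table)
        data = _RunData(cohort, table, scaler, meta["cost_mean"],
                        meta["cost_std"], raw)
        return TrainedModel(model=model, table=table, scaler=scaler,
                            cost_mean=meta["cost_mean"], cost_std=meta["cost_std"],
                            params=params, config=config, history=[],
                            split_ids={k: list(v) for k, v in meta["split_ids"].items()},
                            _run_data=data)


def _bucketed_batches(persons: list[Person], batch_size: int,
                      rng: Optional[np.random.Generator] = None) -> list[list[Person]]:
    """Batches of persons with similar sequence lengths (padding efficiency);
    batch order shuffled when an RNG is given."""
    ordered = sorted(persons, key=lambda p: (len(p.records), p.person_id))
    batches = [ordered[i:i + batch_size] for i in range(0, len(ordered), batch_size)]
    if rng is not None and len(batches) > 1:
        batches = [batches[i] for i in rng.permutation(len(batches))]
    return batches


class _Adam:
    def __init__(self, n: int, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad * grad
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _positive_person_ids(persons: Iterable[Person], main_task: str) -> set[str]:
    """Persons carrying at least one CA record positive for the main task."""
    out: set[str] = set()
    for p in persons:
        if main_task == "mortality":
            labels = label_mortality(p)
            eligible = [True] * len(labels)
        else:
            raw = label_readmission(p)
            labels = [0 if v is None else v for v in raw]
            eligible = [v is not None for v in raw]
        for r, y, ok in zip(p.records, labels, eligible):
            if ok and r.is_ca and y == 1:
                out.add(p.person_id)
                break
    return out


def train(cohort: Cohort, params: HVecParams = HVecParams(),
          config: TrainingConfig = TrainingConfig(),
          raw_features: Optional[dict[str, np.ndarray]] = None,
          table: Optional[CodeEmbeddingTable] = None,
          ) -> tuple[TrainedModel, list[dict]]:
    """Train an HVec model on a person-level 70/15/15 split of the cohort.

    Fully reproducible under fixed ``config.seed`` / ``params.init_seed``.
    ``raw_features``/``table`` allow sharing the (split-independent)
    unscaled feature matrices across grid runs.

    Returns the trained bundle and the per-epoch history (task losses and
    main-task validation AUROC).
    """
    from .evaluation import compute_auroc  # local import to avoid a cycle

    params.validate()
    config.validate()
    train_p, val_p, test_p = split_cohort(cohort, seed=config.seed)
    if not train_p or not val_p or not test_p:
        raise ValueError("empty split")

    if table is None:
        table = make_table_for_cohort(cohort, dimension=params.code_embed_size,
                                      seed=params.init_seed)
    if raw_features is None:
        raw_features = featurize_cohort_raw(cohort, table)

    train_rows = np.concatenate([raw_features[p.person_id] for p in train_p])
    scaler = FeatureScaler().fit(train_rows)
    log_costs = np.array([math.log1p(sum(r.costs)) for p in train_p for r in p.records])
    cost_mean = float(log_costs.mean())
    cost_std = float(log_costs.std() or 1.0)

    data = _RunData(cohort, table, scaler, cost_mean, cost_std, raw_features)
    model = HVecModel(params)
    tasks = [config.main_task] + (list(AUX_TASKS) if config.multitask else [])
    positive_ids = _positive_person_ids(train_p, config.main_task)

    rng = np.random.default_rng(config.seed)
    theta = model.param_vector()
    adam = _Adam(theta.size, params.learning_rate)
    l2_mask = model.weight_mask_vector()

    history: list[dict] = []
    best_auroc = -np.inf
    best_theta = theta.copy()
    best_epoch = 0
    stale = 0

    for epoch in range(1, config.max_epochs + 1):
        epoch_losses = {t: 0.0 for t in tasks}
        n_batches = 0
        for batch_persons in _bucketed_batches(train_p, config.batch_persons, rng):
            if config.upsampling_rate > 1:
                batch_persons = upsample_batch(
                    batch_persons, positive_ids, config.upsampling_rate,
                    seed=int(rng.integers(2 ** 31)),
                )
            datas = [data.get(p.person_id) for p in batch_persons]
            batch = _pad_batch(datas)
            cache = model.forward_batch(batch["X"], batch["lengths"],
                                        training=True, rng=rng)
            h = cache["h"]
            weights = np.where(batch["y_ca"] > 0.5, config.event_weight_pos,
                               config.event_weight_neg) * batch["mask"]
            dh_stack = []
            head_grads = []
            for t_name in tasks:
                loss, dh, hg = _task_loss_and_grads(model, h, batch, t_name, weights)
                epoch_losses[t_name] += loss
                dh_stack.append(dh)
                head_grads.append(hg)
            grads = model.backward_tasks(cache, np.stack(dh_stack), head_grads)
            G = grads[0] + params.l2_weight * l2_mask * theta
            V_list = [grads[k] for k in range(1, grads.shape[0])]
            direction = combine_gradients(G, V_list)
            theta = adam.step(theta, direction)
            model.set_param_vector(theta)
            n_batches += 1

        # validation AUROC on the untouched split
        bundle = TrainedModel(model, table, scaler, cost_mean, cost_std, params,
                              config, history, {}, _run_data=data)
        _, val_scores, val_labels, _ = bundle.predict_scores(val_p, config.main_task)
        if val_labels.size and 0 < val_labels.sum() < val_labels.size:
            val_auroc = compute_auroc(val_scores, val_labels)
        else:
            val_auroc = float("nan")
        row = {"epoch": epoch, "val_auroc_main": val_auroc}
        row.update({f"loss_{t}": epoch_losses[t] / max(n_batches, 1) for t in tasks})
        history.append(row)

        if not math.isnan(val_auroc):
            if val_auroc > best_auroc:
                best_auroc = val_auroc
                best_theta = theta.copy()
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break

    if best_auroc > -np.inf:
        model.set_param_vector(best_theta)
    trained = TrainedModel(
        model=model, table=table, scaler=scaler, cost_mean=cost_mean,
        cost_std=cost_std, params=params, config=config, history=history,
        split_ids={"train": [p.person_id for p in train_p],
                   "val": [p.person_id for p in val_p],
                   "test": [p.person_id for p in test_p]},
        _run_data=data,
    )
    return trained, history
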