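"""End-to-end experiment orchestration: simulate -> prepare -> TFR -> train -> eval.

One :class:`ExperimentConfig` fully determines an experiment: a master seed
fans out to per-stage seeds by fixed offsets so stages are independently
reproducible, every stage logs its record counts, and the final report is a
plain dict (JSON-serializable) with metrics for both the balanced and the
natural (unbalanced) test composition.

The two building blocks are usable on their own: :func:`prepare_dataset`
turns an annotated record into per-split time-frequency image stacks, and
:func:`fit_and_evaluate` trains a classifier on such a dataset and scores
the held-out test split.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from capnet.augment import (
    AugmentConfig,
    apply_tf_augment,
    fit_norm_stats,
    normalize,
    random_time_shift,
)
from capnet.evaluation import evaluate_predictions, subtype_tpr
from capnet.nn.models import build_model
from capnet.nn.training import TrainConfig, predict, train
from capnet.segmentation import (
    FS_ANALYSIS,
    SplitSpec,
    assign_splits,
    attach_splits,
    balance_classes,
    extract_segments,
    resample_record,
    trim_edges,
)
from capnet.simulate import SimConfig, generate_record
from capnet.tfr import compute_tfr

__all__ = [
    "ExperimentConfig",
    "prepare_dataset",
    "fit_and_evaluate",
    "run_experiment",
    "sweep",
    "SEED_OFFSETS",
]

#: Fixed per-stage seed offsets derived from the master seed.
SEED_OFFSETS = {"simulate": 101, "balance": 202, "train": 303, "eval": 505}

AUGMENT_STRATEGIES = ("none", "tf", "shift", "tf+shift")


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: data source, windowing, TFR method, training recipe."""

    window_s: int = 5
    tfr_method: str = "SPWVD"
    augment_strategy: str = "none"
    sim: SimConfig = field(default_factory=SimConfig)
    train_cfg: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            model_variant="small_cnn", batch_size=16, learning_rate=0.05, epochs=5
        )
    )
    augment_cfg: AugmentConfig = field(default_factory=AugmentConfig)
    n_freq: int | None = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_s not in (1, 3, 5, 7, 9, 11):
            raise ValueError("window_s must be one of 1, 3, 5, 7, 9, 11")
        if self.tfr_method.upper() not in ("SPEC", "WVD", "SPWVD"):
            raise ValueError("tfr_method must be SPEC, WVD or SPWVD")
        if self.augment_strategy not in AUGMENT_STRATEGIES:
            raise ValueError(f"augment_strategy must be one of {AUGMENT_STRATEGIES}")


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def _tfr_stack(segments, method: str, n_freq: int | None = None) -> np.ndarray:
    kwargs = {} if n_freq is None or method == "SPEC" else {"n_freq": n_freq}
    return np.stack(
        [compute_tfr(s.samples, method, **kwargs).values for s in segments]
    ).astype(np.float32)


def _labels_int(segments) -> np.ndarray:
    return np.array([1 if s.center_label == "A" else 0 for s in segments], dtype=int)


def prepare_dataset(
    record,
    window_s: int,
    method: str,
    balance_seed: int,
    margin_s: int = 0,
    split_spec: SplitSpec = SplitSpec(),
    n_freq: int | None = None,
) -> dict:
    """Record -> per-split TFR image stacks with leakage-free block splits.

    Train and validation splits are class-balanced per recording; the test
    split keeps its natural composition (balanced evaluation subsamples at
    scoring time).  With ``margin_s`` > 0 the train images are computed on
    windows extended by that many seconds per side (for random time-shift
    augmentation) and edge trimming enforces the extended coverage.
    ``n_freq`` overrides the Wigner transforms' frequency-bin count (the
    default is the next power of two above the window length; smaller
    grids trade frequency resolution for speed).
    """
    method = method.upper()
    rec32 = resample_record(record) if record.fs_hz != FS_ANALYSIS else record
    window_ext = window_s + 2 * margin_s
    split_map = assign_splits(rec32.duration_s, split_spec)
    segments = attach_splits(extract_segments(rec32, window_s), split_map)
    n_extracted = len(segments)
    segments = trim_edges(segments, window_ext, split_map)
    n_trimmed = len(segments)

    train_val = balance_classes(
        [s for s in segments if s.split in ("train", "val")], balance_seed
    )
    train_segs = [s for s in train_val if s.split == "train"]
    val_segs = [s for s in train_val if s.split == "val"]
    test_segs = [s for s in segments if s.split == "test"]
    if not train_segs or not test_segs:
        raise RuntimeError("empty train or test split after preparation")

    target_w = window_s * FS_ANALYSIS
    if margin_s:
        ext = {s.center_time_s: s for s in extract_segments(rec32, window_ext)}
        train_X = _tfr_stack([ext[s.center_time_s] for s in train_segs], method, n_freq)
    else:
        train_X = _tfr_stack(train_segs, method, n_freq)
    data = {
        "method": method,
        "window_s": window_s,
        "margin_s": margin_s,
        "target_n_time": target_w,
        "train_X": train_X,
        "train_y": _labels_int(train_segs),
        "val_X": _tfr_stack(val_segs, method, n_freq) if val_segs else None,
        "val_y": _labels_int(val_segs) if val_segs else None,
        "test_X": _tfr_stack(test_segs, method, n_freq),
        "test_labels": np.array([s.center_label for s in test_segs]),
        "test_subtypes": np.array([s.center_subtype for s in test_segs]),
        "counts": {
            "extracted": n_extracted,
            "after_trim": n_trimmed,
            "train": len(train_segs),
            "val": len(val_segs),
            "test_unbalanced": len(test_segs),
        },
    }
    return data


def fit_and_evaluate(
    data: dict,
    train_cfg: TrainConfig,
    eval_seed: int,
    augment_strategy: str = "none",
    augment_cfg: AugmentConfig = AugmentConfig(),
    shuffle_label_seed: int | None = None,
) -> dict:
    """Train on a prepared dataset and score the test split both ways.

    ``shuffle_label_seed`` permutes the training and validation labels (a
    chance-level control: any apparent skill after shuffling indicates
    leakage).  Returns a dict with the trained model, history, and metrics
    for balanced and unbalanced test composition.
    """
    if augment_strategy not in AUGMENT_STRATEGIES:
        raise ValueError(f"augment_strategy must be one of {AUGMENT_STRATEGIES}")
    use_tf = "tf" in augment_strategy.split("+")
    use_shift = "shift" in augment_strategy.split("+")
    if use_shift and data["margin_s"] == 0:
        raise ValueError("shift augmentation needs a dataset prepared with margin_s > 0")

    stats = fit_norm_stats(data["train_X"])
    norm = lambda X: np.stack([normalize(im, stats) for im in X])
    target_w = data["target_n_time"]

    train_y = data["train_y"].copy()
    val_y = None if data["val_y"] is None else data["val_y"].copy()
    if shuffle_label_seed is not None:
        rng = np.random.default_rng(shuffle_label_seed)
        train_y = rng.permutation(train_y)
        if val_y is not None:
            val_y = rng.permutation(val_y)

    train_X = norm(data["train_X"])
    if use_shift:
        def augment_fn(batch, rng):
            out = np.stack([random_time_shift(im, target_w, rng) for im in batch])
            if use_tf:
                out = np.stack([apply_tf_augment(im, augment_cfg, rng) for im in out])
            return out
    elif data["margin_s"]:
        # dataset carries extended train windows but shifts are off: center-crop
        m = data["margin_s"] * FS_ANALYSIS
        train_X = train_X[:, :, m : m + target_w]
        augment_fn = (
            (lambda batch, rng: np.stack([apply_tf_augment(im, augment_cfg, rng) for im in batch]))
            if use_tf
            else None
        )
    else:
        augment_fn = (
            (lambda batch, rng: np.stack([apply_tf_augment(im, augment_cfg, rng) for im in batch]))
            if use_tf
            else None
        )

    model = build_model(train_cfg.model_variant, (train_X.shape[1], target_w), seed=train_cfg.seed)
    val_set = None
    if data["val_X"] is not None and len(data["val_X"]):
        val_set = (norm(data["val_X"]), val_y)
    trained = train(model, (train_X, train_y), val_set, train_cfg, augment_fn=augment_fn)

    test_X = norm(data["test_X"])
    _, pred = predict(model, test_X, train_cfg.batch_size)
    out = {
        "model": trained,
        "norm_stats": stats,
        "history": trained.history,
        "val_acc": trained.history[-1].get("val_acc"),
        "best_val_acc": max(
            (h.get("val_acc", -1.0) for h in trained.history), default=None
        ),
    }
    for mode in ("balanced", "unbalanced"):
        rep, counts = evaluate_predictions(
            pred, data["test_labels"], data["test_subtypes"], mode=mode, seed=eval_seed
        )
        out[mode] = {
            "metrics": rep.as_percent(),
            "counts": {"tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn},
            "subtype_tpr": {k: round(100 * v, 1) for k, v in subtype_tpr(counts).items()},
        }
    return out


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run all stages from one config and return the report dict.

    If ``out_dir`` is given, intermediate artifacts (record, test TFR
    batch, report) are persisted there.
    """
    t_start = time.time()
    master = config.seed
    seeds = {
        stage: master + off for stage, off in SEED_OFFSETS.items()
    }

    sim_cfg = replace(config.sim, seed=seeds["simulate"])
    record = generate_record(sim_cfg)

    margin_s = (
        int(np.ceil(config.augment_cfg.time_shift_margin_s))
        if "shift" in config.augment_strategy
        else 0
    )
    data = prepare_dataset(
        record, config.window_s, config.tfr_method, seeds["balance"], margin_s,
        n_freq=config.n_freq,
    )
    train_cfg = replace(config.train_cfg, seed=seeds["train"])
    result = fit_and_evaluate(
        data, train_cfg, seeds["eval"], config.augment_strategy, config.augment_cfg
    )

    report = {
        "config": _config_dict(config),
        "seeds": seeds,
        "hashes": {"signal": _sha(record.samples), "train_X": _sha(data["train_X"])},
        "stages": {
            "simulate": {
                "duration_s": record.duration_s,
                "a_seconds": int(np.sum(record.binary_labels == "A")),
            },
            "prepare": data["counts"],
            "tfr": {"method": data["method"], "image_shape": list(data["train_X"].shape[1:])},
            "train": {
                "epochs": len(result["history"]),
                "best_epoch": result["model"].best_epoch,
                "final_train_acc": result["history"][-1]["train_acc"],
            },
        },
        "balanced": result["balanced"],
        "unbalanced": result["unbalanced"],
        "history": result["history"],
        "elapsed_s": round(time.time() - t_start, 2),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from capnet import io as cio

        cio.save_record(out_dir / "record.h5", record, seed=sim_cfg.seed)
        cio.save_tfr_batch(
            out_dir / "tfr_test.h5",
            data["test_X"],
            data["test_labels"],
            data["test_subtypes"],
            np.array(["test"] * len(data["test_labels"])),
            data["method"],
            config.window_s,
        )
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["sim"]["phases"] = {k: asdict(v) for k, v in config.sim.phases.items()}
    return d


def sweep(
    base: ExperimentConfig,
    tfr_methods: list[str],
    window_sizes: list[int],
    out_dir: str | Path | None = None,
) -> dict:
    """Grid over TFR method x window size; returns {method: {window: report}}.

    The grid is also rendered as a CSV accuracy table (rows = methods,
    columns = window sizes, balanced test accuracy in percent).
    """
    results: dict = {}
    for method in tfr_methods:
        results[method] = {}
        for w in window_sizes:
            cfg = replace(base, tfr_method=method, window_s=w)
            results[method][w] = run_experiment(cfg)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        lines = ["method," + ",".join(f"{w}s" for w in window_sizes)]
        for method in tfr_methods:
            accs = [
                f"{results[method][w]['balanced']['metrics']['ACC']:.1f}"
                for w in window_sizes
            ]
            lines.append(method + "," + ",".join(accs))
        (out_dir / "sweep_accuracy.csv").write_text("\n".join(lines) + "\n")
        with open(out_dir / "sweep_reports.json", "w") as fh:
            json.dump(results, fh, indent=2, default=str)
    return results
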