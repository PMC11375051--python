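"""End-to-end orchestration of the three experimental settings.

Setting I trains SVMs on deep features from the Gabor subband streams —
each single subband and the fused all-GW block — per backbone and kernel.
Setting II compares original-image features, all-GW features and their
fusion.  Setting III fuses the per-backbone blocks across backbones,
runs the mRMR ablation sweep, and reports the best feature count per
kernel together with the full metric suite, confusion matrix and ROC
curves.

A single master seed fans out deterministically to the synthetic-data,
split, augmentation, training and SVM sub-seeds, so a full run is
reproducible bit for bit.  All heavy intermediates (subband datasets,
trained ensembles, feature matrices) are computed once per run context
and shared across the three settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from gaborderm.classify import SVMSpec, train_classifier
from gaborderm.data import (
    AugmentationSpec,
    DatasetTable,
    TrainConfig,
    augment_train,
    load_dataset,
    stratified_split,
)
from gaborderm.features import STREAMS, FeatureMatrix, fuse_backbones, fuse_streams
from gaborderm.gabor import decompose, default_bank
from gaborderm.metrics import compute_metrics, confusion_matrix, roc_curves
from gaborderm.mrmr import ablation_sweep
from gaborderm.network import BackboneSpec, extract_features, train_ensemble
from gaborderm.synthetic import SynthSpec, generate_dataset

__all__ = [
    "RunConfig",
    "SettingReport",
    "PipelineContext",
    "prepare",
    "run_setting_one",
    "run_setting_two",
    "run_setting_three",
]

KERNELS = ("linear", "quadratic", "gaussian")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``synth`` (a SynthSpec) or ``dataset_dir``+``metadata`` must
    be provided.  ``augmentation=None`` skips training-set augmentation —
    the default for synthetic runs, whose oriented-texture class signal
    is not invariant under the reference rotation/shear ranges.
    """

    synth: SynthSpec | None = field(default_factory=SynthSpec)
    dataset_dir: str | None = None
    metadata: str | None = None
    backbones: tuple = ("tiny-test",)
    train: TrainConfig = TrainConfig(epochs=10, learning_rate=0.01)
    augmentation: AugmentationSpec | None = None
    train_frac: float = 0.70
    mrmr_ks: tuple | None = None
    kernels: tuple = KERNELS
    seed: int = 0
    out_dir: str | None = None

    def sub_seeds(self) -> dict:
        state = np.random.SeedSequence(self.seed).generate_state(5)
        names = ("synth", "split", "augment", "train", "svm")
        return {n: int(s % (2**31)) for n, s in zip(names, state)}


@dataclass
class SettingReport:
    """Results of one experimental setting."""

    setting: str
    accuracies: pd.DataFrame  # feature configuration x kernel
    selection_order: list | None = None
    best_k: dict | None = None  # kernel -> (k, accuracy)
    sweep: object | None = None
    eval_reports: dict | None = None  # kernel -> EvalReport
    confusions: dict | None = None  # kernel -> ConfusionMatrix
    rocs: dict | None = None  # kernel -> ROCData


@dataclass
class PipelineContext:
    """Shared intermediates: split tables, subband streams, features."""

    config: RunConfig
    train_table: DatasetTable
    test_table: DatasetTable
    # backbone -> stream -> FeatureMatrix
    train_features: dict
    test_features: dict

    @property
    def y_train(self):
        return np.array(self.train_table.labels)

    @property
    def y_test(self):
        return np.array(self.test_table.labels)


def _decompose_table(table: DatasetTable, bank) -> dict:
    """Per-stream datasets: original plus the four rendered subbands."""
    streams = {s: [] for s in STREAMS}
    for rec in table:
        sub = decompose(rec.pixels, bank)
        streams["original"].append(rec)
        for tag in ("GW1", "GW2", "GW3", "GW4"):
            streams[tag].append(replace(rec, pixels=sub.rendered[tag]))
    return {s: DatasetTable(records=recs) for s, recs in streams.items()}


def prepare(config: RunConfig) -> PipelineContext:
    """Load/generate data, split, decompose, train ensembles, extract features."""
    seeds = config.sub_seeds()
    if config.dataset_dir is not None:
        table = load_dataset(
            config.dataset_dir,
            config.metadata or Path(config.dataset_dir) / "metadata.csv",
        )
    elif config.synth is not None:
        table, _ = generate_dataset(replace(config.synth, seed=seeds["synth"]))
    else:
        raise ValueError("config needs either synth or dataset_dir")
    if not config.backbones:
        raise ValueError("config.backbones must list at least one backbone")

    train_tbl, test_tbl = stratified_split(
        table, config.train_frac, seed=seeds["split"]
    )
    bank = default_bank()
    train_streams = _decompose_table(train_tbl, bank)
    test_streams = _decompose_table(test_tbl, bank)

    if config.augmentation is not None and config.augmentation.copies_per_image:
        aug = replace(config.augmentation, seed=seeds["augment"])
        fit_streams = {
            s: augment_train(t, aug) for s, t in train_streams.items()
        }
    else:
        fit_streams = train_streams

    train_features, test_features = {}, {}
    train_cfg = replace(config.train, seed=seeds["train"])
    for name in config.backbones:
        spec = BackboneSpec(name)
        ensemble = train_ensemble(spec, fit_streams, train_cfg)
        train_features[name] = {
            s: extract_features(ensemble.branches[s], train_streams[s])
            for s in STREAMS
        }
        test_features[name] = {
            s: extract_features(ensemble.branches[s], test_streams[s])
            for s in STREAMS
        }
    return PipelineContext(
        config=config,
        train_table=train_tbl,
        test_table=test_tbl,
        train_features=train_features,
        test_features=test_features,
    )


def _svm_accuracy(ctx, train_fm, test_fm, kernel) -> float:
    seeds = ctx.config.sub_seeds()
    model = train_classifier(
        train_fm.values, ctx.y_train, SVMSpec(kernel=kernel),
        seed=seeds["svm"],
    )
    return float(np.mean(model.predict(test_fm.values) == ctx.y_test))


def _gw_tags():
    return ["GW1", "GW2", "GW3", "GW4"]


def run_setting_one(
    config: RunConfig, ctx: PipelineContext | None = None
) -> SettingReport:
    """Single-subband and all-GW accuracies per backbone and kernel."""
    ctx = ctx or prepare(config)
    rows = []
    for backbone in config.backbones:
        tr, te = ctx.train_features[backbone], ctx.test_features[backbone]
        for tag in _gw_tags():
            rows.append(_accuracy_row(ctx, backbone, tag, tr, te, [tag]))
        rows.append(
            _accuracy_row(ctx, backbone, "AllGW", tr, te, _gw_tags())
        )
    return SettingReport(
        setting="I",
        accuracies=pd.DataFrame(rows).set_index(["backbone", "features"]),
    )


def _accuracy_row(ctx, backbone, label, tr, te, streams) -> dict:
    train_fm = fuse_streams([tr[s] for s in streams])
    test_fm = fuse_streams([te[s] for s in streams])
    row = {"backbone": backbone, "features": label}
    for kernel in ctx.config.kernels:
        row[kernel] = _svm_accuracy(ctx, train_fm, test_fm, kernel)
    return row


def run_setting_two(
    config: RunConfig, ctx: PipelineContext | None = None
) -> SettingReport:
    """Original-only vs all-GW vs fused accuracies per backbone and kernel."""
    ctx = ctx or prepare(config)
    rows = []
    for backbone in config.backbones:
        tr, te = ctx.train_features[backbone], ctx.test_features[backbone]
        rows.append(
            _accuracy_row(ctx, backbone, "Original", tr, te, ["original"])
        )
        rows.append(_accuracy_row(ctx, backbone, "AllGW", tr, te, _gw_tags()))
        rows.append(
            _accuracy_row(ctx, backbone, "Fused", tr, te, list(STREAMS))
        )
    return SettingReport(
        setting="II",
        accuracies=pd.DataFrame(rows).set_index(["backbone", "features"]),
    )


def run_setting_three(
    config: RunConfig, ctx: PipelineContext | None = None
) -> SettingReport:
    """Cross-backbone fusion + mRMR sweep + full evaluation at the best k."""
    ctx = ctx or prepare(config)
    seeds = config.sub_seeds()
    arity = len(config.backbones)
    train_fused = fuse_backbones(
        [
            fuse_streams([ctx.train_features[b][s] for s in STREAMS])
            for b in config.backbones
        ],
        expected_arity=arity,
    )
    test_fused = fuse_backbones(
        [
            fuse_streams([ctx.test_features[b][s] for s in STREAMS])
            for b in config.backbones
        ],
        expected_arity=arity,
    )
    d = train_fused.n_features
    ks = list(config.mrmr_ks) if config.mrmr_ks else _default_ks(d)

    curve = ablation_sweep(
        train_fused,
        ctx.y_train,
        test_fused,
        ctx.y_test,
        ks=ks,
        kernels=config.kernels,
        svm_seed=seeds["svm"],
    )
    from gaborderm.mrmr import discretize, fit_discretization, mrmr_select

    rule = fit_discretization(train_fused.values)
    selection = mrmr_select(
        discretize(train_fused.values, rule), ctx.y_train, ks[-1]
    )

    best_k, eval_reports, confusions, rocs = {}, {}, {}, {}
    rows = []
    for kernel in config.kernels:
        k, acc = curve.best_k(kernel)
        best_k[kernel] = (k, acc)
        cols = selection.order[:k]
        model = train_classifier(
            train_fused.values[:, cols], ctx.y_train,
            SVMSpec(kernel=kernel), seed=seeds["svm"],
        )
        y_pred = model.predict(test_fused.values[:, cols])
        cm = confusion_matrix(ctx.y_test, y_pred)
        report = compute_metrics(cm)
        scores = model.decision_scores(test_fused.values[:, cols])
        roc = roc_curves(scores, ctx.y_test)
        report.auc = roc.auc
        eval_reports[kernel] = report
        confusions[kernel] = cm
        rocs[kernel] = roc
        rows.append(
            {"backbone": "fused", "features": f"best_k={k}",
             "kernel": kernel, "accuracy": acc}
        )

    report_df = pd.DataFrame(rows).set_index(["backbone", "features", "kernel"])
    out = SettingReport(
        setting="III",
        accuracies=report_df,
        selection_order=selection.order,
        best_k=best_k,
        sweep=curve,
        eval_reports=eval_reports,
        confusions=confusions,
        rocs=rocs,
    )
    if config.out_dir:
        _write_setting_three(out, config.out_dir)
    return out


def _default_ks(d: int) -> list:
    step = max(5, d // 7)
    ks = list(range(step, d + 1, step))
    if ks[-1] != d:
        ks.append(d)
    return ks


def _write_setting_three(report: SettingReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.accuracies.to_csv(out / "setting3_accuracies.csv")
    with open(out / "selection_order.txt", "w") as fh:
        fh.write("\n".join(str(i) for i in report.selection_order) + "\n")
    sweep_rows = []
    for kernel, accs in report.sweep.accuracy.items():
        for k, a in zip(report.sweep.ks, accs):
            sweep_rows.append({"k": k, "kernel": kernel, "accuracy": a})
    pd.DataFrame(sweep_rows).to_csv(out / "ablation_sweep.csv", index=False)
    for kernel, rep in report.eval_reports.items():
        with open(out / f"metrics_{kernel}.txt", "w") as fh:
            for key, val in rep.to_dict().items():
                fh.write(f"{key}\t{val:.6f}\n")
        report.confusions[kernel].to_frame().to_csv(
            out / f"confusion_{kernel}.csv"
        )
        roc_rows = []
        for cls, (fpr, tpr) in report.rocs[kernel].curves.items():
            for f, t in zip(fpr, tpr):
                roc_rows.append({"class": cls, "fpr": f, "tpr": t})
        pd.DataFrame(roc_rows).to_csv(
            out / f"roc_{kernel}.csv", index=False
        )
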