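"""The m x 2 cross-validation experiment harness.

The reference protocol compares four classifiers on identical test halves
over ``m`` repeated stratified half/half splits of an imbalanced cohort:

1. **svm** — plain C-SVM on the raw (imbalanced) training half;
2. **biased_svm** — per-class penalties, C- derived from the class ratio;
3. **smote_svm** — minority oversampled by SMOTE (N = K = 5), then C-SVM;
4. **ru_smote_svm** — the combined balancer (boundary-noise removal, RU,
   SMOTE with N = K = 3), then C-SVM.

Each repeat evaluates all four on the same held-out half; metrics are
averaged arithmetically across repeats.  Because Table-style summaries can
be read either as means of per-repeat metrics or as metrics of summed
counts, :class:`ExperimentResult` reports both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import KernelSpec, biased_penalty_from_ratio, train_biased_svm, train_csvm
from .datasets import ExperimentConfig, LabeledDataset
from .metrics import ConfusionMatrix, MetricReport, confusion, evaluate
from .resampling import ResampleParams, balance, oversample_minority

__all__ = ["CLASSIFIER_NAMES", "ExperimentResult", "split_half",
           "run_comparison", "ratio_sweep"]

CLASSIFIER_NAMES = ("svm", "biased_svm", "smote_svm", "ru_smote_svm")


def split_half(dataset: LabeledDataset, seed: int
               ) -> tuple[LabeledDataset, LabeledDataset]:
    """One stratified half/half split.

    Each class is split as evenly as possible; with an odd class count the
    extra sample goes to the training half.  The halves partition the
    dataset exactly.
    """
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (1, -1):
        rows = np.flatnonzero(dataset.labels == cls)
        if len(rows) < 2:
            raise ValueError(f"class {cls:+d} has fewer than 2 samples")
        rows = rng.permutation(rows)
        n_train = (len(rows) + 1) // 2
        train_idx.extend(rows[:n_train])
        test_idx.extend(rows[n_train:])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


@dataclass
class ExperimentResult:
    """Per-repeat confusion matrices and metrics, plus aggregates."""

    confusions: dict[str, list[ConfusionMatrix]]
    reports: dict[str, list[MetricReport]]
    config: ExperimentConfig = field(default_factory=ExperimentConfig)

    @property
    def n_repeats(self) -> int:
        return len(next(iter(self.confusions.values())))

    def mean_metrics(self) -> pd.DataFrame:
        """Arithmetic mean of each metric across repeats (rows = classifiers)."""
        rows = {}
        for name in self.confusions:
            frames = [r.as_dict() for r in self.reports[name]]
            keys = frames[0].keys()
            rows[name] = {
                k: (np.mean([f[k] for f in frames])
                    if all(f[k] is not None for f in frames) else None)
                for k in keys
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    def mean_confusion(self) -> pd.DataFrame:
        """Mean confusion counts across repeats, rounded for display."""
        rows = {}
        for name, cms in self.confusions.items():
            rows[name] = {
                "TP": round(np.mean([c.tp for c in cms])),
                "FN": round(np.mean([c.fn for c in cms])),
                "FP": round(np.mean([c.fp for c in cms])),
                "TN": round(np.mean([c.tn for c in cms])),
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    def pooled_metrics(self) -> pd.DataFrame:
        """Metrics of the summed confusion counts (the other Table reading)."""
        rows = {}
        for name, cms in self.confusions.items():
            total = cms[0]
            for c in cms[1:]:
                total = total + c
            rows[name] = evaluate(total).as_dict()
        return pd.DataFrame.from_dict(rows, orient="index")

    def summary(self) -> str:
        mm = self.mean_metrics().round(4)
        mc = self.mean_confusion()
        table = pd.concat([mc, mm[["accuracy", "g_mean", "f_measure",
                                   "acc_plus", "acc_minus"]]], axis=1)
        lines = [
            f"Four-classifier comparison, m = {self.n_repeats} stratified "
            f"half/half splits (seed {self.config.seed})",
            table.to_string(),
        ]
        return "\n".join(lines)


def _train_four(train: LabeledDataset, config: ExperimentConfig, seed: int):
    """Fit the four classifiers of the comparison on one training half."""
    kernel = KernelSpec(config.kernel, config.gamma)
    std = config.standardize
    models = {}
    models["svm"] = train_csvm(train, config.c, kernel, standardize=std)

    n_ratio = train.n_majority / train.n_minority
    c_minus = biased_penalty_from_ratio(config.c, n_ratio)
    models["biased_svm"] = train_biased_svm(train, config.c, c_minus, kernel,
                                            standardize=std)

    ss = np.random.SeedSequence(seed)
    s_smote, s_ru = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))
    smote_train = oversample_minority(train, config.smote_n, config.smote_k,
                                      seed=s_smote, standardize=std)
    models["smote_svm"] = train_csvm(smote_train, config.c, kernel, standardize=std)

    if config.resample == "auto":
        params: ResampleParams | str = "auto"
    else:
        params = ResampleParams(ru_rounds=config.ru_rounds,
                                k_neighbors=config.ru_smote_k,
                                amplification=config.ru_smote_n)
    balanced = balance(train, params, seed=s_ru, standardize=std)
    models["ru_smote_svm"] = train_csvm(balanced, config.c, kernel, standardize=std)
    return models


def run_comparison(dataset: LabeledDataset,
                   config: ExperimentConfig) -> ExperimentResult:
    """Run the four-classifier protocol over m repeated half splits.

    Within one repeat all four classifiers are trained on the same training
    half and evaluated on the same test half.  With ``config.swap_halves``
    each split is also run with the halves exchanged (2x-style CV).
    """
    confusions: dict[str, list[ConfusionMatrix]] = {n: [] for n in CLASSIFIER_NAMES}
    reports: dict[str, list[MetricReport]] = {n: [] for n in CLASSIFIER_NAMES}
    ss = np.random.SeedSequence(config.seed)
    for child in ss.spawn(config.cv_repeats):
        rseed = int(child.generate_state(1)[0] % (2 ** 31))
        train, test = split_half(dataset, seed=rseed)
        folds = [(train, test)]
        if config.swap_halves:
            folds.append((test, train))
        for tr, te in folds:
            models = _train_four(tr, config, seed=rseed)
            for name, model in models.items():
                cm = confusion(te.labels, model.predict(te.features))
                confusions[name].append(cm)
                reports[name].append(evaluate(cm))
    return ExperimentResult(confusions, reports, config)


def _evaluate_four(train: LabeledDataset, test: LabeledDataset,
                   config: ExperimentConfig, seed: int
                   ) -> dict[str, ConfusionMatrix]:
    models = _train_four(train, config, seed=seed)
    return {name: confusion(test.labels, m.predict(test.features))
            for name, m in models.items()}


def ratio_sweep(dataset_specs, config: ExperimentConfig,
                test_dataset: LabeledDataset | None = None) -> pd.DataFrame:
    """Accuracy of the four classifiers across training-set class ratios.

    Each spec in ``dataset_specs`` generates a training set; all are
    evaluated against one fixed test set (by default a 75/454 cohort drawn
    from the same cluster model as the first spec).  Returns a table with
    one row per spec (indexed by its majority:minority ratio) and one
    accuracy column per classifier.
    """
    from dataclasses import replace

    from .synthetic import make_gaussian_imbalanced

    specs = list(dataset_specs)
    if not specs:
        raise ValueError("no dataset specs given")
    if test_dataset is None:
        test_spec = replace(specs[0], n_min=75, n_maj=454, noise_fraction=0.0,
                            seed=specs[0].seed + 90001)
        test_dataset = make_gaussian_imbalanced(test_spec)
    rows = []
    index = []
    for spec in specs:
        train = make_gaussian_imbalanced(spec)
        cms = _evaluate_four(train, test_dataset, config, seed=spec.seed)
        rows.append({name: evaluate(cm).accuracy for name, cm in cms.items()})
        index.append(round(spec.n_ratio, 3))
    return pd.DataFrame(rows, index=pd.Index(index, name="n_ratio"))
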