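"""Feature-table assembly, group statistics, and leave-one-person-out
cross-validated classification.

Each retained 4-s epoch yields 18 features: three time-domain statistics
(mean, variance, IQR), six spectral quantities (five relative band
powers and the total 0.5-45 Hz power), four entropies (ApEn, PermEn,
SampEn, MSE) and five connectivity-graph metrics (mean degree,
clustering, path length, efficiency, small-worldness).  Scalar features
are computed per channel and averaged over the 19 channels; graph
features are computed once per epoch from the all-channel graph.

Classification is evaluated with leave-one-person-out cross-validation:
one fold per subject, all of that subject's epochs as the test set, so
train and test never share a subject.  Features are standardised with
train-fold statistics only.  AD is the positive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .complexity import EntropyConfig, apen, mse, permen, sampen
from .core import EpochSet
from .network import NetworkConfig, network_features
from .spectral import SpectralConfig, relative_band_power, time_domain, welch_psd

logger = logging.getLogger("eegdx")

#: Fixed order of the 18 per-epoch features.
FEATURE_NAMES: tuple[str, ...] = (
    "mean", "variance", "iqr",
    "rbp_delta", "rbp_theta", "rbp_alpha", "rbp_beta", "rbp_gamma",
    "total_power",
    "apen", "permen", "sampen", "mse",
    "mean_degree", "clustering", "path_length", "efficiency",
    "small_worldness",
)

KEY_COLUMNS: tuple[str, ...] = ("subject_id", "epoch_index", "group")

POSITIVE_GROUP = "AD"
NEGATIVE_GROUP = "CN"


def _channel_features(x: np.ndarray, fs: float, spectral_cfg: SpectralConfig,
                      entropy_cfg: EntropyConfig) -> dict[str, float]:
    m, v, iqr = time_domain(x)
    freqs, density = welch_psd(x, fs, spectral_cfg.welch)
    rbp, total = relative_band_power(freqs, density, spectral_cfg.bands)
    out = {"mean": m, "variance": v, "iqr": iqr, "total_power": total}
    for band, value in rbp.items():
        out[f"rbp_{band}"] = value
    out["apen"] = apen(x, m=entropy_cfg.apen_m,
                       r_factor=entropy_cfg.apen_r_factor)
    out["permen"] = permen(x, n=entropy_cfg.permen_order)
    out["sampen"] = sampen(x, m=entropy_cfg.sampen_m,
                           r_factor=entropy_cfg.sampen_r_factor)
    out["mse"] = mse(x, m=entropy_cfg.mse_m,
                     r_factor=entropy_cfg.mse_r_factor,
                     tau=entropy_cfg.mse_tau,
                     r_on_coarse=entropy_cfg.mse_r_on_coarse,
                     average_scales=entropy_cfg.mse_average_scales)
    return out


def extract_features(
    epochs: EpochSet,
    spectral_cfg: SpectralConfig | None = None,
    entropy_cfg: EntropyConfig | None = None,
    network_cfg: NetworkConfig | None = None,
    seed: int = 0,
    average_channels_first: bool = False,
) -> pd.DataFrame:
    """Build the per-epoch feature table.

    Returns a DataFrame keyed by (subject_id, epoch_index) with the
    group label and the 18 features.  Epochs with any undefined feature
    (e.g. SampEn with no template match, or a graph too sparse for a
    small-worldness estimate) are dropped, with the count logged.

    ``average_channels_first`` switches the scalar features to the
    alternative aggregation: average the 19 channel signals into one
    virtual channel before computing features, instead of averaging
    per-channel features.
    """
    spectral_cfg = spectral_cfg or SpectralConfig()
    entropy_cfg = entropy_cfg or EntropyConfig()
    network_cfg = network_cfg or NetworkConfig()
    entropy_cfg.validate()
    network_cfg.validate()

    rows = []
    if len(epochs) == 0:
        logger.warning("extract_features: empty epoch set")
    for count, ep in enumerate(epochs.retained):
        if average_channels_first:
            scalar = _channel_features(ep.data.mean(axis=0), ep.fs,
                                       spectral_cfg, entropy_cfg)
        else:
            per_channel = [
                _channel_features(ep.data[i], ep.fs, spectral_cfg,
                                  entropy_cfg)
                for i in range(ep.n_channels)
            ]
            scalar = {k: float(np.mean([c[k] for c in per_channel]))
                      for k in per_channel[0]}
        epoch_seed = int(np.random.SeedSequence(
            (int(seed), count)).generate_state(1)[0] & 0x7FFFFFFF)
        scalar.update(network_features(ep.data, network_cfg,
                                       seed=epoch_seed))
        row = {"subject_id": ep.subject_id, "epoch_index": ep.epoch_index,
               "group": ep.group}
        row.update({k: scalar[k] for k in FEATURE_NAMES})
        rows.append(row)

    table = pd.DataFrame(rows, columns=list(KEY_COLUMNS) + list(FEATURE_NAMES))
    n_before = len(table)
    table = table.dropna()
    dropped = n_before - len(table)
    if dropped:
        logger.info("extract_features: dropped %d/%d epochs with undefined "
                    "features", dropped, n_before)
    return table.reset_index(drop=True)


def group_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature Welch two-sample t-test between AD and CN epochs.

    Returns one row per feature: group means and SDs, the t statistic,
    the p value, the effect direction (sign of mean_AD - mean_CN) and
    significance stars at 0.05 / 0.01 / 0.001.  Features constant in
    both groups have an undefined t statistic and are excluded (logged).
    """
    groups = set(table["group"].unique())
    if not {POSITIVE_GROUP, NEGATIVE_GROUP} <= groups:
        raise ValueError(
            f"both groups {POSITIVE_GROUP!r} and {NEGATIVE_GROUP!r} must be "
            f"present (found {sorted(groups)})")
    ad = table[table["group"] == POSITIVE_GROUP]
    cn = table[table["group"] == NEGATIVE_GROUP]
    if len(ad) < 2 or len(cn) < 2:
        raise ValueError("need >= 2 epochs per group")

    rows = []
    for feat in FEATURE_NAMES:
        a, c = ad[feat].to_numpy(), cn[feat].to_numpy()
        if a.std(ddof=1) == 0 and c.std(ddof=1) == 0:
            logger.info("group_stats: %s constant in both groups; excluded",
                        feat)
            continue
        t, p = stats.ttest_ind(a, c, equal_var=False)
        direction = int(np.sign(a.mean() - c.mean()))
        stars = ("***" if p < 0.001 else "**" if p < 0.01
                 else "*" if p < 0.05 else "")
        rows.append({
            "feature": feat,
            "mean_AD": a.mean(), "sd_AD": a.std(ddof=1),
            "mean_CN": c.mean(), "sd_CN": c.std(ddof=1),
            "t": float(t), "p": float(p),
            "direction": direction, "stars": stars,
        })
    return pd.DataFrame(rows)


@dataclass
class ConfusionCounts:
    """Epoch-level confusion counts for one fold (AD positive)."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class CVResult:
    """Aggregated leave-one-person-out result for one classifier.

    Rates are percentages (0-100), computed from the summed confusion
    counts over all folds:

        accuracy    = (TP + TN) / (TP + TN + FP + FN)
        sensitivity = TP / (TP + FN)
        specificity = TN / (TN + FP)
    """

    classifier: str
    fold_subjects: list[str] = field(default_factory=list)
    fold_counts: list[ConfusionCounts] = field(default_factory=list)

    @property
    def counts(self) -> ConfusionCounts:
        total = ConfusionCounts()
        for c in self.fold_counts:
            total = total + c
        return total

    @property
    def accuracy(self) -> float:
        c = self.counts
        return 100.0 * (c.tp + c.tn) / c.total

    @property
    def sensitivity(self) -> float:
        c = self.counts
        return 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else float("nan")

    @property
    def specificity(self) -> float:
        c = self.counts
        return 100.0 * c.tn / (c.tn + c.fp) if c.tn + c.fp else float("nan")

    def subject_level_accuracy(self) -> float:
        """Majority-vote accuracy over subjects (extension beyond the
        epoch-level protocol)."""
        correct = 0
        for subject, c in zip(self.fold_subjects, self.fold_counts):
            is_ad = c.tp + c.fn > 0
            votes_ad = c.tp + c.fp
            votes_cn = c.tn + c.fn
            predicted_ad = votes_ad > votes_cn
            correct += int(predicted_ad == is_ad)
        return 100.0 * correct / len(self.fold_subjects)


CLASSIFIER_NAMES = ("decision_tree", "random_forest", "svm")


@dataclass
class ClassifierConfig:
    """Hyperparameters of the three classifiers."""

    rf_n_estimators: int = 100
    dt_max_depth: int | None = None
    svm_c: float = 1.0
    svm_gamma: str | float = "median"  # median heuristic on train rows
    standardize: bool = True


def _median_heuristic_gamma(x: np.ndarray, rng: np.random.Generator) -> float:
    """RBF bandwidth 1 / (2 median^2) of pairwise train distances."""
    if len(x) > 500:
        x = x[rng.choice(len(x), 500, replace=False)]
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    med = np.sqrt(np.median(d2[np.triu_indices(len(x), k=1)]))
    if med <= 0:
        return 1.0 / x.shape[1]
    return 1.0 / (2.0 * med ** 2)


def _make_classifier(name: str, cfg: ClassifierConfig, seed: int,
                     x_train: np.ndarray, rng: np.random.Generator):
    if name == "decision_tree":
        return DecisionTreeClassifier(criterion="gini",
                                      max_depth=cfg.dt_max_depth,
                                      random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=cfg.rf_n_estimators,
                                      random_state=seed)
    if name == "svm":
        gamma = (cfg.svm_gamma if isinstance(cfg.svm_gamma, (int, float))
                 else _median_heuristic_gamma(x_train, rng))
        return SVC(C=cfg.svm_c, kernel="rbf", gamma=gamma)
    raise ValueError(
        f"unknown classifier {name!r}; options: {CLASSIFIER_NAMES}")


def lopo_split(table: pd.DataFrame):
    """Leave-one-person-out folds: (train_index, test_index) per subject."""
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects for leave-one-person-out CV")
    for subject in subjects:
        test = table.index[table["subject_id"] == subject]
        train = table.index[table["subject_id"] != subject]
        yield subject, train, test


def evaluate(table: pd.DataFrame, classifier: str = "random_forest",
             seed: int = 0,
             cfg: ClassifierConfig | None = None) -> CVResult:
    """Leave-one-person-out evaluation of one classifier.

    Features are standardised per fold using train-row statistics only;
    the model never sees the held-out subject.  Fixed seed gives a
    reproducible result.
    """
    if classifier not in CLASSIFIER_NAMES:
        raise ValueError(
            f"unknown classifier {classifier!r}; options: {CLASSIFIER_NAMES}")
    cfg = cfg or ClassifierConfig()
    x_all = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y_all = (table["group"] == POSITIVE_GROUP).to_numpy()
    result = CVResult(classifier=classifier)
    rng = np.random.default_rng(seed)
    for subject, train, test in lopo_split(table):
        x_train, x_test = x_all[train], x_all[test]
        y_train, y_test = y_all[train], y_all[test]
        if cfg.standardize:
            scaler = StandardScaler().fit(x_train)
            x_train = scaler.transform(x_train)
            x_test = scaler.transform(x_test)
        model = _make_classifier(classifier, cfg, seed, x_train, rng)
        model.fit(x_train, y_train)
        pred = model.predict(x_test)
        result.fold_subjects.append(subject)
        result.fold_counts.append(ConfusionCounts(
            tp=int(np.sum(pred & y_test)),
            fp=int(np.sum(pred & ~y_test)),
            tn=int(np.sum(~pred & ~y_test)),
            fn=int(np.sum(~pred & y_test)),
        ))
    return result


def evaluate_all(table: pd.DataFrame, seed: int = 0,
                 cfg: ClassifierConfig | None = None
                 ) -> dict[str, CVResult]:
    """Evaluate all three classifiers under the same folds and seed."""
    return {name: evaluate(table, name, seed=seed, cfg=cfg)
            for name in CLASSIFIER_NAMES}


def results_frame(results: dict[str, CVResult]) -> pd.DataFrame:
    """One row per classifier: accuracy / sensitivity / specificity (%)."""
    return pd.DataFrame([
        {"classifier": name,
         "accuracy": r.accuracy,
         "sensitivity": r.sensitivity,
         "specificity": r.specificity,
         "n_epochs": r.counts.total}
        for name, r in results.items()
    ])
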