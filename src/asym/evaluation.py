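"""Metrics, cross-validated comparison with paired significance testing,
calibration binning, attention-direction statistics, efficiency profiling
and the ablation harness.

All headline metrics are percentages.  FLOPs are counted analytically per
layer as 2 x multiply-accumulates; this convention is stamped into every
efficiency report.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .interaction import A2V, V2A, AttentionMap
from .model import AsymModel, ModelConfig
from .train import Sample, TrainConfig, predict_proba, train_model

FLOPS_CONVENTION = "2 x MAC (one multiply-accumulate = 2 FLOPs)"


# ---------------------------------------------------------------------------
# Confusion counts and the five metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def from_predictions(y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return ConfusionCounts(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()))


@dataclass
class MetricsReport:
    """The five classification metrics, in percent; a metric whose
    denominator is zero is reported as NaN and listed in ``undefined``."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    undefined: list[str] = field(default_factory=list)

    @property
    def macro_avg(self) -> float:
        vals = [self.accuracy, self.precision, self.recall,
                self.specificity, self.f1]
        return float(np.mean(vals))

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "specificity": self.specificity,
                "f1": self.f1, "avg": self.macro_avg}


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return 100.0 * num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, specificity and F1, as percentages.

    F1 is the harmonic mean of precision and recall,
    2 * P * R / (P + R).
    """
    und: list[str] = []
    acc = _ratio(c.tp + c.tn, c.n, "accuracy", und)
    prec = _ratio(c.tp, c.tp + c.fp, "precision", und)
    rec = _ratio(c.tp, c.tp + c.fn, "recall", und)
    spec = _ratio(c.tn, c.tn + c.fp, "specificity", und)
    if math.isnan(prec) or math.isnan(rec) or prec + rec == 0:
        und.append("f1")
        f1 = math.nan
    else:
        f1 = f1_from_precision_recall(prec, rec)
    return MetricsReport(acc, prec, rec, spec, f1, und)


def f1_from_precision_recall(precision_pct: float, recall_pct: float) -> float:
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


# ---------------------------------------------------------------------------
# One-sided Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks of |d| (zeros dropped) and the positive-difference mask."""
    d = diffs[diffs != 0]
    order = np.argsort(np.abs(d), kind="stable")
    ranks = np.empty(len(d))
    ranks[order] = np.arange(1, len(d) + 1, dtype=float)
    # average tied ranks
    absd = np.abs(d)
    for val in np.unique(absd):
        mask = absd == val
        if mask.sum() > 1:
            ranks[mask] = ranks[mask].mean()
    return ranks, d > 0


def wilcoxon_onesided(paired_a, paired_b, method: str = "auto",
                      exact_limit: int = 25) -> float:
    """P(one-sided) that scores in ``paired_a`` exceed ``paired_b``.

    Zero differences are dropped; if all differences are zero the p-value
    is reported as 1.  For n <= ``exact_limit`` non-zero pairs the exact
    null distribution of the positive-rank sum is enumerated (all 2^n
    sign patterns, aggregated by dynamic programming over doubled ranks so
    tied average ranks stay integral); above that a normal approximation
    with continuity correction is used.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    ranks, positive = _signed_ranks(a - b)
    n = len(ranks)
    if n == 0:
        return 1.0
    w_plus = float(ranks[positive].sum())
    if method == "exact" or (method == "auto" and n <= exact_limit):
        return _wilcoxon_exact_p(ranks, w_plus)
    return _wilcoxon_normal_p(ranks, w_plus)


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    r2 = np.rint(2.0 * ranks).astype(int)       # doubled ranks are integers
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    w2 = int(round(2.0 * w_plus))
    p = counts[w2:].sum() / counts.sum()
    return float(p)


def _wilcoxon_normal_p(ranks: np.ndarray, w_plus: float) -> float:
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    var = (ranks ** 2).sum() / 4.0   # tie-adjusted: sum r_i^2 / 4
    z = (w_plus - 0.5 - mean) / math.sqrt(var)
    return float(0.5 * math.erfc(z / math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationTable:
    """Equal-width probability bins [0, 0.1), ..., [0.9, 1.0] (last bin
    right-closed); empty bins have count 0 and NaN rates."""

    edges: np.ndarray
    counts: np.ndarray
    mean_predicted: np.ndarray
    positive_rate: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def expected_calibration_error(self) -> float:
        occ = self.counts > 0
        w = self.counts[occ] / self.n
        return float((w * np.abs(self.mean_predicted[occ]
                                 - self.positive_rate[occ])).sum())


def calibration_table(probs, labels, n_bins: int = 10) -> CalibrationTable:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.min() < 0.0 or probs.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.minimum((probs * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=probs, minlength=n_bins)
    pos = np.bincount(idx, weights=labels, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_pred = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        pos_rate = np.where(counts > 0, pos / np.maximum(counts, 1), np.nan)
    return CalibrationTable(edges, counts, mean_pred, pos_rate)


# ---------------------------------------------------------------------------
# k-fold evaluation
# ---------------------------------------------------------------------------

@dataclass
class FoldResults:
    per_fold: list[MetricsReport]
    fold_seeds: list[int]

    def mean_std(self) -> dict[str, tuple[float, float]]:
        out = {}
        for key in ("accuracy", "precision", "recall", "specificity", "f1"):
            vals = np.array([getattr(r, key) for r in self.per_fold])
            out[key] = (float(vals.mean()), float(vals.std(ddof=1)))
        return out

    def scores(self, key: str = "accuracy") -> np.ndarray:
        return np.array([getattr(r, key) for r in self.per_fold])


def stratified_folds(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """Disjoint, class-stratified fold index lists (round-robin deal)."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < k:
            raise ValueError(f"class {c} has fewer samples ({len(idx)}) "
                             f"than folds ({k})")
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f)) for f in folds]


def kfold_evaluate(model_factory, samples: list[Sample], k: int = 5,
                   seed: int = 0) -> FoldResults:
    """Stratified k-fold: ``model_factory(fold_seed)`` must return an object
    with ``fit(samples)`` and ``predict(samples) -> 0/1 labels``."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = [s.label for s in samples]
    folds = stratified_folds(labels, k, seed)
    reports, fold_seeds = [], []
    for i, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train = [s for j, s in enumerate(samples) if j not in test_set]
        test = [samples[j] for j in test_idx]
        fold_seed = seed + 1000 * (i + 1)
        model = model_factory(fold_seed)
        model.fit(train)
        pred = np.asarray(model.predict(test), dtype=int)
        counts = ConfusionCounts.from_predictions([s.label for s in test], pred)
        reports.append(compute_metrics(counts))
        fold_seeds.append(fold_seed)
    return FoldResults(reports, fold_seeds)


# ---------------------------------------------------------------------------
# Attention-direction statistics
# ---------------------------------------------------------------------------

@dataclass
class AttentionDirectionStats:
    mean_weight: dict[str, float]
    intensity: dict[str, float]
    concentration: dict[str, float]
    ridge_offset: dict[str, float]
    p_value: float                 # paired one-sided test on intensity


def attention_direction_stats(maps: dict[str, list[AttentionMap]]
                              ) -> AttentionDirectionStats:
    """Per-direction summary over paired per-sample attention maps.

    The paired comparison (one-sided Wilcoxon signed-rank, alternative:
    first direction greater) is run on the per-sample attention intensity,
    the mean over queries of the maximum attention weight.
    """
    dirs = list(maps)
    if len(dirs) != 2:
        raise ValueError("expected maps for exactly two directions")
    n0, n1 = len(maps[dirs[0]]), len(maps[dirs[1]])
    if n0 != n1:
        raise ValueError("directions must cover the same samples")
    stats = {d: {
        "mean_weight": np.array([m.mean_weight() for m in maps[d]]),
        "intensity": np.array([m.intensity() for m in maps[d]]),
        "concentration": np.array([m.concentration_index() for m in maps[d]]),
        "ridge": np.array([m.ridge_offset() for m in maps[d]]),
    } for d in dirs}
    a = stats[dirs[0]]["intensity"]
    b = stats[dirs[1]]["intensity"]
    p = wilcoxon_onesided(a, b) if len(a) >= 5 else math.nan
    return AttentionDirectionStats(
        mean_weight={d: float(stats[d]["mean_weight"].mean()) for d in dirs},
        intensity={d: float(stats[d]["intensity"].mean()) for d in dirs},
        concentration={d: float(stats[d]["concentration"].mean())
                       for d in dirs},
        ridge_offset={d: float(np.median(stats[d]["ridge"])) for d in dirs},
        p_value=p)


# ---------------------------------------------------------------------------
# Efficiency profiling
# ---------------------------------------------------------------------------

@dataclass
class EfficiencyReport:
    params: int
    params_m: float
    flops_g: dict[int, float]
    per_submodule_params: dict[str, int]
    convention: str = FLOPS_CONVENTION


def parameter_census(model) -> dict[str, int]:
    """Unique trainable parameters attributed to the first top-level
    submodule that owns them (shared parameters counted once)."""
    seen: set[int] = set()
    census: dict[str, int] = {}
    for name, child in model.named_children():
        n = 0
        for _, p in child.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                n += p.data.size
        census[name] = int(n)
    own = 0
    for attr, val in vars(model).items():
        from .nn import Parameter
        if isinstance(val, Parameter) and id(val) not in seen:
            seen.add(id(val))
            own += val.data.size
    if own:
        census["<own>"] = int(own)
    return census


def profile_efficiency(model, lengths=(500, 1000, 10000, 20000, 50000)
                       ) -> EfficiencyReport:
    census = parameter_census(model)
    total = model.n_parameters()
    assert total == sum(census.values()), "census mismatch"
    flops = {int(t): float(model.flops(int(t))) / 1e9 for t in lengths}
    return EfficiencyReport(params=total, params_m=total / 1e6,
                            flops_g=flops, per_submodule_params=census)


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------

ABLATION_SWITCHES = ("audio_only", "video_only", "no_cma", "uni_mamba",
                     "no_fpn", "no_gd", "no_enhance")


def apply_switches(cfg: ModelConfig, switches) -> ModelConfig:
    from dataclasses import replace
    unknown = [s for s in switches if s not in ABLATION_SWITCHES]
    if unknown:
        raise ValueError(f"unknown ablation switches: {unknown}")
    if "audio_only" in switches and "video_only" in switches:
        raise ValueError("audio_only and video_only are contradictory")
    return replace(cfg, **{s: True for s in switches})


def run_ablation(base_cfg: ModelConfig, switch_sets, train_samples,
                 test_samples, train_cfg: TrainConfig, f_audio: int,
                 f_video: int, seed: int = 0,
                 val_samples=None) -> dict[tuple, MetricsReport]:
    """Train and evaluate one model per switch combination."""
    results: dict[tuple, MetricsReport] = {}
    for switches in switch_sets:
        switches = tuple(switches)
        cfg = apply_switches(base_cfg, switches)
        rng = np.random.default_rng(seed)
        model = AsymModel(cfg, f_audio, f_video, rng)
        train_model(model, train_samples, val_samples, train_cfg,
                    np.random.default_rng(seed + 1))
        probs = predict_proba(model, test_samples, train_cfg.batch_size)
        pred = (probs >= 0.5).astype(int)
        counts = ConfusionCounts.from_predictions(
            [s.label for s in test_samples], pred)
        results[switches] = compute_metrics(counts)
    return results
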