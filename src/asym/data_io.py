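"""Dataset plumbing: CSV manifests, random-segment augmentation,
stratified splitting, and the synthetic two-stream generator.

The generator emits per-sample pairs of temporally aligned streams whose
cross-modal correlation is class-dependently lagged (the positive class's
video stream trails its audio stream by ``lag`` steps) and whose
within-stream structure mixes three degradation scales: transient spike
events (video), periodic amplitude modulation with class-dependent decay
(audio), and slow drift (video).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .interaction import AUDIO, VIDEO, ModalSequence
from .train import Sample

logger = logging.getLogger(__name__)

SamplePair = tuple[ModalSequence, ModalSequence]


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentSpec:
    max_segments: int = 5
    min_length: int = 500
    length_mode: str = "min"     # "min": f_length >= min_length; "exact": ==
    seed: int = 0

    def __post_init__(self):
        if self.min_length < 1 or self.max_segments < 1:
            raise ValueError("min_length and max_segments must be >= 1")
        if self.length_mode not in ("min", "exact"):
            raise ValueError(f"unknown length_mode {self.length_mode!r}")


def _n_feasible_crops(t: int, min_len: int, mode: str) -> int:
    if t < min_len:
        return 0
    if mode == "exact":
        return t - min_len + 1
    m = t - min_len + 1
    return m * (m + 1) // 2


def augment_random_segments(pair: SamplePair, spec: AugmentSpec
                            ) -> list[SamplePair]:
    """Jointly crop up to ``max_segments`` label-inheriting sub-sequence
    pairs, each with the same (t_start, f_length) in both modalities.

    Returns an empty list (with a logged warning) when the sequence is
    shorter than ``min_length``.  The number of segments is
    min(max_segments, number of distinct feasible crops), deterministic
    given the seed.
    """
    audio, video = pair
    t = min(audio.n_steps, video.n_steps)
    if t < spec.min_length:
        logger.warning(
            "sample %s: length %d < min segment length %d; no augmented "
            "segments produced", audio.sample_id, t, spec.min_length)
        return []
    rng = np.random.default_rng(spec.seed)
    n_target = min(spec.max_segments,
                   _n_feasible_crops(t, spec.min_length, spec.length_mode))
    crops: list[tuple[int, int]] = []
    seen = set()
    guard = 0
    while len(crops) < n_target and guard < 1000 * spec.max_segments:
        guard += 1
        if spec.length_mode == "exact":
            f_len = spec.min_length
        else:
            f_len = int(rng.integers(spec.min_length, t + 1))
        t_start = int(rng.integers(0, t - f_len + 1))
        if (t_start, f_len) in seen:
            continue
        seen.add((t_start, f_len))
        crops.append((t_start, f_len))
    out = []
    for i, (t0, f_len) in enumerate(crops):
        sl = slice(t0, t0 + f_len)
        out.append((
            ModalSequence(f"{audio.sample_id}_aug{i}", AUDIO,
                          audio.features[sl], audio.label),
            ModalSequence(f"{video.sample_id}_aug{i}", VIDEO,
                          video.features[sl], video.label),
        ))
    return out


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not math.isclose(sum(self.ratios), 1.0, abs_tol=1e-9):
            raise ValueError("train/val/test ratios must sum to 1")
        if any(not 0.0 < r < 1.0 for r in self.ratios):
            raise ValueError("each ratio must lie in (0, 1)")


@dataclass
class ClassSplit:
    n_train: int
    n_val: int
    n_test: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class SplitResult:
    per_class: list[ClassSplit]

    def totals(self) -> tuple[int, int, int]:
        return (sum(c.n_train for c in self.per_class),
                sum(c.n_val for c in self.per_class),
                sum(c.n_test for c in self.per_class))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(class_sizes, spec: SplitSpec) -> SplitResult:
    """Per-class train/val/test partition counts plus shuffled index lists.

    Rounding rule: the train and test shares are rounded half-up per
    class; validation receives the remainder.
    """
    r_train, _, r_test = spec.ratios
    result = []
    for c, n in enumerate(class_sizes):
        if n < 1:
            raise ValueError(f"class {c} has no samples")
        n_train = _round_half_up(r_train * n)
        n_test = _round_half_up(r_test * n)
        n_val = n - n_train - n_test
        if min(n_train, n_val, n_test) <= 0:
            raise ValueError(
                f"class {c} (n={n}) yields an empty partition: "
                f"train={n_train}, val={n_val}, test={n_test}")
        idx = np.random.default_rng(spec.seed + c).permutation(n)
        result.append(ClassSplit(
            n_train, n_val, n_test,
            np.sort(idx[:n_train]),
            np.sort(idx[n_train:n_train + n_val]),
            np.sort(idx[n_train + n_val:])))
    return SplitResult(result)


def split_pairs(pairs: list[SamplePair], spec: SplitSpec
                ) -> dict[str, list[SamplePair]]:
    """Apply the stratified split to concrete sample pairs by label."""
    by_class: dict[int, list[SamplePair]] = {}
    for p in pairs:
        by_class.setdefault(int(p[0].label), []).append(p)
    labels = sorted(by_class)
    res = stratified_split([len(by_class[c]) for c in labels], spec)
    out: dict[str, list[SamplePair]] = {"train": [], "val": [], "test": []}
    for cs, c in zip(res.per_class, labels):
        group = by_class[c]
        out["train"] += [group[i] for i in cs.train_idx]
        out["val"] += [group[i] for i in cs.val_idx]
        out["test"] += [group[i] for i in cs.test_idx]
    return out


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    n_per_class: int = 50
    t_range: tuple[int, int] = (600, 600)
    f_audio: int = 12
    f_video: int = 20
    lag: int = 8                      # audio leads video, positive class only
    # (negative-class, positive-class) values for each degradation cue
    transient_rate: tuple[float, float] = (0.01, 0.05)
    modulation_decay: tuple[float, float] = (0.0, 3.0)
    drift_slope: tuple[float, float] = (0.0, -1.0)
    cue_presence: float = 0.8         # per-sample probability a cue is active
    ar_coeff: float = 0.6
    modulation_depth: float = 0.8
    modulation_cycles: float = 4.0
    noise_scale: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.lag >= self.t_range[0]:
            raise ValueError("lag must be smaller than the shortest sequence")
        if any(r < 0 for r in self.transient_rate):
            raise ValueError("transient rates must be >= 0")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    innov = rng.normal(size=n) * math.sqrt(1.0 - phi * phi)
    z = np.empty(n)
    acc = rng.normal()
    for i in range(n):
        acc = phi * acc + innov[i]
        z[i] = acc
    return z


def generate_synthetic(spec: SyntheticSpec) -> list[SamplePair]:
    """Draw ``2 * n_per_class`` balanced, seed-reproducible sample pairs.

    A shared latent AR(1) signal drives both streams.  Positive class:
    the video stream is the latent delayed by ``lag``; the audio stream's
    periodic amplitude modulation decays; the video stream carries
    transient spikes at an elevated rate plus a negative drift.  Negative
    class: zero lag, stationary modulation, baseline rates.  Observations
    are a rank-1 linear mixing to F_a / F_v channels plus white noise.
    """
    master = np.random.default_rng(spec.seed)
    mix_a = master.normal(size=spec.f_audio)
    mix_a /= np.linalg.norm(mix_a)
    mix_v = master.normal(size=spec.f_video)
    mix_v /= np.linalg.norm(mix_v)
    seeds = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_per_class)
    pairs: list[SamplePair] = []
    for i, ss in enumerate(seeds):
        label = i % 2
        rng = np.random.default_rng(ss)
        t_lo, t_hi = spec.t_range
        T = int(rng.integers(t_lo, t_hi + 1)) if t_hi > t_lo else t_lo
        lag = spec.lag if label == 1 else 0
        z = _ar1(rng, T + spec.lag, spec.ar_coeff)
        src_audio = z[spec.lag:spec.lag + T].copy()
        src_video = z[spec.lag - lag:spec.lag - lag + T].copy()

        active = rng.random(3) < spec.cue_presence if label == 1 \
            else np.zeros(3, dtype=bool)
        tt = np.arange(T) / T
        # audio cue: periodic amplitude modulation, decaying for positives
        decay = spec.modulation_decay[1] if active[0] \
            else spec.modulation_decay[0]
        phase = rng.uniform(0, 2 * math.pi)
        env = 1.0 + spec.modulation_depth * np.exp(-decay * tt) * \
            np.sin(2 * math.pi * spec.modulation_cycles * tt + phase)
        src_audio *= env
        # video cue: transient spike events at class-dependent rate
        rate = spec.transient_rate[1] if active[1] else spec.transient_rate[0]
        spikes = rng.random(T) < rate
        src_video = src_video + spikes * rng.uniform(2.0, 4.0, size=T) \
            * rng.choice([-1.0, 1.0], size=T)
        # video cue: slow drift
        slope = spec.drift_slope[1] if active[2] else spec.drift_slope[0]
        src_video = src_video + slope * tt

        x_audio = (np.outer(src_audio, mix_a)
                   + spec.noise_scale * rng.normal(size=(T, spec.f_audio)))
        x_video = (np.outer(src_video, mix_v)
                   + spec.noise_scale * rng.normal(size=(T, spec.f_video)))
        sid = f"synth_{i:04d}"
        pairs.append((
            ModalSequence(sid, AUDIO, x_audio.astype(np.float32), label),
            ModalSequence(sid, VIDEO, x_video.astype(np.float32), label),
        ))
    return pairs


def pairs_to_samples(pairs: list[SamplePair]) -> list[Sample]:
    return [Sample(a.sample_id, a.features, v.features, int(a.label))
            for a, v in pairs]


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["sample_id", "audio_path", "video_path", "label"]


@dataclass
class Manifest:
    rows: pd.DataFrame
    root: Path | None = None

    def __post_init__(self):
        missing = [c for c in MANIFEST_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        dup = self.rows["sample_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate sample_id at row {int(np.flatnonzero(dup)[0])}")
        for i, lab in enumerate(self.rows["label"]):
            if int(lab) not in (0, 1):
                raise ValueError(f"row {i}: label must be 0 or 1, got {lab!r}")

    def __len__(self) -> int:
        return len(self.rows)


def _load_array(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"array file not found: {path}")
    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D matrix, got shape {arr.shape}")
    return np.asarray(arr, dtype=np.float32)


def load_sample(row, root: Path | None = None) -> SamplePair:
    root = Path(root) if root is not None else Path(".")
    audio = _load_array(root / str(row["audio_path"]))
    video = _load_array(root / str(row["video_path"]))
    label = int(row["label"])
    sid = str(row["sample_id"])
    return (ModalSequence(sid, AUDIO, audio, label),
            ModalSequence(sid, VIDEO, video, label))


def read_manifest(path) -> Manifest:
    path = Path(path)
    df = pd.read_csv(path)
    return Manifest(df, root=path.parent)


def load_manifest_pairs(manifest: Manifest) -> list[SamplePair]:
    out = []
    for i, row in manifest.rows.iterrows():
        try:
            out.append(load_sample(row, root=manifest.root))
        except (ValueError, FileNotFoundError) as e:
            raise type(e)(f"manifest row {i} "
                          f"(sample {row['sample_id']!r}): {e}") from e
    return out


def split_from_manifest(manifest: Manifest, pairs: list[SamplePair]
                        ) -> dict[str, list[SamplePair]]:
    """Partition pairs by the manifest's externally supplied split column."""
    if "split" not in manifest.rows.columns:
        raise ValueError("manifest has no 'split' column")
    assignment = dict(zip(manifest.rows["sample_id"].astype(str),
                          manifest.rows["split"].astype(str)))
    out: dict[str, list[SamplePair]] = {"train": [], "val": [], "test": []}
    for pair in pairs:
        part = assignment.get(pair[0].sample_id)
        if part not in out:
            raise ValueError(
                f"sample {pair[0].sample_id!r}: split must be "
                f"train/val/test, got {part!r}")
        out[part].append(pair)
    return out


def write_dataset(pairs: list[SamplePair], out_dir) -> Manifest:
    """Write per-sample arrays plus a manifest.csv under ``out_dir``."""
    out_dir = Path(out_dir)
    (out_dir / "arrays").mkdir(parents=True, exist_ok=True)
    rows = []
    for a, v in pairs:
        ap = f"arrays/{a.sample_id}_audio.npy"
        vp = f"arrays/{v.sample_id}_video.npy"
        np.save(out_dir / ap, a.features)
        np.save(out_dir / vp, v.features)
        rows.append({"sample_id": a.sample_id, "audio_path": ap,
                     "video_path": vp, "label": int(a.label)})
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(out_dir / "manifest.csv", index=False)
    return Manifest(df, root=out_dir)
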