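"""Registered two-contrast synthetic brain-like phantoms.

Each phantom slice is built from one tissue label map (background, fat rim,
white-matter-like interior, gray-matter-like band/blobs, fluid pockets) and
rendered twice with contrast-specific class intensities: the contrast-1
("T1-like") table brightens fat and darkens fluid, the contrast-2 ("T2-like")
table brightens fluid. The two renderings share the label map exactly, so
every pair is registered by construction and pixelwise metrics are meaningful.
A smooth multiplicative bias field and additive Gaussian noise emulate the
low-frequency intensity variation and noise of real acquisitions.

Dataset manifests are lazy: they store per-slice seeds and render images on
demand, so full-study bookkeeping (thousands of subjects) costs nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

BACKGROUND, FAT, WM, GM, FLUID = 0, 1, 2, 3, 4
CLASS_NAMES = {BACKGROUND: "background", FAT: "fat", WM: "wm", GM: "gm",
               FLUID: "fluid"}

# class mean intensities on the [0, 1] render scale
CONTRAST1_TABLE = {BACKGROUND: 0.02, FAT: 0.95, WM: 0.75, GM: 0.55, FLUID: 0.15}
CONTRAST2_TABLE = {BACKGROUND: 0.02, FAT: 0.55, WM: 0.45, GM: 0.65, FLUID: 0.95}


@dataclass(frozen=True)
class PhantomConfig:
    size: tuple[int, int] = (128, 128)
    intensity_contrast1: dict = field(default_factory=lambda: dict(CONTRAST1_TABLE))
    intensity_contrast2: dict = field(default_factory=lambda: dict(CONTRAST2_TABLE))
    noise_sigma: float = 0.02
    bias_amplitude: float = 0.1

    def __post_init__(self):
        t1, t2 = self.intensity_contrast1, self.intensity_contrast2
        if not (t1[FAT] > t1[WM] > t1[GM] > t1[FLUID]):
            raise ValueError("contrast-1 table must order fat > WM > GM > fluid")
        if not (t2[FLUID] > t2[GM] > t2[WM]):
            raise ValueError("contrast-2 table must order fluid > GM > WM")

    def to_dict(self) -> dict:
        return {
            "size": list(self.size),
            "intensity_contrast1": {str(k): v for k, v in
                                    self.intensity_contrast1.items()},
            "intensity_contrast2": {str(k): v for k, v in
                                    self.intensity_contrast2.items()},
            "noise_sigma": self.noise_sigma,
            "bias_amplitude": self.bias_amplitude,
        }

    @staticmethod
    def from_dict(d: dict) -> "PhantomConfig":
        return PhantomConfig(
            size=tuple(d["size"]),
            intensity_contrast1={int(k): v for k, v in
                                 d["intensity_contrast1"].items()},
            intensity_contrast2={int(k): v for k, v in
                                 d["intensity_contrast2"].items()},
            noise_sigma=d["noise_sigma"],
            bias_amplitude=d["bias_amplitude"],
        )


@dataclass
class SubjectRecord:
    """One registered slice pair sharing a single tissue label map."""

    subject_id: str
    label_map: np.ndarray  # (H, W) int class labels
    contrast1: np.ndarray  # (H, W) float32 in [-1, 1], T1-like
    contrast2: np.ndarray  # (H, W) float32 in [-1, 1], T2-like
    split: str = "train"


def _ellipse_mask(h, w, cy, cx, ry, rx, shape_grid=None):
    yy, xx = np.mgrid[0:h, 0:w] if shape_grid is None else shape_grid
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _label_map(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Randomized nested-ellipse anatomy: fat rim, WM interior, GM band +
    blobs, central fluid pockets."""
    yy, xx = np.mgrid[0:h, 0:w]
    cy = h / 2 + rng.uniform(-0.03, 0.03) * h
    cx = w / 2 + rng.uniform(-0.03, 0.03) * w
    ry = rng.uniform(0.36, 0.44) * h
    rx = rng.uniform(0.36, 0.44) * w
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2

    labels = np.full((h, w), BACKGROUND, dtype=np.int8)
    labels[r2 <= 1.0] = FAT
    labels[r2 <= 0.85**2] = WM
    band = (r2 > 0.58**2) & (r2 <= 0.85**2)
    labels[band] = GM
    # a few GM-like blobs inside the WM
    for _ in range(rng.integers(2, 5)):
        bcy = cy + rng.uniform(-0.25, 0.25) * ry
        bcx = cx + rng.uniform(-0.25, 0.25) * rx
        bry = rng.uniform(0.04, 0.10) * h
        brx = rng.uniform(0.04, 0.10) * w
        blob = _ellipse_mask(h, w, bcy, bcx, bry, brx, (yy, xx))
        labels[blob & (labels == WM)] = GM
    # fluid pockets (ventricle-like), mirrored about the midline
    vry = rng.uniform(0.10, 0.16) * h
    vrx = rng.uniform(0.035, 0.06) * w
    voff = rng.uniform(0.06, 0.11) * w
    for sgn in (-1.0, 1.0):
        vent = _ellipse_mask(h, w, cy, cx + sgn * voff, vry, vrx, (yy, xx))
        labels[vent & (r2 <= 0.58**2)] = FLUID
    return labels


def _bias_field(h: int, w: int, amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """1 + amplitude * (sum of 2-3 low-frequency cosine components, in [-1,1])."""
    yy, xx = np.mgrid[0:h, 0:w]
    m = int(rng.integers(2, 4))
    fld = np.zeros((h, w))
    for _ in range(m):
        fy = rng.uniform(0.5, 1.5) / h
        fx = rng.uniform(0.5, 1.5) / w
        phase = rng.uniform(0, 2 * np.pi)
        fld += np.cos(2 * np.pi * (fy * yy + fx * xx) + phase)
    return 1.0 + amplitude * fld / m


def _render(labels: np.ndarray, table: dict, bias: np.ndarray,
            noise_sigma: float, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros(labels.shape)
    for cls, mean in table.items():
        img[labels == cls] = mean
    img = img * bias
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=labels.shape)
    return np.clip(img * 2.0 - 1.0, -1.0, 1.0).astype(np.float32)


def generate_phantom(config: PhantomConfig, subject_seed: int,
                     max_retries: int = 10) -> SubjectRecord:
    """One registered contrast pair; retries with perturbed seeds if the
    random geometry degenerates (a tissue class ends up empty)."""
    h, w = config.size
    for attempt in range(max_retries):
        rng = np.random.default_rng(int(subject_seed) + attempt)
        labels = _label_map(h, w, rng)
        if all(np.any(labels == cls) for cls in (FAT, WM, GM, FLUID)):
            break
    else:
        raise RuntimeError(f"degenerate phantom geometry for seed {subject_seed}")
    bias = _bias_field(h, w, config.bias_amplitude, rng)
    img1 = _render(labels, config.intensity_contrast1, bias,
                   config.noise_sigma, rng)
    img2 = _render(labels, config.intensity_contrast2, bias,
                   config.noise_sigma, rng)
    return SubjectRecord(subject_id=f"sub-{subject_seed}", label_map=labels,
                         contrast1=img1, contrast2=img2)


@dataclass
class SliceEntry:
    subject_id: str
    slice_index: int
    seed: int
    split: str = "train"


@dataclass
class DatasetManifest:
    """Slice-level records plus the per-domain training slice lists.

    Every entry denotes one registered contrast pair. Training streams for the
    two domains are separate index lists so a dataset can be subsampled
    per-domain (the training data are consumed unpaired).
    """

    config: PhantomConfig
    entries: list[SliceEntry]
    train_a: list[int] = field(default_factory=list)
    train_b: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.train_a and not self.train_b:
            idx = [i for i, e in enumerate(self.entries) if e.split == "train"]
            self.train_a = list(idx)
            self.train_b = list(idx)

    # -- bookkeeping ----------------------------------------------------------

    @property
    def total_slices(self) -> int:
        return 2 * len(self.entries)

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.subject_id, None)
        return list(seen)

    def split_counts(self) -> dict[str, int]:
        split_of: dict[str, str] = {}
        for e in self.entries:
            split_of.setdefault(e.subject_id, e.split)
        counts: dict[str, int] = {}
        for sp in split_of.values():
            counts[sp] = counts.get(sp, 0) + 1
        return counts

    # -- materialization ------------------------------------------------------

    def render(self, index: int) -> SubjectRecord:
        e = self.entries[index]
        rec = generate_phantom(self.config, e.seed)
        rec.subject_id = e.subject_id
        rec.split = e.split
        return rec

    def training_images(self, domain: str) -> list[np.ndarray]:
        """Materialized training slices for one domain ('a' = contrast 1)."""
        idx = self.train_a if domain == "a" else self.train_b
        attr = "contrast1" if domain == "a" else "contrast2"
        return [getattr(self.render(i), attr) for i in idx]

    def paired_slices(self, split: str) -> list[tuple[np.ndarray, np.ndarray]]:
        """Registered (contrast1, contrast2) pairs for a given split."""
        out = []
        for i, e in enumerate(self.entries):
            if e.split == split:
                rec = self.render(i)
                out.append((rec.contrast1, rec.contrast2))
        return out

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "entries": [vars(e) for e in self.entries],
            "train_a": list(self.train_a),
            "train_b": list(self.train_b),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @staticmethod
    def from_dict(d: dict) -> "DatasetManifest":
        return DatasetManifest(
            config=PhantomConfig.from_dict(d["config"]),
            entries=[SliceEntry(**e) for e in d["entries"]],
            train_a=list(d["train_a"]),
            train_b=list(d["train_b"]),
        )

    @staticmethod
    def load(path) -> "DatasetManifest":
        with open(path) as fh:
            return DatasetManifest.from_dict(json.load(fh))


def _slice_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def split_subjects(subject_ids: list, master_seed: int):
    """Shuffle ids, then assign floor(10%) validation, floor(20%) test,
    remainder training. Counts are deterministic in n."""
    n = len(subject_ids)
    if n < 10:
        raise ValueError(f"need at least 10 subjects to split, got {n}")
    rng = np.random.default_rng(master_seed)
    order = list(rng.permutation(n))
    n_val = n // 10
    n_test = (2 * n) // 10
    val = [subject_ids[i] for i in order[:n_val]]
    test = [subject_ids[i] for i in order[n_val : n_val + n_test]]
    train = [subject_ids[i] for i in order[n_val + n_test :]]
    return train, val, test


def generate_dataset(n_subjects: int, slices_per_contrast: int,
                     config: PhantomConfig | None = None,
                     master_seed: int = 0) -> DatasetManifest:
    """Lazy manifest of n_subjects x slices_per_contrast registered pairs.

    Each subject contributes ``slices_per_contrast`` independent 2-D slices
    per contrast; total slice count is n_subjects * slices_per_contrast * 2.
    Subjects are split 70/10/20 when there are at least 10 of them, otherwise
    everything is tagged train.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or PhantomConfig()
    root = np.random.SeedSequence(master_seed)
    subject_seqs = root.spawn(n_subjects)
    ids = [f"sub-{i:05d}" for i in range(n_subjects)]
    if n_subjects >= 10:
        train, val, test = split_subjects(ids, master_seed)
        split_of = {sid: "train" for sid in train}
        split_of.update({sid: "val" for sid in val})
        split_of.update({sid: "test" for sid in test})
    else:
        split_of = {sid: "train" for sid in ids}
    entries = []
    for sid, sseq in zip(ids, subject_seqs):
        for k, slice_seq in enumerate(sseq.spawn(slices_per_contrast)):
            entries.append(SliceEntry(subject_id=sid, slice_index=k,
                                      seed=_slice_seed(slice_seq),
                                      split=split_of[sid]))
    return DatasetManifest(config=config, entries=entries)


def subsample_manifest(manifest: DatasetManifest, n_slices: int,
                       seed: int = 0) -> DatasetManifest:
    """Uniformly subsample the training slices to ``n_slices`` total,
    balanced across the two domains; validation/test are untouched."""
    if n_slices % 2:
        raise ValueError("n_slices must be even (balanced across domains)")
    half = n_slices // 2
    if half > len(manifest.train_a) or half > len(manifest.train_b):
        raise ValueError(
            f"requested {n_slices} training slices but only "
            f"{len(manifest.train_a) + len(manifest.train_b)} available")
    rng = np.random.default_rng(seed)
    pick_a = sorted(rng.choice(len(manifest.train_a), size=half, replace=False))
    pick_b = sorted(rng.choice(len(manifest.train_b), size=half, replace=False))
    return DatasetManifest(
        config=manifest.config,
        entries=list(manifest.entries),
        train_a=[manifest.train_a[i] for i in pick_a],
        train_b=[manifest.train_b[i] for i in pick_b],
    )
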