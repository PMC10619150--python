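"""Dataset manifests, stratified 4:1 splitting, x3 augmentation bookkeeping,
and a synthetic leaf-disease image generator.

The nine-class apple-leaf task distinguishes eight diseases plus healthy
leaves by lesion phenotype: rust shows many small red-orange pustules, grey
spot small grey lesions, frogeye ringed yellow-brown spots, Alternaria dark
brown spots, scab olive blotches, brown spot a large chlorotic (yellowed)
region with brown patches, mosaic yellow mottling, and powdery mildew
whitened veins with pale speckles.  The synthetic generator draws those
phenotypes procedurally on a vein-textured green leaf so the whole training /
evaluation / explanation pipeline can run end to end without any external
image collection.  Generation is a pure function of (spec, seed).

The split rule is stratified per class with ``test = floor(n / 5)`` — a 4:1
train:test ratio — and the augmentation rule appends ``factor - 1``
transformed copies (horizontal flip, small rotations) of every training
original, so an augmented training set is exactly ``factor`` times the
original one.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

#: the nine classes, lexicographic (stable label order)
APPLE_LEAF_CLASSES = (
    "Alternaria leaf spot", "Brown spot", "Frogeye leaf spot", "Grey spot",
    "Health", "Mosaic", "Powdery mildew", "Rust", "Scab",
)

#: per-class sample totals of the multi-source apple-leaf collection the
#: architecture was developed against (inputs to the split arithmetic)
APPLE_LEAF_CLASS_TOTALS = {
    "Alternaria leaf spot": 657,
    "Brown spot": 442,
    "Frogeye leaf spot": 3179,
    "Grey spot": 356,
    "Health": 879,
    "Mosaic": 395,
    "Powdery mildew": 1183,
    "Rust": 2752,
    "Scab": 5407,
}

#: channel means/sds used to normalize inputs (natural-image convention)
NORM_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
NORM_SD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


def stratified_split(per_class_counts) -> list[tuple[int, int]]:
    """Per-class (train, test) counts under the stratified 4:1 rule.

    ``test = floor(n / 5)`` and ``train = n - test`` for every class; this
    reproduces the per-class figures of the reference collection exactly.
    """
    out = []
    for n in per_class_counts:
        n = int(n)
        if n < 1:
            raise ValueError(f"class counts must be positive, got {n}")
        test = n // 5
        out.append((n - test, test))
    return out


@dataclass
class DatasetManifest:
    """Ordered class list plus one row per image.

    ``entries`` columns: path, label, split ('train'/'test'/'' before
    assignment), origin ('original'/'augmented').
    """
    classes: tuple[str, ...]
    entries: pd.DataFrame
    seed: int | None = None

    def __post_init__(self):
        required = {"path", "label", "split", "origin"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")

    @property
    def label_to_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.classes)}

    def subset(self, split: str) -> pd.DataFrame:
        return self.entries[self.entries["split"] == split]

    def class_counts(self, split: str | None = None,
                     origin: str | None = None) -> dict[str, int]:
        df = self.entries
        if split is not None:
            df = df[df["split"] == split]
        if origin is not None:
            df = df[df["origin"] == origin]
        counts = df["label"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in self.classes}

    def to_csv(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# classes={'|'.join(self.classes)};seed={self.seed}\n")
            self.entries.to_csv(fh, index=False)

    @staticmethod
    def from_csv(path) -> "DatasetManifest":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().strip()
            classes: tuple[str, ...] = ()
            seed = None
            if header.startswith("# classes="):
                body = header[2:]
                cpart, spart = body.split(";seed=")
                classes = tuple(cpart[len("classes="):].split("|"))
                seed = None if spart == "None" else int(spart)
                df = pd.read_csv(fh, keep_default_na=False)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, keep_default_na=False)
        if not classes:
            classes = tuple(sorted(df["label"].unique()))
        return DatasetManifest(classes=classes, entries=df, seed=seed)


def assign_split(manifest: DatasetManifest, seed: int) -> DatasetManifest:
    """Random per-class train/test assignment honoring the floor(n/5) rule.

    Reproducible: the permutation of each class's files is drawn from
    ``numpy.random.default_rng(seed)`` over classes in label order.
    """
    rng = np.random.default_rng(seed)
    df = manifest.entries.copy().reset_index(drop=True)
    split_col = np.array([""] * len(df), dtype=object)
    for cls in manifest.classes:
        idx = df.index[(df["label"] == cls) & (df["origin"] == "original")].to_numpy()
        if len(idx) == 0:
            raise ValueError(f"class {cls!r} has no images")
        (_, n_test), = stratified_split([len(idx)])
        perm = rng.permutation(len(idx))
        test_idx = idx[perm[:n_test]]
        split_col[idx] = "train"
        split_col[test_idx] = "test"
    df["split"] = split_col
    return DatasetManifest(classes=manifest.classes, entries=df, seed=seed)


def _augment_image(img: Image.Image, copy_index: int,
                   rng: np.random.Generator) -> Image.Image:
    """Default transform ladder: first copy flips, later copies rotate."""
    if copy_index == 1:
        return img.transpose(Image.FLIP_LEFT_RIGHT)
    angle = float(rng.uniform(-25.0, 25.0))
    out = img.rotate(angle, resample=Image.BILINEAR)
    if copy_index % 2 == 1:
        out = out.transpose(Image.FLIP_LEFT_RIGHT)
    return out


def augment_training_set(manifest: DatasetManifest, factor: int = 3,
                         seed: int = 0, *,
                         write_images: bool = True) -> DatasetManifest:
    """Append ``factor - 1`` transformed copies of every training original.

    The test split is untouched; augmented rows carry origin='augmented'.
    With ``write_images=False`` only the bookkeeping rows are appended
    (dataset-arithmetic checks on manifests without materialized files).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return manifest
    rng = np.random.default_rng(seed)
    rows = []
    train = manifest.entries[(manifest.entries["split"] == "train")
                             & (manifest.entries["origin"] == "original")]
    for _, row in train.iterrows():
        src = Path(row["path"])
        img = None
        for k in range(1, factor):
            dst = src.with_name(f"{src.stem}_aug{k}{src.suffix or '.png'}")
            if write_images:
                if img is None:
                    img = Image.open(src).convert("RGB")
                _augment_image(img, k, rng).save(dst)
            rows.append({"path": str(dst), "label": row["label"],
                         "split": "train", "origin": "augmented"})
    entries = pd.concat([manifest.entries, pd.DataFrame(rows)],
                        ignore_index=True)
    return DatasetManifest(classes=manifest.classes, entries=entries,
                           seed=manifest.seed)


# --------------------------------------------------------------------------
# synthetic leaf-disease generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionPhenotype:
    """Class-conditional lesion statistics, in pixels and 8-bit RGB."""
    spot_count_mean: float = 0.0        # Poisson mean of lesion count
    spot_count_min: int = 0
    spot_radius: float = 0.0            # mean radius, px (at 96 px image)
    spot_radius_sd: float = 0.0
    spot_color: tuple[int, int, int] = (0, 0, 0)
    spot_color_sd: float = 10.0
    ring_color: tuple[int, int, int] | None = None   # halo around each spot
    blotchy: bool = False               # irregular multi-lobe lesions
    chlorosis: bool = False             # one large yellowed region first
    mosaic: bool = False                # angular yellow mottling patches
    vein_whitening: bool = False        # whitened venation + pale speckles


#: default phenotypes at image_size 96 (radii scale linearly with size)
DEFAULT_PHENOTYPES: dict[str, LesionPhenotype] = {
    "Alternaria leaf spot": LesionPhenotype(
        spot_count_mean=5, spot_count_min=4, spot_radius=7, spot_radius_sd=1.0,
        spot_color=(88, 42, 26)),
    "Brown spot": LesionPhenotype(
        spot_count_mean=6, spot_count_min=4, spot_radius=5, spot_radius_sd=1.0,
        spot_color=(105, 55, 22), chlorosis=True),
    "Frogeye leaf spot": LesionPhenotype(
        spot_count_mean=7, spot_count_min=5, spot_radius=5, spot_radius_sd=1.0,
        spot_color=(190, 150, 90), ring_color=(90, 52, 32)),
    "Grey spot": LesionPhenotype(
        spot_count_mean=11, spot_count_min=8, spot_radius=3.5, spot_radius_sd=0.6,
        spot_color=(168, 168, 166)),
    "Health": LesionPhenotype(),
    "Mosaic": LesionPhenotype(mosaic=True),
    "Powdery mildew": LesionPhenotype(vein_whitening=True),
    "Rust": LesionPhenotype(
        spot_count_mean=16, spot_count_min=11, spot_radius=3.0, spot_radius_sd=0.5,
        spot_color=(215, 70, 25)),
    "Scab": LesionPhenotype(
        spot_count_mean=7, spot_count_min=5, spot_radius=5, spot_radius_sd=1.0,
        spot_color=(45, 50, 22), blotchy=True),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings: which classes, how many images, at what size."""
    image_size: int = 96
    n_per_class: int = 200
    seed: int = 0
    classes: tuple[str, ...] = APPLE_LEAF_CLASSES
    phenotypes: dict[str, LesionPhenotype] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPES))
    noise_sd: float = 4.0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        missing = [c for c in self.classes if c not in self.phenotypes]
        if missing:
            raise ValueError(f"no phenotype for classes {missing}")


def _disk_mask(size: int, cy: float, cx: float, r: float,
               yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _paint(img: np.ndarray, mask: np.ndarray, color, rng, sd: float) -> None:
    c = np.asarray(color, dtype=np.float32) + rng.normal(0, sd, 3)
    img[mask] = 0.15 * img[mask] + 0.85 * c[None, :]


def render_leaf(class_name: str, rng: np.random.Generator,
                spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw one leaf image; returns (HxWx3 uint8, HxW bool lesion mask)."""
    s = spec.image_size
    ph = spec.phenotypes[class_name]
    scale = s / 96.0
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)

    base = np.array([58, 118, 48], dtype=np.float32) + rng.normal(0, 8, 3)
    img = np.empty((s, s, 3), dtype=np.float32)
    img[:] = base[None, None, :]
    # gentle illumination gradient
    gdir = rng.normal(size=2)
    gdir /= np.hypot(*gdir) + 1e-9
    img += ((yy * gdir[0] + xx * gdir[1]) / s * rng.uniform(4, 12))[..., None]

    # venation: central main vein plus symmetric side veins
    vein = np.zeros((s, s), dtype=bool)
    cx = s / 2 + rng.uniform(-3, 3) * scale
    vein |= np.abs(xx - cx) < 1.2 * scale
    n_side = 6
    for i in range(n_side):
        y0 = (i + 0.5) * s / n_side + rng.uniform(-2, 2)
        slope = rng.uniform(0.45, 0.8)
        for sign in (-1.0, 1.0):
            d = np.abs((yy - y0) - sign * slope * (xx - cx))
            vein |= (d < 0.9 * scale) & (np.abs(xx - cx) < s * 0.45)
    vein_color = base * 0.9
    img[vein] = vein_color[None, :]

    lesion = np.zeros((s, s), dtype=bool)

    if ph.vein_whitening:
        white = np.array([208, 208, 200], dtype=np.float32) + rng.normal(0, 6, 3)
        img[vein] = 0.2 * img[vein] + 0.8 * white[None, :]
        lesion |= vein
        for _ in range(int(rng.poisson(12)) + 6):
            r = rng.uniform(1.5, 3.5) * scale
            m = _disk_mask(s, rng.uniform(0, s), rng.uniform(0, s), r, yy, xx)
            _paint(img, m, (215, 215, 205), rng, 6)
            lesion |= m

    if ph.mosaic:
        n_patches = int(rng.poisson(7)) + 4
        for _ in range(n_patches):
            cy0, cx0 = rng.uniform(0, s, 2)
            ry, rx = rng.uniform(6, 16, 2) * scale
            theta = rng.uniform(0, np.pi)
            ct, st = np.cos(theta), np.sin(theta)
            u = (yy - cy0) * ct + (xx - cx0) * st
            v = -(yy - cy0) * st + (xx - cx0) * ct
            m = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
            _paint(img, m, (205, 200, 60), rng, 8)
            lesion |= m

    if ph.chlorosis:
        cy0, cx0 = rng.uniform(s * 0.25, s * 0.75, 2)
        r = rng.uniform(0.28, 0.40) * s
        m = _disk_mask(s, cy0, cx0, r, yy, xx)
        _paint(img, m, (200, 160, 35), rng, 8)
        lesion |= m

    if ph.spot_count_mean > 0:
        n_spots = max(int(rng.poisson(ph.spot_count_mean)), ph.spot_count_min)
        for _ in range(n_spots):
            r = max(float(rng.normal(ph.spot_radius, ph.spot_radius_sd)), 1.0) \
                * scale
            cy0, cx0 = rng.uniform(r, s - r, 2)
            if ph.ring_color is not None:
                ring = _disk_mask(s, cy0, cx0, r * 1.6, yy, xx)
                _paint(img, ring, ph.ring_color, rng, ph.spot_color_sd)
                lesion |= ring
            if ph.blotchy:
                m = np.zeros((s, s), dtype=bool)
                for _ in range(3):
                    oy, ox = rng.normal(0, r * 0.7, 2)
                    m |= _disk_mask(s, cy0 + oy, cx0 + ox, r, yy, xx)
            else:
                m = _disk_mask(s, cy0, cx0, r, yy, xx)
            _paint(img, m, ph.spot_color, rng, ph.spot_color_sd)
            lesion |= m

    img += rng.normal(0, spec.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), lesion


def generate_synthetic_arrays(spec: SyntheticSpec
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-memory generation: (images uint8 NxHxWx3, labels int N, masks bool).

    Deterministic: one child generator per (class, index) derived from
    ``spec.seed`` via ``spawn_key``-free integer seeding.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class * len(spec.classes)
    images = np.empty((n, spec.image_size, spec.image_size, 3), dtype=np.uint8)
    labels = np.empty(n, dtype=np.int64)
    masks = np.empty((n, spec.image_size, spec.image_size), dtype=bool)
    i = 0
    for ci, cls in enumerate(spec.classes):
        for _ in range(spec.n_per_class):
            images[i], masks[i] = render_leaf(cls, rng, spec)
            labels[i] = ci
            i += 1
    return images, labels, masks


def generate_synthetic_dataset(spec: SyntheticSpec, out_dir) -> DatasetManifest:
    """Write the synthetic images as PNGs (one subdirectory per class) and
    return the matching manifest (splits unassigned)."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out_dir}: {e}") from e
    images, labels, _ = generate_synthetic_arrays(spec)
    rows = []
    for ci, cls in enumerate(spec.classes):
        cdir = out_dir / cls.replace(" ", "_")
        cdir.mkdir(exist_ok=True)
        for j, idx in enumerate(np.nonzero(labels == ci)[0]):
            p = cdir / f"{cls.replace(' ', '_').lower()}_{j:04d}.png"
            Image.fromarray(images[idx]).save(p)
            rows.append({"path": str(p), "label": cls, "split": "",
                         "origin": "original"})
    manifest = DatasetManifest(classes=tuple(spec.classes),
                               entries=pd.DataFrame(rows), seed=spec.seed)
    return manifest


def load_image_folder(path) -> DatasetManifest:
    """Enumerate an image folder (one subdirectory per class) into a manifest.

    Class order is lexicographic; unreadable files are skipped with a logged
    warning; an empty class directory is an error naming the class.
    """
    path = Path(path)
    if not path.is_dir():
        raise NotADirectoryError(str(path))
    classes = tuple(sorted(d.name for d in path.iterdir() if d.is_dir()))
    if not classes:
        raise ValueError(f"no class subdirectories under {path}")
    rows = []
    for cls in classes:
        files = sorted((path / cls).glob("*"))
        files = [f for f in files
                 if f.suffix.lower() in (".png", ".jpg", ".jpeg")]
        if not files:
            raise ValueError(f"class directory {cls!r} contains no images")
        for f in files:
            rows.append({"path": str(f), "label": cls, "split": "",
                         "origin": "original"})
    return DatasetManifest(classes=classes, entries=pd.DataFrame(rows))


def load_arrays(manifest: DatasetManifest, split: str, *,
                image_size: int = 96, normalize: bool = True,
                mean: np.ndarray = NORM_MEAN, sd: np.ndarray = NORM_SD
                ) -> tuple[np.ndarray, np.ndarray]:
    """Decode a manifest split to (X float32 Nx3xHxW, y int N).

    Images are resized, scaled to [0, 1] and channel-normalized; grayscale
    files are replicated to three channels; corrupt files are skipped with a
    logged warning and count.
    """
    df = manifest.subset(split)
    lab2idx = manifest.label_to_index
    xs, ys, skipped = [], [], 0
    for _, row in df.iterrows():
        try:
            img = Image.open(row["path"]).convert("RGB")
        except OSError:
            skipped += 1
            logger.warning("skipping unreadable image %s", row["path"])
            continue
        if img.size != (image_size, image_size):
            img = img.resize((image_size, image_size), Image.BILINEAR)
        xs.append(np.asarray(img, dtype=np.float32))
        ys.append(lab2idx[row["label"]])
    if skipped:
        logger.warning("skipped %d unreadable images", skipped)
    if not xs:
        raise ValueError(f"no readable images in split {split!r}")
    X = np.stack(xs) / 255.0
    if normalize:
        X = (X - mean[None, None, None, :]) / sd[None, None, None, :]
    return np.ascontiguousarray(X.transpose(0, 3, 1, 2)), np.asarray(ys)


def preprocess_images(images: np.ndarray, *, normalize: bool = True
                      ) -> np.ndarray:
    """uint8 NxHxWx3 (or HxWx3) -> float32 Nx3xHxW, normalized as above."""
    if images.ndim == 3:
        images = images[None]
    X = images.astype(np.float32) / 255.0
    if normalize:
        X = (X - NORM_MEAN[None, None, None, :]) / NORM_SD[None, None, None, :]
    return np.ascontiguousarray(X.transpose(0, 3, 1, 2))


def color_texture_features(images: np.ndarray) -> np.ndarray:
    """Eight per-image color/texture summaries (nearest-class-mean baseline).

    Channel means, gray-level spread, edge density, and dark / red-dominant /
    yellow pixel fractions — enough to separate the synthetic phenotypes but
    far weaker than a CNN.
    """
    if images.ndim == 3:
        images = images[None]
    x = images.astype(np.float32) / 255.0
    r, g, b = x[..., 0], x[..., 1], x[..., 2]
    gray = x.mean(axis=-1)
    gy = np.abs(np.diff(gray, axis=1)).mean(axis=(1, 2))
    gx = np.abs(np.diff(gray, axis=2)).mean(axis=(1, 2))
    feats = [
        r.mean(axis=(1, 2)), g.mean(axis=(1, 2)), b.mean(axis=(1, 2)),
        gray.std(axis=(1, 2)),
        gy + gx,                                   # edge density
        (gray < 0.22).mean(axis=(1, 2)),           # dark-lesion fraction
        ((r - g) > 0.08).mean(axis=(1, 2)),        # red-dominant fraction
        ((r > 0.5) & (g > 0.45) & (b < 0.3)).mean(axis=(1, 2)),  # yellow
    ]
    return np.stack(feats, axis=1)


def nearest_class_mean_accuracy(features: np.ndarray, labels: np.ndarray,
                                train_mask: np.ndarray) -> float:
    """Accuracy of a nearest class-mean classifier on the held-out part."""
    mu = features[train_mask].mean(axis=0)
    sd = features[train_mask].std(axis=0) + 1e-9
    z = (features - mu) / sd
    classes = np.unique(labels[train_mask])
    centers = np.stack([z[train_mask & (labels == c)].mean(axis=0)
                        for c in classes])
    d = ((z[None, ~train_mask, :] - centers[:, None, :]) ** 2).sum(axis=2)
    pred = classes[d.argmin(axis=0)]
    return float((pred == labels[~train_mask]).mean())
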