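"""Image-to-feature backends with a uniform ``images -> FeatureView`` surface.

Three backends share the interface:

* ``cnn_pool`` — a frozen InceptionResNet-v2 global-average-pool feature
  (1536-d), capturing fine local morphology; requires torch + timm.
* ``vit_head`` — a frozen ViT-B/16 pre-softmax head feature (the 1000-unit
  fully connected layer), capturing global context; requires torch + timm.
* ``toy`` — a deterministic closed-form image statistic (per-channel means
  and variances plus coarse 4x4 grayscale block means, 22-d) needing no
  weights, so the full pipeline runs and is testable offline.

All backends are frozen extractors: no training, no dropout, no
augmentation, so two runs over the same images produce identical matrices.
Deep backends resize with bilinear interpolation to their input size; the
resize convention is recorded in the FeatureView metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from PIL import Image

from .data_io import DatasetManifest, FeatureView, InputError

__all__ = ["BackendSpec", "BackendUnavailableError", "extract", "TOY_DIM"]

TOY_DIM = 22  # 3 channel means + 3 channel variances + 16 block means

_DEEP_MODELS = {
    # backend -> (timm model id, input px, reported output dim)
    "cnn_pool": ("inception_resnet_v2", 299, 1536),
    "vit_head": ("vit_base_patch16_224", 224, 1000),
}


class BackendUnavailableError(RuntimeError):
    """The backend's libraries or weights are not available (a configuration
    problem, distinct from invalid input data)."""


@dataclass(frozen=True)
class BackendSpec:
    name: str  # cnn_pool | vit_head | toy
    weights_source: Optional[str] = None
    input_size: Optional[int] = None
    output_dim: Optional[int] = None

    def __post_init__(self) -> None:
        if self.name not in ("cnn_pool", "vit_head", "toy"):
            raise ValueError(f"unknown backend {self.name!r}")
        if self.name == "toy":
            object.__setattr__(self, "output_dim", TOY_DIM)
        else:
            model, px, dim = _DEEP_MODELS[self.name]
            if self.input_size is None:
                object.__setattr__(self, "input_size", px)
            if self.output_dim is None:
                object.__setattr__(self, "output_dim", dim)
            if self.weights_source is None:
                object.__setattr__(self, "weights_source", model)


def _load_image(path: Optional[str], sample_id: str) -> Image.Image:
    if not path:
        raise InputError(f"sample {sample_id!r} has no image_path")
    try:
        img = Image.open(path)
        img.load()
    except (OSError, ValueError) as e:
        raise InputError(f"unreadable image for sample {sample_id!r}: {e}") from None
    return img.convert("RGB")


def _toy_features(img: Image.Image) -> np.ndarray:
    """Per-channel means/variances and 4x4 grayscale block means, on [0, 1]."""
    arr = np.asarray(img, dtype=float) / 255.0  # H x W x 3
    means = arr.mean(axis=(0, 1))
    variances = arr.var(axis=(0, 1))
    gray = arr.mean(axis=2)
    h, w = gray.shape
    hb = np.array_split(np.arange(h), 4)
    wb = np.array_split(np.arange(w), 4)
    blocks = [gray[np.ix_(hi, wi)].mean() for hi in hb for wi in wb]
    return np.concatenate([means, variances, blocks])


def _deep_extractor(spec: BackendSpec):
    try:
        import timm
        import torch
    except ImportError as e:
        raise BackendUnavailableError(
            f"backend {spec.name!r} needs torch and timm "
            f"(install the 'deep' extra); import failed: {e}"
        ) from None
    model_id, _, _ = _DEEP_MODELS[spec.name]
    source = spec.weights_source or model_id
    if spec.name == "cnn_pool":
        # global-average-pool feature, no classification head
        model = timm.create_model(source, pretrained=True, num_classes=0,
                                  global_pool="avg")
    else:
        # keep the 1000-unit head; take its pre-softmax output
        model = timm.create_model(source, pretrained=True)
    model.eval()
    for p in model.parameters():
        p.requires_grad_(False)

    mean = np.array([0.485, 0.456, 0.406])
    sd = np.array([0.229, 0.224, 0.225])

    def run(img: Image.Image) -> np.ndarray:
        resized = img.resize((spec.input_size, spec.input_size), Image.BILINEAR)
        x = np.asarray(resized, dtype=np.float32) / 255.0
        x = (x - mean) / sd
        t = torch.from_numpy(x.transpose(2, 0, 1)[None]).float()
        with torch.no_grad():
            out = model(t)
        return out.numpy().ravel().astype(float)

    return run


def extract(manifest: DatasetManifest, spec: BackendSpec) -> FeatureView:
    """Extract one feature row per manifest sample, in manifest order."""
    if spec.name == "toy":
        runner = _toy_features
    else:
        runner = _deep_extractor(spec)
    rows = []
    for s in manifest.samples:
        img = _load_image(s.image_path, s.sample_id)
        rows.append(runner(img))
    matrix = np.vstack(rows) if rows else np.empty((0, spec.output_dim))
    return FeatureView(
        view_name=spec.name,
        sample_ids=tuple(manifest.sample_ids),
        matrix=matrix,
        metadata={
            "backend": spec.name,
            "weights_source": spec.weights_source,
            "input_size": spec.input_size,
            "resize": "bilinear" if spec.name != "toy" else "none",
        },
    )
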