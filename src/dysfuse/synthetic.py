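"""Two-view synthetic feature generator with complementary class sensitivity.

Emulates the statistical structure the fusion pipeline is designed for:
a class-imbalanced binary problem (presence P of dysplasia outnumbering
absence A roughly 3:1) observed through two feature views with *asymmetric*
separability — one view discriminates the presence class well (a local-detail
view), the other the absence class (a global-context view).

Model: each view draws class-conditional spherical Gaussians with diagonal
covariance. A configurable fraction of dimensions carry signal (a mean shift
between classes); the rest are pure noise. A linear SVM is Bayes-consistent
under this model, so closed-form expectations exist for test oracles.

Asymmetry mechanism: a mean shift alone cannot make sensitivity and
specificity differ at a symmetric threshold, so "view favors class c" is
realized by class-conditional variance scaling — the favored class is drawn
with a tighter standard deviation and the other class with a wider one. The
tight class forms a compact, reliably-classified cluster while the diffuse
class spills across the decision boundary, which is exactly the
SEN/SPE-specialist behavior the fusion rule exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import (
    Category,
    DatasetManifest,
    FeatureView,
    Label,
    Sample,
    merge_labels,
    write_feature_view,
    write_manifest,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "asymmetry_preset"]

# Class-conditional sd multipliers realizing the favored/disfavored asymmetry
# at full separation (delta >= 2). The asymmetry interpolates linearly toward
# symmetric unit scaling as delta -> 0, so a zero-separation config is a true
# null (no class signal in means *or* variances).
FAVORED_SD_SCALE = 0.35
DISFAVORED_SD_SCALE = 1.1
_FULL_ASYMMETRY_DELTA = 2.0


def _sd_scales(delta: float) -> tuple[float, float]:
    t = min(abs(delta) / _FULL_ASYMMETRY_DELTA, 1.0)
    fav = 1.0 + t * (FAVORED_SD_SCALE - 1.0)
    dis = 1.0 + t * (DISFAVORED_SD_SCALE - 1.0)
    return fav, dis


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    delta1/delta2 are standardized mean shifts (Mahalanobis-style separation
    at noise_sd=1) between the class means in each view, applied across the
    signal-carrying axes. View 1 favors class P, view 2 favors class A.
    """

    n_P: int = 180
    n_A: int = 57
    d1: int = 64
    d2: int = 48
    delta1: float = 2.0
    delta2: float = 2.0
    overlap_axis_fraction: float = 0.25
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_P <= 0 or self.n_A <= 0:
            raise ValueError("class counts must be positive")
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValueError("feature dimensions must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 < self.overlap_axis_fraction <= 1):
            raise ValueError("overlap_axis_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticDataset:
    manifest: DatasetManifest
    view1: FeatureView
    view2: FeatureView
    truth: tuple[Label, ...]


def _sample_view(
    rng: np.random.Generator,
    n_p: int,
    n_a: int,
    d: int,
    delta: float,
    frac: float,
    noise_sd: float,
    favored: Label,
    view_name: str,
    sample_ids: tuple[str, ...],
) -> FeatureView:
    n_signal = max(1, int(round(frac * d)))
    # per-axis shift so the total separation across signal axes is ~delta
    shift = delta / np.sqrt(n_signal)
    mean_p = np.zeros(d)
    mean_p[:n_signal] = shift
    fav_scale, dis_scale = _sd_scales(delta)
    sd_p = noise_sd * (fav_scale if favored is Label.P else dis_scale)
    sd_a = noise_sd * (fav_scale if favored is Label.A else dis_scale)
    x_p = rng.normal(loc=mean_p, scale=sd_p, size=(n_p, d))
    x_a = rng.normal(loc=0.0, scale=sd_a, size=(n_a, d))
    return FeatureView(
        view_name=view_name,
        sample_ids=sample_ids,
        matrix=np.vstack([x_p, x_a]),
        metadata={"favored_class": favored.value, "n_signal_axes": n_signal},
    )


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a two-view dataset; a fixed seed reproduces it bit-exactly.

    Rows are ordered P-block then A-block in both views, with identical
    sample-id order. Categories are synthesized consistently with the labels
    (P rows alternate between the two presence categories, A rows are
    leukoplakia without dysplasia).
    """
    rng = np.random.default_rng(config.seed)
    ids = tuple(
        [f"P{i:04d}" for i in range(config.n_P)]
        + [f"A{i:04d}" for i in range(config.n_A)]
    )
    truth = tuple([Label.P] * config.n_P + [Label.A] * config.n_A)
    cats = [
        Category.LEUKO_DYSPLASIA if i % 2 == 0 else Category.OSCC
        for i in range(config.n_P)
    ] + [Category.LEUKO_NO_DYSPLASIA] * config.n_A
    manifest = merge_labels(
        DatasetManifest(tuple(Sample(sid, cat) for sid, cat in zip(ids, cats)))
    )
    view1 = _sample_view(
        rng, config.n_P, config.n_A, config.d1, config.delta1,
        config.overlap_axis_fraction, config.noise_sd, Label.P, "view1", ids,
    )
    view2 = _sample_view(
        rng, config.n_P, config.n_A, config.d2, config.delta2,
        config.overlap_axis_fraction, config.noise_sd, Label.A, "view2", ids,
    )
    return SyntheticDataset(manifest=manifest, view1=view1, view2=view2, truth=truth)


def asymmetry_preset(
    imbalance_ratio: float,
    strength: float,
    n_P: int | None = None,
    n_A: int | None = None,
    seed: int = 0,
) -> SyntheticConfig:
    """Config whose view-1 classifier is a sensitivity specialist and whose
    view-2 classifier is a specificity specialist at default training settings.

    ``strength`` scales the standardized separation in both views; near zero
    both views carry almost no class signal and classifiers are near chance.
    Class counts default to ``n_A = 57`` scaled by the imbalance ratio, and
    can be pinned explicitly.
    """
    if imbalance_ratio < 1:
        raise ValueError("imbalance_ratio must be >= 1")
    if not (0 < strength <= 5):
        raise ValueError("strength must be in (0, 5]")
    if n_A is None:
        n_A = 57
    if n_P is None:
        n_P = int(round(imbalance_ratio * n_A))
    return SyntheticConfig(
        n_P=n_P,
        n_A=n_A,
        delta1=strength,
        delta2=strength,
        seed=seed,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a synthetic dataset (manifest, two views, truth column)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": out / "manifest.csv",
        "view1": out / "view1.csv",
        "view2": out / "view2.csv",
        "truth": out / "truth.csv",
    }
    write_manifest(dataset.manifest, paths["manifest"])
    write_feature_view(dataset.view1, paths["view1"])
    write_feature_view(dataset.view2, paths["view2"])
    with open(paths["truth"], "w") as fh:
        fh.write("sample_id,label\n")
        for sid, lab in zip(dataset.manifest.sample_ids, dataset.truth):
            fh.write(f"{sid},{lab.value}\n")
    return paths
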