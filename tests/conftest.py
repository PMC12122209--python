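import numpy as np
import pytest

from dysfuse.data_io import (
    Category,
    DatasetManifest,
    FeatureView,
    Sample,
    merge_labels,
)


@pytest.fixture
def paper_counts_manifest() -> DatasetManifest:
    """Manifest with the published category composition: 89 leukoplakia with
    dysplasia, 57 without, 91 OSCC."""
    samples = []
    for cat, n, tag in (
        (Category.LEUKO_DYSPLASIA, 89, "LD"),
        (Category.LEUKO_NO_DYSPLASIA, 57, "LN"),
        (Category.OSCC, 91, "OS"),
    ):
        samples.extend(Sample(f"{tag}{i:03d}", cat) for i in range(n))
    return DatasetManifest(tuple(samples))


@pytest.fixture
def labeled_paper_manifest(paper_counts_manifest) -> DatasetManifest:
    return merge_labels(paper_counts_manifest)


@pytest.fixture
def tiny_view() -> FeatureView:
    rng = np.random.default_rng(7)
    ids = tuple(f"s{i}" for i in range(6))
    return FeatureView("tiny", ids, rng.normal(size=(6, 3)))


def make_separable_view(seed: int = 0):
    """Two linearly separable 4-point clouds with fixed coordinates.

    Returns (view, labels): four P points around (+3, +3) and four A points
    around (-3, -3), separated by a wide margin.
    """
    from dysfuse.data_io import Label

    pts = np.array(
        [
            [3.0, 3.0], [3.5, 2.5], [2.5, 3.5], [3.2, 3.1],   # P
            [-3.0, -3.0], [-3.5, -2.5], [-2.5, -3.5], [-3.2, -3.1],  # A
        ]
    )
    ids = tuple(f"p{i}" for i in range(4)) + tuple(f"a{i}" for i in range(4))
    labels = [Label.P] * 4 + [Label.A] * 4
    return FeatureView("sep", ids, pts), labels
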