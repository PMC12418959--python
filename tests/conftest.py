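import numpy as np
import pytest

from mlmf.data import OmicsView, align_views, build_indicator_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_view(values, name="v", sample_prefix="s"):
    """Wrap a raw matrix as an OmicsView with generated labels."""
    values = np.asarray(values, dtype=float)
    d, n = values.shape
    return OmicsView(
        name=name,
        features=tuple(f"{name}_f{i}" for i in range(d)),
        samples=tuple(f"{sample_prefix}{j:03d}" for j in range(n)),
        values=values,
    )


def make_single_view_dataset(values, name="v"):
    return align_views([make_view(values, name=name)])


def complete_indicator(view, dataset):
    return build_indicator_matrix(view, dataset.intact_samples)
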