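import numpy as np
import pytest

from erfscope.architectures import make_erf_variant, build_network


@pytest.fixture(scope="session")
def tiny_variant_spec():
    """Smallest-ERF variant scaled down for fast forward passes."""
    return make_erf_variant("erf11", width_multiplier=0.0625, n_classes=4,
                            input_size=32, seed=7)


@pytest.fixture(scope="session")
def tiny_network(tiny_variant_spec):
    return build_network(tiny_variant_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def empirical_erf(spec, rng, channel_sum=True):
    """Gradient-support oracle for the theoretical receptive field.

    Builds the bare linear convolution stack (no normalization or
    nonlinearity, random weights), backpropagates a unit impulse from a
    centred unit of the last convolutional layer to the input, and returns
    the side of the bounding box of non-zero input-gradient support.
    Independent of the analytic receptive-field arithmetic.
    """
    net = build_network(spec, batchnorm=False, activation=None,
                        rng=np.random.default_rng(rng.integers(2**31)))
    x = rng.normal(size=(1, 1, spec.input_size, spec.input_size)
                   ).astype(np.float32)
    feats = net.features(x, training=True)
    df = np.zeros_like(feats)
    centre = feats.shape[2] // 2
    if channel_sum:
        df[0, :, centre, centre] = 1.0
    else:
        df[0, 0, centre, centre] = 1.0
    dx = net.backward_from_features(df)[0, 0]
    rows = np.nonzero(np.abs(dx).sum(axis=1))[0]
    cols = np.nonzero(np.abs(dx).sum(axis=0))[0]
    if rows.size == 0:
        return 0
    return int(max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))
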