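import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_block(height=8, width=8, channels=8, seed=0, rowconv_kernel=3):
    """A randomly initialised MsHop block with a non-trivial output fusion."""
    from asgbc.mshop import MsHopBlock, MsHopConfig

    gen = np.random.default_rng(seed)
    cfg = MsHopConfig.for_shape(height, width, channels, rowconv_kernel)
    block = MsHopBlock(channels, height, width, cfg, gen)
    # the output fusion is zero-initialised by design; randomise it so the
    # oracle comparison exercises the whole expression
    block.fuse_out.weight.data = gen.normal(0, 0.3, block.fuse_out.weight.shape)
    block.fuse_out.bias.data = gen.normal(0, 0.1, block.fuse_out.bias.shape)
    return block
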