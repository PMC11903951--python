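import random

import pytest
from hypothesis import HealthCheck, settings

from corestream import ChannelConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def config_for(n_internal: int, n_external: int) -> ChannelConfig:
    return ChannelConfig(
        internal=tuple(f"AI{k}" for k in range(1, n_internal + 1)),
        external=tuple(f"AX{k}" for k in range(1, n_external + 1)),
    )


#: every valid (n_internal, n_external) cardinality, 20 in total
ALL_CARDINALITIES = [
    (ni, ne) for ni in range(7) for ne in range(3) if 1 <= ni + ne <= 8
]


@pytest.fixture
def rng():
    return random.Random(20260925)


def random_frame(rng: random.Random, config: ChannelConfig, seq=None):
    from corestream import DataFrame

    return DataFrame(
        seq=rng.randrange(4096) if seq is None else seq,
        internal={ch: rng.randrange(1 << 12) for ch in config.internal},
        external={ch: rng.randrange(1 << 24) for ch in config.external},
        i1=rng.randrange(2),
        i2=rng.randrange(2),
        o1=rng.randrange(2),
        o2=rng.randrange(2),
    )
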