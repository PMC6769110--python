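import numpy as np
import pytest

from edflazy.fixtures import ChannelSpec, FixtureSpec, generate_edf, generate_psg_like


class MemStrategy:
    """In-memory loading strategy: the simplest oracle backend."""

    def __init__(self, data: bytes):
        self.data = data

    def read(self, offset: int, length: int) -> bytes:
        return self.data[offset : offset + length]

    def size(self) -> int:
        return len(self.data)


class CountingStrategy:
    """Wraps a strategy, recording every read for laziness assertions."""

    def __init__(self, inner):
        self.inner = inner
        self.reads: list[tuple[int, int]] = []

    def read(self, offset: int, length: int) -> bytes:
        self.reads.append((offset, length))
        return self.inner.read(offset, length)

    def size(self) -> int:
        return self.inner.size()

    @property
    def bytes_read(self) -> int:
        return sum(length for _, length in self.reads)


@pytest.fixture(scope="session")
def psg_truth():
    """A 19-channel, 60 s PSG-like recording with known samples."""
    return generate_edf(generate_psg_like(seed=3))


@pytest.fixture(scope="session")
def psg_strategy(psg_truth):
    return MemStrategy(psg_truth.raw_bytes)


@pytest.fixture(scope="session")
def small_truth():
    """Two channels with very different rates, handy for trimming edge cases."""
    spec = FixtureSpec(
        seed=7,
        duration_s=10.0,
        channels=(
            ChannelSpec("EEG C4-A1", 100.0, "gaussian-noise", amplitude=150.0),
            ChannelSpec("AIRFLOW", 4.0, "sine", amplitude=80.0),
        ),
    )
    return generate_edf(spec)


@pytest.fixture(scope="session")
def long_truth():
    """A 700 s low-rate recording for cache-span arithmetic."""
    spec = FixtureSpec(
        seed=11,
        duration_s=700.0,
        channels=(ChannelSpec("AIRFLOW", 10.0, "sine", amplitude=50.0),),
    )
    return generate_edf(spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, psg_truth, small_truth):
    d = tmp_path_factory.mktemp("edf_fixtures")
    (d / "psg.edf").write_bytes(psg_truth.raw_bytes)
    (d / "small.edf").write_bytes(small_truth.raw_bytes)
    return d


@pytest.fixture(scope="session")
def http_base(fixture_dir):
    from edflazy.testserver import serve_directory

    with serve_directory(fixture_dir) as url:
        yield url


def random_fixture_spec(rng: np.random.Generator) -> FixtureSpec:
    """A small randomized but always-valid fixture spec."""
    from fractions import Fraction

    record_duration = Fraction(int(rng.choice([1, 2]))) / int(rng.choice([1, 2]))
    n_records = int(rng.integers(2, 12))
    n_channels = int(rng.integers(1, 5))
    channels = []
    for i in range(n_channels):
        spr = int(rng.integers(1, 64))
        fs = spr / record_duration
        channels.append(
            ChannelSpec(
                label=f"CH{i} R{spr}",
                fs=float(fs),
                waveform=str(rng.choice(["sine", "gaussian-noise", "ramp", "constant"])),
                amplitude=float(rng.uniform(1.0, 190.0)),
                wave_hz=float(rng.choice([0.5, 1.0, 2.0])),
                digital_min=-2048,
                digital_max=2047,
            )
        )
    return FixtureSpec(
        seed=int(rng.integers(0, 2**31)),
        duration_s=float(n_records * record_duration),
        record_duration_s=record_duration,
        channels=tuple(channels),
    )
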