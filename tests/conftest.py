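import pytest

from deltafiber import synthetic_data


@pytest.fixture(scope="session")
def crystal_like_sequence():
    """Synthetic δ(1–101)-like record: 62-residue coiled coil + 5 strict repeats."""
    record, truth = synthetic_data.gen_repeat_sequence(
        5, 0, {"cc": 62, "tail": 0}, seed=1)
    return str(record.seq), truth


@pytest.fixture(scope="session")
def full_length_sequence():
    """Full-length δ-like record with strict and relaxed bracelet regions."""
    record, truth = synthetic_data.gen_repeat_sequence(
        5, 11, {"cc": 62, "spacer": 43, "tail": 97}, seed=1)
    return str(record.seq), truth


@pytest.fixture(scope="session")
def ideal_pentamer():
    """Noiseless 5-repeat C5 pentamer with the crystal-region geometry."""
    return synthetic_data.gen_pentamer_coords(
        5, rise=15.0, tilt=45.0, strand_radius=6.0, loop_radius=9.5,
        noise_sd=0.0, seed=0)
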