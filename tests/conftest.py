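import numpy as np
import pytest

from epiclass import Antigen, Region
from epiclass.synth import SynthConfig, generate_dataset


@pytest.fixture
def toy_antigen() -> Antigen:
    """17-residue sequence with one central epitope and flanking negatives."""
    return Antigen(
        id="toy",
        sequence="SYVDLFIRETDFLSLDE",
        regions=[
            Region(1, 5, "nonepitope"),
            Region(6, 11, "epitope"),
            Region(12, 17, "nonepitope"),
        ],
    )


@pytest.fixture(scope="session")
def small_panel() -> list[Antigen]:
    """Ten short synthetic antigens with a strong compositional signal."""
    cfg = SynthConfig(
        n_antigens=10,
        length_range=(60, 90),
        epitope_length_range=(8, 14),
        effect_size=3.0,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_peptide(rng: np.random.Generator, length: int) -> str:
    from epiclass.io import CANONICAL_AA

    return "".join(rng.choice(list(CANONICAL_AA), size=length))
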