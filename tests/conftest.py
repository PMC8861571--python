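import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fdqsar import descriptors as desc
from fdqsar import synthetic_data as sd
from fdqsar.smiles_graph import parse

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synthetic_frame() -> pd.DataFrame:
    """Default 169-compound synthetic dataset with computed descriptors."""
    frame = sd.generate_dataset().set_index("id")
    computed = pd.DataFrame(
        [desc.descriptor_vector(parse(s)) for s in frame["smiles"]],
        index=frame.index,
    )
    return frame.join(computed)


@pytest.fixture(scope="session")
def split_groups(synthetic_frame):
    groups = {
        g: list(synthetic_frame.index[synthetic_frame["split"] == g])
        for g in ("active", "passive", "calibration", "validation")
    }
    train = groups["active"] + groups["passive"] + groups["calibration"]
    return groups, train, groups["validation"]


@pytest.fixture(scope="session")
def sample_smiles() -> list[str]:
    """A diverse pool of generator SMILES plus hand-picked structures."""
    cfg = sd.SyntheticConfig()
    rng = np.random.default_rng(17)
    pool = [sd.generate_compound(rng, cfg, i)[1] for i in range(200)]
    pool += [
        "C",
        "CCO",
        "c1ccccc1",
        "C(=O)O",
        "CC(=O)NC",
        "[NH3+]c1ccccc1",
        "O=C(O)c1ccccc1[N+](=O)[O-]",
        "C1CC1.CCO",
        "c1ccc2ccccc2c1",
        "C%10CCCCC%10",
    ]
    return pool
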