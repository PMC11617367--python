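import numpy as np
import pytest

from dualprot import PipelineConfig, ReferenceProtein
from dualprot.simulate import AA_FREQS


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


def random_protein_seq(rng, length):
    letters = np.array(list(AA_FREQS))
    probs = np.array(list(AA_FREQS.values()))
    return "".join(rng.choice(letters, size=length, p=probs / probs.sum()))


@pytest.fixture(scope="session")
def toy_db():
    """Deterministic 6-protein reference database."""
    rng = np.random.default_rng(42)
    return [ReferenceProtein(accession=f"TOY{i + 1:03d}",
                             sequence=random_protein_seq(rng, L),
                             name=f"TOY{i + 1:03d}_TEST")
            for i, L in enumerate((80, 120, 200, 350, 500, 650))]
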