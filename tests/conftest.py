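import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pipel import LABEL_NONPIP, LABEL_PIP, Peptide, PeptideDataset
from pipel.ensemble import BackendSpec
from pipel.synthetic import SynthSpec, generate

# singleton grid: skips hyperparameter search, keeps tests fast
FAST_RF = BackendSpec("RF", {"n_estimators": [100]})


@pytest.fixture
def fast_backend():
    return FAST_RF


@pytest.fixture
def tiny_dataset():
    """Hand-built dataset with 4 positives and 6 negatives."""
    peps = [
        Peptide(f"p{i}", s, LABEL_PIP)
        for i, s in enumerate(["RLRLR", "LRLRLL", "RRLLRR", "LLRRL"], 1)
    ] + [
        Peptide(f"n{i}", s, LABEL_NONPIP)
        for i, s in enumerate(
            ["GDPGD", "DPGDP", "GGDDP", "PDGPD", "DGDGP", "PPGDD"], 1)
    ]
    return PeptideDataset(peps)


@pytest.fixture
def separable_dataset():
    """Synthetic strongly separated 1:1 dataset (Arg/Leu vs Gly/Asp/Pro)."""
    return generate(SynthSpec(n_pos=60, n_neg=60, effect_size=5.0, seed=7))


def random_peptides(rng: np.random.Generator, n: int, lo: int = 5, hi: int = 25,
                    label: str = LABEL_PIP, prefix: str = "r"):
    from pipel import CANONICAL_ALPHABET
    alphabet = list(CANONICAL_ALPHABET)
    peps = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        peps.append(Peptide(f"{prefix}{i}", "".join(rng.choice(alphabet, L)), label))
    return peps
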