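import numpy as np
import pytest

from hcpk.binding import BindingConstants, BindingSystem


@pytest.fixture
def default_system() -> BindingSystem:
    """Typical plasma milieu: albumin 600 uM, CBG 700 nM, 13% cleaved."""
    return BindingSystem(TotA=600_000.0, TotC_total=700.0, RC=0.13)


@pytest.fixture
def protein_free_system() -> BindingSystem:
    return BindingSystem(TotA=0.0, TotC_total=0.0, RC=0.0)


def random_system(rng: np.random.Generator) -> BindingSystem:
    """A physiologically plausible random binding milieu."""
    return BindingSystem(
        TotA=float(rng.uniform(2e5, 1e6)),
        TotC_total=float(rng.uniform(100.0, 1500.0)),
        RC=float(rng.uniform(0.0, 1.0)),
        constants=BindingConstants(
            K_A=float(rng.uniform(1e5, 6e5)),
            K_Ci=float(rng.uniform(10.0, 100.0)),
            K_Ce=float(rng.uniform(150.0, 1000.0)),
        ),
    )
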