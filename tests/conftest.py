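import numpy as np
import pytest

from lanthakit.binding import (
    BindingSite,
    BindingSystem,
    ChelatorSpecies,
    MetalSpecies,
    MixtureSpec,
)


@pytest.fixture
def single_site_system():
    """One EF site binding one metal: has a closed-form quadratic solution."""
    def make(kd=1e-6):
        return BindingSystem(
            sites=[BindingSite("EF", {"Tb3+": kd})],
            metals=[MetalSpecies("Tb3+")],
        )
    return make


@pytest.fixture
def two_site_competition_system():
    """EF/CD sites, Tb3+ plus Gd3+ competitor, study-condition affinities."""
    return BindingSystem.two_site({"Tb3+": 3e-13, "Gd3+": 7.5e-13})


@pytest.fixture
def study_mixture():
    """4 µM protein + 10 µM Tb3+, the competition-titration baseline."""
    return MixtureSpec(4e-6, {"Tb3+": 10e-6})


@pytest.fixture
def nta_system():
    """Two-site Tb3+ system with the NTA chelator (KD 5.6e-12 M)."""
    return BindingSystem.two_site(
        {"Tb3+": 3e-13},
        chelators=[ChelatorSpecies("NTA", {"Tb3+": 5.6e-12})],
    )


def quadratic_bound(p_tot, m_tot, kd):
    """Closed-form 1:1 complex concentration (independent oracle)."""
    b = p_tot + m_tot + kd
    return (b - np.sqrt(b * b - 4 * p_tot * m_tot)) / 2.0
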