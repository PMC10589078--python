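from hypothesis import HealthCheck, settings
import pytest

from pollenniche.taxonomy import Lineage

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def acer_rubrum():
    return Lineage(
        ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Sapindales",
         "Sapindaceae", "Acer", "Acer rubrum")
    )


@pytest.fixture
def malus_domestica():
    return Lineage(
        ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Rosales",
         "Rosaceae", "Malus", "Malus domestica")
    )


@pytest.fixture
def prunus_avium():
    return Lineage(
        ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Rosales",
         "Rosaceae", "Prunus", "Prunus avium")
    )
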