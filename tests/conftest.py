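import numpy as np
import pytest

import pvsflow as pf


@pytest.fixture(scope="session")
def fluid_unit():
    """Unit-viscosity fluid; resistance scales linearly with mu anyway."""
    return pf.FluidSpec(mu=1.0, Q=2.19e4)


def ellipse_section(b: float, c: float, n: int = 256, z: float = 0.0) -> pf.CrossSection:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return pf.CrossSection(
        z=z, vertices=np.column_stack([b * np.cos(th), c * np.sin(th)])
    )


def ellipse_R_exact(b: float, c: float, mu: float = 1.0) -> float:
    """Closed-form resistance per unit length of an elliptical duct."""
    return 4.0 * mu * (b**2 + c**2) / (np.pi * b**3 * c**3)


@pytest.fixture(scope="session")
def sinusoid_duct():
    """Circular duct with r = 50 + 1.5 sin(2*pi*z/50), two wavelengths."""
    return pf.make_sinusoidal_duct(pf.SinusoidSpec())


@pytest.fixture(scope="session")
def bilobe_duct():
    return pf.make_bilobed_duct(pf.BilobeSpec())


@pytest.fixture(scope="session")
def sinusoid_oracle(sinusoid_duct, fluid_unit):
    """Axisymmetric Stokes solution of the sinusoidal test duct."""
    return pf.axisym_resistance_profile(sinusoid_duct, fluid_unit)


@pytest.fixture(scope="session")
def near_round_sections():
    """20 bumpy near-round sections with minor/major axis ratio > 0.7.

    Random near-elliptical shapes with smooth boundary harmonics, emulating
    moderately irregular, not-too-oblong duct cross sections.
    """
    rng = np.random.default_rng(7)
    out = []
    while len(out) < 20:
        b = 5.0 * (1.0 + 0.4 * rng.random())
        sec = pf.make_perturbed_ellipse_section(
            b=b, c=5.0, harmonic_amp=0.025, seed=int(rng.integers(1 << 31))
        )
        m = pf.polygon_metrics(sec)
        if 1.0 / m.beta > 0.7:
            out.append((sec, m))
    return out
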