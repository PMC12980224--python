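"""Shared fixtures: reference tables and small simulated datasets."""

import numpy as np
import pytest

from cosolv import (
    SoluteDescriptors,
    SolventLFERCoefficients,
)
from cosolv.core import ETHANOL, ETHYL_ACETATE, BinarySolubilityProfile
from cosolv.synthetic import (
    ProfileSimSpec,
    load_reference_table,
    simulate_binary_profile,
    simulate_kat_parameters,
)


@pytest.fixture(scope="session")
def pure_solubility():
    return load_reference_table("pure_solubility")


@pytest.fixture(scope="session")
def water_solubility():
    return load_reference_table("water_solubility").set_index("solute")["x"]


@pytest.fixture(scope="session")
def cnibs_coefficients():
    return load_reference_table("cnibs_coefficients")


@pytest.fixture(scope="session")
def lfer_coefficients():
    df = load_reference_table("lfer_coefficients")
    return {
        r.solvent: SolventLFERCoefficients(
            r.c, r.e, r.s, r.a, r.b, r.v, solvent=r.solvent
        )
        for r in df.itertuples()
    }


@pytest.fixture(scope="session")
def synthetic_descriptors():
    df = load_reference_table("solute_descriptors_synthetic")
    return {
        r.solute: SoluteDescriptors(r.E, r.S, r.A, r.B, r.V, solute=r.solute)
        for r in df.itertuples()
    }


@pytest.fixture(scope="session")
def resveratrol_ethanol_spec():
    """Noise-free simulation spec of the resveratrol / ethanol + ester system."""
    return ProfileSimSpec(
        x1_pure=2583e-5,
        x2_pure=895.0e-5,
        s_coeffs=(4.3347, -1.0773),
        noise_sigma=0.0,
        solute="trans-resveratrol",
    )


@pytest.fixture(scope="session")
def noisefree_profile(resveratrol_ethanol_spec):
    return simulate_binary_profile(resveratrol_ethanol_spec)


@pytest.fixture(scope="session")
def kat_params_default():
    return simulate_kat_parameters()


def make_kat_profile(params, coeffs, noise_sigma=0.0, seed=0):
    """Response profile generated from a dict of KAT term coefficients."""
    grid = np.array([p.x2_ethyl_acetate for p in params])
    mu = []
    for p in params:
        h = p.deltaH2 / 1000.0
        terms = {
            "intercept": 1.0,
            "alpha": p.alpha,
            "alpha^2": p.alpha**2,
            "beta": p.beta,
            "beta^2": p.beta**2,
            "pi_star": p.pi_star,
            "pi_star^2": p.pi_star**2,
            "dh2": h,
            "dh2^2": h**2,
        }
        mu.append(sum(c * terms[t] for t, c in coeffs.items()))
    mu = np.asarray(mu)
    if noise_sigma:
        rng = np.random.default_rng(seed)
        mu = mu * np.exp(rng.normal(0.0, noise_sigma, size=mu.size))
    return BinarySolubilityProfile.from_arrays(
        "synthetic solute", ETHANOL, ETHYL_ACETATE, grid, mu
    )
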