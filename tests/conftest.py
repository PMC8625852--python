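import numpy as np
import pytest
from hypothesis import settings

from invitrodist import ChemicalRecord, SystemSpec, random_panel
from invitrodist.eqp import M3_PER_M2_TO_UL

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel_500():
    """Seeded 500-chemical random panel spanning the declared property space."""
    return random_panel(seed=20260923, n=500)


@pytest.fixture(scope="session")
def neutral_panel_50():
    return random_panel(seed=7, n=50, ion_classes=("neutral",))


@pytest.fixture
def default_system():
    return SystemSpec()


@pytest.fixture
def serum_free_system():
    return SystemSpec(fbs_fraction=0.0)


def brute_force_cw(m_t_umol, capacities_ul):
    """Independent mass-balance solve: root-find the freely-dissolved
    concentration at which the summed phase masses equal the dose.

    Deliberately avoids the closed-form division it is used to check.
    """
    from scipy.optimize import brentq

    def residual(c_w_um):
        return sum(c_w_um * cap * 1e-6 for cap in capacities_ul.values()) - m_t_umol

    v_water = capacities_ul["water"]
    upper = m_t_umol / (v_water * 1e-6)  # all mass in water alone
    return brentq(residual, 0.0, upper, xtol=1e-18, rtol=1e-14)


def capacities_of(parts, vols):
    """Phase capacities in uL-of-water equivalents, mirrored for the oracle."""
    return {
        "water": vols.v_water,
        "headspace": parts.d_aw * vols.v_air,
        "albumin": parts.d_saw * vols.v_albumin,
        "serum_lipid": parts.d_slw * vols.v_serum_lipid,
        "other_dom": parts.d_dsw * vols.v_other_dom,
        "cells": parts.d_cw_adj * vols.v_cells,
        "plastic": parts.d_plw * vols.a_plastic_m2 * M3_PER_M2_TO_UL,
    }
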