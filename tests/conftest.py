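import numpy as np
import pytest

import oxsel as ox


@pytest.fixture(scope="session")
def oil_quant():
    """NMR group concentrations of the oxidized rapeseed oil (mol/kg TAG)."""
    return ox.NmrGroupQuant(aldehyde=0.022, epoxide=0.167, hydroperoxide=0.236)


@pytest.fixture(scope="session")
def oil_profile(oil_quant):
    """Per-chain fractions at the reported 3-decimal precision."""
    return ox.fa_profile_from_nmr(oil_quant, round_decimals=3)


@pytest.fixture(scope="session")
def oil_dist(oil_profile):
    return ox.tag_distribution(oil_profile)


@pytest.fixture(scope="session")
def design():
    return ox.generate_design()


@pytest.fixture(scope="session")
def conditions(design):
    return ox.resolve_conditions(design)


def sodiated_ion(species, n_ox):
    return ox.TargetIon(
        species, n_ox, ox.ADDUCTS["[M+Na]+"], ox.adduct_mz(species, n_ox, "[M+Na]+")
    )


def ammoniated_ion(species, n_ox):
    return ox.TargetIon(
        species, n_ox, ox.ADDUCTS["[M+NH4]+"], ox.adduct_mz(species, n_ox, "[M+NH4]+")
    )


@pytest.fixture(scope="session")
def ooo_na_pair():
    """(3ox-OOO, OOO) sodiated target pair for stage-2 selectivity."""
    return sodiated_ion(ox.OOO, 3), sodiated_ion(ox.OOO, 0)


def random_profile(rng):
    p = rng.dirichlet([1.0, 1.0, 1.0])
    return ox.FaOxidationProfile(p0=float(p[0]), p1=float(p[1]), p2=float(p[2]))
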