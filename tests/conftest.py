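"""Shared fixtures: parameter sets sized for fast, exact property checks."""

from __future__ import annotations

import numpy as np
import pytest

from ivive.params import (
    CompoundProperties,
    DosingRegimen,
    PBPKParameters,
    TissueParameters,
    human_parameters,
)


def make_two_tissue_params(
    fu_plasma: float = 0.06,
    blood_plasma_ratio: float = 0.73,
    hepatic_clearance: float = 50.0,
    brain_ps: float = 0.5,
) -> PBPKParameters:
    """A compact body (liver + brain) for fast exact property tests."""
    return PBPKParameters(
        body_weight=70.0,
        cardiac_output=300.0,
        volume_arterial=1.5,
        volume_venous=3.5,
        lung=TissueParameters("lung", 0.4, 0.5, 300.0, 20.0, 0.01),
        tissues=(
            TissueParameters("liver", 0.3, 1.8, 200.0, 100.0, 0.001),
            TissueParameters("brain", 0.07, 1.45, 100.0, brain_ps, 0.001),
        ),
        hepatic_clearance=hepatic_clearance,
        compound=CompoundProperties(645.31, fu_plasma, blood_plasma_ratio, "amiodarone"),
    )


def make_one_compartment_params(
    blood_volume: float = 5.0, clearance: float = 0.5
) -> PBPKParameters:
    """Near-degenerate body that collapses to one well-stirred blood pool.

    Auxiliary volumes are tiny and flows/PS huge, so the whole system behaves
    as a single pool of volume ``blood_volume`` (the sum of all blood-side
    volumes) eliminated at ``clearance``; all unbound fractions are 1 so the
    closed form (D/V) exp(-CL/V t) applies.
    """
    aux = 0.01
    q = 1.0e5
    return PBPKParameters(
        body_weight=70.0,
        cardiac_output=q,
        volume_arterial=aux,
        volume_venous=blood_volume - 5 * aux,
        lung=TissueParameters("lung", aux, aux, q, 1.0e5, 1.0),
        tissues=(TissueParameters("liver", aux, aux, q, 1.0e5, 1.0),),
        hepatic_clearance=clearance,
        compound=CompoundProperties(645.31, 1.0, 1.0, "probe"),
    )


@pytest.fixture(scope="session")
def human_params():
    return human_parameters()


@pytest.fixture(scope="session")
def small_params():
    return make_two_tissue_params()


@pytest.fixture
def bolus_100():
    return DosingRegimen(dose=100.0)
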