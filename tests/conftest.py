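"""Shared fixtures: small synthetic ensembles and decay data."""

import numpy as np
import pytest

from methylscape import (
    RotamerJumpSpec,
    analytic_o2_for_jump_model,
    simulate_weighted_ensemble,
)
from methylscape.reweight import EnsembleReweighter, ReweightTargets

# Canonical methionine chi3 geometry: trans/gauche± wells 120° apart at the
# tetrahedral polar bond angle.
MET_WELLS = (60.0, 180.0, -60.0)
THETA_TET = 109.47122063449069  # arccos(-1/3) in degrees


@pytest.fixture(scope="session")
def small_recovery():
    """5-residue, 4000-frame recovery fixture (unit-test scale)."""
    # iid equilibrium sampling: the downstream stages depend only on the
    # stationary law, and uncorrelated frames are the cleanest fixture
    prior = RotamerJumpSpec(
        well_angles=MET_WELLS,
        populations=(1 / 3, 1 / 3, 1 / 3),
        kinetics="iid",
        libration_sd=0.0,
        theta_bond=THETA_TET,
        n_frames=4000,
        seed=7,
    )
    target_pops = (0.6, 0.2, 0.2)
    ens, target_o2, labels = simulate_weighted_ensemble(prior, target_pops, 5, seed=7)
    targets = ReweightTargets(
        residue_ids=list(ens.residue_ids),
        o2_mean=target_o2,
        o2_sd=np.full(5, 0.02),
    )
    return {
        "prior": prior,
        "target_pops": np.asarray(target_pops),
        "ensemble": ens,
        "targets": targets,
        "labels": labels,
        "target_o2": target_o2,
    }


@pytest.fixture(scope="session")
def small_recovery_fit(small_recovery):
    """Solved low-θ reweighting of the small recovery fixture.

    Reached through the warm-started continuation path (decreasing θ), the
    intended way to approach a weakly regularized solve: the near-flat
    valley at θ = 0.01 is entered from the well-conditioned solution above.
    """
    rw = EnsembleReweighter(small_recovery["ensemble"], small_recovery["targets"])
    lcurve = rw.l_curve(np.geomspace(0.01, 100.0, 5))
    return rw, lcurve.results[0]


@pytest.fixture(scope="session")
def equal_three_site_o2():
    spec = RotamerJumpSpec(
        well_angles=MET_WELLS,
        populations=(1 / 3, 1 / 3, 1 / 3),
        libration_sd=0.0,
        theta_bond=THETA_TET,
        n_frames=10,
        seed=0,
    )
    return analytic_o2_for_jump_model(spec)
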