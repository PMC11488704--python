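import copy

import numpy as np
import pytest
from hypothesis import settings
from lifelines import KaplanMeierFitter

from sincea.cea import ReferenceSurvival
from sincea.km_reconstruction import reconstruct_ipd
from sincea.survival_models import fit_all_families, select_best
from sincea.synthetic_data import (
    REFERENCE_ARM,
    default_trial_spec,
    default_workbook,
    digitize_km,
    simulate_trial,
)

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trial_ipd():
    """Synthetic trial (n=300/arm, fixed seed): per-arm PFS/OS pseudo-IPD."""
    return simulate_trial(default_trial_spec(seed=1, n_per_arm=300))


@pytest.fixture(scope="session")
def reference_curves(trial_ipd):
    """Digitized reference-arm curves (1-month grid, 3-month risk table)."""
    return {ep: digitize_km(trial_ipd[REFERENCE_ARM][ep]) for ep in ("pfs", "os")}


@pytest.fixture(scope="session")
def reference_fits(reference_curves):
    """Selected parametric fits for the reconstructed reference arm."""
    selected = {}
    for ep, curve in reference_curves.items():
        fits = fit_all_families(reconstruct_ipd(curve))
        selected[ep] = select_best(fits)
    return ReferenceSurvival(pfs=selected["pfs"], os=selected["os"])


@pytest.fixture(scope="session")
def _workbook_template():
    return default_workbook()


@pytest.fixture
def workbook(_workbook_template):
    """Fresh deep copy per test (the workbook is mutable)."""
    return copy.deepcopy(_workbook_template)


def km_on_grid(ipd, grid):
    """KM survival of an IPD frame evaluated at grid times (test oracle)."""
    kmf = KaplanMeierFitter().fit(ipd["time_months"], event_observed=ipd["event"])
    return kmf.survival_function_at_times(np.asarray(grid)).to_numpy(dtype=float)
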