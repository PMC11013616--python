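import numpy as np
import pytest

import ssmetab as sm

#: noise model with every stochastic/nuisance term switched off
QUIET = sm.NoiseModel(
    sigma_log=0.0, intensity_sd=0.0, baseline_amplitude=0.0,
    shift_jitter_sd=0.0, water_amplitude=0.0, urea_amplitude=0.0,
)


@pytest.fixture(scope="session")
def quiet_noise():
    return QUIET


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort shared by read-only tests."""
    design = sm.CohortDesign(seed=0)
    conc, clinical, manifest = sm.generate_cohort(design)
    return design, conc, clinical, manifest


def contrast_screen(seed, case="PAG", control="PAC", effects=None, planted=None,
                    **screen_kw):
    """Generate a cohort, render/calibrate the contrast's spectra, bucket,
    quantify and screen.  ``effects={}`` gives the global null."""
    kw = {}
    if effects is not None:
        kw["effects"] = effects
        kw["planted"] = planted if planted is not None else {}
    design = sm.CohortDesign(seed=seed, **kw)
    conc, clinical, manifest = sm.generate_cohort(design)
    mask = clinical["group"].isin([case, control]).to_numpy()
    spectra = sm.synthesize_cohort_spectra(conc, design)
    spectra = [sm.calibrate(s) for s, m in zip(spectra, mask) if m]
    bins = sm.bin_spectra(spectra)
    quant = sm.quantify(spectra, sm.default_assignment_map())
    table = sm.screen_contrast(quant, bins, clinical.loc[mask], case, control,
                               seed=seed, **screen_kw)
    return table, manifest


@pytest.fixture(scope="session")
def pag_pac_screen():
    """One seeded PAG-vs-PAC screen under the default planted effects."""
    return contrast_screen(seed=7)
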