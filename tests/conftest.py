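import numpy as np
import pytest

from mitoquant import flux, synthetic


@pytest.fixture
def constants():
    """Worked-example constants: BP 0.1, max H+/O2 1, pH 7.4, pK1 6.093,
    P/O ratios 2.5 / 0.1 / 0.1, ATP/lactate 1."""
    return flux.BioenergeticConstants(
        ph=7.4, pk1=6.093, buffering_power=0.1, max_h_per_o2=1.0,
        po_oxphos=2.5, po_tca=0.1, po_glyc=0.1, atp_per_lactate=1.0)


@pytest.fixture
def noise_free_truth():
    """Noise-free well: basal 100, non-mito 20, coupled 0.75, maximal 180."""
    return synthetic.FluxGroundTruth(
        basal_ocr=100.0, nonmito_ocr=20.0, coupled_fraction=0.75,
        maximal_ocr=180.0, ecar=10.0, noise_sd=0.0)


@pytest.fixture
def noise_free_plate(noise_free_truth):
    return synthetic.generate_flux_plate([noise_free_truth])


def make_recovery_plate(n_wells=96, noise_sd=5.0, seed=0):
    """96 identical-truth wells at 5% noise, distinct noise seeds."""
    rng = np.random.default_rng(seed)
    truths = [
        synthetic.FluxGroundTruth(
            basal_ocr=100.0, nonmito_ocr=20.0, coupled_fraction=0.75,
            maximal_ocr=180.0, ecar=10.0, noise_sd=noise_sd,
            seed=int(rng.integers(2 ** 31)))
        for _ in range(n_wells)
    ]
    return synthetic.generate_flux_plate(truths), truths[0]
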