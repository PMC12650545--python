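import numpy as np
import pytest

from phenolmetry.ratiometric import calibrate
from phenolmetry.simulate import PhenolRedBandModel, plate_from_model
from phenolmetry.spectra import average_replicates

# the canonical validation conditions: titration steps spanning the
# indication window, saturating extremes at pH 5.5/9.5, stock at 7.4
IN_RANGE_STEPS = [round(6.9 + 0.1 * i, 2) for i in range(13)]
EXTREME_ACID = 5.5
EXTREME_BASE = 9.5
STOCK_PH = 7.4


@pytest.fixture
def noiseless_model():
    return PhenolRedBandModel(noise_sd=0.0)


@pytest.fixture
def noisy_model():
    return PhenolRedBandModel(noise_sd=0.002, seed=42)


def make_validation_plate(model, replicates=3):
    """Plate with the in-range titration series plus saturating extremes;
    the pH 7.4 step doubles as the stock sample."""
    steps = IN_RANGE_STEPS + [EXTREME_ACID, EXTREME_BASE]
    return plate_from_model(model, steps, replicates=replicates, stock_ph=STOCK_PH)


def calibrate_plate(plate, method="two_point", sign_mode="magnitude"):
    return calibrate(
        plate.wavelengths,
        average_replicates(plate, f"ph{STOCK_PH:.2f}"),
        average_replicates(plate, f"ph{EXTREME_ACID:.2f}"),
        average_replicates(plate, f"ph{EXTREME_BASE:.2f}"),
        STOCK_PH,
        sign_mode=sign_mode,
        method=method,
    )


@pytest.fixture
def noiseless_plate(noiseless_model):
    return make_validation_plate(noiseless_model, replicates=1)


@pytest.fixture
def noiseless_calibration(noiseless_plate):
    return calibrate_plate(noiseless_plate)
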