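import numpy as np
import pytest

from ohcmobility import (
    CircleRoi,
    FrapSimParams,
    RecoveryCurve,
    RoiSet,
    correct_and_normalize,
    simulate_frap_series,
)


def roiset_from_ground_truth(series) -> RoiSet:
    """Build the suggested ROI set a simulated FRAP series carries."""
    gt = series.ground_truth

    def circ(key):
        return CircleRoi(tuple(gt[key]["center"]), gt[key]["radius_px"])

    return RoiSet(bleach=circ("roi_bleach"), reference=circ("roi_reference"),
                  background=circ("roi_background"))


def simulated_curve(seed: int, **overrides) -> RecoveryCurve:
    """One simulated, corrected, normalized recovery curve."""
    params = FrapSimParams(seed=seed, **overrides)
    series = simulate_frap_series(params)
    return correct_and_normalize(series, roiset_from_ground_truth(series))


def flat_null_curve(rng, n_post=18, noise_sd=3.0, frame_interval=10.0) -> RecoveryCurve:
    """A no-recovery curve: f fluctuates around 0 after the bleach."""
    n_pre = 5
    n = n_pre + n_post
    times = np.arange(n) * frame_interval
    f = np.concatenate([
        100.0 + rng.normal(0, noise_sd, n_pre),
        rng.normal(0, noise_sd, n_post),
    ])
    f[n_pre] = 0.0  # normalization anchor
    corrected = 25.0 + f * 0.75
    return RecoveryCurve(
        times_s=times, raw_i=corrected, corrected_i=corrected, f_percent=f,
        i_min=25.0, i_max=100.0, bleach_efficiency_percent=25.0,
        bleach_frame_index=n_pre,
    )


@pytest.fixture(scope="session")
def mobile_curves():
    """Ten simulated curves at the mobile regime phi=0.75, D=0.1, w=2 um."""
    return [simulated_curve(seed) for seed in range(1, 11)]


@pytest.fixture(scope="session")
def immobile_curves():
    """Simulated curves with no mobile fraction (phi=0)."""
    return [simulated_curve(seed, mobile_fraction=0.0) for seed in range(1, 6)]
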