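import numpy as np
import pytest

from fusbeam import (
    ArrayGeometry,
    PulseSpec,
    RoiPolygon,
    ScattererPhantom,
    TxEvent,
    focus_delays,
    make_tone_burst,
)


@pytest.fixture(scope="session")
def geom_small() -> ArrayGeometry:
    """16-element array: cheap enough for oracle comparisons."""
    return ArrayGeometry(n_elements=16, pitch=0.3e-3, f0=5.0e6, fs=20.0e6, c=1540.0)


@pytest.fixture(scope="session")
def geom_mid() -> ArrayGeometry:
    """64-element array used for imaging-quality tests."""
    return ArrayGeometry(n_elements=64, pitch=0.3e-3, f0=5.0e6, fs=20.0e6, c=1540.0)


@pytest.fixture(scope="session")
def geom_full() -> ArrayGeometry:
    """The reference 128-element, 5 MHz probe."""
    return ArrayGeometry()


@pytest.fixture(scope="session")
def vis_pulse() -> PulseSpec:
    return PulseSpec(5.0e6, 2, "visualization")


@pytest.fixture(scope="session")
def vis_wave(vis_pulse, geom_small):
    return make_tone_burst(vis_pulse, geom_small.fs)


@pytest.fixture()
def rect_roi() -> RoiPolygon:
    return RoiPolygon(
        [[-2e-3, 26e-3], [2e-3, 26e-3], [2e-3, 30e-3], [-2e-3, 30e-3]]
    )


def focused_tx(geom: ArrayGeometry, focus) -> TxEvent:
    return TxEvent(delays=focus_delays(geom, focus), kind="focused",
                   focus=(float(focus[0]), float(focus[1])))


def direct_rf_oracle(phantom: ScattererPhantom, geom: ArrayGeometry,
                     tx: TxEvent, waveform: np.ndarray, n_samples: int,
                     t0: float = 0.0) -> np.ndarray:
    """Brute-force per-path channel-data reference.

    The waveform is piecewise linear through its samples and tapers to zero
    over one sample beyond the end (the continuous tone burst returns to
    zero there), matching the simulator's convention.
    """
    w_pad = np.append(np.asarray(waveform, float), 0.0)
    tw = np.arange(w_pad.size) / geom.fs
    ex = geom.element_x
    lam = geom.wavelength
    rf = np.zeros((geom.n_elements, n_samples))
    tgrid = t0 + np.arange(n_samples) / geom.fs
    for s in range(phantom.n_scatterers):
        xs, zs = phantom.positions[s]
        r = np.hypot(ex - xs, zs)
        g = 1.0 / np.maximum(r, lam)
        for j in range(geom.n_elements):
            for i in range(geom.n_elements):
                tt = tgrid - tx.delays[i] - (r[i] + r[j]) / geom.c
                rf[j] += (phantom.amplitudes[s] * g[i] * g[j]
                          * np.interp(tt, tw, w_pad, left=0.0, right=0.0))
    return rf
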