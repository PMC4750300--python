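import math

import pytest

from ciliometry.synth import GroundTruthCilium, RenderConfig, render_stack


@pytest.fixture
def render_single():
    """Render one noise-free cilium in a tight volume; returns (stack, annotation, truth)."""

    def _render(length_um: float, elevation_deg: float, *, azimuth_deg: float = 0.0,
                dxy: float = 0.1, dz: float = 0.25, noise_sd: float = 0.0, seed: int = 0):
        m_xy, m_z = 0.8, 1.0
        el = math.radians(elevation_deg)
        az = math.radians(azimuth_deg)
        ex = length_um * math.cos(el) * abs(math.cos(az))
        ey = length_um * math.cos(el) * abs(math.sin(az))
        zext = length_um * math.sin(el)
        nx = int(math.ceil((ex + 2 * m_xy) / dxy)) + 1
        ny = int(math.ceil((ey + 2 * m_xy) / dxy)) + 1
        nz = int(math.ceil((zext + 2 * m_z) / dz)) + 1
        cfg = RenderConfig(shape=(nz, ny, nx), dxy=dxy, dz=dz, noise_sd=noise_sd, seed=seed)
        truth = GroundTruthCilium("c0", (m_xy, m_xy, m_z), length_um, elevation_deg,
                                  azimuth_deg)
        stack, anns = render_stack([truth], cfg)
        return stack, anns[0], truth

    return _render
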