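import numpy as np
import pytest

from planardose import CompartmentKinetics, Patient
from planardose.dosimetry import DoseConfig, PhantomMasses, SFactorTable


@pytest.fixture
def lu177():
    """Lu-177 DOTA-TATE kinetics: 69 h high; 61/2.4 h low with 1/6-5/6 weights."""
    return CompartmentKinetics(t_half_M_h=69.0, t_half_S_h=61.0, t_half_F_h=2.4)


@pytest.fixture
def patient_m():
    return Patient(sex="M", weight_kg=73.0, administered_activity_MBq=7400.0)


@pytest.fixture
def masses():
    return PhantomMasses(m_BM_g=1170.0, m_body_g=73000.0, m_low_g=71000.0)


@pytest.fixture
def sfactors():
    """A small synthetic S-factor table (synthetic values, not reference-phantom data)."""
    return SFactorTable(
        phantom="M",
        entries={
            ("red_marrow", "red_marrow"): 0.1,
            ("high", "red_marrow"): 2e-3,
            ("low", "red_marrow"): 1e-3,
        },
        provenance="synthetic test fixture",
    )


@pytest.fixture
def dose_config():
    return DoseConfig()


def flood_fill_nuf(image: np.ndarray, c_thr: float, connectivity: int = 8) -> int:
    """Brute-force connected-component count of {pixels > c_thr}.

    Independent oracle: explicit pixel-by-pixel BFS flood fill, no library
    labeling involved.
    """
    mask = np.asarray(image) > c_thr
    visited = np.zeros_like(mask, dtype=bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    n = 0
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not visited[r, c]:
                n += 1
                stack = [(r, c)]
                visited[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < rows and 0 <= c2 < cols and mask[r2, c2] and not visited[r2, c2]:
                            visited[r2, c2] = True
                            stack.append((r2, c2))
    return n
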