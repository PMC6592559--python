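import numpy as np
import pandas as pd
import pytest

from ipcquant import RoiTraceSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trace_frames(
    n_rois: int = 3,
    n_frames: int = 5,
    dt: float = 5.0,
    treatment: str = "HL3",
    brain: str = "b1",
    with_background: bool = False,
    gfp: bool = False,
    base: float = 100.0,
) -> pd.DataFrame:
    """Small well-formed tidy trace table (0.2 Hz grid by default)."""
    rows = []
    for r in range(n_rois):
        t = np.arange(n_frames) * dt
        row = {
            "brain_id": brain,
            "roi_id": f"r{r + 1}",
            "treatment": treatment,
            "t": t,
        }
        if gfp:
            row["gfp"] = base + 10.0 * r + np.linspace(0, 5, n_frames)
        else:
            row["cfp"] = base + 10.0 * r + np.linspace(0, 5, n_frames)
            row["yfp"] = 1.5 * base + 10.0 * r - np.linspace(0, 5, n_frames)
        if with_background:
            for col in (("bg_gfp",) if gfp else ("bg_cfp", "bg_yfp")):
                row[col] = np.full(n_frames, 10.0)
        rows.append(pd.DataFrame(row))
    return pd.concat(rows, ignore_index=True)


@pytest.fixture
def small_traces() -> RoiTraceSet:
    return RoiTraceSet(frames=make_trace_frames(), application_time=100.0, frame_rate=0.2)
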