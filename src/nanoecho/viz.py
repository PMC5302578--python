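"""B-mode rendering and detection-map overlays."""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .features import FeatureMap
from .rfsim import RFFrame

__all__ = ["b_mode", "save_overlay"]


def b_mode(frame: RFFrame, dynamic_range_db: float = 40.0) -> np.ndarray:
    """Log-compressed envelope image in [0, 1] (tracks x samples)."""
    env = np.abs(hilbert(frame.as_float(), axis=-1))
    peak = env.max()
    if peak == 0:
        return np.zeros_like(env)
    db = 20.0 * np.log10(np.maximum(env / peak, 1e-12))
    return np.clip(1.0 + db / dynamic_range_db, 0.0, 1.0)


def save_overlay(path, frame: RFFrame, fmap: FeatureMap,
                 det_map: np.ndarray, dynamic_range_db: float = 40.0,
                 color=(1.0, 0.45, 0.0)) -> None:
    """Write a PNG of the B-mode image with colored detected pixels.

    Detected grid pixels are painted at their window-center locations
    (depth is the vertical axis, as on an echograph screen).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = b_mode(frame, dynamic_range_db).T  # depth down the page
    rgb = np.repeat(img[:, :, None], 3, axis=2)
    lat = fmap.lat_centers
    ax_c = fmap.ax_centers
    det = np.asarray(det_map, dtype=bool)
    ii, jj = np.nonzero(det)
    rgb[ax_c[jj][:, None], lat[ii][:, None], :] = np.asarray(color)
    fig, axis = plt.subplots(figsize=(4, 6))
    axis.imshow(rgb, aspect="auto", interpolation="nearest")
    axis.set_xlabel("track")
    axis.set_ylabel("depth sample")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
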