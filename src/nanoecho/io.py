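"""HDF5 containers for simulated RF acquisitions and feature maps."""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np

from .features import FeatureMap, WindowSpec
from .rfsim import (AcquisitionSpec, GroundTruthMask, PhantomSpec,
                    SimulatedAcquisition)

__all__ = ["save_acquisition", "load_acquisition",
           "save_feature_maps", "load_feature_maps"]


def save_acquisition(path, sim: SimulatedAcquisition) -> None:
    """Write frames, ground-truth mask and full provenance to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=sim.frames, compression="gzip")
        f.create_dataset("mask", data=sim.mask.values, compression="gzip")
        f.create_dataset("lateral_offsets_mm", data=sim.lateral_offsets_mm)
        f.attrs["acquisition"] = json.dumps(asdict(sim.acquisition))
        phantom = asdict(sim.phantom)
        phantom["layer_boundaries_mm"] = list(phantom["layer_boundaries_mm"])
        f.attrs["phantom"] = json.dumps(phantom)
        f.attrs["scale"] = sim.scale


def load_acquisition(path) -> SimulatedAcquisition:
    with h5py.File(path, "r") as f:
        acq_d = json.loads(f.attrs["acquisition"])
        ph_d = json.loads(f.attrs["phantom"])
        ph_d["layer_boundaries_mm"] = tuple(ph_d["layer_boundaries_mm"])
        return SimulatedAcquisition(
            frames=f["frames"][...],
            mask=GroundTruthMask(f["mask"][...]),
            acquisition=AcquisitionSpec(**acq_d),
            phantom=PhantomSpec(**ph_d),
            scale=float(f.attrs["scale"]),
            lateral_offsets_mm=f["lateral_offsets_mm"][...])


def save_feature_maps(path, maps: list[FeatureMap]) -> None:
    """Write a stack of feature maps (one per frame) sharing one grid."""
    if not maps:
        raise ValueError("nothing to save")
    with h5py.File(path, "w") as f:
        f.create_dataset("features",
                         data=np.stack([m.values for m in maps]),
                         compression="gzip")
        f.create_dataset("lat_centers", data=maps[0].lat_centers)
        f.create_dataset("ax_centers", data=maps[0].ax_centers)
        f.create_dataset("frame_indices",
                         data=np.array([m.frame_index for m in maps]))
        f.attrs["window_spec"] = json.dumps(asdict(maps[0].window))
        f.attrs["band_mhz"] = list(maps[0].band_mhz)


def load_feature_maps(path) -> list[FeatureMap]:
    with h5py.File(path, "r") as f:
        w = WindowSpec(**json.loads(f.attrs["window_spec"]))
        band = tuple(f.attrs["band_mhz"])
        vals = f["features"][...]
        lat = f["lat_centers"][...]
        ax = f["ax_centers"][...]
        idx = f["frame_indices"][...]
        return [FeatureMap(vals[k], lat, ax, w, int(idx[k]), band)
                for k in range(vals.shape[0])]
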