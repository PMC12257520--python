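"""Trajectory container: estimator series, centroids, velocities, beads.

The archive is the single hand-off object between the simulation engine
and the analysis pipelines.  It persists to a chunked HDF5 container
(one file per run) and exports bead-annotated extended-XYZ snapshots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["TrajectoryArchive"]


@dataclass
class TrajectoryArchive:
    config: dict
    masses: np.ndarray  # (n_mol, 3)
    species: list  # per-site species of one molecule, e.g. ["O", "H", "D"]
    cell_length: float
    times: np.ndarray  # (n_frames,), ps
    centroid_positions: np.ndarray  # (n_frames, n_mol, 3, 3), unwrapped
    volumes: np.ndarray  # (n_frames,)
    estimators: dict  # name -> (n_frames,)
    velocity_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    centroid_velocities: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 0, 0)))
    dipoles: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    bead_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    bead_positions: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 0, 0, 0)))

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_molecules(self) -> int:
        return self.centroid_positions.shape[1]

    @property
    def n_beads(self) -> int:
        return int(self.config.get("n_beads", 1))

    @property
    def temperature(self) -> float:
        return float(self.config["temperature"])

    def estimator_frame(self):
        """Estimator time series as a pandas DataFrame indexed by time (ps)."""
        import pandas as pd

        return pd.DataFrame(self.estimators, index=pd.Index(self.times, name="time_ps"))

    def with_stride(self, stride: int) -> "TrajectoryArchive":
        """Sub-sampled copy keeping every ``stride``-th frame of each series."""
        return TrajectoryArchive(
            config=dict(self.config),
            masses=self.masses,
            species=list(self.species),
            cell_length=self.cell_length,
            times=self.times[::stride],
            centroid_positions=self.centroid_positions[::stride],
            volumes=self.volumes[::stride],
            estimators={k: v[::stride] for k, v in self.estimators.items()},
            velocity_times=self.velocity_times[::stride],
            centroid_velocities=self.centroid_velocities[::stride],
            dipoles=self.dipoles[::stride],
            bead_times=self.bead_times[::stride],
            bead_positions=self.bead_positions[::stride],
        )

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.attrs["config"] = json.dumps(self.config)
            h5.attrs["species"] = json.dumps(list(self.species))
            h5.attrs["cell_length"] = self.cell_length
            h5.create_dataset("masses", data=self.masses)
            h5.create_dataset("times", data=self.times)
            h5.create_dataset("centroid_positions", data=self.centroid_positions)
            h5.create_dataset("volumes", data=self.volumes)
            est = h5.create_group("estimators")
            for k, v in self.estimators.items():
                est.create_dataset(k, data=v)
            h5.create_dataset("velocity_times", data=self.velocity_times)
            h5.create_dataset("centroid_velocities", data=self.centroid_velocities)
            h5.create_dataset("dipoles", data=self.dipoles)
            h5.create_dataset("bead_times", data=self.bead_times)
            h5.create_dataset("bead_positions", data=self.bead_positions)

    @classmethod
    def load(cls, path) -> "TrajectoryArchive":
        with h5py.File(path, "r") as h5:
            try:
                config = json.loads(h5.attrs["config"])
                species = json.loads(h5.attrs["species"])
                return cls(
                    config=config,
                    masses=h5["masses"][()],
                    species=species,
                    cell_length=float(h5.attrs["cell_length"]),
                    times=h5["times"][()],
                    centroid_positions=h5["centroid_positions"][()],
                    volumes=h5["volumes"][()],
                    estimators={k: h5["estimators"][k][()] for k in h5["estimators"]},
                    velocity_times=h5["velocity_times"][()],
                    centroid_velocities=h5["centroid_velocities"][()],
                    dipoles=h5["dipoles"][()],
                    bead_times=h5["bead_times"][()],
                    bead_positions=h5["bead_positions"][()],
                )
            except KeyError as exc:
                raise IOError(f"truncated or invalid archive {path}: missing {exc}") from exc
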