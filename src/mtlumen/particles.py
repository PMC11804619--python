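"""Particle tables.

A :class:`ParticleSet` wraps a pandas DataFrame with the fixed schema
``particle_id, mt_id, x_nm, y_nm, z_nm, s_nm, mass_kda, class_label`` (plus
optional ``score`` and ``intensity`` columns produced by detection).  ``s_nm``
is the arclength position of the particle's projection onto its MT
centerline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ParticleSet", "PARTICLE_COLUMNS"]

PARTICLE_COLUMNS = ["particle_id", "mt_id", "x_nm", "y_nm", "z_nm",
                    "s_nm", "mass_kda", "class_label"]


@dataclass
class ParticleSet:
    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in PARTICLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"particle table missing columns {missing}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, positions: np.ndarray, mt_id, s_nm=None,
                    mass_kda=None, class_label=None, **extra) -> "ParticleSet":
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = positions.shape[0]
        if positions.size == 0:
            positions = positions.reshape(0, 3)
            n = 0
        tbl = pd.DataFrame({
            "particle_id": np.arange(n),
            "mt_id": np.broadcast_to(np.asarray(mt_id), (n,)).copy(),
            "x_nm": positions[:, 0] if n else np.array([]),
            "y_nm": positions[:, 1] if n else np.array([]),
            "z_nm": positions[:, 2] if n else np.array([]),
            "s_nm": np.broadcast_to(np.nan if s_nm is None else np.asarray(s_nm, float), (n,)).copy(),
            "mass_kda": np.broadcast_to(np.nan if mass_kda is None else np.asarray(mass_kda, float), (n,)).copy(),
            "class_label": np.broadcast_to("" if class_label is None else np.asarray(class_label), (n,)).copy(),
        })
        for k, v in extra.items():
            tbl[k] = v
        return cls(tbl)

    @classmethod
    def empty(cls) -> "ParticleSet":
        return cls.from_arrays(np.empty((0, 3)), mt_id=np.array([], dtype=int))

    @staticmethod
    def concat(sets: list["ParticleSet"]) -> "ParticleSet":
        if not sets:
            return ParticleSet.empty()
        tbl = pd.concat([s.table for s in sets], ignore_index=True)
        tbl["particle_id"] = np.arange(len(tbl))
        return ParticleSet(tbl)

    def __len__(self) -> int:
        return len(self.table)

    def positions(self) -> np.ndarray:
        return self.table[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)

    def arclengths(self) -> np.ndarray:
        return self.table["s_nm"].to_numpy(dtype=float)

    def mt_ids(self) -> np.ndarray:
        return self.table["mt_id"].to_numpy()

    def for_mt(self, mt_id) -> "ParticleSet":
        return ParticleSet(self.table[self.table["mt_id"] == mt_id].copy())

    def filter_class(self, label) -> "ParticleSet":
        return ParticleSet(self.table[self.table["class_label"] == label].copy())

    def to_csv(self, path) -> None:
        cols = PARTICLE_COLUMNS + [c for c in self.table.columns if c not in PARTICLE_COLUMNS]
        self.table[cols].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ParticleSet":
        return cls(pd.read_csv(path))
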