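"""Bundled reference tables, trajectory IO, and synthetic experiment fixtures.

The package ships two small CSV tables: the physiological parameter ranges of
the model inputs/outputs, and the characteristic parameters (rho, alpha, b0,
Td, Tm) of 21 scratch-assay conditions across nine cell lines used for
calibration and validation.  Missing entries are preserved as missing, never
zero-filled; values flagged as derived from raw data in the original sources
carry a ``derived`` tag.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from importlib import resources
from importlib.metadata import version

import numpy as np
import pandas as pd

from .lattice import CAParams, Trajectory

__all__ = [
    "DataIntegrityError",
    "CellLineRecord",
    "load_cell_lines",
    "load_parameter_table",
    "make_synthetic_experiment",
    "write_trajectory",
    "read_trajectory",
    "read_experiment_csv",
]


class DataIntegrityError(RuntimeError):
    """A bundled data file does not match its recorded checksum."""


_CHECKSUMS = {
    "cell_lines.csv": "4e67eda4b7884269fe9a46caa997b1646de6a3814be4c9622f989ef48ea26147",
    "parameter_ranges.csv": "49f255c3121aa2dbd3cbb567f6cb79c54f27ccf41b22a00dc912b4373cb832bd",
}


@dataclass(frozen=True)
class CellLineRecord:
    """One experimental scratch-assay condition.

    ``rho`` (cells/µm²) and ``b0`` (µm) may be None when the source did not
    report them; ``derived`` lists fields that were derived from raw data
    rather than read off directly.
    """

    cell_line: str
    id: int
    rho: float | None
    alpha_exp: float  # 1/h
    b0: float | None  # µm
    td: float  # h
    tm: float  # h
    reference: str
    derived: tuple[str, ...] = ()

    @property
    def phi(self) -> float:
        return self.tm / self.td

    def simulation_params(self, delta: float = 20.0, **overrides) -> CAParams:
        """CAParams for this record (requires rho and b0; delta defaults to
        the 20 µm used when geometry is held fixed)."""
        if self.rho is None or self.b0 is None:
            raise ValueError(f"record Id {self.id} lacks rho or b0; cannot simulate")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # some records sit outside the soft ranges
            return CAParams(
                tm=self.tm, td=self.td, rho=self.rho, delta=delta, b0=self.b0,
                **overrides,
            )


def _read_bundled(name: str) -> pd.DataFrame:
    ref = resources.files("woundca.tables").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise DataIntegrityError(
            f"bundled table {name} checksum mismatch: {digest} != {_CHECKSUMS[name]}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_parameter_table() -> pd.DataFrame:
    """Physiological ranges of model inputs and outputs (verbatim values)."""
    return _read_bundled("parameter_ranges.csv")


def load_cell_lines() -> list[CellLineRecord]:
    """The 21 bundled cell-line conditions, missing values preserved."""
    df = _read_bundled("cell_lines.csv")
    records = []
    for row in df.itertuples(index=False):
        derived = tuple(str(row.derived).split(";")) if pd.notna(row.derived) else ()
        records.append(
            CellLineRecord(
                cell_line=str(row.cell_line),
                id=int(row.id),
                rho=None if pd.isna(row.rho) else float(row.rho),
                alpha_exp=float(row.alpha),
                b0=None if pd.isna(row.b0) else float(row.b0),
                td=float(row.td),
                tm=float(row.tm),
                reference="" if pd.isna(row.reference) else str(row.reference),
                derived=derived,
            )
        )
    return records


def make_synthetic_experiment(
    alpha: float,
    noise_sd: float = 0.02,
    t_end: float = 10.0,
    dt: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic A/A0 curve emulating a measured wound-closure time series.

    The noiseless curve is max(0, 1 - alpha*t); Gaussian noise of standard
    deviation ``noise_sd`` is added and the result clipped to [0, 1.05].
    Deterministic under ``seed``.  This is a test fixture standing in for
    real image-derived curves, which the package does not ship.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    times = np.arange(0.0, t_end + dt / 2, dt)
    values = np.maximum(0.0, 1.0 - alpha * times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=times.shape)
    return times, np.clip(values, 0.0, 1.05)


def write_trajectory(traj: Trajectory, csv_path, sidecar_path=None) -> None:
    """Write a trajectory as tidy CSV (time_h, area_um2, a_over_a0) plus a
    JSON sidecar of parameters, seed and package version."""
    df = pd.DataFrame(
        {"time_h": traj.times, "area_um2": traj.areas, "a_over_a0": traj.normalized}
    )
    df.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        payload = asdict(traj.params)
        payload["closed"] = traj.closed
        try:
            payload["woundca_version"] = version("woundca")
        except Exception:
            payload["woundca_version"] = "unknown"
        with open(sidecar_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_trajectory(csv_path, params: CAParams | None = None) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    df = pd.read_csv(csv_path)
    areas = df["area_um2"].to_numpy(float)
    return Trajectory(
        times=df["time_h"].to_numpy(float),
        areas=areas,
        normalized=df["a_over_a0"].to_numpy(float),
        closed=bool(areas[-1] == 0),
        params=params,
    )


def read_experiment_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an experimental curve as a 2-column CSV (time_h, a_over_a0)."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    return df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float)


def write_grid_snapshot(state, path) -> None:
    """Write the occupancy grid as a plain-text 0/1 matrix (one row per
    lattice row), suitable for diffing and quick visual inspection."""
    with open(path, "w") as fh:
        for row in state.grid:
            fh.write("".join("1" if v else "0" for v in row))
            fh.write("\n")
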