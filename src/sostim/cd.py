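"""Time-by-region current-density (CD) matrices.

The CD matrix is the common currency of the whole pipeline: a detected
slow oscillation (SO) is represented by the current density of ``n``
brain regions in ``m`` time bins of width Δt covering the second around
its trough (−500 ms to +500 ms), and a simulated stimulation paradigm is
represented the same way, which is what makes sleep events and
stimulation candidates directly comparable and classifiable.

Units are arbitrary but must be consistent across a dataset: the forward
model that would fix an absolute scale is external to this package, so
synthetic transfer operators are normalised to unit mean magnitude and
all downstream statistics are documented for their scale sensitivity.

Flattened feature vectors are **time-major**: bin 0's regions first, then
bin 1's, and so on. Every consumer of flattened features (classifier,
feature weights, optimisation objective) uses :func:`flatten_cd` /
:func:`feature_index` so the ordering cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .montage import Montage, Paradigm
from .regions import DEFAULT_REGIONS, RegionSet
from .waveforms import VALID_DT_MS, bin_waveform

#: analysis window around the SO trough, ms
WINDOW_MS = (-500, 500)


@dataclass(frozen=True)
class CDMatrix:
    """m × n current density: m = 1000/dt time bins, n regions."""

    values: np.ndarray
    dt: int
    regions: RegionSet = field(default_factory=lambda: DEFAULT_REGIONS)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if self.dt not in VALID_DT_MS:
            raise ValueError(f"dt must be one of {VALID_DT_MS}, got {self.dt}")
        m = 1000 // self.dt
        if values.shape != (m, len(self.regions)):
            raise ValueError(
                f"expected shape ({m}, {len(self.regions)}) for dt={self.dt} ms "
                f"and {len(self.regions)} regions, got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("CD values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_elements(self) -> int:
        return self.values.size

    def bin_times(self) -> np.ndarray:
        """Bin-centre times relative to the trough, ms."""
        edges = np.linspace(WINDOW_MS[0], WINDOW_MS[1], self.n_bins + 1)
        return (edges[:-1] + edges[1:]) / 2


def make_cd(values, dt: int, regions: RegionSet = DEFAULT_REGIONS) -> CDMatrix:
    """Validate and wrap raw values as a :class:`CDMatrix`."""
    return CDMatrix(values=np.asarray(values, dtype=float), dt=dt, regions=regions)


def feature_index(time_bin: int, region: int, n_regions: int) -> int:
    """Position of (time_bin, region) in the flattened feature vector."""
    return time_bin * n_regions + region


def flatten_cd(cd: CDMatrix) -> np.ndarray:
    """Time-major flattening: bin 0 regions 0..n−1, bin 1 regions 0..n−1, …"""
    return cd.values.reshape(-1)


def unflatten_cd(x: np.ndarray, dt: int,
                 regions: RegionSet = DEFAULT_REGIONS) -> CDMatrix:
    m = 1000 // dt
    return make_cd(np.asarray(x, dtype=float).reshape(m, len(regions)), dt, regions)


def average_cd(cds: list[CDMatrix]) -> CDMatrix:
    """Element-wise mean CD; inputs must share dt and region set."""
    if not cds:
        raise ValueError("cannot average an empty list of CD matrices")
    dt = cds[0].dt
    regions = cds[0].regions
    for cd in cds[1:]:
        if cd.dt != dt:
            raise ValueError(f"mixed dt values: {dt} ms vs {cd.dt} ms")
        if cd.regions.names != regions.names:
            raise ValueError("mixed region sets")
    mean = np.mean([cd.values for cd in cds], axis=0)
    return CDMatrix(values=mean, dt=dt, regions=regions)


class TransferModel:
    """Linear map: montage at unit waveform amplitude → per-region CD vector.

    Stands in for a finite-element forward solve. Linearity in the
    waveform amplitude is definitional here, so the CD a paradigm evokes
    in time bin b is simply ``vector(montage) * mean_amplitude(b)``.
    """

    provenance = "abstract"

    def __init__(self, regions: RegionSet = DEFAULT_REGIONS):
        self.regions = regions

    def vector(self, montage: Montage) -> np.ndarray:
        raise NotImplementedError


class ImportedTransferModel(TransferModel):
    """Transfer vectors imported from an external forward model, keyed by montage."""

    provenance = "imported"

    def __init__(self, table: dict[str, np.ndarray],
                 regions: RegionSet = DEFAULT_REGIONS):
        super().__init__(regions)
        self._table = {}
        for key, vec in table.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (len(regions),):
                raise ValueError(
                    f"transfer vector for {key!r} has shape {vec.shape}, "
                    f"expected ({len(regions)},)"
                )
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite transfer vector for {key!r}")
            self._table[key] = vec

    def vector(self, montage: Montage) -> np.ndarray:
        key = montage.key
        if key in self._table:
            return self._table[key]
        flipped = montage.flipped().key
        if flipped in self._table:
            return -self._table[flipped]
        raise KeyError(f"montage {key!r} not present in imported transfer model")


def estimate_paradigm_cd(p: Paradigm, tm: TransferModel) -> CDMatrix:
    """CD evoked by a paradigm under the linear forward model.

    The waveform is reduced to per-bin mean amplitudes and each bin's
    region row is the montage transfer vector scaled by that mean.
    """
    binned = bin_waveform(p.waveform, p.dt)
    vec = np.asarray(tm.vector(p.montage), dtype=float)
    if vec.shape != (len(tm.regions),):
        raise ValueError("transfer vector length does not match region set")
    values = np.outer(binned.means, vec)
    return CDMatrix(values=values, dt=p.dt, regions=tm.regions)


# ---------------------------------------------------------------------------
# persistence


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def write_cd_store(path, cds: list[CDMatrix], labels: list[str]) -> None:
    """Write labelled CD matrices to an HDF5 store.

    Layout: ``/cd`` (k × m × n float64), ``/labels`` (k, bytes), file
    attrs ``dt_ms`` and ``regions``.
    """
    if len(cds) != len(labels):
        raise ValueError("need one label per CD matrix")
    if not cds:
        raise ValueError("empty CD store")
    dt = cds[0].dt
    regions = cds[0].regions
    for cd in cds:
        if cd.dt != dt or cd.regions.names != regions.names:
            raise ValueError("all matrices in a store must share dt and regions")
    stack = np.stack([cd.values for cd in cds])
    with h5py.File(path, "w") as f:
        f.create_dataset("cd", data=stack)
        f.create_dataset(
            "labels", data=np.array([l.encode() for l in labels])
        )
        f.attrs["dt_ms"] = dt
        f.attrs["regions"] = [r.encode() for r in regions.names]


def read_cd_store(path) -> tuple[list[CDMatrix], list[str]]:
    """Read an HDF5 CD store written by :func:`write_cd_store`."""
    with h5py.File(path, "r") as f:
        if "cd" not in f or "labels" not in f:
            raise ValueError("CD store must contain /cd and /labels datasets")
        stack = np.asarray(f["cd"])
        labels = [_as_str(l) for l in f["labels"][()]]
        dt = int(f.attrs["dt_ms"])
        names = tuple(_as_str(r) for r in f.attrs["regions"])
    regions = RegionSet(names)
    if stack.ndim != 3:
        raise ValueError("/cd must be a k × m × n array")
    if stack.shape[0] != len(labels):
        raise ValueError(
            f"{stack.shape[0]} matrices but {len(labels)} labels in store"
        )
    m = 1000 // dt
    if stack.shape[1:] != (m, len(regions)):
        raise ValueError(
            f"store declares dt={dt} ms and {len(regions)} regions, expected "
            f"matrices of shape ({m}, {len(regions)}), got {stack.shape[1:]}"
        )
    cds = [CDMatrix(values=v, dt=dt, regions=regions) for v in stack]
    return cds, labels


def import_cd(path) -> list[tuple[CDMatrix, str]]:
    """Load labelled CD matrices from HDF5 (``.h5``) or flattened CSV.

    The CSV layout is one flattened time-major row per SO plus a
    ``label`` column; metadata columns ``dt_ms`` must be constant.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        cds, labels = read_cd_store(path)
        return list(zip(cds, labels))
    df = pd.read_csv(path)
    required = {"label", "dt_ms"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV CD store needs columns {sorted(required)}")
    dts = df["dt_ms"].unique()
    if len(dts) != 1:
        raise ValueError(f"mixed dt values in one file: {sorted(dts)}")
    dt = int(dts[0])
    feat_cols = [c for c in df.columns if c not in required]
    m = 1000 // dt
    n = len(feat_cols) // m
    if m * n != len(feat_cols) or n != len(DEFAULT_REGIONS):
        raise ValueError(
            f"expected {m} bins × {len(DEFAULT_REGIONS)} regions = "
            f"{m * len(DEFAULT_REGIONS)} feature columns, got {len(feat_cols)}"
        )
    out = []
    for _, row in df.iterrows():
        cd = unflatten_cd(row[feat_cols].to_numpy(dtype=float), dt)
        out.append((cd, str(row["label"])))
    return out
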